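"""Library-size normalization, log transformation, replicate means and PCA.

Sequencing depth differs between libraries, so raw counts are not comparable
across samples.  The pipeline uses median-of-ratios size factors: each
sample's factor is the median, over genes expressed in every sample, of that
sample's count divided by the gene's geometric mean across samples.  Counts
divided by their size factor are then placed on a variance-tamed log2 scale
via a pseudocount transform, log2(count/sf + pseudocount).  This plays the
role of a regularized log transform with a fully explicit formula (it is not
DESeq2's rlog shrinkage estimator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import CountMatrix, SampleDesign

__all__ = ["size_factors", "log_normalize", "normalized_counts", "replicate_means", "pca"]


def _counts_frame(counts) -> pd.DataFrame:
    return counts.df if isinstance(counts, CountMatrix) else pd.DataFrame(counts)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (one positive scale per sample).

    For gene g with geometric mean ``geomean_g`` across samples, sample j's
    factor is ``median_g counts[g, j] / geomean_g`` over the "usable" genes
    (geomean > 0, i.e. positive count in every sample).  Zero-geomean genes
    are excluded and cannot influence the factors.  The median uses the
    midpoint convention for even counts of usable genes.  Factors are not
    rescaled afterwards; any global rescaling cancels in ratios.
    """
    df = _counts_frame(counts)
    arr = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(arr)
    loggeo = logc.mean(axis=1)  # -inf whenever a gene has a zero count
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined -- filter the matrix or add samples"
        )
    logratios = logc[usable] - loggeo[usable, None]
    sf = np.exp(np.median(logratios, axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def normalized_counts(counts, sf: pd.Series) -> pd.DataFrame:
    """Counts divided column-wise by their size factors (linear scale)."""
    df = _counts_frame(counts)
    if not np.all(np.asarray(sf, dtype=float) > 0):
        raise ValueError("size factors must all be positive")
    return df / np.asarray(sf.reindex(df.columns), dtype=float)


def log_normalize(counts, sf: pd.Series, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), gene x sample.

    The pseudocount (default 1) keeps zeros finite and tames the variance of
    low counts; the transform is monotone in counts and invariant to scaling
    a count and its size factor together.
    """
    if not pseudocount > 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    return np.log2(normalized_counts(counts, sf) + pseudocount)


def replicate_means(expr: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Average biological replicates: one column per (species, group).

    Means are arithmetic on the (log) scale of ``expr``.  Columns are named
    by group when a single species is present, else ``species:group``; order
    follows first appearance in the design.
    """
    missing = [s for s in expr.columns if s not in set(design.sample_ids)]
    if missing:
        raise ValueError(
            f"samples present in expression but absent from design: "
            f"{', '.join(missing)}"
        )
    single_species = len(design.species) == 1
    cols, out = [], {}
    for _, row in design.df.drop_duplicates(["species", "group"]).iterrows():
        sp, grp = row["species"], row["group"]
        samples = [
            s for s in design.samples_in_group(grp, sp) if s in expr.columns
        ]
        if not samples:
            raise ValueError(
                f"group {grp!r} (species {sp!r}) has no samples in the "
                "expression matrix"
            )
        label = grp if single_species else f"{sp}:{grp}"
        out[label] = expr[samples].mean(axis=1)
        cols.append(label)
    return pd.DataFrame(out)[cols]


def pca(expr: pd.DataFrame, n_components: int = 2):
    """Principal component analysis with samples as observations.

    Genes are the (centered) features.  Returns ``(scores, loadings,
    variance_fractions)``: scores is samples x components, loadings is
    genes x components with orthonormal columns, and variance fractions are
    non-increasing and sum to at most 1.
    """
    n_genes, n_samples = expr.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n_genes, n_samples - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for a "
            f"{n_genes} x {n_samples} matrix, got {n_components}"
        )
    X = expr.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("expression matrix has no variance; PCA undefined")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(scores, index=expr.columns, columns=comp_names)
    loadings = pd.DataFrame(model.components_.T, index=expr.index, columns=comp_names)
    return scores, loadings, model.explained_variance_ratio_.copy()
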