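"""Negative-binomial Wald differential expression with BH correction.

Counts for gene g in sample j are modelled as NB with mean
``mu_gj = sf_j * q_g(group_j)`` and gene-wise dispersion ``alpha_g``
(variance mu + alpha * mu^2).  Group abundances ``q`` are maximized by
Newton iteration on the NB likelihood with the dispersion plugged in; the
effect size is ``log2fc = log2((q_A + c) / (q_B + c))`` with a small
stabilizer c (0.5 normalized counts) so that empty groups stay finite.  The
standard error comes from the Fisher information of q at the optimum via the
delta method, the Wald statistic is log2fc / se with a standard-normal
reference, and multiplicity is handled by Benjamini-Hochberg over all genes
with nonzero counts in the contrast.

Dispersions are method-of-moments per gene, shrunk toward a fitted
mean-dispersion trend ``alpha(mu) = a0 + a1/mu``.  This is a deliberately
minimal test: no outlier refitting, no independent filtering, no shrinkage
of the fold change itself -- selection uses the raw MLE log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from scipy import stats

from .io import CountMatrix, SampleDesign
from .normalize import normalized_counts, size_factors

__all__ = [
    "ALPHA_MIN",
    "DEGeneSet",
    "bh_adjust",
    "estimate_dispersions",
    "de_test",
    "filter_de",
]

ALPHA_MIN = 1e-8
ALPHA_MAX = 100.0
LFC_STABILIZER = 0.5  # normalized counts added to each group mean for log2fc
Q_FLOOR = 1e-12

RESULT_COLUMNS = ["base_mean", "log2fc", "se", "wald", "p", "q", "tested"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted vector, mapped back
    to the input order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1] and not be NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# dispersion estimation


def _contrast_frame(counts, design: SampleDesign, groups, species=None):
    df = counts.df if isinstance(counts, CountMatrix) else pd.DataFrame(counts)
    sample_lists = []
    for g in groups:
        samples = [
            s
            for s in design.samples_in_group(g, species)
            if s in df.columns
        ]
        if len(samples) == 0:
            raise ValueError(f"contrast group {g!r} absent from the count matrix")
        if len(samples) < 2:
            raise ValueError(
                f"group {g!r} has {len(samples)} replicate(s); need >= 2"
            )
        sample_lists.append(samples)
    return df, sample_lists


def estimate_dispersions(
    counts,
    design: SampleDesign,
    contrast_groups,
    sf: pd.Series | None = None,
    shrink_weight: float = 0.5,
    species: str | None = None,
) -> pd.DataFrame:
    """Per-gene NB dispersions for the samples of the given groups.

    Returns a frame with columns ``mu`` (mean normalized count over the
    contrast samples), ``alpha_mom`` (method-of-moments estimate
    ``max(0, (s2 - mu)/mu^2)`` with the variance pooled within groups),
    ``alpha_trend`` (fitted trend ``a0 + a1/mu``) and ``alpha`` (the final
    estimate, a weighted average ``(1-w)*mom + w*trend`` floored at 1e-8).
    The trend is fitted by non-negative least squares of the gene-wise
    moments estimates on ``[1, 1/mu]``.
    """
    if len(contrast_groups) < 2:
        raise ValueError("need at least two groups to pool dispersions")
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must lie in [0, 1]")
    df, sample_lists = _contrast_frame(counts, design, contrast_groups, species)
    all_samples = [s for group in sample_lists for s in group]
    if sf is None:
        sf = size_factors(df)
    norm = normalized_counts(df[all_samples], sf.reindex(all_samples))

    mu = norm.mean(axis=1).to_numpy()
    # within-group variances pooled by degrees of freedom
    ss = np.zeros(len(df))
    dof = 0
    for samples in sample_lists:
        sub = norm[samples].to_numpy()
        ss += sub.var(axis=1, ddof=1) * (len(samples) - 1)
        dof += len(samples) - 1
    s2 = ss / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (s2 - mu) / mu**2
    mom = np.where(mu > 0, mom, 0.0)
    mom = np.clip(mom, 0.0, ALPHA_MAX)

    expressed = mu > 0
    if expressed.sum() >= 2:
        X = np.column_stack([np.ones(expressed.sum()), 1.0 / mu[expressed]])
        coef, _ = scipy.optimize.nnls(X, mom[expressed])
        a0, a1 = coef
    else:
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, Q_FLOOR), 0.0)
    trend = np.clip(trend, 0.0, ALPHA_MAX)

    alpha = (1.0 - shrink_weight) * mom + shrink_weight * trend
    out = pd.DataFrame(
        {
            "mu": mu,
            "alpha_mom": np.maximum(mom, ALPHA_MIN),
            "alpha_trend": trend,
            "alpha": np.maximum(alpha, ALPHA_MIN),
        },
        index=df.index,
    )
    out.attrs["trend_coef"] = (float(a0), float(a1))
    return out


# ---------------------------------------------------------------------------
# group-mean MLE


def _nb_group_mle(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 60):
    """Vectorized Newton solve of the NB score equation for group abundance q.

    y: genes x samples counts of one group; sf: per-sample size factors;
    alpha: per-gene dispersion.  Solves sum_j [y_j/q - (y_j + r) sf_j /
    (r + sf_j q)] = 0 with r = 1/alpha, iterating in log q for positivity.
    Genes with all-zero counts get q = 0.  Returns (q_hat, fisher_info).
    """
    y = np.asarray(y, dtype=float)
    sf = np.asarray(sf, dtype=float)
    r = 1.0 / np.maximum(alpha, ALPHA_MIN)
    q = np.maximum(y.sum(axis=1) / sf.sum(), Q_FLOOR)
    zero = y.sum(axis=1) == 0
    ysum = y.sum(axis=1)
    logq = np.log(q)
    for _ in range(n_iter):
        q = np.exp(logq)
        denom = r[:, None] + sf[None, :] * q[:, None]
        score = ysum / q - ((y + r[:, None]) * sf[None, :] / denom).sum(axis=1)
        # derivative of the score wrt q
        dscore = -ysum / q**2 + (
            (y + r[:, None]) * sf[None, :] ** 2 / denom**2
        ).sum(axis=1)
        # Newton in log-space: d/dlogq = q * score
        g = q * score
        h = q * score + q**2 * dscore
        # Newton where the curvature is usable, small uphill move otherwise
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = g / h
        step = np.where(h < 0, newton, -0.1 * np.sign(g))
        step = np.clip(step, -2.0, 2.0)
        logq = logq - np.where(zero, 0.0, step)
        if np.max(np.abs(step[~zero]), initial=0.0) < 1e-12:
            break
    q = np.where(zero, 0.0, np.exp(logq))
    qsafe = np.maximum(q, Q_FLOOR)
    # observed information (negative second derivative of the log-likelihood
    # at the optimum); falls back to the expected information
    # sum_j sf_j / (q (1 + alpha sf_j q)) where the curvature degenerates
    denom = r[:, None] + sf[None, :] * qsafe[:, None]
    observed = ysum / qsafe**2 - (
        (y + r[:, None]) * sf[None, :] ** 2 / denom**2
    ).sum(axis=1)
    expected = (
        sf[None, :]
        / (qsafe[:, None] * (1.0 + alpha[:, None] * sf[None, :] * qsafe[:, None]))
    ).sum(axis=1)
    info = np.where(observed > 0, observed, expected)
    return q, info


@dataclass
class DEGeneSet:
    """Genes passing the selection filters for one contrast."""

    contrast: str
    genes: list[str]
    direction: dict[str, int] = field(default_factory=dict)  # +1 up in A, -1 up in B
    fdr_max: float = 0.05
    min_fold: float = 2.0

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.direction


def de_test(
    counts,
    design: SampleDesign,
    contrast: tuple[str, str],
    sf: pd.Series | None = None,
    dispersions: pd.DataFrame | None = None,
    shrink_weight: float = 0.5,
    species: str | None = None,
) -> pd.DataFrame:
    """Wald test of group A versus group B under the NB model.

    Returns a frame over the full input gene universe with columns
    ``base_mean, log2fc, se, wald, p, q, tested``.  Genes with all-zero
    counts in both groups are not tested (``tested`` False, statistics NaN)
    and are excluded from the BH family.  ``log2fc`` is oriented numerator
    (A) over denominator (B): positive means higher in A.
    """
    group_a, group_b = contrast
    df, (samples_a, samples_b) = _contrast_frame(
        counts, design, (group_a, group_b), species
    )
    if sf is None:
        sf = size_factors(df)
    if dispersions is None:
        dispersions = estimate_dispersions(
            df, design, (group_a, group_b), sf=sf,
            shrink_weight=shrink_weight, species=species,
        )
    alpha = dispersions["alpha"].reindex(df.index).to_numpy()

    ya = df[samples_a].to_numpy(dtype=float)
    yb = df[samples_b].to_numpy(dtype=float)
    sfa = sf.reindex(samples_a).to_numpy(dtype=float)
    sfb = sf.reindex(samples_b).to_numpy(dtype=float)

    tested = (ya.sum(axis=1) + yb.sum(axis=1)) > 0

    qa, info_a = _nb_group_mle(ya, sfa, alpha)
    qb, info_b = _nb_group_mle(yb, sfb, alpha)

    c = LFC_STABILIZER
    log2fc = np.log2((qa + c) / (qb + c))
    ln2sq = np.log(2.0) ** 2
    var = 1.0 / (info_a * (qa + c) ** 2 * ln2sq) + 1.0 / (info_b * (qb + c) ** 2 * ln2sq)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))

    base_mean = np.concatenate([ya / sfa, yb / sfb], axis=1).mean(axis=1)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "q": np.nan,
            "tested": tested,
        },
        index=df.index,
    )
    out.loc[~tested, ["log2fc", "se", "wald", "p"]] = np.nan
    out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out.attrs["contrast"] = f"{group_a}:{group_b}"
    out.attrs["n_excluded_all_zero"] = int((~tested).sum())
    return out


def filter_de(
    results: pd.DataFrame,
    fdr_max: float = 0.05,
    min_fold: float = 2.0,
    contrast: str | None = None,
) -> DEGeneSet:
    """Select genes with ``q <= fdr_max`` and ``|log2fc| >= log2(min_fold)``.

    The fold-change filter is on the absolute log2 fold change, i.e. a
    min_fold of 2 keeps genes at least two-fold up or down.  Direction is
    kept per gene (+1 higher in the contrast numerator).
    """
    if min_fold < 1:
        raise ValueError(f"min_fold must be >= 1, got {min_fold}")
    if not 0 <= fdr_max <= 1:
        raise ValueError(f"fdr_max must lie in [0, 1], got {fdr_max}")
    min_lfc = np.log2(min_fold)
    mask = (
        results["tested"].astype(bool)
        & (results["q"] <= fdr_max)
        & (results["log2fc"].abs() >= min_lfc)
    )
    genes = list(results.index[mask])
    direction = {
        g: (1 if results.at[g, "log2fc"] > 0 else -1) for g in genes
    }
    label = contrast or results.attrs.get("contrast", "contrast")
    return DEGeneSet(
        contrast=label,
        genes=genes,
        direction=direction,
        fdr_max=fdr_max,
        min_fold=min_fold,
    )
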