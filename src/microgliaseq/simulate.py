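"""Synthetic RNA-seq experiments with planted truth.

The generator emulates the structure of the real experiments the pipeline
targets: gene x sample matrices of negative-binomial counts for a handful
of biological conditions (three larval timepoints plus a brain-cell
reference, three replicates each), uneven library depths, a mean-dependent
dispersion trend, and -- for cross-species runs -- a second species with
its own microglia/brain contrast, an ortholog map mixing 1:1, 1:many and
unmapped genes, and a planted "microglia signature" gene set that is
conserved in a configurable fraction of genes.

Counts for gene g in sample j are drawn NB with
``mean = baseline_g * 2^(lfc of j's group) * libsize_j`` and dispersion
``alpha = a0 + a1 / mean`` (gamma-Poisson mixture).  Baselines are
log-normal, library-size factors log-uniform in [0.5, 2].  Every run is
driven by one seeded generator, so the same configuration and seed
reproduce bit-identical output, and each run emits a truth table
sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, OrthologMap, SampleDesign, write_table

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_temporal_patterns",
    "simulate_dual_species",
    "TEMPORAL_PATTERNS",
]

# canonical per-group log2 offsets (timepoint order 3, 5, 7 dpf) realizing
# each of the six temporal sign patterns, scaled by the effect size
TEMPORAL_PATTERNS = {
    "G1": (1.0, 0.0, 0.0),
    "G2": (1.0, 1.0, 0.0),
    "G3": (0.0, 1.0, 0.0),
    "G4": (0.0, 1.0, 1.0),
    "G5": (0.0, 0.0, 1.0),
    "G6": (1.0, 0.0, 1.0),
}


def _default_groups() -> dict[str, int]:
    return {"3dpf": 3, "5dpf": 3, "7dpf": 3, "brain": 3}


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    ``groups`` maps condition label to replicate count (default: the three
    larval timepoints plus a brain-cell reference, three replicates each).
    Baseline means are log-normal (natural-log mean 4, sd 2: median ~55
    counts, range spanning single digits to tens of thousands).  The
    dispersion trend ``a0 + a1/mean`` defaults to a0 = 0.05, a1 = 1 --
    moderate biological overdispersion with the usual excess at low means.
    DE genes receive a signed log2 fold change of magnitude drawn uniform
    in [lfc_low, lfc_high] (or exactly ``lfc_value`` when set), at least
    one two-fold change by default.
    """

    n_genes: int = 2000
    groups: dict[str, int] = field(default_factory=_default_groups)
    species: str = "zebrafish"
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 2.0
    dispersion_a0: float = 0.05
    dispersion_a1: float = 1.0
    de_fraction: float = 0.1
    de_n: int | None = None  # exact number of DE genes; overrides de_fraction
    lfc_low: float = 1.0
    lfc_high: float = 3.0
    lfc_value: float | None = None  # fixed |log2FC| for every DE gene
    min_de_mean: float | None = None  # floor on the baseline of planted genes
    libsize_low: float = 0.5
    libsize_high: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.groups or any(r < 2 for r in self.groups.values()):
            raise ValueError("every group needs >= 2 replicates")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.baseline_log_sd < 0 or self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("distribution parameters must be non-negative")
        if not 0 < self.libsize_low <= self.libsize_high:
            raise ValueError("library-size bounds must satisfy 0 < low <= high")
        if self.lfc_value is None and not 0 < self.lfc_low <= self.lfc_high:
            raise ValueError("log2FC bounds must satisfy 0 < low <= high")


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic dataset.

    ``genes`` holds one row per gene: baseline mean, DE indicator, the
    per-group log2 offsets (columns ``lfc_<group>``) and, where relevant,
    the planted temporal group and signature membership.  ``lib_sizes`` are
    the true per-sample depth factors.
    """

    config: SimConfig
    seed: int
    genes: pd.DataFrame
    lib_sizes: pd.Series

    def contrast_lfc(self, group_a: str, group_b: str) -> pd.Series:
        """True log2 fold change of group_a over group_b per gene."""
        return self.genes[f"lfc_{group_a}"] - self.genes[f"lfc_{group_b}"]

    def de_genes(self, group_a: str, group_b: str) -> list[str]:
        lfc = self.contrast_lfc(group_a, group_b)
        return list(lfc.index[lfc != 0])

    def write(self, genes_path, libs_path=None) -> None:
        write_table(self.genes, genes_path)
        if libs_path is not None:
            write_table(self.lib_sizes.rename("lib_size").to_frame(), libs_path)


def _draw_counts(
    rng: np.random.Generator,
    baseline: np.ndarray,
    lfc_by_group: pd.DataFrame,
    config: SimConfig,
    gene_ids: list[str],
) -> tuple[CountMatrix, SampleDesign, pd.Series]:
    groups = list(config.groups)
    sample_ids, sample_group = [], []
    for g in groups:
        for rep in range(1, config.groups[g] + 1):
            sample_ids.append(f"{g}_r{rep}")
            sample_group.append(g)
    n_samples = len(sample_ids)
    libs = np.exp(
        rng.uniform(np.log(config.libsize_low), np.log(config.libsize_high), n_samples)
    )
    group_idx = np.array([groups.index(g) for g in sample_group])
    lfc_mat = lfc_by_group[groups].to_numpy()  # genes x groups
    mean = baseline[:, None] * 2.0 ** lfc_mat[:, group_idx] * libs[None, :]
    alpha = config.dispersion_a0 + np.divide(
        config.dispersion_a1, mean, out=np.zeros_like(mean), where=mean > 0
    )
    lam = np.where(
        alpha > 1e-12,
        rng.gamma(shape=1.0 / np.maximum(alpha, 1e-12), scale=mean * np.maximum(alpha, 1e-12)),
        mean,
    )
    counts = rng.poisson(lam)
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": sample_group,
                "replicate": [int(s.rsplit("_r", 1)[1]) for s in sample_ids],
                "species": config.species,
            }
        )
    )
    libs = pd.Series(libs, index=sample_ids, name="lib_size")
    return cm, design, libs


def _baseline(rng, config: SimConfig) -> np.ndarray:
    return rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)


def _n_de(rng, config: SimConfig) -> int:
    if config.de_n is not None:
        if not 0 <= config.de_n <= config.n_genes:
            raise ValueError("de_n must lie in [0, n_genes]")
        return config.de_n
    return int(round(config.de_fraction * config.n_genes))


def _lfc_magnitudes(rng, config: SimConfig, n: int) -> np.ndarray:
    if config.lfc_value is not None:
        return np.full(n, float(config.lfc_value))
    return rng.uniform(config.lfc_low, config.lfc_high, n)


def simulate_experiment(config: SimConfig):
    """One-species experiment: DE genes perturb a single non-reference group.

    The first group in ``config.groups`` is the reference; each planted DE
    gene gets a signed log2 offset in one randomly chosen other group.
    Returns ``(CountMatrix, SampleDesign, SyntheticTruth)``.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline = _baseline(rng, config)
    groups = list(config.groups)
    lfc = pd.DataFrame(
        0.0, index=gene_ids, columns=[f"lfc_{g}" for g in groups]
    )
    n_de = _n_de(rng, config)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    if config.min_de_mean is not None:
        baseline[de_idx] = np.maximum(baseline[de_idx], config.min_de_mean)
    if n_de and len(groups) > 1:
        target = rng.integers(1, len(groups), size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        mag = _lfc_magnitudes(rng, config, n_de)
        for i, gi in enumerate(de_idx):
            lfc.iloc[gi, target[i]] = sign[i] * mag[i]
    lfc.columns = [f"lfc_{g}" for g in groups]
    counts, design, libs = _draw_counts(rng, baseline, lfc.set_axis(groups, axis=1), config, gene_ids)
    truth_genes = pd.DataFrame({"baseline": baseline}, index=gene_ids)
    truth_genes["is_de"] = False
    truth_genes.iloc[de_idx, truth_genes.columns.get_loc("is_de")] = True
    truth_genes = pd.concat([truth_genes, lfc], axis=1)
    truth_genes.index.name = "gene_id"
    truth = SyntheticTruth(config=config, seed=config.seed, genes=truth_genes, lib_sizes=libs)
    return counts, design, truth


def simulate_temporal_patterns(
    config: SimConfig,
    genes_per_group: int,
    effect_size: float = 2.0,
    min_mean: float | None = None,
):
    """Plant pure exemplars of the six temporal expression patterns.

    The first three groups of the configuration are taken as the 3/5/7 dpf
    timepoints; ``genes_per_group`` genes per pattern receive the pattern's
    canonical per-group log2 offsets scaled by ``effect_size``, with their
    baselines floored at ``min_mean`` when given.  Remaining genes are flat.
    Returns ``(CountMatrix, SampleDesign, SyntheticTruth)`` with a
    ``temporal_group`` column in the truth table.
    """
    if genes_per_group < 1:
        raise ValueError("genes_per_group must be >= 1")
    groups = list(config.groups)
    if len(groups) < 3:
        raise ValueError("temporal simulation needs >= 3 groups (timepoints)")
    n_planted = 6 * genes_per_group
    if n_planted > config.n_genes:
        raise ValueError(
            f"6 x {genes_per_group} planted genes exceed n_genes={config.n_genes}"
        )
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline = _baseline(rng, config)
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    if min_mean is not None:
        baseline[planted_idx] = np.maximum(baseline[planted_idx], min_mean)

    lfc = pd.DataFrame(0.0, index=gene_ids, columns=groups)
    temporal = pd.Series("none", index=gene_ids, name="temporal_group")
    timepoints = groups[:3]
    for p, pattern in enumerate(TEMPORAL_PATTERNS):
        idx = planted_idx[p * genes_per_group:(p + 1) * genes_per_group]
        offsets = np.array(TEMPORAL_PATTERNS[pattern]) * effect_size
        for tp, off in zip(timepoints, offsets):
            lfc.iloc[idx, lfc.columns.get_loc(tp)] = off
        temporal.iloc[idx] = pattern

    counts, design, libs = _draw_counts(rng, baseline, lfc, config, gene_ids)
    truth_genes = pd.DataFrame({"baseline": baseline}, index=gene_ids)
    truth_genes["is_de"] = temporal.to_numpy() != "none"
    truth_genes["temporal_group"] = temporal.to_numpy()
    for g in groups:
        truth_genes[f"lfc_{g}"] = lfc[g].to_numpy()
    truth_genes.index.name = "gene_id"
    truth = SyntheticTruth(config=config, seed=config.seed, genes=truth_genes, lib_sizes=libs)
    return counts, design, truth


def simulate_dual_species(
    config: SimConfig,
    conservation_fraction: float,
    signature_size: int,
    effect_size: float = 3.0,
    brain_group: str = "brain",
    one_to_one_fraction: float = 0.8,
    one_to_many_fraction: float = 0.1,
    ortholog_baseline_sd: float = 1.0,
    species_b: str = "speciesB",
):
    """Two-species experiment with a planted microglia signature.

    Species A follows ``config`` (its non-brain groups are microglia at the
    larval timepoints, plus a brain-cell reference); species B has one
    microglia and one brain group with the same replicate count and gene
    count.  An ortholog map links the species: ``one_to_one_fraction`` of
    A's genes map 1:1, ``one_to_many_fraction`` map to two B genes each,
    and the rest are unmapped.  Orthologous genes share their baseline up
    to log-normal noise of scale ``ortholog_baseline_sd`` (natural-log
    units), so mean expression is correlated across species as it is
    between real orthologs; unmapped B genes draw independent baselines.
    ``signature_size`` genes among A's mapped
    genes are elevated by ``effect_size`` log2 units in every A microglia
    group; a ``conservation_fraction`` of their orthologs is elevated in B
    microglia too, and B's signature is completed to the same size with
    independently chosen B genes, so the two species' true signatures
    overlap by exactly the conserved genes.

    Returns ``(counts_a, design_a, counts_b, design_b, OrthologMap,
    truth_a, truth_b)``.
    """
    if not 0.0 <= conservation_fraction <= 1.0:
        raise ValueError("conservation_fraction must lie in [0, 1]")
    if brain_group not in config.groups:
        raise ValueError(f"config must contain the brain group {brain_group!r}")
    if one_to_one_fraction + one_to_many_fraction > 1.0:
        raise ValueError("ortholog fractions exceed 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes_a = [f"ga{i:05d}" for i in range(n)]

    # ortholog map: shuffle A genes, then slice into 1:1, 1:2 and unmapped
    n11 = int(round(one_to_one_fraction * n))
    n12 = int(round(one_to_many_fraction * n))
    perm = rng.permutation(n)
    a_one = [genes_a[i] for i in perm[:n11]]
    a_two = [genes_a[i] for i in perm[n11:n11 + n12]]
    pairs = []
    b_counter = 0

    def next_b():
        nonlocal b_counter
        gid = f"gb{b_counter:05d}"
        b_counter += 1
        return gid

    ortholog_of: dict[str, list[str]] = {}
    for ga in a_one:
        gb = next_b()
        pairs.append((ga, gb))
        ortholog_of[ga] = [gb]
    for ga in a_two:
        gbs = [next_b(), next_b()]
        for gb in gbs:
            pairs.append((ga, gb))
        ortholog_of[ga] = gbs
    n_b_extra = n - b_counter if n > b_counter else int(round(0.1 * n))
    genes_b = [f"gb{i:05d}" for i in range(b_counter)] + [
        f"gb{b_counter + i:05d}" for i in range(n_b_extra)
    ]
    orthologs = OrthologMap(pd.DataFrame(pairs, columns=["gene_a", "gene_b"]))

    mapped_a = a_one + a_two
    if signature_size > len(mapped_a):
        raise ValueError(
            f"signature_size={signature_size} exceeds {len(mapped_a)} mapped genes"
        )

    # species A: signature elevated in every microglia (non-brain) group
    sig_a = sorted(rng.choice(mapped_a, size=signature_size, replace=False))
    n_cons = int(round(conservation_fraction * signature_size))
    conserved = set(sig_a[:n_cons]) if n_cons else set()
    # (sig_a was drawn randomly; slice order is as sorted, itself random wrt truth)
    groups_a = list(config.groups)
    mg_groups = [g for g in groups_a if g != brain_group]
    baseline_a = _baseline(rng, config)
    if config.min_de_mean is not None:
        sig_pos = [genes_a.index(g) for g in sig_a]
        baseline_a[sig_pos] = np.maximum(baseline_a[sig_pos], config.min_de_mean)
    lfc_a = pd.DataFrame(0.0, index=genes_a, columns=groups_a)
    lfc_a.loc[sig_a, mg_groups] = effect_size
    counts_a, design_a, libs_a = _draw_counts(rng, baseline_a, lfc_a, config, genes_a)

    # species B: conserved orthologs + independent filler genes elevated in microglia
    sig_b = sorted({ortholog_of[ga][0] for ga in sig_a if ga in conserved})
    mapped_b = [gb for ga in mapped_a for gb in ortholog_of[ga]]
    non_conserved_b = [gb for gb in mapped_b if gb not in set(sig_b)]
    n_fill = signature_size - len(sig_b)
    fill = sorted(rng.choice(non_conserved_b, size=n_fill, replace=False)) if n_fill else []
    sig_b = sorted(set(sig_b) | set(fill))

    config_b = replace(
        config,
        n_genes=len(genes_b),
        groups={"microglia": next(iter(config.groups.values())), brain_group: config.groups[brain_group]},
        species=species_b,
        seed=config.seed,  # same stream continues; rng is shared below
    )
    baseline_b = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(genes_b))
    # mapped orthologs inherit their partner's baseline up to log-normal noise
    if ortholog_baseline_sd >= 0:
        a_index = {g: i for i, g in enumerate(genes_a)}
        b_index = {g: i for i, g in enumerate(genes_b)}
        noise = rng.normal(0.0, ortholog_baseline_sd, len(genes_b))
        for ga in mapped_a:
            ba = baseline_a[a_index[ga]]
            for gb in ortholog_of[ga]:
                j = b_index[gb]
                baseline_b[j] = ba * np.exp(noise[j])
    if config.min_de_mean is not None:
        sig_pos_b = [genes_b.index(g) for g in sig_b]
        baseline_b[sig_pos_b] = np.maximum(baseline_b[sig_pos_b], config.min_de_mean)
    lfc_b = pd.DataFrame(0.0, index=genes_b, columns=list(config_b.groups))
    lfc_b.loc[sig_b, "microglia"] = effect_size
    counts_b, design_b, libs_b = _draw_counts(rng, baseline_b, lfc_b, config_b, genes_b)

    truth_a_genes = pd.DataFrame({"baseline": baseline_a}, index=genes_a)
    truth_a_genes["signature"] = truth_a_genes.index.isin(sig_a)
    truth_a_genes["conserved"] = truth_a_genes.index.isin(conserved)
    for g in groups_a:
        truth_a_genes[f"lfc_{g}"] = lfc_a[g].to_numpy()
    truth_a_genes.index.name = "gene_id"
    truth_b_genes = pd.DataFrame({"baseline": baseline_b}, index=genes_b)
    truth_b_genes["signature"] = truth_b_genes.index.isin(sig_b)
    for g in config_b.groups:
        truth_b_genes[f"lfc_{g}"] = lfc_b[g].to_numpy()
    truth_b_genes.index.name = "gene_id"

    truth_a = SyntheticTruth(config=config, seed=config.seed, genes=truth_a_genes, lib_sizes=libs_a)
    truth_b = SyntheticTruth(config=config_b, seed=config.seed, genes=truth_b_genes, lib_sizes=libs_b)
    return counts_a, design_a, counts_b, design_b, orthologs, truth_a, truth_b
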