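"""End-to-end orchestration of the comparative analysis.

One configuration file drives the full chain: size factors and log
expression for the primary (query) dataset, PCA, the three timepoint
contrasts and their temporal grouping, microglia-versus-brain contrasts per
timepoint, and -- when a second dataset and ortholog map are given -- joint
renormalization, per-group correlations with the Hotelling-Williams
comparison, overlap enrichment of the two species' microglia gene lists and
optional category enrichment against a gene-set collection.  Every stage
writes its table before the next starts, and a manifest records the
parameters, seed, package version and input checksums, so a run is an
auditable pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .diffexpr import de_test, estimate_dispersions, filter_de
from .enrichment import category_enrichment, overlap_enrichment
from .io import (
    CountMatrix,
    get_logger,
    load_config,
    read_count_matrix,
    read_design,
    read_gene_sets,
    read_ortholog_map,
    write_table,
)
from .normalize import log_normalize, pca, replicate_means, size_factors
from .temporal import assign_groups, sign_calls
from .xspecies import compare_species, joint_renormalize, map_orthologs

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = get_logger("pipeline")

DEFAULT_PARAMS = {
    "fdr_max": 0.05,
    "min_fold": 2.0,
    "pseudocount": 1.0,
    "ortholog_policy": "max_mean",
    "min_category_size": 10,
    "pca_components": 2,
    "strict_temporal": False,
    "dispersion_shrink_weight": 0.5,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, completed outputs remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfig:
    """Validated pipeline configuration.

    Required keys: ``counts_a``, ``design_a``, ``outdir``; the timepoint
    groups of the query dataset (``timepoint_groups``, default
    3dpf/5dpf/7dpf) and its brain reference group (``brain_group``,
    default "brain").  Optional: ``counts_b``/``design_b`` plus
    ``orthologs`` for the cross-species half (the reference dataset's
    microglia and brain groups via ``ref_microglia_group`` /
    ``ref_brain_group``), ``gene_sets`` (GMT) for category enrichment,
    ``seed`` and a ``params`` block overriding the stage defaults.
    """

    def __init__(self, raw: dict, base_dir: Path | None = None):
        base = Path(base_dir) if base_dir else Path.cwd()
        self.raw = raw

        def resolve(key, required=False):
            val = raw.get(key)
            if val is None:
                if required:
                    raise ValueError(f"configuration key {key!r} is required")
                return None
            p = Path(val)
            p = p if p.is_absolute() else base / p
            if not p.exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
            return p

        self.counts_a = resolve("counts_a", required=True)
        self.design_a = resolve("design_a", required=True)
        self.counts_b = resolve("counts_b")
        self.design_b = resolve("design_b")
        self.orthologs = resolve("orthologs")
        self.gene_sets = resolve("gene_sets")
        if (self.counts_b is None) != (self.design_b is None):
            raise ValueError("counts_b and design_b must be given together")
        if self.counts_b is not None and self.orthologs is None:
            raise ValueError("cross-species run needs an ortholog map")
        out = raw.get("outdir")
        if not out:
            raise ValueError("configuration key 'outdir' is required")
        self.outdir = Path(out) if Path(out).is_absolute() else base / out
        self.timepoint_groups = list(raw.get("timepoint_groups", ["3dpf", "5dpf", "7dpf"]))
        if len(self.timepoint_groups) != 3:
            raise ValueError("timepoint_groups must list exactly three groups")
        self.brain_group = raw.get("brain_group", "brain")
        self.ref_microglia_group = raw.get("ref_microglia_group", "microglia")
        self.ref_brain_group = raw.get("ref_brain_group", "brain")
        self.seed = int(raw.get("seed", 0))
        self.params = dict(DEFAULT_PARAMS)
        extra = raw.get("params") or {}
        unknown = set(extra) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
        self.params.update(extra)
        if not 0 <= self.params["fdr_max"] <= 1:
            raise ValueError("fdr_max must lie in [0, 1]")
        if self.params["min_fold"] < 1:
            raise ValueError("min_fold must be >= 1")
        if self.params["pseudocount"] <= 0:
            raise ValueError("pseudocount must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        return cls(load_config(path), base_dir=path.parent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage, writing each table into ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).  A stage
    failure raises :class:`PipelineError` naming the stage; tables written
    by earlier stages are left in place.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "package": "microgliaseq",
        "version": __version__,
        "seed": config.seed,
        "parameters": p,
        "inputs": {},
        "outputs": [],
        "stages": [],
    }
    for key in ("counts_a", "design_a", "counts_b", "design_b", "orthologs", "gene_sets"):
        path = getattr(config, key)
        if path is not None:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    def emit(name: str, df: pd.DataFrame, index=True):
        path = outdir / name
        write_table(df, path, index=index)
        manifest["outputs"].append(name)

    current = "load_inputs"
    try:
        counts_a = read_count_matrix(config.counts_a)
        design_a = read_design(config.design_a)
        design_a.check_against(counts_a)
        manifest["stages"].append(current)

        current = "normalize"
        sf_a = size_factors(counts_a)
        expr_a = log_normalize(counts_a, sf_a, pseudocount=p["pseudocount"])
        means_a = replicate_means(expr_a, design_a)
        emit("size_factors_a.tsv", sf_a.to_frame())
        emit("expression_a.tsv", expr_a)
        emit("replicate_means_a.tsv", means_a)
        manifest["stages"].append(current)

        current = "pca"
        scores, _, varfrac = pca(expr_a, n_components=p["pca_components"])
        emit("pca_scores_a.tsv", scores)
        emit(
            "pca_variance_a.tsv",
            pd.DataFrame(
                {"component": scores.columns, "variance_fraction": varfrac}
            ),
            index=False,
        )
        manifest["stages"].append(current)

        current = "de_timepoints"
        t3, t5, t7 = config.timepoint_groups
        de_tables = {}
        filtered = {}
        for a, b in ((t3, t5), (t3, t7), (t5, t7)):
            label = f"{a}v{b}"
            disp = estimate_dispersions(
                counts_a, design_a, (a, b), sf=sf_a,
                shrink_weight=p["dispersion_shrink_weight"],
            )
            res = de_test(counts_a, design_a, (a, b), sf=sf_a, dispersions=disp)
            de_tables[label] = res
            filtered[label] = filter_de(
                res, fdr_max=p["fdr_max"], min_fold=p["min_fold"], contrast=label
            )
            tbl = res.copy()
            tbl["passed"] = tbl.index.isin(filtered[label].genes)
            emit(f"de_{label}.tsv", tbl)
        manifest["stages"].append(current)

        current = "temporal_groups"
        keys = [f"{t3}v{t5}", f"{t3}v{t7}", f"{t5}v{t7}"]
        signs = sign_calls(
            (de_tables[keys[0]], filtered[keys[0]]),
            (de_tables[keys[1]], filtered[keys[1]]),
            (de_tables[keys[2]], filtered[keys[2]]),
        )
        groups_tbl = assign_groups(signs, strict=p["strict_temporal"])
        emit("temporal_groups.tsv", groups_tbl)
        manifest["stages"].append(current)

        mg_lists = {}
        if config.brain_group in design_a.groups:
            current = "de_vs_brain"
            for tp in config.timepoint_groups:
                label = f"{tp}_vs_{config.brain_group}"
                res = de_test(counts_a, design_a, (tp, config.brain_group), sf=sf_a,
                              shrink_weight=p["dispersion_shrink_weight"])
                sel = filter_de(res, fdr_max=p["fdr_max"], min_fold=p["min_fold"],
                                contrast=label)
                up = [g for g in sel.genes if sel.direction[g] > 0]
                mg_lists[tp] = up
                tbl = res.copy()
                tbl["passed"] = tbl.index.isin(sel.genes)
                emit(f"de_{label}.tsv", tbl)
                emit(
                    f"microglia_genes_{tp}.tsv",
                    pd.Series(up, name="gene_id").to_frame(),
                    index=False,
                )
            manifest["stages"].append(current)

        if config.counts_b is not None:
            current = "load_reference"
            counts_b = read_count_matrix(config.counts_b)
            design_b = read_design(config.design_b)
            design_b.check_against(counts_b)
            orthomap = read_ortholog_map(config.orthologs)
            manifest["stages"].append(current)

            current = "xspecies_correlation"
            paired_a, paired_b, pairs = map_orthologs(
                counts_a.df, counts_b.df, orthomap,
                policy=p["ortholog_policy"], input_scale="counts",
            )
            combined, sf_joint = joint_renormalize(
                paired_a, paired_b, pseudocount=p["pseudocount"],
                label_a="a", label_b="b",
            )
            emit("joint_size_factors.tsv", sf_joint.to_frame())
            expr_ja = combined[[c for c in combined.columns if c.startswith("a:")]]
            expr_jb = combined[[c for c in combined.columns if c.startswith("b:")]]
            expr_ja = expr_ja.rename(columns=lambda c: c[2:])
            expr_jb = expr_jb.rename(columns=lambda c: c[2:])
            means_ja = replicate_means(expr_ja, design_a)
            means_jb = replicate_means(expr_jb, design_b)
            query = means_ja[config.timepoint_groups]
            reference = means_jb[config.ref_microglia_group]
            corr_tbl, williams_tbl = compare_species(query, reference)
            corr_tbl = corr_tbl.assign(policy=p["ortholog_policy"])
            emit("xspecies_correlations.tsv", corr_tbl)
            emit("xspecies_williams.tsv", williams_tbl, index=False)
            manifest["stages"].append(current)

            current = "de_reference"
            res_b = de_test(
                counts_b, design_b,
                (config.ref_microglia_group, config.ref_brain_group),
                shrink_weight=p["dispersion_shrink_weight"],
            )
            sel_b = filter_de(res_b, fdr_max=p["fdr_max"], min_fold=p["min_fold"],
                              contrast="ref_microglia_vs_brain")
            ref_list = [g for g in sel_b.genes if sel_b.direction[g] > 0]
            tbl = res_b.copy()
            tbl["passed"] = tbl.index.isin(sel_b.genes)
            emit("de_reference_microglia.tsv", tbl)
            manifest["stages"].append(current)

            current = "overlap_enrichment"
            # universe: ortholog pairs detected (nonzero) in both datasets
            detected = (paired_a.sum(axis=1) > 0) & (paired_b.sum(axis=1) > 0)
            uni_pairs = pairs[detected.to_numpy()]
            a2pair = dict(zip(uni_pairs["gene_a"], uni_pairs.index))
            b2pair = dict(zip(uni_pairs["gene_b"], uni_pairs.index))
            universe = list(uni_pairs.index)
            ref_pairs = {b2pair[g] for g in ref_list if g in b2pair}
            rows = []
            for tp, genes in mg_lists.items():
                tp_pairs = {a2pair[g] for g in genes if g in a2pair}
                res = overlap_enrichment(tp_pairs, ref_pairs, universe)
                rows.append({"timepoint": tp, **res.as_dict()})
            if rows:
                emit("overlap_enrichment.tsv", pd.DataFrame(rows), index=False)
            manifest["stages"].append(current)

        if config.gene_sets is not None and mg_lists:
            current = "category_enrichment"
            annotation = read_gene_sets(config.gene_sets)
            universe_genes = list(counts_a.df.index[counts_a.df.sum(axis=1) > 0])
            for tp, genes in mg_lists.items():
                cats = category_enrichment(
                    genes, annotation, universe_genes,
                    min_size=p["min_category_size"],
                )
                emit(f"category_enrichment_{tp}.tsv", cats)
            manifest["stages"].append(current)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        log.error("stage %s failed: %s", current, exc)
        raise PipelineError(current, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), outdir)
    return manifest
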