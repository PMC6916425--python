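"""Cross-species comparison: ortholog mapping, joint renormalization,
correlation of mean expression, and the Hotelling-Williams test.

Two datasets are made comparable by restricting both to orthologous gene
pairs, concatenating the paired count matrices column-wise and recomputing
size factors on the combined matrix (normalization rescales samples
relative to one another, so each cross-dataset analysis gets its own
renormalization).  Similarity between a query expression profile and a
reference is a Pearson correlation of log-scale replicate means over the
ortholog pairs.  Whether two such correlations sharing the reference differ
is decided by the Hotelling-Williams t-test for dependent correlations:
with r12 and r13 the two correlations to the shared reference, r23 the
correlation between the two query profiles, n gene pairs,
|R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 and rbar = (r12 + r13)/2,

    t = (r12 - r13) * sqrt( (n-1)(1+r23) /
          ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r23)^3 ) ),   df = n - 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, OrthologMap, get_logger
from .normalize import log_normalize, size_factors

__all__ = [
    "CorrelationResult",
    "WilliamsResult",
    "map_orthologs",
    "joint_renormalize",
    "correlate",
    "williams_test",
    "compare_species",
]

POLICIES = ("one_to_one_only", "max_mean", "sum")

log = get_logger("xspecies")


@dataclass
class CorrelationResult:
    r: float
    n_pairs: int


@dataclass
class WilliamsResult:
    r12: float
    r13: float
    r23: float
    n: int
    t: float
    df: int
    p: float


def map_orthologs(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    orthologs: OrthologMap,
    policy: str = "max_mean",
    input_scale: str = "log",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pair the two matrices on orthologous genes under a multi-mapping policy.

    Policies: ``one_to_one_only`` drops every multi-mapped gene;
    ``max_mean`` resolves each multi-mapped gene to the partner with the
    highest mean expression (deterministic, ties broken by identifier);
    ``sum`` aggregates the counts of a gene's many partners and is only
    valid on count-scale input (``input_scale="counts"``).

    Returns ``(paired_a, paired_b, pairs)`` where the paired matrices share
    a row index of ``gene_a|gene_b`` pair identifiers and ``pairs`` lists
    gene_a, gene_b and the relation realized in the restricted map.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown ortholog policy {policy!r}; use one of {POLICIES}")
    if policy == "sum" and input_scale != "counts":
        raise ValueError("policy 'sum' is only valid on count-scale input")
    sub = orthologs.restrict(expr_a.index, expr_b.index).df

    if policy == "one_to_one_only":
        sub = sub[sub["relation"] == "one_to_one"].copy()
        if len(sub) == 0:
            raise ValueError("no one-to-one ortholog pair left after restriction")
    elif policy == "max_mean":
        mean_a = expr_a.mean(axis=1)
        mean_b = expr_b.mean(axis=1)
        sub = sub.assign(
            _ma=sub["gene_a"].map(mean_a), _mb=sub["gene_b"].map(mean_b)
        )
        # resolve gene_a multi-maps to the highest-mean b partner, then the
        # converse; sort by identifier first so ties break deterministically
        sub = sub.sort_values(["gene_a", "gene_b"], kind="stable")
        sub = sub.sort_values("_mb", kind="stable").drop_duplicates("gene_a", keep="last")
        sub = sub.sort_values(["gene_a", "gene_b"], kind="stable")
        sub = sub.sort_values("_ma", kind="stable").drop_duplicates("gene_b", keep="last")
        sub = sub.drop(columns=["_ma", "_mb"]).sort_values(
            ["gene_a", "gene_b"], kind="stable"
        )
    else:  # sum: aggregate counts within connected ortholog components
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a_gene, b_gene in zip(sub["gene_a"], sub["gene_b"]):
            ra, rb = find(f"a\t{a_gene}"), find(f"b\t{b_gene}")
            if ra != rb:
                parent[rb] = ra
        comps: dict[str, tuple[list[str], list[str]]] = {}
        seen_a, seen_b = set(), set()
        for a_gene, b_gene in zip(sub["gene_a"], sub["gene_b"]):
            root = find(f"a\t{a_gene}")
            members = comps.setdefault(root, ([], []))
            if a_gene not in seen_a:
                members[0].append(a_gene)
                seen_a.add(a_gene)
            if b_gene not in seen_b:
                members[1].append(b_gene)
                seen_b.add(b_gene)
        rows = []
        for a_genes, b_genes in comps.values():
            a_genes, b_genes = sorted(a_genes), sorted(b_genes)
            if len(a_genes) == 1 and len(b_genes) == 1:
                relation = "one_to_one"
            elif len(a_genes) > 1 and len(b_genes) > 1:
                relation = "many_to_many"
            else:
                relation = "one_to_many"
            rows.append(
                {
                    "pair_id": f"{a_genes[0]}|{b_genes[0]}",
                    "gene_a": a_genes[0],
                    "gene_b": b_genes[0],
                    "relation": relation,
                    "_a_genes": a_genes,
                    "_b_genes": b_genes,
                }
            )
        rows.sort(key=lambda r: r["pair_id"])
        paired_a = pd.DataFrame(
            [expr_a.loc[r["_a_genes"]].sum(axis=0) for r in rows],
            index=[r["pair_id"] for r in rows],
        )
        paired_b = pd.DataFrame(
            [expr_b.loc[r["_b_genes"]].sum(axis=0) for r in rows],
            index=[r["pair_id"] for r in rows],
        )
        pairs = pd.DataFrame(
            [{k: r[k] for k in ("gene_a", "gene_b", "relation")} for r in rows],
            index=[r["pair_id"] for r in rows],
        )
        return paired_a, paired_b, pairs

    pair_ids = [f"{a}|{b}" for a, b in zip(sub["gene_a"], sub["gene_b"])]
    paired_a = expr_a.loc[sub["gene_a"]].set_axis(pair_ids, axis=0)
    paired_b = expr_b.loc[sub["gene_b"]].set_axis(pair_ids, axis=0)
    pairs = sub.set_axis(pair_ids, axis=0)
    return paired_a, paired_b, pairs


def joint_renormalize(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 1.0,
    label_a: str = "a",
    label_b: str = "b",
) -> tuple[pd.DataFrame, pd.Series]:
    """Renormalize two paired count matrices as one combined dataset.

    The matrices must already be restricted to the shared ortholog row
    space (same row index).  Columns are concatenated (prefixed
    ``label:sample`` to stay unique), size factors recomputed on the
    combined matrix, and the pseudocount log2 transform applied.  Returns
    (combined log-expression, combined size factors).
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("paired matrices must share the same ortholog row index")
    a = counts_a.add_prefix(f"{label_a}:")
    b = counts_b.add_prefix(f"{label_b}:")
    combined = pd.concat([a, b], axis=1)
    sf = size_factors(combined)
    return log_normalize(combined, sf, pseudocount=pseudocount), sf


def correlate(mean_a, mean_b) -> CorrelationResult:
    """Pearson correlation between two mean-expression vectors."""
    x = np.asarray(mean_a, dtype=float)
    y = np.asarray(mean_b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError(f"need >= 3 gene pairs to correlate, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n_pairs=int(x.size))


def williams_test(
    r12: float, r13: float, r23: float, n: int, alternative: str = "two-sided"
) -> WilliamsResult:
    """Hotelling-Williams t-test for two dependent correlations.

    Tests whether the correlation of variable 1 with 2 differs from the
    correlation of variable 1 with 3, given that both share variable 1 and
    the 2-3 correlation is r23; n is the number of observations (here:
    ortholog gene pairs), df = n - 3.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError(
            f"degenerate correlation matrix (|R| = {detR:.3g} <= 0); "
            "the three correlations are mutually inconsistent"
        )
    rbar = 0.5 * (r12 + r13)
    df = n - 3
    denom = 2.0 * (n - 1) / df * detR + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WilliamsResult(
        r12=float(r12), r13=float(r13), r23=float(r23),
        n=int(n), t=float(t), df=int(df), p=float(min(p, 1.0)),
    )


def compare_species(
    query_means: pd.DataFrame,
    reference_mean: pd.Series,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate each query group with a reference profile and compare.

    ``query_means`` holds one column per query group (e.g. the 3/5/7 dpf
    replicate means) and ``reference_mean`` the single reference profile,
    both over the same ortholog pairs.  Returns a per-group correlation
    table and, for every pair of query groups, a Hotelling-Williams test of
    whether their correlations to the shared reference differ (r23 is the
    correlation between the two query groups themselves).
    """
    if query_means.shape[1] < 2:
        raise ValueError("need >= 2 query groups to compare")
    if not query_means.index.equals(reference_mean.index):
        raise ValueError("query and reference must share the same gene-pair index")
    groups = list(query_means.columns)
    corr_rows = []
    for g in groups:
        res = correlate(query_means[g], reference_mean)
        corr_rows.append({"group": g, "r": res.r, "n_pairs": res.n_pairs})
    corr_table = pd.DataFrame(corr_rows).set_index("group")

    n = int(len(reference_mean))
    will_rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            r12 = corr_table.at[g1, "r"]
            r13 = corr_table.at[g2, "r"]
            r23 = correlate(query_means[g1], query_means[g2]).r
            w = williams_test(r12, r13, r23, n, alternative=alternative)
            will_rows.append(
                {
                    "group_1": g1, "group_2": g2,
                    "r1_ref": w.r12, "r2_ref": w.r13, "r12": w.r23,
                    "n": w.n, "t": w.t, "df": w.df, "p": w.p,
                }
            )
    williams_table = pd.DataFrame(will_rows)
    return corr_table, williams_table
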