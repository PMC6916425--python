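"""Classification of genes into six developmental expression groups.

Three pairwise contrasts between larval timepoints (3 vs 5, 3 vs 7 and
5 vs 7 days post fertilization, each oriented earlier-over-later) yield a
sign triple per gene: +1 if the gene is significantly higher at the earlier
timepoint, -1 if higher at the later one, 0 if not selected in that
contrast.  A priority-ordered decision table maps triples to six groups:

  G1  higher at 3 dpf than 5 and/or 7 dpf
  G2  higher at 3 and 5 dpf than 7 dpf
  G3  higher at 5 dpf than 3 and/or 7 dpf
  G4  lower at 3 dpf than 5 and 7 dpf
  G5  higher at 7 dpf than 3 and/or 5 dpf
  G6  higher at 3 and 7 dpf than 5 dpf

Conjunctive groups (G2, G6, G4) are matched first so that, e.g., a gene
higher at both 3 and 5 dpf versus 7 dpf lands in G2 rather than G1; the
first match wins in the order G2, G6, G4, G1, G3, G5.  Genes selected in no
contrast are unassigned, so the labels partition the input by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import DEGeneSet
from .io import get_logger

__all__ = ["GROUPS", "UNASSIGNED", "sign_calls", "assign_groups", "classify_triple"]

GROUPS = ("G1", "G2", "G3", "G4", "G5", "G6")
UNASSIGNED = "unassigned"

log = get_logger("temporal")


def sign_calls(
    de_3v5: tuple[pd.DataFrame, DEGeneSet],
    de_3v7: tuple[pd.DataFrame, DEGeneSet],
    de_5v7: tuple[pd.DataFrame, DEGeneSet],
) -> pd.DataFrame:
    """Build the per-gene sign triple table from the three filtered contrasts.

    Each argument is a (DE result table, filtered gene set) pair; the three
    result tables must share one gene universe, and each contrast must be
    oriented earlier timepoint over later (positive log2fc = higher earlier).
    Returns a frame with columns ``s35, s37, s57`` over the union of genes
    selected in at least one contrast.
    """
    inputs = {"s35": de_3v5, "s37": de_3v7, "s57": de_5v7}
    universes = [frozenset(res.index) for res, _ in inputs.values()]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError(
            "the three contrasts were not computed on the same gene universe"
        )
    selected: set[str] = set()
    for _, geneset in inputs.values():
        selected |= set(geneset.genes)
    genes = sorted(selected)
    out = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                       columns=list(inputs), dtype=int)
    for col, (_, geneset) in inputs.items():
        for g in geneset.genes:
            out.at[g, col] = geneset.direction[g]
    return out


def classify_triple(s35: int, s37: int, s57: int) -> str:
    """Apply the decision table to one sign triple."""
    if s37 == 1 and s57 == 1:
        return "G2"
    if s35 == 1 and s57 == -1:
        return "G6"
    if s35 == -1 and s37 == -1:
        return "G4"
    if s35 == 1 or s37 == 1:
        return "G1"
    if s35 == -1 or s57 == 1:
        return "G3"
    if s37 == -1 or s57 == -1:
        return "G5"
    return UNASSIGNED


def _contradictory(s35, s37, s57) -> np.ndarray:
    """Triples violating order transitivity (3>5>7 yet 7>3, or the reverse)."""
    cyc_down = (s35 == 1) & (s57 == 1) & (s37 == -1)
    cyc_up = (s35 == -1) & (s57 == -1) & (s37 == 1)
    return cyc_down | cyc_up


def assign_groups(signs: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Assign each gene exactly one temporal group label.

    In the default mode, transitivity-violating triples (a cycle like
    3 > 5, 5 > 7 yet 7 > 3) fall through the decision table like any other
    triple.  With ``strict=True`` they are routed to ``unassigned`` with a
    logged warning instead.
    """
    for col in ("s35", "s37", "s57"):
        if col not in signs.columns:
            raise ValueError(f"sign table missing column {col!r}")
        bad = ~signs[col].isin((-1, 0, 1))
        if bad.any():
            raise ValueError(
                f"sign column {col!r} contains values outside {{-1, 0, +1}}"
            )
    labels = [
        classify_triple(row.s35, row.s37, row.s57)
        for row in signs.itertuples()
    ]
    out = signs.copy()
    out["group"] = labels
    if strict:
        contradictory = _contradictory(
            signs["s35"].to_numpy(), signs["s37"].to_numpy(), signs["s57"].to_numpy()
        )
        n_bad = int(contradictory.sum())
        if n_bad:
            log.warning(
                "%d gene(s) with transitivity-violating sign triples routed "
                "to unassigned (strict mode)",
                n_bad,
            )
            out.loc[contradictory, "group"] = UNASSIGNED
    return out


def group_sizes(assignment: pd.DataFrame) -> pd.Series:
    """Number of genes per group label, in G1..G6 + unassigned order."""
    counts = assignment["group"].value_counts()
    order = list(GROUPS) + [UNASSIGNED]
    return counts.reindex(order, fill_value=0).astype(int)
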