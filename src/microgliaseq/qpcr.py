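"""Comparative Ct (delta-delta-Ct) relative quantification for qPCR.

Each reaction yields a threshold cycle Ct; lower Ct means more template.
Expression of a target gene is first normalized to a reference gene
(e.g. beta-actin) within the same sample, dCt = Ct_target - Ct_reference,
then referred to a calibrator sample, ddCt = dCt_sample - dCt_calibrator.
Assuming perfect doubling per cycle, relative expression is 2^(-ddCt): one
cycle earlier than the calibrator is a two-fold increase.  Amplification
efficiency is fixed at 2; technical duplicates are averaged on the Ct scale
before any delta is taken.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "ddct_table"]

REQUIRED_COLUMNS = ("gene", "group", "replicate", "ct_target", "ct_reference")


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression 2^(-ddCt) of a sample against a calibrator."""
    for name, v in (
        ("ct_target_sample", ct_target_sample),
        ("ct_ref_sample", ct_ref_sample),
        ("ct_target_calibrator", ct_target_calibrator),
        ("ct_ref_calibrator", ct_ref_calibrator),
    ):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    dct_sample = ct_target_sample - ct_ref_sample
    dct_cal = ct_target_calibrator - ct_ref_calibrator
    return float(2.0 ** (-(dct_sample - dct_cal)))


def ddct_table(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-gene, per-group fold changes with mean +/- SD over replicates.

    ``records`` needs columns gene, group, replicate, ct_target,
    ct_reference (one row per biological replicate; technical duplicates
    already averaged).  Each replicate of a group is calibrated against the
    same-index replicate of the calibrator group -- each independent
    experiment carries its own calibrator -- so the calibrator group's fold
    is exactly 1 in every replicate and its SD is 0 by construction.
    Returns a frame with columns gene, group, n, fold_mean, fold_sd.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s): {', '.join(missing)}")
    rec = records.copy()
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(rec[col], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"column {col!r} must hold finite positive Ct values")
        rec[col] = vals
    rec["dct"] = rec["ct_target"] - rec["ct_reference"]

    rows = []
    for gene, gdf in rec.groupby("gene", sort=False):
        cal = gdf[gdf["group"] == calibrator_group].set_index("replicate")["dct"]
        if cal.empty:
            raise ValueError(
                f"calibrator group {calibrator_group!r} missing for gene {gene!r}"
            )
        for group, sub in gdf.groupby("group", sort=False):
            cal_dct = sub["replicate"].map(cal)
            if cal_dct.isna().any():
                missing_reps = sorted(sub.loc[cal_dct.isna(), "replicate"])
                raise ValueError(
                    f"gene {gene!r}, group {group!r}: no calibrator replicate "
                    f"{missing_reps} to pair with"
                )
            folds = 2.0 ** (-(sub["dct"].to_numpy() - cal_dct.to_numpy()))
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n": len(folds),
                    "fold_mean": float(np.mean(folds)),
                    "fold_sd": float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
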