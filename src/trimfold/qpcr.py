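"""Comparative-CT (2^-ddCT) relative quantification and platform concordance.

Cycle thresholds are averaged over wells, normalized to a reference gene
within each condition (dCT = CT_target - CT_reference), and contrasted
between conditions (ddCT = dCT_treatment - dCT_control).  Relative
expression is 2^-ddCT, assuming perfect doubling per cycle; the signed fold
convention is shared with the microarray branch so both platforms report on
the same scale.  Concordance is the Pearson correlation between
platform-matched fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import signed_fold_change

logger = logging.getLogger("trimfold")


@dataclass(frozen=True)
class StabilityReport:
    """Reference-gene constancy check across conditions."""

    reference_gene: str
    condition_means: dict[str, float]
    max_abs_difference: float
    tolerance: float
    passed: bool


def _well_means(ct: pd.DataFrame) -> pd.DataFrame:
    return (ct.groupby(["condition", "gene_id"], sort=True)["ct"]
            .mean().reset_index())


def reference_stability(ct: pd.DataFrame, reference_gene: str,
                        tolerance: float = 0.5) -> StabilityReport:
    """Check that the reference gene's CT is constant across conditions.

    Reports per-condition mean CT and the largest absolute between-condition
    difference; fails if that difference exceeds ``tolerance`` cycles.
    """
    ref = ct[ct["gene_id"] == reference_gene]
    conditions = ct["condition"].unique()
    missing = [c for c in conditions if c not in set(ref["condition"])]
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in condition(s) "
            f"{missing}")
    means = ref.groupby("condition", sort=True)["ct"].mean()
    if len(means) == 1:
        logger.warning("only one condition present; reference stability is "
                       "trivially satisfied")
        diff = 0.0
    else:
        diff = float(means.max() - means.min())
    return StabilityReport(reference_gene=reference_gene,
                           condition_means=means.to_dict(),
                           max_abs_difference=diff,
                           tolerance=tolerance,
                           passed=diff <= tolerance)


def delta_delta_ct(ct: pd.DataFrame, reference_gene: str,
                   control_label: str = "control",
                   treatment_label: str = "treatment") -> pd.DataFrame:
    """Relative expression of each target gene by the comparative-CT method.

    Well replicates are averaged first; genes absent in one condition are
    skipped with a warning.  Output columns: gene_id, delta_ct_treatment,
    delta_ct_control, delta_delta_ct, relative_expression, qpcr_fold_change.
    """
    means = _well_means(ct)
    wide = means.pivot(index="gene_id", columns="condition", values="ct")
    for label in (control_label, treatment_label):
        if label not in wide.columns:
            raise ValueError(f"condition {label!r} not present in CT table")
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} not in CT table")
    ref = wide.loc[reference_gene]
    if ref[[control_label, treatment_label]].isna().any():
        raise ValueError(
            f"reference gene {reference_gene!r} missing in a condition")

    targets = wide.drop(index=reference_gene)
    incomplete = targets[[control_label, treatment_label]].isna().any(axis=1)
    if incomplete.any():
        skipped = sorted(targets.index[incomplete])
        logger.warning("skipping %d gene(s) not measured in both conditions: %s",
                       len(skipped), ", ".join(skipped[:10]))
        targets = targets[~incomplete]

    d_treat = targets[treatment_label] - ref[treatment_label]
    d_ctrl = targets[control_label] - ref[control_label]
    ddct = d_treat - d_ctrl
    rel = np.exp2(-ddct)
    out = pd.DataFrame({
        "gene_id": targets.index,
        "delta_ct_treatment": d_treat.to_numpy(),
        "delta_ct_control": d_ctrl.to_numpy(),
        "delta_delta_ct": ddct.to_numpy(),
        "relative_expression": rel.to_numpy(),
        "qpcr_fold_change": signed_fold_change(rel.to_numpy()),
    })
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def concordance(array_records: pd.DataFrame, qpcr_records: pd.DataFrame,
                scale: str = "fold") -> dict:
    """Pearson correlation between microarray and qPCR fold changes.

    ``scale='fold'`` correlates signed fold changes (the usual validation
    scatter-plot axes); ``'log2'`` correlates log2 ratios, which is less
    sensitive to single very large folds.  Returns r, n, slope and intercept
    of the least-squares line.
    """
    if scale not in ("fold", "log2"):
        raise ValueError(f"unknown scale {scale!r}")
    merged = array_records.merge(qpcr_records, on="gene_id", how="inner")
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 genes shared between platforms, got {len(merged)}")
    if scale == "fold":
        x = merged["fold_change"].to_numpy(dtype=float)
        y = merged["qpcr_fold_change"].to_numpy(dtype=float)
    else:
        x = merged["log2_ratio"].to_numpy(dtype=float)
        y = -merged["delta_delta_ct"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one platform; correlation undefined")
    fit = stats.linregress(x, y)
    return {
        "r": float(fit.rvalue),
        "n": int(len(merged)),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "scale": scale,
    }
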