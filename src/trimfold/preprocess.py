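"""Cross-array scale-factor normalization and trimmed-mean summarization.

Two single-channel arrays (one pooled control, one pooled treatment
hybridization) are put on a common scale with a single multiplicative
factor,

    SF = mean(control spot medians) / mean(treatment spot medians),

applied to every treatment spot, after which each gene's five replicate
spots are summarized by discarding exactly one maximum and one minimum
adjusted value and averaging the remaining three.  The order is fixed:
scale first, then trim — the trim operates on adjusted signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("trimfold")


class DegenerateInputError(ValueError):
    """Input that makes the operation undefined (e.g. zero array mean)."""


@dataclass(frozen=True)
class ScaleFactor:
    """The cross-array normalization ratio and the two means behind it."""

    value: float
    control_mean: float
    treatment_mean: float

    def __post_init__(self):
        if not (np.isfinite(self.value) and self.value > 0):
            raise DegenerateInputError(f"scale factor must be positive, got {self.value}")


def array_mean_signal(table: pd.DataFrame, array_id: str,
                      exclude_genes: Optional[Iterable[str]] = None) -> float:
    """Arithmetic mean of all spot median signals on one array.

    ``exclude_genes`` removes named spots (e.g. control oligos, or spike-ins
    whose intensities should not drive the normalization) from the mean.
    """
    mask = table["array_id"] == array_id
    if not mask.any():
        raise KeyError(f"array {array_id!r} not present in table")
    if exclude_genes is not None:
        mask &= ~table["gene_id"].isin(set(exclude_genes))
        if not mask.any():
            raise DegenerateInputError(
                f"array {array_id!r}: every spot excluded from the mean")
    return float(table.loc[mask, "signal"].mean())


def compute_scale_factor(table: pd.DataFrame, control_array: str,
                         treatment_array: str,
                         exclude_genes: Optional[Iterable[str]] = None
                         ) -> ScaleFactor:
    mu_control = array_mean_signal(table, control_array, exclude_genes)
    mu_treatment = array_mean_signal(table, treatment_array, exclude_genes)
    if mu_treatment <= 0:
        raise DegenerateInputError(
            f"treatment array {treatment_array!r} has non-positive mean signal")
    return ScaleFactor(value=mu_control / mu_treatment,
                       control_mean=mu_control, treatment_mean=mu_treatment)


def apply_scale_factor(table: pd.DataFrame, treatment_array: str,
                       sf: ScaleFactor) -> pd.DataFrame:
    """Multiply every spot on the treatment array by ``sf.value``.

    Control spots are untouched; afterwards the two array means agree to
    floating-point precision.
    """
    if not (np.isfinite(sf.value) and sf.value > 0):
        raise DegenerateInputError("scale factor must be finite and positive")
    out = table.copy()
    mask = out["array_id"] == treatment_array
    out.loc[mask, "signal"] = out.loc[mask, "signal"] * sf.value
    return out


def trimmed_mean(values: np.ndarray) -> tuple[float, int, int]:
    """Summarize one replicate group; returns (mean, n_used, n_discarded).

    With five or more values exactly one occurrence of the maximum and one
    of the minimum are discarded (ties still lose only one value per
    extreme).  Four values lose max and min (average of 2); three are
    averaged untrimmed.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 3:
        raise ValueError(f"trimmed mean needs >= 3 values, got {n}")
    if n == 3:
        kept = v
    else:
        kept = v[1:-1]
    return float(kept.mean()), len(kept), n - len(kept)


def trimmed_mean_summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, array) trimmed-mean summaries of adjusted spot signals.

    Groups with fewer than three replicates are excluded (logged); run this
    on the scale-adjusted table.
    """
    df = table.sort_values(["array_id", "gene_id", "probe_index"],
                           kind="mergesort")
    counts = df.groupby(["array_id", "gene_id"], sort=False).size()
    bad = counts[counts < 3]
    if len(bad):
        pairs = list(bad.index)
        logger.warning("excluding %d (gene, array) group(s) with <3 replicates",
                       len(pairs))
        drop = pd.MultiIndex.from_tuples(pairs)
        keyed = df.set_index(["array_id", "gene_id"])
        df = keyed[~keyed.index.isin(drop)].reset_index()
        counts = counts[counts >= 3]

    meta = df.groupby(["array_id", "gene_id"], sort=False).agg(
        condition=("condition", "first"), phase=("phase", "first"))

    if counts.nunique() == 1:
        # fast path: uniform replicate count -> one vectorized sort
        r = int(counts.iloc[0])
        mat = df["signal"].to_numpy(dtype=float).reshape(-1, r)
        mat = np.sort(mat, axis=1)
        kept = mat if r == 3 else mat[:, 1:-1]
        summary = kept.mean(axis=1)
        n_used = kept.shape[1]
        out = meta.reset_index()
        out["signal"] = summary
        out["n_used"] = n_used
        out["n_discarded"] = r - n_used
    else:
        rows = []
        for (aid, gid), grp in df.groupby(["array_id", "gene_id"], sort=False):
            mean, used, discarded = trimmed_mean(grp["signal"].to_numpy())
            rows.append((gid, aid, grp["condition"].iloc[0],
                         grp["phase"].iloc[0], mean, used, discarded))
        out = pd.DataFrame(rows, columns=["gene_id", "array_id", "condition",
                                          "phase", "signal", "n_used",
                                          "n_discarded"])
        return out.reset_index(drop=True)
    return out[["gene_id", "array_id", "condition", "phase", "signal",
                "n_used", "n_discarded"]].reset_index(drop=True)


def normalize_and_summarize(table: pd.DataFrame, control_array: str,
                            treatment_array: str,
                            exclude_genes: Optional[Iterable[str]] = None
                            ) -> tuple[pd.DataFrame, ScaleFactor]:
    """Scale the treatment array against the control, then summarize."""
    sf = compute_scale_factor(table, control_array, treatment_array,
                              exclude_genes)
    adjusted = apply_scale_factor(table, treatment_array, sf)
    logger.info("scale factor %s -> %s: %.6f", control_array,
                treatment_array, sf.value)
    return trimmed_mean_summarize(adjusted), sf
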