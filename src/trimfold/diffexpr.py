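"""Expression ratios, the signed fold-change convention, and DE calls.

The expression ratio is treatment / control on summarized signals.  Fold
changes use the symmetric reporting convention common for single-channel
ratio data: a ratio >= 1 is reported as-is, a ratio < 1 as minus its
reciprocal, so 4-fold repression reads -4 rather than 0.25 and |fold| >= 1
always.  Differential expression is threshold-only (default: more than
3-fold in either direction) — single pooled arrays per condition carry no
within-gene variance to test.
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
import pandas as pd

logger = logging.getLogger("trimfold")

ArrayLike = Union[float, np.ndarray]


def signed_fold_change(ratio: ArrayLike) -> ArrayLike:
    """Map a positive expression ratio to the signed fold convention.

    ratio >= 1 -> ratio; ratio < 1 -> -1/ratio.  Output magnitude is always
    >= 1 and never falls in the open interval (-1, 1).
    """
    r = np.asarray(ratio, dtype=float)
    if (r <= 0).any() or not np.isfinite(r).all():
        raise ValueError("expression ratio must be positive and finite")
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def log2_ratio(ratio: ArrayLike) -> ArrayLike:
    r = np.asarray(ratio, dtype=float)
    if (r <= 0).any() or not np.isfinite(r).all():
        raise ValueError("expression ratio must be positive and finite")
    out = np.log2(r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def expression_ratio(treatment: pd.DataFrame, control: pd.DataFrame,
                     floor: float = 1.0) -> pd.DataFrame:
    """Per-gene treatment/control ratios from two summarized arrays.

    Genes must be summarized on both arrays.  A control summary at or below
    the signal floor makes the ratio undefined — the gene is excluded and
    logged.  A treatment summary at or below the floor is clipped up to the
    floor and flagged, so strong repression is still reported (bounded).
    """
    t = treatment.set_index("gene_id")["signal"]
    c = control.set_index("gene_id")["signal"]
    shared = t.index.intersection(c.index)
    dropped = len(t.index.symmetric_difference(c.index))
    if dropped:
        logger.warning("%d gene(s) summarized on only one array; excluded",
                       dropped)
    t, c = t.loc[shared], c.loc[shared]

    undefined = c <= floor
    if undefined.any():
        logger.warning("%d gene(s) with control summary <= floor %g excluded",
                       int(undefined.sum()), floor)
    t, c = t[~undefined], c[~undefined]

    floored = t <= floor
    if floored.any():
        logger.warning("%d gene(s) with treatment summary <= floor %g; "
                       "ratio computed against the floor", int(floored.sum()),
                       floor)
    ratio = np.maximum(t, floor) / c
    out = pd.DataFrame({
        "gene_id": ratio.index,
        "ratio": ratio.to_numpy(),
        "treatment_floored": floored.to_numpy(),
    })
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def fold_change_table(treatment: pd.DataFrame, control: pd.DataFrame,
                      phase: str, floor: float = 1.0,
                      threshold: float = 3.0,
                      strict: bool = True) -> pd.DataFrame:
    """Assemble the per-gene fold-change records for one contrast."""
    ratios = expression_ratio(treatment, control, floor=floor)
    r = ratios["ratio"].to_numpy()
    fold = signed_fold_change(r)
    records = pd.DataFrame({
        "gene_id": ratios["gene_id"],
        "phase": phase,
        "ratio": r,
        "fold_change": fold,
        "log2_ratio": log2_ratio(r),
        "de_call": _de_call(fold, threshold, strict),
        "treatment_floored": ratios["treatment_floored"],
    })
    return records


def _de_call(fold: np.ndarray, threshold: float, strict: bool) -> np.ndarray:
    if strict:
        up = fold > threshold
        down = fold < -threshold
    else:
        up = fold >= threshold
        down = fold <= -threshold
    return np.where(up, "up", np.where(down, "down", "none"))


def call_differential(records: pd.DataFrame, threshold: float = 3.0,
                      strict: bool = True
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into up- and down-regulated lists at a fold threshold.

    Strict mode uses ``> threshold`` ("more than N-fold"); inclusive mode
    ``>=``.  Both lists are sorted by |fold change| descending, ties broken
    by gene id.
    """
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    call = _de_call(records["fold_change"].to_numpy(), threshold, strict)
    out = records.assign(de_call=call)

    def _ranked(sub: pd.DataFrame) -> pd.DataFrame:
        sub = sub.assign(_mag=sub["fold_change"].abs())
        sub = sub.sort_values(["_mag", "gene_id"],
                              ascending=[False, True], kind="mergesort")
        return sub.drop(columns="_mag").reset_index(drop=True)

    up = _ranked(out[out["de_call"] == "up"])
    down = _ranked(out[out["de_call"] == "down"])
    return up, down
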