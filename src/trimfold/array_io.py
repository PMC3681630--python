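"""Tabular I/O for the pipeline.

Everything on disk is plain tab-separated text with a header row.  Spot-level
intensities are written with 17 significant digits so that every float
round-trips bit-exactly through read/write; derived results (fold changes,
p-values) are written with a fixed 6-decimal format for stable, diffable
output files.

A minimal GenePix-style dialect (``gpr_subset``) is also supported: a
tab-delimited spot file whose header names an id column and a median-signal
column.  Only those two columns are consumed; replicate indices are assigned
by order of appearance of repeated ids.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("trimfold")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file (missing columns, non-numeric values, ...)."""


PROBE_COLUMNS = ["gene_id", "probe_index", "array_id", "condition", "phase", "signal"]
GENE_SIGNAL_COLUMNS = ["gene_id", "array_id", "condition", "phase", "signal",
                       "n_used", "n_discarded"]
FOLD_COLUMNS = ["gene_id", "phase", "ratio", "fold_change", "log2_ratio", "de_call"]
ANNOTATION_COLUMNS = ["term_id", "term_label", "gene_id"]
CT_COLUMNS = ["condition", "gene_id", "well", "ct"]

#: Full-precision float format: round-trips IEEE doubles exactly.
FULL_PRECISION = "%.17g"
#: Fixed-precision format for derived result tables.
RESULT_PRECISION = "%.6f"


# ---------------------------------------------------------------------------
# generic helpers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: PathLike, columns: Sequence[str],
               float_format: str = FULL_PRECISION) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for writing: {missing}")
    df.loc[:, list(columns)].to_csv(
        path, sep="\t", index=False, float_format=float_format,
        lineterminator="\n",
    )


def _numeric(df: pd.DataFrame, column: str, path: PathLike,
             kind: str = "float") -> pd.Series:
    """Convert a column to numbers; a bad cell raises naming its file line."""
    raw = df[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}: non-numeric {column} value {raw[bad].iloc[0]!r} on line {line}"
        )
    if converted.isna().any():
        line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: empty {column} value on line {line}")
    if kind == "int":
        as_int = converted.astype(np.int64)
        if not np.array_equal(as_int.to_numpy(), converted.to_numpy()):
            raise FormatError(f"{path}: non-integer values in column {column}")
        return as_int
    return converted.astype(float)


# ---------------------------------------------------------------------------
# probe-level spot tables
# ---------------------------------------------------------------------------

def validate_probe_table(df: pd.DataFrame,
                         n_probe_reps: Optional[int] = None) -> pd.DataFrame:
    """Check the structural invariants of a probe-level signal table.

    Every gene must appear on every array with the same number of replicate
    spots (``n_probe_reps`` when given), and all signals must be finite and
    non-negative.
    """
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"probe table missing columns: {missing}")
    sig = df["signal"].to_numpy(dtype=float)
    if not np.isfinite(sig).all():
        raise ValueError("probe table contains non-finite signals")
    if (sig < 0).any():
        raise ValueError("probe table contains negative signals")
    counts = df.groupby(["array_id", "gene_id"], sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("unequal replicate counts across (gene, array) groups")
    reps = int(counts.iloc[0])
    if n_probe_reps is not None and reps != n_probe_reps:
        raise ValueError(f"expected {n_probe_reps} replicates per gene, found {reps}")
    per_array = df.groupby("array_id", sort=False)["gene_id"].agg(frozenset)
    if per_array.nunique() != 1:
        raise ValueError("gene sets differ between arrays")
    return df


def _filter_replicate_counts(df: pd.DataFrame, path: PathLike, min_reps: int,
                             expected_reps: Optional[int]) -> pd.DataFrame:
    counts = df.groupby(["array_id", "gene_id"], sort=False).size()
    bad = counts[counts < min_reps]
    if len(bad):
        drop = set(bad.index.get_level_values("gene_id"))
        logger.warning(
            "%s: excluding %d gene(s) with fewer than %d replicate spots: %s",
            path, len(drop), min_reps, ", ".join(sorted(drop)[:10]),
        )
        df = df[~df["gene_id"].isin(drop)].reset_index(drop=True)
        counts = counts[counts >= min_reps]
    if expected_reps is not None:
        odd = counts[counts != expected_reps]
        if len(odd):
            genes = sorted(set(odd.index.get_level_values("gene_id")))
            logger.warning(
                "%s: %d gene(s) deviate from the %d-replicate design: %s",
                path, len(genes), expected_reps, ", ".join(genes[:10]),
            )
    return df


def read_probe_table(path: PathLike, dialect: str = "tsv", *,
                     array_id: Optional[str] = None,
                     condition: str = "unspecified",
                     phase: str = "unspecified",
                     id_column: str = "ID",
                     signal_column: str = "F532 Median",
                     min_reps: int = 3,
                     expected_reps: Optional[int] = None) -> pd.DataFrame:
    """Load a probe-level signal table.

    ``dialect='tsv'`` expects the pipeline's native schema; ``'gpr_subset'``
    expects a GenePix-style tab-delimited spot file from which only the id
    and median-signal columns are taken (``array_id``/``condition``/``phase``
    metadata then come from the keyword arguments).

    Genes with fewer than ``min_reps`` spots on an array are dropped with a
    warning — the trimmed mean needs at least three values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in PROBE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        out = pd.DataFrame({
            "gene_id": df["gene_id"].astype(str),
            "probe_index": _numeric(df, "probe_index", path, kind="int"),
            "array_id": df["array_id"].astype(str),
            "condition": df["condition"].astype(str),
            "phase": df["phase"].astype(str),
            "signal": _numeric(df, "signal", path),
        })
    elif dialect == "gpr_subset":
        out = _read_gpr_subset(path, array_id or path.stem, condition, phase,
                               id_column, signal_column)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if (out["signal"] < 0).any():
        bad = out.index[out["signal"] < 0][0]
        raise FormatError(f"{path}: negative signal in data row {bad + 1}")
    out = _filter_replicate_counts(out, path, min_reps, expected_reps)
    return out.reset_index(drop=True)


def _read_gpr_subset(path: Path, array_id: str, condition: str, phase: str,
                     id_column: str, signal_column: str) -> pd.DataFrame:
    """Parse the named-column subset of a GenePix-style spot file.

    The header row is located by name, so ATF-style preamble lines before it
    are skipped.  Quoting around header fields is tolerated.
    """
    header_row = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            fields = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]
            if id_column in fields and signal_column in fields:
                header_row = i
                break
    if header_row is None:
        raise FormatError(
            f"{path}: no header row containing {id_column!r} and {signal_column!r}"
        )
    df = pd.read_csv(path, sep="\t", skiprows=header_row, dtype=str)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    ids = df[id_column].astype(str).str.strip().str.strip('"')
    keep = ids.notna() & (ids != "") & (ids.str.lower() != "nan")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("%s: dropping %d spot(s) without an id", path, n_drop)
    df = df[keep]
    ids = ids[keep]
    # line numbers in _numeric are relative to the located header
    signal = _numeric(df.reset_index(drop=True).assign(_sig=df[signal_column].values),
                      "_sig", path).to_numpy()
    out = pd.DataFrame({"gene_id": ids.to_numpy()})
    out["probe_index"] = out.groupby("gene_id").cumcount() + 1
    out["array_id"] = array_id
    out["condition"] = condition
    out["phase"] = phase
    out["signal"] = signal
    return out


def write_probe_table(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path, PROBE_COLUMNS, FULL_PRECISION)


# ---------------------------------------------------------------------------
# summarized / result tables
# ---------------------------------------------------------------------------

def write_gene_signal_table(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path, GENE_SIGNAL_COLUMNS, FULL_PRECISION)


def read_gene_signal_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return pd.DataFrame({
        "gene_id": df["gene_id"].astype(str),
        "array_id": df["array_id"].astype(str),
        "condition": df["condition"].astype(str),
        "phase": df["phase"].astype(str),
        "signal": _numeric(df, "signal", path),
        "n_used": _numeric(df, "n_used", path, kind="int"),
        "n_discarded": _numeric(df, "n_discarded", path, kind="int"),
    })


def write_results(df: pd.DataFrame, path: PathLike,
                  columns: Optional[Sequence[str]] = None) -> None:
    """Write a derived-results table with deterministic 6-decimal floats.

    An empty frame produces a header-only file; identical inputs produce
    byte-identical files.
    """
    cols = list(columns) if columns is not None else list(df.columns)
    _write_tsv(df, path, cols, RESULT_PRECISION)


def read_fold_changes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FOLD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = pd.DataFrame({
        "gene_id": df["gene_id"].astype(str),
        "phase": df["phase"].astype(str),
        "ratio": _numeric(df, "ratio", path),
        "fold_change": _numeric(df, "fold_change", path),
        "log2_ratio": _numeric(df, "log2_ratio", path),
        "de_call": df["de_call"].astype(str),
    })
    return out


def write_annotation(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path, ANNOTATION_COLUMNS)


def read_annotation(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df[ANNOTATION_COLUMNS].astype(str)


def write_ct_table(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path, CT_COLUMNS, FULL_PRECISION)


def read_ct_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = pd.DataFrame({
        "condition": df["condition"].astype(str),
        "gene_id": df["gene_id"].astype(str),
        "well": _numeric(df, "well", path, kind="int"),
        "ct": _numeric(df, "ct", path),
    })
    if (out["ct"] <= 0).any() or not np.isfinite(out["ct"]).all():
        raise ValueError(f"{path}: CT values must be finite and positive")
    return out


def write_gene_list(genes: Sequence[str], path: PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: PathLike) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]
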