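"""Delimited-text table schemas and validated readers/writers.

All tables are comma-separated with documented headers; months are integers
1-12, stages and phases are fixed uppercase tokens, missing values are empty
fields (never sentinels).  Readers collect row-level validation problems
with line numbers and return the valid rows; unknown stage or phase tokens
are a hard error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from opdpipe.errors import SchemaError
from opdpipe.stages import ALL_COMPONENTS, MaturityPhase, OocyteStage
from opdpipe.stereology import FieldCount

__all__ = [
    "FEMALES_COLUMNS",
    "GRID_COUNTS_COLUMNS",
    "MEASUREMENTS_COLUMNS",
    "ValidationIssue",
    "TableReadResult",
    "read_females",
    "read_grid_counts",
    "read_measurements",
    "write_females",
    "write_grid_counts",
    "write_measurements",
    "field_counts_from_frame",
    "frame_from_field_counts",
    "file_digest",
]

FEMALES_COLUMNS = (
    "female_id", "month", "TL_cm", "WW_g", "EW_g", "GW_g", "GWf_g",
    "MAT", "MAO", "POF_present",
)
GRID_COUNTS_COLUMNS = ("female_id", "field_id", "component", "hits", "n_points")
MEASUREMENTS_COLUMNS = ("female_id", "stage", "L_um", "S_um", "through_nucleus")

_VALID_PHASES = {p.value for p in MaturityPhase}
_VALID_STAGES = {s.value for s in OocyteStage}


@dataclass(frozen=True)
class ValidationIssue:
    line: int  # 1-based file line (header is line 1)
    message: str


@dataclass
class TableReadResult:
    frame: pd.DataFrame
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def _check_header(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _hard_error_tokens(frame: pd.DataFrame, column: str, valid: set, path) -> None:
    present = set(frame[column].dropna().astype(str))
    unknown = sorted(present - valid)
    if unknown:
        raise SchemaError(f"{path}: unknown {column} tokens {unknown}")


def read_females(path) -> TableReadResult:
    """Read and validate the per-female fish records table."""
    frame = pd.read_csv(path)
    _check_header(frame, FEMALES_COLUMNS, path)
    _hard_error_tokens(frame, "MAT", _VALID_PHASES, path)
    _hard_error_tokens(frame, "MAO", _VALID_STAGES, path)
    issues: list[ValidationIssue] = []
    keep = np.ones(len(frame), dtype=bool)
    months = pd.to_numeric(frame["month"], errors="coerce")
    bad_month = months.isna() | (months < 1) | (months > 12) | (months % 1 != 0)
    for i in np.flatnonzero(bad_month.to_numpy()):
        issues.append(ValidationIssue(i + 2, f"month {frame['month'].iloc[i]!r} not in 1-12"))
        keep[i] = False
    tl = pd.to_numeric(frame["TL_cm"], errors="coerce")
    bad_tl = tl.isna() | (tl <= 0)
    for i in np.flatnonzero(bad_tl.to_numpy()):
        issues.append(ValidationIssue(i + 2, f"TL_cm {frame['TL_cm'].iloc[i]!r} must be > 0"))
        keep[i] = False
    for col in ("WW_g", "GW_g", "GWf_g"):
        w = pd.to_numeric(frame[col], errors="coerce")
        bad = w.notna() & (w < 0)
        for i in np.flatnonzero(bad.to_numpy()):
            issues.append(ValidationIssue(i + 2, f"{col} must be >= 0"))
            keep[i] = False
    out = frame.loc[keep].copy()
    out["month"] = pd.to_numeric(out["month"]).astype(int)
    out["POF_present"] = out["POF_present"].map(_parse_bool)
    return TableReadResult(out.reset_index(drop=True), issues)


def read_grid_counts(path) -> TableReadResult:
    """Read and validate the long grid-count table (one row per field x component)."""
    frame = pd.read_csv(path)
    _check_header(frame, GRID_COUNTS_COLUMNS, path)
    _hard_error_tokens(frame, "component", set(ALL_COMPONENTS), path)
    issues: list[ValidationIssue] = []
    keep = np.ones(len(frame), dtype=bool)
    hits = pd.to_numeric(frame["hits"], errors="coerce")
    bad = hits.isna() | (hits < 0) | (hits % 1 != 0)
    for i in np.flatnonzero(bad.to_numpy()):
        issues.append(
            ValidationIssue(i + 2, f"hits {frame['hits'].iloc[i]!r} must be a count")
        )
        keep[i] = False
    out = frame.loc[keep].copy()
    out["hits"] = pd.to_numeric(out["hits"]).astype(int)
    out["n_points"] = pd.to_numeric(out["n_points"]).astype(int)
    # per-field totals must match the declared point count
    for (fid, field_id), grp in out.groupby(["female_id", "field_id"]):
        total = grp["hits"].sum()
        npts = grp["n_points"].iloc[0]
        if total != npts:
            issues.append(
                ValidationIssue(
                    int(grp.index[0]) + 2,
                    f"field {field_id} of female {fid}: hits sum {total} != "
                    f"n_points {npts}",
                )
            )
            keep[grp.index] = False
    out = frame.loc[keep].copy()
    out["hits"] = pd.to_numeric(out["hits"]).astype(int)
    out["n_points"] = pd.to_numeric(out["n_points"]).astype(int)
    return TableReadResult(out.reset_index(drop=True), issues)


def read_measurements(path) -> TableReadResult:
    """Read and validate the oocyte axis-measurement table."""
    frame = pd.read_csv(path)
    _check_header(frame, MEASUREMENTS_COLUMNS, path)
    _hard_error_tokens(frame, "stage", _VALID_STAGES, path)
    issues: list[ValidationIssue] = []
    keep = np.ones(len(frame), dtype=bool)
    L = pd.to_numeric(frame["L_um"], errors="coerce")
    S = pd.to_numeric(frame["S_um"], errors="coerce")
    bad = L.isna() | S.isna() | (S <= 0) | (L < S)
    for i in np.flatnonzero(bad.to_numpy()):
        issues.append(
            ValidationIssue(
                i + 2,
                f"axes L={frame['L_um'].iloc[i]!r}, S={frame['S_um'].iloc[i]!r} "
                "violate L >= S > 0",
            )
        )
        keep[i] = False
    out = frame.loc[keep].copy()
    out["through_nucleus"] = out["through_nucleus"].map(_parse_bool)
    return TableReadResult(out.reset_index(drop=True), issues)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no", "", "nan"):
        return False
    raise SchemaError(f"cannot parse boolean {value!r}")


def _write(frame: pd.DataFrame, path, columns) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False, columns=list(columns))
    tmp.replace(path)  # atomic on POSIX
    return path


def write_females(frame: pd.DataFrame, path) -> Path:
    cols = [c for c in FEMALES_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    return _write(frame, path, cols + extra)


def write_grid_counts(frame: pd.DataFrame, path) -> Path:
    return _write(frame, path, GRID_COUNTS_COLUMNS)


def write_measurements(frame: pd.DataFrame, path) -> Path:
    return _write(frame, path, MEASUREMENTS_COLUMNS)


def field_counts_from_frame(frame: pd.DataFrame) -> list[FieldCount]:
    """Long grid-count table -> FieldCount objects."""
    counts = []
    for (fid, field_id), grp in frame.groupby(["female_id", "field_id"], sort=False):
        hits = dict(zip(grp["component"].astype(str), grp["hits"].astype(int)))
        counts.append(
            FieldCount(
                field_id=str(field_id),
                n_points=int(grp["n_points"].iloc[0]),
                hits=hits,
                female_id=str(fid),
            )
        )
    return counts


def frame_from_field_counts(counts: Sequence[FieldCount]) -> pd.DataFrame:
    """FieldCount objects -> long grid-count table."""
    rows = []
    for fc in counts:
        for comp, c in fc.hits.items():
            rows.append(
                {
                    "female_id": fc.female_id,
                    "field_id": fc.field_id,
                    "component": comp,
                    "hits": int(c),
                    "n_points": fc.n_points,
                }
            )
    return pd.DataFrame(rows, columns=list(GRID_COUNTS_COLUMNS))


def file_digest(path) -> str:
    """SHA-256 of a file's bytes, for run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
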