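"""Cohort and report readers/writers (UTF-8 CSV interchange).

Cohorts travel as CSV with the canonical header (see
:data:`booscore.schema.COHORT_COLUMNS`); performance tables mirror the
published layout with fixed 3-decimal formatting.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .schema import (
    COHORT_COLUMNS,
    CONTINUOUS_VARS,
    LABEL_COLUMN,
    LUTD_LABELS,
    PHYSICAL_DOMAIN,
)

REPORT_COLUMNS = (
    "target", "split", "threshold", "direction",
    "sensitivity", "specificity", "auc", "ci_low", "ci_high",
)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`InputError` with row/column context for missing columns,
    non-numeric cells, unknown LUTD labels or out-of-range values. Missing
    values are not permitted on any canonical column.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    for col in CONTINUOUS_VARS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"{path}: non-numeric or missing value in column {col!r} at row {row}"
            )
        lo, hi = PHYSICAL_DOMAIN[col]
        out = ~coerced.between(lo, hi)
        if out.any():
            row = int(np.flatnonzero(out)[0])
            raise InputError(
                f"{path}: {col}={coerced.iloc[row]!r} at row {row} outside [{lo}, {hi}]"
            )
        df[col] = coerced.astype(float)
    unknown = ~df[LABEL_COLUMN].isin(LUTD_LABELS)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise InputError(
            f"{path}: unknown lutd_label {df[LABEL_COLUMN].iloc[row]!r} at row {row}; "
            f"expected one of {LUTD_LABELS}"
        )
    df[LABEL_COLUMN] = df[LABEL_COLUMN].astype("object")
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in canonical column order (extra columns, e.g. an
    appended score, are kept after the canonical ones)."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort missing columns {missing}")
    extra = [c for c in cohort.columns if c not in COHORT_COLUMNS]
    cohort[list(COHORT_COLUMNS) + extra].to_csv(path, index=False)


def write_performance_report(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a performance table CSV, one row per (target, split), numeric
    columns at fixed 3-decimal formatting."""
    if rows is None or len(rows) == 0:
        raise InputError("performance report has no rows")
    missing = [c for c in REPORT_COLUMNS if c not in rows.columns]
    if missing:
        raise InputError(f"performance rows missing columns {missing}")
    out = rows.copy()
    for col in ("threshold", "sensitivity", "specificity", "auc", "ci_low", "ci_high"):
        out[col] = out[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.3f}"
        )
    cols = list(REPORT_COLUMNS) + (["error"] if "error" in out.columns else [])
    out[cols].to_csv(path, index=False)


def read_performance_report(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse report {path}: {exc}") from exc
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing report columns {missing}")
    return df
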