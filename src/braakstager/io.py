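"""Cohort table reading/writing with schema validation.

Tables are UTF-8 CSV/TSV with a header row; the delimiter is inferred from
the extension.  Empty cells are missing values.  The reader validates the
required staging columns and numeric types, reporting row/column context.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .atlas import N_STAGES

REQUIRED_COLUMNS: List[str] = (
    ["subject_id", "visit", "diagnosis"]
    + [f"suvr_braak{i}" for i in range(1, N_STAGES + 1)]
    + ["suvr_meta_roi", "suvr_amyloid"]
)

NUMERIC_COLUMNS_PREFIXES = ("suvr_", "csf_", "plasma_", "hippocampal_")


class SchemaError(ValueError):
    """Raised when a table violates the cohort schema."""


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_cohort_table(
    path,
    required: Optional[Iterable[str]] = None,
    check_duplicates: bool = True,
) -> pd.DataFrame:
    """Read and validate a cohort table.

    Raises :class:`SchemaError` naming any missing required column, any
    unparseable numeric cell (with row and column), or a duplicated
    (subject_id, visit) pair.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=True)
    required = REQUIRED_COLUMNS if required is None else list(required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns: {missing}")

    numeric_cols = [
        c
        for c in df.columns
        if c.startswith(NUMERIC_COLUMNS_PREFIXES)
        or c
        in (
            "age_years",
            "mmse",
            "moca",
            "cdr",
            "parental_onset_age",
            "true_stage",
        )
        or c in _TEST_COLS
    ]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & parsed.isna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise SchemaError(
                f"{path.name}: unparseable numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row + 2} (1-based incl. header)"
            )
        df[col] = parsed
    if "true_amyloid_positive" in df.columns:
        df["true_amyloid_positive"] = df["true_amyloid_positive"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
    if "psen1_carrier" in df.columns:
        df["psen1_carrier"] = df["psen1_carrier"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )

    if check_duplicates and {"subject_id", "visit"}.issubset(df.columns):
        dup = df.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "visit"]].to_records(index=False).tolist()
            raise SchemaError(f"{path.name}: duplicate (subject, visit) pairs: {pairs}")
    return df


_TEST_COLS = {
    "logical_memory_immediate",
    "logical_memory_delayed",
    "ravlt_immediate",
    "ravlt_delayed",
    "category_fluency",
    "boston_naming",
    "borb",
    "trails_b_time",
    "digit_span_backward",
    "letter_fluency",
}


def write_cohort_table(df: pd.DataFrame, path) -> Path:
    """Write a table as CSV/TSV (delimiter from the extension); lossless with
    :func:`read_cohort_table` for all supported columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=False)
    return path
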