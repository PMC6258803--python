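"""Cohort CSV reading and writing.

One flat schema, units frozen in the column names: comma-separated, UTF-8,
header row mandatory, '.' decimal separator, empty fields for missing
optional values. Floats are written with 12 significant digits so a
write→read round trip reproduces values well past 10 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_sim import SyntheticPatient
from .errors import SchemaError

__all__ = ["COHORT_COLUMNS", "read_cohort", "write_cohort", "cohort_to_dataframe"]

logger = logging.getLogger(__name__)

#: Ordered cohort CSV columns.
COHORT_COLUMNS = (
    "id",
    "bmi",
    "bmi_category",
    "d_ap_cm",
    "d_lat_cm",
    "d_e_cm",
    "d_in_cm",
    "d_ratio",
    "ctdi_vol_mgy",
    "scan_length_cm",
    "dlp_mgycm",
    "conversion_factor",
    "ssde_mgy",
    "phantom_cm",
)

_NUMERIC_COLUMNS = tuple(c for c in COHORT_COLUMNS if c not in ("id", "bmi_category"))

#: Attribute on SyntheticPatient providing each numeric column.
_PATIENT_ATTRS = {
    "bmi": "bmi",
    "d_ap_cm": "d_ap",
    "d_lat_cm": "d_lat",
    "d_e_cm": "d_e",
    "d_in_cm": "d_in",
    "d_ratio": "d_ratio",
    "ctdi_vol_mgy": "ctdi_vol",
    "scan_length_cm": "scan_length",
    "dlp_mgycm": "dlp",
    "conversion_factor": "conversion_factor",
    "ssde_mgy": "ssde",
}


def cohort_to_dataframe(
    rows: Sequence[SyntheticPatient], phantom_cm: int = 32
) -> pd.DataFrame:
    """Arrange simulated patients into the cohort CSV schema."""
    if len(rows) == 0:
        raise SchemaError("cohort is empty")
    data: dict[str, object] = {"id": [r.id for r in rows]}
    data["bmi"] = [r.bmi for r in rows]
    data["bmi_category"] = [r.bmi_category for r in rows]
    for col, attr in _PATIENT_ATTRS.items():
        if col == "bmi":
            continue
        data[col] = [getattr(r, attr) for r in rows]
    data["phantom_cm"] = [phantom_cm] * len(rows)
    return pd.DataFrame(data, columns=list(COHORT_COLUMNS))


def write_cohort(rows, path: str | Path) -> None:
    """Write a cohort (DataFrame in schema order, or simulated patients) as
    CSV. Missing optional values are written as empty fields."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in rows.columns]
        if missing:
            raise SchemaError(f"cohort is missing required columns: {', '.join(missing)}")
        df = rows.loc[:, list(COHORT_COLUMNS)]
    else:
        df = cohort_to_dataframe(list(rows))
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into a DataFrame.

    Mandatory columns are checked by name (a schema error lists any that are
    absent); unknown columns are preserved with a logged warning; a value
    that fails numeric parsing is reported with its row number (1-based,
    excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required columns: {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns in %s: %s", path, ", ".join(unknown))

    out = df.copy()
    for col in _NUMERIC_COLUMNS:
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(
                f"unparseable numeric value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at data row {row} of {path}"
            )
        out[col] = converted
    return out
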