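"""Cohort CSV dialect.

One RFC-4180 UTF-8 CSV with a header row, "." decimal, one subject per row.
Column names match the data dictionary case-insensitively; sex accepts
"male"/"female" and "M"/"F". Unknown columns are preserved with a warning.
Mandatory columns: id, sex, age. In lenient mode unparseable cells become
missing; in strict mode they raise :class:`~simscore.errors.FormatError`
naming the row and column.
"""

from __future__ import annotations

import logging
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: column -> (kind, unit, description); kinds: str, float, bool
COLUMN_DICTIONARY: Dict[str, Tuple[str, str, str]] = {
    "id": ("str", "", "opaque subject identifier, unique"),
    "sex": ("str", "", "male | female"),
    "age": ("float", "years", "age at inclusion"),
    "weight": ("float", "kg", "body weight"),
    "height": ("float", "cm", "body height"),
    "bmi": ("float", "kg/m2", "body mass index"),
    "waist": ("float", "cm", "waist circumference"),
    "sbp": ("float", "mmHg", "systolic blood pressure"),
    "dbp": ("float", "mmHg", "diastolic blood pressure"),
    "glucose_0": ("float", "mmol/L", "OGTT glucose, 0 min (fasting)"),
    "glucose_30": ("float", "mmol/L", "OGTT glucose, 30 min"),
    "glucose_120": ("float", "mmol/L", "OGTT glucose, 120 min"),
    "insulin_0": ("float", "mIU/L", "OGTT insulin, 0 min (fasting)"),
    "insulin_30": ("float", "mIU/L", "OGTT insulin, 30 min"),
    "insulin_120": ("float", "mIU/L", "OGTT insulin, 120 min"),
    "cholesterol": ("float", "mmol/L", "total cholesterol"),
    "hdl": ("float", "mmol/L", "HDL cholesterol"),
    "ldl": ("float", "mmol/L", "LDL cholesterol"),
    "triglycerides": ("float", "mmol/L", "triglycerides"),
    "hba1c": ("float", "%", "glycated hemoglobin"),
    "crp": ("float", "mg/L", "C-reactive protein"),
    "pai1": ("float", "U/mL", "plasminogen activator inhibitor-1"),
    "homocysteine": ("float", "umol/L", "homocysteine"),
    "uric_acid": ("float", "umol/L", "uric acid"),
    "alt": ("float", "U/L", "alanine aminotransferase"),
    "ast": ("float", "U/L", "aspartate aminotransferase"),
    "ggt": ("float", "U/L", "gamma-glutamyl transpeptidase"),
    "urea": ("float", "mmol/L", "urea"),
    "creatinine": ("float", "umol/L", "creatinine"),
    "creatinine_clearance": ("float", "mL/min", "creatinine clearance"),
    "microalbuminuria": ("float", "mg/24h", "24-hour urinary albumin"),
    "on_lipid_therapy": ("bool", "", "lipid-lowering therapy"),
    "on_antihypertensive_therapy": ("bool", "", "antihypertensive therapy"),
    "known_dm2": ("bool", "", "previously diagnosed type-2 diabetes"),
    # derived columns (scores module)
    "sims": ("float", "", "siMS score"),
    "homa_ir": ("float", "", "HOMA-IR"),
    "fli": ("float", "", "fatty liver index, 0-100"),
    "insulin_mean": ("float", "mIU/L", "mean OGTT insulin (0/30/120 min)"),
    "log_alt": ("float", "", "ln ALT"),
    "log_ggt": ("float", "", "ln GGT"),
    "log_fli": ("float", "", "ln FLI"),
    "log_crp": ("float", "", "ln CRP"),
    "log_homa_ir": ("float", "", "ln HOMA-IR"),
    # classification columns (classify module)
    "wc_flag": ("bool", "", "IDF waist criterion"),
    "tg_flag": ("bool", "", "IDF triglyceride criterion"),
    "hdl_flag": ("bool", "", "IDF HDL criterion"),
    "bp_flag": ("bool", "", "IDF blood-pressure criterion"),
    "gly_flag": ("bool", "", "IDF glycemia criterion"),
    "n_criteria": ("float", "", "number of IDF criteria met, 0-5"),
    "ms_label": ("str", "", "ms | pre_ms | no_criteria"),
    "glyco_label": ("str", "", "normal | ifg | igt | dm"),
    "obesity_label": ("str", "", "overweight | obese | out_of_cohort"),
    "age_group": ("str", "", "young (<=30) | older (31+)"),
}

MANDATORY_COLUMNS = ("id", "sex", "age")

_SEX_ALIASES = {"m": "male", "f": "female", "male": "male", "female": "female"}
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def read_cohort(path, strict: bool = False) -> pd.DataFrame:
    """Read a cohort CSV into a typed DataFrame (row count preserved)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in COLUMN_DICTIONARY:
            rename[col] = key
        else:
            logger.warning("unknown column %r preserved as-is", col)
    df = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {', '.join(missing)}")

    for col in df.columns:
        kind = COLUMN_DICTIONARY.get(col, ("str",))[0]
        if kind == "float":
            coerced = pd.to_numeric(df[col], errors="coerce")
            if strict:
                bad = df[col].notna() & coerced.isna()
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise FormatError(
                        f"unparseable value {df[col].iloc[row]!r} in column "
                        f"{col!r}, row {row + 2} (1-based, header included)"
                    )
            df[col] = coerced
        elif kind == "bool":
            df[col] = df[col].map(_parse_bool_factory(col, strict))

    df["sex"] = df["sex"].map(_parse_sex_factory(strict))
    ids = df["id"]
    if ids.duplicated().any():
        msg = f"duplicate ids: {sorted(ids[ids.duplicated()].unique())[:5]}"
        if strict:
            raise FormatError(msg)
        logger.warning(msg)
    return df


def _parse_bool_factory(col, strict):
    def parse(value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return False
        s = str(value).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        if strict:
            raise FormatError(f"unparseable boolean {value!r} in column {col!r}")
        return False
    return parse


def _parse_sex_factory(strict):
    def parse(value):
        s = str(value).strip().lower()
        if s in _SEX_ALIASES:
            return _SEX_ALIASES[s]
        if strict:
            raise FormatError(f"unparseable sex value {value!r}")
        return np.nan
    return parse


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write the cohort CSV; columns ordered per the data dictionary, unknown
    columns appended in their incoming order."""
    known = [c for c in COLUMN_DICTIONARY if c in df.columns]
    unknown = [c for c in df.columns if c not in COLUMN_DICTIONARY]
    df[known + unknown].to_csv(path, index=False)


def data_dictionary() -> pd.DataFrame:
    """The column dictionary as a table (column, kind, unit, description)."""
    return pd.DataFrame(
        [(c, k, u, d) for c, (k, u, d) in COLUMN_DICTIONARY.items()],
        columns=["column", "kind", "unit", "description"],
    )
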