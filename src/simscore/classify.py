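"""IDF metabolic-syndrome classification and OGTT glycoregulation staging.

The IDF definition makes central obesity mandatory: waist circumference
≥ 94 cm (men) / ≥ 80 cm (women), plus at least two of

* triglycerides ≥ 1.7 mmol/L, or lipid-lowering therapy;
* HDL cholesterol < 1.03 mmol/L (men) / < 1.29 mmol/L (women), or therapy;
* SBP ≥ 135 or DBP ≥ 85 mmHg, or antihypertensive therapy;
* fasting glucose ≥ 5.6 mmol/L, or previously diagnosed type-2 diabetes.

Subjects meeting fewer than three criteria are labelled *pre-MS* (at least
one criterion) or *no_criteria*. Note the blood-pressure threshold used here
is 135/85 as in the source cohort's protocol, configurable via module
constants; the conventional IDF systolic cutoff is 130.

Glycoregulation is staged from the 75-g OGTT with standard WHO/ADA cutoffs:
diabetes if fasting ≥ 7.0 mmol/L or 2-h ≥ 11.1 mmol/L (or already known),
else impaired glucose tolerance (IGT) if 2-h in [7.8, 11.1), else impaired
fasting glucose (IFG) if fasting in [5.6, 7.0), else normal. Precedence
DM > IGT > IFG keeps the labels exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .records import PatientRecord

# IDF component thresholds (configurable: the BP cutoffs in particular)
WC_CUTOFF = {"male": 94.0, "female": 80.0}  # cm
TG_CUTOFF = 1.7  # mmol/L
HDL_CUTOFF = {"male": 1.03, "female": 1.29}  # mmol/L
SBP_CUTOFF = 135.0  # mmHg
DBP_CUTOFF = 85.0  # mmHg
GLY_CUTOFF = 5.6  # mmol/L fasting

# OGTT staging cutoffs (WHO/ADA)
DM_FASTING = 7.0
DM_2H = 11.1
IGT_2H_LOW = 7.8
IFG_LOW = 5.6

OBESITY_CUTOFF = 30.0  # BMI, strict
OVERWEIGHT_CUTOFF = 25.0
YOUNG_MAX_AGE = 30  # inclusive upper bound of the young group

MS_LABELS = ("ms", "pre_ms", "no_criteria")
GLYCO_LABELS = ("normal", "ifg", "igt", "dm")


@dataclass(frozen=True)
class IdfComponentFlags:
    wc_flag: bool
    tg_flag: bool
    hdl_flag: bool
    bp_flag: bool
    gly_flag: bool

    @property
    def n_criteria(self) -> int:
        return sum((self.wc_flag, self.tg_flag, self.hdl_flag, self.bp_flag, self.gly_flag))


@dataclass(frozen=True)
class MsClassification:
    label: str
    flags: IdfComponentFlags


def evaluate_idf_components(record: PatientRecord) -> IdfComponentFlags:
    """Evaluate the five IDF component criteria for one record.

    Lipid therapy triggers both the triglyceride and the HDL criterion
    (both are treated with the same drug classes and the source protocol
    attaches "or applied therapy" to each).
    """
    required = ("waist", "triglycerides", "hdl", "sbp", "dbp", "glucose_0")
    missing = [f for f in required if getattr(record, f) is None]
    if missing:
        raise DomainError(f"IDF evaluation needs fields: {', '.join(missing)}")
    return IdfComponentFlags(
        wc_flag=record.waist >= WC_CUTOFF[record.sex],
        tg_flag=record.triglycerides >= TG_CUTOFF or record.on_lipid_therapy,
        hdl_flag=record.hdl < HDL_CUTOFF[record.sex] or record.on_lipid_therapy,
        bp_flag=(
            record.sbp >= SBP_CUTOFF
            or record.dbp >= DBP_CUTOFF
            or record.on_antihypertensive_therapy
        ),
        gly_flag=record.glucose_0 >= GLY_CUTOFF or record.known_dm2,
    )


def classify_ms(flags: IdfComponentFlags) -> MsClassification:
    """MS iff central obesity plus ≥2 other criteria; else pre-MS if any
    criterion is met; else no_criteria."""
    n_other = flags.n_criteria - int(flags.wc_flag)
    if flags.wc_flag and n_other >= 2:
        label = "ms"
    elif flags.n_criteria >= 1:
        label = "pre_ms"
    else:
        label = "no_criteria"
    return MsClassification(label=label, flags=flags)


def classify_glycoregulation(
    glucose_0: float,
    glucose_120: Optional[float],
    known_dm2: bool = False,
) -> Optional[str]:
    """OGTT stage: 'dm' | 'igt' | 'ifg' | 'normal'; None when the 2-h value
    is missing and no diabetes can be concluded without it."""
    if not glucose_0 > 0:
        raise DomainError(f"glucose_0 must be strictly positive, got {glucose_0!r}")
    if known_dm2 or glucose_0 >= DM_FASTING:
        return "dm"
    if glucose_120 is None:
        return None
    if glucose_120 >= DM_2H:
        return "dm"
    if glucose_120 >= IGT_2H_LOW:
        return "igt"
    if glucose_0 >= IFG_LOW:
        return "ifg"
    return "normal"


def classify_obesity(bmi: float) -> str:
    """'obese' if BMI > 30, 'overweight' if BMI > 25 (strict inequalities),
    'out_of_cohort' below the study's inclusion threshold."""
    if bmi > OBESITY_CUTOFF:
        return "obese"
    if bmi > OVERWEIGHT_CUTOFF:
        return "overweight"
    return "out_of_cohort"


def assign_age_group(age: float) -> str:
    """'young' (≤30 years) or 'older' (31+)."""
    if not age > 0:
        raise DomainError(f"age must be strictly positive, got {age!r}")
    return "young" if age <= YOUNG_MAX_AGE else "older"


def classify_record(record: PatientRecord) -> MsClassification:
    return classify_ms(evaluate_idf_components(record))


# ---------------------------------------------------------------------------
# vectorized table-level classification


def classify_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Append IDF flags, n_criteria, ms_label, glyco_label, obesity_label and
    age_group columns. Rows with missing inputs get NaN labels, not errors."""
    out = df.copy()

    def col(name: str) -> pd.Series:
        if name in out.columns:
            return pd.to_numeric(out[name], errors="coerce")
        return pd.Series(np.nan, index=out.index)

    def flag(name: str) -> pd.Series:
        if name in out.columns:
            return out[name].fillna(False).astype(bool)
        return pd.Series(False, index=out.index)

    sex = out["sex"]
    wc_cut = sex.map(WC_CUTOFF)
    hdl_cut = sex.map(HDL_CUTOFF)
    lipid_rx = flag("on_lipid_therapy")

    out["wc_flag"] = col("waist") >= wc_cut
    out["tg_flag"] = (col("triglycerides") >= TG_CUTOFF) | lipid_rx
    out["hdl_flag"] = (col("hdl") < hdl_cut) | lipid_rx
    out["bp_flag"] = (
        (col("sbp") >= SBP_CUTOFF)
        | (col("dbp") >= DBP_CUTOFF)
        | flag("on_antihypertensive_therapy")
    )
    out["gly_flag"] = (col("glucose_0") >= GLY_CUTOFF) | flag("known_dm2")
    flags = out[["wc_flag", "tg_flag", "hdl_flag", "bp_flag", "gly_flag"]]
    out["n_criteria"] = flags.sum(axis=1).astype(int)

    n_other = out["n_criteria"] - out["wc_flag"].astype(int)
    out["ms_label"] = np.select(
        [out["wc_flag"] & (n_other >= 2), out["n_criteria"] >= 1],
        ["ms", "pre_ms"],
        default="no_criteria",
    )

    g0, g120 = col("glucose_0"), col("glucose_120")
    dm = flag("known_dm2") | (g0 >= DM_FASTING) | (g120 >= DM_2H)
    igt = ~dm & (g120 >= IGT_2H_LOW)
    ifg = ~dm & ~igt & g120.notna() & (g0 >= IFG_LOW)
    normal = ~dm & ~igt & g120.notna() & (g0 < IFG_LOW)
    out["glyco_label"] = np.select([dm, igt, ifg, normal], list(GLYCO_LABELS[::-1]), default=None)

    bmi = col("bmi")
    out["obesity_label"] = np.select(
        [bmi > OBESITY_CUTOFF, bmi > OVERWEIGHT_CUTOFF],
        ["obese", "overweight"],
        default="out_of_cohort",
    )
    out["age_group"] = np.where(col("age") <= YOUNG_MAX_AGE, "young", "older")
    return out
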