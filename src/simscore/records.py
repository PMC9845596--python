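"""Per-subject domain types.

:class:`PatientRecord` holds one subject's raw measurements in SI clinical
units (glucose and lipids in mmol/L, insulin in mIU/L, pressures in mmHg,
waist/height in cm, weight in kg). Optional biomarkers may be ``None``;
every physiological quantity must be strictly positive when present.

:class:`ScorePanel` holds the derived quantities: the siMS score, HOMA-IR,
the fatty liver index (FLI), BMI, the mean OGTT insulin, and natural-log
transforms of the skewed markers used in correlation analyses. Fields are
``None`` whenever their inputs were absent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

from .errors import DomainError

SEXES = ("male", "female")

#: numeric PatientRecord fields that must be strictly positive when present
POSITIVE_FIELDS = (
    "age",
    "weight",
    "height",
    "bmi",
    "waist",
    "sbp",
    "dbp",
    "glucose_0",
    "glucose_30",
    "glucose_120",
    "insulin_0",
    "insulin_30",
    "insulin_120",
    "cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
    "hba1c",
    "crp",
    "pai1",
    "homocysteine",
    "uric_acid",
    "alt",
    "ast",
    "ggt",
    "urea",
    "creatinine",
    "creatinine_clearance",
    "microalbuminuria",
)


@dataclass
class PatientRecord:
    id: str
    sex: str
    age: float
    weight: Optional[float] = None
    height: Optional[float] = None
    bmi: Optional[float] = None  # may be supplied instead of height
    waist: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    glucose_0: Optional[float] = None
    glucose_30: Optional[float] = None
    glucose_120: Optional[float] = None
    insulin_0: Optional[float] = None
    insulin_30: Optional[float] = None
    insulin_120: Optional[float] = None
    cholesterol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    triglycerides: Optional[float] = None
    hba1c: Optional[float] = None
    crp: Optional[float] = None
    pai1: Optional[float] = None
    homocysteine: Optional[float] = None
    uric_acid: Optional[float] = None
    alt: Optional[float] = None
    ast: Optional[float] = None
    ggt: Optional[float] = None
    urea: Optional[float] = None
    creatinine: Optional[float] = None
    creatinine_clearance: Optional[float] = None
    microalbuminuria: Optional[float] = None
    on_lipid_therapy: bool = False
    on_antihypertensive_therapy: bool = False
    known_dm2: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in POSITIVE_FIELDS:
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DomainError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class ScorePanel:
    sims: Optional[float] = None
    homa_ir: Optional[float] = None
    fli: Optional[float] = None
    bmi: Optional[float] = None
    insulin_mean: Optional[float] = None
    log_alt: Optional[float] = None
    log_ggt: Optional[float] = None
    log_fli: Optional[float] = None
    log_crp: Optional[float] = None
    log_homa_ir: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
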