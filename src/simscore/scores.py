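"""Derived metabolic scores.

The central quantity is the **siMS score**, a continuous quantification of
the metabolic syndrome: each syndrome component is divided by its diagnostic
reference value and the ratios are summed, with waist circumference
normalized by body height,

    siMS = 2·WC/height + Gly/5.6 + Tg/1.7 + SBP/130 − HDL/(1.03 ♂ | 1.3 ♀)

where WC and height are in cm, fasting glucose (Gly) and triglycerides (Tg)
in mmol/L, SBP in mmHg and HDL cholesterol in mmol/L. A male subject sitting
exactly at every reference value with WC = height/2 scores 3.0.

Also provided: HOMA-IR (fasting insulin × fasting glucose / 22.5), the fatty
liver index (FLI; logistic score of triglycerides, BMI, GGT and waist, in
[0, 100]), BMI, the unweighted mean of the 0/30/120-min OGTT insulin values,
and natural-log transforms used in correlation screens. Triglycerides enter
the FLI in mmol/L, matching the compressed FLI scale of the cohort these
conventions come from (medians near 5), not the mg/dL convention of the
original FLI literature.

Scalar functions raise :class:`~simscore.errors.DomainError` on non-positive
inputs; the record/table-level wrappers treat missing inputs as missing
outputs and never raise on absent optional biomarkers.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .records import PatientRecord, ScorePanel, SEXES

#: siMS reference (denominator) values
SIMS_GLUCOSE_REF = 5.6  # mmol/L, fasting
SIMS_TG_REF = 1.7  # mmol/L
SIMS_SBP_REF = 130.0  # mmHg
SIMS_HDL_REF = {"male": 1.03, "female": 1.3}  # mmol/L

HOMA_DENOMINATOR = 22.5

_FLI_COEF = (0.953, 0.139, 0.718, 0.053)
_FLI_INTERCEPT = -15.745


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise DomainError(f"{name} must be strictly positive, got {value!r}")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index: weight (kg) divided by squared height (m)."""
    _require_positive(weight=weight, height=height)
    return weight / (height / 100.0) ** 2


def derive_height(weight: float, bmi: float) -> float:
    """Height (cm) implied by weight (kg) and BMI; inverse of :func:`compute_bmi`."""
    _require_positive(weight=weight, bmi=bmi)
    return 100.0 * math.sqrt(weight / bmi)


def compute_sims(
    waist: float,
    height: float,
    glucose_0: float,
    triglycerides: float,
    sbp: float,
    hdl: float,
    sex: str,
) -> float:
    """siMS score (dimensionless). ``glucose_0`` is the fasting OGTT value."""
    _require_positive(
        waist=waist,
        height=height,
        glucose_0=glucose_0,
        triglycerides=triglycerides,
        sbp=sbp,
        hdl=hdl,
    )
    if sex not in SEXES:
        raise DomainError(f"sex must be one of {SEXES}, got {sex!r}")
    return (
        2.0 * waist / height
        + glucose_0 / SIMS_GLUCOSE_REF
        + triglycerides / SIMS_TG_REF
        + sbp / SIMS_SBP_REF
        - hdl / SIMS_HDL_REF[sex]
    )


def compute_homa_ir(insulin_0: float, glucose_0: float) -> float:
    """HOMA-IR: fasting insulin (mIU/L) × fasting glucose (mmol/L) / 22.5."""
    _require_positive(insulin_0=insulin_0, glucose_0=glucose_0)
    return insulin_0 * glucose_0 / HOMA_DENOMINATOR


def compute_fli(triglycerides: float, bmi: float, ggt: float, waist: float) -> float:
    """Fatty liver index in (0, 100); triglycerides in mmol/L, GGT in U/L."""
    _require_positive(triglycerides=triglycerides, bmi=bmi, ggt=ggt, waist=waist)
    a, b, c, d = _FLI_COEF
    z = (
        a * math.log(triglycerides)
        + b * bmi
        + c * math.log(ggt)
        + d * waist
        + _FLI_INTERCEPT
    )
    # logistic in a numerically stable form
    if z >= 0:
        return 100.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return 100.0 * e / (1.0 + e)


def compute_insulin_mean(
    insulin_0: Optional[float],
    insulin_30: Optional[float],
    insulin_120: Optional[float],
) -> Optional[float]:
    """Unweighted mean of the three OGTT insulin samples; None if any is missing."""
    values = (insulin_0, insulin_30, insulin_120)
    if any(v is None for v in values):
        return None
    _require_positive(insulin_0=insulin_0, insulin_30=insulin_30, insulin_120=insulin_120)
    return sum(values) / 3.0


def _log_or_none(value: Optional[float]) -> Optional[float]:
    if value is None or not value > 0:
        return None
    return math.log(value)


def score_record(record: PatientRecord) -> ScorePanel:
    """Compute every derivable panel field for one record.

    Height may be derived from weight and a supplied BMI; BMI from weight and
    height. Fields whose inputs are absent stay ``None`` — a partial panel,
    never an exception. A record that supports the siMS inputs but lacks a
    valid sex cannot occur (:class:`PatientRecord` validates sex on
    construction).
    """
    panel = ScorePanel()

    height = record.height
    bmi = record.bmi
    if bmi is None and record.weight is not None and height is not None:
        bmi = compute_bmi(record.weight, height)
    if height is None and record.weight is not None and bmi is not None:
        height = derive_height(record.weight, bmi)
    panel.bmi = bmi

    sims_inputs = (record.waist, height, record.glucose_0, record.triglycerides,
                   record.sbp, record.hdl)
    if all(v is not None for v in sims_inputs):
        panel.sims = compute_sims(*sims_inputs, record.sex)

    if record.insulin_0 is not None and record.glucose_0 is not None:
        panel.homa_ir = compute_homa_ir(record.insulin_0, record.glucose_0)

    fli_inputs = (record.triglycerides, bmi, record.ggt, record.waist)
    if all(v is not None for v in fli_inputs):
        panel.fli = compute_fli(*fli_inputs)

    panel.insulin_mean = compute_insulin_mean(
        record.insulin_0, record.insulin_30, record.insulin_120
    )

    panel.log_alt = _log_or_none(record.alt)
    panel.log_ggt = _log_or_none(record.ggt)
    panel.log_crp = _log_or_none(record.crp)
    panel.log_fli = _log_or_none(panel.fli)
    panel.log_homa_ir = _log_or_none(panel.homa_ir)
    return panel


# ---------------------------------------------------------------------------
# vectorized table-level scoring


def score_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Append panel columns (bmi, sims, homa_ir, fli, insulin_mean, log_*) to
    a cohort table. Missing inputs propagate as NaN; rows are never dropped.
    """
    out = df.copy()
    n = len(out)

    def col(name: str) -> pd.Series:
        if name in out.columns:
            return pd.to_numeric(out[name], errors="coerce")
        return pd.Series(np.nan, index=out.index)

    weight, height, bmi = col("weight"), col("height"), col("bmi")
    bmi = bmi.where(bmi.notna(), weight / (height / 100.0) ** 2)
    height = height.where(height.notna(), 100.0 * np.sqrt(weight / bmi))
    out["bmi"] = bmi
    out["height"] = height

    if "sex" in out.columns:
        hdl_ref = out["sex"].map(SIMS_HDL_REF)
    else:
        hdl_ref = pd.Series(np.nan, index=out.index)
    out["sims"] = (
        2.0 * col("waist") / height
        + col("glucose_0") / SIMS_GLUCOSE_REF
        + col("triglycerides") / SIMS_TG_REF
        + col("sbp") / SIMS_SBP_REF
        - col("hdl") / hdl_ref
    )
    out["homa_ir"] = col("insulin_0") * col("glucose_0") / HOMA_DENOMINATOR

    a, b, c, d = _FLI_COEF
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (
            a * np.log(col("triglycerides"))
            + b * bmi
            + c * np.log(col("ggt"))
            + d * col("waist")
            + _FLI_INTERCEPT
        )
        out["fli"] = 100.0 * (1.0 / (1.0 + np.exp(-z)))
        out["insulin_mean"] = (col("insulin_0") + col("insulin_30") + col("insulin_120")) / 3.0
        for source, target in (
            ("alt", "log_alt"),
            ("ggt", "log_ggt"),
            ("crp", "log_crp"),
        ):
            values = col(source)
            out[target] = np.where(values > 0, np.log(values), np.nan)
        out["log_fli"] = np.where(out["fli"] > 0, np.log(out["fli"]), np.nan)
        out["log_homa_ir"] = np.where(out["homa_ir"] > 0, np.log(out["homa_ir"]), np.nan)
    assert len(out) == n
    return out
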