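"""Renal-function estimation and chronic-kidney-disease staging.

Two estimators are implemented:

* the short (4-variable) MDRD equation for estimated glomerular filtration
  rate, eGFR = 186 * Scr^-1.154 * age^-0.203 * 0.742 (if female), in
  ml/min/1.73 m^2.  The 186 coefficient is the one applicable to creatinine
  measured with the (non-IDMS-traceable) Jaffe assay; it is configurable for
  IDMS-calibrated laboratories (175).  The Black-ethnicity factor (x1.212) is
  off by default and available as a flag.
* Cockcroft-Gault creatinine clearance,
  CC = (140 - age) * weight / (72 * Scr), x0.85 if female, in ml/min — the
  estimator on which most drug-label renal dosing recommendations are based.

Staging follows the National Kidney Foundation bins applied identically to
either estimate: stage 1 >= 90, stage 2 [60, 90), stage 3 [30, 60),
stage 4 [15, 30), stage 5 < 15.  Bins are half-open at the lower edge, so a
value of exactly 60 is stage 2 and exactly 30 is stage 3.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Sex",
    "Subject",
    "RenalAssessment",
    "egfr_smdrd",
    "cc_cockcroft_gault",
    "convert_creatinine_umol_l",
    "ckd_stage",
    "assess",
    "MDRD_JAFFE_COEFFICIENT",
    "MDRD_IDMS_COEFFICIENT",
]

logger = logging.getLogger(__name__)

MDRD_JAFFE_COEFFICIENT = 186.0
MDRD_IDMS_COEFFICIENT = 175.0
MDRD_FEMALE_FACTOR = 0.742
MDRD_BLACK_FACTOR = 1.212
CG_FEMALE_FACTOR = 0.85

#: mg/dl per umol/l for creatinine.
CREATININE_UMOL_PER_MG_DL = 88.4


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Subject(BaseModel):
    """One person's demographics, chemistry, and optional precomputed metrics.

    ``override_cc_ml_min`` / ``override_egfr`` let callers pin the renal
    metrics exactly (e.g. when reconstructing published table cells); when
    present they take precedence over the formulas and a warning is logged.
    Weight may be omitted only when ``override_cc_ml_min`` is given, since
    Cockcroft-Gault cannot be computed without it.
    """

    subject_id: str
    age_years: float = Field(ge=18, le=120)
    sex: Sex
    weight_kg: Optional[float] = Field(default=None, gt=0)
    serum_creatinine_mg_dl: Optional[float] = Field(default=None, gt=0)
    serum_potassium_mmol_l: Optional[float] = Field(default=None, ge=1.5, le=9.0)
    override_cc_ml_min: Optional[float] = Field(default=None, gt=0)
    override_egfr: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _computable(self) -> "Subject":
        if self.serum_creatinine_mg_dl is None and (
            self.override_cc_ml_min is None or self.override_egfr is None
        ):
            raise ValueError(
                f"subject {self.subject_id!r}: serum creatinine required "
                "unless both renal overrides are given"
            )
        return self


class RenalAssessment(BaseModel):
    """Both renal-function estimates and the corresponding CKD stages."""

    subject_id: str
    egfr_smdrd: float = Field(gt=0)
    cc_cg: float = Field(gt=0)
    stage_smdrd: int = Field(ge=1, le=5)
    stage_cc: int = Field(ge=1, le=5)


def egfr_smdrd(
    scr_mg_dl: float,
    age_years: float,
    sex: Sex,
    *,
    coefficient: float = MDRD_JAFFE_COEFFICIENT,
    black_ethnicity: bool = False,
) -> float:
    """Short-MDRD estimated GFR in ml/min/1.73 m^2."""
    if not scr_mg_dl > 0:
        raise ValueError(f"serum creatinine must be > 0, got {scr_mg_dl}")
    if not 18 <= age_years <= 120:
        raise ValueError(f"age must be in [18, 120] years, got {age_years}")
    val = coefficient * scr_mg_dl ** -1.154 * age_years ** -0.203
    if Sex(sex) is Sex.FEMALE:
        val *= MDRD_FEMALE_FACTOR
    if black_ethnicity:
        val *= MDRD_BLACK_FACTOR
    return val


def cc_cockcroft_gault(
    scr_mg_dl: float, age_years: float, weight_kg: float, sex: Sex
) -> float:
    """Cockcroft-Gault creatinine clearance in ml/min."""
    if not scr_mg_dl > 0:
        raise ValueError(f"serum creatinine must be > 0, got {scr_mg_dl}")
    if not 18 <= age_years < 140:
        raise ValueError(f"age must be in [18, 140) years, got {age_years}")
    if not weight_kg > 0:
        raise ValueError(f"weight must be > 0 kg, got {weight_kg}")
    val = (140.0 - age_years) * weight_kg / (72.0 * scr_mg_dl)
    if Sex(sex) is Sex.FEMALE:
        val *= CG_FEMALE_FACTOR
    return val


def convert_creatinine_umol_l(value_umol_l: float) -> float:
    """Convert serum creatinine from umol/l to mg/dl (divide by 88.4)."""
    if not value_umol_l > 0:
        raise ValueError(f"creatinine must be > 0, got {value_umol_l}")
    return value_umol_l / CREATININE_UMOL_PER_MG_DL


def ckd_stage(estimate: float) -> int:
    """CKD stage 1-5 from a renal-function estimate (either estimator)."""
    if not estimate > 0 or not math.isfinite(estimate):
        raise ValueError(f"renal estimate must be positive and finite, got {estimate}")
    if estimate >= 90:
        return 1
    if estimate >= 60:
        return 2
    if estimate >= 30:
        return 3
    if estimate >= 15:
        return 4
    return 5


def assess(
    subject: Subject,
    *,
    mdrd_coefficient: float = MDRD_JAFFE_COEFFICIENT,
    black_ethnicity: bool = False,
) -> RenalAssessment:
    """Compute both estimates and stages for one subject.

    Override fields, when present, take precedence over the formulas.
    """
    if subject.override_egfr is not None:
        egfr = subject.override_egfr
        logger.warning("subject %s: using override eGFR %.2f", subject.subject_id, egfr)
    else:
        egfr = egfr_smdrd(
            subject.serum_creatinine_mg_dl,
            subject.age_years,
            subject.sex,
            coefficient=mdrd_coefficient,
            black_ethnicity=black_ethnicity,
        )
    if subject.override_cc_ml_min is not None:
        cc = subject.override_cc_ml_min
        logger.warning("subject %s: using override CC %.2f", subject.subject_id, cc)
    else:
        if subject.weight_kg is None:
            raise ValueError(
                f"subject {subject.subject_id!r}: weight required to compute "
                "creatinine clearance and no override_cc_ml_min given"
            )
        cc = cc_cockcroft_gault(
            subject.serum_creatinine_mg_dl,
            subject.age_years,
            subject.weight_kg,
            subject.sex,
        )
    return RenalAssessment(
        subject_id=subject.subject_id,
        egfr_smdrd=egfr,
        cc_cg=cc,
        stage_smdrd=ckd_stage(egfr),
        stage_cc=ckd_stage(cc),
    )
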