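"""Per-drug appropriateness classification under each renal-function estimator.

A regularly taken drug (>= 3 intakes per week) is *potentially inappropriate*
for a subject under a given estimator when the estimate is strictly below the
threshold of at least one applicable rule; a value exactly equal to the
threshold is appropriate (recommendations are written "< X ml/min").  Among
several violated rules, an avoid rule outranks reduce-dose and, within the
same action, the higher threshold is reported — the clinically strongest
violated recommendation.

The two per-estimator verdicts for one (subject, drug) pair combine into one
of four concordance categories; the headline discordance is
"appropriate by sMDRD but inappropriate by CC", the pattern produced when the
eGFR reported by laboratories overlooks a clearance-based dosing rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .renal import RenalAssessment
from .rules import Action, DrugRule, RuleSet, normalize_drug_name

__all__ = [
    "REGULAR_MIN_TIMES_PER_WEEK",
    "Estimator",
    "UseStatus",
    "ConcordanceCategory",
    "DrugExposure",
    "UseClassification",
    "is_regular",
    "classify_drug_use",
    "classify_subject",
    "concordance",
]

#: Regular intake means at least this many intakes per week.
REGULAR_MIN_TIMES_PER_WEEK = 3.0


class Estimator(str, Enum):
    CC = "cc"
    SMDRD = "smdrd"


class UseStatus(str, Enum):
    POTENTIALLY_INAPPROPRIATE = "potentially_inappropriate"
    RENALLY_APPROPRIATE = "renally_appropriate"
    NOT_GOVERNED = "not_governed"


class ConcordanceCategory(str, Enum):
    BOTH_APPROPRIATE = "both_appropriate"
    BOTH_INAPPROPRIATE = "both_inappropriate"
    APPROPRIATE_SMDRD_INAPPROPRIATE_CC = "appropriate_smdrd_inappropriate_cc"
    INAPPROPRIATE_SMDRD_APPROPRIATE_CC = "inappropriate_smdrd_appropriate_cc"


@dataclass(frozen=True)
class DrugExposure:
    """One drug taken by one subject, with weekly intake frequency."""

    subject_id: str
    drug_name: str
    times_per_week: float

    def __post_init__(self) -> None:
        if self.times_per_week < 0:
            raise ValueError(
                f"times_per_week must be >= 0, got {self.times_per_week} "
                f"for {self.drug_name!r}"
            )
        object.__setattr__(self, "drug_name", normalize_drug_name(self.drug_name))

    @property
    def regular(self) -> bool:
        return is_regular(self.times_per_week)


def is_regular(times_per_week: float) -> bool:
    return times_per_week >= REGULAR_MIN_TIMES_PER_WEEK


@dataclass(frozen=True)
class UseClassification:
    """Verdict for one (subject, drug, estimator) triple."""

    subject_id: str
    drug_name: str
    estimator: Estimator
    status: UseStatus
    violated_rule: Optional[DrugRule] = None

    def __post_init__(self) -> None:
        flagged = self.status is UseStatus.POTENTIALLY_INAPPROPRIATE
        if flagged != (self.violated_rule is not None):
            raise ValueError(
                "violated_rule must be present exactly when status is "
                "potentially_inappropriate"
            )


def _rule_severity(rule: DrugRule) -> tuple[int, float]:
    # avoid outranks reduce_dose; then higher threshold
    return (1 if rule.action is Action.AVOID else 0, rule.threshold_ml_min)


def classify_drug_use(
    assessment: RenalAssessment,
    rules: Sequence[DrugRule],
    estimator: Estimator,
    *,
    subject_id: Optional[str] = None,
    drug_name: str = "",
) -> UseClassification:
    """Classify one drug for one subject under one estimator.

    ``rules`` are all the rules applicable to a single drug; an empty
    sequence yields ``NOT_GOVERNED``.  Comparison is strict: the use is
    flagged iff the estimate is < some rule's threshold.
    """
    estimator = Estimator(estimator)
    value = assessment.cc_cg if estimator is Estimator.CC else assessment.egfr_smdrd
    sid = subject_id if subject_id is not None else assessment.subject_id
    if not rules:
        return UseClassification(sid, drug_name, estimator, UseStatus.NOT_GOVERNED)
    violated = [r for r in rules if value < r.threshold_ml_min]
    if not violated:
        return UseClassification(
            sid, drug_name, estimator, UseStatus.RENALLY_APPROPRIATE
        )
    worst = max(violated, key=_rule_severity)
    return UseClassification(
        sid, drug_name, estimator, UseStatus.POTENTIALLY_INAPPROPRIATE, worst
    )


def classify_subject(
    assessment: RenalAssessment,
    exposures: Iterable[DrugExposure],
    rule_set: RuleSet,
) -> list[UseClassification]:
    """Classify every regularly taken drug of one subject, both estimators.

    Non-regular exposures (< 3 times/week) are excluded entirely; regularly
    taken drugs without an applicable rule yield ``NOT_GOVERNED`` entries so
    that "taking at least one analyzed drug" denominators remain computable.
    """
    out: list[UseClassification] = []
    for exp in exposures:
        if exp.subject_id != assessment.subject_id:
            raise ValueError(
                f"exposure for {exp.subject_id!r} passed with assessment "
                f"of {assessment.subject_id!r}"
            )
        if not exp.regular:
            continue
        rules = rule_set.applicable_rules(exp.drug_name)
        for est in (Estimator.CC, Estimator.SMDRD):
            out.append(
                classify_drug_use(
                    assessment, rules, est, drug_name=exp.drug_name
                )
            )
    return out


def concordance(
    class_cc: UseClassification, class_smdrd: UseClassification
) -> ConcordanceCategory:
    """Combine the two per-estimator verdicts for one (subject, drug) pair."""
    if (
        class_cc.subject_id != class_smdrd.subject_id
        or class_cc.drug_name != class_smdrd.drug_name
    ):
        raise ValueError("classifications refer to different subject/drug pairs")
    if class_cc.estimator is not Estimator.CC or class_smdrd.estimator is not Estimator.SMDRD:
        raise ValueError("expected (cc, smdrd) classifications in that order")
    flag_cc = class_cc.status is UseStatus.POTENTIALLY_INAPPROPRIATE
    flag_sm = class_smdrd.status is UseStatus.POTENTIALLY_INAPPROPRIATE
    if flag_cc and flag_sm:
        return ConcordanceCategory.BOTH_INAPPROPRIATE
    if flag_cc:
        return ConcordanceCategory.APPROPRIATE_SMDRD_INAPPROPRIATE_CC
    if flag_sm:
        return ConcordanceCategory.INAPPROPRIATE_SMDRD_APPROPRIATE_CC
    return ConcordanceCategory.BOTH_APPROPRIATE
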