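"""Risky drug-combination detection.

Two combination families are screened:

1. drugs raising the risk of pre-renal kidney injury — NSAIDs, diuretics and
   ACE inhibitors / angiotensin-receptor blockers ("triple whammy" when all
   three are present; ACEI and ARB are merged into a single class, as the
   combination literature treats them);
2. drugs that promote potassium retention — ACEI, ARB, aldosterone
   antagonists, potassium-sparing diuretics, and potassium-containing agents
   — counted as distinct drugs (spironolactone belongs to two of those
   classes but counts once).

Hyperkalaemia is flagged at a configurable serum-potassium cutoff, inclusive,
defaulting to the conventional 5.5 mmol/l.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .rules import (
    NSAID_CLASSES,
    POTASSIUM_RAISING_CLASSES,
    DrugClass,
    RuleSet,
    normalize_drug_name,
)
from .screening import DrugExposure

__all__ = [
    "DEFAULT_HYPERKALAEMIA_THRESHOLD",
    "ComboProfile",
    "prerenal_combo_flags",
    "potassium_drug_count",
    "hyperkalaemia_flag",
    "combo_profile",
]

DEFAULT_HYPERKALAEMIA_THRESHOLD = 5.5  # mmol/l, inclusive


@dataclass(frozen=True)
class ComboProfile:
    """Per-subject combination flags and potassium-raising drug count.

    Pair flags are not mutually exclusive: a subject on triple therapy
    carries all three pair flags and the triple flag.
    """

    subject_id: str
    has_acei_arb: bool = False
    has_diuretic: bool = False
    has_nsaid: bool = False
    pair_acei_arb_diuretic: bool = False
    pair_acei_arb_nsaid: bool = False
    pair_diuretic_nsaid: bool = False
    triple: bool = False
    n_prerenal_drugs: int = 0
    k_drug_count: int = 0
    hyperkalaemia: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.triple and not (
            self.pair_acei_arb_diuretic
            and self.pair_acei_arb_nsaid
            and self.pair_diuretic_nsaid
        ):
            raise ValueError("triple flag requires all three pair flags")


def _regular_names(exposures: Iterable[DrugExposure]) -> set[str]:
    return {normalize_drug_name(e.drug_name) for e in exposures if e.regular}


def prerenal_combo_flags(
    exposures: Iterable[DrugExposure], rule_set: RuleSet, subject_id: str = ""
) -> ComboProfile:
    """Flags for the pre-renal-injury combination (ACEI/ARB, diuretic, NSAID).

    Only regular exposures count.  The NSAID class here includes the
    meloxicam/nimesulide subgroup but never low-dose aspirin.
    """
    taken = _regular_names(exposures)
    acei_arb = rule_set.drugs_in_classes([DrugClass.ACEI, DrugClass.ARB])
    diuretics = rule_set.drugs_in_class(DrugClass.DIURETIC)
    nsaids = rule_set.drugs_in_classes(NSAID_CLASSES)

    has_a = bool(taken & acei_arb)
    has_d = bool(taken & diuretics)
    has_n = bool(taken & nsaids)
    return ComboProfile(
        subject_id=subject_id,
        has_acei_arb=has_a,
        has_diuretic=has_d,
        has_nsaid=has_n,
        pair_acei_arb_diuretic=has_a and has_d,
        pair_acei_arb_nsaid=has_a and has_n,
        pair_diuretic_nsaid=has_d and has_n,
        triple=has_a and has_d and has_n,
        n_prerenal_drugs=len(taken & (acei_arb | diuretics | nsaids)),
    )


def potassium_drug_count(exposures: Iterable[DrugExposure], rule_set: RuleSet) -> int:
    """Number of distinct regularly taken drugs with a potassium-raising class."""
    taken = _regular_names(exposures)
    k_drugs = rule_set.drugs_in_classes(POTASSIUM_RAISING_CLASSES)
    return len(taken & k_drugs)


def hyperkalaemia_flag(
    potassium_mmol_l: Optional[float],
    threshold: float = DEFAULT_HYPERKALAEMIA_THRESHOLD,
) -> Optional[bool]:
    """Inclusive comparison; ``None`` (missing potassium) stays ``None``.

    Subjects with missing potassium are excluded from hyperkalaemia
    denominators downstream rather than silently counted as normal.
    """
    if potassium_mmol_l is None:
        return None
    return potassium_mmol_l >= threshold


def combo_profile(
    exposures: Iterable[DrugExposure],
    rule_set: RuleSet,
    subject_id: str = "",
    potassium_mmol_l: Optional[float] = None,
    hyperkalaemia_threshold: float = DEFAULT_HYPERKALAEMIA_THRESHOLD,
) -> ComboProfile:
    """Full per-subject profile: pre-renal flags + potassium drug count + flag."""
    exposures = list(exposures)
    base = prerenal_combo_flags(exposures, rule_set, subject_id=subject_id)
    return ComboProfile(
        **{
            **base.__dict__,
            "k_drug_count": potassium_drug_count(exposures, rule_set),
            "hyperkalaemia": hyperkalaemia_flag(
                potassium_mmol_l, hyperkalaemia_threshold
            ),
        }
    )
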