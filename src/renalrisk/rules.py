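"""Renal dosing rule knowledge base.

Encodes a curated list of 38 renally risky drugs/drug groups, each carrying an
*avoid* or *reduce-dose* recommendation below a creatinine-clearance threshold
(in ml/min; the same numeric cutoffs are conventionally applied to eGFR values
in ml/min/1.73 m^2 without body-surface de-indexing), plus pharmacological
class tags (ACEI, ARB, diuretic, NSAID, potassium-raising classes) required by
the drug-combination analyses.

The rules file is a flat UTF-8 delimited table (comma or tab, auto-detected
from the header line) with columns ``drug, action, threshold_ml_min, classes,
source``; ``classes`` is a pipe-separated list.  Rows may be threshold rules,
class-tag-only entries (e.g. individual ACE inhibitors that carry no dosing
threshold of their own), or both.  A packaged default encodes the published
38-drug list.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "Action",
    "DrugClass",
    "DrugRule",
    "DrugClassTag",
    "RuleSet",
    "RuleValidationError",
    "load_rules",
    "write_rules",
    "default_rules_path",
]

#: The only thresholds that occur in the curated recommendation list (ml/min).
ALLOWED_THRESHOLDS = frozenset({25.0, 30.0, 35.0, 40.0, 50.0, 60.0, 70.0, 80.0})


class Action(str, enum.Enum):
    """Recommendation type below the threshold."""

    AVOID = "avoid"
    REDUCE_DOSE = "reduce_dose"


class DrugClass(str, enum.Enum):
    """Pharmacological classes used by the combination analyses.

    ``NSAID_MELOXICAM_NIMESULIDE`` is the reporting subgroup (meloxicam and
    nimesulide are tabulated separately from the remaining NSAIDs); both
    subgroups count as NSAIDs for combination logic.  Low-dose aspirin is
    deliberately tagged ``OTHER``: it is never treated as an NSAID.
    """

    NSAID = "nsaid"
    NSAID_MELOXICAM_NIMESULIDE = "nsaid_meloxicam_nimesulide"
    ACEI = "acei"
    ARB = "arb"
    DIURETIC = "diuretic"
    ALDOSTERONE_ANTAGONIST = "aldosterone_antagonist"
    POTASSIUM_SPARING_DIURETIC = "potassium_sparing_diuretic"
    POTASSIUM_CONTAINING_AGENT = "potassium_containing_agent"
    OTHER = "other"


#: Classes whose members raise serum potassium (ACEI + ARB + aldosterone
#: antagonists + potassium-sparing diuretics + potassium-containing agents).
POTASSIUM_RAISING_CLASSES = frozenset(
    {
        DrugClass.ACEI,
        DrugClass.ARB,
        DrugClass.ALDOSTERONE_ANTAGONIST,
        DrugClass.POTASSIUM_SPARING_DIURETIC,
        DrugClass.POTASSIUM_CONTAINING_AGENT,
    }
)

#: Both NSAID subgroups together — the NSAID class for combination logic.
NSAID_CLASSES = frozenset({DrugClass.NSAID, DrugClass.NSAID_MELOXICAM_NIMESULIDE})

#: Name of the group-level NSAID rule entry; its threshold rule applies to any
#: drug tagged with an NSAID class.
NSAID_GROUP_NAME = "nsaids"


class RuleValidationError(ValueError):
    """Raised when a rules file fails schema or invariant validation."""


def normalize_drug_name(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class DrugRule:
    """One avoid/reduce-dose recommendation for one drug or drug group."""

    drug_name: str
    action: Action
    threshold_ml_min: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.threshold_ml_min not in ALLOWED_THRESHOLDS:
            raise RuleValidationError(
                f"rule for {self.drug_name!r}: threshold {self.threshold_ml_min} "
                f"not one of the allowed values {sorted(ALLOWED_THRESHOLDS)}"
            )


@dataclass(frozen=True)
class DrugClassTag:
    """Class membership of one drug (a drug may carry several classes)."""

    drug_name: str
    classes: frozenset[DrugClass]


@dataclass
class RuleSet:
    """Validated collection of threshold rules and class tags.

    A drug may carry multiple rules with distinct thresholds (e.g.
    rivaroxaban: reduce dose < 50 ml/min and avoid < 30 ml/min).
    """

    rules: list[DrugRule] = field(default_factory=list)
    class_tags: list[DrugClassTag] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rules_by_drug: dict[str, list[DrugRule]] = {}
        for r in self.rules:
            self._rules_by_drug.setdefault(r.drug_name, []).append(r)
        for drug, rules in self._rules_by_drug.items():
            thresholds = [r.threshold_ml_min for r in rules]
            if len(set(thresholds)) != len(thresholds):
                raise RuleValidationError(
                    f"duplicate threshold for drug {drug!r}: {thresholds}"
                )
        self._classes_by_drug: dict[str, frozenset[DrugClass]] = {}
        for t in self.class_tags:
            if t.drug_name in self._classes_by_drug:
                raise RuleValidationError(f"duplicate class tag row for {t.drug_name!r}")
            self._classes_by_drug[t.drug_name] = t.classes

    @property
    def governed_drugs(self) -> set[str]:
        """Drugs with at least one threshold rule under their own name."""
        return set(self._rules_by_drug)

    def lookup(self, drug_name: str) -> list[DrugRule]:
        """Exact (case-insensitive, whitespace-normalized) name lookup.

        Returns an empty list when the drug carries no rule under its own
        name — absence is a valid result, not an error.
        """
        return list(self._rules_by_drug.get(normalize_drug_name(drug_name), []))

    def classes_of(self, drug_name: str) -> frozenset[DrugClass]:
        return self._classes_by_drug.get(normalize_drug_name(drug_name), frozenset())

    def applicable_rules(self, drug_name: str) -> list[DrugRule]:
        """Rules governing a drug: its own rules plus group-level rules.

        A drug tagged with an NSAID class inherits the group-level NSAID rule
        even though it has no rule row of its own.
        """
        name = normalize_drug_name(drug_name)
        rules = list(self._rules_by_drug.get(name, []))
        if name != NSAID_GROUP_NAME and self.classes_of(name) & NSAID_CLASSES:
            rules.extend(self._rules_by_drug.get(NSAID_GROUP_NAME, []))
        return rules

    def is_governed(self, drug_name: str) -> bool:
        return bool(self.applicable_rules(drug_name))

    def drugs_in_class(self, class_tag: Union[DrugClass, str]) -> set[str]:
        """All drug names carrying the given class tag."""
        try:
            tag = DrugClass(class_tag)
        except ValueError as exc:
            raise RuleValidationError(f"unknown drug class {class_tag!r}") from exc
        return {d for d, cls in self._classes_by_drug.items() if tag in cls}

    def drugs_in_classes(self, tags: Iterable[Union[DrugClass, str]]) -> set[str]:
        """Union of :meth:`drugs_in_class` over several tags (distinct names)."""
        out: set[str] = set()
        for t in tags:
            out |= self.drugs_in_class(t)
        return out


_COLUMNS = ["drug", "action", "threshold_ml_min", "classes", "source"]


def default_rules_path() -> Path:
    """Path of the packaged default rules table."""
    return Path(resources.files("renalrisk") / "data" / "table1_rules.csv")


def _detect_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    return ","


def load_rules(path: Union[str, Path, None] = None) -> RuleSet:
    """Load and validate a rules file; ``None`` loads the packaged default.

    Raises :class:`RuleValidationError` naming the offending row and field on
    malformed input.  An empty rules file (header only) yields an empty
    RuleSet without error.
    """
    src = Path(path) if path is not None else default_rules_path()
    text = src.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise RuleValidationError(f"rules file {src} is empty (no header)")
    delim = _detect_delimiter(lines[0])
    header = [h.strip().lower() for h in lines[0].split(delim)]
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise RuleValidationError(f"rules file {src}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in _COLUMNS}

    rules: list[DrugRule] = []
    tags: dict[str, set[DrugClass]] = {}
    for row_no, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        drug = normalize_drug_name(cells[idx["drug"]])
        if not drug:
            raise RuleValidationError(f"row {row_no}: empty drug name")
        action_raw = cells[idx["action"]]
        thr_raw = cells[idx["threshold_ml_min"]]
        classes_raw = cells[idx["classes"]]
        source = cells[idx["source"]]

        if bool(action_raw) != bool(thr_raw):
            raise RuleValidationError(
                f"row {row_no} ({drug}): action and threshold_ml_min must be "
                "given together"
            )
        if action_raw:
            try:
                action = Action(action_raw.lower())
            except ValueError:
                raise RuleValidationError(
                    f"row {row_no} ({drug}): unknown action {action_raw!r}"
                ) from None
            try:
                threshold = float(thr_raw)
            except ValueError:
                raise RuleValidationError(
                    f"row {row_no} ({drug}): threshold_ml_min {thr_raw!r} is not a number"
                ) from None
            try:
                rules.append(DrugRule(drug, action, threshold, source))
            except RuleValidationError as exc:
                raise RuleValidationError(f"row {row_no}: {exc}") from None
        elif not classes_raw:
            raise RuleValidationError(
                f"row {row_no} ({drug}): row carries neither a rule nor a class tag"
            )
        if classes_raw:
            cls: set[DrugClass] = set()
            for c in classes_raw.split("|"):
                try:
                    cls.add(DrugClass(c.strip().lower()))
                except ValueError:
                    raise RuleValidationError(
                        f"row {row_no} ({drug}): unknown class {c.strip()!r}"
                    ) from None
            tags.setdefault(drug, set()).update(cls)

    return RuleSet(
        rules=rules,
        class_tags=[DrugClassTag(d, frozenset(c)) for d, c in sorted(tags.items())],
    )


def write_rules(rule_set: RuleSet, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a RuleSet back to the flat-table format (round-trips with load)."""
    by_drug_rules: dict[str, list[DrugRule]] = {}
    for r in rule_set.rules:
        by_drug_rules.setdefault(r.drug_name, []).append(r)
    tag_map = {t.drug_name: t.classes for t in rule_set.class_tags}

    buf = io.StringIO()
    buf.write(delimiter.join(_COLUMNS) + "\n")
    written_tags: set[str] = set()
    for drug in sorted(set(by_drug_rules) | set(tag_map)):
        cls = "|".join(sorted(c.value for c in tag_map.get(drug, frozenset())))
        rules = by_drug_rules.get(drug, [])
        if rules:
            for i, r in enumerate(sorted(rules, key=lambda x: -x.threshold_ml_min)):
                row_cls = cls if i == 0 else ""
                buf.write(
                    delimiter.join(
                        [
                            drug,
                            r.action.value,
                            f"{r.threshold_ml_min:g}",
                            row_cls,
                            r.source,
                        ]
                    )
                    + "\n"
                )
        else:
            buf.write(delimiter.join([drug, "", "", cls, "class-list"]) + "\n")
        written_tags.add(drug)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
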