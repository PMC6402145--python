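"""Cohort-level tables: staging, drug use, combinations, potassium, hyperkalaemia.

The report mirrors the five-table layout of population screening studies:

* a CKD staging table (counts and percentages per stage, per estimator);
* a per-drug use table — total users, potentially inappropriate and renally
  appropriate users with the percentages of subjects below/above each drug's
  threshold, the inappropriate share among users, and the discordant share
  (appropriate by sMDRD yet inappropriate by creatinine clearance);
* a pre-renal combination table (ACEI/ARB + diuretic + NSAID pairs and the
  triple), overall and stratified at 60 ml/min under each estimator;
* the distribution of concurrently taken potassium-raising drugs; and
* hyperkalaemia prevalence by potassium-drug count and stratum, with a
  Cochran-Armitage trend test per stratum.

All percentages are stored as full-precision floats (render at 2 decimals);
counts are never rounded.  Per-table significance uses the Yates-corrected
chi-square at a configurable alpha (default 0.05) with no multiple-testing
correction.  Pair rows of the combination table overlap by design: a subject
on triple therapy appears in all three pair rows and in the triple row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import renal
from .combos import DEFAULT_HYPERKALAEMIA_THRESHOLD, ComboProfile, combo_profile
from .renal import RenalAssessment, Sex, Subject
from .rules import NSAID_CLASSES, Action, DrugClass, RuleSet, load_rules, normalize_drug_name
from .screening import (
    REGULAR_MIN_TIMES_PER_WEEK,
    DrugExposure,
    UseClassification,
)
from .stats import chi2_trend, chi2_yates

__all__ = [
    "CohortReport",
    "ReportError",
    "subjects_to_frame",
    "exposures_to_frame",
    "assess_cohort",
    "staging_table",
    "drug_use_table",
    "combo_table",
    "potassium_tables",
    "build_report",
]

STRATA = ["cc_lt60", "cc_ge60", "smdrd_lt60", "smdrd_ge60"]
STRATIFICATION_CUTOFF = 60.0  # ml/min or ml/min/1.73 m^2

_SUBJECT_COLUMNS = [
    "subject_id",
    "age_years",
    "sex",
    "weight_kg",
    "serum_creatinine_mg_dl",
    "serum_potassium_mmol_l",
    "override_cc_ml_min",
    "override_egfr",
]


class ReportError(RuntimeError):
    """Raised when a pipeline stage cannot proceed; message names the stage."""


# ---------------------------------------------------------------------------
# input coercion


def subjects_to_frame(
    subjects: Union[pd.DataFrame, Iterable[Union[Subject, Mapping[str, Any]]]],
) -> pd.DataFrame:
    """Coerce subjects (DataFrame, Subject objects, or dicts) to a frame.

    Unlike :class:`~renalrisk.renal.Subject`, the frame may contain
    incomplete rows (missing creatinine or weight) — those are excluded, with
    reasons, by :func:`assess_cohort`, mirroring how population studies drop
    subjects without blood samples or anthropometrics.
    """
    if isinstance(subjects, pd.DataFrame):
        df = subjects.copy()
    else:
        rows = []
        for s in subjects:
            if isinstance(s, Subject):
                rows.append(s.model_dump())
            else:
                rows.append(dict(s))
        df = pd.DataFrame(rows)
    if "subject_id" not in df.columns:
        raise ReportError("subjects input lacks a subject_id column")
    for col in _SUBJECT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_SUBJECT_COLUMNS]
    df["subject_id"] = df["subject_id"].astype(str)
    df["sex"] = df["sex"].map(lambda s: Sex(s).value if pd.notna(s) else np.nan)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].unique()[:5]
        raise ReportError(f"duplicate subject_id values: {list(dupes)}")
    return df


def exposures_to_frame(
    exposures: Union[pd.DataFrame, Iterable[DrugExposure]],
) -> pd.DataFrame:
    """Coerce exposures to a frame; duplicate (subject, drug) rows keep the
    maximum times_per_week."""
    if isinstance(exposures, pd.DataFrame):
        df = exposures.copy()
        needed = {"subject_id", "drug_name", "times_per_week"}
        missing = needed - set(df.columns)
        if missing:
            raise ReportError(f"exposures input lacks column(s) {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [
                {
                    "subject_id": e.subject_id,
                    "drug_name": e.drug_name,
                    "times_per_week": e.times_per_week,
                }
                for e in exposures
            ],
            columns=["subject_id", "drug_name", "times_per_week"],
        )
    df["subject_id"] = df["subject_id"].astype(str)
    df["drug_name"] = df["drug_name"].map(normalize_drug_name)
    df["times_per_week"] = pd.to_numeric(df["times_per_week"])
    df = (
        df.groupby(["subject_id", "drug_name"], as_index=False)["times_per_week"]
        .max()
        .reset_index(drop=True)
    )
    return df


# ---------------------------------------------------------------------------
# cohort assessment


def _stage_vector(values: np.ndarray) -> np.ndarray:
    bins = np.select(
        [values >= 90, values >= 60, values >= 30, values >= 15],
        [1, 2, 3, 4],
        default=5,
    )
    return bins.astype(int)


def assess_cohort(
    subjects: pd.DataFrame,
    *,
    mdrd_coefficient: float = renal.MDRD_JAFFE_COEFFICIENT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized renal assessment of a cohort frame.

    Returns ``(assessments, exclusions)``.  ``assessments`` has one row per
    analyzable subject (subject_id, egfr_smdrd, cc_cg, stage_smdrd, stage_cc,
    serum_potassium_mmol_l); ``exclusions`` lists dropped subjects with a
    reason each.  Equivalent, subject by subject, to
    :func:`renalrisk.renal.assess` (property-tested).
    """
    df = subjects
    reasons = pd.Series("", index=df.index, dtype=object)

    has_scr = df["serum_creatinine_mg_dl"].notna() & (
        df["serum_creatinine_mg_dl"] > 0
    )
    has_weight = df["weight_kg"].notna() & (df["weight_kg"] > 0)
    has_age = df["age_years"].notna() & df["age_years"].between(18, 120)
    has_sex = df["sex"].notna()
    ov_egfr = df["override_egfr"].notna()
    ov_cc = df["override_cc_ml_min"].notna()

    need_formula_egfr = ~ov_egfr
    need_formula_cc = ~ov_cc
    ok = pd.Series(True, index=df.index)

    bad_scr = (need_formula_egfr | need_formula_cc) & ~has_scr
    reasons[bad_scr] = "missing serum creatinine"
    ok &= ~bad_scr
    bad_anthro = need_formula_cc & ~bad_scr & ~has_weight
    reasons[bad_anthro] = "missing anthropometrics"
    ok &= ~bad_anthro
    bad_demo = ok & ((need_formula_egfr | need_formula_cc) & ~(has_age & has_sex))
    reasons[bad_demo] = "missing or out-of-range age/sex"
    ok &= ~bad_demo

    excl = pd.DataFrame(
        {"subject_id": df.loc[~ok, "subject_id"], "reason": reasons[~ok]}
    ).reset_index(drop=True)

    kept = df[ok]
    if kept.empty:
        raise ReportError(
            f"assessment stage: no analyzable subjects remain "
            f"({len(excl)} excluded: {excl['reason'].value_counts().to_dict()})"
        )

    scr = kept["serum_creatinine_mg_dl"].to_numpy(dtype=float)
    age = kept["age_years"].to_numpy(dtype=float)
    female = (kept["sex"] == Sex.FEMALE.value).to_numpy()

    with np.errstate(invalid="ignore"):
        egfr = mdrd_coefficient * scr**-1.154 * age**-0.203
        egfr = np.where(female, egfr * renal.MDRD_FEMALE_FACTOR, egfr)
        weight = kept["weight_kg"].to_numpy(dtype=float)
        cc = (140.0 - age) * weight / (72.0 * scr)
        cc = np.where(female, cc * renal.CG_FEMALE_FACTOR, cc)

    egfr = np.where(ov_egfr[ok], kept["override_egfr"].to_numpy(dtype=float), egfr)
    cc = np.where(ov_cc[ok], kept["override_cc_ml_min"].to_numpy(dtype=float), cc)

    assessments = pd.DataFrame(
        {
            "subject_id": kept["subject_id"].to_numpy(),
            "egfr_smdrd": egfr,
            "cc_cg": cc,
            "stage_smdrd": _stage_vector(egfr),
            "stage_cc": _stage_vector(cc),
            "serum_potassium_mmol_l": kept["serum_potassium_mmol_l"].to_numpy(
                dtype=float
            ),
        }
    ).reset_index(drop=True)
    return assessments, excl


def _assessments_frame(
    assessments: Union[pd.DataFrame, Iterable[RenalAssessment]],
) -> pd.DataFrame:
    if isinstance(assessments, pd.DataFrame):
        return assessments
    rows = [a.model_dump() for a in assessments]
    df = pd.DataFrame(rows)
    if "serum_potassium_mmol_l" not in df.columns:
        df["serum_potassium_mmol_l"] = np.nan
    return df


# ---------------------------------------------------------------------------
# tables


def staging_table(
    assessments: Union[pd.DataFrame, Iterable[RenalAssessment]],
) -> pd.DataFrame:
    """Counts and percentages per CKD stage for both estimators."""
    df = _assessments_frame(assessments)
    if df.empty:
        raise ReportError("staging stage: empty cohort")
    n = len(df)
    out = pd.DataFrame(index=pd.Index([1, 2, 3, 4, 5], name="ckd_stage"))
    for est, col in (("smdrd", "stage_smdrd"), ("cc", "stage_cc")):
        counts = df[col].value_counts().reindex(out.index, fill_value=0)
        out[f"{est}_n"] = counts.astype(int)
        out[f"{est}_pct"] = 100.0 * counts / n
    return out


def _drug_user_sets(
    exposures: pd.DataFrame, rule_set: RuleSet
) -> list[tuple[str, Action, float, set[str]]]:
    """Rows of the drug-use table: (label, action, threshold, user ids).

    Drugs with their own threshold rules get one row per rule.  Drugs
    governed only through the NSAID group rule are folded into two aggregate
    rows (plain NSAIDs, and the meloxicam/nimesulide subgroup), mirroring how
    the published tables split the class.
    """
    regular = exposures[exposures["times_per_week"] >= REGULAR_MIN_TIMES_PER_WEEK]
    users_by_drug = regular.groupby("drug_name")["subject_id"].agg(set)

    rows: list[tuple[str, Action, float, set[str]]] = []
    nsaid_plain = rule_set.drugs_in_class(DrugClass.NSAID)
    nsaid_special = rule_set.drugs_in_class(DrugClass.NSAID_MELOXICAM_NIMESULIDE)
    group_rules = rule_set.lookup("nsaids")

    for drug in sorted(set(users_by_drug.index) & rule_set.governed_drugs):
        if drug == "nsaids":
            continue  # folded into the aggregate NSAID row
        for rule in sorted(rule_set.lookup(drug), key=lambda r: -r.threshold_ml_min):
            rows.append((drug, rule.action, rule.threshold_ml_min, users_by_drug[drug]))

    def _group_users(members: set[str]) -> set[str]:
        out: set[str] = set()
        for d in members:
            out |= users_by_drug.get(d, set())
        return out

    if group_rules:
        rule = group_rules[0]
        plain_users = _group_users(nsaid_plain | {"nsaids"})
        special_users = _group_users(nsaid_special)
        if plain_users:
            rows.append(("nsaids", rule.action, rule.threshold_ml_min, plain_users))
        if special_users:
            rows.append(
                (
                    "meloxicam and nimesulide",
                    rule.action,
                    rule.threshold_ml_min,
                    special_users,
                )
            )
    return rows


def drug_use_table(
    classifications: Optional[Sequence[UseClassification]],
    exposures: Union[pd.DataFrame, Iterable[DrugExposure]],
    assessments: Union[pd.DataFrame, Iterable[RenalAssessment]],
    rule_set: RuleSet,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-drug use table with both estimators and the discordant column.

    ``classifications`` may be ``None``; the table is computed directly from
    exposures, assessments and the rule thresholds (one row per rule for
    multi-rule drugs).  Denominators: "% below threshold" uses the analyzable
    subjects whose estimate falls below that drug's threshold; "% of users"
    uses the drug's regular users.  The conservation invariant
    inappropriate + appropriate = users is asserted on every run.
    """
    adf = _assessments_frame(assessments)
    edf = exposures_to_frame(exposures)
    n_total = len(adf)
    if n_total == 0:
        raise ReportError("drug-use stage: empty cohort")
    cc = adf.set_index("subject_id")["cc_cg"]
    egfr = adf.set_index("subject_id")["egfr_smdrd"]
    edf = edf[edf["subject_id"].isin(cc.index)]

    records = []
    for label, action, thr, users in _drug_user_sets(edf, rule_set):
        uids = pd.Index(sorted(users))
        rec: dict[str, Any] = {
            "drug": label,
            "action": action.value,
            "threshold_ml_min": thr,
            "users_n": len(uids),
            "users_pct": 100.0 * len(uids) / n_total,
        }
        user_cc = cc.loc[uids]
        user_egfr = egfr.loc[uids]
        for est, values, user_values in (
            ("cc", cc, user_cc),
            ("smdrd", egfr, user_egfr),
        ):
            below_n = int((values < thr).sum())
            above_n = n_total - below_n
            inapp_n = int((user_values < thr).sum())
            app_n = len(uids) - inapp_n
            assert inapp_n + app_n == len(uids)
            rec[f"{est}_inappropriate_n"] = inapp_n
            rec[f"{est}_inappropriate_pct_below"] = (
                100.0 * inapp_n / below_n if below_n else np.nan
            )
            rec[f"{est}_appropriate_n"] = app_n
            rec[f"{est}_appropriate_pct_above"] = (
                100.0 * app_n / above_n if above_n else np.nan
            )
            rec[f"{est}_inappropriate_pct_users"] = (
                100.0 * inapp_n / len(uids) if len(uids) else np.nan
            )
            # user prevalence below vs above the threshold
            a, b = inapp_n, below_n - inapp_n
            c, d = app_n, above_n - app_n
            try:
                _, p = chi2_yates(a, b, c, d)
            except ValueError:
                p = np.nan
            rec[f"{est}_p"] = p
            rec[f"{est}_significant"] = bool(p < alpha) if np.isfinite(p) else False
        disc = int(((user_cc < thr) & (user_egfr >= thr)).sum())
        rec["discordant_n"] = disc
        rec["discordant_pct_users"] = 100.0 * disc / len(uids) if len(uids) else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _strata_masks(adf: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "cc_lt60": adf["cc_cg"] < STRATIFICATION_CUTOFF,
        "cc_ge60": adf["cc_cg"] >= STRATIFICATION_CUTOFF,
        "smdrd_lt60": adf["egfr_smdrd"] < STRATIFICATION_CUTOFF,
        "smdrd_ge60": adf["egfr_smdrd"] >= STRATIFICATION_CUTOFF,
    }


def _profiles_frame(profiles: Iterable[ComboProfile]) -> pd.DataFrame:
    df = pd.DataFrame([p.__dict__ for p in profiles])
    if df.empty:
        raise ReportError("combination stage: no profiles")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


COMBO_ROWS = [
    ("acei_arb_diuretic", "pair_acei_arb_diuretic"),
    ("acei_arb_nsaid", "pair_acei_arb_nsaid"),
    ("diuretic_nsaid", "pair_diuretic_nsaid"),
    ("acei_arb_diuretic_nsaid", "triple"),
]


def combo_table(
    profiles: Iterable[ComboProfile],
    assessments: Union[pd.DataFrame, Iterable[RenalAssessment]],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pre-renal combination rows, overall and per 60 ml/min stratum."""
    pdf = _profiles_frame(profiles).set_index("subject_id")
    adf = _assessments_frame(assessments).set_index("subject_id")
    pdf = pdf.reindex(adf.index, fill_value=False)
    masks = _strata_masks(adf)
    n_total = len(adf)

    records = []
    for label, flag_col in COMBO_ROWS:
        flags = pdf[flag_col].astype(bool)
        rec: dict[str, Any] = {
            "combination": label,
            "total_n": int(flags.sum()),
            "total_pct": 100.0 * flags.sum() / n_total,
        }
        for stratum, mask in masks.items():
            k = int((flags & mask.to_numpy()).sum())
            n = int(mask.sum())
            rec[f"{stratum}_n"] = k
            rec[f"{stratum}_pct"] = 100.0 * k / n if n else np.nan
        for est in ("cc", "smdrd"):
            a = rec[f"{est}_lt60_n"]
            b = int(masks[f"{est}_lt60"].sum()) - a
            c = rec[f"{est}_ge60_n"]
            d = int(masks[f"{est}_ge60"].sum()) - c
            try:
                _, p = chi2_yates(a, b, c, d)
            except ValueError:
                p = np.nan
            rec[f"{est}_p"] = p
            rec[f"{est}_significant"] = bool(p < alpha) if np.isfinite(p) else False
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("combination")


K_COUNT_LEVELS = [1, 2, 3, 4]  # level 4 pools counts >= 4


def potassium_tables(
    profiles: Iterable[ComboProfile],
    assessments: Union[pd.DataFrame, Iterable[RenalAssessment]],
    *,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Potassium-raising drug count distribution and hyperkalaemia prevalence.

    Returns ``(k_counts, hyperkalaemia, trend)``.  Hyperkalaemia denominators
    include only subjects with a defined flag (non-missing potassium);
    subjects taking zero potassium-raising drugs are not tabulated.  The
    trend table carries the Cochran-Armitage statistic over drug count
    (groups with zero total dropped) per stratum.
    """
    pdf = _profiles_frame(profiles).set_index("subject_id")
    adf = _assessments_frame(assessments).set_index("subject_id")
    pdf = pdf.reindex(adf.index)
    pdf["k_drug_count"] = pdf["k_drug_count"].fillna(0).astype(int)
    masks = _strata_masks(adf)
    n_total = len(adf)
    level = pdf["k_drug_count"].clip(upper=4)

    k_records = []
    for lev in K_COUNT_LEVELS:
        sel = (level == lev).to_numpy()
        rec: dict[str, Any] = {
            "k_drug_count": lev,
            "total_n": int(sel.sum()),
            "total_pct": 100.0 * sel.sum() / n_total,
        }
        for stratum, mask in masks.items():
            k = int((sel & mask.to_numpy()).sum())
            n = int(mask.sum())
            rec[f"{stratum}_n"] = k
            rec[f"{stratum}_pct"] = 100.0 * k / n if n else np.nan
        k_records.append(rec)
    k_counts = pd.DataFrame.from_records(k_records).set_index("k_drug_count")

    flag = pdf["hyperkalaemia"]
    defined = flag.notna().to_numpy()
    flag_true = flag.eq(True).to_numpy()

    h_records = []
    for lev in K_COUNT_LEVELS:
        sel = (level == lev).to_numpy() & defined
        rec = {"k_drug_count": lev}
        for stratum, mask in masks.items():
            m = sel & mask.to_numpy()
            n = int(m.sum())
            k = int((m & flag_true).sum())
            rec[f"{stratum}_k"] = k
            rec[f"{stratum}_n"] = n
            rec[f"{stratum}_pct"] = 100.0 * k / n if n else np.nan
        for est in ("cc", "smdrd"):
            a, b = rec[f"{est}_lt60_k"], rec[f"{est}_lt60_n"] - rec[f"{est}_lt60_k"]
            c, d = rec[f"{est}_ge60_k"], rec[f"{est}_ge60_n"] - rec[f"{est}_ge60_k"]
            try:
                _, p = chi2_yates(a, b, c, d)
            except ValueError:
                p = np.nan
            rec[f"{est}_p"] = p
            rec[f"{est}_significant"] = bool(p < alpha) if np.isfinite(p) else False
        h_records.append(rec)
    hyper = pd.DataFrame.from_records(h_records).set_index("k_drug_count")

    t_records = []
    for stratum in STRATA:
        successes = hyper[f"{stratum}_k"].tolist()
        totals = hyper[f"{stratum}_n"].tolist()
        try:
            stat, p = chi2_trend(successes, totals)
        except ValueError:
            stat, p = np.nan, np.nan
        t_records.append(
            {
                "stratum": stratum,
                "statistic": stat,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    trend = pd.DataFrame.from_records(t_records).set_index("stratum")
    return k_counts, hyper, trend


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class CohortReport:
    """Assembled cohort tables plus run metadata (JSON-serializable)."""

    staging: pd.DataFrame
    drug_use: pd.DataFrame
    combos: pd.DataFrame
    k_counts: pd.DataFrame
    hyperkalaemia: pd.DataFrame
    hyperkalaemia_trend: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    _TABLES = (
        "staging",
        "drug_use",
        "combos",
        "k_counts",
        "hyperkalaemia",
        "hyperkalaemia_trend",
    )

    @staticmethod
    def _native(v: Any) -> Any:
        if v is None or (np.isscalar(v) and pd.isna(v)):
            return None
        if isinstance(v, (np.bool_, bool)):
            return bool(v)
        if isinstance(v, np.integer):
            return int(v)
        if isinstance(v, np.floating):
            return float(v)
        return v

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"metadata": self.metadata}
        for name in self._TABLES:
            df: pd.DataFrame = getattr(self, name)
            df = df.reset_index(drop=df.index.name is None)
            out[name] = {
                "columns": list(df.columns),
                "rows": [
                    [self._native(v) for v in row]
                    for row in df.to_numpy(dtype=object)
                ],
            }
        return out

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "CohortReport":
        kwargs: dict[str, Any] = {"metadata": dict(payload["metadata"])}
        index_cols = {
            "staging": "ckd_stage",
            "combos": "combination",
            "k_counts": "k_drug_count",
            "hyperkalaemia": "k_drug_count",
            "hyperkalaemia_trend": "stratum",
        }
        for name in cls._TABLES:
            tbl = payload[name]
            df = pd.DataFrame(tbl["rows"], columns=tbl["columns"])
            if name in index_cols:
                df = df.set_index(index_cols[name])
            kwargs[name] = df
        return cls(**kwargs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortReport):
            return NotImplemented
        return json.dumps(self.to_dict(), default=str) == json.dumps(
            other.to_dict(), default=str
        )


def build_report(
    subjects: Union[pd.DataFrame, Iterable[Union[Subject, Mapping[str, Any]]]],
    exposures: Union[pd.DataFrame, Iterable[DrugExposure]],
    rule_set: Optional[RuleSet] = None,
    *,
    hyperkalaemia_threshold: float = DEFAULT_HYPERKALAEMIA_THRESHOLD,
    alpha: float = 0.05,
    mdrd_coefficient: float = renal.MDRD_JAFFE_COEFFICIENT,
    seed: Optional[int] = None,
) -> CohortReport:
    """Run the full pipeline: assess, classify, profile, tabulate.

    Subjects that cannot be assessed (missing creatinine or anthropometrics
    without overrides) are excluded and counted in the metadata, never
    silently dropped.  Deterministic: the same inputs give a bit-identical
    report.
    """
    if rule_set is None:
        rule_set = load_rules()
    sdf = subjects_to_frame(subjects)
    edf = exposures_to_frame(exposures)
    assessments, exclusions = assess_cohort(sdf, mdrd_coefficient=mdrd_coefficient)

    known = set(sdf["subject_id"])
    orphans = sorted(set(edf["subject_id"]) - known)
    edf = edf[edf["subject_id"].isin(set(assessments["subject_id"]))]

    regular = edf[edf["times_per_week"] >= REGULAR_MIN_TIMES_PER_WEEK]
    k_map = assessments.set_index("subject_id")["serum_potassium_mmol_l"]
    grouped = {
        sid: grp for sid, grp in regular.groupby("subject_id")
    }
    profiles = []
    for sid in assessments["subject_id"]:
        grp = grouped.get(sid)
        exp = (
            [
                DrugExposure(sid, r.drug_name, r.times_per_week)
                for r in grp.itertuples()
            ]
            if grp is not None
            else []
        )
        k_val = k_map.loc[sid]
        profiles.append(
            combo_profile(
                exp,
                rule_set,
                subject_id=sid,
                potassium_mmol_l=None if pd.isna(k_val) else float(k_val),
                hyperkalaemia_threshold=hyperkalaemia_threshold,
            )
        )

    k_counts, hyper, trend = potassium_tables(profiles, assessments, alpha=alpha)
    report = CohortReport(
        staging=staging_table(assessments),
        drug_use=drug_use_table(None, edf, assessments, rule_set, alpha=alpha),
        combos=combo_table(profiles, assessments, alpha=alpha),
        k_counts=k_counts,
        hyperkalaemia=hyper,
        hyperkalaemia_trend=trend,
        metadata={
            "n_input": int(len(sdf)),
            "n_analyzable": int(len(assessments)),
            "n_excluded": int(len(exclusions)),
            "exclusion_reasons": exclusions["reason"].value_counts().to_dict(),
            "orphan_exposure_subjects": orphans,
            "hyperkalaemia_threshold_mmol_l": hyperkalaemia_threshold,
            "stratification_cutoff": STRATIFICATION_CUTOFF,
            "alpha": alpha,
            "mdrd_coefficient": mdrd_coefficient,
            "n_rules": len(rule_set.rules),
            "n_governed_drugs": len(rule_set.governed_drugs),
            "seed": seed,
        },
    )
    return report
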