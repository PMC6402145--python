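"""Appropriateness classification and estimator concordance."""

import numpy as np
import pytest

from renalrisk.renal import RenalAssessment
from renalrisk.rules import Action, DrugRule
from renalrisk.screening import (
    ConcordanceCategory,
    DrugExposure,
    Estimator,
    UseClassification,
    UseStatus,
    classify_drug_use,
    classify_subject,
    concordance,
)


def make_assessment(cc: float, egfr: float, sid: str = "s") -> RenalAssessment:
    from renalrisk.renal import ckd_stage

    return RenalAssessment(
        subject_id=sid,
        egfr_smdrd=egfr,
        cc_cg=cc,
        stage_smdrd=ckd_stage(egfr),
        stage_cc=ckd_stage(cc),
    )


DIGOXIN = DrugRule("digoxin", Action.REDUCE_DOSE, 50.0)
RIVA_REDUCE = DrugRule("rivaroxaban", Action.REDUCE_DOSE, 50.0)
RIVA_AVOID = DrugRule("rivaroxaban", Action.AVOID, 30.0)


class TestClassifyDrugUse:
    def test_below_threshold_flagged(self):
        c = classify_drug_use(make_assessment(45, 70), [DIGOXIN], Estimator.CC)
        assert c.status is UseStatus.POTENTIALLY_INAPPROPRIATE
        assert c.violated_rule == DIGOXIN

    def test_exact_threshold_is_appropriate(self):
        # recommendations are written "< X ml/min": strict comparison
        c = classify_drug_use(make_assessment(50, 70), [DIGOXIN], Estimator.CC)
        assert c.status is UseStatus.RENALLY_APPROPRIATE
        assert c.violated_rule is None

    def test_severity_precedence_avoid_over_reduce(self):
        c = classify_drug_use(
            make_assessment(25, 70), [RIVA_REDUCE, RIVA_AVOID], Estimator.CC
        )
        assert c.status is UseStatus.POTENTIALLY_INAPPROPRIATE
        assert c.violated_rule == RIVA_AVOID

    def test_between_thresholds_only_reduce_violated(self):
        c = classify_drug_use(
            make_assessment(40, 70), [RIVA_REDUCE, RIVA_AVOID], Estimator.CC
        )
        assert c.violated_rule == RIVA_REDUCE

    def test_higher_threshold_wins_within_same_action(self):
        r60 = DrugRule("x", Action.REDUCE_DOSE, 60.0)
        r30 = DrugRule("x", Action.REDUCE_DOSE, 30.0)
        c = classify_drug_use(make_assessment(20, 70), [r30, r60], Estimator.CC)
        assert c.violated_rule == r60

    def test_no_rules_not_governed(self):
        c = classify_drug_use(make_assessment(10, 10), [], Estimator.CC)
        assert c.status is UseStatus.NOT_GOVERNED

    def test_smdrd_estimator_uses_egfr(self):
        c = classify_drug_use(make_assessment(80, 45), [DIGOXIN], Estimator.SMDRD)
        assert c.status is UseStatus.POTENTIALLY_INAPPROPRIATE


class TestClassifySubject:
    def test_nonregular_exposures_excluded(self, default_rules):
        a = make_assessment(40, 40)
        out = classify_subject(
            a, [DrugExposure("s", "digoxin", 2)], default_rules
        )
        assert out == []

    def test_metformin_both_estimators(self, default_rules):
        a = make_assessment(40, 55)
        out = classify_subject(a, [DrugExposure("s", "metformin", 7)], default_rules)
        assert len(out) == 2
        statuses = {c.estimator: c.status for c in out}
        assert statuses[Estimator.CC] is UseStatus.POTENTIALLY_INAPPROPRIATE
        assert statuses[Estimator.SMDRD] is UseStatus.POTENTIALLY_INAPPROPRIATE

    def test_one_side_of_threshold_each(self, default_rules):
        a = make_assessment(55, 65)
        out = classify_subject(a, [DrugExposure("s", "metformin", 7)], default_rules)
        statuses = {c.estimator: c.status for c in out}
        assert statuses[Estimator.CC] is UseStatus.POTENTIALLY_INAPPROPRIATE
        assert statuses[Estimator.SMDRD] is UseStatus.RENALLY_APPROPRIATE
        cat = concordance(
            next(c for c in out if c.estimator is Estimator.CC),
            next(c for c in out if c.estimator is Estimator.SMDRD),
        )
        assert cat is ConcordanceCategory.APPROPRIATE_SMDRD_INAPPROPRIATE_CC

    def test_ungoverned_drug_retained_as_not_governed(self, default_rules):
        a = make_assessment(40, 40)
        out = classify_subject(a, [DrugExposure("s", "vitamin c", 7)], default_rules)
        assert {c.status for c in out} == {UseStatus.NOT_GOVERNED}

    def test_mismatched_subject_rejected(self, default_rules):
        a = make_assessment(40, 40, sid="s1")
        with pytest.raises(ValueError):
            classify_subject(a, [DrugExposure("s2", "digoxin", 7)], default_rules)

    def test_brute_force_oracle_equivalence(self, default_rules):
        # naked re-evaluation of every rule for random subjects
        rng = np.random.default_rng(7)
        drugs = sorted(default_rules.governed_drugs) + ["ibuprofen", "meloxicam"]
        for _ in range(1000):
            cc = float(rng.uniform(5, 130))
            egfr = float(rng.uniform(5, 130))
            drug = drugs[rng.integers(len(drugs))]
            a = make_assessment(cc, egfr)
            out = classify_subject(a, [DrugExposure("s", drug, 7)], default_rules)
            rules = default_rules.applicable_rules(drug)
            for c in out:
                value = cc if c.estimator is Estimator.CC else egfr
                expect_flag = any(value < r.threshold_ml_min for r in rules)
                assert (
                    c.status is UseStatus.POTENTIALLY_INAPPROPRIATE
                ) == expect_flag
                if expect_flag:
                    violated = [r for r in rules if value < r.threshold_ml_min]
                    worst = max(
                        violated,
                        key=lambda r: (r.action is Action.AVOID, r.threshold_ml_min),
                    )
                    assert c.violated_rule == worst

    def test_lowering_cc_never_unflags(self, default_rules):
        # monotonicity of the cc verdict in the cc value
        rng = np.random.default_rng(11)
        for _ in range(200):
            cc = float(rng.uniform(5, 130))
            a_hi = make_assessment(cc, 70)
            a_lo = make_assessment(cc * 0.7, 70)
            for drug in ("digoxin", "metformin", "rivaroxaban"):
                rules = default_rules.applicable_rules(drug)
                hi = classify_drug_use(a_hi, rules, Estimator.CC)
                lo = classify_drug_use(a_lo, rules, Estimator.CC)
                if hi.status is UseStatus.POTENTIALLY_INAPPROPRIATE:
                    assert lo.status is UseStatus.POTENTIALLY_INAPPROPRIATE


class TestConcordance:
    @pytest.mark.parametrize(
        "cc_flag,smdrd_flag,expected",
        [
            (False, False, ConcordanceCategory.BOTH_APPROPRIATE),
            (True, True, ConcordanceCategory.BOTH_INAPPROPRIATE),
            (True, False, ConcordanceCategory.APPROPRIATE_SMDRD_INAPPROPRIATE_CC),
            (False, True, ConcordanceCategory.INAPPROPRIATE_SMDRD_APPROPRIATE_CC),
        ],
    )
    def test_four_way_partition(self, cc_flag, smdrd_flag, expected):
        def make(est, flag):
            return UseClassification(
                "s",
                "digoxin",
                est,
                UseStatus.POTENTIALLY_INAPPROPRIATE if flag else UseStatus.RENALLY_APPROPRIATE,
                DIGOXIN if flag else None,
            )

        assert (
            concordance(make(Estimator.CC, cc_flag), make(Estimator.SMDRD, smdrd_flag))
            is expected
        )

    def test_mismatched_pair_rejected(self):
        a = UseClassification("s", "digoxin", Estimator.CC, UseStatus.RENALLY_APPROPRIATE)
        b = UseClassification("s", "metformin", Estimator.SMDRD, UseStatus.RENALLY_APPROPRIATE)
        with pytest.raises(ValueError):
            concordance(a, b)

    def test_classification_invariant_flag_iff_rule(self):
        with pytest.raises(ValueError):
            UseClassification(
                "s", "digoxin", Estimator.CC, UseStatus.POTENTIALLY_INAPPROPRIATE
            )
        with pytest.raises(ValueError):
            UseClassification(
                "s", "digoxin", Estimator.CC, UseStatus.RENALLY_APPROPRIATE, DIGOXIN
            )
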