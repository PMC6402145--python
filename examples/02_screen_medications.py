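"""Screen one subject's medications against the renal dosing rules.

Each regularly taken drug (>= 3 times/week) is classified under both
renal-function estimators; the concordance category says whether the two
estimators agree on the verdict.
"""

from renalrisk import (
    DrugExposure,
    Estimator,
    Sex,
    Subject,
    assess,
    classify_subject,
    concordance,
    load_rules,
)

rules = load_rules()  # packaged 38-drug knowledge base

subject = Subject(subject_id="p1", age_years=82, sex=Sex.FEMALE,
                  weight_kg=55, serum_creatinine_mg_dl=1.0)
exposures = [
    DrugExposure("p1", "metformin", 7),    # avoid below 60 ml/min
    DrugExposure("p1", "digoxin", 7),      # reduce dose below 50 ml/min
    DrugExposure("p1", "ibuprofen", 2),    # taken too rarely to count
]

assessment = assess(subject)
print(f"eGFR {assessment.egfr_smdrd:.1f}, CC {assessment.cc_cg:.1f}")

classifications = classify_subject(assessment, exposures, rules)
by_key = {(c.drug_name, c.estimator): c for c in classifications}
for drug in ("metformin", "digoxin"):
    cc = by_key[(drug, Estimator.CC)]
    sm = by_key[(drug, Estimator.SMDRD)]
    cat = concordance(cc, sm)
    print(f"{drug:10s} cc={cc.status.value:26s} smdrd={sm.status.value:26s}"
          f" -> {cat.value}")

# Ibuprofen at twice a week is not regular intake and is excluded; metformin
# is flagged by the clearance but not by the eGFR — the discordance pattern
# that makes the choice of estimator clinically consequential.
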