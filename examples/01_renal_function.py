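"""Estimate renal function two ways and stage chronic kidney disease.

The short-MDRD eGFR (ml/min/1.73 m^2) is what laboratories report alongside
serum creatinine; the Cockcroft-Gault creatinine clearance (ml/min) is what
drug labels base their renal dosing rules on.  For an older woman with low
body weight the two can disagree by an entire CKD stage.
"""

from renalrisk import Sex, Subject, assess

subjects = [
    Subject(subject_id="man-60y-72kg", age_years=60, sex=Sex.MALE,
            weight_kg=72, serum_creatinine_mg_dl=1.0),
    Subject(subject_id="woman-85y-50kg", age_years=85, sex=Sex.FEMALE,
            weight_kg=50, serum_creatinine_mg_dl=1.1),
]

for s in subjects:
    a = assess(s)
    print(
        f"{s.subject_id}: eGFR {a.egfr_smdrd:5.1f} (stage {a.stage_smdrd})  "
        f"CC {a.cc_cg:5.1f} (stage {a.stage_cc})"
    )

# The 85-year-old woman has a near-normal eGFR but a clearance in the
# moderately-impaired range: dosing decisions made from the laboratory eGFR
# alone would overlook her reduced clearance.
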