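# renalrisk

Screening of **renal risk drugs** in older-adult cohorts: medications that
should be avoided, or need a dose reduction, once kidney function falls below
a stated threshold.

Kidney function in an older person can be estimated two ways, and the two
estimates often disagree in exactly the people who take the most medication:

* the short (4-variable) **MDRD** equation, the eGFR that laboratories print
  next to serum creatinine,

  `eGFR = 186 · Scr^(−1.154) · age^(−0.203) · 0.742 (if female)`  [ml/min/1.73 m²]

  (186 is the coefficient for Jaffe-assay creatinine; configurable);

* the **Cockcroft–Gault** creatinine clearance, the estimator on which most
  drug-label renal dosing recommendations were registered,

  `CC = (140 − age) · weight / (72 · Scr) · 0.85 (if female)`  [ml/min].

Because CC scales with body weight and falls linearly with age, an
80-year-old woman of 50 kg can have a near-normal eGFR but a clearance in
the moderately impaired range — so a prescriber reading only the laboratory
eGFR can overlook a clearance-based dosing rule. Quantifying how often that
happens at population scale is what this package is for.

## What it does

* **Rules knowledge base** — a flat, diff-able table of 38 drugs/drug groups
  with avoid / reduce-dose thresholds (25–80 ml/min) plus pharmacological
  class tags (ACEI, ARB, diuretic, NSAID, potassium-raising classes).
* **Dual renal assessment** — both estimators, NKF CKD staging
  (≥90, 60–89, 30–59, 15–29, <15), unit conversion, per-subject overrides.
* **Appropriateness screening** — every regularly taken (≥3×/week) governed
  drug is classified per estimator (strictly below threshold ⇒ potentially
  inappropriate) and the per-drug verdicts combine into a four-way
  concordance category; the clinically interesting cell is *appropriate by
  sMDRD but inappropriate by CC*.
* **Combination detection** — ACEI/ARB + diuretic + NSAID pairs and the
  "triple whammy"; counts of concurrently taken potassium-raising drugs;
  hyperkalaemia flag (default ≥5.5 mmol/l, inclusive, configurable).
* **Cohort statistics** — staging, drug-use, combination, potassium-count
  and hyperkalaemia tables with Yates-corrected χ² and Cochran–Armitage
  trend tests.
* **Synthetic cohort generator** — a seeded stand-in for the (undeposited)
  survey data the method was designed for: age 76 ± 11, 48.2 % women,
  calibrated so ~19 % of subjects have eGFR < 60 but ~38 % have CC < 60.

## Worked example

```python
from renalrisk import Sex, Subject, assess

a = assess(Subject(subject_id="woman-85y-50kg", age_years=85, sex=Sex.FEMALE,
                   weight_kg=50, serum_creatinine_mg_dl=1.1))
print(a.egfr_smdrd, a.cc_cg, a.stage_smdrd, a.stage_cc)
```

prints `eGFR 50.2 (stage 3)  CC 29.5 (stage 4)` — one full CKD stage of
disagreement from a single creatinine value. At cohort scale
(`examples/04_cohort_report.py`, 4 514 simulated subjects, seed 1):

```
               drug  users_n  cc_inappropriate_pct_users  smdrd_inappropriate_pct_users  discordant_pct_users
             nsaids      391                       24.55                           8.18                 16.62
          piracetam      263                       38.02                          15.21                 23.57
            digoxin      165                       46.67                          18.18                 28.48
```

46.7 % of simulated digoxin users sit below the 50 ml/min clearance
threshold, and for 28.5 % of them the eGFR alone would have called the use
appropriate. The `examples/` directory holds one short narrative script per
capability; a thin CLI (`renalrisk simulate|stage|screen`) covers batch use
from a shell.

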