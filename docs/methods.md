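# Methods

## Renal-function estimation

Two estimators are computed for every subject from one serum creatinine
value (mg/dl; µmol/l inputs are divided by 88.4):

* short-MDRD eGFR `186 · Scr^(−1.154) · age^(−0.203) · 0.742(female)` in
  ml/min/1.73 m². The coefficient defaults to 186, the value applicable to
  creatinine measured with a non-IDMS-traceable Jaffe assay; IDMS-calibrated
  laboratories should pass 175. The Black-ethnicity factor (×1.212) is off
  by default and exposed as a flag.
* Cockcroft–Gault clearance `(140 − age) · weight / (72 · Scr) · 0.85(female)`
  in ml/min.

CKD staging uses the National Kidney Foundation bins with half-open
intervals closed at the lower edge: `[90, ∞) → 1, [60, 90) → 2,
[30, 60) → 3, [15, 30) → 4, (0, 15) → 5`; a value of exactly 60 is stage 2
and exactly 30 is stage 3.

Dosing thresholds are expressed in ml/min and compared numerically against
eGFR values in ml/min/1.73 m² without body-surface de-indexing. That mirrors
clinical practice (labels quote clearances, laboratories report indexed
eGFR) and is deliberate: the size of the disagreement this shortcut induces
is the quantity the screening measures.

Subjects may carry `override_cc_ml_min` / `override_egfr` fields that bypass
the formulas (a warning is logged). These exist so cohorts can be
reconstructed from published joint counts, where the renal metrics are known
only as "below/above threshold".

## Appropriateness classification

A drug exposure counts only when regular, defined as ≥ 3 intakes per week.
Classification against a rule is strict: potentially inappropriate iff the
estimate is **strictly below** the threshold (rules are written
"< X ml/min", so a value equal to the threshold is appropriate). When a drug
carries several rules (rivaroxaban: reduce-dose < 50 and avoid < 30), the
reported violated rule is the most severe one: avoid outranks reduce-dose,
then the higher threshold. Drugs without an applicable rule yield explicit
`not_governed` entries rather than being dropped, so "taking ≥ 1 analyzed
drug" denominators remain reproducible.

Individual NSAIDs carry no threshold of their own; they inherit the
group-level avoid < 50 ml/min rule through their class tag. The reporting
layer splits NSAID users into two aggregate rows — plain NSAIDs and the
meloxicam/nimesulide subgroup — and low-dose aspirin is never tagged as an
NSAID anywhere.

Each (subject, governed drug) pair gets one of four concordance categories
from its two per-estimator verdicts; the headline discordance is
*appropriate by sMDRD but inappropriate by CC*.

## Combination analyses

ACEI and ARB are merged into one class. The pre-renal ("triple whammy")
analysis flags pairs and the triple over {ACEI/ARB, diuretic, NSAID}; pair
rows deliberately overlap (a triple-therapy subject appears in all three
pair rows and the triple row). Diuretic membership is broad — loop,
thiazide/thiazide-like and potassium-sparing agents all count — even where a
drug has no dosing threshold of its own.

Potassium-raising drugs are the union of ACEI, ARB, aldosterone antagonists,
potassium-sparing diuretics and potassium-containing agents, counted as
distinct drugs: spironolactone belongs to two of these classes but counts
once. Which potassium-containing agents exist in a market is configuration,
not ground truth; the default tags potassium chloride and citrate.
Hyperkalaemia is potassium ≥ 5.5 mmol/l (inclusive) by default — a
conventional clinical cutoff, configurable, and always recorded in report
metadata. Subjects with missing potassium are excluded from hyperkalaemia
denominators, never counted as normal.

## Statistical tests

* Yates-corrected χ² on 2×2 tables: `Σ (max(|O − E| − 0.5, 0))² / E`, p from
  the χ²(1) upper tail. Flooring the correction at zero avoids inflating the
  statistic when |O − E| < 0.5 in tiny tables. Zero row/column margins are an
  error, not a zero.
* Cochran–Armitage trend test over ordered groups with equally spaced
  scores; the statistic is invariant to affine rescaling of the scores.
  Groups with zero total are dropped; groups with total ≥ 1 (even 1/1) are
  kept. Degenerate cases (all or no successes) return statistic 0, p 1.

Significance is reported as an exact p plus a boolean mark at α = 0.05; no
multiple-testing correction is applied, matching the single-table reporting
convention the output imitates. Percentages are stored at full precision and
rendered at 2 decimals; counts are never rounded. The stratification cutoff
for the combination and potassium tables is fixed at 60 (ml/min or
ml/min/1.73 m², per estimator).

## Synthetic cohort generator

The generator emulates a community-dwelling Polish older-adult survey
population at the level needed to exercise every pipeline stage:

| parameter | default | notes |
|---|---|---|
| age | N(76, 11²) truncated [55, 105] y | |
| female fraction | 0.482 | |
| weight | N(76, 12²) men, N(65, 12²) women, truncated [35, 140] kg | |
| log creatinine | µ = −0.125, σ = 0.32, +0.004/y age, −0.15 female | calibrated, see below |
| potassium | 4.52 + 0.12·(k-drug count) + 0.25·1[CC<60] + N(0, 0.6²), clipped [2.5, 8.0] mmol/l | ≈8 % hyperkalaemia at 1 drug/preserved clearance, ≈25 % at 3 drugs/CC<60 |
| drug exposure | per-drug Bernoulli at configured regular-use prevalence | governed drugs at published total-population prevalences |
| renal enrichment | odds multipliers on exposure when CC < 60 | marginal prevalence preserved (see below) |
| regular share | 0.95 of exposures ≥ 3×/week | |
| missingness | 0.207 of subjects lose creatinine or weight, MCAR | mirrors the survey's exclusion rate |

The creatinine (µ, σ) defaults come from one run of the packaged
`calibrate_creatinine` grid search (common random numbers, coarse grid plus
one refinement, n = 20 000, seed 0) against the targets *19 % of analyzable
subjects with eGFR < 60* and *38 % with CC < 60*; with these defaults the
simulated fractions land within ±1 point of the targets across seeds. The
CC-vs-eGFR gap is not injected: it emerges mechanically from the weight and
age terms of the Cockcroft–Gault formula (among simulated subjects aged ≥ 80
under 60 kg, mean CC is well below mean eGFR).

Renal enrichment multiplies the exposure *odds* for subjects with CC < 60
(e.g. digoxin ×3, metformin ×0.45) while solving the complementary
probability so the marginal prevalence stays at the configured value — so
prevalence recovery and renal-use gradients hold simultaneously. Exposures
are otherwise independent across drugs: no comorbidity correlation structure
is modelled, so combination prevalences (e.g. ACEI/ARB + diuretic
co-prescription) are lower than real co-prescribing would produce. Passing
tests on this generator therefore demonstrate correctness of the screening
arithmetic and qualitative patterns (discordance direction, enrichment
gradients, potassium trend), not real-world prevalence estimates.

Statistical note on prevalence-recovery checks: the per-drug sampling bound
(observed regular-use prevalence within 3 binomial SE of the configured
value) is verified jointly over ~40 drugs; a joint assertion of a 3-SE bound
would fail ~8 % of the time by construction, so the suite asserts every drug
within 4 SE and ≥ 90 % of drugs within 3 SE, which has the intended ≈3-sigma
joint error rate.

A fixture builder (`build_fixture_cohort`) constructs exact-count cohorts
from joint-cell specifications, pinning renal metrics through the override
fields. It is the mechanism used to reconstruct published table cells
(synthetic stand-ins — the original survey data are not public).

## Problem sizes

The test suite reconstructs published cells at their printed sizes (61–4 514
subjects), runs oracle comparisons at 1 000 random inputs, and checks
simulation calibration at n = 20 000 — one simulate call of well under a
minute; the whole suite runs in seconds.

## Known limitations

* Exact generic-name matching only (normalized case/whitespace); no brand
  names or ATC codes. The rules file supports editing and an alias layer can
  be built on top, but matching stays exact by design.
* Dose magnitudes are out of scope: a "reduce dose" drug taken at a reduced
  dose still screens as potentially inappropriate; conversely the avoid-type
  findings are unaffected.
* The generator's independence assumptions (above) understate combination
  prevalences; its staging distribution is correct only near the 60-unit
  cutoff that the calibration targets.
* The hyperkalaemia threshold, potassium-agent list and ACEI/ARB rosters are
  configuration with sensible defaults, not claims about any particular
  market or era.
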