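"""Detect risky drug combinations: the 'triple whammy' and potassium load.

An ACEI/ARB plus a diuretic plus an NSAID each impair renal perfusion by a
different mechanism; together they raise the risk of acute pre-renal kidney
injury.  Separately, drugs that promote potassium retention are counted per
subject, and serum potassium is flagged at >= 5.5 mmol/l.
"""

from renalrisk import DrugExposure, combo_profile, load_rules

rules = load_rules()

regimens = {
    "double": ["ramipril", "hydrochlorothiazide"],
    "triple whammy": ["ramipril", "hydrochlorothiazide", "ibuprofen"],
    "potassium heavy": ["ramipril", "losartan", "spironolactone",
                        "potassium chloride"],
}

for name, drugs in regimens.items():
    exposures = [DrugExposure("s", d, 7) for d in drugs]
    p = combo_profile(exposures, rules, subject_id="s", potassium_mmol_l=5.6)
    print(
        f"{name:16s} pairs=({int(p.pair_acei_arb_diuretic)},"
        f"{int(p.pair_acei_arb_nsaid)},{int(p.pair_diuretic_nsaid)}) "
        f"triple={p.triple} k_drugs={p.k_drug_count} "
        f"hyperkalaemia={p.hyperkalaemia}"
    )

# The pair flags are (ACEI/ARB+diuretic, ACEI/ARB+NSAID, diuretic+NSAID);
# k_drugs counts distinct potassium-raising drugs (spironolactone belongs to
# two such classes but counts once).
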