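import pytest
from hypothesis import settings

from renalrisk.rules import RuleSet, load_rules

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_rules() -> RuleSet:
    return load_rules()


# Published drug-use table cells reconstructed as joint-count fixtures.
# Per drug: users, threshold, cc-inappropriate (a), smdrd-inappropriate (b),
# discordant d (cc below & smdrd at/above); the four joint cells follow as
# both = a - d, smdrd-only = b - both, neither = users - a - smdrd-only.
TABLE3_CELLS = {
    "digoxin": dict(users=204, thr=50, cc_inapp=95, smdrd_inapp=34, discordant=63),
    "ranitidine": dict(users=100, thr=50, cc_inapp=42, smdrd_inapp=15, discordant=28),
    "spironolactone": dict(users=330, thr=30, cc_inapp=35, smdrd_inapp=11, discordant=25),
    "fenofibrate": dict(users=61, thr=60, cc_inapp=24, smdrd_inapp=24, discordant=4),
    "piracetam": dict(users=342, thr=50, cc_inapp=128, smdrd_inapp=57, discordant=77),
}


def table3_fixture_cells(drug: str) -> list[dict]:
    """Joint-count cells for one drug's published row (see TABLE3_CELLS)."""
    c = TABLE3_CELLS[drug]
    thr = c["thr"]
    both = c["cc_inapp"] - c["discordant"]
    smdrd_only = c["smdrd_inapp"] - both
    neither = c["users"] - c["cc_inapp"] - smdrd_only
    lo, hi = thr - 10.0, thr + 10.0
    return [
        {"n": both, "cc": lo, "egfr": lo, "drugs": [drug]},
        {"n": c["discordant"], "cc": lo, "egfr": hi, "drugs": [drug]},
        {"n": smdrd_only, "cc": hi, "egfr": lo, "drugs": [drug]},
        {"n": neither, "cc": hi, "egfr": hi, "drugs": [drug]},
    ]
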