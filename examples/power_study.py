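"""Scaled power comparison under bidirectional effects.

Scenario I.5 gives 7.5% of the rare variants a +1.64 SD effect and 7.5%
a -1.64 SD effect.  One-directional burden tests (WE, VT) should fail
here while variance-based (SKAT) and regression methods keep power.
Sizes are scaled down so the example runs in about a minute.
"""

import warnings

from rarereg import GenotypeProfile, SCENARIOS, estimate_power

warnings.filterwarnings("ignore")

profile = GenotypeProfile(400, 24, 20, name="demo")
results = estimate_power(
    SCENARIOS["I.5"], profile,
    ["WE", "VT", "SKAT", "RR.l10"],
    S=60, B=99, alpha=0.05, seed=5,
)

print(f"{'method':<10} {'power':>6} {'mc_se':>6}")
for label, r in results.items():
    print(f"{label:<10} {r.power:6.3f} {r.mc_se:6.3f}")

print(
    "\nPower is the fraction of 60 simulated datasets with empirical "
    "p <= 0.05 (99 permutations\neach); mc_se is its binomial standard "
    "error.  WE and VT sit near the 5% null rate because\npositive and "
    "negative effects cancel in a signed burden sum, while SKAT and ridge "
    "detect\nthe inflated phenotype variance among carriers."
)
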