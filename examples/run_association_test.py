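"""Test one gene for association with a continuous trait.

Simulates a small sequenced gene in which 10% of the rare variants shift
the phenotype by 1.64 SD, then runs ridge regression and the LASSO with
permutation significance, plus the SKAT comparator.
"""

import numpy as np

from rarereg import GenotypeProfile, SCENARIOS, run_test, simulate_dataset

rng = np.random.default_rng(7)
profile = GenotypeProfile(n_individuals=500, n_variants=30, n_rare=25, name="demo")
G, y, effects = simulate_dataset(profile, SCENARIOS["I.1"], rng)

causal = [G.variant_ids[j] for j in np.flatnonzero(effects != 0)]
print(f"simulated gene: {G.n_variants} variants, {sum(G.maf < 0.01)} rare; "
      f"causal = {causal}")

for method in ["RR.l10", "LASSO.AIC", "SKAT"]:
    res = run_test(method, G, y, B=999, seed=1)
    line = f"{res.method_label:<12} statistic={res.observed:8.3f}  p={res.p_value:.3f}"
    if res.selected_labels:
        line += f"  selected={res.selected_labels}"
    print(line)

print(
    "\nEach p-value is empirical: (1 + #permutations with a statistic at "
    "least as large)/(B+1),\nwith the model-size/penalty selection redone "
    "inside every permutation.\nA p below 0.05 flags the gene as associated; "
    "the LASSO's selected list points at\nthe variants driving the fit "
    "(compare with the causal list above)."
)
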