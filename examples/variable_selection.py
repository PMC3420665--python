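"""Which variants does the LASSO keep under AIC, BIC and GIC?

Simulates datasets with modest (1 SD) effects at 10% of rare variants
and compares how many variables — and how many truly causal ones — each
information criterion retains.
"""

import numpy as np

from rarereg import (
    GenotypeProfile,
    SCENARIOS,
    SelectionCriterion,
    effect_sizes,
    lasso_select,
    select_causal,
    simulate_genotypes,
    simulate_phenotype,
)

rng = np.random.default_rng(11)
profile = GenotypeProfile(500, 40, 34, name="demo")
scen = SCENARIOS["I.3"]

counts = {c: {"total": [], "causal": []} for c in ("aic", "bic", "gic")}
for _ in range(50):
    G = simulate_genotypes(profile, rng)
    d = select_causal(G.maf, scen, rng)
    delta = effect_sizes(G.maf, d, scen)
    y = simulate_phenotype(G, delta, rng)
    truth = set(np.flatnonzero(delta != 0).tolist())
    for crit in counts:
        fit = lasso_select(G.values, y, SelectionCriterion(crit))
        counts[crit]["total"].append(fit.selected.size)
        counts[crit]["causal"].append(len(truth & set(fit.selected.tolist())))

print(f"{'criterion':<10} {'mean selected':>14} {'mean causal kept':>17}")
for crit, rec in counts.items():
    print(f"{crit.upper():<10} {np.mean(rec['total']):14.2f} "
          f"{np.mean(rec['causal']):17.2f}")

print(
    "\nAIC penalizes model size least, so it keeps the most variables — "
    "catching more of\nthe causal ones at the cost of more false "
    "inclusions; BIC and GIC prune harder."
)
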