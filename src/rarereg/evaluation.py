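"""Power / type-I-error harness and causal-variant-recovery reporting.

``estimate_power`` simulates S datasets under a scenario, runs each
requested test with B permutations per dataset, and reports the fraction
of empirical p-values at or below alpha together with its binomial
Monte-Carlo standard error.  For the sparse methods (LASSO, SPLS) it also
summarizes variable selection: the mean numbers of design columns
selected, of true causal variants among them, and of pooled columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeMatrix, build_pooled_variables
from .models import ModelFit
from .permutation import MethodSpec, run_test
from .simulate import GenotypeProfile, ScenarioConfig, simulate_dataset

__all__ = ["PowerResult", "estimate_power", "selection_report"]

SPARSE_METHODS = ("LASSO", "SPLS")


@dataclass
class PowerResult:
    """Empirical power of one method under one scenario."""

    method_label: str
    scenario_id: str
    S: int
    B: int
    alpha: float
    p_values: np.ndarray
    selection_summary: dict | None = None
    seed: int | None = None

    @property
    def power(self) -> float:
        return float(np.mean(self.p_values <= self.alpha))

    @property
    def mc_se(self) -> float:
        """Binomial standard error sqrt(power (1-power) / S)."""
        pw = self.power
        return float(np.sqrt(pw * (1.0 - pw) / self.S))

    def to_record(self) -> dict:
        rec = {
            "method": self.method_label,
            "scenario": self.scenario_id,
            "S": self.S,
            "B": self.B,
            "alpha": self.alpha,
            "power": self.power,
            "mc_se": self.mc_se,
            "seed": self.seed,
        }
        if self.selection_summary is not None:
            rec["selection"] = self.selection_summary
        return rec


def selection_report(
    fits: list[ModelFit],
    truth_sets: list[np.ndarray],
    origins: list[list[str]],
) -> dict:
    """Average variable-selection counts for sparse fits.

    ``truth_sets`` holds, per dataset, the design-column indices of the
    truly causal variants; ``origins`` the per-column origin tags
    ('original'/'pooled') of each dataset's design.  Only LASSO and SPLS
    fits are accepted — the other methods keep every column and have no
    selection to report.
    """
    if not fits:
        raise ValueError("no fits to report on")
    totals, causals, pooled = [], [], []
    for fit, truth, origin in zip(fits, truth_sets, origins):
        if fit.method not in SPARSE_METHODS:
            raise ValueError(f"selection_report requires LASSO/SPLS, got {fit.method}")
        sel = np.asarray(fit.selected, dtype=int)
        totals.append(sel.size)
        causals.append(np.intersect1d(sel, np.asarray(truth, int)).size)
        pooled.append(sum(origin[j] == "pooled" for j in sel))
    return {
        "mean_total_selected": float(np.mean(totals)),
        "mean_causal_selected": float(np.mean(causals)),
        "mean_pooled_selected": float(np.mean(pooled)),
        "n_datasets": len(fits),
    }


def estimate_power(
    scenario: ScenarioConfig,
    profile: GenotypeProfile,
    methods: list[str | MethodSpec],
    S: int = 1000,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict[str, PowerResult]:
    """Empirical power per method from S simulated datasets.

    Each dataset draws a fresh genotype panel, a fresh causal-variant
    set and a fresh phenotype; every method is tested on the same
    dataset with its own permutation stream.  All randomness descends
    from ``seed`` through spawned generator streams, so results are
    reproducible and independent of method ordering.
    """
    if S < 1 or B < 1 or not (0 < alpha < 1):
        raise ValueError("require S >= 1, B >= 1 and alpha in (0, 1)")
    specs = [MethodSpec.parse(m) if isinstance(m, str) else m for m in methods]
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate method labels: {labels}")

    ss = np.random.SeedSequence(seed)
    dataset_seeds = ss.spawn(S)
    pvals: dict[str, list[float]] = {lab: [] for lab in labels}
    sparse_fits: dict[str, list[ModelFit]] = {lab: [] for lab in labels}
    truth_sets: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    origins: dict[str, list[list[str]]] = {lab: [] for lab in labels}

    for s_idx in range(S):
        data_rng = np.random.default_rng(dataset_seeds[s_idx])
        G, y, delta = simulate_dataset(profile, scenario, data_rng)
        causal_idx = np.flatnonzero(delta != 0)
        need_pooled = any(sp.pooled for sp in specs)
        design = build_pooled_variables(G) if need_pooled else None
        method_seeds = dataset_seeds[s_idx].spawn(len(specs))
        # spawn order is fixed by the sorted label so --methods order is irrelevant
        order = np.argsort(labels, kind="stable")
        for rank_pos, m_idx in enumerate(order):
            sp = specs[m_idx]
            rng = np.random.default_rng(method_seeds[rank_pos])
            res = run_test(sp, G, y, B=B, rng=rng, design=design)
            pvals[sp.label].append(res.p_value)
            if sp.method in SPARSE_METHODS and res.observed_fit is not None:
                sparse_fits[sp.label].append(res.observed_fit)
                truth_sets[sp.label].append(causal_idx)
                n_cols = (design.matrix.shape[1] if sp.pooled and design is not None
                          else G.n_variants)
                if sp.pooled and design is not None:
                    origins[sp.label].append(list(design.origin))
                else:
                    origins[sp.label].append(["original"] * n_cols)

    out: dict[str, PowerResult] = {}
    for sp in specs:
        lab = sp.label
        sel = None
        if sp.method in SPARSE_METHODS and sparse_fits[lab]:
            sel = selection_report(sparse_fits[lab], truth_sets[lab], origins[lab])
        out[lab] = PowerResult(
            method_label=lab,
            scenario_id=scenario.scenario_id,
            S=S,
            B=B,
            alpha=alpha,
            p_values=np.asarray(pvals[lab]),
            selection_summary=sel,
            seed=seed,
        )
    return out
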