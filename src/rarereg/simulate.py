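"""Synthetic genotypes and phenotype scenarios for power evaluation.

Real Sanger-sequenced genotypes for the three study genes are private, so
the generator emulates their marginal structure: gene-sized panels of
polymorphic variants with a fixed number of rare (MAF < 1%) sites, rare
MAFs drawn from a neutral-spectrum-like 1/x density and common MAFs
uniform, genotypes Binomial(2, q) per individual (optionally with a
latent AR(1) Gaussian copula for linkage disequilibrium).

Phenotypes are continuous: non-carriers of any causal variant draw from
N(0, 1); a carrier draws from N(+/- delta, 1) where delta belongs to the
rarest causal variant the individual carries.  Two scenario families are
provided: effect size constant across MAF (set I) and effect size
inversely dependent on MAF via a pluggable weight, default 1/sqrt(q),
calibrated so the mean causal effect hits the scenario target (set II).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import stats as sps

from .genotype import GenotypeMatrix

__all__ = [
    "GenotypeProfile",
    "ScenarioConfig",
    "GENE_PROFILES",
    "SCENARIOS",
    "simulate_genotypes",
    "select_causal",
    "effect_sizes",
    "simulate_phenotype",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GenotypeProfile:
    """Marginal description of one gene's variant panel."""

    n_individuals: int = 1998
    n_variants: int = 98
    n_rare: int = 85  # variants with realized MAF < 0.01
    rare_maf_range: tuple[float, float] | None = None  # default [1/(2n), 0.01)
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    ld_rho: float = 0.0  # AR(1) latent correlation between adjacent variants
    name: str = "custom"

    def __post_init__(self):
        if self.n_rare > self.n_variants:
            raise ValueError("n_rare cannot exceed n_variants")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def rare_range(self) -> tuple[float, float]:
        if self.rare_maf_range is not None:
            return self.rare_maf_range
        return (1.0 / (2 * self.n_individuals), 0.01)


#: Panels sized like the three Sanger-sequenced study genes.
GENE_PROFILES: dict[str, GenotypeProfile] = {
    "geneA": GenotypeProfile(1998, 98, 85, name="geneA"),
    "geneB": GenotypeProfile(1998, 28, 26, name="geneB"),
    "geneC": GenotypeProfile(1998, 122, 99, name="geneC"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One phenotype-simulation scenario.

    ``causal_fraction`` is the proportion of eligible (rare) variants
    made causal; the fixed-count "Rare/Common" design instead sets
    ``n_rare_causal``/``n_common_causal``.  ``deleterious_fraction``
    applies only to bidirectional scenarios and is the share of eligible
    variants with positive effect (the rest of the causal set is
    protective).  Effects are in phenotype-SD units; ``maf_dependent``
    switches on the inverse-MAF effect weighting (scenario set II).
    """

    scenario_id: str
    causal_maf_threshold: float = 0.01
    causal_fraction: float | None = 0.10
    n_rare_causal: int | None = None
    n_common_causal: int | None = None
    bidirectional: bool = False
    deleterious_fraction: float = 0.075
    effect_rare: float = 1.64
    effect_common: float = 0.07
    maf_dependent: bool = False
    maf_weight: Callable[[np.ndarray], np.ndarray] | None = None

    def weight(self, q: np.ndarray) -> np.ndarray:
        if self.maf_weight is not None:
            return self.maf_weight(q)
        return 1.0 / np.sqrt(q)


def _set_I() -> dict[str, ScenarioConfig]:
    return {
        "I.1": ScenarioConfig("I.1", 0.01, 0.10, effect_rare=1.64),
        "I.2": ScenarioConfig(
            "I.2", 0.01, None, n_rare_causal=4, n_common_causal=4,
            effect_rare=1.64, effect_common=0.07,
        ),
        "I.3": ScenarioConfig("I.3", 0.01, 0.10, effect_rare=1.0),
        "I.4": ScenarioConfig("I.4", 0.01, 0.20, effect_rare=1.0),
        "I.5": ScenarioConfig(
            "I.5", 0.01, 0.15, bidirectional=True, deleterious_fraction=0.075,
            effect_rare=1.64,
        ),
        "I.6": ScenarioConfig("I.6", 0.001, 0.20, effect_rare=1.64),
    }


SCENARIOS: dict[str, ScenarioConfig] = {}
SCENARIOS.update(_set_I())
for _sid, _cfg in _set_I().items():
    _sid2 = "II." + _sid.split(".")[1]
    SCENARIOS[_sid2] = replace(_cfg, scenario_id=_sid2, maf_dependent=True)
#: Null scenario: no causal variants, phenotype pure N(0, 1) noise.
SCENARIOS["null"] = ScenarioConfig("null", 0.01, 0.0)


def _draw_rare_maf(lo: float, hi: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample from density proportional to 1/x on [lo, hi) (inverse-CDF)."""
    u = rng.random(size)
    return lo * (hi / lo) ** u


def _draw_genotype_column(
    q: float, n: int, rng: np.random.Generator, latent: np.ndarray | None = None
) -> np.ndarray:
    if latent is None:
        return rng.binomial(2, q, size=n).astype(float)
    cut = sps.norm.ppf(q)
    return (latent < cut).sum(axis=1).astype(float)


def simulate_genotypes(
    profile: GenotypeProfile, rng: np.random.Generator, max_tries: int = 1000
) -> GenotypeMatrix:
    """Simulate a polymorphic gene panel matching the profile.

    Each column is redrawn until it is polymorphic and its realized MAF
    falls in the intended rarity class (rare: MAF < 0.01; common:
    MAF >= 0.01), so the returned panel has exactly ``n_rare`` rare
    sites.  With ``ld_rho > 0`` genotypes are generated from two latent
    AR(1) Gaussian haplotypes per individual, thresholded per variant.
    """
    n, p = profile.n_individuals, profile.n_variants
    n_common = p - profile.n_rare
    lo, hi = profile.rare_range
    clo, chi = profile.common_maf_range

    latents = None
    if profile.ld_rho > 0:
        latents = _ar1_latent(n, p, profile.ld_rho, rng)

    cols = np.empty((n, p))
    classes = np.array([True] * profile.n_rare + [False] * n_common)
    for j in range(p):
        rare = classes[j]
        for attempt in range(max_tries):
            q = (
                _draw_rare_maf(lo, hi, 1, rng)[0]
                if rare
                else rng.uniform(clo, chi)
            )
            lat = latents[:, :, j] if latents is not None else None
            g = _draw_genotype_column(q, n, rng, lat)
            realized = g.sum() / (2 * n)
            realized = min(realized, 1 - realized)
            if realized <= 0:
                continue
            if rare and realized < 0.01:
                break
            if not rare and realized >= 0.01:
                break
        else:
            raise RuntimeError(
                f"could not realize a {'rare' if rare else 'common'} polymorphic "
                f"variant in {max_tries} tries (n={n})"
            )
        cols[:, j] = g
    order = rng.permutation(p)
    ids = [f"{profile.name}_v{j + 1}" for j in range(p)]
    return GenotypeMatrix.from_values(cols[:, order], [ids[j] for j in order])


def _ar1_latent(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Two latent AR(1) Gaussian haplotype fields per individual: (n, 2, p)."""
    z = rng.standard_normal((n, 2, p))
    out = np.empty_like(z)
    out[:, :, 0] = z[:, :, 0]
    w = np.sqrt(1 - rho**2)
    for j in range(1, p):
        out[:, :, j] = rho * out[:, :, j - 1] + w * z[:, :, j]
    return out


def _round_count(x: float) -> int:
    """Round half to even, with a floor of one causal variant."""
    return max(1, int(np.round(x)))


def select_causal(
    maf: np.ndarray, scenario: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Signed causal-direction indicator per variant (+1/-1/0).

    The causal set is sampled uniformly without replacement from variants
    with MAF below the scenario threshold (plus, for the fixed-count
    design, from the common variants).  Bidirectional scenarios split the
    causal set into deleterious (+) and protective (-) halves.
    """
    maf = np.asarray(maf, float)
    eligible = np.flatnonzero(maf < scenario.causal_maf_threshold)
    directions = np.zeros(maf.size)

    if scenario.n_rare_causal is not None:
        if eligible.size < scenario.n_rare_causal:
            raise ValueError(
                f"only {eligible.size} variants below MAF "
                f"{scenario.causal_maf_threshold}; need {scenario.n_rare_causal}"
            )
        chosen = rng.choice(eligible, size=scenario.n_rare_causal, replace=False)
        directions[chosen] = 1.0
        common = np.flatnonzero(maf >= 0.01)
        if scenario.n_common_causal:
            if common.size < scenario.n_common_causal:
                raise ValueError(
                    f"only {common.size} common variants; need {scenario.n_common_causal}"
                )
            chosen_c = rng.choice(common, size=scenario.n_common_causal, replace=False)
            directions[chosen_c] = 1.0
        return directions

    frac = scenario.causal_fraction or 0.0
    if frac <= 0:
        return directions  # null scenario
    if eligible.size == 0:
        raise ValueError(
            f"no variant with MAF below {scenario.causal_maf_threshold}"
        )
    total = min(_round_count(frac * eligible.size), eligible.size)
    chosen = rng.choice(eligible, size=total, replace=False)
    if scenario.bidirectional:
        n_del = min(_round_count(scenario.deleterious_fraction * eligible.size), total)
        directions[chosen[:n_del]] = 1.0
        directions[chosen[n_del:]] = -1.0
    else:
        directions[chosen] = 1.0
    return directions


def effect_sizes(
    maf: np.ndarray, directions: np.ndarray, scenario: ScenarioConfig
) -> np.ndarray:
    """Signed per-variant effect sizes (phenotype-SD units).

    Constant-effect scenarios assign the scenario's rare effect to every
    causal rare variant (and the common effect to causal common ones).
    MAF-dependent scenarios scale a weight w(q) — default 1/sqrt(q) — by
    a constant solved so the mean effect over the rare causal set equals
    the scenario target exactly.
    """
    maf = np.asarray(maf, float)
    directions = np.asarray(directions, float)
    delta = np.zeros(maf.size)
    rare_causal = (directions != 0) & (maf < scenario.causal_maf_threshold)
    common_causal = (directions != 0) & ~rare_causal
    if rare_causal.any():
        if scenario.maf_dependent:
            w = scenario.weight(maf[rare_causal])
            c = scenario.effect_rare * rare_causal.sum() / w.sum()
            delta[rare_causal] = c * w
        else:
            delta[rare_causal] = scenario.effect_rare
    if common_causal.any():
        delta[common_causal] = scenario.effect_common
    return delta * np.sign(directions)


def simulate_phenotype(
    G: GenotypeMatrix, effects: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Continuous phenotype under the rarest-carried-causal-variant rule.

    Non-carriers draw from N(0, 1).  A carrier of one or more causal
    variants draws from N(delta_{j*}, 1) where j* is, among the causal
    variants the individual carries, the one with the smallest MAF (its
    signed effect supplies the mean).
    """
    effects = np.asarray(effects, float)
    n = G.n_individuals
    means = np.zeros(n)
    causal = np.flatnonzero(effects != 0)
    if causal.size:
        order = causal[np.argsort(G.maf[causal], kind="stable")]
        carried = G.values[:, order] > 0  # columns in increasing-MAF order
        has = carried.any(axis=1)
        first = np.argmax(carried, axis=1)
        means[has] = effects[order][first[has]]
    return means + rng.standard_normal(n)


def simulate_dataset(
    profile: GenotypeProfile,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """One full dataset: genotypes, phenotype, signed per-variant effects."""
    G = simulate_genotypes(profile, rng)
    directions = select_causal(G.maf, scenario, rng)
    delta = effect_sizes(G.maf, directions, scenario)
    y = simulate_phenotype(G, delta, rng)
    return G, y, delta
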