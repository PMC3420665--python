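"""Reference rare-variant tests: weighted sum (WE), variable threshold
(VT) and the sequence kernel association test (SKAT), all as scalar
statistics to be calibrated by permutation.

WE is adapted to continuous traits as the absolute correlation between
the phenotype and the Madsen-Browning weighted allele count.  VT takes
the maximum standardized burden score over the same MAF-threshold
lattice used for pooled-predictor augmentation.  SKAT is the
variance-component score Q = r' G W^2 G' r with Beta(1, 25) density
weights on the sample MAFs; no asymptotic p-value is needed because
significance is always assessed by permutation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .genotype import GenotypeMatrix

__all__ = ["we_statistic", "vt_statistic", "skat_statistic", "vt_thresholds"]


def _abs_corr(y: np.ndarray, s: np.ndarray) -> float:
    yc = y - y.mean()
    sc = s - s.mean()
    denom = np.linalg.norm(yc) * np.linalg.norm(sc)
    if denom <= 0 or not np.isfinite(denom):
        return 0.0
    return float(abs(yc @ sc) / denom)


def we_weights(G: GenotypeMatrix) -> np.ndarray:
    """Madsen-Browning weights 1/sqrt(n q (1-q)); monomorphic columns get 0."""
    q = G.maf
    n = G.n_individuals
    w = np.zeros_like(q)
    ok = (q > 0) & (q < 1)
    w[ok] = 1.0 / np.sqrt(n * q[ok] * (1.0 - q[ok]))
    return w


def we_statistic(G: GenotypeMatrix, y: np.ndarray) -> float:
    """|cor(y, S)| for the weighted per-individual score S_i = sum_j w_j g_ij."""
    s = G.values @ we_weights(G)
    return _abs_corr(np.asarray(y, float), s)


def vt_thresholds(G: GenotypeMatrix, t_max: float = 0.05) -> np.ndarray:
    """Rarity-threshold lattice: t_max plus each observed MAF below it."""
    maf = G.maf
    obs = np.unique(maf[(maf > 0) & (maf < t_max)])
    return np.concatenate(([t_max], obs[::-1]))


def vt_statistic(
    G: GenotypeMatrix, y: np.ndarray, thresholds: np.ndarray | None = None
) -> float:
    """Variable-threshold burden statistic.

    For each threshold t, with pooled count C_t(i) over variants of
    MAF <= t, the score is z(t) = |sum_i (y_i - ybar) C_t(i)| /
    sqrt(sum_i C_t(i)^2); the statistic is the maximum over the lattice.
    """
    y = np.asarray(y, float)
    if thresholds is None:
        thresholds = vt_thresholds(G)
    yc = y - y.mean()
    best = 0.0
    for t in np.atleast_1d(thresholds):
        members = G.maf <= t
        if not members.any():
            continue
        C = G.values[:, members].sum(axis=1)
        denom = np.sqrt(float(C @ C))
        if denom <= 0:
            continue
        z = abs(float(yc @ C)) / denom
        best = max(best, z)
    return best


def skat_weights(maf: np.ndarray, a1: float = 1.0, a2: float = 25.0) -> np.ndarray:
    """Beta-density variant weights evaluated at the sample MAF."""
    return stats.beta.pdf(np.clip(maf, 1e-12, 1 - 1e-12), a1, a2)


def skat_statistic(
    G: GenotypeMatrix, y: np.ndarray, a1: float = 1.0, a2: float = 25.0
) -> float:
    """SKAT score statistic Q = r' G W^2 G' r with intercept-only residuals."""
    y = np.asarray(y, float)
    r = y - y.mean()
    w = skat_weights(G.maf, a1, a2)
    v = (G.values * w).T @ r
    return float(v @ v)
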