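"""Regularized multiple-regression fits and their association statistics.

Five methods operate on an n x p genotype (possibly pooled-augmented)
design and a continuous phenotype:

* principal components regression (PCR) and partial least squares (PLS)
  — feature extraction; association measured by the correlation between
  the phenotype and the fitted values;
* ridge regression (RR) — L2 shrinkage via the SVD; same correlation
  statistic;
* LASSO and sparse PLS (SPLS) — variable selection with the penalty /
  sparsity parameter chosen by an information criterion (AIC, BIC or a
  generalized IC), scored by the -log10 p-value of the post-selection
  F-test of the chosen model.

Columns are mean-centered but not variance-scaled by default: unit-variance
scaling would inflate near-monomorphic rare-variant columns, and the fixed
ridge penalties are calibrated on raw allele counts.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import lasso_path

__all__ = [
    "ModelFit",
    "SelectionCriterion",
    "fit_pcr",
    "fit_pls",
    "fit_ridge",
    "choose_k",
    "lasso_select",
    "spls_select",
    "information_criterion",
    "post_selection_f_pvalue",
]

_RANK_RTOL = 1e-10


@dataclass
class ModelFit:
    """One fitted regression model and its scalar association statistic.

    ``fit_statistic`` is oriented so that larger means stronger evidence
    of association: the phenotype/fitted-value correlation for RR, PCR and
    PLS, and -log10 of the post-selection F-test p-value for LASSO and
    SPLS.  ``selected`` indexes design columns with nonzero effect (all
    columns for the non-sparse methods).
    """

    method: str
    hyperparams: dict = field(default_factory=dict)
    intercept: float = 0.0
    coefficients: np.ndarray | None = None
    fitted: np.ndarray | None = None
    selected: np.ndarray | None = None
    fit_statistic: float = 0.0
    degenerate: bool = False


@dataclass(frozen=True)
class SelectionCriterion:
    """Information-criterion penalty: IC = n*log(RSS/n) + multiplier * df.

    ``aic`` uses multiplier 2, ``bic`` uses log(n) and ``gic`` uses the
    high-dimensional form (log log n) * (log p); a fixed numeric
    multiplier may be supplied to override the formula.
    """

    kind: str = "bic"
    multiplier_override: float | None = None

    def multiplier(self, n: int, p: int) -> float:
        if self.multiplier_override is not None:
            return float(self.multiplier_override)
        kind = self.kind.lower()
        if kind == "aic":
            return 2.0
        if kind == "bic":
            return float(np.log(n))
        if kind == "gic":
            return float(np.log(np.log(n)) * np.log(max(p, 2)))
        raise ValueError(f"unknown criterion {self.kind!r}")


def _center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    ybar = float(y.mean())
    return Xc, y - ybar, ybar


def _corr_statistic(y: np.ndarray, fitted: np.ndarray) -> float:
    """Pearson correlation of phenotype and fitted values; 0 if either is flat."""
    ys = y - y.mean()
    fs = fitted - fitted.mean()
    denom = np.linalg.norm(ys) * np.linalg.norm(fs)
    if denom <= 0 or not np.isfinite(denom):
        return 0.0
    return float(ys @ fs / denom)


def _svd(Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = d[0] * max(Xc.shape) * _RANK_RTOL if d.size and d[0] > 0 else 0.0
    rank = int((d > tol).sum())
    return U, d, Vt, rank


def fit_pcr(X: np.ndarray, y: np.ndarray, k: int) -> ModelFit:
    """Principal components regression with ``k`` components.

    The fitted response is ybar + sum_{m<=k} u_m u_m' y_c where u_m are
    left singular vectors of the column-centered design, ordered by
    decreasing singular value.  With k equal to the design rank this is
    the ordinary least-squares fit.
    """
    Xc, yc, ybar = _center(X, y)
    U, d, Vt, rank = _svd(Xc)
    if not (1 <= k <= rank):
        raise ValueError(f"k must be in [1, rank={rank}], got {k}")
    uy = U[:, :k].T @ yc
    fitted = ybar + U[:, :k] @ uy
    beta = Vt[:k].T @ (uy / d[:k])
    return ModelFit(
        method="PCR",
        hyperparams={"k": k},
        intercept=ybar - float(X.mean(axis=0) @ beta),
        coefficients=beta,
        fitted=fitted,
        selected=np.arange(X.shape[1]),
        fit_statistic=_corr_statistic(y, fitted),
    )


def _pls_path(Xc: np.ndarray, yc: np.ndarray, k_max: int):
    """Iterative PLS1 recursion (predictor deflation).

    Returns per-component scores z_m, the cumulative fitted response
    (about zero) after each component, and the weight/loading history
    needed to reconstruct coefficients.
    """
    Xd = Xc.copy()
    n = Xc.shape[0]
    fitted = np.zeros(n)
    scores, weights, loadings, gammas, cum_fit = [], [], [], [], []
    for _ in range(k_max):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(yc)):
            break
        z = Xd @ w
        zz = float(z @ z)
        if zz <= 0 or not np.isfinite(zz):
            break
        gamma = float(z @ yc) / zz
        fitted = fitted + gamma * z
        p_load = Xd.T @ z / zz
        Xd = Xd - np.outer(z, p_load)
        scores.append(z)
        weights.append(w)
        loadings.append(p_load)
        gammas.append(gamma)
        cum_fit.append(fitted.copy())
    return scores, weights, loadings, gammas, cum_fit


def _pls_coefficients(weights, loadings, gammas) -> np.ndarray:
    """Map PLS scores back to original-variable coefficients."""
    W = np.column_stack(weights)
    P = np.column_stack(loadings)
    g = np.asarray(gammas)
    # scores satisfy Z = Xc W (P'W)^{-1}; y-fit = Z g, so beta = W (P'W)^{-1} g
    R = P.T @ W
    return W @ np.linalg.solve(R, g)


def fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> ModelFit:
    """Partial least squares with ``k`` orthogonal scores.

    The first weight vector is proportional to X'y_c and the design is
    deflated between components; the fitted response is
    ybar + sum_{m<=k} z_m z_m' y_c / (z_m' z_m).  Exhausting the column
    space (k = rank) reproduces ordinary least squares.
    """
    Xc, yc, ybar = _center(X, y)
    _, _, _, rank = _svd(Xc)
    if not (1 <= k <= rank):
        raise ValueError(f"k must be in [1, rank={rank}], got {k}")
    scores, weights, loadings, gammas, cum_fit = _pls_path(Xc, yc, k)
    if not scores:  # X'y_c = 0: no covariance to model
        return ModelFit(
            method="PLS",
            hyperparams={"k": k},
            intercept=ybar,
            coefficients=np.zeros(X.shape[1]),
            fitted=np.full_like(y, ybar, dtype=float),
            selected=np.arange(X.shape[1]),
            fit_statistic=0.0,
            degenerate=True,
        )
    fitted = ybar + cum_fit[-1]
    beta = _pls_coefficients(weights, loadings, gammas)
    return ModelFit(
        method="PLS",
        hyperparams={"k": len(scores)},
        intercept=ybar - float(X.mean(axis=0) @ beta),
        coefficients=beta,
        fitted=fitted,
        selected=np.arange(X.shape[1]),
        fit_statistic=_corr_statistic(y, fitted),
    )


def choose_k(
    X: np.ndarray,
    y: np.ndarray,
    rule: str = "variance_explained",
    theta: float = 0.80,
    method: str = "pcr",
) -> int:
    """Pick the number of components for PCR or PLS.

    ``rule='one'`` returns 1.  ``rule='variance_explained'`` returns the
    smallest k whose training R-squared reaches ``theta`` times the
    full-rank R-squared (theta in (0, 1); default 0.80).
    """
    if rule == "one":
        return 1
    if rule != "variance_explained":
        raise ValueError(f"unknown rule {rule!r}")
    if not (0.0 < theta < 1.0):
        # theta == 1 is allowed as the limit: full rank
        if theta == 1.0:
            Xc, _, _ = _center(X, y)
            return _svd(Xc)[3]
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    r2 = _r2_profile(X, y, method)
    if r2.size == 0 or r2[-1] <= 0:
        return 1
    target = theta * r2[-1]
    return int(np.argmax(r2 >= target - 1e-12) + 1)


def _r2_profile(X: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    """Training R^2 after 1..rank components, for PCR or PLS."""
    Xc, yc, _ = _center(X, y)
    tss = float(yc @ yc)
    if tss <= 0:
        return np.zeros(0)
    if method == "pcr":
        U, d, Vt, rank = _svd(Xc)
        uy = U[:, :rank].T @ yc
        return np.cumsum(uy**2) / tss
    if method == "pls":
        _, _, _, rank = _svd(Xc)
        _, _, _, _, cum_fit = _pls_path(Xc, yc, rank)
        if not cum_fit:
            return np.zeros(0)
        return np.array([1.0 - float((yc - f) @ (yc - f)) / tss for f in cum_fit])
    raise ValueError(f"unknown method {method!r}")


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> ModelFit:
    """Ridge regression via the SVD of the centered design.

    Fitted response: ybar + sum_m u_m (d_m^2 / (d_m^2 + lambda)) u_m' y_c
    over all positive singular directions.  lambda = 0 gives the
    (pseudoinverse) ordinary least-squares fit; large lambda shrinks the
    fit to the mean.
    """
    if lam < 0:
        raise ValueError(f"ridge penalty must be nonnegative, got {lam}")
    Xc, yc, ybar = _center(X, y)
    U, d, Vt, rank = _svd(Xc)
    d = d[:rank]
    shrink = d**2 / (d**2 + lam)
    uy = U[:, :rank].T @ yc
    fitted = ybar + U[:, :rank] @ (shrink * uy)
    beta = Vt[:rank].T @ (shrink * uy / d)
    return ModelFit(
        method="RR",
        hyperparams={"lambda": lam},
        intercept=ybar - float(X.mean(axis=0) @ beta),
        coefficients=beta,
        fitted=fitted,
        selected=np.arange(X.shape[1]),
        fit_statistic=_corr_statistic(y, fitted),
    )


def information_criterion(
    rss: float, n: int, df: int, criterion: SelectionCriterion, p: int | None = None
) -> float:
    """n*log(RSS/n) + multiplier*df; RSS of 0 maps to -inf (degenerate winner)."""
    if df < 0:
        raise ValueError("df must be nonnegative")
    mult = criterion.multiplier(n, p if p is not None else df)
    if rss <= 0:
        return -np.inf
    return float(n * np.log(rss / n) + mult * df)


def post_selection_f_pvalue(
    X: np.ndarray, y: np.ndarray, selected: np.ndarray
) -> tuple[float, bool]:
    """F-test p-value of the OLS refit on the selected columns.

    Returns ``(p, degenerate)``.  An empty selection gives p = 1; a
    saturated or perfect fit gives the smallest positive float with the
    degeneracy flag set.
    """
    selected = np.asarray(selected, dtype=int)
    n = len(y)
    s = selected.size
    if s == 0:
        return 1.0, False
    if s >= n - 1:
        return sys.float_info.min, True
    Xc, yc, _ = _center(X[:, selected], y)
    tss = float(yc @ yc)
    if tss <= 0:
        return 1.0, True
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    rss = float(resid @ resid)
    if rss <= tss * 1e-14:
        return sys.float_info.min, True
    F = ((tss - rss) / s) / (rss / (n - s - 1))
    return float(stats.f.sf(F, s, n - s - 1)), False


def _score_sparse_fit(
    X: np.ndarray, y: np.ndarray, selected: np.ndarray
) -> tuple[float, bool]:
    """-log10 post-selection F-test p; empty models score 0."""
    p, degen = post_selection_f_pvalue(X, y, selected)
    return -float(np.log10(p)), degen


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    criterion: SelectionCriterion = SelectionCriterion("bic"),
    n_alphas: int = 100,
) -> ModelFit:
    """LASSO with the penalty chosen by an information criterion.

    A descending log-spaced path of 100 penalties runs from
    lambda_max = max_j |X_j' y_c| / n (the smallest penalty with an empty
    model) down to eps*lambda_max with eps = 1e-3 when n > p and 1e-2
    otherwise.  Each path solution is scored by
    IC = n*log(RSS/n) + multiplier * (number of nonzero coefficients) and
    the minimizer returned; ties go to the sparser (larger-penalty) end.
    The association score is -log10 of the selected model's F-test p.
    """
    Xc, yc, ybar = _center(X, y)
    n, p = Xc.shape
    if float(yc @ yc) <= 0 or not np.any(np.abs(Xc.T @ yc) > 0):
        return ModelFit(
            method="LASSO",
            hyperparams={"criterion": criterion.kind},
            intercept=ybar,
            coefficients=np.zeros(p),
            fitted=np.full_like(y, ybar, dtype=float),
            selected=np.array([], dtype=int),
            fit_statistic=0.0,
            degenerate=True,
        )
    eps = 1e-3 if n > p else 1e-2
    alphas, coefs, _ = lasso_path(Xc, yc, eps=eps, alphas=n_alphas)
    resid = yc[:, None] - Xc @ coefs
    rss = (resid**2).sum(axis=0)
    df = (coefs != 0).sum(axis=0)
    mult = criterion.multiplier(n, p)
    with np.errstate(divide="ignore"):
        ic = np.where(rss > 0, n * np.log(np.maximum(rss, 1e-300) / n) + mult * df, -np.inf)
    best = int(np.argmin(ic))  # argmin takes the first (largest-penalty) tie
    beta = coefs[:, best]
    selected = np.flatnonzero(beta)
    stat, degen = _score_sparse_fit(X, y, selected)
    fitted = ybar + Xc @ beta
    return ModelFit(
        method="LASSO",
        hyperparams={"criterion": criterion.kind, "lambda": float(alphas[best])},
        intercept=ybar - float(X.mean(axis=0) @ beta),
        coefficients=beta,
        fitted=fitted,
        selected=selected,
        fit_statistic=stat if selected.size else 0.0,
        degenerate=degen,
    )


def spls_select(
    X: np.ndarray,
    y: np.ndarray,
    K_max: int | None = None,
    eta_grid: np.ndarray | None = None,
    criterion: SelectionCriterion = SelectionCriterion("bic"),
) -> ModelFit:
    """Sparse PLS with (K, eta) chosen by an information criterion.

    For each sparsity level eta, components are built iteratively: the
    PLS direction X_d' y_c is hard-thresholded, zeroing entries whose
    magnitude falls below eta times the largest magnitude; variables
    surviving any of the first K components form the active set, on which
    a plain PLS fit with K components supplies the residual sum of
    squares.  IC = n*log(RSS/n) + multiplier * |active set| is minimized
    over the (K, eta) grid; the score is -log10 of the post-selection
    F-test p-value on the active set.  eta = 0 reproduces plain PLS.
    """
    Xc, yc, ybar = _center(X, y)
    n, p = Xc.shape
    _, _, _, rank = _svd(Xc)
    if K_max is None:
        K_max = min(10, rank)
    K_max = max(1, min(K_max, rank))
    if eta_grid is None:
        eta_grid = np.arange(0.1, 0.91, 0.1)
    mult = criterion.multiplier(n, p)
    tss = float(yc @ yc)
    if tss <= 0 or not np.any(np.abs(Xc.T @ yc) > 0):
        return ModelFit(
            method="SPLS",
            hyperparams={"criterion": criterion.kind},
            intercept=ybar,
            coefficients=np.zeros(p),
            fitted=np.full_like(y, ybar, dtype=float),
            selected=np.array([], dtype=int),
            fit_statistic=0.0,
            degenerate=True,
        )

    best = None  # (ic, K, eta, active)
    for eta in np.atleast_1d(eta_grid):
        Xd = Xc.copy()
        active: set[int] = set()
        for K in range(1, K_max + 1):
            w = Xd.T @ yc
            amax = np.abs(w).max()
            if amax <= 1e-12:
                break
            w_thr = np.where(np.abs(w) >= eta * amax, w, 0.0)
            active |= set(np.flatnonzero(w_thr).tolist())
            z = Xd @ w_thr
            zz = float(z @ z)
            if zz <= 0:
                break
            Xd = Xd - np.outer(z, Xd.T @ z / zz)
            idx = np.fromiter(sorted(active), dtype=int)
            rss = _pls_rss(Xc[:, idx], yc, min(K, idx.size))
            ic = n * np.log(max(rss, 1e-300) / n) + mult * idx.size if rss > 0 else -np.inf
            if best is None or ic < best[0]:
                best = (ic, K, float(eta), idx)

    if best is None:
        selected = np.array([], dtype=int)
        K_sel, eta_sel = 0, float(np.atleast_1d(eta_grid)[0])
    else:
        _, K_sel, eta_sel, selected = best

    beta = np.zeros(p)
    fitted = np.full_like(y, ybar, dtype=float)
    if selected.size:
        sub = fit_pls(X[:, selected], y, min(K_sel, _svd(Xc[:, selected])[3]))
        beta[selected] = sub.coefficients
        fitted = sub.fitted
    stat, degen = (_score_sparse_fit(X, y, selected) if selected.size else (0.0, False))
    return ModelFit(
        method="SPLS",
        hyperparams={"criterion": criterion.kind, "K": K_sel, "eta": eta_sel},
        intercept=ybar - float(X.mean(axis=0) @ beta),
        coefficients=beta,
        fitted=fitted,
        selected=selected,
        fit_statistic=stat,
        degenerate=degen,
    )


def _pls_rss(Xsub: np.ndarray, yc: np.ndarray, k: int) -> float:
    """Residual sum of squares of a k-component PLS fit on centered data."""
    Xc = Xsub - Xsub.mean(axis=0)
    _, _, _, _, cum_fit = _pls_path(Xc, yc, max(k, 1))
    if not cum_fit:
        return float(yc @ yc)
    f = cum_fit[min(k, len(cum_fit)) - 1]
    r = yc - f
    return float(r @ r)
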