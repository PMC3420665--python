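"""Regression fits: OLS equivalences, closed forms, selection criteria."""

import numpy as np
import pytest
from scipy import stats

from rarereg import (
    SelectionCriterion,
    choose_k,
    fit_pcr,
    fit_pls,
    fit_ridge,
    information_criterion,
    lasso_select,
    post_selection_f_pvalue,
    spls_select,
)


def ols_fitted(X, y):
    Z = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return Z @ beta


class TestOLSEquivalences:
    """Ridge(0), PCR(rank) and PLS(rank) all reproduce least squares."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=40)
        target = ols_fitted(X, y)
        for fit in (fit_ridge(X, y, 0.0), fit_pcr(X, y, 6), fit_pls(X, y, 6)):
            np.testing.assert_allclose(fit.fitted, target, atol=1e-8)

    def test_rank_deficient_ridge_zero_uses_pseudoinverse(self, rng):
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3, p=4
        y = rng.normal(size=20)
        fit = fit_ridge(X, y, 0.0)
        np.testing.assert_allclose(fit.fitted, ols_fitted(X, y), atol=1e-8)

    def test_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2 * x[:, 0] + rng.normal(size=30)
        target = ols_fitted(x, y)
        np.testing.assert_allclose(fit_pcr(x, y, 1).fitted, target, atol=1e-10)
        np.testing.assert_allclose(fit_pls(x, y, 1).fitted, target, atol=1e-10)


class TestRidge:
    def test_closed_form_toy(self):
        # centered single column [1,-1], y=[2,0], lambda=2: d^2=2 -> shrink 1/2
        fit = fit_ridge(np.array([[1.0], [-1.0]]), np.array([2.0, 0.0]), 2.0)
        np.testing.assert_allclose(fit.fitted, [1.5, 0.5])

    def test_huge_penalty_shrinks_to_mean(self, regression_problem):
        # fitted values collapse to the mean; the correlation statistic,
        # being scale-invariant, converges to its (smaller) heavy-shrinkage
        # limit rather than to zero
        X, y = regression_problem
        fit = fit_ridge(X, y, 1e12)
        np.testing.assert_allclose(fit.fitted, np.full_like(y, y.mean()), atol=1e-6)
        assert fit.fit_statistic <= fit_ridge(X, y, 0.0).fit_statistic

    def test_statistic_monotone_in_penalty(self, regression_problem):
        X, y = regression_problem
        stats_ = [fit_ridge(X, y, lam).fit_statistic
                  for lam in [0.0, 1.0, 10.0, 100.0, 1e4]]
        assert all(a >= b - 1e-12 for a, b in zip(stats_, stats_[1:]))

    def test_negative_penalty_rejected(self, regression_problem):
        X, y = regression_problem
        with pytest.raises(ValueError):
            fit_ridge(X, y, -1.0)


class TestPCR:
    def test_hand_svd_two_by_two(self):
        # columns [1,-1] and [1,1]: singular directions are the columns
        # themselves; with y=[2,0], k=1 keeps the larger-variance direction.
        X = np.array([[1.0, 1.0], [-1.0, 1.0]])
        y = np.array([2.0, 0.0])
        Xc = X - X.mean(axis=0)  # [[0... wait columns already centered]]
        U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
        yc = y - y.mean()
        expected = y.mean() + U[:, :1] @ (U[:, :1].T @ yc)
        fit = fit_pcr(X, y, 1)
        np.testing.assert_allclose(fit.fitted, expected, atol=1e-12)

    def test_k_beyond_rank_raises(self, regression_problem):
        X, y = regression_problem
        with pytest.raises(ValueError):
            fit_pcr(X, y, X.shape[1] + 1)

    def test_components_ordered_by_singular_value(self, rng):
        # y aligned with the top-variance direction: k=1 captures it
        n = 200
        t = rng.normal(size=n)
        X = np.column_stack([3 * t + 0.05 * rng.normal(size=n),
                             rng.normal(size=n)])
        y = t
        f1 = fit_pcr(X, y, 1)
        assert f1.fit_statistic > 0.99


class TestChooseK:
    def test_rule_one(self, regression_problem):
        X, y = regression_problem
        assert choose_k(X, y, rule="one") == 1

    def test_y_in_first_component_span(self, rng):
        n = 100
        t = rng.normal(size=n)
        X = np.column_stack([5 * t, rng.normal(size=n) * 0.1])
        y = 2 * (t - t.mean())
        assert choose_k(X, y, theta=0.99, method="pcr") == 1

    def test_theta_one_gives_full_rank(self, regression_problem):
        X, y = regression_problem
        assert choose_k(X, y, theta=1.0) == np.linalg.matrix_rank(X - X.mean(0))

    @pytest.mark.parametrize("method", ["pcr", "pls"])
    def test_matches_exhaustive_sweep(self, rng, method):
        X = rng.normal(size=(80, 6))
        y = X @ np.array([1.0, -1.0, 0.5, 0, 0, 0]) + rng.normal(size=80)
        theta = 0.8
        fitter = fit_pcr if method == "pcr" else fit_pls
        r2 = []
        for k in range(1, 7):
            f = fitter(X, y, k)
            resid = y - f.fitted
            r2.append(1 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))
        target = theta * r2[-1]
        expected = next(k for k, v in enumerate(r2, start=1) if v >= target - 1e-12)
        assert choose_k(X, y, theta=theta, method=method) == expected


class TestPLS:
    def test_first_weight_proportional_to_covariance(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 0] + rng.normal(size=50)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        z = Xc @ w
        expected_first = y.mean() + z * (z @ yc) / (z @ z)
        fit = fit_pls(X, y, 1)
        np.testing.assert_allclose(fit.fitted, expected_first, atol=1e-10)

    def test_zero_covariance_null_fit(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x
        fit = fit_pls(X, y, 1)
        assert fit.fit_statistic == 0.0
        assert fit.degenerate

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(60, 5))
        y = X @ np.array([1.0, 0.5, 0, 0, -1.0]) + rng.normal(size=60)
        k = 3
        ref = PLSRegression(n_components=k, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(
            fit_pls(X, y, k).fitted, ref.predict(X).ravel(), atol=1e-8
        )


class TestInformationCriterion:
    def test_aic_log_one(self):
        crit = SelectionCriterion("aic")
        assert information_criterion(100.0, 100, 3, crit) == pytest.approx(6.0)

    def test_bic_value(self):
        crit = SelectionCriterion("bic")
        assert information_criterion(100.0, 100, 3, crit) == pytest.approx(
            3 * np.log(100), abs=1e-10
        )

    def test_gic_value(self):
        crit = SelectionCriterion("gic")
        expected = 3 * np.log(np.log(100)) * np.log(50)
        assert information_criterion(100.0, 100, 3, crit, p=50) == pytest.approx(
            expected, abs=1e-10
        )
        assert expected == pytest.approx(17.92, abs=0.01)

    def test_zero_rss_wins_immediately(self):
        assert information_criterion(0.0, 50, 2, SelectionCriterion("aic")) == -np.inf


class TestFTest:
    def test_empty_selection_p_one(self, regression_problem):
        X, y = regression_problem
        p, degen = post_selection_f_pvalue(X, y, np.array([], dtype=int))
        assert p == 1.0 and not degen

    def test_worked_case_n10_s2(self):
        # R^2 = 0.5, s=2, n=10 -> F = 3.5, p from F(2, 7)
        rng = np.random.default_rng(5)
        # construct data with exact R^2 = 0.5 via orthogonal pieces
        n = 10
        x1 = np.linspace(-1, 1, n)
        x2 = x1**2 - np.mean(x1**2)
        e = rng.normal(size=n)
        e -= e.mean()
        # orthogonalize noise against [x1, x2]
        Z = np.column_stack([x1, x2])
        e -= Z @ np.linalg.lstsq(Z, e, rcond=None)[0]
        signal = x1 / np.linalg.norm(x1)
        noise = e / np.linalg.norm(e)
        y = signal + noise  # ESS = RSS = 1
        p, _ = post_selection_f_pvalue(np.column_stack([x1, x2]), y, np.array([0, 1]))
        expected = stats.f.sf(3.5, 2, 7)
        assert expected == pytest.approx(0.0885, abs=5e-4)
        assert p == pytest.approx(expected, rel=1e-6)

    def test_perfect_fit_degenerate(self):
        x = np.arange(10.0)[:, None]
        y = 2 * x[:, 0] + 1
        p, degen = post_selection_f_pvalue(x, y, np.array([0]))
        assert degen and p < 1e-300


class TestLasso:
    def test_empty_model_at_lambda_max(self, rng):
        # weak noise response: BIC should keep the empty model;
        # statistic is then exactly 0
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50) * 0.01
        fit = lasso_select(X, y, SelectionCriterion("bic"))
        assert fit.selected.size == 0 or fit.fit_statistic >= 0

    def test_kkt_at_selected_lambda(self, rng):
        X = rng.normal(size=(60, 8))
        y = X @ np.r_[2.0, np.zeros(7)] + rng.normal(size=60)
        fit = lasso_select(X, y, SelectionCriterion("aic"))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        resid = yc - Xc @ fit.coefficients
        lam = fit.hyperparams["lambda"]
        inactive = np.setdiff1d(np.arange(8), fit.selected)
        assert (np.abs(Xc[:, inactive].T @ resid) / 60 <= lam + 1e-8).all()

    def test_orthonormal_design_soft_threshold(self, rng):
        # On an orthonormal design the LASSO path is soft-thresholding of
        # the OLS coefficients; the IC minimum must match an exhaustive
        # evaluation over the same path grid.
        n, p = 64, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        Q -= Q.mean(axis=0)
        # re-orthonormalize after centering
        Q, _ = np.linalg.qr(Q)
        beta = np.array([3.0, -2.0, 1.0, 0.0, 0.0, 0.0])
        y = Q @ beta + 0.3 * rng.normal(size=n)
        crit = SelectionCriterion("bic")
        fit = lasso_select(Q, y, crit)
        yc = y - y.mean()
        ols = Q.T @ yc / (Q**2).sum(axis=0)  # per-column OLS (orthogonal)
        lam = fit.hyperparams["lambda"]
        col_ss = (Q - Q.mean(0)).T @ (Q - Q.mean(0))
        scale = np.diag(col_ss) / n
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam / scale, 0.0)
        np.testing.assert_allclose(fit.coefficients, soft, atol=1e-6)

    def test_bic_recovers_strong_predictor(self):
        # one predictor with beta=2, sigma=0.5, n=200: BIC keeps it nearly always
        hits = 0
        n_sim = 200
        rng = np.random.default_rng(11)
        for _ in range(n_sim):
            X = rng.normal(size=(200, 5))
            y = 2.0 * X[:, 0] + 0.5 * rng.normal(size=200)
            fit = lasso_select(X, y, SelectionCriterion("bic"))
            hits += 0 in fit.selected
        assert hits / n_sim > 0.95


class TestSPLS:
    def test_eta_zero_equals_pls(self, regression_problem):
        X, y = regression_problem
        crit = SelectionCriterion("bic")
        fit = spls_select(X, y, K_max=3, eta_grid=np.array([0.0]), criterion=crit)
        assert fit.selected.size == X.shape[1]
        ref = fit_pls(X, y, fit.hyperparams["K"])
        np.testing.assert_allclose(fit.coefficients, ref.coefficients, atol=1e-8)

    def test_eta_near_one_keeps_dominant_only(self, rng):
        # one dominant loading: at eta=0.9 with K=1 only it survives
        n = 100
        X = rng.normal(size=(n, 5)) * 0.1
        X[:, 2] = rng.normal(size=n)
        y = 3 * X[:, 2] + 0.1 * rng.normal(size=n)
        Xc = X - X.mean(0)
        w = np.abs(Xc.T @ (y - y.mean()))
        assert w.argmax() == 2  # construction check
        fit = spls_select(X, y, K_max=1, eta_grid=np.array([0.9]),
                          criterion=SelectionCriterion("bic"))
        assert fit.selected.tolist() == [2]

    def test_grid_minimizer_matches_brute_force(self, rng):
        from rarereg.models import _pls_rss

        X = rng.normal(size=(50, 6))
        y = X @ np.r_[1.5, np.zeros(5)] + rng.normal(size=50)
        crit = SelectionCriterion("bic")
        etas = np.array([0.2, 0.6])
        fit = spls_select(X, y, K_max=2, eta_grid=etas, criterion=crit)
        # brute-force the (K, eta) grid with the same component recursion
        Xc, yc = X - X.mean(0), y - y.mean()
        n = 50
        best = (np.inf, None)
        for eta in etas:
            Xd = Xc.copy()
            active: set = set()
            for K in (1, 2):
                w = Xd.T @ yc
                w_thr = np.where(np.abs(w) >= eta * np.abs(w).max(), w, 0.0)
                active |= set(np.flatnonzero(w_thr).tolist())
                z = Xd @ w_thr
                Xd = Xd - np.outer(z, Xd.T @ z / (z @ z))
                idx = np.array(sorted(active))
                rss = _pls_rss(Xc[:, idx], yc, min(K, idx.size))
                ic = n * np.log(rss / n) + crit.multiplier(n, 6) * idx.size
                if ic < best[0]:
                    best = (ic, set(idx.tolist()))
        assert set(fit.selected.tolist()) == best[1]
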