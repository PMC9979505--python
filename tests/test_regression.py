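"""The four per-class fitters against closed-form and brute-force oracles."""

import numpy as np
import pytest

from bprx.regression import (
    _drlr_smooth,
    drlr_objective,
    fit_cart,
    fit_drlr,
    fit_lasso,
    fit_ols,
)


def _linear_problem(rng, n=50, p=3, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y, beta


class TestOLS:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        y = 2 * X[:, 0] - 3 * X[:, 1]
        m = fit_ols(X, y)
        assert np.allclose(m.coef_, [2.0, -3.0], atol=1e-8)
        assert m.intercept_ == pytest.approx(0.0, abs=1e-8)

    def test_constant_outcome(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        m = fit_ols(X, np.full(30, 7.0))
        assert np.allclose(m.coef_, 0.0, atol=1e-8)
        assert m.intercept_ == pytest.approx(7.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X, y, _ = _linear_problem(rng, noise=0.5)
        m = fit_ols(X, y)
        Xa = np.column_stack([X, np.ones(len(X))])
        theta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)  # normal-equations oracle
        assert np.allclose(m.coef_, theta[:-1], atol=1e-8)
        assert m.intercept_ == pytest.approx(theta[-1], abs=1e-8)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x, rng.normal(size=30)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(X, x, feature_names=["a", "a_doubled", "b"], ridge_fallback=False)
        m = fit_ols(X, x)  # ridge fallback engages silently
        assert "ridge_fallback" in m.hyperparams


class TestLasso:
    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(4)
        X, y, _ = _linear_problem(rng, noise=0.3)
        ols = fit_ols(X, y)
        lasso = fit_lasso(X, y, lam=0.0)
        assert np.allclose(lasso.coef_, ols.coef_, atol=1e-6)

    def test_large_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(5)
        X, y, _ = _linear_problem(rng, noise=0.3)
        m = fit_lasso(X, y, lam=1e4)
        assert np.allclose(m.coef_, 0.0)

    def test_soft_threshold_closed_form(self):
        """1-D design normalized to sum(x^2)=n: minimizing MSE + lam|b| gives
        b = sign(b_ols) * max(|b_ols| - lam/2, 0)."""
        rng = np.random.default_rng(6)
        n = 200
        x = rng.normal(size=n)
        x = x - x.mean()
        x = x / np.sqrt(np.mean(x**2))  # sum(x^2) = n exactly
        y = 0.8 * x + 0.1 * rng.normal(size=n)
        y = y - y.mean()
        b_ols = float(x @ y / (x @ x))
        for lam in (0.1, 0.5, 2.0):
            m = fit_lasso(x[:, None], y, lam=lam)
            expected = np.sign(b_ols) * max(abs(b_ols) - lam / 2.0, 0.0)
            assert m.coef_[0] == pytest.approx(expected, abs=1e-6)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            fit_lasso(np.ones((5, 1)), np.ones(5), lam=-1.0)


class TestCART:
    def test_constant_outcome_single_leaf(self):
        X = np.random.default_rng(7).normal(size=(30, 2))
        m = fit_cart(X, np.full(30, 3.0), max_depth=3, min_samples_leaf=1)
        assert np.allclose(m.predict(X), 3.0)

    def test_depth_one_step_function(self):
        """A depth-1 tree on y = 1{x1 > 0} recovers the exhaustive-search
        split: threshold near 0, leaf means 0 and 1."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(float)
        m = fit_cart(X, y, max_depth=1, min_samples_leaf=1)
        # exhaustive oracle over candidate thresholds on each feature
        best = None
        for j in range(2):
            for thr in np.unique(X[:, j]):
                left = y[X[:, j] <= thr]
                right = y[X[:, j] > thr]
                if len(left) == 0 or len(right) == 0:
                    continue
                sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
                if best is None or sse < best[0]:
                    best = (sse, j)
        assert best[1] == 0  # oracle splits on x1
        tree = m.model_.tree_
        assert tree.feature[0] == 0
        assert abs(tree.threshold[0]) < 0.2
        leaf_means = sorted(np.unique(m.predict(X)))
        assert leaf_means == pytest.approx([0.0, 1.0])

    def test_irrelevant_feature_permutation_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(150, 3))
        y = np.where(X[:, 0] > 0, 5.0, 1.0)
        m = fit_cart(X, y, max_depth=2, min_samples_leaf=1)
        Xp = X.copy()
        Xp[:, 2] = rng.permutation(Xp[:, 2])
        assert np.allclose(m.predict(X), m.predict(Xp))

    def test_importances_nonnegative(self):
        rng = np.random.default_rng(10)
        X, y, _ = _linear_problem(rng, noise=0.2)
        m = fit_cart(X, y, max_depth=4)
        assert (m.coef_ >= 0).all()

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="max_depth"):
            fit_cart(np.ones((5, 1)), np.ones(5), max_depth=0)


class TestDRLR:
    def test_intercept_only_is_median(self):
        """With absolute loss the optimal constant is the median, not the
        mean: y = {1, 2, 100} fits intercept 2 (OLS would give 34.33)."""
        X = np.zeros((3, 1))
        y = np.array([1.0, 2.0, 100.0])
        m = fit_drlr(X, y, epsilon=0.0)
        assert m.intercept_ == pytest.approx(2.0, abs=1e-6)
        ols = fit_ols(X, y)
        assert ols.intercept_ == pytest.approx(34.333333, abs=1e-4)

    def test_epsilon_zero_matches_quantile_regression(self):
        """LAD limit cross-checked against median regression (IRLS path in
        statsmodels — an algorithm independent of both package solvers)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        X, y, _ = _linear_problem(rng, n=120, p=4, noise=0.5)
        m = fit_drlr(X, y, epsilon=0.0)
        qr = sm.QuantReg(y, sm.add_constant(X)).fit(q=0.5)
        obj_pkg = drlr_objective(m.coef_, m.intercept_, X, y, 0.0)
        obj_sm = drlr_objective(qr.params[1:], qr.params[0], X, y, 0.0)
        assert obj_pkg <= obj_sm + 1e-6 * max(1.0, abs(obj_sm))

    def test_large_epsilon_shrinks_coefficients(self):
        """The penalty dominates: coefficient norm decays like O(1/epsilon)."""
        rng = np.random.default_rng(12)
        X, y, _ = _linear_problem(rng, noise=0.5)
        norms = [
            np.linalg.norm(fit_drlr(X, y, epsilon=e).coef_) for e in (1.0, 100.0, 1e4)
        ]
        assert norms[1] < norms[0] and norms[2] < norms[1]
        assert norms[1] < 0.05 and norms[2] < 1e-3

    def test_smooth_solver_restart_invariance(self):
        """Convexity: different start points land on the same objective."""
        rng = np.random.default_rng(13)
        X, y, _ = _linear_problem(rng, n=80, p=4, noise=0.5)
        eps = 0.05
        b1, i1 = _drlr_smooth(X, y, eps)
        theta0 = rng.normal(size=5) * 5
        b2, i2 = _drlr_smooth(X, y, eps, theta0=theta0)
        o1 = drlr_objective(b1, i1, X, y, eps)
        o2 = drlr_objective(b2, i2, X, y, eps)
        assert abs(o1 - o2) < 1e-6 * max(1.0, abs(o1))

    def test_polyhedral_ground_metrics_solve(self):
        rng = np.random.default_rng(14)
        X, y, _ = _linear_problem(rng, n=60, p=3, noise=0.3)
        for metric in ("l1", "linf"):
            m = fit_drlr(X, y, epsilon=0.05, ground_metric=metric)
            assert np.isfinite(m.train_loss)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            fit_drlr(np.ones((5, 1)), np.ones(5), epsilon=-0.1)


def test_all_fitters_invariant_to_row_order():
    rng = np.random.default_rng(15)
    X, y, _ = _linear_problem(rng, n=60, p=3, noise=0.4)
    perm = rng.permutation(len(y))
    for fit, kwargs in [
        (fit_ols, {}),
        (fit_lasso, {"lam": 0.1}),
        (fit_cart, {"max_depth": 3}),
        (fit_drlr, {"epsilon": 0.05}),
    ]:
        a = fit(X, y, **kwargs)
        b = fit(X[perm], y[perm], **kwargs)
        assert np.allclose(a.predict(X), b.predict(X), atol=1e-5)
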