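"""Per-drug-class outcome regressions: OLS, LASSO, CART and DRLR.

Each drug class gets its own regression of next-period SBP on the visit
features; the fitted coefficient vector then serves two purposes — direct
prediction (LASSO/CART) and as feature weights for the counterfactual
nearest-neighbor metric (OLS/DRLR).

DRLR — distributionally robust linear regression — is the robust member of
the family.  It hedges the absolute-loss regression against all data
distributions within a Wasserstein ball of radius epsilon around the
empirical distribution, which reduces to the regularized program

    min_{beta, b}  (1/N) sum_i |y_i - x_i' beta - b|  +  eps * ||(-beta, 1)||_*

where ||.||_* is the dual of the ground metric on (x, y) space.  The
absolute loss already blunts vertical outliers (entry errors in outcome
measurements); the Wasserstein penalty additionally controls sensitivity
to perturbations of the design.  With the default l2 ground metric the
dual norm is sqrt(1 + ||beta||^2); l1 and l-infinity ground metrics give
polyhedral penalties and are solved exactly as linear programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy.optimize import linprog, minimize
from sklearn.linear_model import Lasso
from sklearn.tree import DecisionTreeRegressor

ALGORITHMS = ("DRLR", "OLS", "LASSO", "CART")

# hyperparameter grids used when a validation set is supplied
LASSO_GRID = tuple(float(x) for x in np.logspace(-4, 1, 11))
DRLR_GRID = (0.0, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3)
CART_DEPTH_GRID = (2, 3, 4, 5, 6, 8)


@dataclass
class FittedRegressor:
    """A fitted per-class outcome model.

    ``coef_`` is the linear coefficient vector for OLS/LASSO/DRLR; for CART
    it is the (non-negative) impurity-based importance vector standing in
    as metric weights, while prediction goes through the stored tree.
    """

    drug_class: Optional[str]
    algorithm: str
    coef_: np.ndarray
    intercept_: float
    hyperparams: dict = field(default_factory=dict)
    train_loss: float = float("nan")
    feature_names: Optional[list[str]] = None
    model_: object = None  # the tree, for CART

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.algorithm == "CART":
            return self.model_.predict(X)
        return X @ self.coef_ + self.intercept_

    @property
    def metric_weights(self) -> np.ndarray:
        """|beta| per feature — the weights of the KNN distance metric."""
        return np.abs(self.coef_)


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
    return X, y


def fit_ols(
    X, y, drug_class: Optional[str] = None,
    feature_names: Optional[Sequence[str]] = None,
    ridge_fallback: bool = True,
) -> FittedRegressor:
    """Ordinary least squares with an explicit collinearity check.

    Rank-deficient designs either fall back to a minuscule ridge
    (``ridge_fallback=True``, the default) or raise an error naming the
    dependent columns, identified from a pivoted QR of the design.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    Xa = np.column_stack([X, np.ones(n)])
    rank = np.linalg.matrix_rank(Xa)
    hyper = {}
    if rank < p + 1:
        if not ridge_fallback:
            _, R, piv = sla.qr(Xa, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(Xa.shape) * np.finfo(float).eps
            bad = sorted(piv[np.flatnonzero(diag < tol)])
            names = (
                [feature_names[j] if j < p else "intercept" for j in bad]
                if feature_names is not None
                else [f"column {j}" for j in bad]
            )
            raise ValueError(f"rank-deficient design; collinear columns: {names}")
        # tiny ridge on the features (intercept unpenalized)
        lam = 1e-8
        G = Xa.T @ Xa + lam * np.diag([1.0] * p + [0.0])
        theta = np.linalg.solve(G, Xa.T @ y)
        hyper = {"ridge_fallback": lam}
    else:
        theta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    beta, b = theta[:p], float(theta[p])
    resid = y - X @ beta - b
    return FittedRegressor(
        drug_class=drug_class, algorithm="OLS", coef_=beta, intercept_=b,
        hyperparams=hyper, train_loss=float(np.mean(resid**2)),
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def fit_lasso(
    X, y, lam: Optional[float] = None,
    validation: Optional[tuple[np.ndarray, np.ndarray]] = None,
    drug_class: Optional[str] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> FittedRegressor:
    """L1-penalized least squares minimizing MSE + lam * ||beta||_1.

    When ``lam`` is omitted it is chosen on the validation set by MSE
    (the grid is recorded in ``hyperparams``).  Note the scikit-learn
    parameterization ``alpha = lam / 2`` under its 1/(2n) loss scaling.
    """
    X, y = _as_xy(X, y)
    if lam is not None and lam < 0:
        raise ValueError(f"lasso penalty must be >= 0, got {lam}")

    def _fit(l):
        if l == 0.0:
            base = fit_ols(X, y, feature_names=feature_names)
            return base.coef_, base.intercept_
        m = Lasso(alpha=l / 2.0, fit_intercept=True, max_iter=100_000, tol=1e-10)
        m.fit(X, y)
        return m.coef_.copy(), float(m.intercept_)

    hyper = {}
    if lam is None:
        if validation is None:
            lam = 0.01
        else:
            Xv, yv = _as_xy(*validation)
            scores = []
            for l in LASSO_GRID:
                beta, b = _fit(l)
                scores.append(float(np.mean((yv - Xv @ beta - b) ** 2)))
            lam = LASSO_GRID[int(np.argmin(scores))]
            hyper["grid"] = list(LASSO_GRID)
    beta, b = _fit(lam)
    resid = y - X @ beta - b
    hyper["lambda"] = lam
    return FittedRegressor(
        drug_class=drug_class, algorithm="LASSO", coef_=beta, intercept_=b,
        hyperparams=hyper,
        train_loss=float(np.mean(resid**2) + lam * np.abs(beta).sum()),
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def fit_cart(
    X, y, max_depth: Optional[int] = None,
    validation: Optional[tuple[np.ndarray, np.ndarray]] = None,
    min_samples_leaf: int = 5,
    drug_class: Optional[str] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> FittedRegressor:
    """Variance-reduction regression tree; leaf means predict.

    The tree has no coefficient vector, so the impurity-based feature
    importances (total variance reduction per feature, normalized) stand in
    as the non-negative ``coef_`` used by the KNN metric when requested.
    """
    X, y = _as_xy(X, y)
    if max_depth is not None and max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    hyper = {}
    if max_depth is None:
        if validation is not None:
            Xv, yv = _as_xy(*validation)
            scores = []
            for d in CART_DEPTH_GRID:
                t = DecisionTreeRegressor(max_depth=d, min_samples_leaf=min_samples_leaf, random_state=0)
                t.fit(X, y)
                scores.append(float(np.mean((yv - t.predict(Xv)) ** 2)))
            max_depth = CART_DEPTH_GRID[int(np.argmin(scores))]
            hyper["grid"] = list(CART_DEPTH_GRID)
        else:
            max_depth = 5
    tree = DecisionTreeRegressor(max_depth=max_depth, min_samples_leaf=min_samples_leaf, random_state=0)
    tree.fit(X, y)
    hyper["max_depth"] = max_depth
    hyper["min_samples_leaf"] = min_samples_leaf
    resid = y - tree.predict(X)
    return FittedRegressor(
        drug_class=drug_class, algorithm="CART",
        coef_=tree.feature_importances_.copy(), intercept_=0.0,
        hyperparams=hyper, train_loss=float(np.mean(resid**2)),
        feature_names=list(feature_names) if feature_names is not None else None,
        model_=tree,
    )


# ---------------------------------------------------------------------------
# DRLR


def drlr_objective(beta: np.ndarray, intercept: float, X, y, epsilon: float,
                   ground_metric: str = "l2") -> float:
    """(1/N) sum |residual| + epsilon * dual-norm of (-beta, 1)."""
    X, y = _as_xy(X, y)
    beta = np.asarray(beta, dtype=float)
    resid = y - X @ beta - intercept
    loss = float(np.mean(np.abs(resid)))
    if ground_metric == "l2":
        pen = float(np.sqrt(1.0 + beta @ beta))
    elif ground_metric == "linf":  # dual norm is l1
        pen = float(np.abs(beta).sum() + 1.0)
    elif ground_metric == "l1":  # dual norm is l-infinity
        pen = float(max(np.abs(beta).max(initial=0.0), 1.0))
    else:
        raise ValueError(f"unknown ground metric {ground_metric!r}")
    return loss + epsilon * pen


def _drlr_lp(X, y, epsilon: float, ground_metric: str):
    """Exact LP solve for the polyhedral cases (epsilon=0 or l1/linf metric).

    Variables: residual envelopes t (n), split coefficients beta+/- (2p),
    free intercept b (split), and for the l1 ground metric an envelope s
    for max(||beta||_inf, 1).
    """
    n, p = X.shape
    # columns: t(n), bp(p), bm(p), b_pos, b_neg [, s]
    n_var = n + 2 * p + 2 + (1 if (ground_metric == "l1" and epsilon > 0) else 0)
    c = np.zeros(n_var)
    c[:n] = 1.0 / n
    if epsilon > 0:
        if ground_metric == "linf":
            c[n: n + 2 * p] = epsilon
        elif ground_metric == "l1":
            c[-1] = epsilon
        else:
            raise ValueError("LP path only handles polyhedral penalties")

    rows, cols, vals, b_ub = [], [], [], []

    def add(r, cidx, v):
        rows.append(r)
        cols.append(cidx)
        vals.append(v)

    r = 0
    for i in range(n):
        # residual_i - t_i <= 0  and  -residual_i - t_i <= 0
        for sign in (1.0, -1.0):
            add(r, i, -1.0)
            for j in range(p):
                add(r, n + j, -sign * X[i, j])
                add(r, n + p + j, sign * X[i, j])
            add(r, n + 2 * p, -sign)
            add(r, n + 2 * p + 1, sign)
            b_ub.append(-sign * y[i])
            r += 1
    if ground_metric == "l1" and epsilon > 0:
        for j in range(p):  # bp_j + bm_j - s <= 0
            add(r, n + j, 1.0)
            add(r, n + p + j, 1.0)
            add(r, n_var - 1, -1.0)
            b_ub.append(0.0)
            r += 1

    from scipy.sparse import coo_matrix

    A = coo_matrix((vals, (rows, cols)), shape=(r, n_var))
    bounds = [(0, None)] * n + [(0, None)] * (2 * p) + [(0, None), (0, None)]
    if ground_metric == "l1" and epsilon > 0:
        bounds.append((1.0, None))
    res = linprog(c, A_ub=A.tocsr(), b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"DRLR linear program failed to converge: {res.message}")
    z = res.x
    beta = z[n: n + p] - z[n + p: n + 2 * p]
    b = float(z[n + 2 * p] - z[n + 2 * p + 1])
    return beta, b


def _drlr_smooth(X, y, epsilon: float, theta0: Optional[np.ndarray] = None):
    """Pseudo-Huber continuation + L-BFGS for the l2 dual-norm penalty."""
    n, p = X.shape
    if theta0 is None:
        theta0 = np.zeros(p + 1)
        theta0[p] = np.median(y)
    theta = np.asarray(theta0, dtype=float).copy()

    def make_obj(mu):
        def f(th):
            beta, b = th[:p], th[p]
            r = y - X @ beta - b
            s = np.sqrt(r * r + mu * mu)
            loss = np.mean(s - mu)
            q = np.sqrt(1.0 + beta @ beta)
            g_r = -(r / s) / n
            grad = np.empty(p + 1)
            grad[:p] = X.T @ g_r + epsilon * beta / q
            grad[p] = g_r.sum()
            return loss + epsilon * q, grad

        return f

    for mu in (10.0, 1.0, 0.1, 0.01, 1e-3, 1e-4, 1e-5, 1e-6):
        res = minimize(
            make_obj(mu), theta, jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
        )
        theta = res.x
    return theta[:p], float(theta[p])


def fit_drlr(
    X, y, epsilon: Optional[float] = None,
    ground_metric: str = "l2",
    validation: Optional[tuple[np.ndarray, np.ndarray]] = None,
    drug_class: Optional[str] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> FittedRegressor:
    """Wasserstein-robust absolute-loss regression.

    ``epsilon`` is the ambiguity radius; 0 recovers plain least absolute
    deviations.  When omitted, it is chosen on the validation set by mean
    absolute error over a logarithmic grid.  Polyhedral penalties (epsilon=0
    or l1/linf ground metrics) are solved exactly as linear programs; the
    l2 dual-norm case uses smoothing continuation with L-BFGS, checked to
    1e-6 relative objective against the nonsmooth objective.
    """
    X, y = _as_xy(X, y)
    if epsilon is not None and epsilon < 0:
        raise ValueError(f"ambiguity radius must be >= 0, got {epsilon}")
    if ground_metric not in ("l2", "l1", "linf"):
        raise ValueError(f"unknown ground metric {ground_metric!r}")

    def _solve(eps):
        if eps == 0.0 or ground_metric in ("l1", "linf"):
            return _drlr_lp(X, y, eps, "linf" if eps == 0.0 else ground_metric)
        return _drlr_smooth(X, y, eps)

    hyper = {"ground_metric": ground_metric}
    if epsilon is None:
        if validation is None:
            epsilon = 0.01
        else:
            Xv, yv = _as_xy(*validation)
            scores = []
            for eps in DRLR_GRID:
                beta, b = _solve(eps)
                scores.append(float(np.mean(np.abs(yv - Xv @ beta - b))))
            epsilon = DRLR_GRID[int(np.argmin(scores))]
            hyper["grid"] = list(DRLR_GRID)
    beta, b = _solve(epsilon)
    hyper["epsilon"] = epsilon
    obj = drlr_objective(beta, b, X, y, epsilon, ground_metric)
    return FittedRegressor(
        drug_class=drug_class, algorithm="DRLR", coef_=beta, intercept_=b,
        hyperparams=hyper, train_loss=obj,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


FITTERS = {"OLS": fit_ols, "LASSO": fit_lasso, "CART": fit_cart, "DRLR": fit_drlr}


def fit_algorithm(
    algorithm: str, X, y,
    validation=None, drug_class=None, feature_names=None, **kwargs
) -> FittedRegressor:
    """Dispatch to one of the four fitters by algorithm name."""
    algorithm = algorithm.upper()
    if algorithm == "OLS":
        return fit_ols(X, y, drug_class=drug_class, feature_names=feature_names, **kwargs)
    if algorithm == "LASSO":
        return fit_lasso(X, y, validation=validation, drug_class=drug_class,
                         feature_names=feature_names, **kwargs)
    if algorithm == "CART":
        return fit_cart(X, y, validation=validation, drug_class=drug_class,
                        feature_names=feature_names, **kwargs)
    if algorithm == "DRLR":
        return fit_drlr(X, y, validation=validation, drug_class=drug_class,
                        feature_names=feature_names, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
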