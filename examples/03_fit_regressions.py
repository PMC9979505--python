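"""Fit the four per-class outcome regressions; see robustness to outliers.

DRLR (distributionally robust linear regression) minimizes mean absolute
loss plus a Wasserstein-ambiguity penalty on the coefficients.  Unlike
least squares it barely moves when a tenth of the outcomes are corrupted
by +/- 50 mmHg entry errors — the situation real blood-pressure charting
produces.
"""

import numpy as np

from bprx.regression import fit_cart, fit_drlr, fit_lasso, fit_ols

rng = np.random.default_rng(0)
n, p = 300, 5
X = rng.normal(size=(n, p))
beta_true = np.array([4.0, -3.0, 2.0, 0.0, 1.0])
y_clean = X @ beta_true + 140.0 + rng.normal(size=n)

# corrupt 10% of outcomes with +/- 50 mmHg entry errors
y = y_clean.copy()
idx = rng.choice(n, size=30, replace=False)
y[idx] += rng.choice([-1.0, 1.0], size=30) * 50.0

print(f"true coefficients:  {beta_true}")
for name, model in [
    ("OLS  ", fit_ols(X, y)),
    ("LASSO", fit_lasso(X, y, lam=0.1)),
    ("DRLR ", fit_drlr(X, y, epsilon=0.01)),
]:
    err = np.linalg.norm(model.coef_ - beta_true)
    print(f"{name} coef error under contamination: {err:6.3f}   "
          f"beta_hat = {np.round(model.coef_, 2)}")

cart = fit_cart(X, y, max_depth=4)
print(f"CART  importance (sums to 1):              {np.round(cart.coef_, 2)}")
print("\nThe robust fit's error stays near the clean-data level; OLS is "
      "dragged by the corrupted rows.")
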