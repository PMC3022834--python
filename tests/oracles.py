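"""Independent brute-force oracles for the random-intercept model.

These build the full marginal covariance V = sigma_e^2 (I + lambda Z Z')
explicitly and evaluate the exact (restricted) log-likelihood, maximising it
by dense multi-stage grid search over log(lambda).  They share no code with
the profiled fitter under test.
"""

import math

import numpy as np


def _loglik_at(y, X, groups, lam, reml=True):
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    codes = np.unique(groups, return_inverse=True)[1]
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    Q = float(r @ Vi @ r)
    dof = n - p if reml else n
    sigma2 = Q / dof
    _, logdet_v = np.linalg.slogdet(V)
    ll = -0.5 * (dof * (math.log(2 * math.pi * sigma2) + 1.0) + logdet_v)
    if reml:
        _, logdet_a = np.linalg.slogdet(A)
        ll -= 0.5 * logdet_a
    return ll, beta, sigma2


def grid_fit(y, X, groups, reml=True, stages=3, width=16.0, points=81):
    """Dense multi-stage grid maximisation over log(lambda), with lambda=0
    always included and a final parabolic-vertex refinement (the criterion is
    float-flat near the optimum, so the vertex is read off at a stage where
    differences still exceed rounding noise).
    Returns (beta, lambda, sigma_e^2, loglik)."""
    best = (-np.inf, 0.0)
    lo, hi = -width, width
    grid = vals = None
    for _ in range(stages):
        grid = np.linspace(lo, hi, points)
        vals = [(_loglik_at(y, X, groups, math.exp(t), reml=reml))[0] for t in grid]
        j = int(np.nanargmax(vals))
        if vals[j] > best[0]:
            best = (vals[j], math.exp(grid[j]))
        step = grid[1] - grid[0]
        lo, hi = grid[j] - step, grid[j] + step
    j = int(np.nanargmax(vals))
    if 0 < j < len(grid) - 1:
        t3, v3 = grid[j - 1:j + 2], np.asarray(vals[j - 1:j + 2])
        denom = v3[0] - 2 * v3[1] + v3[2]
        if denom < 0:  # concave: quadratic vertex
            h = (t3[2] - t3[0]) / 2
            t_hat = t3[1] + 0.5 * h * (v3[0] - v3[2]) / denom
            ll_hat, _, _ = _loglik_at(y, X, groups, math.exp(t_hat), reml=reml)
            if ll_hat >= best[0] - 1e-9:
                best = (max(ll_hat, best[0]), math.exp(t_hat))
    ll0, _, _ = _loglik_at(y, X, groups, 0.0, reml=reml)
    lam = 0.0 if ll0 >= best[0] else best[1]
    ll, beta, sigma2 = _loglik_at(y, X, groups, lam, reml=reml)
    return beta, lam, sigma2, ll
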