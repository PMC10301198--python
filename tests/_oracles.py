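"""Independent reference solvers used only by the test suite.

The ε-SVR dual is a convex QP in the 2m stacked multipliers (a, a_hat):

    min  0.5 * x' Q x + p' x
    s.t. s' x = 0,  0 <= x <= C,

with Q = (s s') ∘ tile(K), p = [eps - y; eps + y] and signs
s = [+1...; -1...].  Solving it densely with a general-purpose NLP solver
gives a reference completely independent of the package's SMO updates.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def qp_svr_dual(K: np.ndarray, y: np.ndarray, C: float, eps: float):
    """Dense solve of the ε-SVR dual; returns (beta, bias).

    Small problems only (the QP has 2m variables).  The bias averages the
    KKT estimates over multipliers away from their box bounds.
    """
    m = K.shape[0]
    s = np.concatenate([np.ones(m), -np.ones(m)])
    Q = np.outer(s, s) * np.tile(K, (2, 2))
    p = np.concatenate([eps - y, eps + y])

    def f(x):
        return 0.5 * x @ Q @ x + p @ x

    def jac(x):
        return Q @ x + p

    res = minimize(
        f,
        x0=np.zeros(2 * m),
        jac=jac,
        bounds=[(0.0, C)] * (2 * m),
        constraints=[{"type": "eq", "fun": lambda x: s @ x, "jac": lambda x: s}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, f"reference QP failed: {res.message}"
    x = res.x
    beta = x[:m] - x[m:]
    g = K @ beta
    slack = 1e-6 * C
    est, weight = [], []
    a, ah = x[:m], x[m:]
    for i in range(m):
        if slack < a[i] < C - slack:
            est.append(y[i] - eps - g[i])
        if slack < ah[i] < C - slack:
            est.append(y[i] + eps - g[i])
    if est:
        bias = float(np.mean(est))
    else:
        # midpoint of the KKT-feasible interval for b
        lo, hi = -np.inf, np.inf
        for i in range(m):
            if a[i] <= slack and ah[i] <= slack:
                lo = max(lo, y[i] - g[i] - eps)
                hi = min(hi, y[i] - g[i] + eps)
            elif a[i] >= C - slack:
                hi = min(hi, y[i] - g[i] - eps)
            elif ah[i] >= C - slack:
                lo = max(lo, y[i] - g[i] + eps)
        bias = float(0.5 * (lo + hi)) if np.isfinite(lo) and np.isfinite(hi) else 0.0
    return beta, bias


def qp_predict(X_train: np.ndarray, beta: np.ndarray, bias: float, X: np.ndarray, gamma: float):
    """Decision function of a dense-QP solution at new points."""
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X_train**2, axis=1)[None, :]
        - 2.0 * X @ X_train.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0)) @ beta + bias
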