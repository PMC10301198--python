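"""ε-support-vector regression with an RBF kernel.

The model minimizes ``0.5 ||w||^2 + C * sum(xi + xi_hat)`` subject to the
ε-insensitive constraints ``|y_i - f(x_i)| <= eps + slack``.  Training
solves the Wolfe dual

    max  -0.5 * sum_ij (a_i - ah_i)(a_j - ah_j) K(x_i, x_j)
         - eps * sum_i (a_i + ah_i) + sum_i y_i (a_i - ah_i)
    s.t. sum_i (a_i - ah_i) = 0,   0 <= a_i, ah_i <= C,

by sequential minimal optimization on the 2m-variable box/equality QP:
at each step the maximal-violating pair of multipliers is updated
analytically, exactly the working-set strategy used by production SVM
solvers.  The inner loop is numba-compiled; kernel matrices are built
once per fit with vectorized numpy.

Correctness is defined against a dense quadratic-programming solve of the
same dual (see the test suite), not against any particular update order.

Features are standardized to zero mean / unit variance with training-split
statistics by default — the RBF distance has to weigh °C, lux and μS/cm
channels comparably — while targets stay on their native percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SolverError",
    "SVRHyperparams",
    "SVRModel",
    "rbf_kernel",
    "squared_distances",
    "solve_dual",
    "fit",
    "predict",
    "fitness_mse",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.01  # width of the insensitive tube, target (%) units

#: KKT stationarity tolerance; tight enough that the decision function
#: agrees with a dense QP optimum to well below 1e-4.
DEFAULT_TOL = 1e-5
MAX_ITER = 100_000


class SolverError(RuntimeError):
    """Dual solver failed to reach the KKT tolerance within its iteration cap."""


@dataclass(frozen=True)
class SVRHyperparams:
    """Penalty C, RBF width gamma and tube half-width epsilon."""

    c_penalty: float
    gamma: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not self.c_penalty > 0:
            raise ValueError(f"c_penalty must be > 0, got {self.c_penalty}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")


@dataclass
class SVRModel:
    """Fitted dual solution: coefficients ``beta_i = a_i - ah_i``, bias, and scaler."""

    dual_coeffs: np.ndarray
    bias: float
    support_inputs: np.ndarray  # standardized training inputs
    hyperparams: SVRHyperparams
    n_train: int
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    kernel: str = "rbf"
    solver_iterations: int = 0
    kkt_gap: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "dual_coeffs": self.dual_coeffs.tolist(),
            "bias": self.bias,
            "support_inputs": self.support_inputs.tolist(),
            "n_train": self.n_train,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "hyperparams": {
                "c_penalty": self.hyperparams.c_penalty,
                "gamma": self.hyperparams.gamma,
                "epsilon": self.hyperparams.epsilon,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        hp = SVRHyperparams(**d["hyperparams"])
        return cls(
            dual_coeffs=np.asarray(d["dual_coeffs"], dtype=float),
            bias=float(d["bias"]),
            support_inputs=np.asarray(d["support_inputs"], dtype=float),
            hyperparams=hp,
            n_train=int(d["n_train"]),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            kernel=d.get("kernel", "rbf"),
        )


def rbf_kernel(u, v, gamma: float) -> float:
    """Gaussian kernel ``exp(-gamma * ||u - v||^2)``; 1.0 at zero distance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    d = u - v
    return float(np.exp(-gamma * np.dot(d, d)))


def squared_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between the rows of A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


@njit(cache=True)
def _smo(K, y, C, eps, tol, max_iter):  # pragma: no cover - compiled
    """Maximal-violating-pair SMO on the 2m-variable dual QP.

    Variables t < m are the a_i, t >= m the ah_i (sign -1).  Returns the
    multiplier vector, final gradient, iteration count and KKT gap.
    """
    m = K.shape[0]
    n = 2 * m
    alpha = np.zeros(n)
    G = np.empty(n)
    for i in range(m):
        G[i] = eps - y[i]
        G[m + i] = eps + y[i]
    it = 0
    gap = np.inf
    while it < max_iter:
        v_up = -np.inf
        v_lo = np.inf
        i_up = -1
        j_lo = -1
        for t in range(n):
            a = alpha[t]
            if t < m:
                v = -G[t]
                if a < C and v > v_up:
                    v_up = v
                    i_up = t
                if a > 0.0 and v < v_lo:
                    v_lo = v
                    j_lo = t
            else:
                v = G[t]
                if a > 0.0 and v > v_up:
                    v_up = v
                    i_up = t
                if a < C and v < v_lo:
                    v_lo = v
                    j_lo = t
        gap = v_up - v_lo
        if gap <= tol:
            break
        i = i_up
        j = j_lo
        si = 1.0 if i < m else -1.0
        sj = 1.0 if j < m else -1.0
        ii = i % m
        jj = j % m
        quad = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if quad < 1e-12:
            quad = 1e-12
        d = gap / quad
        # box limits keeping both multipliers in [0, C]
        dmax_i = (C - alpha[i]) if si > 0.0 else alpha[i]
        dmax_j = alpha[j] if sj > 0.0 else (C - alpha[j])
        if d > dmax_i:
            d = dmax_i
        if d > dmax_j:
            d = dmax_j
        alpha[i] += si * d
        alpha[j] -= sj * d
        for t in range(n):
            s = 1.0 if t < m else -1.0
            tt = t % m
            G[t] += s * d * (K[tt, ii] - K[tt, jj])
        it += 1
    return alpha, G, it, gap


def solve_dual(
    K: np.ndarray,
    y: np.ndarray,
    c_penalty: float,
    epsilon: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, float, int, float]:
    """Solve the ε-SVR dual for a precomputed kernel matrix.

    Returns ``(beta, bias, iterations, kkt_gap)`` where
    ``beta_i = a_i - ah_i``.  The bias averages the per-sample KKT
    estimates ``y_i -+ eps - sum_j beta_j K_ij`` over multipliers strictly
    inside ``(0, C)``; if no multiplier is interior it falls back to the
    midpoint of the KKT-feasible bias interval.

    Raises
    ------
    SolverError
        If the KKT gap is still above ``tol`` after ``max_iter`` updates.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    m = K.shape[0]
    alpha, G, it, gap = _smo(K, y, float(c_penalty), float(epsilon), float(tol), int(max_iter))
    if gap > tol:
        raise SolverError(
            f"SMO did not converge: KKT gap {gap:.3e} > tol {tol:.1e} "
            f"after {it} iterations (m={m}, C={c_penalty}, eps={epsilon})"
        )
    beta = alpha[:m] - alpha[m:]
    # bias: v_t = -s_t * G_t equals b at any interior multiplier
    slack = 1e-9 * c_penalty
    v = np.concatenate([-G[:m], G[m:]])
    interior = (alpha > slack) & (alpha < c_penalty - slack)
    if np.any(interior):
        bias = float(np.mean(v[interior]))
    else:
        up_mask = np.concatenate([alpha[:m] < c_penalty - slack, alpha[m:] > slack])
        lo_mask = np.concatenate([alpha[:m] > slack, alpha[m:] < c_penalty - slack])
        hi = np.max(v[up_mask]) if np.any(up_mask) else 0.0
        lo = np.min(v[lo_mask]) if np.any(lo_mask) else 0.0
        bias = float(0.5 * (hi + lo))
    return beta, bias, int(it), float(gap)


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return mean, scale


def fit(
    train,
    hp: SVRHyperparams,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
    standardize: bool = True,
) -> SVRModel:
    """Fit an ε-SVR on a dataset or ``(X, y)`` pair.

    ``train`` may be anything with ``features()``/``targets()`` methods
    (a :class:`~eagletune.synthetic_data.SensorDataset`) or a tuple of
    arrays.  With ``standardize=False`` the features are assumed to be on
    a comparable scale already; the stored scaler is then the identity, so
    the fit equals one on externally pre-standardized features.
    """
    X, y = _as_xy(train)
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 training samples, got {X.shape[0]}")
    if standardize:
        mean, scale = _standardize_stats(X)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    K = np.exp(-hp.gamma * squared_distances(Xs, Xs))
    beta, bias, it, gap = solve_dual(K, y, hp.c_penalty, hp.epsilon, tol=tol, max_iter=max_iter)
    return SVRModel(
        dual_coeffs=beta,
        bias=bias,
        support_inputs=Xs,
        hyperparams=hp,
        n_train=X.shape[0],
        scaler_mean=mean,
        scaler_scale=scale,
        solver_iterations=it,
        kkt_gap=gap,
    )


def predict(model: SVRModel, x) -> np.ndarray | float:
    """Evaluate the decision function ``sum_i beta_i K(x_i, x) + b``.

    Accepts a single feature vector (returns a float) or a 2-D matrix of
    rows (returns a vector).  Inputs are expected on the native training
    scale; the model applies its stored standardization.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.support_inputs.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.support_inputs.shape[1]}, got {X.shape[1]}"
        )
    Xs = (X - model.scaler_mean) / model.scaler_scale
    Kc = np.exp(-model.hyperparams.gamma * squared_distances(Xs, model.support_inputs))
    out = Kc @ model.dual_coeffs + model.bias
    return float(out[0]) if single else out


def fitness_mse(hp: SVRHyperparams, train, holdout, tol: float = 1e-3) -> float:
    """Holdout mean-squared error of an SVR fitted with ``hp`` — the tuning objective.

    Fits on ``train``, predicts the ``holdout`` targets and returns their
    MSE.  Solver failures (non-convergence at an unfavourable ``(C, gamma)``)
    yield ``+inf`` so a minimizer simply discards the candidate.  The
    default solver tolerance is coarser than :func:`fit`'s: during a search
    thousands of fits are ranked, not reported.
    """
    X_hold, y_hold = _as_xy(holdout)
    if X_hold.shape[0] == 0:
        raise ValueError("holdout must be non-empty")
    try:
        model = fit(train, hp, tol=tol)
        pred = predict(model, X_hold)
    except SolverError:
        return float("inf")
    mse = float(np.mean((pred - y_hold) ** 2))
    return mse if np.isfinite(mse) else float("inf")


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "features") and hasattr(data, "targets"):
        return np.asarray(data.features(), dtype=float), np.asarray(data.targets(), dtype=float)
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)
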