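"""Regression evaluation metrics: MSE, RMSE and R².

R² is reported in its standard coefficient-of-determination form
``1 - SS_res / SS_tot``.  An explained-variance ratio
``sum((yhat - ybar)**2) / sum((y - ybar)**2)`` is kept alongside as
``r2_ratio`` — the two coincide for ordinary least squares but differ for
a general predictor, and reported soil-moisture R² values conventionally
mean the standard form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["Metrics", "compute_metrics"]


@dataclass(frozen=True)
class Metrics:
    """Evaluation summary; ``mse`` in target units squared, ``rmse`` in target units."""

    mse: float
    rmse: float
    r2: float
    r2_ratio: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(measured, predicted) -> Metrics:
    """Compute MSE, RMSE and R² of ``predicted`` against ``measured``.

    Parameters
    ----------
    measured, predicted : array-like
        Equal-length vectors of finite values.

    Returns
    -------
    Metrics
        ``r2`` is NaN (with a warning) when ``measured`` is constant, since
        the total sum of squares vanishes and no variance can be explained.
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.ndim != 1 or yhat.ndim != 1 or y.shape != yhat.shape:
        raise ValueError(f"measured and predicted must be equal-length vectors, got {y.shape} and {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("inputs must be finite")

    resid = y - yhat
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    ybar = float(np.mean(y))
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0.0:
        warnings.warn("measured values are constant; R2 is undefined", RuntimeWarning, stacklevel=2)
        r2 = float("nan")
        r2_ratio = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        r2_ratio = float(np.sum((yhat - ybar) ** 2)) / ss_tot
    return Metrics(mse=mse, rmse=rmse, r2=r2, r2_ratio=r2_ratio, n=int(y.size))
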