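"""Standard continuous test functions for exercising the optimizer.

All are minimization problems with optimum 0 at the origin.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sphere", "rastrigin", "ackley"]


def sphere(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def rastrigin(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def ackley(x) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    s1 = np.sum(x * x) / n
    s2 = np.sum(np.cos(2.0 * np.pi * x)) / n
    return float(-20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e)
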