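"""Matérn-5/2 covariance functions.

The Matérn kernel with smoothness 5/2 is exactly twice differentiable, which
constrains the inferred log-density function to a realistic degree of
smoothness (infinitely smooth kernels such as the RBF over-smooth sharp
density transitions).  For ``u = ||x - y|| / l``:

    k(x, y) = variance * (1 + sqrt(5) u + 5 u^2 / 3) * exp(-sqrt(5) u)
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .containers import KernelSpec

__all__ = ["matern52", "matern52_cross", "matern52_from_distance", "matern52_ddist"]

_SQRT5 = np.sqrt(5.0)


def matern52_from_distance(dist, length_scale: float, variance: float = 1.0):
    """Kernel value as a function of Euclidean distance."""
    u = np.asarray(dist, dtype=float) / length_scale
    out = variance * (1.0 + _SQRT5 * u + (5.0 / 3.0) * u**2) * np.exp(-_SQRT5 * u)
    return out if out.shape else float(out)


def matern52(a, b, spec: KernelSpec) -> float:
    """Kernel between two single states."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    return float(
        matern52_from_distance(
            np.linalg.norm(a - b), spec.length_scale, spec.variance
        )
    )


def matern52_cross(X, Y, spec: KernelSpec) -> np.ndarray:
    """Cross-covariance matrix between two sets of states (rows)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return matern52_from_distance(cdist(X, Y), spec.length_scale, spec.variance)


def matern52_ddist(dist, length_scale: float, variance: float = 1.0):
    """Derivative of the kernel with respect to the distance.

    d/du [(1 + s5 u + 5u^2/3) e^{-s5 u}] = -(5u/3)(1 + s5 u) e^{-s5 u},
    times 1/l for the chain rule on ``u = dist / l``.
    """
    dist = np.asarray(dist, dtype=float)
    u = dist / length_scale
    out = (
        variance
        * (-(5.0 / 3.0) * u * (1.0 + _SQRT5 * u) * np.exp(-_SQRT5 * u))
        / length_scale
    )
    return out if out.shape else float(out)
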