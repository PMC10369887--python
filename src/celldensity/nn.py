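"""Nearest-neighbor distances and the Poisson point-process likelihood.

Under a homogeneous Poisson point process of intensity ``rho`` in ``d``
dimensions, the distance ``r`` from a point to its nearest neighbor has
probability density

    f_NN(r | rho) = exp(-rho * b(r, d)) * rho * db(r, d)/dr

where ``b(r, d)`` is the volume of the d-ball of radius ``r``.  Maximising
this likelihood in ``rho`` for an observed nearest-neighbor distance ``dn``
(with a Jeffreys-style correction absorbing the prior-free mode shift) gives
the closed-form heuristic estimate

    rho_hat(dn | d) = (d - 1) * Gamma(d/2 + 1) / (d * dn**d * pi**(d/2))

which this module exposes alongside the exact log-pdf, exact and approximate
nearest-neighbor search, and the classical 1/kNN-distance baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln
from sklearn.neighbors import NearestNeighbors

from .containers import NNDistances, as_state_matrix

__all__ = [
    "ball_volume",
    "nn_log_pdf",
    "ml_density_estimate",
    "ml_log_density_estimate",
    "compute_nn_distances",
    "knn_inverse_baseline",
]

#: above this many cells, ``compute_nn_distances(..., approximate=None)``
#: switches to approximate search if pynndescent is importable.
APPROX_THRESHOLD = 50_000


def _log_unit_ball_volume(d: int) -> float:
    # log of pi^{d/2} / Gamma(d/2 + 1)
    return 0.5 * d * np.log(np.pi) - gammaln(0.5 * d + 1.0)


def ball_volume(r, d: int):
    """Volume of the ``d``-dimensional ball of radius ``r``:
    ``pi^{d/2} r^d / Gamma(d/2 + 1)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    out = np.exp(_log_unit_ball_volume(d) + d * np.log(r))
    return out if out.shape else float(out)


def nn_log_pdf(r, rho, d: int):
    """Log-density of the nearest-neighbor distance under intensity ``rho``.

    ``log f_NN(r | rho) = -rho*b(r,d) + log(rho) + log(d) + log V_d
    + (d-1)*log(r)`` with ``V_d`` the unit-ball volume.
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    if np.any(rho <= 0):
        raise ValueError("intensity rho must be positive")
    log_vd = _log_unit_ball_volume(d)
    log_db_dr = np.log(d) + log_vd + (d - 1) * np.log(r)
    out = -rho * np.exp(log_vd + d * np.log(r)) + np.log(rho) + log_db_dr
    return out if out.shape else float(out)


def ml_log_density_estimate(dn, d: int):
    """Log of :func:`ml_density_estimate`, computed in log space
    (robust to ``dn**d`` under/overflow in high dimensions)."""
    dn = np.asarray(dn, dtype=float)
    if np.any(dn <= 0):
        raise ValueError("nearest-neighbor distance must be positive")
    if d < 2:
        raise ValueError("density_dim must be >= 2 (the estimate vanishes at d=1)")
    out = (
        np.log(d - 1.0)
        - np.log(float(d))
        + gammaln(0.5 * d + 1.0)
        - d * np.log(dn)
        - 0.5 * d * np.log(np.pi)
    )
    return out if out.shape else float(out)


def ml_density_estimate(dn, d: int):
    """Prior-free closed-form density estimate
    ``(d-1) * Gamma(d/2+1) / (d * dn^d * pi^{d/2})``."""
    out = np.exp(ml_log_density_estimate(dn, d))
    return out if out.shape else float(out)


def _dedup_positive(distances: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
    """Replace exact-zero distances (duplicated coordinates) with the
    smallest positive observed distance times 1e-3.

    If *every* distance is zero (e.g. the whole dataset is duplicated) the
    epsilon policy has no reference scale; each cell then falls back to the
    distance to its nearest distinct-location neighbor, which preserves the
    density ranking of the de-duplicated data.
    """
    zero = distances == 0.0
    if not np.any(zero):
        return distances
    pos = distances[~zero]
    distances = distances.copy()
    if pos.size > 0:
        eps = pos.min() * 1e-3
        warnings.warn(
            f"{int(zero.sum())} duplicated coordinates; their nearest-neighbor "
            f"distance was set to {eps:.3g}",
            stacklevel=3,
        )
        distances[zero] = eps
        return distances
    if X is None:
        raise ValueError("all nearest-neighbor distances are zero")
    warnings.warn(
        "all coordinates are duplicated; using nearest distinct-location "
        "neighbor distances",
        stacklevel=3,
    )
    k = 2
    remaining = np.arange(X.shape[0])
    while remaining.size:
        k = min(2 * k, X.shape[0])
        nbrs = NearestNeighbors(n_neighbors=k).fit(X)
        dk, _ = nbrs.kneighbors(X[remaining])
        first_pos = np.where(dk > 0, dk, np.inf).min(axis=1)
        found = np.isfinite(first_pos)
        distances[remaining[found]] = first_pos[found]
        remaining = remaining[~found]
        if k == X.shape[0]:
            if remaining.size:
                raise ValueError("dataset contains a single distinct coordinate")
            break
    return distances


def compute_nn_distances(
    states,
    density_dim: int | None = None,
    *,
    approximate: bool | None = None,
    seed: int = 0,
) -> NNDistances:
    """Distance from every cell to its nearest distinct neighbor.

    Parameters
    ----------
    states
        StateMatrix / array / DataFrame of cell coordinates.
    density_dim
        Dimensionality ``d`` used in the nearest-neighbor likelihood.
        Defaults to the dimensionality of the state space.
    approximate
        ``True`` forces pynndescent approximate search, ``False`` forces the
        exact tree-based search, ``None`` (default) switches to approximate
        only above :data:`APPROX_THRESHOLD` cells (and falls back to exact if
        pynndescent is unavailable).
    """
    sm = as_state_matrix(states)
    X = sm.coordinates
    if approximate is None:
        approximate = X.shape[0] > APPROX_THRESHOLD
    dist = None
    if approximate:
        try:
            from pynndescent import NNDescent

            index = NNDescent(X, n_neighbors=2, random_state=seed)
            _, d2 = index.neighbor_graph
            dist = d2[:, 1].astype(float)
        except ImportError:  # pragma: no cover - environment dependent
            warnings.warn("pynndescent unavailable; using exact search")
    if dist is None:
        nbrs = NearestNeighbors(n_neighbors=2).fit(X)
        d2, _ = nbrs.kneighbors(X)
        dist = d2[:, 1].astype(float)
    dist = _dedup_positive(dist, X)
    # the likelihood needs d >= 2 (the density estimate vanishes at d = 1),
    # so 1-D state spaces are clamped to d = 2 unless overridden
    d = int(density_dim) if density_dim is not None else max(sm.n_dims, 2)
    return NNDistances(distances=dist, density_dim=d)


def knn_inverse_baseline(states, k: int) -> np.ndarray:
    """Classical baseline: reciprocal of the distance to the k-th nearest
    distinct neighbor (ties broken by cell index)."""
    sm = as_state_matrix(states)
    n = sm.n_cells
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n cells (k={k}, n={n})")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(sm.coordinates)
    dist, _ = nbrs.kneighbors(sm.coordinates)
    dk = _dedup_positive(dist[:, k].astype(float), sm.coordinates)
    return 1.0 / dk
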