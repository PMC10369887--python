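"""Sparse Gaussian-process engine for log-density inference.

The generative model couples every cell's nearest-neighbor distance to a
latent log-density function ``f`` through the Poisson point-process
nearest-neighbor likelihood, with a GP prior on ``f``:

    f ~ GP(m, Matern52(l))            # m, l set by data-driven heuristics
    rho(x) = exp(f(x))
    dn(x_i) ~ NN(rho(x_i), d)

Inference is a MAP estimate in a whitened parameterisation: ``f = m + L y``
with a standard-normal prior on ``y``, where ``L`` is the Cholesky factor of
the training covariance (full GP) or the Nyström factor ``K_xz C^{-T}``
built from k-means landmark states (sparse GP).  The posterior is maximised
with L-BFGS-B using analytic gradients; the additive constant ``log(db/dr)``
of the likelihood is dropped (it does not depend on the parameters).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from .containers import KernelSpec, LandmarkSet, NNDistances, StateMatrix, as_state_matrix
from .kernels import matern52_cross
from .nn import _log_unit_ball_volume, compute_nn_distances, ml_log_density_estimate

logger = logging.getLogger("celldensity")

__all__ = [
    "length_scale_heuristic",
    "mean_constant",
    "select_landmarks",
    "initialize_latent",
    "covariance_rank_check",
    "map_fit",
    "predict_log_density",
    "DensityModel",
    "FunctionTrend",
    "fit_function_trend",
    "DEFAULT_N_LANDMARKS",
]

DEFAULT_N_LANDMARKS = 5000


def length_scale_heuristic(nn: NNDistances, lambda_const: float = 3.0) -> float:
    """Data-driven kernel length scale ``exp(lambda + mean(log dn))``.

    ``lambda = 3`` widens the radius of influence to roughly e^3 ≈ 20 times
    the geometric-mean nearest-neighbor distance, so that each density value
    is supported by a density-dependent effective number of neighbors.
    """
    dist = np.asarray(nn.distances, dtype=float)
    if np.any(dist <= 0):
        raise ValueError("all distances must be positive")
    return float(np.exp(lambda_const + np.mean(np.log(dist))))


def mean_constant(log_estimates) -> float:
    """GP mean: 1st percentile of the heuristic log-density estimates minus
    10 — a log-density implying vanishingly small probability far from data."""
    v = np.asarray(log_estimates, dtype=float)
    if v.size == 0:
        raise ValueError("empty estimate vector")
    return float(np.percentile(v, 1.0) - 10.0)


def select_landmarks(states, k: int, seed: int = 0) -> LandmarkSet:
    """k-means(++) centroids as inducing states; falls back to the training
    states themselves (full-GP mode) when ``k >= n``."""
    sm = as_state_matrix(states)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= sm.n_cells:
        return LandmarkSet(sm.coordinates.copy())
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    km.fit(sm.coordinates)
    return LandmarkSet(km.cluster_centers_)


def _chol_with_jitter(K: np.ndarray, variance: float, jitter: float = 1e-6):
    """Lower Cholesky factor with escalating diagonal jitter (1e-6 to 1e-2
    of the kernel variance); escalations are logged."""
    j = jitter
    while True:
        try:
            C = cholesky(K + j * variance * np.eye(K.shape[0]), lower=True)
            if j > jitter:
                logger.warning("covariance factorization needed jitter %.0e", j)
            return C, j
        except np.linalg.LinAlgError:
            j *= 10.0
            if j > 1e-2:
                raise np.linalg.LinAlgError(
                    "covariance factorization failed even with jitter 1e-2"
                )


def initialize_latent(log_estimates: np.ndarray, factor: np.ndarray) -> np.ndarray:
    """Ridge-regression initialization of the whitened coefficients.

    Solves ``argmin_y ||v - L y||^2 + ||y||^2`` in closed form, where ``v``
    are the (mean-centered) heuristic log-density estimates.  The unit ridge
    emulates the extra smoothness of the true density relative to the noisy
    per-cell estimates.
    """
    v = np.asarray(log_estimates, dtype=float)
    L = np.asarray(factor, dtype=float)
    if L.shape[0] != v.shape[0]:
        raise ValueError(f"factor has {L.shape[0]} rows for {v.shape[0]} estimates")
    A = L.T @ L + np.eye(L.shape[1])
    return cho_solve(cho_factor(A, lower=True), L.T @ v)


def covariance_rank_check(
    landmarks: LandmarkSet, kernel: KernelSpec, tol: float = 1e-6
) -> tuple[int, bool]:
    """Numerical rank of the landmark covariance matrix.

    Returns ``(rank, warned)``; a rank below the number of landmarks means
    the landmark skeleton has exhausted the complexity it can represent and
    adding landmarks would not refine the density function.
    """
    Z = landmarks.locations
    K = matern52_cross(Z, Z, kernel)
    eig = np.linalg.eigvalsh(K)
    rank = int(np.sum(eig > tol * eig.max()))
    warned = rank < landmarks.k
    if warned:
        warnings.warn(
            f"landmark covariance rank {rank} < {landmarks.k} landmarks; "
            "model complexity is exhausted at this length scale",
            stacklevel=2,
        )
    return rank, warned


@dataclass
class DensityModel:
    """Fitted continuous log-density function over the cell-state space.

    ``predict`` evaluates the GP posterior mean
    ``m + k(query, landmarks) @ prediction_weights`` at arbitrary states.
    When ``time_kernel`` is set the landmarks carry a trailing time column
    and the covariance is the product of the state and time Matérn kernels.
    """

    mean_const: float
    kernel: KernelSpec
    landmarks: LandmarkSet
    latent_coefficients: np.ndarray
    prediction_weights: np.ndarray
    density_dim: int
    factor_mode: str
    time_kernel: KernelSpec | None = None
    training_states: StateMatrix | None = None
    training_log_density: np.ndarray | None = None
    optimizer_status: dict = field(default_factory=dict)

    @property
    def n_state_dims(self) -> int:
        d = self.landmarks.locations.shape[1]
        return d - 1 if self.time_kernel is not None else d

    def cross_covariance(self, Q: np.ndarray) -> np.ndarray:
        """Covariance between query rows (augmented with time if temporal)
        and the landmark set."""
        Z = self.landmarks.locations
        if self.time_kernel is None:
            return matern52_cross(Q, Z, self.kernel)
        Ks = matern52_cross(Q[:, :-1], Z[:, :-1], self.kernel)
        Kt = matern52_cross(Q[:, -1:], Z[:, -1:], self.time_kernel)
        return Ks * Kt

    def predict(self, query) -> np.ndarray:
        """Log-density at arbitrary states (rows)."""
        Q = np.atleast_2d(np.asarray(
            query.coordinates if isinstance(query, StateMatrix) else query,
            dtype=float,
        ))
        expected = (
            self.landmarks.locations.shape[1]
            if self.time_kernel is not None
            else self.n_state_dims
        )
        if Q.shape[1] != expected:
            raise ValueError(
                f"query has {Q.shape[1]} columns, model expects {expected}"
            )
        return self.mean_const + self.cross_covariance(Q) @ self.prediction_weights

    __call__ = predict


def _map_fit_core(
    coords: np.ndarray,
    cov: Callable[[np.ndarray, np.ndarray], np.ndarray],
    nn: NNDistances,
    *,
    n_landmarks: int,
    seed: int,
    kernel_variance: float,
    gtol: float,
    maxiter: int,
    jitter: float,
    landmark_coords: np.ndarray | None = None,
):
    """Shared MAP machinery for the state-only and time-continuous models.

    ``coords`` are the rows the covariance function operates on (state
    coordinates, optionally with a trailing time column); ``landmark_coords``
    overrides landmark selection (used by the time model to select landmarks
    in a rescaled augmented space).
    """
    n = coords.shape[0]
    dn = nn.distances
    d = nn.density_dim
    log_est = ml_log_density_estimate(dn, d)
    m = mean_constant(log_est)

    if landmark_coords is None:
        if n <= n_landmarks:
            landmark_coords = coords.copy()
        else:
            km = KMeans(
                n_clusters=n_landmarks, init="k-means++", n_init=1, random_state=seed
            )
            landmark_coords = km.fit(coords).cluster_centers_
    full = landmark_coords.shape[0] >= n and np.array_equal(landmark_coords, coords)
    mode = "full" if full else "sparse"
    logger.info("GP mode: %s (%d landmarks, %d cells)", mode, landmark_coords.shape[0], n)

    Kzz = cov(landmark_coords, landmark_coords)
    C, used_jitter = _chol_with_jitter(Kzz, kernel_variance, jitter)
    if full:
        L = C
    else:
        Kxz = cov(coords, landmark_coords)
        L = solve_triangular(C, Kxz.T, lower=True).T

    # log b(dn_i, d); the parameter-free log(db/dr) term is dropped
    log_b = _log_unit_ball_volume(d) + d * np.log(dn)

    y0 = initialize_latent(log_est - m, L)

    def neg_log_posterior(y):
        f = m + L @ y
        rho_b = np.exp(f + log_b)
        obj = -np.sum(f - rho_b) + 0.5 * y @ y
        grad = L.T @ (rho_b - 1.0) + y
        return obj, grad

    res = minimize(
        neg_log_posterior,
        y0,
        jac=True,
        method="L-BFGS-B",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    if not np.all(np.isfinite(res.x)):
        raise FloatingPointError("optimizer returned non-finite coefficients")
    if not res.success:
        warnings.warn(
            f"MAP optimizer did not converge: {res.message}", stacklevel=2
        )
    y = res.x
    weights = solve_triangular(C.T, y, lower=False)
    status = {
        "success": bool(res.success),
        "message": str(res.message),
        "n_iterations": int(res.nit),
        "objective": float(res.fun),
        "jitter": float(used_jitter),
        "mode": mode,
    }
    return m, landmark_coords, y, weights, m + L @ y, mode, status


def map_fit(
    states,
    nn: NNDistances | None = None,
    *,
    density_dim: int | None = None,
    n_landmarks: int = DEFAULT_N_LANDMARKS,
    length_scale: float | None = None,
    lambda_const: float = 3.0,
    kernel_variance: float = 1.0,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 500,
    jitter: float = 1e-6,
) -> DensityModel:
    """MAP inference of the continuous log-density function.

    Maximises ``sum_i [ -rho_i b(dn_i, d) + log rho_i ] - ||y||^2 / 2`` over
    the whitened coefficients ``y`` with ``log rho_i = m + (L y)_i``.

    Parameters
    ----------
    states
        Cell-state matrix (StateMatrix / array / DataFrame).
    nn
        Precomputed nearest-neighbor distances; computed exactly if omitted.
    density_dim
        Dimensionality ``d`` of the likelihood; defaults to the state-space
        dimensionality.
    n_landmarks
        Landmark budget; the model is a full GP when ``n <= n_landmarks``.
    length_scale
        Kernel length scale; the nearest-neighbor heuristic when ``None``.
    """
    sm = as_state_matrix(states)
    if nn is None:
        nn = compute_nn_distances(sm, density_dim)
    elif density_dim is not None and nn.density_dim != density_dim:
        nn = NNDistances(nn.distances, density_dim)
    if nn.distances.shape[0] != sm.n_cells:
        raise ValueError("nearest-neighbor distances do not match the state matrix")

    l = length_scale if length_scale is not None else length_scale_heuristic(nn, lambda_const)
    spec = KernelSpec(length_scale=l, variance=kernel_variance)

    def cov(A, B):
        return matern52_cross(A, B, spec)

    m, Z, y, w, f_train, mode, status = _map_fit_core(
        sm.coordinates,
        cov,
        nn,
        n_landmarks=n_landmarks,
        seed=seed,
        kernel_variance=kernel_variance,
        gtol=gtol,
        maxiter=maxiter,
        jitter=jitter,
    )
    return DensityModel(
        mean_const=m,
        kernel=spec,
        landmarks=LandmarkSet(Z),
        latent_coefficients=y,
        prediction_weights=w,
        density_dim=nn.density_dim,
        factor_mode=mode,
        training_states=sm,
        training_log_density=f_train,
        optimizer_status=status,
    )


def predict_log_density(model: DensityModel, query) -> np.ndarray:
    """Functional alias for :meth:`DensityModel.predict`."""
    return model.predict(query)


class FunctionTrend:
    """GP-regression posterior mean over a 1-D ordering (e.g. pseudotime).

    Evaluable at arbitrary grid points; used for gene trends and for mapping
    pseudotime to cell-state coordinates along a trajectory.
    """

    def __init__(self, ordering, values, kernel: KernelSpec, noise: float):
        t = np.asarray(ordering, dtype=float).ravel()
        v = np.asarray(values, dtype=float).ravel()
        if t.shape[0] != v.shape[0]:
            raise ValueError("ordering and values must have equal length")
        if not np.all(np.isfinite(t)):
            raise ValueError("ordering must be finite")
        if not noise > 0:
            raise ValueError("noise variance must be > 0")
        self.kernel = kernel
        self.noise = float(noise)
        self.mean = float(np.mean(v))
        self._t = t[:, None]
        K = matern52_cross(self._t, self._t, kernel)
        K[np.diag_indices_from(K)] += self.noise
        self._alpha = cho_solve(cho_factor(K, lower=True), v - self.mean)

    def __call__(self, grid) -> np.ndarray:
        g = np.asarray(grid, dtype=float).ravel()[:, None]
        return self.mean + matern52_cross(g, self._t, self.kernel) @ self._alpha


def fit_function_trend(
    ordering, values, kernel: KernelSpec | None = None, noise: float = 1e-2
) -> FunctionTrend:
    """Smooth trend of ``values`` along a 1-D ``ordering``.

    Defaults to a Matérn-5/2 kernel with unit length scale (pseudotime is
    assumed normalised to [0, 1]) and observation-noise variance 0.01.
    """
    if kernel is None:
        kernel = KernelSpec(length_scale=1.0, variance=1.0)
    return FunctionTrend(ordering, values, kernel, noise)
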