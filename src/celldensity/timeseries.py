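"""Time-continuous cell-state density for time-series single-cell data.

A measurement time coordinate is added to the GP so that temporally close
cells inform each other's density.  The covariance between cells ``i`` and
``j`` is the product kernel

    k(i, j) = Matern52(l_t)(|t_i - t_j|) * Matern52(l)(||x_i - x_j||)

The temporal length scale ``l_t`` is not free: it is fitted so that the
kernel reproduces the empirically observed correlation of per-timepoint
density functions.  The workflow is

1. fit one density function per timepoint from that timepoint's cells only;
2. evaluate every per-timepoint function on the union of all cells and form
   the Pearson correlation matrix ``P`` between timepoints;
3. choose ``l_t = argmin ||P - K_L||_F`` over a bounded positive interval;
4. run the shared MAP machinery on the augmented (state, time) coordinates.

The resulting density function interpolates between measured timepoints and
is differentiable in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import KernelSpec, LandmarkSet, NNDistances, StateMatrix, as_state_matrix
from .gp import DEFAULT_N_LANDMARKS, DensityModel, _map_fit_core, length_scale_heuristic
from .kernels import matern52_cross, matern52_ddist, matern52_from_distance
from .model import CellStateDensity, CellStateDensityResults
from .nn import compute_nn_distances

__all__ = [
    "TimeSeriesStates",
    "fit_timepoint_densities",
    "compute_time_correlations",
    "fit_time_length_scale",
    "fit_time_continuous",
    "predict_at_time",
    "density_time_derivative",
    "TimeContinuousDensity",
    "TimeContinuousDensityResults",
]


@dataclass(frozen=True)
class TimeSeriesStates:
    """Cell states with per-cell measurement times (consistent time units)."""

    states: StateMatrix
    timepoints: np.ndarray

    def __post_init__(self):
        sm = as_state_matrix(self.states)
        t = np.asarray(self.timepoints, dtype=float).ravel()
        if t.shape[0] != sm.n_cells:
            raise ValueError("one timepoint per cell required")
        if not np.all(np.isfinite(t)):
            raise ValueError("timepoints must be finite")
        uniq, counts = np.unique(t, return_counts=True)
        if uniq.size < 2:
            raise ValueError("need at least 2 distinct timepoints")
        if np.any(counts < 2):
            raise ValueError("every timepoint needs at least 2 cells")
        object.__setattr__(self, "states", sm)
        object.__setattr__(self, "timepoints", t)

    @property
    def unique_times(self) -> np.ndarray:
        return np.unique(self.timepoints)


def fit_timepoint_densities(
    data: TimeSeriesStates,
    *,
    min_cells: int = 50,
    on_undersized: str = "skip",
    density_dim: int | None = None,
    n_landmarks: int = DEFAULT_N_LANDMARKS,
    seed: int = 0,
    **fit_kwargs,
) -> dict[float, CellStateDensityResults]:
    """One density function per timepoint, each fitted only on that
    timepoint's cells.

    Timepoints with fewer than ``min_cells`` cells are skipped with a warning
    (``on_undersized="skip"``) or abort the run (``"error"``).
    """
    if on_undersized not in ("skip", "error"):
        raise ValueError("on_undersized must be 'skip' or 'error'")
    out: dict[float, CellStateDensityResults] = {}
    for t in data.unique_times:
        mask = data.timepoints == t
        if mask.sum() < min_cells:
            msg = f"timepoint {t} has {int(mask.sum())} < {min_cells} cells"
            if on_undersized == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; excluded", stacklevel=2)
            continue
        sub = StateMatrix(
            data.states.coordinates[mask], data.states.cell_ids[mask]
        )
        out[float(t)] = CellStateDensity(
            sub, density_dim=density_dim, n_landmarks=n_landmarks
        ).fit(seed=seed, **fit_kwargs)
    if len(out) < 2:
        raise ValueError("fewer than 2 timepoints could be fitted")
    return out


def compute_time_correlations(
    functions: dict[float, CellStateDensityResults], data: TimeSeriesStates
) -> pd.DataFrame:
    """Pearson correlation of per-timepoint log-density functions, each
    evaluated on the union of all cells from all timepoints."""
    times = sorted(functions)
    evals = {}
    X = data.states.coordinates
    for t in times:
        v = functions[t].predict(X)
        if np.std(v) == 0:
            raise ValueError(f"density function at t={t} is constant over all cells")
        evals[t] = v
    P = np.ones((len(times), len(times)))
    for i, t in enumerate(times):
        for j in range(i + 1, len(times)):
            P[i, j] = P[j, i] = np.corrcoef(evals[t], evals[times[j]])[0, 1]
    return pd.DataFrame(P, index=times, columns=times)


def fit_time_length_scale(
    P,
    times=None,
    *,
    bounds: tuple[float, float] = (0.01, 100.0),
    xatol: float = 1e-8,
) -> float:
    """Temporal length scale minimising ``||P - Matern52(l_t)(|t - t'|)||_F``.

    ``bounds`` are multiples of the total time span; hitting either boundary
    raises a warning (the matched correlations are then effectively flat or
    diagonal and the kernel cannot represent them).
    """
    if isinstance(P, pd.DataFrame):
        if times is None:
            times = np.asarray(P.index, dtype=float)
        P = P.to_numpy(dtype=float)
    if times is None:
        raise ValueError("times required when P is a bare array")
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 timepoints")
    span = times.max() - times.min()
    lo, hi = bounds[0] * span, bounds[1] * span
    dt = np.abs(times[:, None] - times[None, :])

    def objective(L):
        return float(np.sum((P - matern52_from_distance(dt, L)) ** 2))

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    if not res.success:
        raise RuntimeError(
            f"temporal length-scale optimization failed on [{lo:.3g}, {hi:.3g}]: "
            f"{res.message}"
        )
    lt = float(res.x)
    if lt <= lo * (1 + 1e-3) or lt >= hi * (1 - 1e-3):
        warnings.warn(
            f"fitted temporal length scale {lt:.4g} sits at the search bound "
            f"[{lo:.4g}, {hi:.4g}]",
            stacklevel=2,
        )
    return lt


def _within_timepoint_nn(data: TimeSeriesStates, density_dim: int | None) -> NNDistances:
    """NN distances computed among cells of the same timepoint: the point
    process realised at time t consists of the cells measured at t."""
    dist = np.empty(data.states.n_cells)
    d = density_dim if density_dim is not None else data.states.n_dims
    for t in data.unique_times:
        mask = data.timepoints == t
        sub = StateMatrix(data.states.coordinates[mask], data.states.cell_ids[mask])
        dist[mask] = compute_nn_distances(sub, d).distances
    return NNDistances(dist, d)


def fit_time_continuous(
    data: TimeSeriesStates,
    time_length_scale: float,
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
    """MAP fit over the augmented (state, time) coordinates with the product
    kernel; landmarks are selected by k-means in a rescaled augmented space
    where a time difference of ``l_t`` matches a state distance of ``l``."""
    nn = _within_timepoint_nn(data, density_dim)
    l = length_scale if length_scale is not None else length_scale_heuristic(nn, lambda_const)
    spec = KernelSpec(length_scale=l, variance=kernel_variance)
    tspec = KernelSpec(length_scale=time_length_scale, variance=1.0)

    X = data.states.coordinates
    A = np.column_stack([X, data.timepoints])

    def cov(U, V):
        Ks = matern52_cross(U[:, :-1], V[:, :-1], spec)
        Kt = matern52_cross(U[:, -1:], V[:, -1:], tspec)
        return Ks * Kt

    landmark_coords = None
    if A.shape[0] > n_landmarks:
        from sklearn.cluster import KMeans

        scale = l / time_length_scale
        B = np.column_stack([X, data.timepoints * scale])
        km = KMeans(n_clusters=n_landmarks, init="k-means++", n_init=1, random_state=seed)
        centers = km.fit(B).cluster_centers_
        centers[:, -1] /= scale
        landmark_coords = centers

    m, Z, y, w, f_train, mode, status = _map_fit_core(
        A,
        cov,
        nn,
        n_landmarks=n_landmarks,
        seed=seed,
        kernel_variance=kernel_variance,
        gtol=gtol,
        maxiter=maxiter,
        jitter=jitter,
        landmark_coords=landmark_coords,
    )
    status["time_range"] = [float(data.timepoints.min()), float(data.timepoints.max())]
    return DensityModel(
        mean_const=m,
        kernel=spec,
        landmarks=LandmarkSet(Z),
        latent_coefficients=y,
        prediction_weights=w,
        density_dim=nn.density_dim,
        factor_mode=mode,
        time_kernel=tspec,
        training_states=data.states,
        training_log_density=f_train,
        optimizer_status=status,
    )


def _augment(query, t: float) -> np.ndarray:
    Q = np.atleast_2d(np.asarray(
        query.coordinates if isinstance(query, StateMatrix) else query, dtype=float
    ))
    return np.column_stack([Q, np.full(Q.shape[0], float(t))])


def predict_at_time(model: DensityModel, query, t: float) -> np.ndarray:
    """Log-density at states ``query`` and time ``t`` (continuous in ``t``);
    warns when ``t`` extrapolates beyond the training time range."""
    if model.time_kernel is None:
        raise ValueError("model has no time component")
    rng = model.optimizer_status.get("time_range")
    if rng is not None and not (rng[0] <= t <= rng[1]):
        warnings.warn(
            f"t={t} is outside the measured time range {rng}; extrapolating",
            stacklevel=2,
        )
    return model.predict(_augment(query, t))


def density_time_derivative(
    model: DensityModel, query, t: float, *, method: str = "analytic"
) -> np.ndarray:
    """Time derivative of the log-density at (query, t).

    ``method="analytic"`` differentiates the temporal kernel factor;
    ``"fd"`` is a central finite difference with step ``1e-4 * l_t`` used as
    an internal consistency check.
    """
    if model.time_kernel is None:
        raise ValueError("model has no time component")
    if method == "fd":
        h = 1e-4 * model.time_kernel.length_scale
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hi = predict_at_time(model, query, t + h)
            lo = predict_at_time(model, query, t - h)
        return (hi - lo) / (2 * h)
    if method != "analytic":
        raise ValueError("method must be 'analytic' or 'fd'")
    A = _augment(query, t)
    Z = model.landmarks.locations
    Ks = matern52_cross(A[:, :-1], Z[:, :-1], model.kernel)
    dt = A[:, -1:] - Z[None, :, -1].reshape(1, -1)
    dKt = matern52_ddist(
        np.abs(dt), model.time_kernel.length_scale, model.time_kernel.variance
    ) * np.sign(dt)
    return (Ks * dKt) @ model.prediction_weights


class TimeContinuousDensity:
    """Model object for time-continuous density estimation.

    ``fit()`` runs the full pipeline (per-timepoint densities, correlation
    matrix, temporal length scale, product-kernel MAP fit) unless a temporal
    length scale is supplied explicitly.
    """

    def __init__(
        self,
        states,
        timepoints,
        *,
        density_dim: int | None = None,
        n_landmarks: int = DEFAULT_N_LANDMARKS,
        length_scale: float | None = None,
        time_length_scale: float | None = None,
        min_cells_per_timepoint: int = 50,
    ):
        self.data = TimeSeriesStates(as_state_matrix(states), timepoints)
        self.density_dim = density_dim
        self.n_landmarks = int(n_landmarks)
        self.length_scale = length_scale
        self.time_length_scale = time_length_scale
        self.min_cells_per_timepoint = int(min_cells_per_timepoint)

    def fit(self, *, seed: int = 0, **fit_kwargs) -> "TimeContinuousDensityResults":
        lt = self.time_length_scale
        per_timepoint = None
        correlations = None
        if lt is None:
            per_timepoint = fit_timepoint_densities(
                self.data,
                min_cells=self.min_cells_per_timepoint,
                density_dim=self.density_dim,
                n_landmarks=self.n_landmarks,
                seed=seed,
            )
            correlations = compute_time_correlations(per_timepoint, self.data)
            lt = fit_time_length_scale(correlations)
        fitted = fit_time_continuous(
            self.data,
            lt,
            density_dim=self.density_dim,
            n_landmarks=self.n_landmarks,
            length_scale=self.length_scale,
            seed=seed,
            **fit_kwargs,
        )
        return TimeContinuousDensityResults(self, fitted, lt, per_timepoint, correlations)


class TimeContinuousDensityResults:
    """Fitted time-continuous density; evaluable at any (state, time)."""

    def __init__(self, model, fitted: DensityModel, time_length_scale,
                 per_timepoint=None, correlations=None):
        self.model = model
        self.model_ = fitted
        self.time_length_scale_ = float(time_length_scale)
        self.timepoint_results_ = per_timepoint
        self.time_correlations_ = correlations

    def predict(self, query, t: float) -> np.ndarray:
        return predict_at_time(self.model_, query, t)

    def time_derivative(self, query, t: float, **kwargs) -> np.ndarray:
        return density_time_derivative(self.model_, query, t, **kwargs)

    def save(self, path: str) -> None:
        from .model import save_model

        save_model(self.model_, path)

    def summary(self) -> str:
        m = self.model_
        st = m.optimizer_status
        rows = [
            ("No. cells", m.training_states.n_cells if m.training_states else "n/a"),
            ("State dims (d')", m.n_state_dims),
            ("GP mode", m.factor_mode),
            ("No. landmarks", m.landmarks.k),
            ("State length scale", f"{m.kernel.length_scale:.6g}"),
            ("Time length scale", f"{self.time_length_scale_:.6g}"),
            ("Time range", st.get("time_range")),
            ("Converged", st.get("success")),
        ]
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Time-Continuous Density MAP Results", "=" * 40]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)
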