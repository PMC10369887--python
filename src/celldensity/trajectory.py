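"""Trajectory-resolved densities and cell-type proportions over time.

Given per-cell pseudotime and fate probabilities (computed externally, e.g.
by a fate-mapping tool), this module

1. selects the cells forming the branch toward a fate ``F`` via a running
   99th-percentile threshold on the fate probabilities,
2. maps pseudotime to the cell-state space with per-dimension GP trends
   (the trajectory curve ``T_F: [0,1] -> R^d'``),
3. evaluates a time-continuous density along the curve to form the joint
   (pseudotime x real-time) density,
4. assigns a cell type to each trajectory segment by the largest cell-type
   density, and integrates the joint density over segments to obtain
   marginal cell-type proportions at every real time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import KernelSpec, StateMatrix, as_state_matrix
from .gp import FunctionTrend
from .timeseries import predict_at_time

logger = logging.getLogger("celldensity")

__all__ = [
    "FateAnnotatedCells",
    "BranchThreshold",
    "branch_threshold",
    "select_branch_cells",
    "TrajectoryCurve",
    "fit_trajectory_curve",
    "JointDensityGrid",
    "compute_joint_density",
    "assign_celltype",
    "marginal_proportions",
]


@dataclass(frozen=True)
class FateAnnotatedCells:
    """Cell states with pseudotime and fate probabilities for one fate.

    Pseudotime is normalised to [0, 1] on construction if it is not already
    (recorded in ``pseudotime_rescaled``).
    """

    states: StateMatrix
    pseudotime: np.ndarray
    fate_probability: np.ndarray
    real_time: np.ndarray | None = None
    cell_type: np.ndarray | None = None
    pseudotime_rescaled: bool = False

    def __post_init__(self):
        sm = as_state_matrix(self.states)
        pt = np.asarray(self.pseudotime, dtype=float).ravel()
        fp = np.asarray(self.fate_probability, dtype=float).ravel()
        if pt.shape[0] != sm.n_cells or fp.shape[0] != sm.n_cells:
            raise ValueError("pseudotime and fate_probability must match cell count")
        rescaled = False
        if pt.min() < 0 or pt.max() > 1:
            lo, hi = pt.min(), pt.max()
            if hi == lo:
                raise ValueError("pseudotime is constant; cannot normalise")
            pt = (pt - lo) / (hi - lo)
            rescaled = True
            logger.info("pseudotime rescaled from [%g, %g] to [0, 1]", lo, hi)
        if fp.min() < 0 or fp.max() > 1:
            raise ValueError("fate probabilities must lie in [0, 1]")
        object.__setattr__(self, "states", sm)
        object.__setattr__(self, "pseudotime", pt)
        object.__setattr__(self, "fate_probability", fp)
        object.__setattr__(self, "pseudotime_rescaled", rescaled)
        if self.real_time is not None:
            rt = np.asarray(self.real_time, dtype=float).ravel()
            if rt.shape[0] != sm.n_cells:
                raise ValueError("real_time must match cell count")
            object.__setattr__(self, "real_time", rt)
        if self.cell_type is not None:
            ct = np.asarray(self.cell_type)
            if ct.shape[0] != sm.n_cells:
                raise ValueError("cell_type must match cell count")
            object.__setattr__(self, "cell_type", ct)


@dataclass(frozen=True)
class BranchThreshold:
    """Running-maximum fate-probability threshold over a pseudotime grid.

    Evaluation at a cell's pseudotime uses the next-larger grid point,
    clamped to the final grid point beyond the grid.
    """

    grid: np.ndarray
    values: np.ndarray

    def __call__(self, pseudotime) -> np.ndarray:
        t = np.asarray(pseudotime, dtype=float)
        idx = np.searchsorted(self.grid, t, side="left")
        idx = np.minimum(idx, self.grid.size - 1)
        out = self.values[idx]
        return out if out.shape else float(out)


def branch_threshold(cells: FateAnnotatedCells, grid_points: int = 500) -> BranchThreshold:
    """Threshold function ``T_F``: at each of ``grid_points`` pseudotime grid
    values, the running maximum of the 99th percentile of fate probabilities
    among cells at or below that grid value (non-decreasing by construction)."""
    if cells.states.n_cells == 0:
        raise ValueError("no cells")
    grid = np.linspace(0.0, 1.0, int(grid_points))
    pt = cells.pseudotime
    fp = cells.fate_probability
    order = np.argsort(pt, kind="stable")
    pt_sorted = pt[order]
    fp_sorted = fp[order]
    vals = np.full(grid.size, -np.inf)
    running = -np.inf
    for g, s in enumerate(grid):
        m = np.searchsorted(pt_sorted, s, side="right")
        if m > 0:
            running = max(running, float(np.percentile(fp_sorted[:m], 99.0)))
        vals[g] = running
    # grid points below the first cell's pseudotime carry no information;
    # backfill with the first populated value (no cell is evaluated there)
    finite = np.isfinite(vals)
    if finite.any() and not finite.all():
        vals[~finite] = vals[finite][0]
    return BranchThreshold(grid=grid, values=vals)


def select_branch_cells(
    cells: FateAnnotatedCells,
    epsilon: float = 0.01,
    *,
    threshold: BranchThreshold | None = None,
    grid_points: int = 500,
) -> np.ndarray:
    """Indices of cells on the branch: ``f_i > T_F(t_i) - epsilon`` with the
    threshold evaluated at the next-larger grid point.  ``epsilon`` controls
    how far a cell may fall below the running threshold and still belong."""
    if threshold is None:
        threshold = branch_threshold(cells, grid_points)
    thr = threshold(cells.pseudotime)
    return np.nonzero(cells.fate_probability > thr - epsilon)[0]


@dataclass(frozen=True)
class TrajectoryCurve:
    """Pseudotime-parameterised curve through the cell-state space:
    per-dimension GP posterior-mean trends ``[0,1] -> R``."""

    trends: tuple

    def __call__(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.column_stack([trend(s) for trend in self.trends])

    @property
    def n_dims(self) -> int:
        return len(self.trends)


def fit_trajectory_curve(
    cells: FateAnnotatedCells,
    branch_indices=None,
    *,
    length_scale: float = 1.0,
    noise: float = 0.01,
) -> TrajectoryCurve:
    """Map pseudotime to each state-space coordinate with a GP trend
    (Matérn-5/2, unit length scale, observation-noise variance 0.01; the GP
    mean is the branch average of the coordinate)."""
    if branch_indices is None:
        branch_indices = np.arange(cells.states.n_cells)
    branch_indices = np.asarray(branch_indices, dtype=int)
    if branch_indices.size < 10:
        raise ValueError(f"only {branch_indices.size} branch cells; need >= 10")
    pt = cells.pseudotime[branch_indices]
    X = cells.states.coordinates[branch_indices]
    kernel = KernelSpec(length_scale=length_scale, variance=1.0)
    trends = tuple(
        FunctionTrend(pt, X[:, m], kernel, noise) for m in range(X.shape[1])
    )
    return TrajectoryCurve(trends=trends)


@dataclass(frozen=True)
class JointDensityGrid:
    """Log-density ``rho(T_F(s), t)`` on a pseudotime x real-time grid."""

    s_grid: np.ndarray
    t_grid: np.ndarray
    log_density: np.ndarray  # shape (len(s_grid), len(t_grid))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log_density,
            index=pd.Index(self.s_grid, name="pseudotime"),
            columns=pd.Index(self.t_grid, name="time"),
        )


def compute_joint_density(
    curve: TrajectoryCurve,
    time_model,
    measured_times,
    *,
    s_points: int = 200,
    t_points_per_interval: int = 500,
) -> JointDensityGrid:
    """Evaluate a time-continuous density model along the trajectory curve.

    ``time_model`` is a fitted time-continuous model (results object or
    DensityModel with a time kernel).  The real-time grid places
    ``t_points_per_interval`` points between each pair of adjacent measured
    timepoints.
    """
    model = getattr(time_model, "model_", time_model)
    measured_times = np.sort(np.unique(np.asarray(measured_times, dtype=float)))
    if measured_times.size < 2:
        raise ValueError("need at least 2 measured timepoints")
    segments = [
        np.linspace(a, b, t_points_per_interval, endpoint=False)
        for a, b in zip(measured_times[:-1], measured_times[1:])
    ]
    t_grid = np.concatenate(segments + [measured_times[-1:]])
    s_grid = np.linspace(0.0, 1.0, int(s_points))
    points = curve(s_grid)
    logd = np.empty((s_grid.size, t_grid.size))
    for j, t in enumerate(t_grid):
        logd[:, j] = predict_at_time(model, points, float(t))
    if not np.all(np.isfinite(logd)):
        raise FloatingPointError("non-finite joint density values")
    return JointDensityGrid(s_grid=s_grid, t_grid=t_grid, log_density=logd)


def assign_celltype(
    curve: TrajectoryCurve, celltype_densities: dict, s_grid
) -> np.ndarray:
    """Per-grid-point cell-type label: the type whose density function is
    largest at the curve point; ties broken by label sort order (logged)."""
    if not celltype_densities:
        raise ValueError("no cell-type density functions given")
    labels = sorted(celltype_densities)
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    points = curve(s_grid)
    scores = np.column_stack(
        [np.asarray(celltype_densities[lab].predict(points)) for lab in labels]
    )
    best = np.argmax(scores, axis=1)  # argmax takes the first (sorted) label on ties
    n_ties = int(np.sum(np.sum(scores == scores.max(axis=1, keepdims=True), axis=1) > 1))
    if n_ties:
        logger.info("%d trajectory grid points had tied cell-type densities", n_ties)
    return np.asarray(labels, dtype=object)[best]


def marginal_proportions(grid: JointDensityGrid, annotation) -> pd.DataFrame:
    """Marginal cell-type proportions over real time.

    The mass of type ``H`` at time ``t`` is the trapezoidal integral of
    ``exp(log rho(T_F(s), t))`` over the pseudotime segments annotated ``H``;
    each grid interval belongs to the label of its left endpoint (exact for
    boundaries that fall on grid points).  Proportions normalise the masses
    across types at each time, so each row sums to 1.
    """
    ann = np.asarray(annotation)
    if ann.shape[0] != grid.s_grid.size:
        raise ValueError("annotation length must match the pseudotime grid")
    labels = sorted(set(ann.tolist()))
    s = grid.s_grid
    ds = np.diff(s)
    out = np.zeros((grid.t_grid.size, len(labels)))
    lab_idx = {lab: j for j, lab in enumerate(labels)}
    for j, _t in enumerate(grid.t_grid):
        col = grid.log_density[:, j]
        rho = np.exp(col - col.max())  # per-time rescale; cancels on normalisation
        interval = 0.5 * (rho[:-1] + rho[1:]) * ds
        mass = np.zeros(len(labels))
        for lab in labels:
            mass[lab_idx[lab]] = interval[ann[:-1] == lab].sum()
        total = mass.sum()
        if total <= 0:
            raise ValueError(f"zero total trajectory mass at time index {j}")
        out[j] = mass / total
    return pd.DataFrame(
        out, index=pd.Index(grid.t_grid, name="time"), columns=labels
    )
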