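"""Seeded synthetic-data generators with exact ground-truth densities.

Three families of fixtures, all pure functions of their spec and seed:

* ``simulate_tree_gmm`` — a Gaussian-mixture "differentiation tree": a tree
  of velocity vectors, each child a slightly perturbed copy of its parent's,
  with one anisotropic Gaussian per tree edge whose principal axes align
  with the velocity and decay exponentially (emulating the low intrinsic
  dimensionality of cell-state manifolds).
* ``simulate_cluster_gmm`` — an arbitrary mixture of mostly isolated
  clusters with randomly drawn means and covariances.
* ``simulate_time_series`` — a mixture whose component means drift linearly
  across measurement timepoints, with per-timepoint exact truth.
* ``simulate_expression_and_peaks`` — a 1-D latent trajectory with a
  programmed low-density corridor, a driver gene ramping inside it, and
  chromatin peaks programmed as primed (open from the start) or
  lineage-specific (opening only late).

Every ground-truth evaluator is exact (mixture log-density in closed form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .containers import StateMatrix
from .timeseries import TimeSeriesStates

__all__ = [
    "GMMGroundTruth",
    "DifferentiationTreeSpec",
    "simulate_tree_gmm",
    "simulate_cluster_gmm",
    "simulate_time_series",
    "OmicsFixture",
    "simulate_expression_and_peaks",
]


@dataclass(frozen=True)
class GMMGroundTruth:
    """Gaussian-mixture ground truth with an exact log-density evaluator."""

    weights: np.ndarray
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        mus = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        chols = []
        for k, S in enumerate(covs):
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"covariance {k} is not symmetric")
            try:
                chols.append(cholesky(S, lower=True))
            except np.linalg.LinAlgError as err:
                raise ValueError(f"covariance {k} is not positive definite") from err
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mus)
        object.__setattr__(self, "covariances", covs)
        object.__setattr__(self, "_chols", chols)

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def log_density(self, X) -> np.ndarray:
        """Exact mixture log-density at the query rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self.n_dims
        comp = np.empty((X.shape[0], self.n_components))
        for k in range(self.n_components):
            C = self._chols[k]
            z = solve_triangular(C, (X - self.means[k]).T, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(C)))
            comp[:, k] = (
                np.log(self.weights[k])
                - 0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z**2, axis=0))
            )
        return logsumexp(comp, axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        counts = rng.multinomial(n, self.weights)
        parts = []
        for k, c in enumerate(counts):
            if c == 0:
                continue
            z = rng.standard_normal((c, self.n_dims))
            parts.append(self.means[k] + z @ self._chols[k].T)
        X = np.vstack(parts)
        return X[rng.permutation(X.shape[0])]


def _aligned_covariance(
    velocity: np.ndarray,
    decay: float,
    *,
    cross_size: float,
    along_size: float,
    floor: float = 1e-3,
) -> np.ndarray:
    """Covariance whose first principal axis follows the velocity.

    The along-velocity standard deviation is ``along_size`` (so adjacent
    edges blend into a continuous tube); the cross-axes start at
    ``cross_size`` and decay exponentially at rate ``decay``, floored to
    keep the matrix positive definite.
    """
    d = velocity.size
    speed = np.linalg.norm(velocity)
    basis = np.eye(d)
    basis[:, 0] = velocity / speed
    Q, _ = np.linalg.qr(basis)
    # QR may flip the sign of the first column; irrelevant for a covariance
    sds = np.maximum(cross_size * np.exp(-decay * np.arange(d)), floor)
    sds[0] = max(along_size, sds[0])
    return (Q * sds**2) @ Q.T


@dataclass(frozen=True)
class DifferentiationTreeSpec:
    """Spec for the differentiation-tree mixture.

    The tree is a chain of short edges (one Gaussian per edge) that
    bifurcates at the ``branch_levels`` depths, so each branch is a smooth
    "tube" through state space rather than a handful of isolated blobs.
    Two systematic trends emulate real differentiation landscapes: component
    scale grows (``size_drift``) and abundance falls (``weight_drift``)
    from the stem toward the differentiated tips, producing the
    multi-order-of-magnitude density decline seen in real data, with
    lognormal random-walk variation on top.  The principal axes of each
    Gaussian decay exponentially (rate ``decay``) away from the velocity
    direction, giving low intrinsic dimensionality.
    """

    depth: int = 12
    branching: int = 2
    branch_levels: tuple = (4, 8)
    step_length: float = 0.6
    perturbation: float = 0.15
    decay: float = 1.0
    dim: int = 10
    cells_per_node: int = 179
    base_size: float = 0.3
    size_drift: float = 0.3
    size_walk: float = 0.15
    weight_drift: float = -0.3
    weight_walk: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("depth", "branching", "step_length", "perturbation",
                     "decay", "dim", "cells_per_node", "base_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def simulate_tree_gmm(
    spec: DifferentiationTreeSpec | None = None, **kwargs
) -> tuple[StateMatrix, GMMGroundTruth]:
    """Sample a differentiation-tree mixture and its exact ground truth.

    One Gaussian per tree edge, centred at the edge midpoint and stretched
    along the edge's velocity vector; each child's velocity is a slightly
    perturbed copy of its parent's, so branches gradually change direction.
    """
    if spec is None:
        spec = DifferentiationTreeSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    d = spec.dim
    step = spec.step_length

    v0 = rng.standard_normal(d)
    v0 *= step / np.linalg.norm(v0)
    # node: (start position, velocity, log size, log weight)
    root = (np.zeros(d), v0, 0.0, 0.0)
    nodes = [root]
    frontier = [root]
    for level in range(1, spec.depth):
        n_children = spec.branching if level in spec.branch_levels else 1
        next_frontier = []
        for start, vel, log_size, log_weight in frontier:
            end = start + vel
            for _ in range(n_children):
                child_vel = vel + rng.normal(scale=spec.perturbation * step, size=d)
                norm = np.linalg.norm(child_vel)
                if norm == 0:
                    raise ValueError("degenerate zero velocity in tree construction")
                child_vel *= step / norm
                child = (
                    end,
                    child_vel,
                    log_size + spec.size_drift + rng.normal(0, spec.size_walk),
                    log_weight + spec.weight_drift + rng.normal(0, spec.weight_walk),
                )
                nodes.append(child)
                next_frontier.append(child)
        frontier = next_frontier

    K = len(nodes)
    weights = np.exp(np.array([node[3] for node in nodes]))
    weights /= weights.sum()
    means = np.array([start + 0.5 * vel for start, vel, _, _ in nodes])
    covs = []
    for _, vel, log_size, _ in nodes:
        size = spec.base_size * np.exp(log_size)
        cov = _aligned_covariance(
            vel, spec.decay, cross_size=size, along_size=0.75 * step
        )
        covs.append(cov)
    truth = GMMGroundTruth(weights, means, np.array(covs))
    X = truth.sample(K * spec.cells_per_node, rng)
    return StateMatrix(X), truth


def simulate_cluster_gmm(
    n_components: int = 10,
    dim: int = 20,
    seed: int = 0,
    *,
    n_cells: int = 5000,
    separation: float = 20.0,
    cluster_scale: float = 1.0,
    scale_variation: float = 0.5,
) -> tuple[StateMatrix, GMMGroundTruth]:
    """Sample a mixture of mostly isolated clusters with random means and
    random (Wishart-style) covariance matrices, plus its exact truth.

    Cluster compactness varies lognormally (``scale_variation`` is the
    log-sd of the per-cluster scale multiplier), giving the islands the
    order-of-magnitude peak-density differences seen between cell types.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    means = rng.normal(scale=separation, size=(n_components, dim))
    scales = np.exp(rng.normal(0.0, scale_variation, size=n_components))
    covs = np.empty((n_components, dim, dim))
    for k in range(n_components):
        A = rng.standard_normal((dim, dim))
        covs[k] = (cluster_scale * scales[k]) ** 2 * (
            A @ A.T / dim + 0.5 * np.eye(dim)
        )
    w = rng.uniform(0.5, 1.5, size=n_components)
    truth = GMMGroundTruth(w / w.sum(), means, covs)
    return StateMatrix(truth.sample(n_cells, rng)), truth


def simulate_time_series(
    n_timepoints: int = 5,
    *,
    n_components: int = 5,
    dim: int = 10,
    drift_magnitude: float = 2.0,
    cells_per_timepoint: int = 600,
    separation: float = 6.0,
    seed: int = 0,
) -> tuple[TimeSeriesStates, dict[float, GMMGroundTruth]]:
    """A drifting time-series mixture with per-timepoint exact truths.

    The component means of a base cluster mixture are translated along a
    fixed random drift vector, linearly in measurement time; timepoints are
    ``0, 1, ..., n_timepoints - 1``.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    _, base = simulate_cluster_gmm(
        n_components, dim, seed=rng.integers(2**31), n_cells=2,
        separation=separation,
    )
    drift = rng.standard_normal(dim)
    drift *= drift_magnitude / np.linalg.norm(drift)

    truths: dict[float, GMMGroundTruth] = {}
    blocks, times = [], []
    for k in range(n_timepoints):
        t = float(k)
        truth_t = GMMGroundTruth(
            base.weights, base.means + t * drift, base.covariances
        )
        truths[t] = truth_t
        blocks.append(truth_t.sample(cells_per_timepoint, rng))
        times.append(np.full(cells_per_timepoint, t))
    data = TimeSeriesStates(
        StateMatrix(np.vstack(blocks)), np.concatenate(times)
    )
    return data, truths


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class OmicsFixture:
    """Paired expression / chromatin toy data on a 1-D latent trajectory."""

    states: StateMatrix
    pseudotime: np.ndarray
    expression: np.ndarray  # (n_cells, n_genes)
    gene_ids: np.ndarray
    driver_gene: str
    accessibility: np.ndarray  # (n_cells, n_peaks)
    peak_ids: np.ndarray
    peak_classes: np.ndarray  # programmed "primed" / "lineage_specific"
    reference_counts: np.ndarray  # per-peak fragment counts in start cells
    corridor: tuple = (0.4, 0.6)
    manifest: dict = field(default_factory=dict)


def simulate_expression_and_peaks(
    *,
    n_cells: int = 400,
    n_background_genes: int = 19,
    n_primed_peaks: int = 5,
    n_lineage_peaks: int = 5,
    corridor_weight: float = 0.05,
    driver_width: float = 0.04,
    background_width: float = 0.12,
    expression_noise: float = 0.005,
    seed: int = 0,
) -> OmicsFixture:
    """Fixture for the change-score and chromatin-score analyses.

    Cells sit on a smooth curve parameterised by latent pseudotime ``s`` with
    a programmed low-density corridor at ``s in (0.4, 0.6)`` (only
    ``corridor_weight`` of cells fall there).  The driver gene ramps steeply
    at the corridor centre (rapid change while transiting the sparse
    region); background genes ramp gently inside the dense segments (gradual
    change within stable compartments).  Expression emulates graph-imputed
    data, so its noise level is small.  Primed peaks are accessible from the
    trajectory start and lineage-specific peaks open only past the corridor,
    both correlated with the driver gene; reference fragment counts are
    Poisson draws over the start population.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 0.4, 0.6
    side = (1.0 - corridor_weight) / 2.0
    seg = rng.choice(3, size=n_cells, p=[side, corridor_weight, side])
    s = np.empty(n_cells)
    s[seg == 0] = rng.uniform(0.0, lo, size=(seg == 0).sum())
    s[seg == 1] = rng.uniform(lo, hi, size=(seg == 1).sum())
    s[seg == 2] = rng.uniform(hi, 1.0, size=(seg == 2).sum())

    # cells sit exactly on the curve: expression is then a smooth function
    # of the observed state, as graph-imputed expression is
    X = np.column_stack([4.0 * s, np.sin(np.pi * s)])

    centers = np.concatenate([
        rng.uniform(0.08, 0.32, size=n_background_genes // 2),
        rng.uniform(0.68, 0.92, size=n_background_genes - n_background_genes // 2),
    ])
    expr = [_sigmoid((s - 0.5) / driver_width)]
    for c in centers:
        expr.append(_sigmoid((s - c) / background_width))
    expr = np.column_stack(expr)
    # graph-imputed expression carries smooth, not i.i.d., noise: neighbors
    # share it, so it nearly cancels in neighbor differences
    n_genes = expr.shape[1]
    amp = rng.normal(scale=expression_noise, size=(3, n_genes))
    freq = rng.uniform(1.0, 4.0, size=(3, n_genes))
    phase = rng.uniform(0, 2 * np.pi, size=(3, n_genes))
    for h in range(3):
        expr += amp[h] * np.sin(2 * np.pi * freq[h] * s[:, None] + phase[h])
    gene_ids = np.array(
        ["driver"] + [f"bg_{j}" for j in range(n_background_genes)]
    )

    acc = []
    classes = []
    peak_ids = []
    for j in range(n_primed_peaks):
        acc.append(0.5 + 0.5 * _sigmoid((s - 0.5) / 0.1))
        classes.append("primed")
        peak_ids.append(f"chr1:{1000 + 2000 * j}-{1500 + 2000 * j}")
    for j in range(n_lineage_peaks):
        acc.append(_sigmoid((s - 0.7) / 0.05))
        classes.append("lineage_specific")
        peak_ids.append(f"chr2:{1000 + 2000 * j}-{1500 + 2000 * j}")
    acc_clean = np.column_stack(acc)

    # reference (stem-population) fragment counts reflect the programmed
    # openness; the rate is chosen so the Poisson openness test operates in
    # its sensitive regime (background lambda ~ 0.05 per effective unit)
    start = s < 0.2
    rate = 600.0
    ref_counts = rng.poisson(rate * acc_clean[start].mean(axis=0))

    acc = acc_clean + rng.normal(scale=0.01, size=acc_clean.shape)
    acc = np.clip(acc, 0.0, None)

    manifest = {
        "n_cells": n_cells,
        "corridor": [lo, hi],
        "corridor_weight": corridor_weight,
        "expression_noise": expression_noise,
        "seed": seed,
    }
    return OmicsFixture(
        states=StateMatrix(X),
        pseudotime=s,
        expression=expr,
        gene_ids=gene_ids,
        driver_gene="driver",
        accessibility=acc,
        peak_ids=np.array(peak_ids),
        peak_classes=np.array(classes),
        reference_counts=ref_counts,
        corridor=(lo, hi),
        manifest=manifest,
    )
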