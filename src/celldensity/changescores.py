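"""Genes driving low-density cell-state transitions.

Rapidly changing genes in sparsely populated regions of the cell-state space
are candidate drivers of cell-state transitions.  For each gene the local
variability in a cell is the largest expression difference toward any of its
k nearest neighbors, normalised by the state-space distance to that
neighbor:

    d_ij = max_{l in N_i} |m_ij - m_lj| / ||x_i - x_l||

The change score of gene ``j`` over a selected cell subset ``S`` weights the
local variabilities by inverse cell-state density, concentrating the score
on changes happening in low-density states:

    s_j = sum_{i in S} d_ij / rho(x_i)

Genes with scores strictly above the 95th percentile are flagged as drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import as_state_matrix

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "local_variability",
    "change_scores",
    "select_driver_genes",
    "change_score_table",
]


@dataclass(frozen=True)
class NeighborGraph:
    """k-nearest-neighbor graph in the cell-state space (no self-loops)."""

    indices: np.ndarray  # (n, k) neighbor indices
    distances: np.ndarray  # (n, k) matching distances, all > 0

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        dist = np.asarray(self.distances, dtype=float)
        if idx.shape != dist.shape:
            raise ValueError("indices and distances must have matching shape")
        if np.any(idx == np.arange(idx.shape[0])[:, None]):
            raise ValueError("neighbor graph contains self-loops")
        if np.any(dist <= 0):
            raise ValueError("neighbor distances must be positive")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "distances", dist)

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def build_neighbor_graph(states, k: int = 15) -> NeighborGraph:
    """Exact kNN graph over the same state space the density model uses."""
    sm = as_state_matrix(states)
    if not 1 <= k < sm.n_cells:
        raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={sm.n_cells})")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(sm.coordinates)
    dist, idx = nbrs.kneighbors(sm.coordinates)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop the self column
    if np.any(dist == 0):
        pos = dist[dist > 0]
        if pos.size == 0:
            raise ValueError("all neighbor distances are zero")
        eps = pos.min() * 1e-3
        warnings.warn(
            "zero neighbor distances (duplicate coordinates) replaced by "
            f"{eps:.3g}",
            stacklevel=2,
        )
        dist = np.where(dist == 0, eps, dist)
    return NeighborGraph(indices=idx, distances=dist)


def local_variability(expression, graph: NeighborGraph) -> np.ndarray:
    """Per-(cell, gene) local variability: the maximum over neighbors of the
    absolute expression change divided by the distance to that neighbor."""
    expr = np.asarray(
        expression.to_numpy() if isinstance(expression, pd.DataFrame) else expression,
        dtype=float,
    )
    if expr.shape[0] != graph.indices.shape[0]:
        raise ValueError("expression rows must match the neighbor graph")
    out = np.zeros_like(expr)
    for col in range(graph.k):
        rate = np.abs(expr - expr[graph.indices[:, col]]) / graph.distances[:, [col]]
        np.maximum(out, rate, out=out)
    return out


def change_scores(variability, log_densities, subset) -> np.ndarray:
    """Density-weighted change score per gene over the subset ``S``:
    ``s_j = sum_{i in S} d_ij / rho(x_i)``."""
    var = np.asarray(variability, dtype=float)
    logd = np.asarray(log_densities, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset is empty")
    inv_rho = np.exp(-logd[subset])
    return inv_rho @ var[subset]


def select_driver_genes(scores, gene_ids=None, percentile: float = 95.0):
    """Genes with scores strictly above the given percentile (linear
    interpolation), sorted by descending score.

    With fewer than 20 genes the percentile is not meaningful; a warning is
    raised and all genes are returned sorted.
    """
    s = np.asarray(scores, dtype=float)
    if gene_ids is None:
        gene_ids = np.array([f"gene_{j}" for j in range(s.size)])
    gene_ids = np.asarray(gene_ids)
    order = np.argsort(-s, kind="stable")
    if s.size < 20:
        warnings.warn(
            f"only {s.size} genes; percentile gating skipped, returning all sorted",
            stacklevel=2,
        )
        return gene_ids[order]
    cut = np.percentile(s, percentile)
    flagged = order[s[order] > cut]
    if flagged.size == 0:
        warnings.warn("no gene strictly exceeds the percentile cut", stacklevel=2)
    return gene_ids[flagged]


def change_score_table(
    expression,
    states,
    log_densities,
    subset,
    *,
    k: int = 15,
    gene_ids=None,
    percentile: float = 95.0,
) -> pd.DataFrame:
    """End-to-end change-score computation returning a per-gene table with
    columns ``score`` and ``driver`` (95th-percentile flag), sorted by
    descending score."""
    if isinstance(expression, pd.DataFrame):
        if gene_ids is None:
            gene_ids = np.asarray(expression.columns)
        expression = expression.to_numpy(dtype=float)
    expr = np.asarray(expression, dtype=float)
    if gene_ids is None:
        gene_ids = np.array([f"gene_{j}" for j in range(expr.shape[1])])
    graph = build_neighbor_graph(states, k=k)
    var = local_variability(expr, graph)
    s = change_scores(var, log_densities, subset)
    if s.size >= 20:
        cut = np.percentile(s, percentile)
        driver = s > cut
    else:
        driver = np.zeros(s.size, dtype=bool)
    df = pd.DataFrame({"score": s, "driver": driver}, index=pd.Index(gene_ids, name="gene"))
    return df.sort_values("score", ascending=False, kind="stable")
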