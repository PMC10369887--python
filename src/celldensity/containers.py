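"""Lightweight data containers shared across the package.

The central object is :class:`StateMatrix`, an ``n x d'`` matrix of cell-state
coordinates (e.g. diffusion components) in which Euclidean distance measures
biological dissimilarity.  All densities in this package are defined over such
a space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateMatrix",
    "NNDistances",
    "KernelSpec",
    "LandmarkSet",
    "as_state_matrix",
]


@dataclass(frozen=True)
class StateMatrix:
    """Cell-state coordinates with per-cell identifiers.

    Parameters
    ----------
    coordinates
        ``(n, d')`` array of real coordinates; all entries must be finite.
    cell_ids
        ``n`` unique identifiers.  Defaults to ``"cell_0" ... "cell_{n-1}"``.
    """

    coordinates: np.ndarray
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if coords.ndim != 2:
            raise ValueError("coordinates must be a 2-D array")
        if coords.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        if coords.shape[1] < 1:
            raise ValueError("need at least 1 dimension")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite entries")
        object.__setattr__(self, "coordinates", coords)
        ids = self.cell_ids
        if ids is None:
            ids = np.array([f"cell_{i}" for i in range(coords.shape[0])])
        else:
            ids = np.asarray(ids)
            if ids.shape[0] != coords.shape[0]:
                raise ValueError(
                    f"{ids.shape[0]} cell_ids for {coords.shape[0]} cells"
                )
            if len(set(ids.tolist())) != ids.shape[0]:
                raise ValueError("cell_ids are not unique")
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StateMatrix":
        """Build from a cells-by-dims DataFrame; the index supplies cell ids."""
        return cls(df.to_numpy(dtype=float), np.asarray(df.index.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"dim_{j}" for j in range(self.n_dims)]
        return pd.DataFrame(self.coordinates, index=self.cell_ids, columns=cols)


def as_state_matrix(states) -> StateMatrix:
    """Coerce an ndarray / DataFrame / StateMatrix into a StateMatrix."""
    if isinstance(states, StateMatrix):
        return states
    if isinstance(states, pd.DataFrame):
        return StateMatrix.from_dataframe(states)
    return StateMatrix(np.asarray(states, dtype=float))


@dataclass(frozen=True)
class NNDistances:
    """Per-cell nearest-neighbor distances plus the dimensionality ``d``
    used by the nearest-neighbor likelihood (``density_dim``)."""

    distances: np.ndarray
    density_dim: int

    def __post_init__(self):
        dist = np.asarray(self.distances, dtype=float)
        if np.any(dist <= 0) or not np.all(np.isfinite(dist)):
            raise ValueError("nearest-neighbor distances must be positive and finite")
        if int(self.density_dim) < 2:
            raise ValueError("density_dim must be >= 2")
        object.__setattr__(self, "distances", dist)
        object.__setattr__(self, "density_dim", int(self.density_dim))


@dataclass(frozen=True)
class KernelSpec:
    """Matérn-5/2 kernel hyperparameters (length scale in coordinate units)."""

    length_scale: float
    variance: float = 1.0

    def __post_init__(self):
        if not self.length_scale > 0:
            raise ValueError("length_scale must be > 0")
        if not self.variance > 0:
            raise ValueError("variance must be > 0")


@dataclass(frozen=True)
class LandmarkSet:
    """Inducing locations for the sparse Gaussian process."""

    locations: np.ndarray

    def __post_init__(self):
        loc = np.atleast_2d(np.asarray(self.locations, dtype=float))
        if not np.all(np.isfinite(loc)):
            raise ValueError("landmark locations must be finite")
        object.__setattr__(self, "locations", loc)

    @property
    def k(self) -> int:
        return self.locations.shape[0]
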