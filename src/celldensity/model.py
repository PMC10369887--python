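"""Model/Results interface for cell-state density estimation.

Follows the familiar two-object pattern: :class:`CellStateDensity` is
constructed from data and configuration, ``fit()`` runs MAP inference and
returns a :class:`CellStateDensityResults` carrying the fitted log-density
function, per-cell densities, diagnostics and a ``summary()`` table.

Example
-------
>>> import numpy as np
>>> from celldensity import CellStateDensity
>>> X = np.random.default_rng(0).normal(size=(500, 2))
>>> res = CellStateDensity(X).fit()
>>> res.log_density[:3]  # doctest: +SKIP
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .containers import KernelSpec, LandmarkSet, NNDistances, StateMatrix, as_state_matrix
from .gp import (
    DEFAULT_N_LANDMARKS,
    DensityModel,
    covariance_rank_check,
    map_fit,
)
from .nn import compute_nn_distances

__all__ = [
    "CellStateDensity",
    "CellStateDensityResults",
    "save_model",
    "load_model",
]


class CellStateDensity:
    """Continuous cell-state density model.

    Parameters
    ----------
    states
        ``(n, d')`` cell-state coordinates (array, DataFrame with cell ids as
        index, or StateMatrix).
    density_dim
        Dimensionality ``d`` used in the nearest-neighbor likelihood;
        defaults to ``d'``.  Override for intrinsic-dimensionality studies.
    n_landmarks
        Landmark budget for the sparse GP (default 5000); a full GP is used
        when the dataset is at most this large.
    length_scale
        Kernel length scale; ``None`` (default) applies the
        nearest-neighbor-distance heuristic ``exp(3 + mean(log dn))``.
    """

    def __init__(
        self,
        states,
        *,
        density_dim: int | None = None,
        n_landmarks: int = DEFAULT_N_LANDMARKS,
        length_scale: float | None = None,
        lambda_const: float = 3.0,
        kernel_variance: float = 1.0,
    ):
        self.states = as_state_matrix(states)
        self.density_dim = density_dim
        self.n_landmarks = int(n_landmarks)
        self.length_scale = length_scale
        self.lambda_const = float(lambda_const)
        self.kernel_variance = float(kernel_variance)
        self._nn: NNDistances | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CellStateDensity":
        return cls(StateMatrix.from_dataframe(df), **kwargs)

    @property
    def nn_distances(self) -> NNDistances:
        """Nearest-neighbor distances (computed lazily, exact search)."""
        if self._nn is None:
            self._nn = compute_nn_distances(self.states, self.density_dim)
        return self._nn

    def fit(
        self,
        *,
        seed: int = 0,
        maxiter: int = 500,
        gtol: float = 1e-6,
        jitter: float = 1e-6,
    ) -> "CellStateDensityResults":
        """Run MAP inference and return the fitted results object."""
        model = map_fit(
            self.states,
            self.nn_distances,
            density_dim=self.density_dim,
            n_landmarks=self.n_landmarks,
            length_scale=self.length_scale,
            lambda_const=self.lambda_const,
            kernel_variance=self.kernel_variance,
            seed=seed,
            maxiter=maxiter,
            gtol=gtol,
            jitter=jitter,
        )
        return CellStateDensityResults(self, model)


class CellStateDensityResults:
    """Fitted cell-state density function.

    Attributes
    ----------
    log_density
        Per-training-cell log-density (GP posterior-mean evaluation).
    model_
        The underlying :class:`~celldensity.gp.DensityModel`.
    """

    def __init__(self, model: CellStateDensity, fitted: DensityModel):
        self.model = model
        self.model_ = fitted

    @property
    def log_density(self) -> np.ndarray:
        return self.model_.training_log_density

    @property
    def params(self) -> np.ndarray:
        """Whitened latent coefficients ``y`` of the MAP solution."""
        return self.model_.latent_coefficients

    @property
    def mean_constant(self) -> float:
        return self.model_.mean_const

    @property
    def kernel(self) -> KernelSpec:
        return self.model_.kernel

    @property
    def landmarks(self) -> LandmarkSet:
        return self.model_.landmarks

    def predict(self, query) -> np.ndarray:
        """Evaluate the log-density function at arbitrary states."""
        return self.model_.predict(query)

    def density_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"log_density": self.log_density},
            index=self.model.states.cell_ids,
        )

    def check_landmark_rank(self, tol: float = 1e-6) -> tuple[int, bool]:
        """Numerical rank of the landmark covariance; a deficient rank means
        the landmark budget exceeds the representable complexity."""
        return covariance_rank_check(self.model_.landmarks, self.model_.kernel, tol)

    def summary(self) -> str:
        m = self.model_
        st = m.optimizer_status
        ld = self.log_density
        rows = [
            ("No. cells", m.training_states.n_cells if m.training_states else "n/a"),
            ("State dims (d')", m.n_state_dims),
            ("Density dim (d)", m.density_dim),
            ("GP mode", m.factor_mode),
            ("No. landmarks", m.landmarks.k),
            ("Length scale", f"{m.kernel.length_scale:.6g}"),
            ("Kernel variance", f"{m.kernel.variance:.6g}"),
            ("Mean constant (m)", f"{m.mean_const:.6g}"),
            ("Converged", st.get("success")),
            ("Iterations", st.get("n_iterations")),
            ("Neg. log posterior", f"{st.get('objective', float('nan')):.6g}"),
            ("Log-density min", f"{ld.min():.4f}"),
            ("Log-density max", f"{ld.max():.4f}"),
        ]
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Cell-State Density MAP Results", "=" * 40]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        save_model(self.model_, path)

    @classmethod
    def load(cls, path: str) -> "CellStateDensityResults":
        fitted = load_model(path)
        shell = CellStateDensity(
            fitted.training_states,
            density_dim=fitted.density_dim,
            n_landmarks=fitted.landmarks.k,
            length_scale=fitted.kernel.length_scale,
            kernel_variance=fitted.kernel.variance,
        )
        return cls(shell, fitted)


def save_model(model: DensityModel, path: str) -> None:
    """Serialize a fitted model to an HDF5 container.

    Arrays are stored as float64 datasets (bit-exact round-trip); scalars and
    configuration go into a JSON manifest attribute.
    """
    manifest = {
        "format": "celldensity-model",
        "version": _pkg_version,
        "mean_const": model.mean_const,
        "length_scale": model.kernel.length_scale,
        "kernel_variance": model.kernel.variance,
        "density_dim": model.density_dim,
        "factor_mode": model.factor_mode,
        "optimizer_status": model.optimizer_status,
        "time_length_scale": (
            model.time_kernel.length_scale if model.time_kernel else None
        ),
        "time_kernel_variance": (
            model.time_kernel.variance if model.time_kernel else None
        ),
    }
    with h5py.File(path, "w") as h5:
        h5.attrs["manifest"] = json.dumps(manifest)
        h5.create_dataset("landmarks", data=model.landmarks.locations)
        h5.create_dataset("latent_coefficients", data=model.latent_coefficients)
        h5.create_dataset("prediction_weights", data=model.prediction_weights)
        if model.training_log_density is not None:
            h5.create_dataset("training_log_density", data=model.training_log_density)
        if model.training_states is not None:
            h5.create_dataset("training_coordinates", data=model.training_states.coordinates)
            h5.create_dataset(
                "training_cell_ids",
                data=np.asarray(model.training_states.cell_ids, dtype="S"),
            )


def load_model(path: str) -> DensityModel:
    """Load a model saved by :func:`save_model`."""
    with h5py.File(path, "r") as h5:
        manifest = json.loads(h5.attrs["manifest"])
        if manifest.get("format") != "celldensity-model":
            raise ValueError(f"{path} is not a celldensity model file")
        landmarks = h5["landmarks"][...]
        y = h5["latent_coefficients"][...]
        w = h5["prediction_weights"][...]
        f_train = (
            h5["training_log_density"][...] if "training_log_density" in h5 else None
        )
        states = None
        if "training_coordinates" in h5:
            ids = h5["training_cell_ids"][...].astype(str)
            states = StateMatrix(h5["training_coordinates"][...], ids)
    time_kernel = None
    if manifest.get("time_length_scale") is not None:
        time_kernel = KernelSpec(
            manifest["time_length_scale"], manifest.get("time_kernel_variance") or 1.0
        )
    return DensityModel(
        mean_const=manifest["mean_const"],
        kernel=KernelSpec(manifest["length_scale"], manifest["kernel_variance"]),
        landmarks=LandmarkSet(landmarks),
        latent_coefficients=y,
        prediction_weights=w,
        density_dim=manifest["density_dim"],
        factor_mode=manifest["factor_mode"],
        time_kernel=time_kernel,
        training_states=states,
        training_log_density=f_train,
        optimizer_status=manifest.get("optimizer_status", {}),
    )
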