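"""Readers/writers, run configuration and manifests.

TSV is the canonical text interchange (cells x dims with a header row and
the cell id as first column); MTX and HDF5 are accepted for matrices.  Every
result writer drops a JSON manifest next to its output recording the exact
configuration, seeds and library versions used.
"""

from __future__ import annotations

import json
import subprocess
import sys
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RunConfig", "read_matrix", "write_matrix", "write_results", "build_manifest"]


@dataclass
class RunConfig:
    """Configuration shared by the CLI subcommands; serialized verbatim into
    every output manifest.  Unknown keys are rejected on load."""

    n_landmarks: int = 5000
    density_dim: int | None = None
    length_scale: float | str = "auto"
    time_length_scale: float | str = "auto"
    gtol: float = 1e-6
    maxiter: int = 500
    seed: int = 0
    knn_k: int = 15
    min_cells_per_timepoint: int = 50

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def resolved_length_scale(self) -> float | None:
        return None if self.length_scale == "auto" else float(self.length_scale)

    def to_dict(self) -> dict:
        return asdict(self)


def _read_id_file(path: str) -> np.ndarray:
    with open(path) as fh:
        return np.array([line.strip() for line in fh if line.strip()])


def read_matrix(
    path: str,
    fmt: str | None = None,
    *,
    id_file: str | None = None,
    cells_as_rows: bool = True,
    dataset: str = "matrix",
    ids_dataset: str = "ids",
) -> pd.DataFrame:
    """Read a cells-by-dims matrix with row ids into a DataFrame.

    ``fmt`` in {tsv, csv, mtx, hdf5}; inferred from the suffix when omitted.
    MTX triplets are accepted in either orientation via ``cells_as_rows``
    and take their row ids from ``id_file`` (one id per line).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx",
               ".h5": "hdf5", ".hdf5": "hdf5"}.get(p.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {p.suffix!r}")
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        bad = df.isna()
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"missing/non-numeric value at row {df.index[i]!r}, "
                f"column {df.columns[j]!r} of {path}"
            )
        try:
            return df.astype(float)
        except ValueError as err:
            raise ValueError(f"non-numeric cell in {path}: {err}") from err
    if fmt == "mtx":
        from scipy.io import mmread

        raw = mmread(path)
        M = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=float)
        if not cells_as_rows:
            M = M.T
        if id_file is not None:
            ids = _read_id_file(id_file)
            if ids.shape[0] != M.shape[0]:
                raise ValueError(
                    f"id file has {ids.shape[0]} ids but matrix has "
                    f"{M.shape[0]} rows"
                )
        else:
            ids = np.array([f"cell_{i}" for i in range(M.shape[0])])
        return pd.DataFrame(M, index=ids)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as h5:
            M = h5[dataset][...]
            if ids_dataset in h5:
                ids = h5[ids_dataset][...].astype(str)
            else:
                ids = np.array([f"cell_{i}" for i in range(M.shape[0])])
        if ids.shape[0] != M.shape[0]:
            raise ValueError(
                f"dataset {ids_dataset!r} has {ids.shape[0]} ids for "
                f"{M.shape[0]} rows"
            )
        return pd.DataFrame(np.asarray(M, dtype=float), index=ids)
    raise ValueError(f"unsupported format {fmt!r}")


def write_matrix(df: pd.DataFrame, path: str) -> None:
    """TSV writer: header row, cell id first column."""
    out = df.copy()
    out.index.name = out.index.name or "cell_id"
    out.to_csv(path, sep="\t")


def _git_hash() -> str:
    try:
        return subprocess.run(
            ["git", "rev-parse", "HEAD"], capture_output=True, text=True,
            timeout=5, check=True,
        ).stdout.strip()
    except Exception:
        return "unknown"


def build_manifest(config: RunConfig, extra: dict | None = None) -> dict:
    import scipy
    import sklearn

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "celldensity": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "git_hash": _git_hash(),
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_results(
    df: pd.DataFrame, path: str, config: RunConfig, extra: dict | None = None
) -> None:
    """Write a result table as TSV plus a sibling ``.manifest.json``."""
    write_matrix(df, path)
    manifest = build_manifest(config, extra)
    with open(str(path) + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
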