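"""Domain types and I/O for methylation matrices and clock model bundles.

DNAm values are held internally on the percent scale [0, 100]; beta-value
inputs in [0, 1] are converted on read.  Missing values stay as NaN and are
never imputed here — every downstream operation declares its own policy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("wkde")

MODEL_FORMAT_VERSION = 1
WEIGHT_BOUNDS = (-10.0, 10.0)


class ModelFormatError(ValueError):
    """Raised when a model bundle is inconsistent, truncated, or incompatible."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """CpG x sample DNAm percentages with optional missing cells.

    Parameters
    ----------
    values
        DataFrame indexed by CpG id with one column per sample id;
        entries are DNAm percent in [0, 100], NaN marks a missing cell.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="cpg_id", columns=None)
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate CpG ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = df.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 100)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"DNAm value out of [0, 100]: {arr[i, j]!r} at "
                f"CpG {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return [str(c) for c in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "MethylationMatrix":
        missing = [c for c in cpg_ids if c not in self.values.index]
        if missing:
            raise KeyError(f"CpGs absent from matrix: {missing[:5]}")
        return MethylationMatrix(self.values.loc[list(cpg_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return MethylationMatrix(self.values[list(sample_ids)])


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid for the 2D kernels: age on one axis, DNAm% on the other.

    Defaults give 101 equally spaced points per axis, so the grid step is
    one year of age and one percentage point of DNAm.
    """

    age_min: float = 0.0
    age_max: float = 100.0
    dnam_min: float = 0.0
    dnam_max: float = 100.0
    n_points: int = 101

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points per axis")
        if not (self.age_max > self.age_min and self.dnam_max > self.dnam_min):
            raise ValueError("grid bounds must be ordered")

    @property
    def age_grid(self) -> np.ndarray:
        return np.linspace(self.age_min, self.age_max, self.n_points)

    @property
    def dnam_grid(self) -> np.ndarray:
        return np.linspace(self.dnam_min, self.dnam_max, self.n_points)

    @property
    def age_step(self) -> float:
        return (self.age_max - self.age_min) / (self.n_points - 1)

    def to_dict(self) -> dict:
        return {
            "age_min": self.age_min,
            "age_max": self.age_max,
            "dnam_min": self.dnam_min,
            "dnam_max": self.dnam_max,
            "n_points": self.n_points,
        }


@dataclass
class DensityKernel:
    """One CpG's 2D density estimate on the grid.

    ``density[j, i]`` is the density for DNAm = j-th DNAm grid value and
    age = i-th age grid value (rows = DNAm, columns = age).  This row/column
    convention is what prediction relies on: a sample's DNAm level selects a
    row, which is then a vector of densities over all grid ages.
    """

    cpg_id: str
    density: np.ndarray
    bandwidths: tuple[float, float]  # (h_age, h_dnam), pre-scaling bandwidths

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 2:
            raise ValueError("kernel density must be a 2D matrix")
        if np.any(self.density < 0):
            raise ValueError(f"negative density in kernel for {self.cpg_id}")
        if not np.any(self.density > 0):
            raise ValueError(f"kernel for {self.cpg_id} is identically zero")
        h_age, h_dnam = self.bandwidths
        if not (h_age > 0 and h_dnam > 0):
            raise ValueError("bandwidths must be positive")


@dataclass
class KernelModel:
    """The serializable clock: signature kernels plus per-CpG weights.

    Weights default to 1.0 (the unweighted clock) and are constrained to
    [-10, 10]; the genetic-algorithm optimizer replaces them.
    """

    grid: GridSpec
    kernels: list[DensityKernel]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.kernels),):
            raise ValueError(
                f"{len(self.kernels)} kernels but {self.weights.size} weights"
            )
        lo, hi = WEIGHT_BOUNDS
        if np.any(self.weights < lo) or np.any(self.weights > hi):
            raise ValueError(f"weights must lie within [{lo}, {hi}]")
        n = self.grid.n_points
        for k in self.kernels:
            if k.density.shape != (n, n):
                raise ValueError(
                    f"kernel {k.cpg_id} has shape {k.density.shape}, "
                    f"expected ({n}, {n})"
                )
        ids = [k.cpg_id for k in self.kernels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate CpG ids among kernels")

    @property
    def cpg_ids(self) -> list[str]:
        return [k.cpg_id for k in self.kernels]

    @property
    def n_cpgs(self) -> int:
        return len(self.kernels)

    def with_weights(self, weights: np.ndarray) -> "KernelModel":
        return KernelModel(self.grid, self.kernels, np.asarray(weights, float),
                           dict(self.provenance))


# ---------------------------------------------------------------------------
# Beta-matrix and sample-table I/O
# ---------------------------------------------------------------------------


def read_beta_matrix(path: str | Path, scale: str = "auto") -> MethylationMatrix:
    """Read a delimited CpG x sample matrix of beta values.

    The first column holds CpG ids and the header row sample ids.  Comma and
    tab delimiters (and CRLF line endings) are both accepted.

    Parameters
    ----------
    scale
        ``"fraction"`` multiplies by 100, ``"percent"`` keeps values as is,
        ``"auto"`` treats the matrix as fractions when its observed maximum
        is <= 1.5 (so percent matrices of uniformly low-methylated probes
        are the only ambiguity, and those are rare in practice).
    """
    if scale not in ("auto", "fraction", "percent"):
        raise ValueError(f"unknown scale {scale!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    finite = df.to_numpy()[np.isfinite(df.to_numpy())]
    if finite.size == 0:
        raise ValueError(f"{path}: matrix holds no finite values")
    if scale == "fraction" or (scale == "auto" and finite.max() <= 1.5):
        df = df * 100.0
        logger.info("read %s as beta fractions, rescaled to percent", path)
    return MethylationMatrix(df)


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path,
                      sep: str = "\t") -> None:
    """Write the matrix on the percent scale (round-trips bit-exactly)."""
    matrix.values.to_csv(path, sep=sep, float_format="%.17g")


_SEXES = {"female", "male", "unknown"}
_GROUPS = {"healthy", "diseased", "unknown"}


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample table with columns sample_id, age[, sex, study, group]."""
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_sample_table(df)


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "sample_id" not in df.columns or "age" not in df.columns:
        raise ValueError("sample table needs columns 'sample_id' and 'age'")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    df["age"] = df["age"].astype(float)
    if not np.all(np.isfinite(df["age"])) or (df["age"] < 0).any():
        raise ValueError("ages must be finite and >= 0")
    for col, allowed, default in (("sex", _SEXES, "unknown"),
                                  ("study", None, "study0"),
                                  ("group", _GROUPS, "unknown")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].astype(str)
        if allowed is not None and not set(df[col]) <= allowed:
            bad = sorted(set(df[col]) - allowed)
            raise ValueError(f"invalid {col} values: {bad}")
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Model bundle: JSON metadata + HDF5 array payload
# ---------------------------------------------------------------------------
#
# Layout (documented so other languages can read it):
#   <dir>/model.json   {"format_version", "grid", "cpg_ids", "weights",
#                       "bandwidths", "provenance"}
#   <dir>/kernels.h5   one float64 dataset per CpG under /kernels/<cpg_id>,
#                      rows = DNAm grid index, columns = age grid index.


def save_model(model: KernelModel, path: str | Path) -> None:
    """Save a model bundle into directory ``path`` (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "grid": model.grid.to_dict(),
        "cpg_ids": model.cpg_ids,
        "weights": [float(w) for w in model.weights],
        "bandwidths": {k.cpg_id: [float(b) for b in k.bandwidths]
                       for k in model.kernels},
        "provenance": model.provenance,
    }
    with open(path / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    with h5py.File(path / "kernels.h5", "w") as h5:
        grp = h5.create_group("kernels")
        for k in model.kernels:
            grp.create_dataset(k.cpg_id, data=k.density, dtype="float64")


def load_model(path: str | Path) -> KernelModel:
    """Load a model bundle, checking version and metadata/payload consistency."""
    path = Path(path)
    meta_path = path / "model.json"
    h5_path = path / "kernels.h5"
    if not meta_path.exists() or not h5_path.exists():
        raise ModelFormatError(f"{path}: incomplete bundle "
                               "(need model.json and kernels.h5)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})")
    grid = GridSpec(**meta["grid"])
    cpg_ids = meta["cpg_ids"]
    weights = np.asarray(meta["weights"], dtype=float)
    lo, hi = WEIGHT_BOUNDS
    if weights.shape != (len(cpg_ids),) or np.any(weights < lo) or np.any(weights > hi):
        raise ModelFormatError("recorded weights invalid or out of [-10, 10]")
    kernels = []
    try:
        with h5py.File(h5_path, "r") as h5:
            stored = set(h5["kernels"].keys())
            missing = [c for c in cpg_ids if c not in stored]
            if missing:
                raise ModelFormatError(
                    f"bundle missing kernels named in metadata: {missing[:5]}")
            for cpg in cpg_ids:
                density = h5["kernels"][cpg][...]
                kernels.append(DensityKernel(
                    cpg_id=cpg,
                    density=density,
                    bandwidths=tuple(meta["bandwidths"][cpg]),
                ))
    except OSError as exc:  # truncated or corrupt HDF5 payload
        raise ModelFormatError(f"{h5_path}: unreadable payload ({exc})") from exc
    try:
        return KernelModel(grid=grid, kernels=kernels, weights=weights,
                           provenance=meta.get("provenance", {}))
    except ValueError as exc:
        raise ModelFormatError(str(exc)) from exc
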