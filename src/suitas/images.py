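"""Volume, mask and event-table I/O and the masked-vectorization contract.

Every pattern-analysis stage in this package operates on masked voxel
vectors rather than 3-D arrays.  The contract is frozen here:

* voxels are ordered by ascending linear index of the stored array with the
  last axis fastest (C order);
* a volume can only be vectorized against a mask defined on the *same* grid
  (identical shape, affines equal within 1e-4 mm) — there is no implicit
  resampling;
* ``unvectorize(vectorize(v))`` restores in-mask voxels exactly and fills
  out-of-mask voxels with a constant (0 by default).

Volumes are read and written as NIfTI via nibabel; event and nuisance
tables are tab-separated files read into pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GridMismatchError",
    "EventsSchemaError",
    "VolumeGrid",
    "Volume",
    "BrainMask",
    "ActivationMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "vectorize",
    "unvectorize",
    "read_events",
    "DEFAULT_CONDITIONS",
]

#: condition vocabulary of the uncertainty-variation threat-anticipation task
DEFAULT_CONDITIONS = ("safety", "low", "medium", "high")

GRID_TOL_MM = 1e-4


class FormatError(ValueError):
    """File does not parse as NIfTI-1/2 or has an unsupported layout."""


class GridMismatchError(ValueError):
    """Volume and mask live on different grids; explicit resampling required."""


class EventsSchemaError(ValueError):
    """Event table is missing required columns or violates the schema."""


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid of a 3-D image: shape plus voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be invertible")
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be 3 positive integers")
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels_total(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid", tol: float = GRID_TOL_MM) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass(frozen=True)
class Volume:
    """A 3-D or 4-D image (data array + grid)."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim not in (3, 4):
            raise FormatError(f"expected 3-D or 4-D data, got {data.ndim}-D")
        if tuple(data.shape[:3]) != self.grid.shape:
            raise GridMismatchError(
                f"data shape {data.shape[:3]} does not match grid {self.grid.shape}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        """Number of time frames (1 for a 3-D volume)."""
        return 1 if self.data.ndim == 3 else int(self.data.shape[3])


@dataclass(frozen=True)
class BrainMask:
    """Analysis mask: ordered in-mask linear voxel indices on a grid.

    ``indices`` are strictly increasing linear indices into the C-ordered
    (last axis fastest) raveled volume; this ordering is the package-wide
    voxel order of all weight, statistic and activation vectors.
    """

    grid: VolumeGrid
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("mask must contain at least one voxel")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("mask indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= self.grid.n_voxels_total:
            raise ValueError("mask indices out of grid bounds")
        idx.flags.writeable = False
        object.__setattr__(self, "indices", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    @classmethod
    def from_array(cls, grid: VolumeGrid, arr: np.ndarray) -> "BrainMask":
        arr = np.asarray(arr)
        if tuple(arr.shape) != grid.shape:
            raise GridMismatchError("mask array shape does not match grid")
        return cls(grid=grid, indices=np.flatnonzero(arr.ravel(order="C") > 0))

    def to_array(self) -> np.ndarray:
        out = np.zeros(self.grid.n_voxels_total, dtype=bool)
        out[self.indices] = True
        return out.reshape(self.grid.shape)

    @property
    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates of in-mask voxels."""
        return np.column_stack(np.unravel_index(self.indices, self.grid.shape))

    def world_coords(self) -> np.ndarray:
        """(n_voxels, 3) world-space (mm) coordinates of in-mask voxels."""
        ijk1 = np.column_stack([self.voxel_coords, np.ones(self.n_voxels)])
        return (ijk1 @ self.grid.affine.T)[:, :3]


@dataclass
class ActivationMap:
    """Masked voxel vector of beta estimates with provenance metadata."""

    mask: BrainMask
    values: np.ndarray
    participant: object = None
    study: object = None
    kind: str = "rating-level"  # rating-level | trial | condition | contrast
    rating: int | None = None
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.mask.n_voxels:
            raise ValueError(
                f"values length {vals.size} != mask n_voxels {self.mask.n_voxels}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("activation map contains non-finite values")
        self.values = vals

    def to_volume(self, fill: float = 0.0) -> Volume:
        return Volume(self.mask.grid, unvectorize(self.values, self.mask, fill=fill))


# ---------------------------------------------------------------------------
# volume I/O


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1/2 file into a :class:`Volume`.

    Raises :class:`FormatError` for files that do not parse or are not
    3-D/4-D.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        affine = np.asarray(img.affine, dtype=float)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed header, wrong magic, ...
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    grid = VolumeGrid(shape=tuple(data.shape[:3]), affine=affine)
    return Volume(grid=grid, data=data)


def write_volume(path: str | Path, volume: Volume) -> None:
    """Write a volume as float32 NIfTI (data preserved to float32 precision)."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BrainMask:
    """Read a binary NIfTI mask (any voxel > 0 is in-mask)."""
    vol = read_volume(path)
    if vol.data.ndim != 3:
        raise FormatError("mask must be a 3-D image")
    return BrainMask.from_array(vol.grid, vol.data)


# ---------------------------------------------------------------------------
# vectorization


def vectorize(volume: Volume | np.ndarray, mask: BrainMask) -> np.ndarray:
    """Extract in-mask voxel values in mask index order.

    For a 4-D volume, returns an (n_frames, n_voxels) matrix.  Raises
    :class:`GridMismatchError` if the volume grid differs from the mask grid
    and ``ValueError`` if any in-mask value is non-finite.
    """
    if isinstance(volume, Volume):
        if not volume.grid.matches(mask.grid):
            raise GridMismatchError(
                "volume grid does not match mask grid; resampling required"
            )
        data = volume.data
    else:
        data = np.asarray(volume)
        if tuple(data.shape[:3]) != mask.grid.shape:
            raise GridMismatchError("array shape does not match mask grid")
    if data.ndim == 3:
        vec = data.ravel(order="C")[mask.indices]
    else:
        flat = data.reshape(-1, data.shape[3], order="C")
        vec = flat[mask.indices, :].T
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite values inside mask")
    return np.asarray(vec, dtype=float)


def unvectorize(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Place a masked vector back into a full 3-D array (out-of-mask = fill)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise ValueError("vector length does not match mask")
    out = np.full(mask.grid.n_voxels_total, fill, dtype=float)
    out[mask.indices] = values
    return out.reshape(mask.grid.shape)


# ---------------------------------------------------------------------------
# event tables

_REQUIRED_EVENT_COLUMNS = (
    "onset",
    "duration",
    "run",
    "condition",
    "rating",
    "shock_followed",
)


def read_events(
    path: str | Path,
    conditions: Sequence[str] | None = DEFAULT_CONDITIONS + ("dummy",),
) -> pd.DataFrame:
    """Read a trial/event table from TSV and validate its schema.

    Required columns: onset (s, 0-based from run start), duration (s), run,
    condition, rating (1–5 or empty for missed trials), shock_followed
    (0/1).  Onsets must be nonnegative and nondecreasing within each run.
    ``conditions=None`` disables the vocabulary check.
    """
    table = pd.read_csv(path, sep="\t")
    return validate_events(table, conditions=conditions)


def validate_events(
    table: pd.DataFrame,
    conditions: Sequence[str] | None = DEFAULT_CONDITIONS + ("dummy",),
) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventsSchemaError(f"event table missing columns: {missing}")
    out = table.copy()
    out["onset"] = out["onset"].astype(float)
    out["duration"] = out["duration"].astype(float)
    out["run"] = out["run"].astype(int)
    out["condition"] = out["condition"].astype(str)
    out["shock_followed"] = out["shock_followed"].astype(bool)
    out["rating"] = pd.to_numeric(out["rating"], errors="coerce").astype("Int64")

    if (out["onset"] < 0).any():
        raise ValueError("onsets must be nonnegative")
    for run, grp in out.groupby("run"):
        if np.any(np.diff(grp["onset"].to_numpy()) < 0):
            raise ValueError(f"onsets must be nondecreasing within run {run}")
    rated = out["rating"].dropna()
    if len(rated) and ((rated < 1) | (rated > 5)).any():
        raise ValueError("ratings must be in 1..5 (or missing)")
    if conditions is not None:
        unknown = set(out["condition"]) - set(conditions)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
    return out
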