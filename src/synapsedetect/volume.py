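"""Volumes, sparse labels and ball annotations, with file I/O.

All 3D data in this package uses a fixed ``(z, y, x)`` axis order with
0-based integer voxel coordinates.  ``z`` is the slice (milling) axis of a
serial-section acquisition, so slice-major storage maps directly onto a
multipage TIFF stack or an HDF5 dataset.

Physical voxel size is carried as ``spacing_nm = (z, y, x)`` in nanometres.
The default of (9, 5, 5) nm corresponds to FIB/SEM acquisition with 5 nm
in-plane pixels and a 9 nm milling depth, which is nearly isotropic and
allows the stack to be treated as one 3D volume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

DEFAULT_SPACING_NM = (9.0, 5.0, 5.0)
DEFAULT_CLASS_NAMES = ("synapse", "membrane", "rest")
DEFAULT_H5_DATASET = "data"


class FormatError(ValueError):
    """Raised when an input file is structurally invalid."""


@dataclass
class Volume3D:
    """A scalar 3D image with voxel-spacing metadata.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.  Integer dtypes are preserved on
        I/O; floats pass through unchanged.
    spacing_nm
        Physical voxel size per axis ``(z, y, x)`` in nanometres.
    """

    data: np.ndarray
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM

    axis_order = ("z", "y", "x")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise FormatError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError(f"spacing_nm must be 3 positive values, got {self.spacing_nm}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise FormatError("volume intensities must be finite (found NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype(self, dtype) -> "Volume3D":
        return Volume3D(self.data.astype(dtype), self.spacing_nm)


def check_coords_in_bounds(coords: np.ndarray, shape: Sequence[int]) -> None:
    """Validate an ``(n, 3)`` array of (z, y, x) coordinates against ``shape``.

    The single shared bounds check used by labels, balls and candidates.
    """
    coords = np.atleast_2d(np.asarray(coords))
    if coords.size == 0:
        return
    if coords.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {coords.shape}")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    if (lo < 0).any() or (hi >= np.asarray(shape)).any():
        bad = coords[((coords < 0) | (coords >= np.asarray(shape))).any(axis=1)][0]
        raise ValueError(f"coordinate {tuple(int(c) for c in bad)} outside volume of shape {tuple(shape)}")


@dataclass
class SparseLabels:
    """Sparse voxel -> class-id assignments for classifier training.

    ``coords`` is an ``(n, 3)`` integer array of (z, y, x); ``class_ids``
    the aligned vector of 1-based class ids.  Class 0 is reserved for
    "unlabeled" in dense label volumes.
    """

    coords: np.ndarray
    class_ids: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64).reshape(-1)
        if len(self.coords) != len(self.class_ids):
            raise ValueError("coords and class_ids must have equal length")
        if len(self.class_ids) and self.class_ids.min() < 1:
            raise FormatError(f"class ids must be >= 1, got {self.class_ids.min()}")
        self.class_names = tuple(self.class_names)
        if len(self.class_names) < 2:
            raise ValueError("at least 2 classes required")

    def __len__(self) -> int:
        return len(self.class_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def classes_present(self) -> np.ndarray:
        return np.unique(self.class_ids)

    def validate_against(self, shape: Sequence[int]) -> None:
        check_coords_in_bounds(self.coords, shape)
        if len(self.class_ids) and self.class_ids.max() > self.n_classes:
            raise ValueError(
                f"class id {self.class_ids.max()} exceeds number of classes {self.n_classes}"
            )

    def counts_per_class(self) -> dict[str, int]:
        out = {}
        for i, name in enumerate(self.class_names, start=1):
            out[name] = int((self.class_ids == i).sum())
        return out


@dataclass
class BallAnnotation:
    """Gold-standard synapse marker: a sphere in voxel space.

    ``center`` is (z, y, x) in voxel coordinates; ``radius_vox`` is
    isotropic in voxel units (placed in pixel space by the annotator).
    """

    center: tuple[float, float, float]
    radius_vox: float

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        if len(self.center) != 3:
            raise ValueError("center must be (z, y, x)")
        self.radius_vox = float(self.radius_vox)
        if not self.radius_vox > 0:
            raise FormatError(f"radius_vox must be > 0, got {self.radius_vox}")

    def validate_against(self, shape: Sequence[int]) -> None:
        c = np.floor(np.asarray(self.center))
        check_coords_in_bounds(c[None, :], shape)


# ---------------------------------------------------------------------------
# volume I/O


def _read_tiff_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in (".tif", ".tiff") and p.is_file()
    )
    if not files:
        raise FormatError(f"no TIFF slices found in directory {path}")
    slices = [tifffile.imread(f) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"ragged slice shapes in {path}: {sorted(shapes)}")
    if slices[0].ndim != 2:
        raise FormatError("directory slices must be 2D images")
    return np.stack(slices, axis=0)


def read_volume(
    path: str | os.PathLike,
    dataset_name: str | None = None,
    spacing_nm: tuple[float, float, float] | None = None,
) -> Volume3D:
    """Read a volume from a multipage TIFF, a directory of 2D TIFFs
    (lexicographic slice order), or an HDF5 file.

    For HDF5, spacing is taken from the dataset's ``spacing_nm`` attribute
    when present; otherwise (and for TIFF) the default (9, 5, 5) nm is used
    unless ``spacing_nm`` is given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")

    read_spacing = None
    if path.is_dir():
        data = _read_tiff_dir(path)
    elif h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if dataset_name is None:
                dsets = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
                if len(dsets) == 1:
                    dataset_name = dsets[0]
                elif DEFAULT_H5_DATASET in f:
                    dataset_name = DEFAULT_H5_DATASET
                else:
                    raise FormatError(
                        f"HDF5 file {path} has {len(dsets)} datasets; pass dataset_name"
                    )
            if dataset_name not in f:
                raise FormatError(f"dataset {dataset_name!r} not in {path}")
            ds = f[dataset_name]
            data = ds[()]
            if "spacing_nm" in ds.attrs:
                read_spacing = tuple(float(s) for s in ds.attrs["spacing_nm"])
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None, ...]

    if data.ndim > 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume in {path}, got ndim={data.ndim}")

    spacing = spacing_nm or read_spacing or DEFAULT_SPACING_NM
    return Volume3D(data, spacing)


def write_volume(vol: Volume3D, path: str | os.PathLike, dataset_name: str = DEFAULT_H5_DATASET) -> None:
    """Write a volume to HDF5 (data + spacing attribute), a multipage TIFF,
    or a directory of per-slice TIFFs (when ``path`` is an existing directory
    or has no recognised suffix and ends with a path separator).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset_name, data=vol.data, compression=None)
            ds.attrs["spacing_nm"] = np.asarray(vol.spacing_nm, dtype=np.float64)
            ds.attrs["axis_order"] = "zyx"
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.data)
    else:
        # directory of slices, one file per z-plane
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(vol.shape[0] - 1)))
        for z in range(vol.shape[0]):
            tifffile.imwrite(path / f"slice_{z:0{width}d}.tif", vol.data[z])


# ---------------------------------------------------------------------------
# labels and balls


def read_labels(path: str | os.PathLike, class_names: Iterable[str] | None = None) -> SparseLabels:
    """Read sparse labels from a CSV (header ``z,y,x,class_id``) or an HDF5
    label volume in which 0 means unlabeled."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    names = tuple(class_names) if class_names is not None else DEFAULT_CLASS_NAMES
    if h5py.is_hdf5(path):
        lab = read_volume(path).data
        if not np.issubdtype(lab.dtype, np.integer):
            raise FormatError("HDF5 label volume must have an integer dtype")
        if lab.min() < 0:
            raise FormatError("label volume must be non-negative (0 = unlabeled)")
        coords = np.argwhere(lab > 0)
        ids = lab[lab > 0]
        return SparseLabels(coords, ids, names)
    df = pd.read_csv(path)
    required = ["z", "y", "x", "class_id"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"label CSV must have header {required}, got {list(df.columns)}")
    if len(df) == 0:
        return SparseLabels(np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=np.int64), names)
    if (df["class_id"] <= 0).any():
        raise FormatError("class_id must be >= 1")
    return SparseLabels(df[["z", "y", "x"]].to_numpy(), df["class_id"].to_numpy(), names)


def write_labels(labels: SparseLabels, path: str | os.PathLike) -> None:
    df = pd.DataFrame(labels.coords, columns=["z", "y", "x"])
    df["class_id"] = labels.class_ids
    df.to_csv(path, index=False)


def read_balls(path: str | os.PathLike) -> list[BallAnnotation]:
    """Read ball annotations from a CSV with header ``z,y,x,radius_vox``."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = ["z", "y", "x", "radius_vox"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"ball CSV must have header {required}, got {list(df.columns)}")
    for col in required:
        if len(df) and not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"column {col!r} must be numeric")
    balls = []
    for row in df.itertuples(index=False):
        balls.append(BallAnnotation((row.z, row.y, row.x), row.radius_vox))
    return balls


def write_balls(balls: Sequence[BallAnnotation], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(b.center[0], b.center[1], b.center[2], b.radius_vox) for b in balls],
        columns=["z", "y", "x", "radius_vox"],
    )
    df.to_csv(path, index=False)
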