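"""Calibration, label-map data model, file I/O and sampling utilities.

Conventions used throughout the package:

* 3D arrays are ordered ``(z, y, x)``; 2D arrays ``(y, x)``.
* All coordinates are 0-based.
* A :class:`Calibration` is mandatory — there is no implicit 1 px = 1 nm.
* Label 0 is background; positive integers are object ids.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import tifffile

ORGANELLE_CLASSES = ("mitochondrion", "er", "crista", "lysosome", "other")

NM_PER_UM = 1000.0


class LabelMapError(ValueError):
    """Raised for malformed label maps or unreadable label files."""


@dataclass(frozen=True)
class Calibration:
    """Physical scale of an image or stack, in nanometres.

    Parameters
    ----------
    px_x_nm, px_y_nm : float
        Pixel pitch along x and y.
    px_z_nm : float, optional
        Slice pitch along z; ``None`` for 2D data.
    """

    px_x_nm: float
    px_y_nm: float
    px_z_nm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("px_x_nm", "px_y_nm"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.px_z_nm is not None and not (self.px_z_nm > 0):
            raise ValueError(f"px_z_nm must be strictly positive, got {self.px_z_nm!r}")

    @property
    def is_3d(self) -> bool:
        return self.px_z_nm is not None

    @property
    def anisotropy_ratio(self) -> Optional[float]:
        """z pitch over x pitch; ``None`` for 2D calibrations."""
        if self.px_z_nm is None:
            return None
        return self.px_z_nm / self.px_x_nm

    @property
    def pixel_area_nm2(self) -> float:
        return self.px_x_nm * self.px_y_nm

    @property
    def voxel_volume_nm3(self) -> float:
        if self.px_z_nm is None:
            raise ValueError("voxel volume requires a 3D calibration")
        return self.px_x_nm * self.px_y_nm * self.px_z_nm

    def spacing(self, ndim: int) -> tuple[float, ...]:
        """Physical sampling per axis in array order (z, y, x) or (y, x)."""
        if ndim == 2:
            return (self.px_y_nm, self.px_x_nm)
        if ndim == 3:
            if self.px_z_nm is None:
                raise ValueError("3D spacing requested from a 2D calibration")
            return (self.px_z_nm, self.px_y_nm, self.px_x_nm)
        raise ValueError(f"unsupported ndim {ndim}")


@dataclass
class LabelMap:
    """Integer-labelled 2D image or 3D volume for one organelle class."""

    labels: np.ndarray
    organelle_class: str
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.organelle_class not in ORGANELLE_CLASSES:
            raise LabelMapError(
                f"unknown organelle class {self.organelle_class!r}; "
                f"expected one of {ORGANELLE_CLASSES}"
            )
        arr = np.asarray(self.labels)
        if arr.ndim not in (2, 3):
            raise LabelMapError(f"label array must be 2D or 3D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.bool_):
                arr = arr.astype(np.uint8)
            else:
                raise LabelMapError(f"labels must be integers, got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise LabelMapError("labels must be non-negative")
        if arr.ndim == 3 and self.calibration.px_z_nm is None:
            raise LabelMapError("3D label map requires a calibration with px_z_nm")
        if arr.ndim == 2 and self.calibration.px_z_nm is not None:
            raise LabelMapError("2D label map given a 3D calibration (px_z_nm set)")
        self.labels = arr

    @property
    def dims(self) -> int:
        return self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def object_ids(self) -> np.ndarray:
        """Sorted positive label values present in the map."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids().size)

    def mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class RoiSample:
    """A reproducible random selection of object ids for measurement."""

    selected_ids: list[int]
    seed: int
    min_n: int = 10
    insufficient: bool = False
    quadrant_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("selected ids must be distinct")
        if len(self.selected_ids) < self.min_n and not self.insufficient:
            raise ValueError(
                "fewer than min_n objects selected but insufficiency flag not set"
            )


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangular region [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def area_px(self) -> int:
        return self.height * self.width


# ---------------------------------------------------------------------------
# I/O


def _read_hdf5(path: str, dataset: Optional[str]) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if dataset is not None:
            if dataset not in f:
                raise LabelMapError(f"dataset {dataset!r} not found in {path}")
            return np.asarray(f[dataset])
        # first dataset found at the root, in insertion order
        for key in f.keys():
            obj = f[key]
            if isinstance(obj, h5py.Dataset):
                return np.asarray(obj)
        raise LabelMapError(f"no dataset at the root of HDF5 file {path}")


def _read_png(path: str) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse redundant colour channels of a greyscale export
        if arr.shape[-1] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]):
            arr = arr[..., 0]
        else:
            raise LabelMapError(f"PNG at {path} is not a single-channel label image")
    return arr


def load_label_map(
    path: str,
    organelle_class: str,
    calibration: Calibration,
    hdf5_dataset: Optional[str] = None,
) -> LabelMap:
    """Load a label map from TIFF/OME-TIFF, PNG (2D) or HDF5.

    Values are preserved bit-exactly and coerced to an integer dtype;
    non-integral floating data is rejected. Multi-page TIFF stacks are
    returned as (z, y, x).
    """
    if not os.path.exists(path):
        raise LabelMapError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path))
    elif ext == ".png":
        arr = _read_png(path)
    elif ext in (".h5", ".hdf5", ".he5"):
        arr = _read_hdf5(path, hdf5_dataset)
    else:
        raise LabelMapError(f"unsupported label file extension {ext!r}")

    arr = np.squeeze(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.bool_):
            arr = arr.astype(np.uint8)
        elif np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise LabelMapError(f"label data in {path} is not integer-valued")
    if ext == ".png" and arr.ndim != 2:
        raise LabelMapError("PNG label maps must be 2D")
    return LabelMap(labels=arr, organelle_class=organelle_class, calibration=calibration)


def save_label_map(map_: LabelMap, path: str, hdf5_dataset: str = "labels") -> None:
    """Write a label map to TIFF, PNG (2D, values < 256) or HDF5."""
    ext = os.path.splitext(path)[1].lower()
    arr = map_.labels
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    elif ext == ".png":
        import imageio.v3 as iio

        if map_.dims != 2:
            raise LabelMapError("PNG output supports 2D label maps only")
        if arr.max(initial=0) > 65535:
            raise LabelMapError("PNG output supports label values up to 65535")
        dtype = np.uint8 if arr.max(initial=0) < 256 else np.uint16
        iio.imwrite(path, arr.astype(dtype))
    elif ext in (".h5", ".hdf5", ".he5"):
        with h5py.File(path, "w") as f:
            f.create_dataset(hdf5_dataset, data=arr)
    else:
        raise LabelMapError(f"unsupported output extension {ext!r}")


# ---------------------------------------------------------------------------
# Sampling


def quadrant_partition(map_: LabelMap, n_rows: int = 2, n_cols: int = 2) -> list[Roi]:
    """Tile a 2D map into an exact n_rows x n_cols rectangular partition.

    When a dimension is not evenly divisible the remainder pixels are
    assigned to the last row/column.
    """
    if map_.dims != 2:
        raise LabelMapError("quadrant_partition requires a 2D label map")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    h, w = map_.shape
    rh, cw = h // n_rows, w // n_cols
    if rh == 0 or cw == 0:
        raise ValueError("more quadrants than pixels along an axis")
    rois = []
    for i in range(n_rows):
        r0 = i * rh
        r1 = (i + 1) * rh if i < n_rows - 1 else h
        for j in range(n_cols):
            c0 = j * cw
            c1 = (j + 1) * cw if j < n_cols - 1 else w
            rois.append(Roi(r0, r1, c0, c1))
    return rois


def assign_objects_to_quadrants(map_: LabelMap, rois: Sequence[Roi]) -> dict[int, int]:
    """Map object id -> quadrant index, assigning by object centroid.

    Objects straddling a border belong to the quadrant containing their
    centroid (rounded down).
    """
    from scipy import ndimage

    ids = map_.object_ids()
    out: dict[int, int] = {}
    if ids.size == 0:
        return out
    centroids = ndimage.center_of_mass(
        np.ones_like(map_.labels, dtype=np.uint8), map_.labels, ids
    )
    for oid, (cy, cx) in zip(ids, centroids):
        for qi, roi in enumerate(rois):
            if roi.row0 <= cy < roi.row1 and roi.col0 <= cx < roi.col1:
                out[int(oid)] = qi
                break
    return out


def sample_objects(map_: LabelMap, min_n: int = 10, seed: int = 0) -> RoiSample:
    """Uniformly sample ``min_n`` object ids without replacement.

    Deterministic for a fixed seed.  If the map holds fewer than ``min_n``
    objects, all are returned and the insufficiency flag is set.
    """
    ids = map_.object_ids()
    if ids.size == 0:
        raise LabelMapError("cannot sample from an empty label map")
    rng = np.random.default_rng(seed)
    if ids.size < min_n:
        return RoiSample(
            selected_ids=[int(i) for i in ids],
            seed=seed,
            min_n=min_n,
            insufficient=True,
        )
    chosen = rng.choice(ids, size=min_n, replace=False)
    return RoiSample(
        selected_ids=sorted(int(i) for i in chosen), seed=seed, min_n=min_n
    )
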