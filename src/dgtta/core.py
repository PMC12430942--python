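"""Canonical volume/label data model, NIfTI I/O, and grid resampling.

All per-voxel fields are channel-major (class channel first) and voxel
indexing is 0-based throughout the package.  Orientation is taken as stored
in the NIfTI header; no RAS canonicalization is performed.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with voxel spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (D, H, W)
        Scalar field over voxel space; stored as floating point.
    spacing : tuple of float
        Physical voxel size in mm per axis, strictly positive.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world matrix.  Defaults to a diagonal matrix built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.affine.copy())


@dataclasses.dataclass
class LabelMap:
    """A hard integer segmentation aligned with a :class:`Volume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    background_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = rounded.astype(np.int32)
        self.data = self.data.astype(np.int32)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def class_ids(self) -> list[int]:
        """Foreground class ids present in the map (background excluded)."""
        ids = np.unique(self.data)
        return [int(i) for i in ids if i != self.background_id]

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.spacing, self.affine.copy(),
                        self.background_id)


@dataclasses.dataclass
class ProbabilityMap:
    """Soft per-class probabilities, channel-major, shape (C, D, H, W)."""

    data: np.ndarray
    class_ids: list[int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("ProbabilityMap data must be (C, D, H, W)")
        if len(self.class_ids) != self.data.shape[0]:
            raise ValueError("class_ids length must match channel count")
        if self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def argmax_labels(self) -> LabelMap:
        idx = np.argmax(self.data, axis=0)
        lut = np.asarray(self.class_ids, dtype=np.int32)
        return LabelMap(lut[idx], self.spacing, self.affine.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_volume(path) -> Volume:
    """Read a 3D NIfTI file as a :class:`Volume` (values cast to float)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D with shape {data.shape}")
    affine = np.asarray(img.affine, dtype=np.float64)
    return Volume(data.astype(np.float64), _spacing_from_affine(affine), affine)


def read_label_map(path) -> LabelMap:
    """Read a 3D NIfTI file as an integer :class:`LabelMap`."""
    v = read_volume(path)
    return LabelMap(np.rint(v.data).astype(np.int32), v.spacing, v.affine)


def read_probability_map(path, class_ids) -> ProbabilityMap:
    """Read a channel-major 4D NIfTI as a :class:`ProbabilityMap`.

    On disk channels are stored on the last NIfTI axis; they are moved back
    to the leading axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=np.float64)
    return ProbabilityMap(np.moveaxis(data, -1, 0).astype(np.float64),
                          list(class_ids), _spacing_from_affine(affine), affine)


def write_volume(obj, path) -> None:
    """Write a Volume / LabelMap / ProbabilityMap to a NIfTI file.

    Label maps keep integer dtype; probability maps are stored as 4D with
    channels on the last axis (channel-major in memory).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, LabelMap):
        data, dtype = obj.data, np.int16 if obj.data.max() < 2**15 else np.int32
    elif isinstance(obj, ProbabilityMap):
        data, dtype = np.moveaxis(obj.data, 0, -1), np.float32
    elif isinstance(obj, Volume):
        data, dtype = obj.data, np.float32
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), obj.affine)
    img.header.set_zooms(obj.spacing if data.ndim == 3 else (*obj.spacing, 1.0))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling

def resample_to_spacing(obj, target_spacing, interpolation: str | None = None):
    """Resample a field to a uniform target voxel size.

    The output grid size is ``round(size * spacing / target)`` per axis.
    Volumes default to linear interpolation, label maps require nearest.
    Probability maps are interpolated linearly per channel and renormalized
    per voxel so the simplex invariant is preserved.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be 3 positive values, got {target_spacing}")

    is_label = isinstance(obj, LabelMap)
    is_prob = isinstance(obj, ProbabilityMap)
    if interpolation is None:
        interpolation = "nearest" if is_label else "linear"
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if is_label and interpolation != "nearest":
        raise ValueError("label maps must be resampled with nearest interpolation")

    src_spacing = np.asarray(obj.spacing)
    tgt = np.asarray(target_spacing)
    shape = np.asarray(obj.shape)
    new_shape = np.maximum(1, np.rint(shape * src_spacing / tgt).astype(int))

    if tuple(new_shape) == tuple(shape) and np.allclose(src_spacing, tgt):
        out = obj.copy() if not is_prob else ProbabilityMap(
            obj.data.copy(), list(obj.class_ids), obj.spacing, obj.affine.copy())
        return out

    zoom = new_shape / shape
    order = 0 if interpolation == "nearest" else 1

    new_affine = obj.affine.copy()
    # keep world direction, rescale voxel size along each axis
    for i in range(3):
        col = obj.affine[:3, i]
        n = np.linalg.norm(col)
        if n > 0:
            new_affine[:3, i] = col / n * tgt[i]

    def _zoom(arr, order):
        return ndimage.zoom(arr, zoom, order=order, mode="nearest",
                            grid_mode=True, prefilter=False,
                            output=np.float64 if order else arr.dtype)

    if is_prob:
        chans = np.stack([_zoom(c, 1) for c in obj.data])
        chans = np.clip(chans, 0.0, None)
        total = chans.sum(axis=0, keepdims=True)
        chans = np.where(total > 1e-12, chans / np.maximum(total, 1e-12), 1.0 / len(chans))
        return ProbabilityMap(chans, list(obj.class_ids), target_spacing, new_affine)
    if is_label:
        return LabelMap(_zoom(obj.data, 0), target_spacing, new_affine, obj.background_id)
    return Volume(_zoom(obj.data, 1), target_spacing, new_affine)
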