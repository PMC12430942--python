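"""Invertible affine spatial augmentation, inverse warping, consistency masks.

The two adaptation branches see the same image region through two random
affine distortions.  After the network has predicted on each distorted
view, the predictions are warped back with the exact inverse transform;
voxels whose pull-back coordinate falls outside the original grid carry no
real image content and are excluded from the consistency loss.  That
out-of-field marker is realized as a boolean validity mask carried with
every warp (a numeric sentinel could collide with real probabilities).

Warping is realized as multiplication by a sparse interpolation matrix, so
it is exactly linear and the gradient of a warped prediction is the
transposed matrix applied to the incoming gradient.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse

from .core import LabelMap, ProbabilityMap, Volume


@dataclasses.dataclass
class AffineRanges:
    """Magnitude ranges of the random affine draws (mild by default)."""

    rotation_deg: float = 10.0
    scale: tuple[float, float] = (0.9, 1.1)
    shear: float = 0.05
    translation_frac: float = 0.05

    def validate(self):
        if self.rotation_deg < 0 or self.shear < 0 or self.translation_frac < 0:
            raise ValueError("ranges must be non-negative")
        if not (0 < self.scale[0] <= self.scale[1]):
            raise ValueError("scale range must be positive and ordered")


@dataclasses.dataclass
class AffineAugmentation:
    """An invertible voxel-coordinate transform with its exact inverse.

    ``matrix`` maps output voxel coordinates to input sampling coordinates
    for the forward warp; the inverse warp samples through
    ``inverse_matrix``.  Both are 4x4 homogeneous matrices composed about
    the volume center.
    """

    matrix: np.ndarray
    inverse_matrix: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is not invertible")
        if self.inverse_matrix is None:
            self.inverse_matrix = np.linalg.inv(self.matrix)
        self.inverse_matrix = np.asarray(self.inverse_matrix, dtype=np.float64)

    @classmethod
    def identity(cls) -> "AffineAugmentation":
        return cls(np.eye(4))

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(),
                "inverse_matrix": self.inverse_matrix.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineAugmentation":
        return cls(np.asarray(d["matrix"]), np.asarray(d["inverse_matrix"]))


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def sample_affine(ranges: AffineRanges, rng: np.random.Generator,
                  shape=None) -> AffineAugmentation:
    """Draw a random rotation/scale/shear/translation about the grid center.

    ``shape`` scales the translation range (fraction of extent); when
    omitted, translation is in absolute voxels of a unit extent.
    """
    ranges.validate()
    ang = np.deg2rad(rng.uniform(-ranges.rotation_deg, ranges.rotation_deg, 3))
    rot = _rotation_matrix(ang)
    sc = rng.uniform(ranges.scale[0], ranges.scale[1])
    shear = np.eye(3)
    for i in range(3):
        for j in range(3):
            if i != j:
                shear[i, j] = rng.uniform(-ranges.shear, ranges.shear)
    lin = rot @ (sc * np.eye(3)) @ shear
    if abs(np.linalg.det(lin)) < 1e-12:
        raise ValueError("degenerate ranges produced a non-invertible matrix")
    extent = np.asarray(shape, dtype=float) if shape is not None else np.ones(3)
    trans = rng.uniform(-ranges.translation_frac, ranges.translation_frac, 3) * extent
    m = np.eye(4)
    m[:3, :3] = lin
    m[:3, 3] = trans
    if shape is not None:
        center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        tc, tci = np.eye(4), np.eye(4)
        tc[:3, 3] = center
        tci[:3, 3] = -center
        m = tc @ m @ tci
    return AffineAugmentation(m)


# ---------------------------------------------------------------------------
# Sampling matrices


def _grid_coords(shape) -> np.ndarray:
    """Homogeneous coordinates (4, N) of every voxel of a grid."""
    d, h, w = shape
    ii, jj, kk = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    return np.stack([ii.ravel(), jj.ravel(), kk.ravel(),
                     np.ones(d * h * w)]).astype(np.float64)


def sampling_matrix(t: AffineAugmentation, shape, direction: str = "forward",
                    method: str = "linear"):
    """Build the sparse interpolation matrix and validity mask for a warp.

    Returns ``(S, valid)`` where ``S`` is (N, N) CSR such that
    ``out.ravel() = S @ in.ravel()`` and ``valid`` is the boolean set of
    output voxels whose pull-back coordinate lies inside the input grid
    (coordinates in [0, n-1] per axis).  Rows of invalid voxels are zero.
    """
    if direction == "forward":
        m = t.matrix
    elif direction == "inverse":
        m = t.inverse_matrix
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n_vox = int(np.prod(shape))
    coords = (m @ _grid_coords(shape))[:3]  # (3, N)
    dims = np.asarray(shape, dtype=np.float64)
    valid = np.all((coords >= 0.0) & (coords <= (dims - 1.0)[:, None]), axis=0)

    cc = np.clip(coords, 0.0, (dims - 1.0)[:, None])
    rows_base = np.arange(n_vox)

    if method == "nearest":
        idx = np.rint(cc).astype(np.int64)
        flat = np.ravel_multi_index(idx, shape)
        data = valid.astype(np.float64)
        S = sparse.csr_matrix((data, (rows_base, flat)), shape=(n_vox, n_vox))
        return S, valid.reshape(shape)
    if method != "linear":
        raise ValueError(f"unknown interpolation {method!r}")

    i0 = np.floor(cc).astype(np.int64)
    i0 = np.minimum(i0, (dims - 1.0).astype(np.int64)[:, None])
    frac = cc - i0
    i1 = np.minimum(i0 + 1, (dims.astype(np.int64) - 1)[:, None])
    rows, cols, vals = [], [], []
    for bz in (0, 1):
        wz = (1 - frac[0]) if bz == 0 else frac[0]
        iz = i0[0] if bz == 0 else i1[0]
        for by in (0, 1):
            wy = (1 - frac[1]) if by == 0 else frac[1]
            iy = i0[1] if by == 0 else i1[1]
            for bx in (0, 1):
                wx = (1 - frac[2]) if bx == 0 else frac[2]
                ix = i0[2] if bx == 0 else i1[2]
                wgt = wz * wy * wx * valid
                nz = wgt > 0
                if not np.any(nz):
                    continue
                rows.append(rows_base[nz])
                cols.append(np.ravel_multi_index((iz[nz], iy[nz], ix[nz]), shape))
                vals.append(wgt[nz])
    S = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_vox, n_vox))
    S.sum_duplicates()
    return S, valid.reshape(shape)


def _compose_valid(S, valid, valid_in):
    """Restrict an output validity mask by the validity of the input field.

    A warped voxel is only trustworthy if every input voxel it interpolates
    from was itself valid; warping the indicator of the input validity and
    thresholding at (almost) one gives exactly that set.
    """
    if valid_in is None:
        return valid
    shape = valid.shape
    covered = (S @ np.asarray(valid_in, dtype=np.float64).ravel()).reshape(shape)
    return valid & (covered >= 1.0 - 1e-9)


def warp(field, t: AffineAugmentation, direction: str = "forward",
         valid_in: np.ndarray | None = None):
    """Warp a Volume / LabelMap / ProbabilityMap through an affine transform.

    Returns ``(warped, valid)``.  Probability fields are warped channel-wise
    with linear interpolation and renormalized on valid voxels; label maps
    use nearest-neighbor.  Invalid voxels are zero-filled and flagged false.
    ``valid_in`` carries the validity of the input field through chained
    warps: output voxels that interpolate from invalid input voxels are
    flagged false as well.
    """
    if isinstance(field, LabelMap):
        S, valid = sampling_matrix(t, field.shape, direction, "nearest")
        valid = _compose_valid(S, valid, valid_in)
        out = (S @ field.data.astype(np.float64).ravel()).reshape(field.shape)
        warped = LabelMap(np.rint(out).astype(np.int32), field.spacing,
                          field.affine.copy(), field.background_id)
        return warped, valid
    if isinstance(field, ProbabilityMap):
        S, valid = sampling_matrix(t, field.shape, direction, "linear")
        valid = _compose_valid(S, valid, valid_in)
        chans = np.stack([(S @ c.ravel()).reshape(field.shape) for c in field.data])
        total = chans.sum(axis=0)
        safe = np.maximum(total, 1e-12)
        chans = np.where(valid & (total > 1e-12), chans / safe, chans)
        chans[:, ~valid] = 0.0
        warped = ProbabilityMap(np.clip(chans, 0.0, 1.0), list(field.class_ids),
                                field.spacing, field.affine.copy())
        return warped, valid
    if isinstance(field, Volume):
        S, valid = sampling_matrix(t, field.shape, direction, "linear")
        valid = _compose_valid(S, valid, valid_in)
        out = (S @ field.data.ravel()).reshape(field.shape)
        return Volume(out, field.spacing, field.affine.copy()), valid
    data = np.asarray(field, dtype=np.float64)
    S, valid = sampling_matrix(t, data.shape, direction, "linear")
    valid = _compose_valid(S, valid, valid_in)
    return (S @ data.ravel()).reshape(data.shape), valid


@dataclasses.dataclass
class ConsistencyMask:
    """Boolean field: true where both inverse-warped branches carry content."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)


def consistency_mask(valid_a: np.ndarray, valid_b: np.ndarray) -> ConsistencyMask:
    """Logical AND of the two branch validity masks."""
    valid_a = np.asarray(valid_a, dtype=bool)
    valid_b = np.asarray(valid_b, dtype=bool)
    if valid_a.shape != valid_b.shape:
        raise ValueError(f"mask shapes differ: {valid_a.shape} vs {valid_b.shape}")
    return ConsistencyMask(valid_a & valid_b)
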