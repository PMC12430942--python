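"""Self-similarity context (SSC) descriptor.

Maps a 1-channel 3D volume to a 12-channel per-voxel descriptor field.
Around every voxel, the six axis neighbors at ``patch_distance`` form a
neighborhood; the descriptor aggregates patch distances between every pair
of *diagonally adjacent* neighbors (the 12 unordered non-opposite pairs),
deliberately ignoring the center patch itself.  Each channel is

    exp(-SSD(pair) / sigma^2)

where SSD is the sum of squared intensity differences between the two
patches and sigma^2 is a noise estimate: the mean of all 12 patch
distances (per voxel by default).  Because both SSD and sigma^2 scale with
the square of any affine intensity change a*x + b, the descriptor is
invariant to such changes — the property that makes it useful across
imaging modalities.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import ndimage

from .core import Volume

# The six axis-aligned unit offsets, in a fixed lexicographic order.
SIX_NEIGHBORHOOD = (
    (-1, 0, 0), (0, -1, 0), (0, 0, -1), (0, 0, 1), (0, 1, 0), (1, 0, 0),
)


def neighbor_pair_offsets(patch_distance: int = 1) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """The 12 unordered non-opposite pairs of 6-neighborhood offsets.

    Opposite pairs (e.g. -x/+x) are excluded: they straddle the center
    patch instead of diagonally connecting adjacent patches.  Enumeration
    order is fixed (lexicographic over the sorted offset list) so channel
    order is reproducible.
    """
    offs = [tuple(patch_distance * o for o in d) for d in SIX_NEIGHBORHOOD]
    pairs = []
    for a, b in itertools.combinations(offs, 2):
        if all(x == -y for x, y in zip(a, b)):
            continue  # opposite neighbors
        pairs.append((a, b))
    assert len(pairs) == 12
    return pairs


def descriptor_channel_count(neighborhood: str = "six") -> int:
    """Channel count of the descriptor for a given neighborhood pattern."""
    if neighborhood != "six":
        raise ValueError(f"unsupported neighborhood {neighborhood!r}")
    return 12


def _shift_replicate(x: np.ndarray, offset) -> np.ndarray:
    """``out[p] = x[p + offset]`` with edge replication at the boundary."""
    m = max(abs(int(o)) for o in offset)
    if m == 0:
        return x.copy()
    pad = np.pad(x, m, mode="edge")
    sl = tuple(slice(m + int(o), m + int(o) + n) for o, n in zip(offset, x.shape))
    return pad[sl]


def patch_ssd_field(x, offset_a, offset_b, patch_size: int = 1) -> np.ndarray:
    """Per-voxel sum of squared differences between two shifted patches.

    At each voxel p the patches of side ``patch_size`` centered at
    ``p + offset_a`` and ``p + offset_b`` are compared.  Realized as a box
    sum of the squared shifted-difference image, with edge replication.
    """
    data = x.data if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)
    offset_a = tuple(int(o) for o in offset_a)
    offset_b = tuple(int(o) for o in offset_b)
    if offset_a == offset_b:
        raise ValueError("offsets must differ (zero-distance pair is meaningless)")
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError("patch_size must be a positive odd integer")
    diff = _shift_replicate(data, offset_a) - _shift_replicate(data, offset_b)
    sq = diff * diff
    if patch_size == 1:
        return sq
    # box sum over the patch = uniform mean * patch volume
    return ndimage.uniform_filter(sq, size=patch_size, mode="nearest") * patch_size**3


def noise_estimate(ssd_fields, epsilon_rel: float = 1e-6,
                   mode: str = "voxel") -> np.ndarray:
    """Noise estimate sigma^2: the mean of all patch distances.

    mode='voxel' (default) averages the 12 SSD values per voxel;
    mode='global' uses one scalar, the mean over all voxels and pairs.
    The result is floored at ``max(epsilon_rel * global mean SSD, 1e-12)``
    so flat regions yield exp(0)=1 instead of 0/0.
    """
    fields = [np.asarray(f, dtype=np.float64) for f in ssd_fields]
    shape = fields[0].shape
    if any(f.shape != shape for f in fields):
        raise ValueError("SSD fields must share a common grid")
    stack = np.stack(fields)
    global_mean = float(stack.mean())
    floor = max(epsilon_rel * global_mean, 1e-12)
    if mode == "voxel":
        sigma2 = stack.mean(axis=0)
    elif mode == "global":
        sigma2 = np.full(shape, global_mean)
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")
    return np.maximum(sigma2, floor)


@dataclasses.dataclass
class SSCDescriptor:
    """12-channel descriptor field with the configuration that produced it."""

    data: np.ndarray  # (12, D, H, W)
    patch_size: int
    patch_distance: int
    pair_offsets: list

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def save(self, path, reference: Volume | None = None) -> None:
        """Export as a channel-last 4D NIfTI for inspection.

        ``reference`` supplies the affine/spacing; defaults to unit spacing.
        """
        import nibabel as nib
        affine = reference.affine if reference is not None else np.eye(4)
        img = nib.Nifti1Image(
            np.moveaxis(self.data, 0, -1).astype(np.float32), affine)
        nib.save(img, str(path))


def compute_ssc(x, patch_size: int = 1, patch_distance: int = 1,
                sigma_mode: str = "voxel") -> SSCDescriptor:
    """Compute the 12-channel self-similarity context descriptor of a volume.

    Parameters
    ----------
    x : Volume or ndarray
        Input volume, at least 3 voxels per axis.
    patch_size, patch_distance : int
        Patch side length and neighbor offset distance in voxels (default 1).
    sigma_mode : {'voxel', 'global'}
        Whether the noise estimate is per voxel or image-global.
    """
    data = x.data if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)
    if data.ndim != 3 or min(data.shape) < 3:
        raise ValueError(f"volume must be 3D with at least 3 voxels per axis, got {data.shape}")
    pairs = neighbor_pair_offsets(patch_distance)
    ssd = [patch_ssd_field(data, a, b, patch_size) for a, b in pairs]
    sigma2 = noise_estimate(ssd, mode=sigma_mode)
    chans = np.stack([np.exp(-f / sigma2) for f in ssd])
    return SSCDescriptor(chans, patch_size, patch_distance, pairs)
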