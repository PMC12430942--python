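"""Independent brute-force reference implementations used only by tests.

These are written against the mathematical definitions directly (explicit
per-voxel loops, all-pairs distances), deliberately sharing no code with
the package's vectorized implementations.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import cdist


def naive_ssc(x: np.ndarray, patch_size: int = 1, patch_distance: int = 1,
              sigma_mode: str = "voxel") -> np.ndarray:
    """Per-voxel triple-loop self-similarity context descriptor.

    Enumerates the six axis neighbors lexicographically, takes the 12
    unordered non-opposite pairs, computes patch SSDs with edge-clamped
    indexing, normalizes by the (per-voxel or global) mean SSD and
    exponentiates.
    """
    x = np.asarray(x, dtype=np.float64)
    shape = x.shape
    neighbors = sorted([(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
                        (0, 0, -1), (0, 0, 1)])
    neighbors = [tuple(patch_distance * o for o in d) for d in neighbors]
    pairs = [(a, b) for a, b in itertools.combinations(neighbors, 2)
             if not all(u == -v for u, v in zip(a, b))]
    assert len(pairs) == 12
    r = patch_size // 2
    patch_offsets = list(itertools.product(range(-r, r + 1), repeat=3))

    def val(p):
        idx = tuple(int(np.clip(c, 0, s - 1)) for c, s in zip(p, shape))
        return x[idx]

    ssd = np.zeros((12, *shape))
    for ci, (da, db) in enumerate(pairs):
        for p in itertools.product(*[range(s) for s in shape]):
            s = 0.0
            for o in patch_offsets:
                pa = tuple(p[i] + da[i] + o[i] for i in range(3))
                pb = tuple(p[i] + db[i] + o[i] for i in range(3))
                s += (val(pa) - val(pb)) ** 2
            ssd[ci][p] = s
    global_mean = ssd.mean()
    floor = max(1e-6 * global_mean, 1e-12)
    if sigma_mode == "voxel":
        sigma2 = np.maximum(ssd.mean(axis=0), floor)
    else:
        sigma2 = np.maximum(np.full(shape, global_mean), floor)
    return np.exp(-ssd / sigma2)


def naive_hd95(mask_p: np.ndarray, mask_g: np.ndarray, spacing) -> float | None:
    """All-pairs pooled symmetric 95th-percentile surface distance."""
    if not mask_p.any() or not mask_g.any():
        return None

    def surface(mask):
        pts = []
        for p in np.argwhere(mask):
            boundary = False
            for ax in range(3):
                for d in (-1, 1):
                    q = p.copy()
                    q[ax] += d
                    if np.any(q < 0) or np.any(q >= np.asarray(mask.shape)):
                        boundary = True
                    elif not mask[tuple(q)]:
                        boundary = True
            if boundary:
                pts.append(p)
        return np.asarray(pts, dtype=np.float64) * np.asarray(spacing)

    sp, sg = surface(mask_p), surface(mask_g)
    dmat = cdist(sp, sg)
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return float(np.percentile(pooled, 95))
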