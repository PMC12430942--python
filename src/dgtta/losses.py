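"""Consistency Dice loss and the assembled test-time objective.

The test-time loss compares the predictions of the two augmented branches
after both have been warped back to the common frame and masked to voxels
where both carry real content:

    L = 1 - (1/|B||C|) sum_{B,C} (2 * sum_w yA*yB + e) / (sum_w yA^d + yB^d + e)

With exponent d=2 the loss is exactly zero whenever the two predictions
agree (any probability field equals itself), so the optimum is genuine
consistency; with d=1 identical-but-soft predictions still incur loss,
which additionally pushes the network toward confident outputs.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .autodiff import Tensor
from .core import ProbabilityMap
from .spatial import AffineAugmentation, ConsistencyMask, consistency_mask, warp


@dataclasses.dataclass
class DiceLossConfig:
    """Configuration of the consistency Dice loss.

    ``class_subset`` lists the class ids to optimize; ``None`` means all
    foreground classes (the background channel is excluded by default).
    """

    exponent_d: int = 2
    epsilon_e: float = 1e-5
    class_subset: list[int] | None = None

    def __post_init__(self):
        if self.exponent_d not in (1, 2):
            raise ValueError("exponent_d must be 1 or 2")
        if self.epsilon_e <= 0:
            raise ValueError("epsilon_e must be positive")
        if self.class_subset is not None and len(self.class_subset) == 0:
            raise ValueError("class_subset must be non-empty")


def _select_channels(class_ids, cfg: DiceLossConfig, background_id: int = 0):
    if cfg.class_subset is None:
        chans = [i for i, c in enumerate(class_ids) if c != background_id]
    else:
        chans = [list(class_ids).index(c) for c in cfg.class_subset]
    if not chans:
        raise ValueError("no channels selected for the loss")
    return chans


def consistency_dice_t(ya: Tensor, yb: Tensor, mask_flat: np.ndarray,
                       cfg: DiceLossConfig, channels) -> Tensor:
    """Differentiable consistency Dice on flattened (C, N) tensors.

    ``mask_flat`` is a boolean (N,) array; sums run over masked voxels only.
    Returns a scalar Tensor; an empty mask yields a constant zero.
    """
    if not np.any(mask_flat):
        warnings.warn("empty consistency mask: no voxels to compare, loss is 0")
        return Tensor(np.zeros((), dtype=ya.data.dtype))
    m = mask_flat.astype(ya.data.dtype)
    d, e = cfg.exponent_d, cfg.epsilon_e
    total = None
    for c in channels:
        ac = _row(ya, c) * m
        bc = _row(yb, c) * m
        inter = (ac * bc).sum()
        denom = (ac ** d).sum() + (bc ** d).sum()
        dice = (2.0 * inter + e) / (denom + e)
        total = dice if total is None else total + dice
    return 1.0 - total * (1.0 / len(channels))


def _row(t: Tensor, c: int) -> Tensor:
    """Select one channel row of a (C, N) tensor."""
    def bw(g, a=t, c=c):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[c] = g
            a._accum(full)
    return Tensor._make(t.data[c], (t,), bw)


def consistency_dice(y_a, y_b, mask=None, cfg: DiceLossConfig | None = None) -> float:
    """Consistency Dice loss between two probability fields (returns float).

    ``y_a``/``y_b`` are :class:`ProbabilityMap` or channel-major ndarrays;
    ``mask`` is a :class:`ConsistencyMask`, boolean array, or ``None`` (all
    voxels).
    """
    cfg = cfg or DiceLossConfig()
    da, ids_a = _as_channels(y_a)
    db, ids_b = _as_channels(y_b)
    if da.shape != db.shape:
        raise ValueError(f"shape mismatch: {da.shape} vs {db.shape}")
    if mask is None:
        mflat = np.ones(da.shape[1:], dtype=bool).ravel()
    else:
        mdata = mask.data if isinstance(mask, ConsistencyMask) else np.asarray(mask, bool)
        if mdata.shape != da.shape[1:]:
            raise ValueError(f"mask shape {mdata.shape} does not match field {da.shape[1:]}")
        mflat = mdata.ravel()
    channels = _select_channels(ids_a, cfg)
    loss = consistency_dice_t(Tensor(da.reshape(da.shape[0], -1)),
                              Tensor(db.reshape(db.shape[0], -1)),
                              mflat, cfg, channels)
    return float(loss.data)


def _as_channels(y):
    if isinstance(y, ProbabilityMap):
        return y.data, list(y.class_ids)
    arr = np.asarray(y, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError("expected a channel-major (C, D, H, W) field")
    return arr, list(range(arr.shape[0]))


def tta_loss(model_out_a, model_out_b, inv_a: AffineAugmentation,
             inv_b: AffineAugmentation, cfg: DiceLossConfig | None = None) -> float:
    """Assembled test-time loss: inverse-warp both branches, mask, Dice.

    Takes the two branch predictions in their augmented frames together
    with the transforms that produced them; both are mapped back with the
    exact inverse, the consistency mask filters inversion artifacts, and
    the masked consistency Dice is returned.
    """
    cfg = cfg or DiceLossConfig()
    ya, valid_a = warp(model_out_a, inv_a, direction="inverse")
    yb, valid_b = warp(model_out_b, inv_b, direction="inverse")
    mc = consistency_mask(valid_a, valid_b)
    return consistency_dice(ya, yb, mc, cfg)
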