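"""Segmentation quality metrics and paired significance testing.

Per-class Dice overlap (reported in percent), the 95th percentile of the
symmetric surface distance set in millimetres (HD95), and the one-sided
Wilcoxon signed-rank test for paired score improvements.

HD95 here pools the directed distances of both surfaces (prediction to
ground truth and vice versa) into one set before taking the percentile;
percentile interpolation is linear between order statistics.  A class
absent from either side has no surface distance and is reported as
undefined (excluded from means, with the exclusion counted).
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import LabelMap


def dice_score(pred: LabelMap, gt: LabelMap, class_id: int) -> float:
    """Dice overlap of one class, in percent.

    100 when the class is absent from both maps (degenerate agreement),
    0 when it is absent from exactly one.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    p = pred.data == class_id
    g = gt.data == class_id
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 100.0
    return 100.0 * 2.0 * float(np.logical_and(p, g).sum()) / (np_ + ng)


def _surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of boundary voxels of a binary mask."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    surf = mask & ~eroded
    pts = np.argwhere(surf).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def hd95(pred: LabelMap, gt: LabelMap, class_id: int,
         spacing=None) -> float | None:
    """95th percentile of the pooled symmetric surface distances, in mm.

    Returns ``None`` when the class is absent from either map (mirrors a
    "--" table entry).
    """
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    spacing = spacing if spacing is not None else gt.spacing
    p = pred.data == class_id
    g = gt.data == class_id
    if not p.any() or not g.any():
        return None
    sp = _surface_points(p, spacing)
    sg = _surface_points(g, spacing)
    d_pg = cKDTree(sg).query(sp)[0]
    d_gp = cKDTree(sp).query(sg)[0]
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def wilcoxon_one_sided(scores_a, scores_b) -> float:
    """p-value of the one-sided signed-rank test for ``b > a``.

    Degenerate input (every pair tied) returns p = 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and equally long")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(b, a, alternative="greater").pvalue)


def significance_stars(p: float) -> str:
    """Star notation at the 0.05 / 0.01 / 0.001 levels."""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclasses.dataclass
class EvalResult:
    """Per-class and mean scores of one prediction/ground-truth set."""

    per_class_dice: dict
    per_class_hd95: dict
    mean_dice: float
    mean_hd95: float | None
    n_samples: int
    n_hd95_undefined: int


def evaluate_pairs(pairs, class_ids) -> EvalResult:
    """Evaluate a list of (prediction, ground truth) label-map pairs."""
    dice = {c: [] for c in class_ids}
    hd = {c: [] for c in class_ids}
    undefined = 0
    for pred, gt in pairs:
        for c in class_ids:
            dice[c].append(dice_score(pred, gt, c))
            h = hd95(pred, gt, c)
            if h is None:
                undefined += 1
            else:
                hd[c].append(h)
    per_dice = {c: float(np.mean(v)) for c, v in dice.items()}
    per_hd = {c: (float(np.mean(v)) if v else None) for c, v in hd.items()}
    hd_vals = [v for v in per_hd.values() if v is not None]
    return EvalResult(per_dice, per_hd, float(np.mean(list(per_dice.values()))),
                      float(np.mean(hd_vals)) if hd_vals else None,
                      len(list(pairs)), undefined)


def results_table(pairs, class_ids, sample_ids=None) -> pd.DataFrame:
    """Long-format per-sample, per-class score table (dice %, hd95 mm)."""
    rows = []
    pairs = list(pairs)
    sample_ids = sample_ids or [f"sample_{i:03d}" for i in range(len(pairs))]
    for sid, (pred, gt) in zip(sample_ids, pairs):
        for c in class_ids:
            rows.append({"sample": sid, "class": c,
                         "dice_pct": dice_score(pred, gt, c),
                         "hd95_mm": hd95(pred, gt, c)})
    return pd.DataFrame(rows)


def mean_foreground_dice(pred: LabelMap, gt: LabelMap) -> float:
    """Mean Dice in percent over the foreground classes of the ground truth."""
    classes = gt.class_ids
    if not classes:
        raise ValueError("ground truth has no foreground classes")
    return float(np.mean([dice_score(pred, gt, c) for c in classes]))
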