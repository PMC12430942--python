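"""Per-sample, source-free test-time adaptation.

Each optimization step draws random patches from the single target volume,
passes two differently spatially-augmented views of every patch through
the network, warps both predictions back with the exact inverse transform,
and minimizes the masked consistency Dice between them.  By default only
branch A carries gradients (branch B is a fixed target), intensity
augmentation is off, and both branches are spatially augmented — the
configuration found to trade off best between conventionally and
domain-generalized pre-trained models.  Gradients of all patches in a step
are accumulated into a single AdamW update, which counters overfitting to
the limited field of view of any individual patch.

The adaptation interface accepts only the pre-trained model and the one
target volume; it never touches training data (source-free by
construction), and adapted weights live on a copy, so the base model can
be reused sample after sample.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .core import ProbabilityMap, Volume
from .gin import GINConfig, gin_augment
from .losses import DiceLossConfig, _select_channels, consistency_dice_t
from .pretrain import SegmentationModel, normalize_volume, predict
from .spatial import AffineAugmentation, AffineRanges, sample_affine, sampling_matrix
from .ssc import compute_ssc


@dataclasses.dataclass
class TTAConfig:
    """Hyperparameters of the adaptation loop.

    Defaults follow the optimization strategy of the method: AdamW with
    learning rate 1e-5 and weight decay 0.01, 12 steps of 16 accumulated
    patches, a three-model ensemble, gradients only in branch A, no
    intensity augmentation, and affine spatial augmentation in both
    branches.
    """

    learning_rate: float = 1e-5
    weight_decay: float = 0.01
    steps: int = 12
    patches_per_step: int = 16
    ensemble_size: int = 3
    grad_branches: str = "A"           # {'A', 'B', 'AB'}
    intensity_aug_in_tta: bool = False
    spatial_aug_branches: str = "AB"   # {'A', 'B', 'AB'}
    parameter_subset: str = "all"      # {'all', 'normalization_only', 'encoder_only'}
    loss_cfg: DiceLossConfig = dataclasses.field(default_factory=DiceLossConfig)
    spatial_ranges: AffineRanges = dataclasses.field(default_factory=AffineRanges)
    patch_size: tuple[int, int, int] | None = None  # None: the training patch size
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1 or self.patches_per_step < 1 or self.ensemble_size < 1:
            raise ValueError("steps, patches and ensemble size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.grad_branches not in ("A", "B", "AB"):
            raise ValueError("grad_branches must be 'A', 'B' or 'AB'")
        if self.spatial_aug_branches not in ("A", "B", "AB"):
            raise ValueError("spatial_aug_branches must be 'A', 'B' or 'AB'")


def _sample_warped_patch(data: np.ndarray, origin, patch, t: AffineAugmentation):
    """Sample an affinely distorted patch view from the full volume.

    The transform acts on local patch coordinates (about the patch center);
    sampling coordinates outside the volume are clamped to the edge, so the
    patch always carries real image content.
    """
    d, h, w = patch
    ii, jj, kk = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel(),
                       np.ones(d * h * w)]).astype(np.float64)
    local = (t.matrix @ coords)[:3]
    global_coords = local + np.asarray(origin, dtype=np.float64)[:, None]
    out = ndimage.map_coordinates(data, global_coords, order=1, mode="nearest")
    return out.reshape(patch)


def _branch_forward(model: SegmentationModel, x_norm: np.ndarray, origin, patch,
                    t: AffineAugmentation, cfg: TTAConfig,
                    rng: np.random.Generator, with_grad: bool):
    """One augmented branch: sample view, feature pipeline, network forward.

    Returns the branch probabilities as a (C, N) tensor in the augmented
    frame (graph-free when ``with_grad`` is false).
    """
    view = _sample_warped_patch(x_norm, origin, patch, t)
    if cfg.intensity_aug_in_tta:
        view = gin_augment(view, model.feature_pipeline.gin_cfg or GINConfig(), rng)
    fp = model.feature_pipeline
    if "ssc" in fp.mode:
        feat = compute_ssc(view, fp.ssc_patch_size, fp.ssc_patch_distance).data
    else:
        feat = view[None]
    xin = Tensor(feat.astype(model.net.dtype))
    if with_grad:
        probs = model.net.forward_probs(xin)
    else:
        with ad.no_grad():
            probs = model.net.forward_probs(xin)
    return probs.reshape(probs.shape[0], -1)


def _patch_loss(model: SegmentationModel, x_norm: np.ndarray, patch,
                cfg: TTAConfig, rng: np.random.Generator):
    """Consistency loss tensor of a single randomly drawn patch."""
    shape = np.asarray(x_norm.shape)
    max_origin = np.maximum(shape - np.asarray(patch), 0)
    origin = tuple(int(rng.integers(0, m + 1)) for m in max_origin)

    transforms = {}
    for branch in ("A", "B"):
        if branch in cfg.spatial_aug_branches:
            transforms[branch] = sample_affine(cfg.spatial_ranges, rng, patch)
        else:
            transforms[branch] = AffineAugmentation.identity()

    outs, valids = {}, {}
    for branch in ("A", "B"):
        with_grad = branch in cfg.grad_branches
        y = _branch_forward(model, x_norm, origin, patch, transforms[branch],
                            cfg, rng, with_grad)
        S, valid = sampling_matrix(transforms[branch], patch, "inverse", "linear")
        y_aligned = ad.sparse_matmul(S.astype(model.net.dtype), y)
        outs[branch] = y_aligned
        valids[branch] = valid
    mask = (valids["A"] & valids["B"]).ravel()
    channels = _select_channels(model.class_ids, cfg.loss_cfg)
    return consistency_dice_t(outs["A"], outs["B"], mask, cfg.loss_cfg, channels), mask


def tta_step(model: SegmentationModel, x_norm: np.ndarray, cfg: TTAConfig,
             rng: np.random.Generator, opt, batched: bool = False) -> float:
    """One adaptation step: accumulate patch gradients, one optimizer update.

    ``batched=True`` builds a single graph over the mean of the patch
    losses instead of backpropagating patch by patch; both produce the same
    update and exist to make that equivalence testable.
    """
    n_p = cfg.patches_per_step
    patch = cfg.patch_size
    model.net.zero_grad()
    losses, any_valid = [], False
    pending = []
    for _ in range(n_p):
        loss, mask = _patch_loss(model, x_norm, patch, cfg, rng)
        if not mask.any():
            continue  # degenerate draw: fully disjoint fields of view
        any_valid = True
        losses.append(float(loss.data))
        if batched:
            pending.append(loss)
        else:
            loss.backward(np.asarray(1.0 / n_p, dtype=model.net.dtype))
    if not any_valid:
        warnings.warn("all patches yielded empty consistency masks; step skipped")
        return float("nan")
    if batched:
        total = pending[0]
        for t in pending[1:]:
            total = total + t
        (total * (1.0 / n_p)).backward()
    opt.step()
    return float(np.mean(losses))


def adapt(model: SegmentationModel, x_t: Volume, cfg: TTAConfig | None = None):
    """Adapt a pre-trained model to a single unlabeled target volume.

    Runs exactly ``cfg.steps`` consistency-optimization steps on a copy of
    the model (the input model is never mutated) and returns the adapted
    model together with the per-step loss trace.
    """
    from .optim import AdamW

    cfg = cfg or TTAConfig()
    if cfg.patch_size is None:
        cfg = dataclasses.replace(cfg, patch_size=(24, 24, 24))
    adapted = model.copy()
    x_norm = normalize_volume(x_t).data
    names = adapted.net.parameter_names(cfg.parameter_subset)
    opt = AdamW({n: adapted.net.params[n] for n in names},
                lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    trace = []
    for _ in range(cfg.steps):
        trace.append(tta_step(adapted, x_norm, cfg, rng, opt))
    return adapted, trace


def adapt_and_predict_ensemble(models, x_t: Volume, cfg: TTAConfig | None = None,
                               predict_kwargs: dict | None = None,
                               member_seeds=None, return_details: bool = False):
    """Adapt every ensemble member to the sample and fuse their predictions.

    Each independently pre-trained model is adapted on the target volume
    with its own randomness stream (override with ``member_seeds``),
    softmax outputs are averaged, and the argmax restricted to the
    configured class subset yields the final label map.  Adapted weights
    are discarded afterwards.
    """
    models = list(models)
    if not models:
        raise ValueError("ensemble must contain at least one model")
    cfg = cfg or TTAConfig()
    predict_kwargs = predict_kwargs or {}
    if member_seeds is None:
        member_seeds = [cfg.seed + 1000 * i for i in range(len(models))]
    mean_probs = None
    class_ids = models[0].class_ids
    details = []
    for model, seed in zip(models, member_seeds):
        member_cfg = dataclasses.replace(cfg, seed=seed)
        adapted, trace = adapt(model, x_t, member_cfg)
        if return_details:
            details.append((adapted, trace))
        pm = predict(adapted, x_t, **predict_kwargs)
        mean_probs = pm.data if mean_probs is None else mean_probs + pm.data
    mean_probs = mean_probs / len(models)
    if cfg.loss_cfg.class_subset is not None:
        keep = set(cfg.loss_cfg.class_subset) | {0}
        for i, c in enumerate(class_ids):
            if c not in keep:
                mean_probs[i] = 0.0
        mean_probs = mean_probs / np.maximum(mean_probs.sum(0, keepdims=True), 1e-12)
    pm = ProbabilityMap(np.clip(mean_probs, 0, 1), list(class_ids),
                        x_t.spacing, x_t.affine.copy())
    seg = pm.argmax_labels()
    return (seg, details) if return_details else seg
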