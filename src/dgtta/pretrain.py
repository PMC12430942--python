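"""Feature pipeline and domain-generalized supervised pre-training.

The segmentation network can be fed raw intensities, GIN-augmented
intensities (training only), the 12-channel self-similarity descriptor, or
the descriptor of the GIN-augmented image (GIN first, then SSC, so the
randomized intensities enrich the descriptor space).  Because the
descriptor changes the input channel count it is active at both training
and inference; GIN is a training-time augmentation only.

Pre-training is plain supervised learning on labeled source volumes with a
Dice + cross-entropy patch loss, class-balanced patch sampling, and Adam.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import LabelMap, ProbabilityMap, Volume
from .gin import GINConfig, gin_augment
from .network import UNet3D
from .optim import AdamW
from .ssc import compute_ssc, descriptor_channel_count

FEATURE_MODES = ("none", "gin", "ssc", "gin+ssc")


@dataclasses.dataclass
class FeaturePipeline:
    """Input-feature configuration of the segmentation network."""

    mode: str = "none"
    gin_cfg: GINConfig | None = None
    ssc_patch_size: int = 1
    ssc_patch_distance: int = 1

    def __post_init__(self):
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if "gin" in self.mode and self.gin_cfg is None:
            self.gin_cfg = GINConfig()

    @property
    def in_channels(self) -> int:
        return descriptor_channel_count() if "ssc" in self.mode else 1

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "ssc_patch_size": self.ssc_patch_size,
             "ssc_patch_distance": self.ssc_patch_distance}
        if self.gin_cfg is not None:
            d["gin_cfg"] = dataclasses.asdict(self.gin_cfg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturePipeline":
        gin_cfg = GINConfig(**d["gin_cfg"]) if "gin_cfg" in d else None
        return cls(d["mode"], gin_cfg, d.get("ssc_patch_size", 1),
                   d.get("ssc_patch_distance", 1))


def apply_feature_pipeline(x, fp: FeaturePipeline, phase: str = "test",
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Map a volume to the network input field (C, D, H, W).

    GIN is applied only in the train phase; the descriptor (when enabled)
    is applied in both phases.  Composition order is GIN first, then SSC.
    """
    if phase not in ("train", "test"):
        raise ValueError(f"unknown phase {phase!r}")
    data = x.data if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)
    use_gin = "gin" in fp.mode and phase == "train"
    if use_gin:
        if rng is None:
            raise ValueError("GIN augmentation requires a random generator")
        data = gin_augment(data, fp.gin_cfg, rng)
    if "ssc" in fp.mode:
        return compute_ssc(data, fp.ssc_patch_size, fp.ssc_patch_distance).data
    return data[None]


def normalize_volume(v: Volume) -> Volume:
    """Per-volume z-score normalization of the intensities."""
    std = v.data.std()
    out = (v.data - v.data.mean()) / (std if std > 1e-12 else 1.0)
    return Volume(out, v.spacing, v.affine.copy())


@dataclasses.dataclass
class TrainConfig:
    """Supervised pre-training hyperparameters."""

    patch_size: tuple[int, int, int] = (24, 24, 24)
    batch_size: int = 2
    epochs: int = 24
    iters_per_epoch: int = 30
    learning_rate: float = 2e-3
    base_channels: int = 8
    normalization_layer: str = "instance"
    foreground_bias: float = 0.5  # fraction of patches centered on a class voxel
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if any(s % 4 for s in self.patch_size):
            raise ValueError("patch dims must be divisible by 4")
        if self.epochs < 1 or self.iters_per_epoch < 1 or self.batch_size < 1:
            raise ValueError("epochs, iters and batch size must be >= 1")


@dataclasses.dataclass
class SegmentationModel:
    """A trained network bundled with its feature pipeline and class list."""

    net: UNet3D
    feature_pipeline: FeaturePipeline
    class_ids: list[int]  # channel order, background first

    def save(self, path) -> None:
        self.net.save(path, extra={"feature_pipeline": self.feature_pipeline.to_dict(),
                                   "class_ids": list(self.class_ids)})

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        net, extra = UNet3D.load(path)
        return cls(net, FeaturePipeline.from_dict(extra["feature_pipeline"]),
                   [int(c) for c in extra["class_ids"]])

    def copy(self) -> "SegmentationModel":
        return SegmentationModel(self.net.copy(), self.feature_pipeline,
                                 list(self.class_ids))


def _log_softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=0, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=0, keepdims=True).log()
    return z - lse


def supervised_loss(logits: Tensor, onehot: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Dice + cross-entropy between patch logits and one-hot labels."""
    logp = _log_softmax(logits)
    n_vox = float(np.prod(onehot.shape[1:]))
    ce = -(logp * Tensor(onehot)).sum() * (1.0 / n_vox)
    p = logp.exp()
    dice_terms = None
    n_fg = onehot.shape[0] - 1
    for c in range(1, onehot.shape[0]):  # foreground channels
        pc = p.reshape(p.shape[0], -1)
        pl = _channel_row(pc, c)
        g = onehot[c].ravel()
        inter = (pl * g).sum()
        denom = pl.sum() + float(g.sum())
        dice = (2.0 * inter + eps) / (denom + eps)
        dice_terms = dice if dice_terms is None else dice_terms + dice
    dice_loss = 1.0 - dice_terms * (1.0 / max(n_fg, 1))
    return ce + dice_loss


def _channel_row(t: Tensor, c: int) -> Tensor:
    def bw(g, a=t, c=c):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[c] = g
            a._accum(full)
    return Tensor._make(t.data[c], (t,), bw)


def _sample_patch_origin(label: np.ndarray, patch, rng, foreground_bias):
    shape = np.asarray(label.shape)
    patch = np.asarray(patch)
    max_origin = shape - patch
    if np.any(max_origin < 0):
        raise ValueError("patch does not fit inside the volume")
    if rng.uniform() < foreground_bias:
        classes = np.unique(label)
        classes = classes[classes != 0]
        if classes.size:
            cid = rng.choice(classes)
            locs = np.argwhere(label == cid)
            center = locs[rng.integers(len(locs))]
            origin = np.clip(center - patch // 2, 0, max_origin)
            return tuple(int(o) for o in origin)
    return tuple(int(rng.integers(0, m + 1)) for m in max_origin)


def pretrain(train_set, fp: FeaturePipeline, cfg: TrainConfig):
    """Supervised pre-training on labeled source volumes.

    Parameters
    ----------
    train_set : list of (Volume, LabelMap)
        Aligned source images and segmentations.
    fp : FeaturePipeline
    cfg : TrainConfig

    Returns
    -------
    (SegmentationModel, dict)
        The trained model and a log with per-iteration and per-epoch loss.
    """
    if not train_set:
        raise ValueError("training set is empty")
    for v, l in train_set:
        if v.shape != l.shape:
            raise ValueError("volume/label shapes differ")

    class_ids = sorted({0} | {c for _, l in train_set for c in l.class_ids})
    if class_ids[0] != 0:
        class_ids = [0] + class_ids
    id_to_chan = {c: i for i, c in enumerate(class_ids)}

    rng = np.random.default_rng(cfg.seed)
    net = UNet3D(fp.in_channels, len(class_ids), cfg.base_channels,
                 cfg.normalization_layer, np.dtype(cfg.dtype),
                 np.random.default_rng(cfg.seed + 1))
    opt = AdamW(net.params, lr=cfg.learning_rate, weight_decay=0.0)

    vols = [normalize_volume(v) for v, _ in train_set]
    labels = [l.data for _, l in train_set]
    # feature fields that never change can be computed once per volume
    static_features = None
    if fp.mode in ("none", "ssc"):
        static_features = [apply_feature_pipeline(v, fp, "test") for v in vols]

    iter_losses, epoch_losses = [], []
    patch = np.asarray(cfg.patch_size)
    for _epoch in range(cfg.epochs):
        ep = []
        for _ in range(cfg.iters_per_epoch):
            vi = int(rng.integers(len(vols)))
            if static_features is not None:
                feat = static_features[vi]
            else:
                feat = apply_feature_pipeline(vols[vi], fp, "train", rng)
            lab = labels[vi]
            net.zero_grad()
            batch_loss = 0.0
            for _ in range(cfg.batch_size):
                o = _sample_patch_origin(lab, patch, rng, cfg.foreground_bias)
                sl = tuple(slice(oo, oo + pp) for oo, pp in zip(o, patch))
                xin = Tensor(feat[(slice(None),) + sl].astype(net.dtype))
                lpatch = lab[sl]
                onehot = np.zeros((len(class_ids), *patch), dtype=net.dtype)
                for c, i in id_to_chan.items():
                    onehot[i] = lpatch == c
                loss = supervised_loss(net.forward(xin), onehot)
                loss.backward(np.asarray(1.0 / cfg.batch_size, dtype=net.dtype))
                batch_loss += loss.item() / cfg.batch_size
            opt.step()
            iter_losses.append(batch_loss)
            ep.append(batch_loss)
        epoch_losses.append(float(np.mean(ep)))
    model = SegmentationModel(net, fp, class_ids)
    log = {"iter_loss": iter_losses, "epoch_loss": epoch_losses,
           "config": dataclasses.asdict(cfg)}
    return model, log


def predict(model: SegmentationModel, x: Volume, patch_size=None,
            stride=None) -> ProbabilityMap:
    """Sliding-window inference with overlap averaging.

    The volume is z-normalized, passed through the test-phase feature
    pipeline, tiled into patches, and the per-patch softmax outputs are
    averaged on overlaps and renormalized per voxel.  Volumes smaller than
    the patch are padded (edge replication) and cropped back.
    """
    patch = np.asarray(patch_size if patch_size is not None else (24, 24, 24))
    stride = np.asarray(stride if stride is not None else np.maximum(5 * patch // 6, 1))
    feat = apply_feature_pipeline(normalize_volume(x), model.feature_pipeline, "test")

    shape = np.asarray(x.shape)
    pad = np.maximum(patch - shape, 0)
    if np.any(pad > 0):
        feat = np.pad(feat, [(0, 0)] + [(0, int(p)) for p in pad], mode="edge")
    padded_shape = np.asarray(feat.shape[1:])

    origins = [sorted(set(list(range(0, int(ps - pp) + 1, int(st))) + [int(ps - pp)]))
               for ps, pp, st in zip(padded_shape, patch, stride)]
    probs = np.zeros((len(model.class_ids), *padded_shape))
    counts = np.zeros(padded_shape)
    for oz in origins[0]:
        for oy in origins[1]:
            for ox in origins[2]:
                sl = (slice(None), slice(oz, oz + patch[0]),
                      slice(oy, oy + patch[1]), slice(ox, ox + patch[2]))
                probs[sl] += model.net.predict_probs(feat[sl])
                counts[sl[1:]] += 1.0
    probs /= counts
    probs = probs[:, :shape[0], :shape[1], :shape[2]]
    probs /= probs.sum(axis=0, keepdims=True)
    return ProbabilityMap(np.clip(probs, 0.0, 1.0), list(model.class_ids),
                          x.spacing, x.affine.copy())
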