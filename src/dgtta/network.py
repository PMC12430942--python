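"""A compact 3D U-Net segmentation backbone.

Three resolution levels with per-channel (instance) normalization and
leaky rectifiers, skip connections by channel concatenation, and a 1x1x1
classification head.  The backbone is deliberately small: the method under
study lives in the input-feature pipeline and the adaptation loop, and
treats the segmentation network as a given.  Inputs are single patches in
channel-major layout (C, D, H, W) whose spatial dims are divisible by 4.
"""
from __future__ import annotations

import io
import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class UNet3D:
    """Encoder-decoder segmentation network on the package's autodiff engine.

    Parameters
    ----------
    in_channels : int
        1 for raw-intensity input, 12 for the self-similarity descriptor.
    n_classes : int
        Output channels (background included).
    base_channels : int
        Width of the first level; deeper levels double it.
    normalization : {'instance', 'batch'}
        Normalization layer flavor.  Patches are processed one at a time,
        where batch normalization reduces to per-channel normalization;
        the option is kept for configuration parity.
    dtype : numpy dtype
        Compute/parameter precision.
    """

    KERNEL = 3

    def __init__(self, in_channels: int, n_classes: int, base_channels: int = 8,
                 normalization: str = "instance", dtype=np.float32,
                 rng: np.random.Generator | None = None):
        if normalization not in ("instance", "batch"):
            raise ValueError(f"unknown normalization {normalization!r}")
        self.in_channels = int(in_channels)
        self.n_classes = int(n_classes)
        self.base_channels = int(base_channels)
        self.normalization = normalization
        self.dtype = np.dtype(dtype)
        rng = rng or np.random.default_rng(0)
        b = self.base_channels
        k3 = self.KERNEL ** 3
        self.params: dict[str, Tensor] = {}

        def conv_params(name, cin, cout, k3_=k3):
            std = np.sqrt(2.0 / (cin * k3_))
            self.params[f"{name}.w"] = Tensor(
                rng.normal(0, std, (cout, cin * k3_)).astype(self.dtype), True)
            self.params[f"{name}.b"] = Tensor(np.zeros(cout, self.dtype), True)

        def norm_params(name, c):
            self.params[f"{name}.g"] = Tensor(np.ones((c, 1, 1, 1), self.dtype), True)
            self.params[f"{name}.beta"] = Tensor(np.zeros((c, 1, 1, 1), self.dtype), True)

        conv_params("enc0", self.in_channels, b); norm_params("n_enc0", b)
        conv_params("enc1", b, 2 * b);           norm_params("n_enc1", 2 * b)
        conv_params("bott", 2 * b, 4 * b);       norm_params("n_bott", 4 * b)
        conv_params("dec1", 6 * b, 2 * b);       norm_params("n_dec1", 2 * b)
        conv_params("dec0", 3 * b, b);           norm_params("n_dec0", b)
        conv_params("head", b, self.n_classes, k3_=1)

    # -- parameter access ------------------------------------------------
    ENCODER_PREFIXES = ("enc0", "enc1", "bott", "n_enc0", "n_enc1", "n_bott")

    def parameter_names(self, subset: str = "all") -> list[str]:
        if subset == "all":
            return list(self.params)
        if subset == "normalization_only":
            return [n for n in self.params if n.startswith("n_")]
        if subset == "encoder_only":
            return [n for n in self.params if n.split(".")[0] in self.ENCODER_PREFIXES]
        raise ValueError(f"unknown parameter subset {subset!r}")

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def copy(self) -> "UNet3D":
        clone = UNet3D.__new__(UNet3D)
        clone.in_channels = self.in_channels
        clone.n_classes = self.n_classes
        clone.base_channels = self.base_channels
        clone.normalization = self.normalization
        clone.dtype = self.dtype
        clone.params = {k: Tensor(v.data.copy(), True) for k, v in self.params.items()}
        return clone

    # -- forward ----------------------------------------------------------
    def _block(self, x: Tensor, conv: str, norm: str) -> Tensor:
        p = self.params
        h = ad.conv3d(x, p[f"{conv}.w"], p[f"{conv}.b"], self.KERNEL)
        h = ad.instance_norm(h, p[f"{norm}.g"], p[f"{norm}.beta"])
        return ad.leaky_relu(h, 0.01)

    def forward(self, x: Tensor) -> Tensor:
        """Logits (n_classes, D, H, W) for one patch."""
        if x.data.shape[0] != self.in_channels:
            raise ValueError(
                f"network expects {self.in_channels} input channels, got {x.data.shape[0]}")
        if any(s % 4 for s in x.data.shape[1:]):
            raise ValueError("patch spatial dims must be divisible by 4")
        x = Tensor(x.data.astype(self.dtype, copy=False), x.requires_grad) \
            if x.data.dtype != self.dtype else x
        e0 = self._block(x, "enc0", "n_enc0")
        e1 = self._block(ad.avg_pool3d(e0), "enc1", "n_enc1")
        bt = self._block(ad.avg_pool3d(e1), "bott", "n_bott")
        d1 = self._block(ad.concat_channels(ad.upsample_nearest3d(bt), e1),
                         "dec1", "n_dec1")
        d0 = self._block(ad.concat_channels(ad.upsample_nearest3d(d1), e0),
                         "dec0", "n_dec0")
        p = self.params
        return ad.conv3d(d0, p["head.w"], p["head.b"], 1)

    def forward_probs(self, x: Tensor) -> Tensor:
        return ad.softmax_channels(self.forward(x))

    def predict_probs(self, patch: np.ndarray) -> np.ndarray:
        """Gradient-free forward pass on a numpy patch."""
        return self.forward_probs(Tensor(patch.astype(self.dtype))).data

    # -- serialization ----------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        """Single-file checkpoint: parameters + architecture config."""
        meta = {
            "in_channels": self.in_channels, "n_classes": self.n_classes,
            "base_channels": self.base_channels,
            "normalization": self.normalization, "dtype": self.dtype.name,
            "extra": extra or {},
        }
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["UNet3D", dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            net = cls(meta["in_channels"], meta["n_classes"], meta["base_channels"],
                      meta["normalization"], np.dtype(meta["dtype"]))
            for k in net.params:
                net.params[k] = Tensor(z[k.replace(".", "__")].copy(), True)
        return net, meta.get("extra", {})
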