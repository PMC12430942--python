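"""Global intensity non-linear (GIN) augmentation.

A shallow convolutional network with freshly randomized weights remaps the
intensities/texture of an input volume; the remapped image is blended with
the original by a random weight alpha:

    GIN(x) = alpha * g(x) + (1 - alpha) * x

Re-randomizing g at every training iteration exposes the segmentation
network to a broad family of intensity appearances of the same geometry,
which is what pushes it toward intensity-invariant features.  The network
is never trained; only its random draw matters, so everything here is
plain (gradient-free) numpy.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .core import Volume


@dataclasses.dataclass
class GINConfig:
    """Architecture and blending configuration of the augmentation network.

    The remapping network is ``n_layers`` convolutions of ``kernel_size``
    with ``hidden_channels`` feature maps and leaky-rectifier
    nonlinearities in between; its output is rescaled to the input's mean
    and standard deviation so augmented images stay in a trainable range.
    ``alpha`` is drawn uniformly on [0, 1] per augmented volume.
    """

    n_layers: int = 4
    hidden_channels: int = 8
    kernel_size: int = 3
    leaky_slope: float = 0.2
    weight_scale: float = 1.0

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_channels < 1:
            raise ValueError("n_layers and hidden_channels must be >= 1")
        if self.kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")


def _conv(x: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    # edge-replicate padding so a constant field maps to a constant field
    c, d, h, wd = x.shape
    n = d * h * wd
    if k == 1:
        return (w @ x.reshape(c, n)).reshape(-1, d, h, wd)
    p = k // 2
    pad = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)), mode="edge")
    wk = w.reshape(w.shape[0], c, k**3)
    out = np.zeros((w.shape[0], n), dtype=x.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = pad[:, i:i + d, j:j + h, l:l + wd].reshape(c, n)
                out += wk[:, :, idx] @ xs
                idx += 1
    return out.reshape(-1, d, h, wd)


def sample_gin_network(cfg: GINConfig, rng: np.random.Generator):
    """Draw a fresh random remapping network g: volume -> volume.

    Returns a callable on 3D arrays.  Two calls with the same generator
    state produce identical mappings.
    """
    k = cfg.kernel_size
    widths = [1] + [cfg.hidden_channels] * (cfg.n_layers - 1) + [1]
    weights = []
    for cin, cout in zip(widths[:-1], widths[1:]):
        fan_in = cin * k**3
        std = cfg.weight_scale * np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, std, size=(cout, cin * k**3)).astype(np.float32))

    def g(x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)[None]
        for i, w in enumerate(weights):
            out = _conv(out, w, k)
            if i < len(weights) - 1:
                out = np.where(out > 0, out, cfg.leaky_slope * out)
        out = out[0]
        # rescale to the input's intensity statistics
        std = out.std()
        out = (out - out.mean()) / (std if std > 1e-12 else 1.0)
        return out * np.asarray(x).std() + np.asarray(x).mean()

    return g


def gin_augment(x, cfg: GINConfig, rng: np.random.Generator,
                alpha: float | None = None):
    """Blend a volume with a freshly randomized intensity remapping.

    ``alpha`` overrides the uniform draw (used for testing the convex-blend
    identity).  Returns the same container type as the input.
    """
    is_vol = isinstance(x, Volume)
    data = x.data if is_vol else np.asarray(x, dtype=np.float64)
    g = sample_gin_network(cfg, rng)
    if alpha is None:
        alpha = float(rng.uniform(0.0, 1.0))
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    out = alpha * g(data) + (1.0 - alpha) * data
    if is_vol:
        return Volume(out, x.spacing, x.affine.copy())
    return out
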