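"""Adam/AdamW parameter updates with decoupled weight decay."""
from __future__ import annotations

import numpy as np


class AdamW:
    """AdamW: Adam moments plus decoupled weight decay.

    ``weight_decay=0`` recovers plain Adam.  Updates are applied in place
    to the tensors handed in at construction.
    """

    def __init__(self, params: dict, lr: float = 1e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = dict(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self, grads: dict | None = None) -> None:
        """One update from ``p.grad`` (or an explicit gradient dict)."""
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k] if grads is not None else p.grad
            if g is None:
                continue
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
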