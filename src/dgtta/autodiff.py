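"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Provides exactly the operations the 3D segmentation network and the
test-time objective need: broadcast arithmetic, exp/log/pow, reductions,
matrix products, 3x3x3 (and 1x1x1) volumetric convolution via im2col,
factor-2 average pooling and nearest upsampling, channel concatenation,
leaky rectifier, and multiplication by a fixed sparse matrix (used for
differentiable spatial warping).  Gradients are accumulated by a
topological sweep over the recorded graph.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse


_grad_enabled = True


class no_grad:
    """Context manager: ops recorded inside build no graph (fixed targets)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g * p * np.power(a.data, p - 1))
        return self._make(np.power(self.data, p), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)
        def bw(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)
        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return self._make(np.log(self.data), (self,), bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))
        return self._make(self.data.reshape(shape), (self,), bw)

    def matmul(self, other):
        other = self._wrap(other)
        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)
        return self._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- gradient machinery ---------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        topo, seen = [], set()
        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


# ---------------------------------------------------------------------------
# Neural-network primitives


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    def bw(g, a=x, mask=mask):
        if a.requires_grad:
            a._accum(g * np.where(mask, 1.0, slope))
    return Tensor._make(np.where(mask, x.data, slope * x.data), (x,), bw)


def _offsets(k: int):
    return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, kernel_size: int = 3) -> Tensor:
    """Volumetric convolution with 'same' zero padding.

    ``x``: (C_in, D, H, W); ``weight``: (C_out, C_in * k^3) with the kernel
    offset as the fastest-varying index; ``bias``: (C_out,).  Realized as a
    shift-and-add over the k^3 kernel offsets so each term is a small dense
    matrix product.
    """
    k = kernel_size
    cin, d, h, w = x.data.shape
    n = d * h * w
    cout = weight.data.shape[0]
    if k == 1:
        xmat = x.data.reshape(cin, n)
        out = (weight.data @ xmat + bias.data[:, None]).reshape(cout, d, h, w)

        def bw1(g, x=x, weight=weight, bias=bias, xmat=xmat):
            gmat = g.reshape(g.shape[0], -1)
            if bias.requires_grad:
                bias._accum(gmat.sum(axis=1))
            if weight.requires_grad:
                weight._accum(gmat @ xmat.T)
            if x.requires_grad:
                x._accum((weight.data.T @ gmat).reshape(x.data.shape))

        return Tensor._make(out, (x, weight, bias), bw1)

    p = k // 2
    pad = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    # weight viewed per offset: (cout, cin, k^3)
    wk = weight.data.reshape(cout, cin, k**3)
    out = np.tile(bias.data[:, None], (1, n)).astype(x.data.dtype)
    for idx, (i, j, l) in enumerate(_offsets(k)):
        xs = pad[:, i:i + d, j:j + h, l:l + w].reshape(cin, n)
        out += wk[:, :, idx] @ xs
    out = out.reshape(cout, d, h, w)

    def bw(g, x=x, weight=weight, bias=bias, pad=pad, k=k,
           dims=(cin, cout, d, h, w, n, p)):
        cin_, cout_, d_, h_, w_, n_, p_ = dims
        gmat = np.ascontiguousarray(g.reshape(cout_, n_))
        if bias.requires_grad:
            bias._accum(gmat.sum(axis=1))
        wk_ = weight.data.reshape(cout_, cin_, k**3)
        gw = np.zeros_like(wk_) if weight.requires_grad else None
        gpad = np.zeros_like(pad) if x.requires_grad else None
        for idx, (i, j, l) in enumerate(_offsets(k)):
            if gw is not None:
                xs = pad[:, i:i + d_, j:j + h_, l:l + w_].reshape(cin_, n_)
                gw[:, :, idx] = gmat @ xs.T
            if gpad is not None:
                tmp = wk_[:, :, idx].T @ gmat
                gpad[:, i:i + d_, j:j + h_, l:l + w_] += tmp.reshape(cin_, d_, h_, w_)
        if gw is not None:
            weight._accum(gw.reshape(cout_, cin_ * k**3))
        if gpad is not None:
            x._accum(gpad[:, p_:p_ + d_, p_:p_ + h_, p_:p_ + w_])

    return Tensor._make(out, (x, weight, bias), bw)


def avg_pool3d(x: Tensor) -> Tensor:
    """Factor-2 average pooling; spatial dims must be even."""
    c, d, h, w = x.data.shape
    out = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
    def bw(g, a=x):
        gg = np.repeat(np.repeat(np.repeat(g, 2, 1), 2, 2), 2, 3) / 8.0
        if a.requires_grad:
            a._accum(gg)
    return Tensor._make(out, (x,), bw)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """Factor-2 nearest-neighbor upsampling."""
    out = np.repeat(np.repeat(np.repeat(x.data, 2, 1), 2, 2), 2, 3)
    def bw(g, a=x):
        c, d, h, w = a.data.shape
        gg = g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
        if a.requires_grad:
            a._accum(gg)
    return Tensor._make(out, (x,), bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[0]
    def bw(g, a=a, b=b, na=na):
        if a.requires_grad:
            a._accum(g[:na])
        if b.requires_grad:
            b._accum(g[na:])
    return Tensor._make(np.concatenate([a.data, b.data], axis=0), (a, b), bw)


def sparse_matmul(S: sparse.spmatrix, x: Tensor) -> Tensor:
    """Apply a fixed sparse matrix row-wise to each channel of ``x``.

    ``x``: (C, N_in) -> (C, N_out); gradient flows as ``S.T @ g``.
    """
    out = (S @ x.data.T).T
    def bw(g, a=x, S=S):
        if a.requires_grad:
            a._accum(np.ascontiguousarray((S.T @ g.T).T))
    return Tensor._make(np.ascontiguousarray(out), (x,), bw)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the leading (channel) axis, numerically shifted."""
    shift = Tensor(x.data.max(axis=0, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=0, keepdims=True)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with affine params.

    ``gamma``/``beta`` have shape (C, 1, 1, 1).
    """
    ax = (1, 2, 3)
    mu = x.mean(axis=ax, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=ax, keepdims=True)
    xhat = xc * ((var + eps) ** -0.5)
    return xhat * gamma + beta
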