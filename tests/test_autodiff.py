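"""Finite-difference validation of the reverse-mode engine.

Every primitive the network and the test-time objective rely on is checked
against central differences on small float64 problems.
"""
import numpy as np
import pytest
from scipy import sparse

from dgtta import autodiff as ad
from dgtta.autodiff import Tensor


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


def check_input_grad(op, x0, atol=1e-6):
    t = Tensor(x0.copy(), requires_grad=True)
    out = op(t)
    loss = (out * out).sum()
    loss.backward()
    num = numeric_grad(lambda x: float((op(Tensor(x)).data ** 2).sum()), x0)
    np.testing.assert_allclose(t.grad, num, atol=atol)


class TestPrimitiveGradients:
    def test_arithmetic_chain(self, rng):
        x0 = rng.normal(size=(3, 4))
        check_input_grad(lambda t: ((t * 2.0 + 1.0) / (t.exp() + 3.0)) ** 2, x0)

    def test_log_sum_mean(self, rng):
        x0 = rng.uniform(1.0, 2.0, size=(4, 5))
        check_input_grad(lambda t: (t.log().sum(axis=1, keepdims=True) * t).mean(), x0)

    def test_matmul(self, rng):
        a0 = rng.normal(size=(3, 4))
        w = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
        t = Tensor(a0.copy(), requires_grad=True)
        ((t @ w) ** 2).sum().backward()
        num = numeric_grad(lambda a: float(((a @ w.data) ** 2).sum()), a0)
        np.testing.assert_allclose(t.grad, num, atol=1e-6)

    @pytest.mark.parametrize("k", [1, 3])
    def test_conv3d_gradients(self, rng, k):
        cin, cout = 2, 3
        x0 = rng.normal(size=(cin, 4, 4, 4))
        w0 = rng.normal(size=(cout, cin * k**3))
        b0 = rng.normal(size=cout)
        w = Tensor(w0.copy(), True)
        b = Tensor(b0.copy(), True)
        x = Tensor(x0.copy(), True)
        (ad.conv3d(x, w, b, k) ** 2).sum().backward()
        f_x = lambda a: float((ad.conv3d(Tensor(a), Tensor(w0), Tensor(b0), k).data ** 2).sum())
        f_w = lambda a: float((ad.conv3d(Tensor(x0), Tensor(a), Tensor(b0), k).data ** 2).sum())
        f_b = lambda a: float((ad.conv3d(Tensor(x0), Tensor(w0), Tensor(a), k).data ** 2).sum())
        np.testing.assert_allclose(x.grad, numeric_grad(f_x, x0), atol=1e-5)
        np.testing.assert_allclose(w.grad, numeric_grad(f_w, w0), atol=1e-5)
        np.testing.assert_allclose(b.grad, numeric_grad(f_b, b0), atol=1e-5)

    def test_pool_and_upsample_gradients(self, rng):
        x0 = rng.normal(size=(2, 4, 4, 4))
        check_input_grad(lambda t: ad.avg_pool3d(t), x0)
        check_input_grad(lambda t: ad.upsample_nearest3d(t), x0)

    def test_leaky_relu_gradient(self, rng):
        x0 = rng.normal(size=(3, 4, 4, 4)) + 0.05  # keep away from the kink
        check_input_grad(lambda t: ad.leaky_relu(t, 0.1), x0)

    def test_concat_gradient(self, rng):
        a0 = rng.normal(size=(2, 3, 3, 3))
        b0 = rng.normal(size=(1, 3, 3, 3))
        a = Tensor(a0.copy(), True)
        b = Tensor(b0.copy(), True)
        (ad.concat_channels(a, b) ** 2).sum().backward()
        np.testing.assert_allclose(a.grad, 2 * a0, atol=1e-12)
        np.testing.assert_allclose(b.grad, 2 * b0, atol=1e-12)

    def test_sparse_matmul_gradient(self, rng):
        S = sparse.random(10, 12, density=0.3, random_state=0, format="csr")
        x0 = rng.normal(size=(2, 12))
        check_input_grad(lambda t: ad.sparse_matmul(S, t), x0)

    def test_softmax_gradient(self, rng):
        x0 = rng.normal(size=(3, 4))
        w = rng.normal(size=(3, 4))
        check_input_grad(lambda t: ad.softmax_channels(t) * w, x0)

    def test_instance_norm_gradient(self, rng):
        x0 = rng.normal(size=(2, 3, 3, 3))
        g = Tensor(rng.normal(size=(2, 1, 1, 1)), True)
        b = Tensor(rng.normal(size=(2, 1, 1, 1)), True)
        check_input_grad(lambda t: ad.instance_norm(t, g, b), x0, atol=1e-4)


class TestEngineSemantics:
    def test_no_grad_builds_no_graph(self, rng):
        x = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        with ad.no_grad():
            out = (x * 2.0).sum()
        assert not out.requires_grad

    def test_detach_blocks_gradient(self, rng):
        x = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        (x.detach() * x).sum().backward()
        np.testing.assert_allclose(x.grad, x.data)

    def test_grad_accumulates_across_backward_calls(self, rng):
        x = Tensor(rng.normal(size=(4,)), requires_grad=True)
        (x * 1.0).sum().backward()
        (x * 1.0).sum().backward()
        np.testing.assert_allclose(x.grad, 2.0 * np.ones(4))

    def test_broadcasting_unbroadcast(self, rng):
        a = Tensor(rng.normal(size=(3, 1)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 4)), requires_grad=True)
        (a * b).sum().backward()
        np.testing.assert_allclose(a.grad, np.full((3, 1), b.data.sum()))
        np.testing.assert_allclose(b.grad, np.full((1, 4), a.data.sum()))
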