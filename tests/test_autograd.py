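"""Finite-difference gradient checks for the reverse-mode engine and an
independent scipy convolution oracle."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from vortexdiff.nn.autograd import (
    Tensor,
    avg_pool2,
    backward,
    batch_norm2d,
    concat,
    conv2d,
    conv_transpose2x2,
    max_pool2,
    npcc_loss,
    relu,
)
from vortexdiff.nn.layers import BatchNorm2d

F32 = np.float32
rng = np.random.default_rng(7)


def numerical_grad(f, x, eps=1e-2):
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def sq_loss_backward(y: Tensor, target):
    """sum((y - t)^2) with analytic seed gradient."""
    loss = Tensor(np.float32(np.sum((y.data - target) ** 2)), True,
                  [(y, lambda g: 2 * (y.data - target) * g)])
    backward(loss)


def assert_grad_close(analytic, numeric, tol=5e-3):
    scale = max(1e-8, np.abs(numeric).max())
    assert np.abs(analytic - numeric).max() / scale < tol


class TestConv2d:
    @pytest.mark.parametrize("dilation", [1, 2, 3])
    def test_gradients_match_finite_differences(self, dilation):
        x = Tensor(rng.standard_normal((2, 6, 6, 3)).astype(F32), requires_grad=True)
        w = Tensor(0.3 * rng.standard_normal((3, 3, 3, 4)).astype(F32), requires_grad=True)
        b = Tensor(0.1 * rng.standard_normal(4).astype(F32), requires_grad=True)
        t = rng.standard_normal((2, 6, 6, 4)).astype(F32)

        def f():
            return float(np.sum((conv2d(Tensor(x.data), w, b, dilation).data - t) ** 2))

        sq_loss_backward(conv2d(x, w, b, dilation), t)
        assert_grad_close(x.grad, numerical_grad(f, x.data))
        assert_grad_close(w.grad, numerical_grad(f, w.data))
        assert_grad_close(b.grad, numerical_grad(f, b.data))

    def test_forward_matches_scipy_correlate(self):
        x = rng.standard_normal((1, 8, 8, 2)).astype(F32)
        w = rng.standard_normal((5, 5, 2, 3)).astype(F32)
        y = conv2d(Tensor(x), Tensor(w)).data
        for o in range(3):
            ref = sum(correlate2d(x[0, :, :, c], w[:, :, c, o], mode="same") for c in range(2))
            assert np.abs(y[0, :, :, o] - ref).max() < 1e-4

    def test_dilated_receptive_footprint(self):
        """An impulse through a dilation-d 5x5 kernel touches a
        ((5-1)d+1)^2 footprint: 5x5 for d=1, 13x13 for d=3."""
        for d, span in [(1, 5), (3, 13)]:
            x = np.zeros((1, 17, 17, 1), dtype=F32)
            x[0, 8, 8, 0] = 1.0
            w = np.ones((5, 5, 1, 1), dtype=F32)
            y = conv2d(Tensor(x), Tensor(w), dilation=d).data[0, :, :, 0]
            rows = np.nonzero(y.any(axis=1))[0]
            assert rows.max() - rows.min() + 1 == span


class TestTransposeConv:
    def test_upsamples_by_two_and_grads(self):
        x = Tensor(rng.standard_normal((1, 4, 4, 2)).astype(F32), requires_grad=True)
        w = Tensor(rng.standard_normal((2, 3, 2, 2)).astype(F32), requires_grad=True)
        t = rng.standard_normal((1, 8, 8, 3)).astype(F32)
        y = conv_transpose2x2(x, w)
        assert y.shape == (1, 8, 8, 3)
        # stride-2 2x2 kernels do not overlap: output block (2h:2h+2, 2w:2w+2)
        # is exactly sum_c x[h, w, c] * w[c, :, :, :]
        expect = np.einsum("c,co->o", x.data[0, 1, 2], w.data[:, :, 0, 1])
        assert np.allclose(y.data[0, 2, 5, :], expect, atol=1e-6)

        def f():
            return float(np.sum((conv_transpose2x2(Tensor(x.data), Tensor(w.data)).data - t) ** 2))

        sq_loss_backward(y, t)
        assert_grad_close(x.grad, numerical_grad(f, x.data))
        assert_grad_close(w.grad, numerical_grad(f, w.data))


class TestPoolsAndPointwise:
    def test_avg_pool_grads(self):
        x = Tensor(rng.standard_normal((2, 4, 4, 3)).astype(F32), requires_grad=True)
        t = rng.standard_normal((2, 2, 2, 3)).astype(F32)

        def f():
            return float(np.sum((avg_pool2(Tensor(x.data)).data - t) ** 2))

        sq_loss_backward(avg_pool2(x), t)
        assert_grad_close(x.grad, numerical_grad(f, x.data))

    def test_max_pool_values_and_grads(self):
        x = Tensor(rng.standard_normal((1, 4, 4, 2)).astype(F32), requires_grad=True)
        y = max_pool2(x)
        assert y.data[0, 0, 0, 0] == x.data[0, :2, :2, 0].max()
        t = rng.standard_normal(y.shape).astype(F32)

        def f():
            return float(np.sum((max_pool2(Tensor(x.data)).data - t) ** 2))

        sq_loss_backward(y, t)
        assert_grad_close(x.grad, numerical_grad(f, x.data))

    def test_relu_and_concat_grads(self):
        a = Tensor(rng.standard_normal((1, 2, 2, 2)).astype(F32), requires_grad=True)
        b = Tensor(rng.standard_normal((1, 2, 2, 3)).astype(F32), requires_grad=True)
        t = rng.standard_normal((1, 2, 2, 5)).astype(F32)
        y = concat([relu(a), b])
        assert y.shape == (1, 2, 2, 5)

        def f():
            return float(np.sum((concat([relu(Tensor(a.data)), Tensor(b.data)]).data - t) ** 2))

        sq_loss_backward(y, t)
        assert_grad_close(a.grad, numerical_grad(f, a.data))
        assert_grad_close(b.grad, numerical_grad(f, b.data))


class TestBatchNorm:
    def test_normalises_and_grads_in_training_mode(self):
        bn = BatchNorm2d(3)
        x = Tensor(rng.standard_normal((4, 3, 3, 3)).astype(F32) * 2 + 1, requires_grad=True)
        y = batch_norm2d(x, bn.gamma, bn.beta, bn.running_mean.copy(), bn.running_var.copy(), True)
        assert np.abs(y.data.mean(axis=(0, 1, 2))).max() < 1e-5
        assert np.abs(y.data.std(axis=(0, 1, 2)) - 1).max() < 1e-3
        t = rng.standard_normal(x.shape).astype(F32)

        def f():
            yy = batch_norm2d(Tensor(x.data), bn.gamma, bn.beta,
                              bn.running_mean.copy(), bn.running_var.copy(), True)
            return float(np.sum((yy.data - t) ** 2))

        sq_loss_backward(y, t)
        assert_grad_close(x.grad, numerical_grad(f, x.data), tol=1e-2)

    def test_eval_mode_uses_running_stats(self):
        bn = BatchNorm2d(2)
        bn.running_mean[:] = [1.0, -1.0]
        bn.running_var[:] = [4.0, 0.25]
        x = Tensor(np.ones((1, 2, 2, 2), dtype=F32))
        y = batch_norm2d(x, bn.gamma, bn.beta, bn.running_mean, bn.running_var, False)
        assert y.data[0, 0, 0, 0] == pytest.approx((1 - 1) / 2.0, abs=1e-4)
        assert y.data[0, 0, 0, 1] == pytest.approx((1 + 1) / 0.5, rel=1e-3)


class TestNPCCLoss:
    def test_matches_metric_and_grad(self):
        from vortexdiff.metrics import npcc as metric_npcc

        p = Tensor(rng.standard_normal((3, 5, 5, 1)).astype(F32), requires_grad=True)
        t = rng.standard_normal((3, 5, 5, 1)).astype(F32)
        loss = npcc_loss(p, t)
        expect = np.mean([metric_npcc(p.data[i, ..., 0], t[i, ..., 0]) for i in range(3)])
        assert float(loss.data) == pytest.approx(expect, abs=1e-6)

        def f():
            return float(npcc_loss(Tensor(p.data), t).data)

        backward(loss)
        assert_grad_close(p.grad, numerical_grad(f, p.data), tol=1e-2)

    def test_constant_image_rejected(self):
        p = Tensor(np.ones((1, 4, 4, 1), dtype=F32), requires_grad=True)
        with pytest.raises(ValueError):
            npcc_loss(p, rng.standard_normal((1, 4, 4, 1)).astype(F32))


def test_backward_requires_scalar():
    x = Tensor(np.ones((2, 2), dtype=F32), requires_grad=True)
    with pytest.raises(ValueError):
        backward(x)
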