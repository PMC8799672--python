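"""Compact reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a convolutional encoder-decoder: same-padded
dilated convolution (im2col + BLAS), 2x2 stride-2 transpose convolution,
2x2 average/max pooling, batch normalization, ReLU, channel concatenation
and the negative-Pearson-correlation loss.  Everything runs in float32 with
images laid out channels-last, (batch, height, width, channels), which keeps
the im2col gather and channel concatenation contiguous.

Each op returns a :class:`Tensor` holding the forward value and a list of
(parent, pullback) pairs; :func:`backward` walks the tape in reverse
topological order accumulating gradients.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "conv2d",
    "conv_transpose2x2",
    "avg_pool2",
    "max_pool2",
    "relu",
    "concat",
    "batch_norm2d",
    "npcc_loss",
]

F32 = np.float32

# Patch matrices below this size are kept from the forward pass for the
# weight gradient; larger ones are rebuilt in the backward pass to bound
# peak memory on full-scale graphs.
_COLS_CACHE_BYTES = 64 * 2**20


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), name: str = ""):
        self.data = np.asarray(data, dtype=F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # parents: sequence of (Tensor, pullback) where pullback(grad_out) -> grad_parent
        self.parents: Sequence[tuple["Tensor", Callable]] = parents
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(F32, copy=False)
        else:
            self.grad = self.grad + g


def backward(loss: Tensor) -> None:
    """Reverse-topological sweep seeding d(loss)/d(loss) = 1.  The tape is
    released as it is consumed (single-shot backward)."""
    if loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    loss._accumulate(np.ones_like(loss.data))
    for node in reversed(order):
        if node.grad is None:
            continue
        for parent, pullback in node.parents:
            parent._accumulate(pullback(node.grad))
        if node.parents:
            node.parents = ()
            node.grad = None  # free intermediate gradients as we go


# ----------------------------------------------------------------- im2col


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(B,H,W,C) -> (B*H*W, k*k*C) patch matrix under 'same' padding."""
    B, H, W, C = x.shape
    d = dilation
    span = (k - 1) * d + 1
    p = span // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((B, H, W, k, k, C), dtype=F32)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, :, ki, kj, :] = xp[:, ki * d : ki * d + H, kj * d : kj * d + W, :]
    return cols.reshape(B * H * W, k * k * C)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padded 2-D convolution (cross-correlation), odd kernel, optional
    dilation.  x: (B,H,W,C); w: (k, k, in, out); b: (out,)."""
    B, H, W, C = x.data.shape
    k, k2, Ci, O = w.data.shape
    if Ci != C or k != k2 or k % 2 == 0:
        raise ValueError(f"bad kernel {w.data.shape} for input {x.data.shape}")
    cols = _im2col(x.data, k, dilation)
    Wm = w.data.reshape(k * k * C, O)
    y = cols @ Wm
    if b is not None:
        y += b.data
    out_data = y.reshape(B, H, W, O)
    cached = cols if cols.nbytes <= _COLS_CACHE_BYTES else None

    def pull_x(g):
        gm = g.reshape(B * H * W, O)
        dcols = (gm @ Wm.T).reshape(B, H, W, k, k, C)
        d = dilation
        span = (k - 1) * d + 1
        p = span // 2
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki * d : ki * d + H, kj * d : kj * d + W, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p : p + H, p : p + W, :]

    def pull_w(g):
        gm = g.reshape(B * H * W, O)
        c = cached if cached is not None else _im2col(x.data, k, dilation)
        return (c.T @ gm).reshape(k, k, C, O)

    parents = [(x, pull_x), (w, pull_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 1, 2))))
    return Tensor(out_data, True, parents)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 transpose convolution with stride 2 (non-overlapping learned
    upsampling).  x: (B,H,W,C); w: (in, out, 2, 2)."""
    B, H, W, C = x.data.shape
    Ci, O, k, k2 = w.data.shape
    if Ci != C or (k, k2) != (2, 2):
        raise ValueError(f"bad transpose kernel {w.data.shape} for input {x.data.shape}")
    # y[b, 2h+u, 2w+v, o] = sum_c x[b,h,w,c] w[c,o,u,v]
    wm = w.data.transpose(2, 3, 0, 1).reshape(4, C, O)  # (u*2+v, C, O)
    y = np.einsum("bhwc,uco->bhwuo", x.data, wm, optimize=True)
    y = y.reshape(B, H, W, 2, 2, O).transpose(0, 1, 3, 2, 4, 5).reshape(B, 2 * H, 2 * W, O)
    out_data = np.ascontiguousarray(y)
    if b is not None:
        out_data += b.data

    def _g6(g):
        return g.reshape(B, H, 2, W, 2, O).transpose(0, 1, 3, 2, 4, 5).reshape(B, H, W, 4, O)

    def pull_x(g):
        g6 = _g6(g)  # (B,H,W,4,O)
        return np.einsum("bhwuo,uco->bhwc", g6, wm, optimize=True)

    def pull_w(g):
        g6 = _g6(g)
        dwm = np.einsum("bhwc,bhwuo->uco", x.data, g6, optimize=True)  # (4,C,O)
        return dwm.reshape(2, 2, C, O).transpose(2, 3, 0, 1)

    parents = [(x, pull_x), (w, pull_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 1, 2))))
    return Tensor(out_data, True, parents)


def avg_pool2(x: Tensor) -> Tensor:
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 needs even spatial dims")
    r = x.data.reshape(B, H // 2, 2, W // 2, 2, C)
    out = r.mean(axis=(2, 4))

    def pull(g):
        return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * F32(0.25)

    return Tensor(out, True, [(x, pull)])


def max_pool2(x: Tensor) -> Tensor:
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2 needs even spatial dims")
    r = x.data.reshape(B, H // 2, 2, W // 2, 2, C)
    out = r.max(axis=(2, 4))
    mask = r == out[:, :, None, :, None, :]
    count = mask.sum(axis=(2, 4), keepdims=True)  # split gradient across ties

    def pull(g):
        gr = (mask / count) * g[:, :, None, :, None, :]
        return gr.reshape(B, H, W, C)

    return Tensor(out, True, [(x, pull)])


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, True, [(x, lambda g: g * mask)])


def concat(xs: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel (last) axis: dense-block / skip wiring."""
    data = np.concatenate([t.data for t in xs], axis=-1)
    parents = []
    start = 0
    for t in xs:
        c = t.data.shape[-1]
        s = slice(start, start + c)
        parents.append((t, (lambda sl: lambda g: g[..., sl])(s)))
        start += c
    return Tensor(data, True, parents)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (B, H, W).  In training mode
    batch statistics are used and the running estimates updated in place; in
    eval mode the running estimates are used."""
    B, H, W, C = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        n = B * H * W
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    invstd = (1.0 / np.sqrt(var + eps)).astype(F32)
    xhat = (x.data - mu) * invstd
    out = gamma.data * xhat + beta.data

    def pull_x(g):
        dxhat = g * gamma.data
        if not training:
            return dxhat * invstd
        n = B * H * W
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (invstd / n) * (n * dxhat - s1 - xhat * s2)

    parents = [
        (x, pull_x),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 1, 2))),
        (beta, lambda g: g.sum(axis=(0, 1, 2))),
    ]
    return Tensor(out, True, parents)


def npcc_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over the batch of the negative Pearson correlation between each
    predicted image and its ground truth (the training loss; -1 is perfect)."""
    t = np.asarray(target, dtype=F32)
    if t.shape != pred.data.shape:
        raise ValueError(f"target shape {t.shape} != prediction shape {pred.data.shape}")
    B = pred.data.shape[0]
    Y = pred.data.reshape(B, -1).astype(np.float64)
    G = t.reshape(B, -1).astype(np.float64)
    y = Y - Y.mean(axis=1, keepdims=True)
    g = G - G.mean(axis=1, keepdims=True)
    sy = np.sqrt((y * y).sum(axis=1))
    sg = np.sqrt((g * g).sum(axis=1))
    if np.any(sy == 0) or np.any(sg == 0):
        raise ValueError("NPCC loss undefined for a constant image in the batch")
    r = (y * g).sum(axis=1) / (sy * sg)
    loss_val = -r.mean()

    def pull(gout):
        # d(-mean r)/dY_b = -(g/(sy sg) - r y / sy^2) / B, already zero-mean
        scale = float(gout) / B
        dY = -(g / (sy * sg)[:, None] - (r / sy**2)[:, None] * y) * scale
        return dY.reshape(pred.data.shape).astype(F32)

    return Tensor(np.float32(loss_val), True, [(pred, pull)])
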