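"""Layer objects over the autograd ops: parameter containers with He-uniform
initialization, train/eval switching and named-parameter traversal."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import (
    Tensor,
    avg_pool2,
    batch_norm2d,
    concat,
    conv2d,
    conv_transpose2x2,
    max_pool2,
    relu,
)

__all__ = ["Module", "Conv2d", "ConvTranspose2x2", "BatchNorm2d"]

F32 = np.float32


class Module:
    """Minimal layer/container base: child modules and Tensor parameters are
    discovered from instance attributes."""

    training: bool = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = state[name].astype(F32).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{i}.running_mean"].astype(F32).copy()
                m.running_var = state[f"__bn{i}.running_var"].astype(F32).copy()
        return self


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(F32)


class Conv2d(Module):
    """Same-padded (odd-kernel) convolution, optionally dilated; weights are
    stored (k, k, in, out) to match the channels-last activations."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dilation: int = 1):
        self.in_ch, self.out_ch, self.kernel, self.dilation = in_ch, out_ch, kernel, dilation
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_uniform(rng, (kernel, kernel, in_ch, out_ch), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=F32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """Stride-2 2x2 transpose convolution (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Tensor(_he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=F32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.n_ch = n_ch
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(n_ch, dtype=F32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=F32), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )
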