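"""LGDiffNet: a dense encoder-decoder for reconstructing phase objects from
multi-mode speckle acquisitions.

Structure (defaults in parentheses):

* input block — three parallel 5x5 convolutions of 8 kernels each with
  dilations 1, 2 and 3, concatenated to 24 feature maps, then 2x2 average
  pooling;
* encoder — ``stages`` (5) repetitions of: transition layer
  (BN -> ReLU -> 5x5 convolution with ``transition_base * 2^i`` kernels,
  i the stage number, base 16 giving 2^(4+i)), dense block (4 convolutions of
  16 kernels, each preceded by BN + ReLU, densely concatenated), 2x2 max
  pooling; the pre-pool feature maps feed the decoder skip connections;
* bottleneck — one transition + dense block;
* decoder — mirrored stages of 2x2 transpose-convolution upsampling,
  concatenation with the matching encoder features, transition and dense
  block;
* output — one more 2x2 transpose-convolution upsample (balancing the
  initial average pool) and a final 5x5 convolution to 1 channel, linear
  activation (the NPCC loss is affine-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, avg_pool2, concat, max_pool2, relu
from .layers import BatchNorm2d, Conv2d, ConvTranspose2x2, Module

__all__ = ["NetworkConfig", "InputBlock", "Transition", "DenseBlock", "LGDiffNet", "layer_graph"]


@dataclass(frozen=True)
class NetworkConfig:
    input_side: int = 256
    input_channels: int = 3
    stages: int = 5
    input_block_kernels: int = 8
    dilations: tuple[int, ...] = (1, 2, 3)
    kernel_size: int = 5
    transition_base: int = 16  # stage i transition has transition_base * 2**i kernels
    dense_convs: int = 4
    dense_growth: int = 16
    output_channels: int = 1

    def __post_init__(self):
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if self.input_side % (2 ** (self.stages + 1)) != 0:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by 2^(stages+1) = {2**(self.stages+1)}"
            )
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same padding)")

    def transition_kernels(self, stage: int) -> int:
        """Kernel count of the transition layer at encoder/decoder stage i
        (1-based); the bottleneck is stage stages + 1."""
        return self.transition_base * 2**stage

    def to_dict(self) -> dict:
        return asdict(self)


# Full-scale configuration of the published architecture and a desk-scale
# variant small enough for CPU end-to-end runs.
FULL_NET = NetworkConfig()
DESK_NET = NetworkConfig(
    input_side=64, stages=2, kernel_size=3, transition_base=8, dense_growth=8,
    input_block_kernels=8,
)


class InputBlock(Module):
    """Three parallel dilated convolutions concatenated, then average pool."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.branches = [
            Conv2d(cfg.input_channels, cfg.input_block_kernels, cfg.kernel_size, rng, dilation=d)
            for d in cfg.dilations
        ]
        self.out_channels = cfg.input_block_kernels * len(cfg.dilations)

    def __call__(self, x: Tensor) -> Tensor:
        feats = concat([b(x) for b in self.branches])
        return avg_pool2(feats)


class Transition(Module):
    """BN -> ReLU -> convolution, resetting the channel count."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng):
        self.bn = BatchNorm2d(in_ch)
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.out_channels = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(relu(self.bn(x)))


class DenseBlock(Module):
    """dense_convs convolutions of dense_growth kernels; layer j consumes the
    concatenation of the block input and all previous layers' outputs, each
    convolution preceded by BN + ReLU.  Output channels =
    in_ch + dense_convs * dense_growth."""

    def __init__(self, in_ch: int, cfg: NetworkConfig, rng):
        self.bns, self.convs = [], []
        ch = in_ch
        for _ in range(cfg.dense_convs):
            self.bns.append(BatchNorm2d(ch))
            self.convs.append(Conv2d(ch, cfg.dense_growth, cfg.kernel_size, rng))
            ch += cfg.dense_growth
        self.out_channels = ch

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for bn, conv in zip(self.bns, self.convs):
            inp = feats[0] if len(feats) == 1 else concat(feats)
            feats.append(conv(relu(bn(inp))))
        return concat(feats)


class LGDiffNet(Module):
    """The full encoder-decoder; deterministic under (config, seed)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        k = cfg.kernel_size
        self.input_block = InputBlock(cfg, rng)
        ch = self.input_block.out_channels

        self.enc_transitions, self.enc_dense = [], []
        skip_channels = []
        for i in range(1, cfg.stages + 1):
            t = Transition(ch, cfg.transition_kernels(i), k, rng)
            d = DenseBlock(t.out_channels, cfg, rng)
            self.enc_transitions.append(t)
            self.enc_dense.append(d)
            skip_channels.append(d.out_channels)
            ch = d.out_channels

        self.bottleneck_t = Transition(ch, cfg.transition_kernels(cfg.stages + 1), k, rng)
        self.bottleneck_d = DenseBlock(self.bottleneck_t.out_channels, cfg, rng)
        ch = self.bottleneck_d.out_channels

        self.dec_up, self.dec_transitions, self.dec_dense = [], [], []
        for j in range(cfg.stages, 0, -1):
            up = ConvTranspose2x2(ch, cfg.transition_kernels(j), rng)
            t = Transition(up.out_ch + skip_channels[j - 1], cfg.transition_kernels(j), k, rng)
            d = DenseBlock(t.out_channels, cfg, rng)
            self.dec_up.append(up)
            self.dec_transitions.append(t)
            self.dec_dense.append(d)
            ch = d.out_channels

        self.final_up = ConvTranspose2x2(ch, cfg.transition_base, rng)
        self.final_conv = Conv2d(cfg.transition_base, cfg.output_channels, k, rng)

    def __call__(self, x) -> Tensor:
        """Forward pass; x is (B, H, W, 3) channels-last."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim != 4 or x.data.shape[-1] != self.cfg.input_channels:
            raise ValueError(
                f"expected (B, H, W, {self.cfg.input_channels}) input, got {x.data.shape}"
            )
        h = self.input_block(x)
        skips = []
        for t, d in zip(self.enc_transitions, self.enc_dense):
            h = d(t(h))
            skips.append(h)
            h = max_pool2(h)
        h = self.bottleneck_d(self.bottleneck_t(h))
        for up, t, d in zip(self.dec_up, self.dec_transitions, self.dec_dense):
            h = up(h)
            h = concat([h, skips.pop()])
            h = d(t(h))
        return self.final_conv(self.final_up(h))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass returning a plain array (B, H, W, 1)."""
        was_training = self.training
        self.eval()
        out = self(Tensor(x)).data
        if was_training:
            self.train()
        return out


def layer_graph(cfg: NetworkConfig) -> list[dict]:
    """Symbolic layer table: name, kind, output shape (C, H, W), parameter
    count and skip/dense connectivity — a pure function of the config."""
    k2 = cfg.kernel_size**2
    rows: list[dict] = []
    side = cfg.input_side

    def add(name, kind, ch, side, params, connects_to=()):
        rows.append(
            {"name": name, "kind": kind, "out_shape": (ch, side, side),
             "params": params, "connects_to": list(connects_to)}
        )

    add("input", "input", cfg.input_channels, side, 0)
    nb = cfg.input_block_kernels
    for d in cfg.dilations:
        add(f"input_block/dil{d}", "conv", nb, side,
            (cfg.input_channels * k2 + 1) * nb, ["input"])
    ch = nb * len(cfg.dilations)
    add("input_block/concat", "concat", ch, side, 0,
        [f"input_block/dil{d}" for d in cfg.dilations])
    side //= 2
    add("input_block/avgpool", "avgpool", ch, side, 0, ["input_block/concat"])

    def transition(name, ch_in, ch_out, side, prev):
        add(name, "transition", ch_out, side, 2 * ch_in + (ch_in * k2 + 1) * ch_out, [prev])
        return ch_out

    def dense(name, ch_in, side, prev):
        ch = ch_in
        p = 0
        for j in range(cfg.dense_convs):
            p += 2 * ch + (ch * k2 + 1) * cfg.dense_growth
            ch += cfg.dense_growth
        add(name, "dense_block", ch, side, p, [prev])
        return ch

    skip_info = []
    prev = "input_block/avgpool"
    for i in range(1, cfg.stages + 1):
        ch = transition(f"enc{i}/transition", ch, cfg.transition_kernels(i), side, prev)
        ch = dense(f"enc{i}/dense", ch, side, f"enc{i}/transition")
        skip_info.append((f"enc{i}/dense", ch))
        side //= 2
        add(f"enc{i}/maxpool", "maxpool", ch, side, 0, [f"enc{i}/dense"])
        prev = f"enc{i}/maxpool"

    ch = transition("bottleneck/transition", ch, cfg.transition_kernels(cfg.stages + 1), side, prev)
    ch = dense("bottleneck/dense", ch, side, "bottleneck/transition")
    prev = "bottleneck/dense"

    for j in range(cfg.stages, 0, -1):
        out = cfg.transition_kernels(j)
        side *= 2
        add(f"dec{j}/up", "transpose_conv", out, side, (ch * 4 + 1) * out, [prev])
        skip_name, skip_ch = skip_info[j - 1]
        add(f"dec{j}/concat", "concat", out + skip_ch, side, 0, [f"dec{j}/up", skip_name])
        ch = transition(f"dec{j}/transition", out + skip_ch, out, side, f"dec{j}/concat")
        ch = dense(f"dec{j}/dense", ch, side, f"dec{j}/transition")
        prev = f"dec{j}/dense"

    side *= 2
    add("final/up", "transpose_conv", cfg.transition_base, side, (ch * 4 + 1) * cfg.transition_base, [prev])
    add("final/conv", "conv", cfg.output_channels, side,
        (cfg.transition_base * k2 + 1) * cfg.output_channels, ["final/up"])
    return rows


def summary(cfg: NetworkConfig) -> str:
    rows = layer_graph(cfg)
    lines = [f"{'layer':<24}{'kind':<16}{'out shape':<18}{'params':>10}"]
    for r in rows:
        c, h, w = r["out_shape"]
        lines.append(f"{r['name']:<24}{r['kind']:<16}{f'{c}x{h}x{w}':<18}{r['params']:>10}")
    lines.append(f"{'total':<58}{sum(r['params'] for r in rows):>10}")
    return "\n".join(lines)
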