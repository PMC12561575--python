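"""SECA: joint channel-spatial attention replacing squeeze-and-excitation.

The block has two multiplicative gates:

* a **channel gate** — the spatially averaged channel descriptor is passed
  through a local 1-D convolution across the channel axis (kernel ``k``,
  zero-padded, no bias) and a sigmoid, yielding one gain in (0, 1) per
  channel.  The 1-D convolution replaces the two fully connected layers of
  squeeze-and-excitation, so the gate costs only ``k`` parameters.
* a **spatial gate** — two 7x7 convolutions (C -> max(8, ceil(C/4)) -> 1,
  reduction ratio 4) followed by a sigmoid produce one gain in (0, 1) per
  spatial position.

``seca_apply`` composes them sequentially, channel first:

    y = x * g_ch(x) * g_sp(x * g_ch(x))

Inside the inverted-bottleneck network the channel gate sits at the classic
squeeze-and-excitation position (on the expanded features) and the spatial
gate acts on the block output; the standalone :class:`SECABlock` applies both
to the same feature map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "SECAConfig",
    "adaptive_channel_kernel",
    "ChannelGate1D",
    "SpatialGate",
    "SECABlock",
    "channel_gate",
    "spatial_gate",
    "seca_apply",
]


def adaptive_channel_kernel(channels: int) -> int:
    """Odd 1-D kernel width for the channel gate: nearest odd to log2(C)/2 + 1/2, >= 3."""
    t = math.log2(channels) / 2.0 + 0.5
    k = 2 * int(round((t - 1.0) / 2.0)) + 1
    return max(3, k)


@dataclass
class SECAConfig:
    channels: int
    channel_kernel: int | None = None  # None -> adaptive rule
    spatial_ratio: int = 4
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.channels <= 0:
            raise ValueError("channels must be positive")
        if self.channel_kernel is None:
            self.channel_kernel = adaptive_channel_kernel(self.channels)
        if self.channel_kernel % 2 == 0:
            raise ValueError("channel gate kernel must be odd")
        if self.spatial_ratio < 1:
            raise ValueError("spatial reduction ratio must be >= 1")

    @property
    def reduced_channels(self) -> int:
        """Hidden width of the spatial gate (min 8 to avoid 1-channel bottlenecks)."""
        return max(8, math.ceil(self.channels / self.spatial_ratio))


class ChannelGate1D(nn.Module):
    """Per-channel sigmoid gains from a local 1-D conv over the pooled descriptor."""

    def __init__(self, channels, kernel=None, rng=None):
        if kernel is None:
            kernel = adaptive_channel_kernel(channels)
        if kernel % 2 == 0:
            raise ValueError("channel gate kernel must be odd")
        self.channels, self.kernel = channels, kernel
        # zero weights: gains start at sigmoid(0) = 0.5 (uniform, noise-free)
        self.weight = nn.Parameter(np.zeros(kernel))

    def gains(self, x):
        """(B, C, H, W) -> (B, C) gains in (0, 1)."""
        s = x.mean(axis=(2, 3))
        pad = self.kernel // 2
        sp = np.pad(s, ((0, 0), (pad, pad)))
        t = np.zeros_like(s)
        for j in range(self.kernel):
            t += self.weight.data[j] * sp[:, j : j + self.channels]
        g = nn.sigmoid(t)
        self._cache = (x, sp, g)
        return g

    def forward(self, x):
        g = self.gains(x)
        return x * g[:, :, None, None]

    def backward(self, grad):
        x, sp, g = self._cache
        b, c, h, w = x.shape
        pad = self.kernel // 2
        gx = grad * g[:, :, None, None]
        gg = np.einsum("bchw,bchw->bc", grad, x)
        gt = gg * g * (1.0 - g)
        dsp = np.zeros_like(sp)
        for j in range(self.kernel):
            self.weight.grad[j] += float(np.sum(gt * sp[:, j : j + c]))
            dsp[:, j : j + c] += gt * self.weight.data[j]
        ds = dsp[:, pad : pad + c]
        gx += ds[:, :, None, None] / (h * w)
        return gx

    def macs(self, h, w):
        return self.kernel * self.channels, (h, w)


class SpatialGate(nn.Module):
    """One sigmoid gain per position from a 7x7 two-conv bottleneck."""

    def __init__(self, channels, ratio=4, kernel=7, rng=None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.reduced = max(8, math.ceil(channels / ratio))
        pad = kernel // 2
        self.conv1 = nn.Conv2d(channels, self.reduced, kernel, padding=pad, bias=True, rng=rng)
        self.act = nn.SiLU()
        self.conv2 = nn.Conv2d(self.reduced, 1, kernel, padding=pad, bias=True, rng=rng)
        # zero output conv: the map starts at sigmoid(0) = 0.5 everywhere
        self.conv2.weight.data[...] = 0.0

    def gate_map(self, x):
        """(B, C, H, W) -> (B, 1, H, W) gains in (0, 1)."""
        m = nn.sigmoid(self.conv2(self.act(self.conv1(x))))
        self._cache = (x, m)
        return m

    def forward(self, x):
        return x * self.gate_map(x)

    def backward(self, grad):
        x, m = self._cache
        gx = grad * m
        gm = np.sum(grad * x, axis=1, keepdims=True)
        gm = gm * m * (1.0 - m)
        gx += self.conv1.backward(self.act.backward(self.conv2.backward(gm)))
        return gx

    def macs(self, h, w):
        m1, _ = self.conv1.macs(h, w)
        m2, _ = self.conv2.macs(h, w)
        return m1 + m2, (h, w)


class SECABlock(nn.Module):
    """Sequential channel-then-spatial gating of one feature map."""

    def __init__(self, config: SECAConfig, rng=None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.channel = ChannelGate1D(config.channels, config.channel_kernel, rng=rng)
        self.spatial = SpatialGate(
            config.channels, config.spatial_ratio, config.spatial_kernel, rng=rng
        )

    def forward(self, x):
        return self.spatial(self.channel(x))

    def backward(self, grad):
        return self.channel.backward(self.spatial.backward(grad))

    def num_parameters_closed_form(self):
        """Weight-count arithmetic for the two gates (checked against the arrays)."""
        c, k = self.config.channels, self.config.channel_kernel
        r, q = self.config.reduced_channels, self.config.spatial_kernel
        return k + (q * q * c * r + r) + (q * q * r * 1 + 1)


def _as_batch(x):
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("feature map must be C x H x W")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    return x[None]


def channel_gate(x, cfg: SECAConfig, weights):
    """Per-channel gains in (0, 1) for one C x H x W feature map."""
    g = ChannelGate1D(cfg.channels, cfg.channel_kernel)
    g.weight.data[...] = np.asarray(weights, dtype=np.float32)
    return g.gains(_as_batch(x))[0]


def spatial_gate(x, cfg: SECAConfig, weights):
    """1 x H x W gains in (0, 1); ``weights`` = (w1, b1, w2, b2) conv tensors."""
    g = SpatialGate(cfg.channels, cfg.spatial_ratio, cfg.spatial_kernel)
    w1, b1, w2, b2 = weights
    g.conv1.weight.data[...] = w1
    g.conv1.bias.data[...] = b1
    g.conv2.weight.data[...] = w2
    g.conv2.bias.data[...] = b2
    return g.gate_map(_as_batch(x))[0]


def seca_apply(x, cfg: SECAConfig, channel_weights, spatial_weights):
    """y = x * g_ch(x) * g_sp(x * g_ch(x)) on one C x H x W feature map."""
    xb = _as_batch(x)
    g = ChannelGate1D(cfg.channels, cfg.channel_kernel)
    g.weight.data[...] = np.asarray(channel_weights, dtype=np.float32)
    x1 = g(xb)
    s = SpatialGate(cfg.channels, cfg.spatial_ratio, cfg.spatial_kernel)
    w1, b1, w2, b2 = spatial_weights
    s.conv1.weight.data[...] = w1
    s.conv1.bias.data[...] = b1
    s.conv2.weight.data[...] = w2
    s.conv2.bias.data[...] = b2
    return s(x1)[0]
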