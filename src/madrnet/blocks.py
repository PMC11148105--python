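"""Reusable computational blocks of the segmentation network.

The network is assembled from four kinds of block:

* :class:`ConvUnit` — the pre-activation convolution unit, batch norm ->
  ReLU -> dilated 2-D convolution with "same" zero padding.
* :class:`MultiDilatedResidualBlock` — four parallel dilated branches
  (rates 1, 3, 5, 11 by default), each a stack of two conv units, summed
  element-wise and added to an identity / 1x1-projection shortcut.  A
  dilated k x k kernel sees an effective window of ``k + (k-1)(d-1)``
  pixels at no extra parameter cost, so the branches read the same feature
  map at four receptive-field scales.
* :class:`ASPP` — atrous spatial pyramid pooling: a 1x1 branch, one 3x3
  branch per dilation rate (6, 12, 18 by default) and a global-pooling
  branch, concatenated on channels and fused by a final 1x1 convolution.
* :class:`CSAM` — channel-then-spatial attention (CBAM-style): a per-channel
  sigmoid gate from pooled channel descriptors through a shared two-layer
  perceptron, followed by a per-pixel sigmoid gate from a 7x7 convolution
  over the channel-pooled mean/max maps.

Every block preserves the spatial dimensions of its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class DilationSpec:
    """An odd square kernel together with its dilation rate."""

    kernel_size: int = 3
    dilation_rate: int = 1

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be a positive integer")


@dataclass(frozen=True)
class AttentionConfig:
    """Channel-spatial attention hyper-parameters.

    ``reduction_ratio`` sets the hidden width C/r of the shared perceptron in
    the channel gate; ``spatial_kernel`` is the convolution size of the
    spatial gate; ``mlp_activation`` selects the hidden-layer nonlinearity
    (a leaky rectifier by default: at the very small hidden widths produced
    by C/r a plain ReLU can leave the whole perceptron dead at
    initialization, blocking gradient flow through the gate).
    """

    reduction_ratio: int = 16
    spatial_kernel: int = 7
    mlp_activation: str = "leaky_relu"  # leaky_relu | relu | none

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be positive")
        if self.mlp_activation not in ("leaky_relu", "relu", "none"):
            raise ValueError("mlp_activation must be leaky_relu, relu or none")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be a positive odd integer")


def effective_kernel_size(spec: DilationSpec | int, dilation_rate: int | None = None) -> int:
    """Effective window of a dilated kernel: ``k + (k-1)(d-1)`` pixels.

    Accepts either a :class:`DilationSpec` or ``(k, d)`` as two integers.
    Equals ``k`` when ``d == 1``; a 1x1 kernel is dilation-invariant.
    """
    if isinstance(spec, DilationSpec):
        k, d = spec.kernel_size, spec.dilation_rate
    else:
        k, d = int(spec), int(dilation_rate)
        if k < 1 or d < 1:
            raise ValueError("kernel size and dilation rate must be positive")
    return k + (k - 1) * (d - 1)


# -------------------------------------------------------------------- blocks
class ConvUnit(nn.Module):
    """Pre-activation unit: batch normalization -> ReLU -> dilated conv."""

    def __init__(self, in_channels: int, out_channels: int,
                 spec: DilationSpec = DilationSpec(), *, rng: np.random.Generator):
        super().__init__()
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, out_channels, spec.kernel_size,
                              dilation=spec.dilation_rate, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(ag.relu(self.bn(x)))


class MultiDilatedResidualBlock(nn.Module):
    """Parallel dilated branches plus a residual shortcut.

    Each branch stacks ``convs_per_branch`` conv units at its dilation rate;
    branch outputs are summed element-wise (rate-ascending order, for
    bit-reproducibility) and added to the shortcut: identity when channel
    counts match, a bias-free 1x1 projection otherwise.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rates: tuple[int, ...] = (1, 3, 5, 11), convs_per_branch: int = 2,
                 *, rng: np.random.Generator):
        super().__init__()
        if not rates:
            raise ValueError("at least one dilation rate is required")
        if convs_per_branch < 1:
            raise ValueError("convs_per_branch must be >= 1")
        self.rates = tuple(sorted(int(r) for r in rates))
        self.branches = nn.ModuleList()
        for r in self.rates:
            units = nn.ModuleList()
            cin = in_channels
            for _ in range(convs_per_branch):
                units.append(ConvUnit(cin, out_channels, DilationSpec(3, r), rng=rng))
                cin = out_channels
            self.branches.append(units)
        if in_channels != out_channels:
            self.projection = nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
        else:
            self.projection = None

    def forward(self, x: Tensor) -> Tensor:
        shortcut = self.projection(x) if self.projection is not None else x
        out = None
        for units in self.branches:
            h = x
            for u in units:
                h = u(h)
            out = h if out is None else out + h
        return shortcut + out


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling with an image-pooling branch.

    Branch layout (``len(rates) + 2`` parallel branches): a 1x1 convolution,
    one 3x3 convolution per dilation rate, and a global-pooling branch
    (global average or max pool -> 1x1 convolution -> broadcast back to
    H x W).  Each branch emits ``out_channels // 4`` channels — the pyramid
    is split into four equal-width dilation partitions, the pooling branch
    matching them — and the concatenation is fused by a final 1x1
    convolution to ``out_channels``.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rates: tuple[int, ...] = (6, 12, 18), pool_mode: str = "avg",
                 branch_channels: int | None = None, *, rng: np.random.Generator):
        super().__init__()
        if pool_mode not in ("avg", "max"):
            raise ValueError("pool_mode must be 'avg' or 'max'")
        self.rates = tuple(int(r) for r in rates)
        self.pool_mode = pool_mode
        w = branch_channels if branch_channels is not None else max(out_channels // 4, 1)
        self.conv1x1 = nn.Conv2d(in_channels, w, 1, rng=rng)
        self.dilated = nn.ModuleList(
            [nn.Conv2d(in_channels, w, 3, dilation=r, rng=rng) for r in self.rates]
        )
        self.pool_conv = nn.Conv2d(in_channels, w, 1, rng=rng)
        self.fuse = nn.Conv2d(w * (len(self.rates) + 2), out_channels, 1, rng=rng)

    @property
    def n_branches(self) -> int:
        return len(self.rates) + 2

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        outs = [self.conv1x1(x)]
        outs += [conv(x) for conv in self.dilated]
        if self.pool_mode == "avg":
            pooled = x.mean(axis=(2, 3), keepdims=True)
        else:
            pooled = x.max(axis=(2, 3), keepdims=True)
        p = self.pool_conv(pooled)
        outs.append(ag.broadcast_to(p, (N, p.shape[1], H, W)))
        return self.fuse(ag.concat(outs, axis=1))


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gate from pooled descriptors.

    ``W_C(F) = sigmoid(W1(W0(avgpool(F))) + W1(W0(maxpool(F))))`` with a
    shared two-layer perceptron of hidden width ``max(C // r, 1)``.  Output
    shape is (N, C, 1, 1) with values strictly in (0, 1).
    """

    def __init__(self, channels: int, cfg: AttentionConfig = AttentionConfig(),
                 *, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.cfg = cfg
        hidden = max(channels // cfg.reduction_ratio, 1)
        self.w0 = nn.Linear(channels, hidden, bias=False, rng=rng)
        self.w1 = nn.Linear(hidden, channels, bias=False, rng=rng)

    def _mlp(self, desc: Tensor) -> Tensor:
        h = self.w0(desc)
        if self.cfg.mlp_activation == "relu":
            h = ag.relu(h)
        elif self.cfg.mlp_activation == "leaky_relu":
            h = ag.leaky_relu(h)
        return self.w1(h)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        flat = x.reshape((N, C, H * W))
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        gate = ag.sigmoid(self._mlp(avg) + self._mlp(mx))
        return gate.reshape((N, C, 1, 1))


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid gate from channel-pooled mean/max maps.

    The channel-wise average and maximum maps are concatenated into a
    2-channel image and convolved with a single 7x7 kernel, then passed
    through a sigmoid.  Output shape is (N, 1, H, W).
    """

    def __init__(self, cfg: AttentionConfig = AttentionConfig(), *, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, cfg.spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=1)))


class CSAM(nn.Module):
    """Sequential channel-spatial attention: F2 = W_S(F1) * F1, F1 = W_C(F) * F."""

    def __init__(self, channels: int, cfg: AttentionConfig = AttentionConfig(),
                 *, rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, cfg, rng=rng)
        self.spatial = SpatialAttention(cfg, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        f1 = self.channel(x) * x
        return self.spatial(f1) * f1
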