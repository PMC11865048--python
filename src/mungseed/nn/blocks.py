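"""Building blocks: inverted residual bottleneck, ECA and DMS attention.

The bottleneck follows the MobileNetV2 pattern (1x1 expand -> 3x3 depthwise
-> 1x1 linear projection, shortcut at stride 1 with matching channels). The
``hp`` variant additionally gates the depthwise stage with a DMS block
(pool, two depthwise 3x3 convolutions with Mish and Sigmoid, residual join),
reweights the projection output with an ECA block, and uses Mish wherever
the baseline uses ReLU6.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .core import Module, Sequential
from .layers import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    ChannelConv1d,
    Conv2d,
    Mish,
    ReLU6,
    Sigmoid,
    UpsampleNearest2d,
)

__all__ = [
    "eca_kernel_size",
    "EcaBlock",
    "DmsBlock",
    "ConvBNAct",
    "InvertedResidual",
]


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel width for efficient channel attention.

    k is derived from the channel count via s = (log2 C + b) / gamma,
    truncated and bumped to the next odd integer when even (so C = 2^(gamma*k - b)
    channels map back to kernel k). Always odd and >= 1.
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    s = (math.log2(channels) + b) / gamma
    k = int(s)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


class EcaBlock(Module):
    """Efficient channel attention: GAP -> width-k 1-D conv -> sigmoid gate.

    Adds exactly k learnable weights (the shared 1-D kernel, no bias).
    """

    def __init__(self, channels: int, gamma: int = 2, b: int = 1, rng=None):
        self.channels = channels
        self.kernel_size = eca_kernel_size(channels, gamma, b)
        self.conv = ChannelConv1d(self.kernel_size, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        y = x.mean(axis=(2, 3))              # (N, C) channel descriptor
        z = self.conv.forward(y)
        gate = F.sigmoid(z)
        self._cache = (x, z, gate, h * w)
        return x * gate[:, :, None, None]

    def backward(self, grad_out):
        x, z, gate, hw = self._cache
        gx = grad_out * gate[:, :, None, None]
        grad_gate = (grad_out * x).sum(axis=(2, 3))
        grad_z = grad_gate * gate * (1.0 - gate)
        grad_y = self.conv.backward(grad_z)
        gx += (grad_y / hw)[:, :, None, None]
        self._cache = None
        return gx


class DmsBlock(Module):
    """Depthwise-Mish-Sigmoid gate with a residual join.

    The input feature map is average-pooled to ``pooled_size``^2, passed
    through two depthwise 3x3 convolutions (bias on the first only) with Mish
    and Sigmoid activations, upsampled back (nearest neighbour) and used as a
    multiplicative gate combined with an additive residual:
    ``out = x + x * gate``. Learnable parameters: 19 per channel.
    """

    def __init__(self, channels: int, pooled_size: int = 5, rng=None):
        self.channels = channels
        self.pooled_size = pooled_size
        self.pool = AdaptiveAvgPool2d(pooled_size)
        self.conv1 = Conv2d(channels, channels, 3, padding=1, groups=channels,
                            bias=True, rng=rng)
        self.act1 = Mish()
        self.conv2 = Conv2d(channels, channels, 3, padding=1, groups=channels,
                            bias=False, rng=rng)
        self.act2 = Sigmoid()
        self.up = UpsampleNearest2d((1, 1))  # retargeted on every forward

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        self.up.target_size = (h, w)
        g = self.pool.forward(x)
        g = self.conv1.forward(g)
        g = self.act1.forward(g)
        g = self.conv2.forward(g)
        g = self.act2.forward(g)
        gate = self.up.forward(g)
        self._cache = (x, gate)
        return x + x * gate

    def backward(self, grad_out):
        x, gate = self._cache
        gx = grad_out * (1.0 + gate)
        grad_gate = grad_out * x
        g = self.up.backward(grad_gate)
        g = self.act2.backward(g)
        g = self.conv2.backward(g)
        g = self.act1.backward(g)
        g = self.conv1.backward(g)
        gx += self.pool.backward(g)
        self._cache = None
        return gx


class ConvBNAct(Module):
    """Convolution (no bias) + batch norm + optional activation."""

    def __init__(self, in_c, out_c, kernel_size, stride=1, groups=1,
                 activation="relu6", rng=None):
        padding = (kernel_size - 1) // 2
        self.conv = Conv2d(in_c, out_c, kernel_size, stride=stride,
                           padding=padding, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_c)
        if activation is None:
            self.act = None
        elif activation == "relu6":
            self.act = ReLU6()
        elif activation == "mish":
            self.act = Mish()
        else:
            raise ValueError(f"unknown activation {activation!r}")

    def forward(self, x):
        x = self.bn.forward(self.conv.forward(x))
        return self.act.forward(x) if self.act is not None else x

    def backward(self, grad_out):
        if self.act is not None:
            grad_out = self.act.backward(grad_out)
        return self.conv.backward(self.bn.backward(grad_out))


class InvertedResidual(Module):
    """MobileNetV2 bottleneck, optionally with DMS/ECA (``variant='hp'``)."""

    def __init__(self, in_c, out_c, expansion, stride, variant="baseline",
                 dms_pooled_size=5, rng=None):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        if expansion < 1:
            raise ValueError(f"expansion factor must be >= 1, got {expansion}")
        if variant not in ("baseline", "hp"):
            raise ValueError(f"unknown variant {variant!r}")
        self.in_c, self.out_c, self.stride = in_c, out_c, stride
        self.expansion = expansion
        self.variant = variant
        self.use_shortcut = stride == 1 and in_c == out_c
        hidden = in_c * expansion
        self.hidden_channels = hidden
        act = "mish" if variant == "hp" else "relu6"
        layers = []
        if expansion != 1:
            layers.append(ConvBNAct(in_c, hidden, 1, activation=act, rng=rng))
        layers.append(ConvBNAct(hidden, hidden, 3, stride=stride, groups=hidden,
                                activation=act, rng=rng))
        if variant == "hp":
            layers.append(DmsBlock(hidden, pooled_size=dms_pooled_size, rng=rng))
        layers.append(ConvBNAct(hidden, out_c, 1, activation=None, rng=rng))
        if variant == "hp":
            layers.append(EcaBlock(out_c, rng=rng))
        self.body = Sequential(*layers)

    def forward(self, x):
        out = self.body.forward(x)
        return x + out if self.use_shortcut else out

    def backward(self, grad_out):
        gx = self.body.backward(grad_out)
        return gx + grad_out if self.use_shortcut else gx
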