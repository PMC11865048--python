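"""Differentiable layers: convolutions, batch normalisation, pooling.

Convolutions are evaluated by an im2col/matmul scheme (depthwise layers get
a dedicated einsum path so a 960-group convolution does not degenerate into
a Python loop). All arrays are NCHW float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import functional as F
from .core import Module, Param

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "Activation",
    "ReLU6",
    "Mish",
    "Sigmoid",
    "AdaptiveAvgPool2d",
    "UpsampleNearest2d",
    "Flatten",
    "Linear",
    "ChannelConv1d",
]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class Conv2d(Module):
    """2-D convolution with group support (G=1 standard, G=C_in depthwise)."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = _pair(kernel_size)
        self.stride = _pair(stride)
        self.padding = _pair(padding)
        self.groups = groups
        kh, kw = self.kernel_size
        rng = rng or np.random.default_rng(0)
        # Kaiming-normal, fan_out mode (matches common CNN initialisation)
        std = np.sqrt(2.0 / (kh * kw * out_channels))
        self.weight = Param(rng.normal(0.0, std, (out_channels, in_channels // groups, kh, kw)))
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self._cache = None

    # -- helpers -------------------------------------------------------------
    def _windows(self, x):
        ph, pw = self.padding
        sh, sw = self.stride
        kh, kw = self.kernel_size
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        return x.shape, win  # padded shape, (N, C, Ho, Wo, kh, kw) view

    def _col2im(self, grad_cols, padded_shape):
        """Scatter (N, C, Ho, Wo, kh, kw) window gradients back to the input."""
        n, c, hp, wp = padded_shape
        kh, kw = self.kernel_size
        sh, sw = self.stride
        ho, wo = grad_cols.shape[2], grad_cols.shape[3]
        gx = np.zeros((n, c, hp, wp))
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + ho * sh:sh, j:j + wo * sw:sw] += grad_cols[:, :, :, :, i, j]
        ph, pw = self.padding
        if ph or pw:
            gx = gx[:, :, ph:hp - ph, pw:wp - pw]
        return gx

    # -- forward/backward ----------------------------------------------------
    def forward(self, x):
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N, {self.in_channels}, H, W), got {x.shape}")
        padded_shape, win = self._windows(x)
        n, _, ho, wo = win.shape[:4]
        kh, kw = self.kernel_size
        g = self.groups
        if g == 1:
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
            wmat = self.weight.value.reshape(self.out_channels, -1)
            out = (cols @ wmat.T).reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
            self._cache = ("standard", padded_shape, cols, (n, ho, wo))
        elif g == self.in_channels == self.out_channels:
            out = np.einsum("nchwij,cij->nchw", win, self.weight.value[:, 0], optimize=True)
            self._cache = ("depthwise", padded_shape, win, None)
        else:
            cig = self.in_channels // g
            cog = self.out_channels // g
            out = np.empty((n, self.out_channels, ho, wo))
            cols_g = []
            for gi in range(g):
                sub = win[:, gi * cig:(gi + 1) * cig]
                cols = sub.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
                wmat = self.weight.value[gi * cog:(gi + 1) * cog].reshape(cog, -1)
                out[:, gi * cog:(gi + 1) * cog] = (
                    (cols @ wmat.T).reshape(n, ho, wo, cog).transpose(0, 3, 1, 2))
                cols_g.append(cols)
            self._cache = ("grouped", padded_shape, cols_g, (n, ho, wo))
        if self.bias is not None:
            out = out + self.bias.value[None, :, None, None]
        self.last_output_hw = (ho, wo)  # read by the cost profiler
        return out

    def backward(self, grad_out):
        mode, padded_shape, cache, dims = self._cache
        kh, kw = self.kernel_size
        g = self.groups
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        if mode == "standard":
            n, ho, wo = dims
            gmat = grad_out.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_channels)
            self.weight.grad += (gmat.T @ cache).reshape(self.weight.value.shape)
            grad_cols = gmat @ self.weight.value.reshape(self.out_channels, -1)
            grad_cols = grad_cols.reshape(n, ho, wo, self.in_channels, kh, kw)
            grad_cols = grad_cols.transpose(0, 3, 1, 2, 4, 5)
        elif mode == "depthwise":
            win = cache
            self.weight.grad[:, 0] += np.einsum("nchw,nchwij->cij", grad_out, win, optimize=True)
            grad_cols = grad_out[:, :, :, :, None, None] * self.weight.value[:, 0][None, :, None, None]
        else:
            n, ho, wo = dims
            cig = self.in_channels // g
            cog = self.out_channels // g
            grad_cols = np.empty((n, self.in_channels, ho, wo, kh, kw))
            for gi, cols in enumerate(cache):
                sl = slice(gi * cog, (gi + 1) * cog)
                gmat = grad_out[:, sl].transpose(0, 2, 3, 1).reshape(n * ho * wo, cog)
                self.weight.grad[sl] += (gmat.T @ cols).reshape(cog, cig, kh, kw)
                gc = (gmat @ self.weight.value[sl].reshape(cog, -1))
                grad_cols[:, gi * cig:(gi + 1) * cig] = (
                    gc.reshape(n, ho, wo, cig, kh, kw).transpose(0, 3, 1, 2, 4, 5))
        self._cache = None
        return self._col2im(grad_cols, padded_shape)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with affine parameters.

    Training mode normalises with batch statistics and tracks running
    moments; eval mode uses the running moments.
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache = None

    def forward(self, x):
        if x.shape[1] != self.num_features:
            raise ValueError(f"expected {self.num_features} channels, got {x.shape[1]}")
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        self.last_elems_per_sample = x[0].size  # read by the cost profiler
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, self.training)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad_out):
        xhat, inv_std, was_training = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        gs = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not was_training:
            self._cache = None
            return grad_out * gs
        m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        mean_g = grad_out.mean(axis=axes)[None, :, None, None]
        mean_gx = (grad_out * xhat).mean(axis=axes)[None, :, None, None]
        self._cache = None
        return gs * (grad_out - mean_g - xhat * mean_gx)


class Activation(Module):
    """Elementwise activation defined by a function/derivative pair."""

    fn = staticmethod(lambda x: x)
    grad_fn = staticmethod(lambda x: np.ones_like(x))

    def forward(self, x):
        self._x = x
        return self.fn(x)

    def backward(self, grad_out):
        g = grad_out * self.grad_fn(self._x)
        self._x = None
        return g


class ReLU6(Activation):
    fn = staticmethod(F.relu6)
    grad_fn = staticmethod(F.relu6_grad)


class Mish(Activation):
    fn = staticmethod(F.mish)
    grad_fn = staticmethod(F.mish_grad)


class Sigmoid(Activation):
    fn = staticmethod(F.sigmoid)
    grad_fn = staticmethod(F.sigmoid_grad)


def _bin_edges(n_in, n_out):
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)  # ceil division
    return starts, ends


class AdaptiveAvgPool2d(Module):
    """Average pooling to a fixed output size with torch-style bins.

    Output sizes larger than the input fall back to the input size (no
    upsampling is invented by the pool); callers that need a fixed spatial
    size afterwards should combine with :class:`UpsampleNearest2d`.
    """

    def __init__(self, output_size):
        self.output_size = _pair(output_size)

    def forward(self, x):
        n, c, h, w = x.shape
        oh = min(self.output_size[0], h)
        ow = min(self.output_size[1], w)
        self._in_shape = x.shape
        if oh == h and ow == w:
            self._bins = None
            return x.copy()
        if (oh, ow) == (1, 1):
            self._bins = "global"
            return x.mean(axis=(2, 3), keepdims=True)
        rs, re = _bin_edges(h, oh)
        cs, ce = _bin_edges(w, ow)
        self._bins = (rs, re, cs, ce)
        out = np.empty((n, c, oh, ow))
        for i in range(oh):
            for j in range(ow):
                out[:, :, i, j] = x[:, :, rs[i]:re[i], cs[j]:ce[j]].mean(axis=(2, 3))
        return out

    def backward(self, grad_out):
        n, c, h, w = self._in_shape
        if self._bins is None:
            return grad_out
        gx = np.zeros(self._in_shape)
        if self._bins == "global":
            gx += grad_out / (h * w)
            return gx
        rs, re, cs, ce = self._bins
        for i in range(grad_out.shape[2]):
            for j in range(grad_out.shape[3]):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                gx[:, :, rs[i]:re[i], cs[j]:ce[j]] += grad_out[:, :, i, j, None, None] / area
        return gx


class UpsampleNearest2d(Module):
    """Nearest-neighbour resize to an explicit target (H, W)."""

    def __init__(self, target_size):
        self.target_size = _pair(target_size)

    def forward(self, x):
        n, c, h, w = x.shape
        th, tw = self.target_size
        ri = (np.arange(th) * h) // th
        ci = (np.arange(tw) * w) // tw
        self._in_shape, self._ri, self._ci = x.shape, ri, ci
        return x[:, :, ri[:, None], ci[None, :]]

    def backward(self, grad_out):
        gx = np.zeros(self._in_shape)
        np.add.at(gx, (slice(None), slice(None), self._ri[:, None], self._ci[None, :]), grad_out)
        return gx


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(rng.normal(0.0, 0.01, (out_features, in_features)))
        self.bias = Param(np.zeros(out_features)) if bias else None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out = out + self.bias.value
        return out

    def backward(self, grad_out):
        self.weight.grad += grad_out.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=0)
        g = grad_out @ self.weight.value
        self._x = None
        return g


class ChannelConv1d(Module):
    """1-D convolution across the channel axis of (N, C) descriptors.

    Used by the efficient-channel-attention block: a single shared kernel of
    odd width k, zero padding k//2, no bias, so the layer has exactly k
    learnable weights regardless of C.
    """

    def __init__(self, kernel_size, rng=None):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel size must be a positive odd integer")
        self.kernel_size = kernel_size
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / kernel_size)
        self.weight = Param(rng.normal(0.0, std, kernel_size))

    def forward(self, x):
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad)))
        win = sliding_window_view(xp, k, axis=1)  # (N, C, k)
        self._win = win
        self.last_channels = x.shape[1]  # read by the cost profiler
        return win @ self.weight.value

    def backward(self, grad_out):
        k = self.kernel_size
        pad = k // 2
        self.weight.grad += np.einsum("nc,nck->k", grad_out, self._win)
        gxp = np.zeros((grad_out.shape[0], grad_out.shape[1] + 2 * pad))
        for j in range(k):
            gxp[:, j:j + grad_out.shape[1]] += grad_out * self.weight.value[j]
        self._win = None
        return gxp[:, pad:pad + grad_out.shape[1]]
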