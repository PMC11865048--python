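"""Scalar/array activation functions and their derivatives.

The classifier uses three nonlinearities: ReLU6 (the stock MobileNetV2
activation, a rectifier clamped to [0, 6]), Mish (``x * tanh(softplus(x))``,
smooth and non-monotonic with a small negative dip) and the logistic sigmoid
(gating in the attention blocks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relu6",
    "relu6_grad",
    "mish",
    "mish_grad",
    "sigmoid",
    "sigmoid_grad",
    "softplus",
]


def softplus(x):
    """ln(1 + e^x), evaluated stably for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    return np.logaddexp(0.0, x)


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_grad(x):
    s = sigmoid(x)
    return s * (1.0 - s)


def relu6(x):
    return np.clip(np.asarray(x, dtype=np.float64), 0.0, 6.0)


def relu6_grad(x):
    x = np.asarray(x, dtype=np.float64)
    return ((x > 0) & (x < 6)).astype(np.float64)


def mish(x):
    x = np.asarray(x, dtype=np.float64)
    return x * np.tanh(softplus(x))


def mish_grad(x):
    """d/dx [x tanh(softplus x)] = tanh(sp) + x * sech^2(sp) * sigmoid(x)."""
    x = np.asarray(x, dtype=np.float64)
    sp = softplus(x)
    t = np.tanh(sp)
    return t + x * (1.0 - t * t) * sigmoid(x)
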