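"""Differentiable functions with fused hand-derived backward passes.

These are written as single graph nodes (rather than compositions of
primitives) because they sit on the hot path of every transformer block; the
analytic gradients are validated against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["softmax", "log_softmax", "gelu", "dropout", "layer_norm"]

_GELU_C = float(np.sqrt(2.0 / np.pi))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - inner))

    return Tensor._make(out_data, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accum(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """tanh approximation of the Gaussian error linear unit."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    d = x.data
    d2 = d * d
    u = _GELU_C * (d + 0.044715 * d2 * d)
    t = np.tanh(u)
    out_data = 0.5 * d * (1.0 + t)

    def backward(g):
        if x.requires_grad:
            du = _GELU_C * (1.0 + 3 * 0.044715 * d2)
            x._accum(g * (0.5 * (1.0 + t) + 0.5 * d * (1.0 - t**2) * du))

    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learnable scale and shift."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * weight.data + bias.data

    def backward(g):
        if weight.requires_grad:
            axes = tuple(range(g.ndim - 1))
            weight._accum((g * xhat).sum(axis=axes))
        if bias.requires_grad:
            axes = tuple(range(g.ndim - 1))
            bias._accum(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * weight.data
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gh - m1 - xhat * m2))

    return Tensor._make(out_data, (x, weight, bias), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
    return x * Tensor(mask)
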