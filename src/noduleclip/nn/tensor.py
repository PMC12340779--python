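"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the recorded graph
in reverse topological order and accumulates gradients into every tensor with
``requires_grad=True``.  All arithmetic follows numpy broadcasting; gradients
of broadcast operands are summed back to the operand's shape.

The engine supports exactly the primitives the transformer stack needs
(elementwise arithmetic, matmul, exp/log/tanh, reductions, reshaping,
slicing, concatenation, embedding lookup and row gathering).  Dtypes are
preserved, so gradient checks can be run in float64 while training runs in
float32.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat", "stack"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording within the block (inference / parameter updates)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    @classmethod
    def _make(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))

        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _is_scalar(x) -> bool:
        return isinstance(x, (int, float, np.integer, np.floating))

    def __add__(self, other):
        if self._is_scalar(other):
            a = self

            def backward_s(g):
                if a.requires_grad:
                    a._accum(g)

            return Tensor._make(a.data + other, (a,), backward_s)
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        if self._is_scalar(other):
            a = self

            def backward_s(g):
                if a.requires_grad:
                    a._accum(g * other)

            return Tensor._make(a.data * other, (a,), backward_s)
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), backward)

    def __truediv__(self, other):
        if self._is_scalar(other):
            a = self

            def backward_s(g):
                if a.requires_grad:
                    a._accum(g / other)

            return Tensor._make(a.data / other, (a,), backward_s)
        other = self._coerce(other)
        return self * other**-1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self**-1.0

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                if b.data.ndim == 1:
                    ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga.reshape(ga.shape), a.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    gb = np.multiply.outer(a.data, g) if g.ndim else a.data * g
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def sqrt(self):
        return self**0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def broadcast_to(self, shape):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))

        return Tensor._make(np.broadcast_to(a.data, shape).copy(), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), backward)

    # ------------------------------------------------------- gather / embed
    def embedding(self, ids: np.ndarray) -> "Tensor":
        """Row lookup ``self[ids]`` for an integer index array (no grad to ids)."""
        a = self
        ids = np.asarray(ids)

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, ids.reshape(-1), g.reshape(-1, a.data.shape[-1]))
                a._accum(full)

        return Tensor._make(a.data[ids], (a,), backward)

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """For x of shape (B, T, D) return x[i, idx[i], :] of shape (B, D)."""
        a = self
        idx = np.asarray(idx)
        rows = np.arange(a.shape[0])

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[rows, idx] = g
                a._accum(full)

        return Tensor._make(a.data[rows, idx], (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)
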