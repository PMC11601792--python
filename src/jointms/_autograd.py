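"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core under the molecular and spectral encoders: a
:class:`Tensor` wrapping a float64 ndarray, a small set of differentiable
operations (dense algebra plus the segment operations graph batching needs),
and topological-order backpropagation. Only the operations the joint-embedding
model uses are implemented; all arithmetic is float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "relu", "log", "exp",
    "sqrt", "tsum", "gather_rows", "segment_sum", "segment_max", "concat",
]


class Tensor:
    """A node in the computation graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # operator sugar (scalars auto-wrapped)
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out._backward = backward
    return out


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    out._backward = backward
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = backward
    return out


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out.data)

    out._backward = backward
    return out


def sqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / out.data)

    out._backward = backward
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

    out._backward = backward
    return out


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows `idx` (with repetition) from a 2-D tensor."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(a.data[idx], parents=(a,))

    def backward(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accumulate(acc)

    out._backward = backward
    return out


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-add: output[s] = sum of rows with segment_ids == s."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    val = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(val, segment_ids, a.data)
    out = Tensor(val, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[segment_ids])

    out._backward = backward
    return out


def segment_max(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-max (graph readout pooling).

    Gradient flows only to the (first) argmax row of each segment/column,
    matching the subgradient convention of max pooling.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    ncol = a.data.shape[1]
    val = np.full((num_segments, ncol), -np.inf)
    np.maximum.at(val, segment_ids, a.data)
    # locate one argmax row per (segment, column) for the backward pass
    argmax = np.zeros((num_segments, ncol), dtype=np.intp)
    found = np.zeros((num_segments, ncol), dtype=bool)
    for row in range(a.data.shape[0]):
        s = segment_ids[row]
        hit = (~found[s]) & (a.data[row] == val[s])
        argmax[s][hit] = row
        found[s] |= hit
    out = Tensor(val, parents=(a,))

    def backward(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            cols = np.arange(ncol)
            for s in range(num_segments):
                acc[argmax[s], cols] += g[s]
            a._accumulate(acc)

    out._backward = backward
    return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out
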