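"""Minimal reverse-mode automatic differentiation over numpy arrays.

The models in this package are small (dense stacks of <100 units, an 8-cell
bidirectional LSTM unrolled over 5 time steps), so a tape-based scalar-loss
autodiff over float64 numpy arrays is sufficient and keeps every gradient
exactly reproducible.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "matmul",
    "relu", "sigmoid", "tanh", "exp", "log", "absolute", "sqrt", "power",
    "tsum", "tmean", "concat", "log_softmax", "softmax",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from unrolled RNNs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # operator sugar (rhs may be a plain number/array)
    def __add__(self, other): return add(self, _as_tensor(other))
    def __radd__(self, other): return add(_as_tensor(other), self)
    def __sub__(self, other): return sub(self, _as_tensor(other))
    def __rsub__(self, other): return sub(_as_tensor(other), self)
    def __mul__(self, other): return mul(self, _as_tensor(other))
    def __rmul__(self, other): return mul(_as_tensor(other), self)
    def __truediv__(self, other): return div(self, _as_tensor(other))
    def __neg__(self): return neg(self)
    def __matmul__(self, other): return matmul(self, _as_tensor(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes numpy broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return _node(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))
    return _node(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return _node(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
    return _node(a.data / b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, -g)
    return _node(-a.data, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)
    return _node(a.data @ b.data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def bw(g):
        _accum(a, g * mask)
    return _node(np.where(mask, a.data, 0.0), (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    def bw(g):
        _accum(a, g * s * (1.0 - s))
    return _node(s, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    def bw(g):
        _accum(a, g * (1.0 - t * t))
    return _node(t, (a,), bw)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    def bw(g):
        _accum(a, g * e)
    return _node(e, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g / a.data)
    return _node(np.log(a.data), (a,), bw)


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)  # subgradient 0 at 0
    def bw(g):
        _accum(a, g * sign)
    return _node(np.abs(a.data), (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    r = np.sqrt(a.data)
    def bw(g):
        _accum(a, g * 0.5 / r)
    return _node(r, (a,), bw)


def power(a: Tensor, p: float) -> Tensor:
    def bw(g):
        _accum(a, g * p * a.data ** (p - 1))
    return _node(a.data ** p, (a,), bw)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g / n, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g / n, a.data.shape).copy())
    return _node(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    sm = np.exp(out)
    def bw(g):
        _accum(a, g - sm * g.sum(axis=axis, keepdims=True))
    return _node(out, (a,), bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))
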