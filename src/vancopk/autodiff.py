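"""Minimal vectorized reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the recurrent PK models: elementwise
arithmetic with broadcasting, exp / expm1 / log / sqrt / tanh / sigmoid,
matrix multiplication, reductions, stacking, and an embedding-mean gather.
Gradients are accumulated by reverse topological traversal of the recorded
graph. Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "exp",
    "expm1",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "stack",
    "concatenate",
    "embedding_mean",
    "where",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        if self.data.dtype != np.float64:
            self.data = self.data.astype(np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data - other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(-g, other.data.shape))

        out._backward = bw
        return out

    def __rsub__(self, other):
        return as_tensor(other).__sub__(self)

    def __truediv__(self, other):
        other = as_tensor(other)
        inv = 1.0 / other.data
        out = Tensor(self.data * inv, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * inv, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(-g * self.data * inv * inv, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other).__truediv__(self)

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, True, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- reductions / shaping --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], True, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(x, fn, dfn):
    """Dispatch: plain arrays go straight through NumPy, Tensors record grads."""
    if not isinstance(x, Tensor):
        return fn(x)
    y = fn(x.data)
    out = Tensor(y, True, (x,))
    out._backward = lambda g: x._accum(g * dfn(x.data, y))
    return out


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def expm1(x):
    return _unary(x, np.expm1, lambda d, y: y + 1.0)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, y: 0.5 / y)


def tanh(x):
    return _unary(x, np.tanh, lambda d, y: 1.0 - y * y)


def sigmoid(x):
    if not isinstance(x, Tensor):
        return 1.0 / (1.0 + np.exp(-x))
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, True, (x,))
    out._backward = lambda g: x._accum(g * y * (1.0 - y))
    return out


def where(cond, a, b):
    """Elementwise select; `cond` is a plain boolean array (not differentiated)."""
    cond = np.asarray(cond)
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.where(cond, a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.where(cond, a.data, b.data), True, (a, b))

    def bw(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))

    out._backward = bw
    return out


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), True, tuple(tensors))

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, pieces):
            t._accum(np.squeeze(p, axis=axis))

    out._backward = bw
    return out


def concatenate(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))

    def bw(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, p in zip(tensors, splits):
            t._accum(p)

    out._backward = bw
    return out


def embedding_mean(table: Tensor, idx: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted mean of embedding rows.

    table: (vocab, d) Tensor; idx: (B, K) int array of row indices (padding
    rows must carry weight 0); weights: (B, K) with rows summing to 1 for
    events with codes and to 0 for events without.  Output: (B, d).
    """
    emb = table.data[idx]                       # (B, K, d)
    out_data = np.einsum("bk,bkd->bd", weights, emb)
    out = Tensor(out_data, True, (table,))

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx.ravel(), (weights[:, :, None] * g[:, None, :]).reshape(-1, table.data.shape[1]))
        table._accum(full)

    out._backward = bw
    return out
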