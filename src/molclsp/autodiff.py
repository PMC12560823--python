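"""Minimal reverse-mode automatic differentiation over NumPy arrays.

All model parameters and activations in this package are float64
:class:`Tensor` objects.  The engine supports exactly the operations the
encoders, fusion block, decoders and losses need: broadcasting arithmetic,
(batched) matrix products, elementwise nonlinearities, reductions, fancy
gather/scatter indexing for graph message passing, concatenation/slicing,
and numerically stable softmax / log-softmax.

Everything is deterministic: no threading, no in-place aliasing of
gradient buffers, plain float64 throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "index_add",
    "softmax",
    "log_softmax",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.name = name

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor{self.shape}(requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autograd plumbing --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            if self.requires_grad or self._prev:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(np.asarray(ga), a.shape))
            if other.requires_grad or other._prev:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(np.asarray(gb), b.shape))

        out._backward = bwd
        return out

    # -- elementwise --------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data ** 2))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape / indexing ---------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(np.transpose(self.data, axes), _prev=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accumulate(np.transpose(g, inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            idx = np.asarray(idx)
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = [tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _prev=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def index_add(n: int, index: np.ndarray, values: Tensor) -> Tensor:
    """Scatter-sum `values` rows into an output of `n` rows: out[i] = sum over
    rows j with index[j] == i.  The workhorse of graph message aggregation."""
    index = np.asarray(index, dtype=np.intp)
    values = tensor(values)
    shape = (n,) + values.data.shape[1:]
    acc = np.zeros(shape, dtype=np.float64)
    np.add.at(acc, index, values.data)
    out = Tensor(acc, _prev=(values,))
    out._backward = lambda g: values._accumulate(g[index])
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant; grad-free shift
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)
    z = x - Tensor(shift)
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def grad_check(fn, params: Iterable[Tensor], eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients
    of scalar-valued `fn()` with respect to `params`."""
    params = list(params)
    for p in params:
        p.zero_grad()
    out = fn()
    out.backward()
    worst = 0.0
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn().item()
            flat[i] = orig - eps
            lo = fn().item()
            flat[i] = orig
            num[i] = (hi - lo) / (2 * eps)
        denom = np.maximum(np.abs(num) + np.abs(analytic.ravel()), 1e-8)
        worst = max(worst, float(np.max(np.abs(num - analytic.ravel()) / denom)))
    return worst
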