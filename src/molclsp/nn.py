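"""Neural-network layers built on the autodiff engine.

Conventions: activations are row-major (sequence/atom index on axis 0,
feature channel on axis 1); all transformer blocks are pre-norm
(``x + sublayer(norm(x))``) so that a block with zeroed projection weights
is an exact identity — a property the fusion module's tests rely on.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, index_add, softmax

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MLP",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "GINLayer",
    "gelu",
    "Adam",
]


def gelu(x: Tensor) -> Tensor:
    # tanh approximation of the Gaussian error linear unit
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x ** 3)).tanh())


class Module:
    """Lightweight container: collects parameters from attributes recursively."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _param(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / math.sqrt(shape[0]) if len(shape) > 1 else 0.02
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = _param(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator):
        self.weight = _param(rng, num, dim, scale=0.02)

    def __call__(self, idx) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred ** 2).mean(axis=-1, keepdims=True)
        return self.gain * (centred / (var + self._eps).sqrt()) + self.shift


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator, act: str = "relu"):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self._act = act

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu() if self._act == "relu" else x.tanh()
        return x


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"width {d} not divisible by {n_heads} heads")
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)
        self.n_heads = n_heads
        self.d_head = d // n_heads

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, dh = self.n_heads, self.d_head
        # (n, d) -> (h, n, dh)
        q = self.q(x).reshape(n, h, dh).transpose(1, 0, 2)
        k = self.k(x).reshape(n, h, dh).transpose(1, 0, 2)
        v = self.v(x).reshape(n, h, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        mixed = (attn @ v).transpose(1, 0, 2).reshape(n, h * dh)
        return self.out(mixed)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 2):
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(d, ff_mult * d, rng)
        self.ff2 = Linear(ff_mult * d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(gelu(self.ff1(self.norm2(x))))


class GINLayer(Module):
    """Graph-isomorphism message passing with edge-feature injection.

    h_i' = MLP((1 + eps) * h_i + sum_{j in N(i)} relu(h_j + W_e e_ij))
    Aggregation is a sum, so the layer is permutation-equivariant exactly.
    """

    def __init__(self, d: int, edge_dim: int, rng: np.random.Generator):
        self.eps = Tensor(np.zeros(1), requires_grad=True)
        self.edge_proj = Linear(edge_dim, d, rng)
        self.update = MLP([d, 2 * d, d], rng)

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_feats: Tensor) -> Tensor:
        n = h.shape[0]
        if edge_index.shape[0] == 0:
            return self.update((1.0 + self.eps) * h)
        src, dst = edge_index[:, 0], edge_index[:, 1]
        msg = (h[src] + self.edge_proj(edge_feats)).relu()
        agg = index_add(n, dst, msg)
        return self.update((1.0 + self.eps) * h + agg)


class Adam:
    """Adam optimizer over a list of tensors (deterministic, CPU float64)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
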