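"""Minimal NumPy neural-net layer library with hand-written backward passes.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad``; ``backward`` returns the
gradient with respect to the layer input.  This keeps the encoder fully
deterministic and dependency-free on CPU.
"""

from __future__ import annotations

import math
from typing import List, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Param",
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "gelu",
    "gelu_grad",
    "softmax",
    "trunc_normal",
    "AdamW",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal samples truncated at two standard deviations (resampled tails)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2.0 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * std
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


class Param:
    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # excluded from weight decay when False (biases, norms)
        self.name = name


class Module:
    def params(self) -> List[Param]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, std: float = 0.02):
        self.w = Param(trunc_normal(rng, (d_in, d_out), std))
        self.b = Param(np.zeros(d_out), decay=False)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self.w.grad += x.reshape(-1, x.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        self.b.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)
        return g @ self.w.value.T

    def params(self) -> List[Param]:
        return [self.w, self.b]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Param(np.ones(dim), decay=False)
        self.beta = Param(np.zeros(dim), decay=False)
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (g * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += g.reshape(-1, d).sum(axis=0)
        gx = g * self.gamma.value
        mean_gx = gx.mean(axis=-1, keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv * (gx - mean_gx - xhat * mean_gx_xhat)

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product self-attention over a token sequence."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        if dim % num_heads != 0:
            raise ValueError("dim must be divisible by num_heads")
        self.dim = dim
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, d = x.shape
        h, hd = self.num_heads, self.head_dim
        qkv = self.qkv.forward(x)  # (b, t, 3d)
        qkv = qkv.reshape(b, t, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3, b, h, t, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) / math.sqrt(hd)  # (b, h, t, t)
        attn = softmax(scores, axis=-1)
        out_h = attn @ v  # (b, h, t, hd)
        out = out_h.transpose(0, 2, 1, 3).reshape(b, t, d)
        self._cache = (q, k, v, attn)
        return self.proj.forward(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        b, h, t, hd = q.shape
        d = self.dim
        g_out = self.proj.backward(g)  # (b, t, d)
        g_h = g_out.reshape(b, t, h, hd).transpose(0, 2, 1, 3)  # (b, h, t, hd)
        g_v = attn.transpose(0, 1, 3, 2) @ g_h
        g_attn = g_h @ v.transpose(0, 1, 3, 2)  # (b, h, t, t)
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_scores /= math.sqrt(hd)
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 1, 3, 2) @ q
        g_qkv = np.stack([g_q, g_k, g_v])  # (3, b, h, t, hd)
        g_qkv = g_qkv.transpose(1, 3, 0, 2, 4).reshape(b, t, 3 * d)
        return self.qkv.backward(g_qkv)

    def params(self) -> List[Param]:
        return self.qkv.params() + self.proj.params()


class AdamW:
    """Adam with decoupled weight decay (decay skipped for ``decay=False`` params)."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-4,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 5e-2,
    ):
        self.parameters = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.parameters]
        self._v = [np.zeros_like(p.value) for p in self.parameters]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.parameters, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.decay and self.weight_decay > 0.0:
                p.value -= lr * self.weight_decay * p.value
            p.value -= lr * update

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0.0
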