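"""Minimal numpy neural-network primitives shared by the LM classifier and the
attention-based tabular baseline.

Everything here is plain numpy with hand-written backward passes: parameters
are ``Param`` objects carrying a value and an accumulated gradient, layers
cache their forward inputs, and a forward pass must be followed by at most one
backward pass before the next forward. ``AdamW`` implements adaptive moments
with decoupled weight decay and global-norm gradient clipping.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

NEG_INF = -1e9  # additive attention mask value


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)


def gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation, as used by GPT-2-family models
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x**3)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    c = math.sqrt(2.0 / math.pi)
    u = c * (x + 0.044715 * x**3)
    t = np.tanh(u)
    du = c * (1.0 + 3 * 0.044715 * x**2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, scale: float = 0.02):
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.g += x2.T @ d2
        self.b.g += d2.sum(axis=0)
        return dout @ self.W.v.T

    def params(self) -> list[tuple[str, Param]]:
        return [("W", self.W), ("b", self.b)]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps
        self._cache = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.v + self.beta.v

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.g += (dout * xhat).reshape(-1, d).sum(axis=0)
        self.beta.g += dout.reshape(-1, d).sum(axis=0)
        dxhat = dout * self.gamma.v
        # standard layernorm backward
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        return dx

    def params(self) -> list[tuple[str, Param]]:
        return [("gamma", self.gamma), ("beta", self.beta)]


class Embedding:
    def __init__(self, rng: np.random.Generator, n: int, dim: int, scale: float = 0.02):
        self.W = Param(rng.normal(0.0, scale, size=(n, dim)))
        self._ids: np.ndarray | None = None

    def __call__(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.W.v[ids]

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self.W.g, self._ids, dout)

    def params(self) -> list[tuple[str, Param]]:
        return [("W", self.W)]


class MultiHeadSelfAttention:
    """Self-attention over a (B, T, d) batch with an additive attention bias.

    The bias has shape (B, 1, T, T) (or broadcastable) and carries 0 for
    allowed key positions and ``NEG_INF`` for masked ones; causality and
    padding are both expressed through it.
    """

    def __init__(self, rng: np.random.Generator, dim: int, n_head: int):
        if dim % n_head:
            raise ValueError(f"hidden size {dim} not divisible by head count {n_head}")
        self.dim = dim
        self.n_head = n_head
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)
        self._cache = None

    def __call__(self, x: np.ndarray, attn_bias: np.ndarray) -> np.ndarray:
        B, T, d = x.shape
        nh, hd = self.n_head, d // self.n_head
        qkv = self.qkv(x)  # (B, T, 3d)
        q, k, v = np.split(qkv, 3, axis=-1)
        # (B, nh, T, hd)
        q = q.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        k = k.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        v = v.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        scale = 1.0 / math.sqrt(hd)
        att = q @ k.transpose(0, 1, 3, 2) * scale + attn_bias
        A = softmax(att, axis=-1)
        y = A @ v  # (B, nh, T, hd)
        out = y.transpose(0, 2, 1, 3).reshape(B, T, d)
        self._cache = (q, k, v, A, scale, (B, T, d, nh, hd))
        return self.proj(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, A, scale, (B, T, d, nh, hd) = self._cache
        dy = self.proj.backward(dout)
        dy = dy.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        dA = dy @ v.transpose(0, 1, 3, 2)
        dv = A.transpose(0, 1, 3, 2) @ dy
        datt = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dq = datt @ k * scale
        dk = datt.transpose(0, 1, 3, 2) @ q * scale
        dq = dq.transpose(0, 2, 1, 3).reshape(B, T, d)
        dk = dk.transpose(0, 2, 1, 3).reshape(B, T, d)
        dv = dv.transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.qkv.backward(np.concatenate([dq, dk, dv], axis=-1))

    def params(self) -> list[tuple[str, Param]]:
        return [("qkv." + n, p) for n, p in self.qkv.params()] + [
            ("proj." + n, p) for n, p in self.proj.params()
        ]


class MLP:
    def __init__(self, rng: np.random.Generator, dim: int, hidden: int):
        self.fc = Linear(rng, dim, hidden)
        self.proj = Linear(rng, hidden, dim)
        self._pre = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        h = self.fc(x)
        self._pre = h
        return self.proj(gelu(h))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.proj.backward(dout) * gelu_grad(self._pre)
        return self.fc.backward(dh)

    def params(self) -> list[tuple[str, Param]]:
        return [("fc." + n, p) for n, p in self.fc.params()] + [
            ("proj." + n, p) for n, p in self.proj.params()
        ]


class TransformerBlock:
    """Pre-norm residual block: x + attn(ln1(x)), then x + mlp(ln2(x))."""

    def __init__(self, rng: np.random.Generator, dim: int, n_head: int, mlp_hidden: int | None = None):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, n_head)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(rng, dim, mlp_hidden or 4 * dim)

    def __call__(self, x: np.ndarray, attn_bias: np.ndarray) -> np.ndarray:
        x = x + self.attn(self.ln1(x), attn_bias)
        x = x + self.mlp(self.ln2(x))
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout + self.ln2.backward(self.mlp.backward(dout))
        dx = dx + self.ln1.backward(self.attn.backward(dx))
        return dx

    def params(self) -> list[tuple[str, Param]]:
        out = []
        for pref, mod in (("ln1", self.ln1), ("attn", self.attn), ("ln2", self.ln2), ("mlp", self.mlp)):
            out += [(f"{pref}.{n}", p) for n, p in mod.params()]
        return out


def causal_attn_bias(attention_mask: np.ndarray) -> np.ndarray:
    """Additive bias combining causality with key-side padding.

    attention_mask: (B, T) with 1 on real tokens, 0 on pads. Returns
    (B, 1, T, T); position i may attend to j iff j <= i and mask[j] == 1.
    """
    B, T = attention_mask.shape
    causal = np.tril(np.ones((T, T), dtype=bool))
    allowed = causal[None, :, :] & (attention_mask[:, None, :] > 0)
    return np.where(allowed, 0.0, NEG_INF)[:, None, :, :]


def padding_attn_bias(attention_mask: np.ndarray) -> np.ndarray:
    """Bidirectional bias masking pad keys only (no causality)."""
    B, T = attention_mask.shape
    allowed = np.broadcast_to(attention_mask[:, None, :] > 0, (B, T, T))
    return np.where(allowed, 0.0, NEG_INF)[:, None, :, :]


class AdamW:
    """Adaptive moments with decoupled weight decay and global-norm clipping.

    Weight decay is applied to matrices only (embeddings and linear weights),
    never to biases or layernorm parameters.
    """

    def __init__(
        self,
        params: Iterable[tuple[str, Param]],
        lr: float = 5e-5,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float = 1.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.v) for _, p in self.params]
        self.s = [np.zeros_like(p.v) for _, p in self.params]

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(sum(float(np.sum(p.g**2)) for _, p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for _, p in self.params:
                    p.g *= scale
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (name, p) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.g
            self.s[i] = self.b2 * self.s[i] + (1 - self.b2) * p.g**2
            update = (self.m[i] / bc1) / (np.sqrt(self.s[i] / bc2) + self.eps)
            if self.wd and p.v.ndim >= 2:
                p.v -= self.lr * self.wd * p.v
            p.v -= self.lr * update


def cross_entropy_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a (B, C) logit batch; returns (loss, dlogits)."""
    B = logits.shape[0]
    logp = log_softmax(logits, axis=-1)
    loss = -float(np.mean(logp[np.arange(B), labels]))
    dlogits = softmax(logits, axis=-1)
    dlogits[np.arange(B), labels] -= 1.0
    return loss, dlogits / B
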