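"""Minimal neural-network core: dense layers, batch/layer norm, dropout,
multi-head self-attention, and Adam, with hand-written backpropagation.

Everything runs in float64 on NumPy.  Layers follow a uniform contract:
``forward(x, training)`` caches what ``backward(dy)`` needs; ``backward``
returns the gradient w.r.t. the input and accumulates parameter gradients
into ``Param.grad``.  Determinism: all random initialisation and dropout
masks come from an explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Dense", "ReLU", "Dropout", "BatchNorm1d", "LayerNorm",
    "MultiHeadSelfAttention", "TransformerBlock", "Sequential", "Adam",
    "softmax", "scaled_dot_attention",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Softmax(Q Kᵀ / √k) V for single 2-D query/key/value matrices.

    The scaling divisor is the square root of the key dimension.  Attention
    weight rows are probability distributions over the value rows.
    """
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    for name, m in (("Q", Q), ("K", K), ("V", V)):
        if np.isnan(m).any():
            raise ValueError(f"NaN in attention input {name}")
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ValueError(
            f"non-conforming attention shapes Q{Q.shape} K{K.shape} V{V.shape}")
    weights = softmax(Q @ K.T / np.sqrt(K.shape[1]), axis=-1)
    return weights @ V


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis; Glorot-uniform initialised."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out)) if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] if self.b is None else [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm1d(Layer):
    """Batch normalisation over axis 0 with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv_std, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if not training:
            return dxhat * inv_std
        n = xhat.shape[0]
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class LayerNorm(Layer):
    """Normalisation over the last axis with learned scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv_std = self._cache
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        return inv_std * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class MultiHeadSelfAttention(Layer):
    """h-head self-attention over a (batch, tokens, d) stack.

    Token-wise projections W_q/W_k/W_v map d → d and are split into h heads
    of width d/h; head outputs are concatenated and mixed by W_O.  No
    positional encoding: the layer is equivariant under token permutation.
    """

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        if d % h != 0:
            raise ValueError(f"head count h={h} must divide token dim d={d}")
        self.d, self.h, self.dh = d, h, d // h
        self.Wq = Dense(d, d, rng)
        self.Wk = Dense(d, d, rng)
        self.Wv = Dense(d, d, rng)
        self.Wo = Dense(d, d, rng)
        self.last_weights: np.ndarray | None = None  # (batch, h, T, T)

    def params(self) -> list[Param]:
        return [p for l in (self.Wq, self.Wk, self.Wv, self.Wo) for p in l.params()]

    def _split(self, x):  # (N,T,d) -> (N,h,T,dh)
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (N,h,T,dh) -> (N,T,d)
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x, training=False):
        q = self._split(self.Wq.forward(x, training))
        k = self._split(self.Wk.forward(x, training))
        v = self._split(self.Wv.forward(x, training))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v
        self.last_weights = attn
        self._cache = (q, k, v, attn)
        return self.Wo.forward(self._merge(ctx), training)

    def backward(self, dy):
        q, k, v, attn = self._cache
        dctx = self._split(self.Wo.backward(dy))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward per row
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.Wq.backward(self._merge(dq))
        dx = dx + self.Wk.backward(self._merge(dk))
        dx = dx + self.Wv.backward(self._merge(dv))
        return dx


class TransformerBlock(Layer):
    """Attention sublayer with residual connection and post-layer-norm."""

    def __init__(self, d: int, h: int, rng: np.random.Generator,
                 residual: bool = True):
        self.attn = MultiHeadSelfAttention(d, h, rng)
        self.norm = LayerNorm(d)
        self.residual = residual

    def params(self) -> list[Param]:
        return self.attn.params() + self.norm.params()

    def forward(self, x, training=False):
        z = self.attn.forward(x, training)
        if self.residual:
            z = x + z
        return self.norm.forward(z, training)

    def backward(self, dy):
        dz = self.norm.backward(dy)
        dx = self.attn.backward(dz)
        return dx + dz if self.residual else dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the customary defaults (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(layers: list[Layer]) -> list[np.ndarray]:
    """Snapshot all parameter values (copies)."""
    return [p.value.copy() for l in layers for p in l.params()]


def set_state(layers: list[Layer], state: list[np.ndarray]) -> None:
    params = [p for l in layers for p in l.params()]
    if len(params) != len(state):
        raise ValueError("state length mismatch")
    for p, v in zip(params, state):
        p.value[...] = v
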