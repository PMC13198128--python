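"""Minimal neural-network toolkit on numpy + autograd.

All model components in this package are pure functions of a parameter
pytree (nested dicts/lists of ``numpy`` arrays) and their inputs, so that
``autograd`` can differentiate end to end and repeated evaluation is
bit-identical.  The toolkit provides the layers the encoders and task
heads need (linear, layer norm, multi-head attention, 1-D convolution,
batch norm, pooling, dropout) plus AdamW/Adam/SGD optimizers and a
cosine learning-rate schedule.
"""

from __future__ import annotations

from typing import Any, Callable, Iterable

import autograd.numpy as np
from autograd import value_and_grad
from autograd.misc import flatten
from autograd.scipy.special import logsumexp

__all__ = [
    "trunc_normal",
    "linear",
    "layer_norm",
    "relu",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "logsumexp",
    "dropout_mask",
    "init_linear",
    "init_layer_norm",
    "init_transformer_layer",
    "transformer_layer",
    "transformer_stack",
    "init_conv1d",
    "conv1d_same",
    "maxpool1d",
    "init_batchnorm",
    "batchnorm",
    "batch_stats",
    "AdamW",
    "Adam",
    "SGD",
    "cosine_schedule",
    "tree_digest",
    "value_and_grad",
    "flatten",
]

NEG_INF = -1e9


# ---------------------------------------------------------------------------
# initialisation


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02):
    """Truncated-normal init (resampled beyond 2 std), the package default."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while np.any(bad):
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


def init_linear(rng, d_in: int, d_out: int, std: float = 0.02, bias: bool = True):
    p = {"W": trunc_normal(rng, (d_in, d_out), std)}
    if bias:
        p["b"] = np.zeros(d_out)
    return p


def init_layer_norm(d: int):
    return {"g": np.ones(d), "b": np.zeros(d)}


# ---------------------------------------------------------------------------
# elementary layers


def linear(p, x):
    y = x @ p["W"]
    if "b" in p:
        y = y + p["b"]
    return y


def layer_norm(p, x, eps: float = 1e-5):
    mu = np.mean(x, axis=-1, keepdims=True)
    var = np.var(x, axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * p["g"] + p["b"]


def relu(x):
    return np.maximum(x, 0.0)


def leaky_relu(x, slope: float = 0.01):
    return np.where(x >= 0, x, slope * x)


def sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def softmax(x, axis=-1):
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    return e / np.sum(e, axis=axis, keepdims=True)


def dropout_mask(rng: np.random.Generator, shape, rate: float):
    """Inverted-dropout mask; ``rate`` is the drop probability."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep


# ---------------------------------------------------------------------------
# transformer encoder


def init_transformer_layer(rng, d: int, heads: int, ffn_mult: int = 4):
    if d % heads != 0:
        raise ValueError(f"width {d} not divisible by heads {heads}")
    return {
        "ln1": init_layer_norm(d),
        "Wqkv": init_linear(rng, d, 3 * d),
        "Wo": init_linear(rng, d, d),
        "ln2": init_layer_norm(d),
        "ffn1": init_linear(rng, d, ffn_mult * d),
        "ffn2": init_linear(rng, ffn_mult * d, d),
    }


def transformer_layer(p, x, mask, heads: int, att_bias=None):
    """Pre-norm transformer encoder layer.

    x: (B, L, D); mask: (B, L) with 1 for valid positions.  Padded
    positions are excluded from attention so appending PAD after EOS
    cannot change any valid position's output.  ``att_bias`` optionally
    carries the precomputed additive attention mask.
    """
    B, L, D = x.shape
    dh = D // heads
    if att_bias is None:
        att_bias = (1.0 - mask[:, None, None, :]) * NEG_INF
    h = layer_norm(p["ln1"], x)
    qkv = np.transpose(np.reshape(linear(p["Wqkv"], h), (B, L, 3, heads, dh)), (2, 0, 3, 1, 4))
    q, k, v = qkv[0], qkv[1], qkv[2]
    att = q @ np.transpose(k, (0, 1, 3, 2)) / np.sqrt(dh) + att_bias
    w = softmax(att, axis=-1)
    o = np.reshape(np.transpose(w @ v, (0, 2, 1, 3)), (B, L, D))
    x = x + linear(p["Wo"], o)
    h2 = layer_norm(p["ln2"], x)
    x = x + linear(p["ffn2"], relu(linear(p["ffn1"], h2)))
    return x


def transformer_stack(layers, x, mask, heads: int):
    att_bias = (1.0 - mask[:, None, None, :]) * NEG_INF
    for p in layers:
        x = transformer_layer(p, x, mask, heads, att_bias=att_bias)
    return x


# ---------------------------------------------------------------------------
# 1-D convolution / pooling / batch norm (for the task heads)


def init_conv1d(rng, c_in: int, c_out: int, kernel: int, std: float = 0.02):
    return {"W": trunc_normal(rng, (c_out, c_in, kernel), std), "b": np.zeros(c_out)}


def _pad_length(x, left: int, right: int, value: float = 0.0):
    B, C, L = x.shape
    if left == 0 and right == 0:
        return x
    pl = np.full((B, C, left), value)
    pr = np.full((B, C, right), value)
    return np.concatenate([pl, x, pr], axis=2)


def conv1d_same(p, x, padding: int | None = None):
    """1-D convolution, stride 1.  x: (B, C_in, L) -> (B, C_out, L_out).

    ``padding=None`` gives 'same' zero padding (output length L); an
    integer gives symmetric zero padding of that size.
    """
    k = p["W"].shape[2]
    if padding is None:
        left = (k - 1) // 2
        right = k - 1 - left
    else:
        left = right = padding
    xp = _pad_length(x, left, right)
    L_out = xp.shape[2] - k + 1
    # stack k shifted views and contract with a single matmul;
    # autograd-friendly and fast for small kernels
    cols = [xp[:, :, i : i + L_out] for i in range(k)]
    stack = np.stack(cols, axis=3)  # (B, C_in, L_out, k)
    B, C_in = xp.shape[0], xp.shape[1]
    flat = np.reshape(np.transpose(stack, (0, 2, 1, 3)), (B, L_out, C_in * k))
    W2 = np.reshape(p["W"], (p["W"].shape[0], C_in * k))  # (C_out, C_in*k)
    y = flat @ W2.T + p["b"]
    return np.transpose(y, (0, 2, 1))


def maxpool1d(x, kernel: int = 2, padding: int = 0):
    """Max pooling with stride = kernel.  x: (B, C, L)."""
    xp = _pad_length(x, padding, padding, value=NEG_INF)
    L = xp.shape[2]
    n = L // kernel
    xp = xp[:, :, : n * kernel]
    B, C = xp.shape[0], xp.shape[1]
    return np.max(np.reshape(xp, (B, C, n, kernel)), axis=3)


def init_batchnorm(c: int):
    return {"g": np.ones(c), "b": np.zeros(c)}


def batch_stats(x, axes=(0, 2)):
    """Per-channel mean/var over batch (and length) axes, outside the graph."""
    x = np.asarray(x)
    return x.mean(axis=axes), x.var(axis=axes)


def batchnorm(p, x, stats, eps: float = 1e-5):
    """Batch norm over channel axis 1 of (B, C, L) or axis 1 of (B, C).

    ``stats`` is a (mean, var) pair: the current batch's statistics in
    training, the running statistics at evaluation.
    """
    mean, var = stats
    if x.ndim == 3:
        mean, var = mean[None, :, None], var[None, :, None]
        g, b = p["g"][None, :, None], p["b"][None, :, None]
    else:
        g, b = p["g"], p["b"]
    return (x - mean) / np.sqrt(var + eps) * g + b


# ---------------------------------------------------------------------------
# optimizers (operate on flattened parameter pytrees)


class _FlatOptimizer:
    def __init__(self, params):
        flat, self._unflatten = flatten(params)
        self._n = flat.shape[0]

    def _flatten(self, tree):
        flat, _ = flatten(tree)
        return flat


class AdamW(_FlatOptimizer):
    """Decoupled weight decay Adam (the pretraining optimizer)."""

    def __init__(self, params, lr=5e-6, weight_decay=1e-4, betas=(0.9, 0.95), eps=1e-8):
        super().__init__(params)
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        self.m = np.zeros(self._n)
        self.v = np.zeros(self._n)
        self.t = 0

    def step(self, params, grads, lr: float | None = None):
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        p = self._flatten(params)
        g = self._flatten(grads)
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        p = p - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)
        return self._unflatten(p)


class Adam(_FlatOptimizer):
    """Adam with L2-coupled weight decay (the downstream-head recipes)."""

    def __init__(self, params, lr=1e-3, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        super().__init__(params)
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        self.m = np.zeros(self._n)
        self.v = np.zeros(self._n)
        self.t = 0

    def step(self, params, grads, lr: float | None = None, weight_decay: float | None = None):
        lr = self.lr if lr is None else lr
        wd = self.wd if weight_decay is None else weight_decay
        b1, b2 = self.betas
        p = self._flatten(params)
        g = self._flatten(grads) + wd * p
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        p = p - lr * mhat / (np.sqrt(vhat) + self.eps)
        return self._unflatten(p)


class SGD(_FlatOptimizer):
    def __init__(self, params, lr=1e-2, momentum=0.0, weight_decay=0.0):
        super().__init__(params)
        self.lr, self.mom, self.wd = lr, momentum, weight_decay
        self.buf = np.zeros(self._n)

    def step(self, params, grads, lr: float | None = None):
        lr = self.lr if lr is None else lr
        p = self._flatten(params)
        g = self._flatten(grads) + self.wd * p
        self.buf = self.mom * self.buf + g
        p = p - lr * self.buf
        return self._unflatten(p)


def cosine_schedule(base_lr: float, total_steps: int, warmup: int = 0, min_lr: float = 0.0) -> Callable[[int], float]:
    """Cosine annealing from ``base_lr`` to ``min_lr`` with linear warmup."""

    def lr_at(step: int) -> float:
        if warmup > 0 and step < warmup:
            return base_lr * (step + 1) / warmup
        denom = max(total_steps - warmup, 1)
        frac = min(max(step - warmup, 0) / denom, 1.0)
        return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + np.cos(np.pi * frac))

    return lr_at


# ---------------------------------------------------------------------------
# misc


def tree_digest(params) -> str:
    """SHA-256 digest of a parameter pytree (frozen-encoder contract)."""
    import hashlib

    flat, _ = flatten(params)
    return hashlib.sha256(np.ascontiguousarray(flat, dtype=np.float64).tobytes()).hexdigest()
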