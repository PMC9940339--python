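"""Neural-network building blocks on top of the autodiff tensors.

Covers what the four generator architectures need: linear/embedding layers,
layer norm, sinusoidal positional encodings, scaled dot-product and
multi-head attention, pre-norm transformer encoder/decoder layers, a
multi-layer LSTM and a GRU cell.
"""
from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concat, embedding, log_softmax, softmax, stack


class Module:
    """Base class: recursive parameter collection + flat state dict."""

    def parameters(self):
        params = []
        for name in sorted(vars(self)):
            params.extend(_collect(getattr(self, name)))
        return params

    def named_state(self, prefix=""):
        out = {}
        for name in sorted(vars(self)):
            _collect_named(getattr(self, name), f"{prefix}{name}", out)
        return out

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state):
        own = self.named_state()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, t in own.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = np.asarray(state[k], np.float32).copy()


def _collect(obj):
    if isinstance(obj, Tensor):
        return [obj] if obj.requires_grad else []
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect(o))
        return out
    return []


def _collect_named(obj, name, out):
    if isinstance(obj, Tensor):
        if obj.requires_grad:
            out[name] = obj
    elif isinstance(obj, Module):
        out.update(obj.named_state(prefix=name + "."))
    elif isinstance(obj, (list, tuple)):
        for i, o in enumerate(obj):
            _collect_named(o, f"{name}.{i}", out)


def _param(rng: np.random.Generator, *shape, scale=None):
    if scale is None:
        scale = 1.0 / math.sqrt(shape[0])
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in, d_out, rng):
        self.weight = _param(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_vocab, d, rng):
        self.weight = Tensor(rng.normal(0, 0.1, size=(n_vocab, d)), requires_grad=True)

    def __call__(self, idx) -> Tensor:
        return embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gain + self.bias


def positional_encoding(p, d_m: int) -> np.ndarray:
    """Sinusoidal position encoding.

    Component 2i is sin(p / 10000^(2i/d_m)) and component 2i+1 is
    cos(p / 10000^(2i/d_m)); ``p`` may be a scalar or an integer array, in
    which case one row per position is returned.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=np.float64))
    i = np.arange(0, d_m, 2, dtype=np.float64)
    denom = np.power(10000.0, i / d_m)
    angles = p_arr[:, None] / denom[None, :]
    out = np.zeros((p_arr.shape[0], d_m), dtype=np.float32)
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles[:, : d_m // 2])
    return out if np.ndim(p) else out[0]


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, mask=None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with optional additive mask (ndarray)."""
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    if mask is not None:
        scores = scores + Tensor(mask)
    return softmax(scores, axis=-1) @ v


class MultiHeadAttention(Module):
    def __init__(self, d_m, n_heads, rng):
        if d_m % n_heads:
            raise ValueError("d_m must be divisible by the head count")
        self.n_heads = n_heads
        self.d_k = d_m // n_heads
        self.w_q = Linear(d_m, d_m, rng)
        self.w_k = Linear(d_m, d_m, rng)
        self.w_v = Linear(d_m, d_m, rng)
        self.w_o = Linear(d_m, d_m, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, l, _ = x.shape
        return x.reshape(b, l, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor, mask=None) -> Tensor:
        b, l_q, d_m = q.shape
        out = scaled_dot_attention(self._split(q), self._split(k), self._split(v), mask)
        out = out.transpose(0, 2, 1, 3).reshape(b, l_q, d_m)
        return self.w_o(out)


class FeedForward(Module):
    def __init__(self, d_m, d_ff, rng):
        self.lin1 = Linear(d_m, d_ff, rng)
        self.lin2 = Linear(d_ff, d_m, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class TransformerEncoderLayer(Module):
    """Pre-norm residual block: self-attention then feed-forward."""

    def __init__(self, d_m, n_heads, d_ff, rng):
        self.attn = MultiHeadAttention(d_m, n_heads, rng)
        self.ff = FeedForward(d_m, d_ff, rng)
        self.norm1 = LayerNorm(d_m)
        self.norm2 = LayerNorm(d_m)

    def __call__(self, x: Tensor, mask=None) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, h, mask)
        return x + self.ff(self.norm2(x))


class TransformerDecoderLayer(Module):
    """Pre-norm block with causal self-attention and encoder cross-attention."""

    def __init__(self, d_m, n_heads, d_ff, rng):
        self.self_attn = MultiHeadAttention(d_m, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_m, n_heads, rng)
        self.ff = FeedForward(d_m, d_ff, rng)
        self.norm1 = LayerNorm(d_m)
        self.norm2 = LayerNorm(d_m)
        self.norm3 = LayerNorm(d_m)

    def __call__(self, x, memory, self_mask=None, cross_mask=None) -> Tensor:
        h = self.norm1(x)
        x = x + self.self_attn(h, h, h, self_mask)
        h = self.norm2(x)
        x = x + self.cross_attn(h, memory, memory, cross_mask)
        return x + self.ff(self.norm3(x))


def causal_mask(length: int) -> np.ndarray:
    mask = np.triu(np.ones((length, length), np.float32), k=1) * -1e9
    return mask[None, None]


def padding_mask(pad: np.ndarray) -> np.ndarray:
    """(B, L) boolean pad indicator -> additive attention mask (B,1,1,L)."""
    return (pad.astype(np.float32) * -1e9)[:, None, None, :]


class LSTMCell(Module):
    def __init__(self, d_in, d_h, rng):
        self.w_x = Linear(d_in, 4 * d_h, rng)
        self.w_h = Linear(d_h, 4 * d_h, rng)
        self.d_h = d_h

    def __call__(self, x, h, c):
        z = self.w_x(x) + self.w_h(h)
        d = self.d_h
        i = z[:, :d].sigmoid()
        f = z[:, d:2 * d].sigmoid()
        g = z[:, 2 * d:3 * d].tanh()
        o = z[:, 3 * d:].sigmoid()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new


class LSTM(Module):
    """Stacked unidirectional LSTM over (B, T, d_in) inputs."""

    def __init__(self, d_in, d_h, n_layers, rng):
        self.cells = [
            LSTMCell(d_in if i == 0 else d_h, d_h, rng) for i in range(n_layers)
        ]
        self.d_h = d_h

    def init_state(self, batch):
        zero = lambda: Tensor(np.zeros((batch, self.d_h), np.float32))
        return [(zero(), zero()) for _ in self.cells]

    def __call__(self, x: Tensor, state=None):
        b, t, _ = x.shape
        if state is None:
            state = self.init_state(b)
        outs = []
        for step in range(t):
            inp = x[:, step, :]
            new_state = []
            for cell, (h, c) in zip(self.cells, state):
                h, c = cell(inp, h, c)
                new_state.append((h, c))
                inp = h
            state = new_state
            outs.append(inp)
        return stack(outs, axis=1), state


class GRUCell(Module):
    def __init__(self, d_in, d_h, rng):
        self.w_x = Linear(d_in, 3 * d_h, rng)
        self.w_h = Linear(d_h, 3 * d_h, rng)
        self.d_h = d_h

    def __call__(self, x, h):
        zx, zh = self.w_x(x), self.w_h(h)
        d = self.d_h
        r = (zx[..., :d] + zh[..., :d]).sigmoid()
        u = (zx[..., d:2 * d] + zh[..., d:2 * d]).sigmoid()
        n = (zx[..., 2 * d:] + r * zh[..., 2 * d:]).tanh()
        return (1.0 - u) * n + u * h


def nll_loss(logits: Tensor, targets: np.ndarray, mask: np.ndarray):
    """Masked mean negative log likelihood.

    logits: (..., V); targets: integer array matching logits[...-1];
    mask: float/bool array, 1 where the position counts.
    Returns (loss Tensor, number of counted positions).
    """
    from .tensor import gather_last

    lp = log_softmax(logits, axis=-1)
    picked = gather_last(lp, targets)
    m = np.asarray(mask, np.float32)
    n = float(m.sum())
    if n == 0:
        raise ValueError("nll_loss: empty mask")
    return -(picked * Tensor(m)).sum() * (1.0 / n), n
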