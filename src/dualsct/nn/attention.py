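"""Windowed multi-head self-attention blocks (Swin-style).

A :class:`SwinBlock` applies pre-norm window attention and an MLP with
residual connections on an NCHW feature map.  Alternating blocks use a
cyclic half-window shift; the shift is implemented with a plain roll
(wrapped windows attend across the cycle without masking — a documented
simplification adequate at the feature-map sizes used here).
"""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import GELU, LayerNorm, Linear

__all__ = ["WindowAttention", "SwinBlock"]


class WindowAttention(Module):
    """Multi-head self-attention over token windows ``(B, T, C)``."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self._cache: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, c = x.shape
        h, dh = self.heads, c // self.heads
        qkv = self.qkv.forward(x).reshape(b, t, 3, h, dh)
        q = qkv[:, :, 0].transpose(0, 2, 1, 3)  # (b, h, t, dh)
        k = qkv[:, :, 1].transpose(0, 2, 1, 3)
        v = qkv[:, :, 2].transpose(0, 2, 1, 3)
        scale = 1.0 / np.sqrt(dh)
        logits = (q @ k.transpose(0, 1, 3, 2)) * scale
        logits -= logits.max(axis=-1, keepdims=True)
        att = np.exp(logits)
        att /= att.sum(axis=-1, keepdims=True)
        out = att @ v  # (b, h, t, dh)
        merged = out.transpose(0, 2, 1, 3).reshape(b, t, c)
        self._cache.append((q, k, v, att, scale))
        return self.proj.forward(merged)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        q, k, v, att, scale = self._cache.pop()
        b, h, t, dh = q.shape
        c = h * dh
        g_merged = self.proj.backward(gy)
        g_out = g_merged.reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        g_att = g_out @ v.transpose(0, 1, 3, 2)
        g_v = att.transpose(0, 1, 3, 2) @ g_out
        # softmax backward
        g_logits = att * (g_att - (g_att * att).sum(axis=-1, keepdims=True))
        g_q = (g_logits @ k) * scale
        g_k = (g_logits.transpose(0, 1, 3, 2) @ q) * scale
        g_qkv = np.empty((b, t, 3, h, dh), dtype=gy.dtype)
        g_qkv[:, :, 0] = g_q.transpose(0, 2, 1, 3)
        g_qkv[:, :, 1] = g_k.transpose(0, 2, 1, 3)
        g_qkv[:, :, 2] = g_v.transpose(0, 2, 1, 3)
        return self.qkv.backward(g_qkv.reshape(b, t, 3 * c))


class SwinBlock(Module):
    """Pre-norm window attention + MLP with residuals on NCHW maps."""

    def __init__(self, dim: int, heads: int, window: int = 4, shift: bool = False,
                 mlp_ratio: float = 2.0, rng: np.random.Generator | None = None):
        self.dim, self.window = dim, window
        self.shift = window // 2 if shift else 0
        self.ln1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng=rng)
        self.ln2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, dim, rng=rng)
        self._cache: list = []

    # -- window bookkeeping -------------------------------------------------
    def _partition(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ww = self.window
        t = x.reshape(n, c, h // ww, ww, w // ww, ww)
        t = t.transpose(0, 2, 4, 3, 5, 1)  # (n, nh, nw, ww, ww, c)
        return t.reshape(n * (h // ww) * (w // ww), ww * ww, c)

    def _unpartition(self, tok: np.ndarray, shape) -> np.ndarray:
        n, c, h, w = shape
        ww = self.window
        t = tok.reshape(n, h // ww, w // ww, ww, ww, c)
        t = t.transpose(0, 5, 1, 3, 2, 4)
        return t.reshape(n, c, h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ww = self.window
        if c != self.dim:
            raise ValueError(f"SwinBlock expected {self.dim} channels, got {c}")
        if h % ww or w % ww:
            raise ValueError(f"feature map {h}x{w} not divisible by window {ww}")
        if self.shift:
            x = np.roll(x, (-self.shift, -self.shift), axis=(2, 3))
        tok = self._partition(x)
        y = tok + self.attn.forward(self.ln1.forward(tok))
        z = y + self.fc2.forward(self.act.forward(self.fc1.forward(self.ln2.forward(y))))
        out = self._unpartition(z, (n, c, h, w))
        if self.shift:
            out = np.roll(out, (self.shift, self.shift), axis=(2, 3))
        self._cache.append((n, c, h, w))
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache.pop()
        if self.shift:
            gy = np.roll(gy, (-self.shift, -self.shift), axis=(2, 3))
        g_z = self._partition(gy)
        g_mlp = self.fc1.backward(self.act.backward(self.fc2.backward(g_z)))
        g_y = g_z + self.ln2.backward(g_mlp)
        g_attn = self.ln1.backward(self.attn.backward(g_y))
        g_tok = g_y + g_attn
        gx = self._unpartition(g_tok, (n, c, h, w))
        if self.shift:
            gx = np.roll(gx, (self.shift, self.shift), axis=(2, 3))
        return gx
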