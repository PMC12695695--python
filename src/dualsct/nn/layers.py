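"""Convolutional, normalization and pointwise layers (NCHW tensors)."""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .core import Module, Param

__all__ = [
    "Conv2d", "InstanceNorm2d", "LeakyReLU", "ReLU", "Tanh", "GELU",
    "NearestUpsample2x", "Linear", "LayerNorm",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Conv2d(Module):
    """2D convolution (cross-correlation) via an im2col lowering.

    'same' padding by default (``pad = k // 2``); He-normal initialization.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, gain: float = 1.0):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        std = gain * np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.bias = Param(np.zeros(cout)) if bias else None
        self._cache: list = []

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.weight.value.dtype)
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"Conv2d expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        ho, wo = self.out_shape(h, w)
        if ho <= 0 or wo <= 0:
            raise ValueError(f"input {h}x{w} too small for k={k}, stride={s}, pad={p}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = np.empty((n, c, k, k, ho * wo), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + s * ho:s, j:j + s * wo:s].reshape(n, c, -1)
        cols2 = cols.reshape(n, c * k * k, ho * wo)
        y = np.matmul(self.weight.value.reshape(self.cout, -1), cols2)
        y = y.reshape(n, self.cout, ho, wo)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache.append((cols2, (n, c, h, w)))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = np.asarray(gy, dtype=self.weight.value.dtype)
        cols2, (n, c, h, w) = self._cache.pop()
        k, s, p = self.k, self.stride, self.pad
        ho, wo = gy.shape[2], gy.shape[3]
        gy2 = gy.reshape(n, self.cout, ho * wo)
        gw = np.matmul(gy2, cols2.transpose(0, 2, 1)).sum(axis=0)
        self.weight.grad += gw.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        gcols = np.matmul(self.weight.value.reshape(self.cout, -1).T, gy2)
        gcols = gcols.reshape(n, c, k, k, ho, wo)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, i, j]
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self._cache: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xh = (x - mu) * inv_std
        self._cache.append((xh, inv_std))
        return self.gamma.value[None, :, None, None] * xh + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xh, inv_std = self._cache.pop()
        self.gamma.grad += (gy * xh).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxh = gy * self.gamma.value[None, :, None, None]
        mean_g = gxh.mean(axis=(2, 3), keepdims=True)
        mean_gx = (gxh * xh).mean(axis=(2, 3), keepdims=True)
        return inv_std * (gxh - mean_g - xh * mean_gx)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._cache: list = []

    def forward(self, x):
        mask = x > 0
        self._cache.append(mask)
        return np.where(mask, x, self.alpha * x)

    def backward(self, gy):
        mask = self._cache.pop()
        return np.where(mask, gy, self.alpha * gy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Module):
    def __init__(self):
        self._cache: list = []

    def forward(self, x):
        y = np.tanh(x)
        self._cache.append(y)
        return y

    def backward(self, gy):
        y = self._cache.pop()
        return gy * (1.0 - y * y)


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def __init__(self):
        self._cache: list = []

    def forward(self, x):
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        self._cache.append((x, phi))
        return x * phi

    def backward(self, gy):
        x, phi = self._cache.pop()
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return gy * (phi + x * pdf)


class NearestUpsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h2, w2 = gy.shape
        return gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Linear(Module):
    """Affine map over the last axis of an arbitrarily batched tensor."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.bias = Param(np.zeros(cout))
        self._cache: list = []

    def forward(self, x):
        x = np.asarray(x, dtype=self.weight.value.dtype)
        self._cache.append(x)
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gy):
        x = self._cache.pop()
        gy2 = gy.reshape(-1, gy.shape[-1])
        x2 = x.reshape(-1, x.shape[-1])
        self.weight.grad += gy2.T @ x2
        self.bias.grad += gy2.sum(axis=0)
        return gy @ self.weight.value


class LayerNorm(Module):
    """Normalization over the last (channel) axis of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps
        self._cache: list = []

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xh = (x - mu) * inv_std
        self._cache.append((xh, inv_std))
        return self.gamma.value * xh + self.beta.value

    def backward(self, gy):
        xh, inv_std = self._cache.pop()
        red = tuple(range(gy.ndim - 1))
        self.gamma.grad += (gy * xh).sum(axis=red)
        self.beta.grad += gy.sum(axis=red)
        gxh = gy * self.gamma.value
        mean_g = gxh.mean(axis=-1, keepdims=True)
        mean_gx = (gxh * xh).mean(axis=-1, keepdims=True)
        return inv_std * (gxh - mean_g - xh * mean_gx)
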