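"""Minimal CPU neural-network core: parameters, modules, Adam.

Layers follow an explicit forward/backward contract: ``forward`` pushes the
activation context it needs onto a per-module cache stack, ``backward`` pops
it (LIFO).  This makes modules re-entrant — a module may be run forward
several times (e.g. both directions of a cycle) as long as backward calls
happen in exactly reverse order of the forwards, which is how the trainers
are written.  Everything is float64 numpy, so runs are bit-reproducible for
a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Param", "Module", "Sequential", "Adam", "use_dtype", "default_dtype"]

_DEFAULT_DTYPE = np.dtype(np.float64)


def default_dtype() -> np.dtype:
    """Dtype new parameters are created with (float64 unless overridden)."""
    return _DEFAULT_DTYPE


@contextmanager
def use_dtype(dtype):
    """Build models under this dtype (float32 halves desk-scale step time)."""
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=default_dtype())
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class; subclasses implement forward(x) and backward(gy)."""

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def parameters(self) -> list[Param]:
        """All Params reachable through attributes (recursively)."""
        seen: list[Param] = []

        def collect(obj):
            if isinstance(obj, Param):
                seen.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return seen

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = v


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam optimizer with the standard default moments (0.9, 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
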