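"""Generator and discriminator architectures for CT synthesis.

Three builders share a uniform contract: inputs are normalized slices in
``[-1, 1]`` shaped ``(batch, channels, H, W)`` with channels = 1 (CBCT) or
2 (CBCT + MRI, CBCT first); generators output one CT channel bounded to
``[-1, 1]`` by a tanh; the discriminator outputs a patch-level logit map.

* :func:`build_resunet` — residual U-Net: encoder/decoder with skip
  connections and pre-activation residual blocks.
* :func:`build_swinunet` — U-shaped network whose blocks use windowed
  multi-head self-attention (convolutional patch embedding / merging).
* :func:`build_discriminator` — strided-convolution PatchGAN critic over
  stacked (condition, candidate) channels.

Reference-scale configurations mirror published widths
(ResUnet [64,128,256,512,1024]; SwinUnet [128,256,512,1024,2048] with heads
[8,16,32,32,32]; discriminator [64,128,256,512]); the desk-scale defaults
used in tests keep the same topology below one million parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import core as _nn_core
from .nn import Conv2d, InstanceNorm2d, LeakyReLU, Module, NearestUpsample2x, ReLU, SwinBlock, Tanh

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig",
    "build_resunet", "build_swinunet", "build_discriminator",
    "count_parameters", "run_generator", "clear_caches",
    "save_generator", "load_generator",
    "ResUNet", "SwinUNet", "PatchDiscriminator",
    "PAPER_RESUNET_FILTERS", "PAPER_SWINUNET_FILTERS", "PAPER_SWINUNET_HEADS",
    "PAPER_DISCRIMINATOR_FILTERS",
]

PAPER_RESUNET_FILTERS = (64, 128, 256, 512, 1024)
PAPER_SWINUNET_FILTERS = (128, 256, 512, 1024, 2048)
PAPER_SWINUNET_HEADS = (8, 16, 32, 32, 32)
PAPER_DISCRIMINATOR_FILTERS = (64, 128, 256, 512)


@dataclass
class GeneratorConfig:
    """Architecture hyper-parameters for either generator family."""

    kind: str = "resunet"                       # {"resunet", "swinunet"}
    in_channels: int = 2                        # 2 iff MRI input enabled
    filters: tuple[int, ...] = (8, 16, 32)      # per-level widths; len == depth
    heads: tuple[int, ...] | None = None        # per-level heads (swinunet)
    blocks_per_level: int = 1
    window: int = 4                             # attention window (swinunet)
    global_skip: bool = True                    # predict a correction on top of
                                                # the (first) CBCT input channel
    norm: bool = False                          # instance norm inside res blocks
    #: scale factor on the initial stem weights of the auxiliary (MRI)
    #: channel.  A small value starts the dual-input model on the CBCT-only
    #: trajectory and lets MRI influence grow where gradients support it.
    aux_init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("resunet", "swinunet"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 (CBCT) or 2 (CBCT+MRI)")
        if self.kind == "swinunet":
            if self.heads is None:
                self.heads = tuple(max(1, f // 8) for f in self.filters)
            if len(self.heads) != len(self.filters):
                raise ValueError("heads must have one entry per level")

    @property
    def depth(self) -> int:
        return len(self.filters)


@dataclass
class DiscriminatorConfig:
    """PatchGAN discriminator hyper-parameters."""

    filters: tuple[int, ...] = (8, 16, 32, 64)
    in_channels: int = 3                        # condition channel(s) + candidate
    norm: bool = True                           # instance norm after block 1

    @property
    def n_blocks(self) -> int:
        return len(self.filters)


class _GlobalSkip(Module):
    """Adds ``atanh(clip(cbct))`` to the pre-activation logits so the network
    starts from an identity CBCT→CT mapping and learns HU corrections.

    ``forward(z, x0)`` is stateful like other layers; backward returns the
    gradient pair (w.r.t. z and w.r.t. the CBCT channel x0).
    """

    _LIM = 0.999

    def __init__(self):
        self._cache: list = []

    def forward(self, z, x0):  # type: ignore[override]
        clipped = np.clip(x0, -self._LIM, self._LIM)
        inside = np.abs(x0) < self._LIM
        self._cache.append((clipped, inside))
        return z + np.arctanh(clipped)

    def backward(self, gy):
        clipped, inside = self._cache.pop()
        gx0 = np.where(inside, gy / (1.0 - clipped * clipped), 0.0)
        return gy, gx0


class _ResBlock(Module):
    """Pre-activation residual block: x + conv(act(norm?(conv(act(norm?(x)))))).

    Normalization is optional: instance statistics discard the absolute
    intensity scale, which the HU-correction task depends on, so desk-scale
    generators default to norm-free blocks with LeakyReLU activations.
    """

    def __init__(self, ch: int, rng: np.random.Generator, norm: bool = False):
        self.n1 = InstanceNorm2d(ch) if norm else None
        self.a1 = LeakyReLU(0.1)
        self.c1 = Conv2d(ch, ch, 3, rng=rng)
        self.n2 = InstanceNorm2d(ch) if norm else None
        self.a2 = LeakyReLU(0.1)
        self.c2 = Conv2d(ch, ch, 3, rng=rng, gain=0.5)

    def forward(self, x):
        y = x if self.n1 is None else self.n1.forward(x)
        y = self.c1.forward(self.a1.forward(y))
        y = y if self.n2 is None else self.n2.forward(y)
        y = self.c2.forward(self.a2.forward(y))
        return x + y

    def backward(self, gy):
        g = self.a2.backward(self.c2.backward(gy))
        if self.n2 is not None:
            g = self.n2.backward(g)
        g = self.a1.backward(self.c1.backward(g))
        if self.n1 is not None:
            g = self.n1.backward(g)
        return gy + g


class ResUNet(Module):
    """Residual U-Net generator (see :func:`build_resunet`)."""

    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E5]))
        f = cfg.filters
        d = cfg.depth
        self.cfg = cfg
        self.stem = Conv2d(cfg.in_channels, f[0], 3, rng=rng)
        if cfg.in_channels > 1 and cfg.aux_init_scale != 1.0:
            self.stem.weight.value[:, 1:] *= cfg.aux_init_scale
        self.enc = [[_ResBlock(f[i], rng, cfg.norm) for _ in range(cfg.blocks_per_level)]
                    for i in range(d)]
        self.down = [Conv2d(f[i], f[i + 1], 3, stride=2, pad=1, rng=rng) for i in range(d - 1)]
        self.up = NearestUpsample2x()
        self.upconv = [Conv2d(f[i + 1], f[i], 3, rng=rng) for i in range(d - 1)]
        self.fuse = [Conv2d(2 * f[i], f[i], 3, rng=rng) for i in range(d - 1)]
        self.dec = [[_ResBlock(f[i], rng, cfg.norm) for _ in range(cfg.blocks_per_level)]
                    for i in range(d - 1)]
        self.head = Conv2d(f[0], 1, 3, rng=rng, gain=0.05)
        self.skip = _GlobalSkip()
        self.act = Tanh()

    def _check(self, x):
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {c}")
        div = 2 ** (self.cfg.depth - 1)
        if h % div or w % div:
            raise ValueError(f"slice {h}x{w} not divisible by 2^(depth-1) = {div}")

    def forward(self, x):
        self._check(x)
        d = self.cfg.depth
        x0 = x[:, :1]
        x = self.stem.forward(x)
        skips = []
        for i in range(d - 1):
            for b in self.enc[i]:
                x = b.forward(x)
            skips.append(x)
            x = self.down[i].forward(x)
        for b in self.enc[d - 1]:
            x = b.forward(x)
        for i in range(d - 2, -1, -1):
            x = self.upconv[i].forward(self.up.forward(x))
            x = np.concatenate([x, skips[i]], axis=1)
            x = self.fuse[i].forward(x)
            for b in self.dec[i]:
                x = b.forward(x)
        z = self.head.forward(x)
        if self.cfg.global_skip:
            z = self.skip.forward(z, x0)
        return self.act.forward(z)

    def backward(self, gy):
        d = self.cfg.depth
        f = self.cfg.filters
        g = self.act.backward(gy)
        gx0 = None
        if self.cfg.global_skip:
            g, gx0 = self.skip.backward(g)
        g = self.head.backward(g)
        gskips: dict[int, np.ndarray] = {}
        for i in range(d - 1):
            for b in reversed(self.dec[i]):
                g = b.backward(g)
            g2 = self.fuse[i].backward(g)
            gskips[i] = g2[:, f[i]:]
            g = self.up.backward(self.upconv[i].backward(np.ascontiguousarray(g2[:, :f[i]])))
        for b in reversed(self.enc[d - 1]):
            g = b.backward(g)
        for i in range(d - 2, -1, -1):
            g = self.down[i].backward(g) + gskips[i]
            for b in reversed(self.enc[i]):
                g = b.backward(g)
        gx = self.stem.backward(g)
        if gx0 is not None:
            gx = gx.copy()
            gx[:, :1] += gx0
        return gx


class SwinUNet(Module):
    """U-shaped generator with windowed self-attention blocks."""

    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x511]))
        f, heads, ww = cfg.filters, cfg.heads, cfg.window
        d = cfg.depth
        self.cfg = cfg
        self.embed = Conv2d(cfg.in_channels, f[0], k=2, stride=2, pad=0, rng=rng)
        if cfg.in_channels > 1 and cfg.aux_init_scale != 1.0:
            self.embed.weight.value[:, 1:] *= cfg.aux_init_scale
        self.enc = [[SwinBlock(f[i], heads[i], ww, shift=bool(j % 2), rng=rng)
                     for j in range(cfg.blocks_per_level)] for i in range(d)]
        self.merge = [Conv2d(f[i], f[i + 1], k=2, stride=2, pad=0, rng=rng) for i in range(d - 1)]
        self.up = NearestUpsample2x()
        self.upconv = [Conv2d(f[i + 1], f[i], 3, rng=rng) for i in range(d - 1)]
        self.fuse = [Conv2d(2 * f[i], f[i], k=1, pad=0, rng=rng) for i in range(d - 1)]
        self.dec = [[SwinBlock(f[i], heads[i], ww, shift=bool(j % 2), rng=rng)
                     for j in range(cfg.blocks_per_level)] for i in range(d - 1)]
        self.head = Conv2d(f[0], 1, 3, rng=rng, gain=0.05)
        self.skip = _GlobalSkip()
        self.act = Tanh()

    def _check(self, x):
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {c}")
        d, ww = self.cfg.depth, self.cfg.window
        if h % 2 ** d or w % 2 ** d:
            raise ValueError(f"slice {h}x{w} not divisible by 2^depth = {2 ** d}")
        for i in range(d):
            side_h, side_w = h // 2 ** (i + 1), w // 2 ** (i + 1)
            if side_h % ww or side_w % ww:
                raise ValueError(
                    f"window {ww} does not divide the {side_h}x{side_w} level-{i} feature map")

    def forward(self, x):
        self._check(x)
        d = self.cfg.depth
        x0 = x[:, :1]
        x = self.embed.forward(x)
        skips = []
        for i in range(d - 1):
            for b in self.enc[i]:
                x = b.forward(x)
            skips.append(x)
            x = self.merge[i].forward(x)
        for b in self.enc[d - 1]:
            x = b.forward(x)
        for i in range(d - 2, -1, -1):
            x = self.upconv[i].forward(self.up.forward(x))
            x = np.concatenate([x, skips[i]], axis=1)
            x = self.fuse[i].forward(x)
            for b in self.dec[i]:
                x = b.forward(x)
        z = self.head.forward(self.up.forward(x))
        if self.cfg.global_skip:
            z = self.skip.forward(z, x0)
        return self.act.forward(z)

    def backward(self, gy):
        d = self.cfg.depth
        f = self.cfg.filters
        g = self.act.backward(gy)
        gx0 = None
        if self.cfg.global_skip:
            g, gx0 = self.skip.backward(g)
        g = self.up.backward(self.head.backward(g))
        gskips: dict[int, np.ndarray] = {}
        for i in range(d - 1):
            for b in reversed(self.dec[i]):
                g = b.backward(g)
            g2 = self.fuse[i].backward(g)
            gskips[i] = g2[:, f[i]:]
            g = self.up.backward(self.upconv[i].backward(np.ascontiguousarray(g2[:, :f[i]])))
        for b in reversed(self.enc[d - 1]):
            g = b.backward(g)
        for i in range(d - 2, -1, -1):
            g = self.merge[i].backward(g) + gskips[i]
            for b in reversed(self.enc[i]):
                g = b.backward(g)
        gx = self.embed.backward(g)
        if gx0 is not None:
            gx = gx.copy()
            gx[:, :1] += gx0
        return gx


class PatchDiscriminator(Module):
    """PatchGAN critic: stride-2 conv blocks then a 1-channel logit head."""

    def __init__(self, cfg: DiscriminatorConfig, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15C]))
        self.cfg = cfg
        layers: list[Module] = []
        cin = cfg.in_channels
        for i, f in enumerate(cfg.filters):
            layers.append(Conv2d(cin, f, k=4, stride=2, pad=1, rng=rng))
            if i > 0 and cfg.norm:
                layers.append(InstanceNorm2d(f))
            layers.append(LeakyReLU(0.2))
            cin = f
        layers.append(Conv2d(cin, 1, k=3, stride=1, pad=1, rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        return self.net.forward(x)

    def backward(self, gy):
        return self.net.backward(gy)


# -- public builders --------------------------------------------------------

def build_resunet(cfg: GeneratorConfig, seed: int = 0, dtype=np.float64) -> ResUNet:
    if cfg.kind != "resunet":
        raise ValueError(f"config kind is {cfg.kind!r}, expected 'resunet'")
    with _nn_core.use_dtype(dtype):
        return ResUNet(cfg, seed=seed)


def build_swinunet(cfg: GeneratorConfig, seed: int = 0, dtype=np.float64) -> SwinUNet:
    if cfg.kind != "swinunet":
        raise ValueError(f"config kind is {cfg.kind!r}, expected 'swinunet'")
    with _nn_core.use_dtype(dtype):
        return SwinUNet(cfg, seed=seed)


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0,
                        dtype=np.float64) -> PatchDiscriminator:
    with _nn_core.use_dtype(dtype):
        return PatchDiscriminator(cfg, seed=seed)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars in a built model."""
    return model.n_parameters()


def clear_caches(model: Module) -> None:
    """Drop all cached forward activations (after inference-only passes)."""
    def walk(obj):
        if isinstance(obj, Module):
            if hasattr(obj, "_cache"):
                obj._cache.clear()
            for v in vars(obj).values():
                walk(v)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                walk(v)
        elif isinstance(obj, dict):
            for v in obj.values():
                walk(v)
    walk(model)


def save_generator(path, model: Module) -> None:
    """Persist a generator (architecture config + weights) as .npz."""
    import json
    from dataclasses import asdict
    cfg = asdict(model.cfg)
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_generator(path) -> Module:
    """Rebuild a generator saved by :func:`save_generator`."""
    import json
    with np.load(path, allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["__config__"]))
        for key in ("filters", "heads"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        cfg = GeneratorConfig(**cfg_dict)
        keys = sorted(k for k in z.files if k.startswith("p"))
        state = [z[k] for k in keys]
    dtype = state[0].dtype
    builder = build_resunet if cfg.kind == "resunet" else build_swinunet
    model = builder(cfg, dtype=dtype)
    model.load_state(state)
    return model


def run_generator(model: Module, x: np.ndarray) -> np.ndarray:
    """Inference forward pass; deterministic for fixed weights and input.

    Accepts ``(C, H, W)`` or ``(N, C, H, W)`` input normalized to [-1, 1];
    returns the predicted CT slice(s), same leading shape, one channel.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    y = model.forward(x)
    clear_caches(model)
    return y[0] if squeeze else y
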