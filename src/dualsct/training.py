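"""Training regimes for CT synthesis.

Implements the optimization protocol used throughout the package: Adam
with generator learning rate 1e-4, batches of three axial slices, and —
for adversarial models — the two-part convergence fix of (a) initializing
the Pix2Pix generator from an MAE-pretrained autoencoder and (b) running
the discriminator at a much lower learning rate (1e-6).  Without that fix
the discriminator wins early (its loss collapses toward zero) and the
generator receives no usable signal.

Four regimes are provided:

* :func:`pretrain_generator` — plain MAE autoencoder training;
* :func:`fit_pix2pix` — conditional GAN on paired (CBCT[+MRI], CT) slices;
* :func:`fit_cyclegan` — unpaired CBCT↔CT cycle-consistent GAN (no MRI);
* :func:`synthesize_volume` — slice-wise inference back to an HU volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import volio
from .generators import Module, clear_caches, run_generator
from .grid import VolumeGrid
from .nn import Adam
from .phantom import GroundTruthTriplet

__all__ = [
    "LossWeights", "TrainConfig", "TrainLog",
    "loss_mae", "loss_pix2pix_generator", "loss_discriminator", "loss_cyclegan",
    "pretrain_generator", "fit_pix2pix", "fit_cyclegan",
    "synthesize_volume", "preprocess_triplet",
]


@dataclass
class LossWeights:
    """Weights of the non-adversarial loss terms.

    ``lambda_l1`` multiplies the L1 reconstruction term of the Pix2Pix
    generator loss; ``lambda_cycle`` the cycle-consistency L1 of the
    CycleGAN.  Defaults follow the original Pix2Pix / CycleGAN recipes.
    """

    lambda_l1: float = 100.0
    lambda_cycle: float = 10.0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.lambda_cycle < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainConfig:
    """Optimization protocol parameters.

    Reference-protocol values: 100 epochs, batch 3, Adam, generator lr
    1e-4, discriminator lr 1e-6; desk-scale smoke runs shrink only the
    epoch count.  ``lr_discriminator`` may not exceed ``lr_generator``
    in adversarial training (the convergence fix); pass
    ``enforce_lr_ratio=False`` to reproduce the collapse mode on purpose.
    """

    epochs: int = 100
    batch: int = 3
    lr_generator: float = 1e-4
    lr_discriminator: float = 1e-6
    seed: int = 0
    with_mri: bool = True
    pretrain_epochs: int = 2
    weights: LossWeights = field(default_factory=LossWeights)
    enforce_lr_ratio: bool = True
    #: restrict the reconstruction (L1/MAE) loss to the body: air outside the
    #: head carries no anatomy and would otherwise dominate the gradient
    #: statistics.  "head" (default) or "none".  The adversarial term always
    #: sees the full slice.
    loss_mask: str = "head"
    #: probability of zeroing the CBCT channel of a batch during MAE
    #: pre-training of a dual-input model (modality dropout).  Forces the
    #: MRI pathway to develop instead of free-riding on the dominant CBCT
    #: channel; ignored for single-input models and during adversarial
    #: training.
    modality_dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch < 1:
            raise ValueError("epochs must be >= 0 and batch >= 1")
        if self.enforce_lr_ratio and self.lr_discriminator > self.lr_generator:
            raise ValueError(
                "lr_discriminator must not exceed lr_generator in adversarial "
                "training (set enforce_lr_ratio=False to override)")


@dataclass
class TrainLog:
    """One record per completed epoch, plus the config snapshot."""

    records: list[dict] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)
    aborted: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# --------------------------------------------------------------------------
# losses (scalars; gradient helpers are private)

def loss_mae(pred: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean absolute error, optionally restricted to a boolean mask."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if mask is None:
        return float(np.mean(np.abs(pred - target)))
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.mean(np.abs(pred[mask] - target[mask])))


def _bce_logits(logits: np.ndarray, label: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(logits) against a constant label,
    with its gradient w.r.t. the logits."""
    x = np.asarray(logits, dtype=float)
    loss = float(np.mean(np.maximum(x, 0) - x * label + np.log1p(np.exp(-np.abs(x)))))
    sig = 1.0 / (1.0 + np.exp(-x))
    return loss, (sig - label) / x.size


def _l1_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = np.asarray(pred, dtype=float) - np.asarray(target, dtype=float)
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def loss_pix2pix_generator(d_scores_fake: np.ndarray, pred: np.ndarray,
                           target: np.ndarray, w: LossWeights) -> float:
    """Generator objective: BCE(D(condition, pred) -> real) + λ_L1 · L1."""
    adv, _ = _bce_logits(d_scores_fake, 1.0)
    return adv + w.lambda_l1 * loss_mae(pred, target)


def loss_discriminator(d_scores_real: np.ndarray, d_scores_fake: np.ndarray) -> float:
    """0.5 · [BCE(real -> 1) + BCE(fake -> 0)] (standard halving convention)."""
    if np.shape(d_scores_real) != np.shape(d_scores_fake):
        raise ValueError("score maps must share a shape")
    lr_, _ = _bce_logits(d_scores_real, 1.0)
    lf_, _ = _bce_logits(d_scores_fake, 0.0)
    return 0.5 * (lr_ + lf_)


def loss_cyclegan(real_a: np.ndarray, real_b: np.ndarray,
                  generators: tuple[Module, Module],
                  discriminators: tuple[Module, Module],
                  w: LossWeights) -> dict[str, float]:
    """Evaluate the CycleGAN objective components (no parameter update).

    ``generators`` = (G_ab, G_ba), ``discriminators`` = (D_a, D_b) where
    domain a = CBCT, b = CT.  Returns adversarial terms in both directions,
    the weighted cycle term and their total.
    """
    g_ab, g_ba = generators
    d_a, d_b = discriminators
    fake_b = g_ab.forward(real_a)
    rec_a = g_ba.forward(fake_b)
    fake_a = g_ba.forward(real_b)
    rec_b = g_ab.forward(fake_a)
    adv_ab, _ = _bce_logits(d_b.forward(fake_b), 1.0)
    adv_ba, _ = _bce_logits(d_a.forward(fake_a), 1.0)
    cycle = loss_mae(rec_a, real_a) + loss_mae(rec_b, real_b)
    for m in (*generators, *discriminators):
        clear_caches(m)
    out = {"adv_ab": adv_ab, "adv_ba": adv_ba, "cycle": w.lambda_cycle * cycle}
    out["total"] = out["adv_ab"] + out["adv_ba"] + out["cycle"]
    return out


# --------------------------------------------------------------------------
# data plumbing

def preprocess_triplet(triplet: GroundTruthTriplet) -> GroundTruthTriplet:
    """Clip CT/CBCT to the HU window and min-max normalize all volumes to
    [-1, 1] (MRI uses its per-volume min/max)."""
    ct = volio.normalize_minmax(volio.clip_hu(triplet.ct), volio.HU_BOUNDS)
    cbct = volio.normalize_minmax(volio.clip_hu(triplet.cbct), volio.HU_BOUNDS)
    mri = volio.normalize_minmax(triplet.mri, volio.NormalizationBounds.from_volume(triplet.mri))
    return GroundTruthTriplet(ct=ct, cbct=cbct, mri=mri, labels=triplet.labels,
                              misalignment=triplet.misalignment)


def _epoch_batches(data: Sequence[GroundTruthTriplet], cfg: TrainConfig,
                   rng: np.random.Generator):
    """Yield (input, target, loss-mask) batches; mask is None when unmasked."""
    if cfg.loss_mask not in ("head", "none"):
        raise ValueError(f"loss_mask must be 'head' or 'none', got {cfg.loss_mask!r}")
    order = rng.permutation(len(data))
    for i in order:
        trip = data[i]
        masks = None
        if cfg.loss_mask == "head":
            masks = trip.labels.head_mask()
        start = 0
        for x, y in volio.iter_axial_slices(trip, batch=cfg.batch,
                                            with_mri=cfg.with_mri):
            b = x.shape[0]
            m = None
            if masks is not None:
                m = np.moveaxis(masks[None, :, :, start:start + b], 3, 0)
            start += b
            yield x, y, m


def _masked_l1_grad(pred: np.ndarray, target: np.ndarray,
                    mask: np.ndarray | None) -> tuple[float, np.ndarray]:
    """L1 over the mask (or everything); gradient is zero outside."""
    if mask is None:
        return _l1_grad(pred, target)
    diff = np.asarray(pred, dtype=float) - np.asarray(target, dtype=float)
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(diff)
    loss = float(np.abs(diff[mask]).mean())
    return loss, np.where(mask, np.sign(diff), 0.0) / n


def _check_finite(*losses: float) -> bool:
    return all(np.isfinite(v) for v in losses)


def _validation_mae(generator: Module, val_data, with_mri: bool) -> float:
    """Masked (head) MAE in HU over the validation triplets."""
    maes = []
    for t in val_data:
        sct = synthesize_volume(generator, t, with_mri=with_mri)
        ct_hu = volio.denormalize(t.ct, volio.HU_BOUNDS)
        maes.append(loss_mae(sct.data, ct_hu.data, mask=t.labels.head_mask()))
    return float(np.mean(maes))


# --------------------------------------------------------------------------
# training loops

def pretrain_generator(model: Module, data: Sequence[GroundTruthTriplet],
                       cfg: TrainConfig) -> tuple[Module, TrainLog]:
    """Train a generator as a plain autoencoder with the MAE loss.

    Used both as the standalone autoencoder regime and as the warm-up that
    initializes adversarial training.
    """
    if cfg.pretrain_epochs < 1:
        raise ValueError("pretrain_epochs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAE]))
    opt = Adam(model.parameters(), lr=cfg.lr_generator)
    log = TrainLog(seed=cfg.seed, config=asdict(cfg))
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]))
    for epoch in range(cfg.pretrain_epochs):
        losses = []
        for x, y, m in _epoch_batches(data, cfg, rng):
            if (cfg.modality_dropout > 0 and x.shape[1] > 1
                    and drop_rng.uniform() < cfg.modality_dropout):
                x = x.copy()
                x[:, 0] = 0.0
            pred = model.forward(x)
            mae, g = _masked_l1_grad(pred, y, m)
            if not _check_finite(mae):
                raise RuntimeError(
                    f"pretraining diverged (non-finite MAE) at epoch {epoch}")
            model.zero_grad()
            model.backward(g)
            opt.step()
            losses.append(mae)
        log.records.append({"epoch": epoch, "gen_loss": float(np.mean(losses))})
    return model, log


def fit_pix2pix(generator: Module, discriminator: Module,
                data: Sequence[GroundTruthTriplet], cfg: TrainConfig,
                val_data: Sequence[GroundTruthTriplet] | None = None,
                ) -> tuple[Module, Module, TrainLog]:
    """Adversarial Pix2Pix training with alternating G/D Adam updates.

    The generator is expected to arrive pre-trained (see
    :func:`pretrain_generator`); the discriminator runs at
    ``cfg.lr_discriminator``.  The best-validation-MAE generator state is
    restored at the end when validation data is given.  Non-finite losses
    abort the run and restore the last completed epoch's weights.
    """
    w = cfg.weights
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF17]))
    opt_g = Adam(generator.parameters(), lr=cfg.lr_generator)
    opt_d = Adam(discriminator.parameters(), lr=cfg.lr_discriminator)
    log = TrainLog(seed=cfg.seed, config=asdict(cfg))
    best = (np.inf, generator.state())
    last_good = generator.state()
    for epoch in range(cfg.epochs):
        g_losses, d_losses = [], []
        for x, y, m in _epoch_batches(data, cfg, rng):
            # ---- generator update
            pred = generator.forward(x)
            d_in_fake = np.concatenate([x, pred], axis=1)
            logits_fake = discriminator.forward(d_in_fake)
            adv, g_logits = _bce_logits(logits_fake, 1.0)
            g_d_input = discriminator.backward(g_logits)
            g_pred_adv = g_d_input[:, x.shape[1]:]
            l1, g_l1 = _masked_l1_grad(pred, y, m)
            generator.zero_grad()
            generator.backward(g_pred_adv + w.lambda_l1 * g_l1)
            opt_g.step()
            discriminator.zero_grad()  # discard grads leaked by the G pass
            # ---- discriminator update
            logits_real = discriminator.forward(np.concatenate([x, y], axis=1))
            logits_fake2 = discriminator.forward(np.concatenate([x, pred], axis=1))
            lr_, g_r = _bce_logits(logits_real, 1.0)
            lf_, g_f = _bce_logits(logits_fake2, 0.0)
            discriminator.backward(0.5 * g_f)   # LIFO: fake pass popped first
            discriminator.backward(0.5 * g_r)
            opt_d.step()
            discriminator.zero_grad()
            g_total = adv + w.lambda_l1 * l1
            d_total = 0.5 * (lr_ + lf_)
            if not _check_finite(g_total, d_total):
                generator.load_state(last_good)
                log.aborted = True
                return generator, discriminator, log
            g_losses.append(g_total)
            d_losses.append(d_total)
        rec = {"epoch": epoch, "gen_loss": float(np.mean(g_losses)),
               "disc_loss": float(np.mean(d_losses)),
               "disc_loss_min": float(np.min(d_losses))}
        if val_data is not None:
            rec["val_mae_hu"] = _validation_mae(generator, val_data, cfg.with_mri)
            if rec["val_mae_hu"] < best[0]:
                best = (rec["val_mae_hu"], generator.state())
        log.records.append(rec)
        last_good = generator.state()
    if val_data is not None and np.isfinite(best[0]):
        generator.load_state(best[1])
    return generator, discriminator, log


def fit_cyclegan(generators: tuple[Module, Module],
                 discriminators: tuple[Module, Module],
                 data: Sequence[GroundTruthTriplet], cfg: TrainConfig,
                 val_data: Sequence[GroundTruthTriplet] | None = None,
                 ) -> tuple[tuple[Module, Module], tuple[Module, Module], TrainLog]:
    """Unpaired CBCT↔CT CycleGAN training (1-channel, no MRI).

    CBCT and CT slices are shuffled independently, so batches are unpaired.
    ``generators`` = (G_ab: CBCT→CT, G_ba: CT→CBCT); ``discriminators`` =
    (D_a judging CBCT-domain images, D_b judging CT-domain images), each
    consuming the candidate image alone.
    """
    g_ab, g_ba = generators
    d_a, d_b = discriminators
    w = cfg.weights
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCCC]))
    opt_g = Adam([*g_ab.parameters(), *g_ba.parameters()], lr=cfg.lr_generator)
    opt_d = Adam([*d_a.parameters(), *d_b.parameters()], lr=cfg.lr_discriminator)
    log = TrainLog(seed=cfg.seed, config=asdict(cfg))

    a_slices = np.concatenate([np.moveaxis(t.cbct.data, 2, 0)[:, None] for t in data])
    b_slices = np.concatenate([np.moveaxis(t.ct.data, 2, 0)[:, None] for t in data])
    n = min(len(a_slices), len(b_slices))
    for epoch in range(cfg.epochs):
        order_a = rng.permutation(len(a_slices))[:n]
        order_b = rng.permutation(len(b_slices))[:n]
        g_losses, d_losses = [], []
        for s in range(0, n, cfg.batch):
            a = a_slices[order_a[s:s + cfg.batch]]
            b = b_slices[order_b[s:s + cfg.batch]]
            # ---- generator update (both directions jointly)
            fake_b = g_ab.forward(a)
            rec_a = g_ba.forward(fake_b)
            fake_a = g_ba.forward(b)
            rec_b = g_ab.forward(fake_a)
            adv_ab, g_dfb = _bce_logits(d_b.forward(fake_b), 1.0)
            adv_ba, g_dfa = _bce_logits(d_a.forward(fake_a), 1.0)
            cyc_a, g_rec_a = _l1_grad(rec_a, a)
            cyc_b, g_rec_b = _l1_grad(rec_b, b)
            g_fa_adv = d_a.backward(g_dfa)
            g_fb_adv = d_b.backward(g_dfb)
            for m in (g_ab, g_ba):
                m.zero_grad()
            # reverse order of the four generator forwards (LIFO caches)
            g_fa_cyc = g_ab.backward(w.lambda_cycle * g_rec_b)     # pops G_ab #2
            g_ba.backward(g_fa_adv + g_fa_cyc)                     # pops G_ba #2
            g_fb_cyc = g_ba.backward(w.lambda_cycle * g_rec_a)     # pops G_ba #1
            g_ab.backward(g_fb_adv + g_fb_cyc)                     # pops G_ab #1
            opt_g.step()
            for m in (d_a, d_b):
                m.zero_grad()
            # ---- discriminator updates
            lra, g_ra = _bce_logits(d_a.forward(a), 1.0)
            lfa, g_fa = _bce_logits(d_a.forward(fake_a), 0.0)
            d_a.backward(0.5 * g_fa)
            d_a.backward(0.5 * g_ra)
            lrb, g_rb = _bce_logits(d_b.forward(b), 1.0)
            lfb, g_fb = _bce_logits(d_b.forward(fake_b), 0.0)
            d_b.backward(0.5 * g_fb)
            d_b.backward(0.5 * g_rb)
            opt_d.step()
            for m in (d_a, d_b):
                m.zero_grad()
            g_total = adv_ab + adv_ba + w.lambda_cycle * (cyc_a + cyc_b)
            d_total = 0.5 * (lra + lfa + lrb + lfb)
            if not _check_finite(g_total, d_total):
                log.aborted = True
                return (g_ab, g_ba), (d_a, d_b), log
            g_losses.append(g_total)
            d_losses.append(d_total)
        rec = {"epoch": epoch, "gen_loss": float(np.mean(g_losses)),
               "disc_loss": float(np.mean(d_losses))}
        if val_data is not None:
            rec["val_mae_hu"] = _validation_mae(g_ab, val_data, with_mri=False)
        log.records.append(rec)
    return (g_ab, g_ba), (d_a, d_b), log


def synthesize_volume(generator: Module, triplet: GroundTruthTriplet,
                      with_mri: bool = True, chunk: int = 8) -> VolumeGrid:
    """Run slice-wise inference over a preprocessed triplet and assemble the
    synthetic CT in HU (denormalized, clipped to [-1024, 3072]).

    Output grid metadata equals the target CT's grid metadata.
    """
    slices = []
    for x, _ in volio.iter_axial_slices(triplet, batch=chunk, with_mri=with_mri):
        pred = run_generator(generator, x)
        slices.append(pred[:, 0])  # (b, H, W)
    stack = np.concatenate(slices, axis=0)            # (K, H, W)
    data = np.moveaxis(stack, 0, 2).astype(float)     # (H, W, K)
    sct_norm = triplet.ct.with_data(data)
    sct = volio.denormalize(sct_norm, volio.HU_BOUNDS)
    return sct.with_data(np.clip(sct.data, volio.HU_BOUNDS.lo, volio.HU_BOUNDS.hi))
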