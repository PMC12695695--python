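"""Reproducible desk-scale studies on synthetic head phantoms.

These drivers wire the full pipeline — phantom simulation, preprocessing,
training, synthesis, evaluation — into fixed-seed experiments small enough
for a single CPU:

* :func:`mri_benefit_study` — the central comparison: ventricle-mask MAE of
  the dual-input (CBCT+MRI) Pix2Pix model versus the CBCT-only model, over
  seed replicates, together with the GAN-vs-autoencoder sharpness contrast.
* :func:`collapse_study` — the adversarial-convergence experiment: equal
  learning rates without generator pre-training drive the discriminator
  loss toward zero, while pre-training plus a 100x-lower discriminator
  rate keeps it bounded away from zero.
* :func:`range_error_study` — propagates synthetic CTs through the
  straight-ray range engine and summarizes beamlet R80 errors against the
  ground-truth CT.

Desk-scale protocol: 64x64x32 phantoms, generator filters (8, 16, 32)
(~50k parameters), batches of 3 slices, Adam throughout, generator
pre-training on a two-stage annealed learning rate (1e-3 then 3e-4)
followed by adversarial fine-tuning with the discriminator 100x slower
than the generator — the reference protocol's optimizer, batch size and
generator:discriminator rate ratio, with rates scaled up so the small
networks move appreciably within a handful of epochs on CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics, proton, training, volio
from .generators import (DiscriminatorConfig, GeneratorConfig,
                         build_discriminator, build_resunet)
from .phantom import GroundTruthTriplet, PhantomSpec, VENTRICLE, generate_triplet

__all__ = [
    "StudyConfig", "phantom_cohort", "train_pix2pix_model", "train_autoencoder",
    "mri_benefit_replicate", "mri_benefit_study", "collapse_study",
    "range_error_study",
]


@dataclass
class StudyConfig:
    """Desk-scale study conditions (cohort sizes, schedules, rates)."""

    n_train: int = 4
    n_test: int = 3
    #: (epochs, generator lr) stages of MAE pre-training
    pretrain_stages: tuple[tuple[int, float], ...] = ((6, 1e-3), (4, 3e-4))
    adversarial_epochs: int = 2
    lr_generator: float = 3e-4
    lr_discriminator: float = 3e-6
    batch: int = 3
    filters: tuple[int, ...] = (8, 16, 32)
    disc_filters: tuple[int, ...] = (8, 16, 32)
    spec_template: PhantomSpec = field(default_factory=PhantomSpec)


def phantom_cohort(n: int, seed: int, spec_template: PhantomSpec | None = None,
                   ) -> list[GroundTruthTriplet]:
    """Generate and preprocess ``n`` independent phantom triplets."""
    template = spec_template or PhantomSpec()
    out = []
    for i in range(n):
        spec = replace(template, seed=int(np.random.default_rng(
            np.random.SeedSequence([seed, i, 0x0C0])).integers(0, 2**31 - 1)))
        out.append(training.preprocess_triplet(generate_triplet(spec)))
    return out


def _pretrain(model, train_data, study: StudyConfig, seed: int, with_mri: bool,
              stages=None):
    log = None
    for block, (epochs, lr) in enumerate(stages or study.pretrain_stages):
        cfg = training.TrainConfig(
            epochs=0, batch=study.batch, lr_generator=lr,
            seed=seed * 97 + block, with_mri=with_mri, pretrain_epochs=epochs)
        model, log = training.pretrain_generator(model, train_data, cfg)
    return model, log


def train_autoencoder(train_data, study: StudyConfig, seed: int, with_mri: bool):
    """MAE-only generator training (the non-adversarial baseline)."""
    cin = 2 if with_mri else 1
    g = build_resunet(GeneratorConfig(in_channels=cin, filters=study.filters),
                      seed=seed, dtype=np.float32)
    return _pretrain(g, train_data, study, seed, with_mri)


def train_pix2pix_model(train_data, study: StudyConfig, seed: int, with_mri: bool,
                        val_data=None, return_autoencoder: bool = False):
    """Reference recipe: MAE pre-training then adversarial fine-tuning.

    With ``return_autoencoder`` the pre-trained generator is also continued
    MAE-only for the same number of extra epochs, giving an equal-epoch
    autoencoder arm for the sharpness comparison.
    """
    cin = 2 if with_mri else 1
    g = build_resunet(GeneratorConfig(in_channels=cin, filters=study.filters),
                      seed=seed, dtype=np.float32)
    g, _ = _pretrain(g, train_data, study, seed, with_mri)
    g_ae = None
    if return_autoencoder:
        g_ae = copy.deepcopy(g)
        g_ae, _ = _pretrain(g_ae, train_data, study, seed + 17, with_mri,
                            stages=((study.adversarial_epochs,
                                     study.lr_generator),))
    d = build_discriminator(DiscriminatorConfig(filters=study.disc_filters,
                                                in_channels=cin + 1),
                            seed=seed, dtype=np.float32)
    cfg = training.TrainConfig(
        epochs=study.adversarial_epochs, batch=study.batch,
        lr_generator=study.lr_generator, lr_discriminator=study.lr_discriminator,
        seed=seed, with_mri=with_mri, pretrain_epochs=1)
    g, d, log = training.fit_pix2pix(g, d, train_data, cfg, val_data=val_data)
    if return_autoencoder:
        return g, d, log, g_ae
    return g, d, log


def mri_benefit_replicate(seed: int, study: StudyConfig | None = None) -> dict:
    """One seed replicate of the dual-input vs CBCT-only comparison."""
    study = study or StudyConfig()
    train_data = phantom_cohort(study.n_train, seed * 2 + 1, study.spec_template)
    test_data = phantom_cohort(study.n_test, seed * 2 + 90001, study.spec_template)
    out = {"seed": seed}
    for with_mri, tag in ((True, "mri"), (False, "nomri")):
        g, d, log, g_ae = train_pix2pix_model(
            train_data, study, seed, with_mri, return_autoencoder=True)
        vent_maes, head_maes, sharp_gan, sharp_ae = [], [], [], []
        for t in test_data:
            ct_hu = volio.denormalize(t.ct, volio.HU_BOUNDS)
            vent = t.labels.mask(VENTRICLE)
            head = t.labels.head_mask()
            sct = training.synthesize_volume(g, t, with_mri=with_mri)
            sct_ae = training.synthesize_volume(g_ae, t, with_mri=with_mri)
            vent_maes.append(metrics.masked_mae(sct, ct_hu, vent))
            head_maes.append(metrics.masked_mae(sct, ct_hu, head))
            sharp_gan.append(metrics.sharpness(sct, head))
            sharp_ae.append(metrics.sharpness(sct_ae, head))
        out[f"vent_mae_{tag}"] = float(np.mean(vent_maes))
        out[f"head_mae_{tag}"] = float(np.mean(head_maes))
        out[f"sharpness_gan_{tag}"] = float(np.mean(sharp_gan))
        out[f"sharpness_ae_{tag}"] = float(np.mean(sharp_ae))
        out[f"min_disc_loss_{tag}"] = float(
            min(r["disc_loss_min"] for r in log.records))
    return out


def mri_benefit_study(seeds=range(5), study: StudyConfig | None = None) -> pd.DataFrame:
    """Seed-replicated study of the dual-input benefit and GAN sharpness.

    Returns one row per seed with ventricle/head MAE for both models and
    the mean-absolute-Laplacian sharpness of the GAN versus autoencoder
    output (both measured over the head).
    """
    rows = [mri_benefit_replicate(int(s), study) for s in seeds]
    return pd.DataFrame(rows)


def collapse_study(seed: int = 0, study: StudyConfig | None = None,
                   epochs: int = 4) -> dict:
    """Adversarial-training stability with and without the convergence fix.

    * ``broken`` arm: randomly initialized generator, discriminator trained
      at the generator's learning rate — the discriminator quickly wins and
      its loss collapses toward zero.
    * ``fixed`` arm: MAE-pretrained generator, discriminator 100x slower.

    Both arms use the plain generator (no global CBCT skip): the collapse
    mode belongs to the vanilla formulation, where a freshly initialized
    generator emits unrealistic images that the discriminator separates
    immediately.  Returns the minimum per-batch discriminator loss of each
    arm.
    """
    study = study or StudyConfig()
    train_data = phantom_cohort(study.n_train, seed * 2 + 71, study.spec_template)
    lr_fast = 1e-3
    results = {}
    for arm in ("broken", "fixed"):
        cin = 2
        g = build_resunet(GeneratorConfig(in_channels=cin, filters=study.filters,
                                          global_skip=False),
                          seed=seed, dtype=np.float32)
        cfg = training.TrainConfig(
            epochs=epochs, batch=study.batch,
            lr_generator=lr_fast,
            lr_discriminator=lr_fast if arm == "broken" else lr_fast * 1e-2,
            seed=seed, with_mri=True, pretrain_epochs=6)
        if arm == "fixed":
            g, _ = training.pretrain_generator(g, train_data, cfg)
        d = build_discriminator(DiscriminatorConfig(filters=study.disc_filters,
                                                    in_channels=cin + 1),
                                seed=seed, dtype=np.float32)
        g, d, log = training.fit_pix2pix(g, d, train_data, cfg)
        results[f"min_disc_loss_{arm}"] = float(
            min(r["disc_loss_min"] for r in log.records))
    return results


def range_error_study(sct, ct_hu, beam: proton.BeamSpec | None = None,
                      curve: proton.SprCurve | None = None) -> dict:
    """Beamlet R80 errors of a synthetic CT against the reference CT."""
    beam = beam or proton.BeamSpec(field_size_mm=80.0, r80_water_mm=120.0)
    curve = curve or proton.default_spr_curve()
    map_ct = proton.compute_r80_map(proton.hu_to_spr(ct_hu, curve), beam)
    map_sct = proton.compute_r80_map(proton.hu_to_spr(sct, curve), beam)
    hist = proton.r80_difference_histogram(map_sct, map_ct, beam.r80_water_mm)
    return {"mean_pct": hist["mean_pct"], "sd_pct": hist["sd_pct"],
            "frac_within_1pct": hist["frac_within_1pct"],
            "n_beamlets": hist["n_beamlets"], "histogram": hist}
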