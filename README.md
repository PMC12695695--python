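# dualsct

Dual-input synthetic-CT generation and proton-range evaluation on
synthetic head phantoms.

## The problem

Adaptive proton therapy (APT) needs an up-to-date CT to recompute dose as a
patient's anatomy changes over a fractionated course. The in-room cone-beam
CT (CBCT) acquired at every session is geometrically convenient but its
Hounsfield units (HU) are unreliable — cupping, scatter, per-session
calibration drift — so it cannot drive dose calculation directly. A common
remedy is to translate the CBCT into a *synthetic CT* (sCT) with a
conditional GAN; because CBCT soft-tissue contrast is poor, the planning
T1-weighted MRI (acquired once, at the start of treatment) can be added as a
second input channel to supply the missing soft-tissue information.

`dualsct` implements that pipeline end to end, exercisable entirely on a
built-in digital head-phantom simulator, for people who want to study the
*mechanics* of dual-input CT synthesis and its dosimetric consequences
without clinical data:

- **`dualsct.phantom`** — seed-reproducible aligned CT/CBCT/T1-MRI triplets
  with ground-truth organ labels (skull, brain, ventricles, eyes, lenses,
  optic nerves, nasal cavities). The CBCT model applies per-tissue HU
  corruption with per-session random offsets, a radial cupping field, blur,
  noise and cylindrical field-of-view truncation.
- **`dualsct.volio`** — NIfTI I/O, rigid resampling into CT space, HU
  clipping to [−1024, 3072], min-max normalization to [−1, 1],
  patient-level train/val/test splits, axial slice batching.
- **`dualsct.generators`** — residual U-Net and windowed-attention
  (Swin-style) U-Net generators and a PatchGAN discriminator, on a compact
  numpy engine (`dualsct.nn`) with explicit backprop and Adam, sized for
  CPU desk-scale experiments.
- **`dualsct.training`** — MAE autoencoder pre-training, Pix2Pix
  conditional-GAN training (L_G = BCE(D(x, G(x)) → real) + λ·‖G(x) − y‖₁,
  λ = 100), unpaired CBCT↔CT CycleGAN (cycle weight 10), and slice-wise
  volume synthesis back to HU.
- **`dualsct.metrics`** — masked MAE / PSNR / 3D SSIM, HU error maps and
  difference histograms, Dice and (percentile) Hausdorff distance,
  per-organ delineation reports, exact Wilcoxon signed-rank comparison.
- **`dualsct.proton`** — piecewise-linear HU→stopping-power-ratio (SPR)
  calibration, SPR relative error, and a straight-ray water-equivalent
  path-length range engine: analytic Bragg-shaped depth dose whose distal
  80 % falloff sits exactly at the configured range in water, per-beamlet
  distal-R80 maps over an 80–100 mm lateral field (1×1 mm² beamlets, 1 mm
  dose grid), water-normalized range-difference histograms, and DVHs.
- **`dualsct.experiments`** — the packaged studies: the five-seed
  dual-input-vs-CBCT-only comparison, the adversarial-stability experiment,
  and sCT range-error summaries.

## A worked example

```bash
python examples/image_quality_metrics.py
```

prints, for one phantom (seed 11):

```
CBCT vs CT over 41384 head voxels
  MAE      33.5 HU   (mean absolute HU error)
  PSNR    36.78 dB   (10 log10(4096^2 / MSE))
  SSIM    0.967      (3D structural similarity, 7^3 windows)
  SPR RE   1.38 %    (mean relative stopping-power error)
```

That is the CBCT's own quality against the ground-truth CT — the baseline a
synthetic CT must beat. Training a dual-input Pix2Pix model at desk scale
(`examples/train_synthesis_model.py`) and scoring its output the same way
cuts the head MAE to ~14 HU and the SPR error to ~0.8 %, and
`examples/proton_range_probe.py` shows the dosimetric counterpart: the raw
CBCT shifts per-beamlet proton range by about −1.3 % of the range in water,
an error the sCT largely removes (>90 % of beamlets within ±1 %).

The same stages are scriptable from a shell:

```bash
dualsct simulate --patients 4 --triplets-per-patient 2 --seed 7 --out cohort/
dualsct train --data cohort/ --model pix2pix --with-mri --out run/
dualsct synthesize --weights run/generator.npz --data cohort/ --out sct.nii
dualsct evaluate --sct sct.nii --ct cohort/patient000_triplet00_ct.nii \
    --labels cohort/patient000_triplet00_labels.nii --mask whole_head --out eval/
dualsct range-eval --sct sct.nii --ct cohort/patient000_triplet00_ct.nii --out range/
```

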