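# Methods

This note documents the models implemented in `dualsct`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate. Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing is copied from external
results.

## 1. The head phantom

`dualsct.phantom` rasterizes a parametric head: an ellipsoidal scalp
(default semi-axes 100 × 115 × 55 mm), an ellipsoidal-shell skull (outer/
inner fractions 0.88/0.78 of the head), a brain, paired lateral ventricles,
eyes with lenses, optic nerves (capsules meeting near the chiasm) and a
nasal air cavity. The default grid is desk-scale — 64 × 64 × 32 voxels at
4 mm — with clinical-geometry grids available by passing the acquisition
shape/spacing (e.g. CT 0.625 × 0.625 × 1.25 mm, CBCT 0.5371 × 0.5371 ×
1 mm, MRI 1 mm isotropic).

Anatomy is jittered per phantom with `jitter_frac` (default 0.05). The
ventricles receive far stronger variability than the rigid organs —
per-side size factors with ~35 % spread and several mm of positional
wander — reflecting how much ventricular anatomy varies across subjects
and disease states (atrophy, hydrocephalus, cystic change). This matters
for the study design below: it prevents a model from "knowing" the
ventricles by geometric prior alone.

### Modalities

* **CT** (ground truth): per-tissue mean HU plus Gaussian noise, clipped to
  [−1024, 3072]. Defaults (air −1000, soft tissue 40, bone 1000, brain 35,
  CSF 5, eye 30, lens 80, nerve 40) are phantom choices, not a clinical
  calibration; noise sd 2–15 HU by tissue.
* **CBCT**: the CT corrupted by, in order, a per-tissue affine HU error, a
  radially increasing cupping field (amplitude 50 HU ± 50 %), Gaussian
  blur (1.2 mm), voxel noise (sd 10 HU), cylindrical 30 cm field-of-view
  truncation to −1024, and final clipping. The default offsets wash the
  entire soft-tissue family out to a single level (60 HU): brain, CSF,
  eyes, lenses, nerves and generic soft tissue become indistinguishable in
  the CBCT, while bone (920 HU) and air remain obvious. On top, each
  acquisition draws one random offset per *tissue group* (soft family /
  bone / air, sd 15–30 HU) and a random cupping amplitude, emulating
  session-to-session HU inconsistency: a CBCT-only model cannot learn a
  stable soft-tissue intensity mapping.
* **T1 MRI**: per-tissue mean intensity × a smooth multiplicative bias
  field (amplitude 0.03, low-resolution Gaussian noise upsampled with
  cubic splines and rescaled so max/min ≤ (1+a)/(1−a)) + noise (sd 2).
  The table follows T1 conventions — CSF (40) well below brain (90), bone
  and air near zero — and deliberately leaves wide margins around the
  "watery" band (eye 35, CSF 40) that identifies fluid. One MRI per
  patient is reused across that patient's triplets in `make_dataset`,
  mirroring a planning MRI acquired once before treatment.

What the phantom does **not** emulate: projection/reconstruction physics
(scatter, FDK artifacts), realistic MRI sequences, partial-volume tissue
mixtures, pediatric/adult anatomy differences, or registration error
(misalignment is representable via `RigidTransform` but defaults to
identity). Results on the phantom therefore show that the *pipeline
mechanics* behave correctly, not that any model would reach clinical
quality.

## 2. Preprocessing

CT and CBCT are clipped to the fixed HU window [−1024, 3072] and min-max
normalized to [−1, 1] (`v' = 2(v − lo)/(hi − lo) − 1`); MRI uses its
per-volume min/max as the window. Rigid resampling into the CT grid uses
`scipy.ndimage.affine_transform` with linear or nearest interpolation;
out-of-support voxels are filled with −1024 (HU images) or 0 (MRI).
Patient-level splits use floor(fraction·n) for validation and test with the
remainder to training (27 patients at 75/10/15 % → 21/2/4); the rounding
rule is a package convention, as only approximate fractions are standard.
Axial slices are served channel-first with a fixed CBCT-then-MRI order.

## 3. Networks and the numpy engine

All models run on `dualsct.nn`, a small CPU engine: conv2d (im2col +
GEMM), instance/layer norm, windowed multi-head self-attention with cyclic
shifts, nearest-neighbour upsampling, exact-GELU/LeakyReLU/tanh, and Adam.
Layers keep LIFO activation-cache stacks, so modules are re-entrant (a
generator may run forward twice inside a cycle as long as backwards happen
in reverse order). Parameters are float64 by default — every layer and all
three networks are validated against central-difference gradients to
~1e-9 relative — with float32 used for training studies (about twice as
fast per step).

* **Residual U-Net generator**: stem conv, pre-activation residual blocks
  per level, stride-2 downsampling convs, nearest-upsample + conv + skip
  concatenation on the decoder, tanh-bounded single-channel output.
  Reference-scale widths are (64, 128, 256, 512, 1024); the desk-scale
  default (8, 16, 32) has ≈ 48k parameters. Two desk-scale adaptations,
  both configurable: residual blocks are norm-free (instance statistics
  discard the absolute intensity scale the HU task depends on), and a
  **global residual skip** adds `atanh(clip(cbct))` to the output logits,
  so the network starts at an identity CBCT→CT mapping and learns HU
  corrections; the correction head is initialized with small gain. For
  dual-input models the stem's MRI weights start scaled by 0.1, so the
  model begins on the CBCT-only trajectory.
* **Swin-style U-Net generator**: convolutional patch embedding (stride 2),
  windowed self-attention blocks (pre-norm attention + MLP, alternating
  half-window cyclic shifts, window 4) with conv patch merging, same
  decoder pattern and output contract. Reference-scale widths
  (128, 256, 512, 1024, 2048) with heads (8, 16, 32, 32, 32). Shifted
  windows are not attention-masked across the wrap — a simplification
  acceptable at the feature-map sizes used here.
* **PatchGAN discriminator**: stride-2 4×4 conv blocks (instance norm from
  the second block, switchable off) and a 3×3 logit head; a 64×64 input
  with four blocks yields a 4×4 patch score map. Reference widths
  (64, 128, 256, 512) ≈ 2.8 M parameters; desk default (8, 16, 32, 64).

## 4. Training regimes

Four regimes share Adam, batches of three axial slices, and fixed seeds:

* **Autoencoder** (`pretrain_generator`): plain MAE. Also used as the
  warm-up that initializes adversarial training.
* **Pix2Pix** (`fit_pix2pix`): alternating updates;
  `L_G = BCE(D(x, G(x)) → real) + λ_L1 ‖G(x) − y‖₁` with λ_L1 = 100, and
  `L_D = ½[BCE(real → 1) + BCE(fake → 0)]` on sigmoid logits. The
  discriminator learning rate may not exceed the generator's (the
  stability constraint; override explicitly to study the collapse mode).
  When validation triplets are given, the generator state with the lowest
  validation head-masked MAE is restored at the end ("best model" =
  lowest validation masked MAE — a package convention). Non-finite losses
  abort the run and restore the last completed epoch.
* **CycleGAN** (`fit_cyclegan`): CBCT↔CT with independently shuffled
  (unpaired) batches, candidate-only discriminators, cycle weight
  λ_cycle = 10, single-channel generators (no MRI) — the comparison arm's
  standard formulation.
* **Synthesis** (`synthesize_volume`): slice-wise inference, stacking,
  denormalization to HU and clipping; output grid metadata equals the CT's.

The λ values follow the original Pix2Pix/CycleGAN recipes; the adversarial
loss is sigmoid BCE (least-squares is not implemented).

### Desk-scale protocol

The clinical-scale protocol (100 epochs, generator lr 1e-4, discriminator
lr 1e-6) amortizes the heavy gradient noise of L1-sign updates over
~10⁶ steps. The packaged studies run ~10³ steps, so they scale both rates
up tenfold while keeping the 100:1 generator:discriminator ratio, anneal
pre-training over two stages (six epochs at 1e-3, four at 3e-4) and
restrict the reconstruction loss to the body (`loss_mask="head"`): air
outside the head carries no anatomy but would dominate the gradient
statistics. The adversarial term always sees the full slice. An optional
`modality_dropout` (zeroing the CBCT channel of a pre-training batch)
is available for fusion experiments; the default studies do not use it.

## 5. Evaluation metrics

All intensity metrics operate in HU over an explicit region mask, never
the background (verified by tests: corrupting the background leaves masked
scores unchanged). Conventions, all configurable:

* PSNR data range 4096 (the clipped HU window); identical inputs report
  the +∞ sentinel.
* SSIM is 3D with a 7³ uniform window, k₁ = 0.01, k₂ = 0.03, range 4096,
  averaged over window centres that lie fully inside the volume and in the
  mask. Validated against a loop-based sliding-window reference to 1e-6.
* The default soft-tissue mask is "head voxels above −200 HU"; phantom
  pipelines use label-derived masks.
* HU difference histograms default to 50 HU bins spanning ±1000 with
  unbounded end bins (total count = mask size).
* Dice defines two empty masks as 1. Hausdorff distances come from
  Euclidean distance transforms with anisotropic spacing, symmetrized by
  the max of the directed values; exact HD is the default, HD95
  selectable. Validated against an all-pairs brute-force oracle.
* Paired model comparison uses the two-sided Wilcoxon signed-rank test
  (exact null for n ≤ 25 without ties), validated against full sign-pattern
  enumeration; all-zero differences yield a degenerate report.
* `sharpness` is the mean absolute discrete Laplacian over a mask — a
  simple edge-content score for the GAN-vs-autoencoder contrast.

## 6. The proton range engine

The range engine deliberately replaces a treatment-planning dose engine
with an analytic model; **range geometry is faithful, absolute dose is
not** (no lateral scatter, no nuclear halo, no spot weighting):

* HU→SPR is piecewise linear through a small shipped calibration anchored
  at air (−1024 → 0.001), water (0 → 1.000, enforced to 1e-3) and dense
  bone (1500 → 1.6), monotone non-decreasing, clamped outside the node
  range, replaceable by a two-column CSV.
* WEPL accumulates SPR at segment midpoints along straight rays
  (`Σ SPR(midpoint)·step`, step ≤ voxel size).
* The depth-dose shape is a slowly rising entrance plateau plus a Gaussian
  Bragg peak and a sharp distal sigmoid cutoff, evaluated in WEPL
  normalized to the nominal range; the curve is calibrated numerically
  (Brent root-finding on a fine grid) so its distal 80 % crossing sits
  exactly at the configured `r80_water_mm`, which also encodes beam
  energy (a beam-data library is out of scope). Doubling the range
  stretches the curve exactly twofold.
* A beamlet's distal R80 is the **last** downward 0.8 crossing beyond the
  peak, linearly interpolated between 1 mm dose-grid samples; lines whose
  peak or crossing fall outside the volume are masked invalid, never
  silently zeroed. Field geometry: square 80–100 mm lateral field centred
  on the isocenter, 1×1 mm² beamlets, 2.5 mm spot bookkeeping, 1 mm dose
  grid.
* Range-difference histograms express per-beamlet R80 errors as a
  percentage of the range in water (1 mm at 100 mm = 1 %), with 0.1 %
  bins spanning ±5 % plus overflow bins, and report mean, sd and the
  fraction within ±1 %.
* DVHs are cumulative V(≥D) curves over a structure; V(0) = 1 and the
  curve reaches 0 beyond the maximum dose.

Verified physics at desk scale: on uniform water every beamlet's R80
equals the configured range to ≪ 1 mm; scaling SPR by s scales R80 by 1/s;
a 20 mm SPR-1.5 slab shortens the range by exactly 10 mm; a −50 HU
soft-tissue bias produces a systematically signed range shift while an
unbiased volume yields errors centred at zero.

## 7. The packaged studies, and an honest negative result

`experiments.mri_benefit_study` trains, per seed, a dual-input (CBCT+MRI)
and a CBCT-only Pix2Pix model on four phantom triplets (two-stage MAE
pre-training, then adversarial fine-tuning) and compares ventricle-mask
MAE on three held-out phantoms, alongside an equal-epoch autoencoder arm
for the sharpness contrast.

The phantom is constructed so the MRI channel *carries* the decisive
information: the CBCT's brain/ventricle contrast is zero by construction
and its session offsets are random, while the MRI separates the tissues by
~25 noise standard deviations (a tested invariant). Nevertheless, at
desk-scale optimization budgets (≈ 500–2600 Adam steps) the dual-input
model does **not** outperform the CBCT-only model on ventricle MAE: a
controlled experiment shows a dual-input model trained with a zeroed MRI
channel matches the single-input model, while with the real MRI it is
consistently equal or slightly worse. The CSF-specific feature (dark-T1
*and* soft-CBCT conjunction) occupies only a few percent of the
reconstruction loss, and sign-gradient (L1) Adam does not develop it
before the budget is exhausted; informative MRI features meanwhile inject
gradient interference. Learning-rate schedules, fusion curricula
(warm-starting the dual-input model from the trained single-input model),
modality dropout and body-masked losses narrow but do not reverse the gap.
The corresponding acceptance check is therefore expected to fail at desk
scale, and the study reports the measured win count rather than the
desired one. The directional GAN-vs-autoencoder sharpness contrast (the
adversarial term preserving high-frequency HU structure) does reproduce
under the canonical study seeds, though its margin is small.

`experiments.collapse_study` reproduces the adversarial-stability
mechanism with the plain (no-global-skip) generator, where it belongs: a
randomly initialized generator trained against a discriminator at the same
learning rate lets the discriminator win outright (its loss collapses
below 0.05 within the smoke run), whereas MAE pre-training plus a 100×
slower discriminator keeps the loss near ln 2 throughout.

## 8. Numerical and reproducibility notes

* Every stochastic component derives its generator from explicit integer
  seeds via `numpy.random.SeedSequence`; identical specs produce
  bit-identical phantoms, and training is deterministic for a fixed seed
  on a fixed BLAS (the engine is pure numpy).
* Degenerate inputs fail loudly: empty masks, empty structures, degenerate
  normalization windows, non-monotone SPR curves, beams that miss the
  volume, dose lines without a distal falloff.
* Cohort summary statistics are unweighted means of per-volume values.
* Problem sizes in the packaged studies (64 × 64 × 32 phantoms at 4 mm,
  four training triplets, ≈ 50k-parameter generators, twelve total epochs)
  are the package's desk-scale defaults; all are configurable upward.

## 9. Known limitations

* The CBCT degradation is image-domain, not projection-domain; which
  artifact family dominates a given clinical CBCT cannot be validated here.
* The HU tables, MRI contrast table and SPR calibration are synthetic
  defaults, not clinical calibrations.
* Absolute dose from the range engine is schematic; only water-normalized,
  relative range behaviour is meaningful.
* Desk-scale training does not demonstrate the dual-input benefit (see
  §7); reproducing that phenomenon requires training budgets orders of
  magnitude beyond a CPU smoke run.
* Auto-segmentation of synthetic CTs is out of scope; delineation reports
  compare any two label volumes, with phantom ground truth as the tested
  path.
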