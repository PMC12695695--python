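"""Synthetic multimodal head phantoms.

Generates seed-reproducible aligned CT / CBCT / T1-MRI volume triplets with
ground-truth organ labels, so the whole synthesis-and-evaluation pipeline is
exercisable without clinical data.  The phantom is a voxelized ellipsoid
head containing the structures that matter for soft-tissue evaluation
(skull, brain, ventricles, eyes, lenses, optic nerves, nasal air cavities).

The three modalities emulate the failure modes that motivate dual-input
synthesis:

* the CT is the ground truth (piecewise-constant HU + mild noise);
* the CBCT carries per-tissue HU corruption, a radial cupping field, blur,
  noise and cylindrical field-of-view truncation — in particular its
  brain/ventricle (CSF) contrast is erased, mimicking CBCT soft-tissue HU
  unreliability;
* the T1 MRI shows strong soft-tissue contrast (dark CSF, bright brain,
  near-zero bone and air) modulated by a smooth multiplicative bias field.

All intensity tables are configurable phantom defaults, not clinical
calibrations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import RigidTransform, VolumeGrid
from . import volio

__all__ = [
    "LABEL_NAMES",
    "PhantomSpec",
    "CbctDegradation",
    "LabelVolume",
    "GroundTruthTriplet",
    "InvalidSpecError",
    "DEFAULT_CT_HU_TABLE",
    "DEFAULT_MRI_TABLE",
    "generate_label_volume",
    "render_ct",
    "simulate_cbct",
    "simulate_t1_mri",
    "generate_triplet",
    "make_dataset",
]

# Integer organ codes of the label volume.
AIR, SOFT_TISSUE, SKULL, BRAIN, VENTRICLE, EYE, LENS, OPTIC_NERVE, NASAL = range(9)

LABEL_NAMES: dict[int, str] = {
    AIR: "background_air",
    SOFT_TISSUE: "soft_tissue",
    SKULL: "skull",
    BRAIN: "brain",
    VENTRICLE: "ventricle",
    EYE: "eye",
    LENS: "lens",
    OPTIC_NERVE: "optic_nerve",
    NASAL: "nasal_air_cavity",
}

ALL_CODES = frozenset(LABEL_NAMES)

HU_MIN, HU_MAX = -1024.0, 3072.0

#: code -> (mean HU, noise sd).  Phantom defaults, not clinical values.
DEFAULT_CT_HU_TABLE: dict[int, tuple[float, float]] = {
    AIR: (-1000.0, 5.0),
    SOFT_TISSUE: (40.0, 3.0),
    SKULL: (1000.0, 15.0),
    BRAIN: (35.0, 3.0),
    VENTRICLE: (5.0, 2.0),
    EYE: (30.0, 3.0),
    LENS: (80.0, 3.0),
    OPTIC_NERVE: (40.0, 3.0),
    NASAL: (-1000.0, 5.0),
}

#: code -> mean T1 intensity (arbitrary units).  CSF dark, brain bright,
#: bone and air near zero — the contrast ordering of a T1-weighted scan.
DEFAULT_MRI_TABLE: dict[int, float] = {
    AIR: 0.0,
    SOFT_TISSUE: 75.0,
    SKULL: 5.0,
    BRAIN: 90.0,
    VENTRICLE: 40.0,
    EYE: 35.0,
    LENS: 70.0,
    OPTIC_NERVE: 80.0,
    NASAL: 0.0,
}


class InvalidSpecError(ValueError):
    """Phantom geometry inconsistent with the requested grid or head bounds."""


@dataclass
class PhantomSpec:
    """Parameters of one phantom realization.

    Defaults use a desk-scale 64x64x32 grid at 4 mm isotropic spacing
    (25.6 x 25.6 x 12.8 cm extent).  Clinical-geometry grids are obtained by
    passing the acquisition spacing/shape explicitly.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    head_axes_mm: tuple[float, float, float] = (100.0, 115.0, 55.0)
    organ_toggles: dict[str, bool] = field(default_factory=lambda: {
        "skull": True, "brain": True, "ventricles": True, "eyes": True,
        "lenses": True, "optic_nerves": True, "nasal_cavities": True,
    })
    seed: int = 0
    jitter_frac: float = 0.05

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be strictly positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")
        if any(a <= 0 for a in self.head_axes_mm):
            raise InvalidSpecError(f"head_axes_mm must be strictly positive, got {self.head_axes_mm}")
        half_extent = 0.5 * np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        if np.any(np.asarray(self.head_axes_mm) > half_extent + 1e-9):
            raise InvalidSpecError(
                f"head semi-axes {self.head_axes_mm} exceed grid half-extent {tuple(half_extent)}")


@dataclass
class LabelVolume:
    """Integer organ-code volume (uint8), codes 0..8 per :data:`LABEL_NAMES`."""

    labels: VolumeGrid

    def __post_init__(self) -> None:
        data = np.asarray(self.labels.data)
        present = set(np.unique(data).tolist())
        bad = present - ALL_CODES
        if bad:
            raise ValueError(f"label volume contains unknown codes {sorted(bad)}")
        self.labels = self.labels.with_data(data.astype(np.uint8))

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels.data, list(codes))

    def head_mask(self) -> np.ndarray:
        """All voxels belonging to the head (everything except background air)."""
        return self.labels.data != AIR


@dataclass
class GroundTruthTriplet:
    """Aligned CT/CBCT/MRI volumes plus ground-truth labels for one session."""

    ct: VolumeGrid
    cbct: VolumeGrid
    mri: VolumeGrid
    labels: LabelVolume
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        ref = self.ct
        for name in ("cbct", "mri"):
            vol = getattr(self, name)
            if not vol.same_grid_as(ref):
                raise ValueError(f"{name} grid metadata differs from CT grid")
        if not self.labels.labels.same_grid_as(ref):
            raise ValueError("label grid metadata differs from CT grid")


@dataclass
class CbctDegradation:
    """CBCT corruption model: per-tissue affine HU error + cupping + blur +
    noise + cylindrical FOV truncation.

    The default per-tissue offsets wash the whole soft-tissue family (soft
    tissue, brain, CSF, eyes, lenses, optic nerves) out to a single level of
    60 HU: the CBCT then carries no soft-tissue discrimination at all,
    while bone and air remain clearly identifiable — the soft-tissue HU
    unreliability that motivates adding MRI.  ``offset_jitter_sd`` draws
    one additional random offset per *jitter group* and acquisition
    (soft-tissue family / bone / air), and ``cupping_jitter`` randomizes
    the cupping amplitude, emulating session-to-session HU inconsistency:
    a CBCT-only model cannot learn a stable soft-tissue intensity mapping.
    """

    hu_scale: dict[int, float] = field(default_factory=lambda: {c: 1.0 for c in ALL_CODES})
    hu_offset: dict[int, float] = field(default_factory=lambda: {
        AIR: 0.0, SOFT_TISSUE: 20.0, SKULL: -80.0, BRAIN: 25.0, VENTRICLE: 55.0,
        EYE: 30.0, LENS: -20.0, OPTIC_NERVE: 20.0, NASAL: 0.0,
    })
    #: per-acquisition random offset sd, drawn once per jitter group
    offset_jitter_sd: dict[int, float] = field(default_factory=lambda: {
        AIR: 0.0, SOFT_TISSUE: 15.0, SKULL: 30.0, BRAIN: 15.0, VENTRICLE: 15.0,
        EYE: 15.0, LENS: 15.0, OPTIC_NERVE: 15.0, NASAL: 0.0,
    })
    #: tissues in the same group share one jitter draw per acquisition, so
    #: their relative CBCT contrast is stable by construction
    jitter_groups: dict[int, int] = field(default_factory=lambda: {
        AIR: 0, NASAL: 0, SKULL: 1, SOFT_TISSUE: 2, BRAIN: 2, VENTRICLE: 2,
        EYE: 2, LENS: 2, OPTIC_NERVE: 2,
    })
    cupping_amplitude: float = 50.0
    cupping_jitter: float = 0.5
    blur_sigma_mm: float = 1.2
    noise_sd: float = 10.0
    fov_diameter_mm: float = 300.0

    @staticmethod
    def identity(fov_diameter_mm: float = 1e6) -> "CbctDegradation":
        return CbctDegradation(
            hu_scale={c: 1.0 for c in ALL_CODES},
            hu_offset={c: 0.0 for c in ALL_CODES},
            offset_jitter_sd={c: 0.0 for c in ALL_CODES},
            cupping_amplitude=0.0, cupping_jitter=0.0, blur_sigma_mm=0.0,
            noise_sd=0.0, fov_diameter_mm=fov_diameter_mm)


# --------------------------------------------------------------------------
# geometry

def _canonical_anatomy(head_axes_mm) -> dict:
    """Organ geometry (centres/axes in mm, head-centred RAS world coords)."""
    ax, ay, az = head_axes_mm
    s = np.array([ax / 100.0, ay / 115.0, az / 55.0])  # scale relative to default head
    def c(x, y, z):
        return np.array([x, y, z]) * s
    return {
        "head": {"center": np.zeros(3), "axes": np.array(head_axes_mm, dtype=float)},
        # skull: ellipsoidal shell (outer/inner as fractions of the head axes)
        "skull": {"outer_frac": 0.88, "inner_frac": 0.78},
        "brain": {"center": c(0.0, -5.0, 8.0), "axes": np.array([0.72 * ax, 0.70 * ay, 0.72 * az])},
        "ventricles": {
            "centers": [c(-16.0, -5.0, 10.0), c(16.0, -5.0, 10.0)],
            "axes": np.array([14.0, 34.0, 16.0]) * s,
        },
        "eyes": {"centers": [c(-30.0, 78.0, -8.0), c(30.0, 78.0, -8.0)], "radius": 12.0 * float(s.min())},
        "lenses": {"offset_y": 9.0 * s[1], "radius": 4.5 * float(s.min())},
        "optic_nerves": {"radius": 4.5 * float(s.min()),
                         "target": c(0.0, 10.0, 0.0)},
        "nasal_cavities": {"center": c(0.0, 68.0, -30.0), "axes": np.array([16.0, 28.0, 18.0]) * s},
    }


def _jitter_anatomy(anat: dict, rng: np.random.Generator, frac: float) -> dict:
    """Randomly perturb organ centres and sizes by a relative fraction."""
    out = copy.deepcopy(anat)
    if frac <= 0:
        return out
    head_axes = out["head"]["axes"]
    # absolute wobbles scale with head size so small test heads stay valid
    size_scale = float(np.mean(head_axes / np.array([100.0, 115.0, 55.0])))
    def wobble(arr, scale):
        return arr + rng.normal(0.0, frac * scale * size_scale, size=np.shape(arr))
    out["brain"]["center"] = wobble(out["brain"]["center"], 10.0)
    # ventricle anatomy varies far more across subjects (and treatment
    # stages, e.g. atrophy, hydrocephalus, cystic change) than the rigid
    # organs: position wanders by several mm and each side's size by tens
    # of percent, so a fixed geometric prior cannot predict them
    out["ventricles"]["centers"] = [wobble(v, 80.0)
                                    for v in out["ventricles"]["centers"]]
    base_axes = out["ventricles"]["axes"]
    out["ventricles"]["axes"] = [np.abs(base_axes * (1 + rng.normal(0, 7.0 * frac, 3)))
                                 for _ in out["ventricles"]["centers"]]
    out["eyes"]["centers"] = [wobble(v, 5.0) for v in out["eyes"]["centers"]]
    out["eyes"]["radius"] = abs(out["eyes"]["radius"] * (1 + rng.normal(0, frac)))
    out["nasal_cavities"]["center"] = wobble(out["nasal_cavities"]["center"], 6.0)
    out["nasal_cavities"]["axes"] = np.abs(out["nasal_cavities"]["axes"] * (1 + rng.normal(0, frac, 3)))
    # keep everything that must sit inside the head actually inside
    for key, centers in (("ventricles", out["ventricles"]["centers"]),
                         ("eyes", out["eyes"]["centers"]),
                         ("nasal_cavities", [out["nasal_cavities"]["center"]])):
        for ctr in centers:
            if np.sum((ctr / head_axes) ** 2) >= 1.0:
                raise InvalidSpecError(f"jittered {key} centre {ctr} left the head ellipsoid")
    return out


def _world_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, VolumeGrid]:
    shape = np.asarray(spec.grid_shape, dtype=int)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = -0.5 * (shape - 1) * spacing  # head-centred grid
    grid = VolumeGrid(np.zeros(tuple(shape), dtype=np.uint8), spacing, origin)
    idx = [np.arange(n) for n in shape]
    xs = origin[0] + idx[0] * spacing[0]
    ys = origin[1] + idx[1] * spacing[1]
    zs = origin[2] + idx[2] * spacing[2]
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
    return x, y, z, grid


def _ellipsoid(x, y, z, center, axes) -> np.ndarray:
    return ((x - center[0]) / axes[0]) ** 2 + ((y - center[1]) / axes[1]) ** 2 \
        + ((z - center[2]) / axes[2]) ** 2 <= 1.0


def _capsule(x, y, z, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (a thick tube)."""
    d = p1 - p0
    L2 = float(np.dot(d, d))
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / max(L2, 1e-12), 0.0, 1.0)
    dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return dist2 <= radius ** 2


def generate_label_volume(spec: PhantomSpec) -> LabelVolume:
    """Rasterize one (jittered) anatomy into an organ-code volume.

    Deterministic for identical spec (including seed).  Organs are painted
    in back-to-front priority order, and every non-background voxel lies
    inside the head ellipsoid.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xA11A]))
    anat = _jitter_anatomy(_canonical_anatomy(spec.head_axes_mm), rng, spec.jitter_frac)
    return rasterize_anatomy(anat, spec)


def rasterize_anatomy(anat: dict, spec: PhantomSpec) -> LabelVolume:
    x, y, z, grid = _world_coords(spec)
    head_axes = anat["head"]["axes"]
    head = _ellipsoid(x, y, z, anat["head"]["center"], head_axes)
    lab = np.zeros(spec.grid_shape, dtype=np.uint8)
    lab[head] = SOFT_TISSUE
    t = spec.organ_toggles

    brain_mask = None
    if t.get("skull", False):
        outer = _ellipsoid(x, y, z, anat["head"]["center"], head_axes * anat["skull"]["outer_frac"])
        inner = _ellipsoid(x, y, z, anat["head"]["center"], head_axes * anat["skull"]["inner_frac"])
        lab[outer & ~inner] = SKULL
        lab[inner] = SOFT_TISSUE
    if t.get("brain", False):
        brain_mask = _ellipsoid(x, y, z, anat["brain"]["center"], anat["brain"]["axes"]) & head
        lab[brain_mask] = BRAIN
    if t.get("nasal_cavities", False):
        nc = anat["nasal_cavities"]
        lab[_ellipsoid(x, y, z, nc["center"], nc["axes"]) & head] = NASAL
    if t.get("ventricles", False):
        if brain_mask is None:
            raise InvalidSpecError("ventricles require the brain toggle")
        vcenters = anat["ventricles"]["centers"]
        vaxes = anat["ventricles"]["axes"]
        if not isinstance(vaxes, list):
            vaxes = [vaxes] * len(vcenters)
        for ctr, axes in zip(vcenters, vaxes):
            vent = _ellipsoid(x, y, z, ctr, axes) & brain_mask
            lab[vent] = VENTRICLE
    eye_centers = anat["eyes"]["centers"]
    if t.get("eyes", False):
        for ctr in eye_centers:
            lab[_ellipsoid(x, y, z, ctr, np.full(3, anat["eyes"]["radius"])) & head] = EYE
    if t.get("optic_nerves", False):
        for ctr in eye_centers:
            tube = _capsule(x, y, z, np.asarray(ctr), anat["optic_nerves"]["target"],
                            anat["optic_nerves"]["radius"]) & head
            lab[tube & (lab != EYE)] = OPTIC_NERVE
    if t.get("lenses", False):
        if not t.get("eyes", False):
            raise InvalidSpecError("lenses require the eyes toggle")
        for ctr in eye_centers:
            lens_ctr = np.asarray(ctr) + np.array([0.0, anat["lenses"]["offset_y"], 0.0])
            lab[_ellipsoid(x, y, z, lens_ctr, np.full(3, anat["lenses"]["radius"])) & head] = LENS

    for name, toggled in t.items():
        code = {"skull": SKULL, "brain": BRAIN, "ventricles": VENTRICLE, "eyes": EYE,
                "lenses": LENS, "optic_nerves": OPTIC_NERVE, "nasal_cavities": NASAL}[name]
        if toggled and not np.any(lab == code):
            raise InvalidSpecError(
                f"toggled organ {name!r} rasterized to zero voxels on grid {spec.grid_shape}")
    return LabelVolume(grid.with_data(lab))


# --------------------------------------------------------------------------
# modality rendering

def render_ct(labels: LabelVolume,
              hu_table: Mapping[int, tuple[float, float]] | None = None,
              seed: int = 0) -> VolumeGrid:
    """Render the ground-truth CT: per-code mean HU + Gaussian noise, clipped
    to [-1024, 3072]."""
    table = DEFAULT_CT_HU_TABLE if hu_table is None else dict(hu_table)
    lab = labels.labels.data
    present = set(np.unique(lab).tolist())
    missing = present - set(table)
    if missing:
        raise KeyError(f"hu_table missing codes {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC7]))
    out = np.zeros(lab.shape, dtype=float)
    for code in sorted(present):
        mean, sd = table[code]
        m = lab == code
        out[m] = mean
        if sd > 0:
            out[m] += rng.normal(0.0, sd, size=int(m.sum()))
    return labels.labels.with_data(np.clip(out, HU_MIN, HU_MAX))


def simulate_cbct(ct: VolumeGrid, labels: LabelVolume,
                  degradation: CbctDegradation | None = None,
                  seed: int = 0) -> VolumeGrid:
    """Corrupt a CT into a CBCT-like volume.

    Applies, in order: per-tissue affine HU error, a radially increasing
    additive cupping field, Gaussian blur, voxel noise, cylindrical FOV
    truncation (outside voxels set to -1024), and final HU clipping.
    """
    deg = CbctDegradation() if degradation is None else degradation
    if deg.fov_diameter_mm <= 0:
        raise ValueError(f"fov_diameter_mm must be > 0, got {deg.fov_diameter_mm}")
    if not ct.same_grid_as(labels.labels):
        raise ValueError("ct and labels are not on the same grid")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCB]))
    lab = labels.labels.data
    out = np.asarray(ct.data, dtype=float).copy()
    # one unit normal per jitter group (drawn for every group, present or
    # not, so the realization per group is independent of anatomy)
    group_unit = {g: rng.standard_normal()
                  for g in sorted(set(deg.jitter_groups.values()))}
    for code in np.unique(lab):
        m = lab == code
        offset = deg.hu_offset.get(int(code), 0.0)
        jit_sd = deg.offset_jitter_sd.get(int(code), 0.0)
        if jit_sd > 0:
            grp = deg.jitter_groups.get(int(code))
            unit = group_unit[grp] if grp is not None else rng.standard_normal()
            offset += jit_sd * unit
        out[m] = out[m] * deg.hu_scale.get(int(code), 1.0) + offset

    shape = np.asarray(ct.shape)
    spacing = ct.spacing_mm
    center_idx = 0.5 * (shape - 1)
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    r_mm = np.hypot((ii - center_idx[0]) * spacing[0], (jj - center_idx[1]) * spacing[1])
    if deg.cupping_amplitude != 0.0:
        amp = deg.cupping_amplitude
        if deg.cupping_jitter > 0:
            amp *= 1.0 + deg.cupping_jitter * rng.uniform(-1.0, 1.0)
        r_max = float(r_mm.max())
        cup = amp * (r_mm / max(r_max, 1e-9)) ** 2
        out += cup[:, :, None]
    if deg.blur_sigma_mm > 0:
        out = ndimage.gaussian_filter(out, sigma=deg.blur_sigma_mm / spacing)
    if deg.noise_sd > 0:
        out += rng.normal(0.0, deg.noise_sd, size=out.shape)
    out[(r_mm > 0.5 * deg.fov_diameter_mm)[:, :, None] & np.ones(ct.shape, bool)] = HU_MIN
    return ct.with_data(np.clip(out, HU_MIN, HU_MAX))


def simulate_t1_mri(labels: LabelVolume,
                    contrast_table: Mapping[int, float] | None = None,
                    bias_field_amplitude: float = 0.03,
                    noise_sd: float = 2.0,
                    seed: int = 0) -> VolumeGrid:
    """Render a T1-weighted MRI: per-code mean intensity times a smooth
    multiplicative bias field, plus noise."""
    table = DEFAULT_MRI_TABLE if contrast_table is None else dict(contrast_table)
    if any(v < 0 for v in table.values()):
        raise ValueError("MRI contrast table entries must be non-negative")
    lab = labels.labels.data
    present = set(np.unique(lab).tolist())
    missing = present - set(table)
    if missing:
        raise KeyError(f"contrast_table missing codes {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3141]))
    out = np.zeros(lab.shape, dtype=float)
    for code in sorted(present):
        out[lab == code] = table[code]
    out *= bias_field(lab.shape, bias_field_amplitude, rng)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return labels.labels.with_data(np.maximum(out, 0.0))


def bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in ``[1 - amplitude, 1 + amplitude]``.

    Built from low-resolution Gaussian noise upsampled with cubic splines
    and rescaled so its extrema never exceed +-amplitude, guaranteeing a
    max/min ratio of at most ``(1 + a)/(1 - a)``.
    """
    if amplitude < 0 or amplitude >= 1:
        raise ValueError("bias amplitude must lie in [0, 1)")
    if amplitude == 0:
        return np.ones(shape)
    coarse_shape = tuple(max(2, s // 8) for s in shape)
    coarse = rng.normal(0.0, 1.0, size=coarse_shape)
    zoom = [s / c for s, c in zip(shape, coarse_shape)]
    fine = ndimage.zoom(coarse, zoom, order=3)
    fine = fine[tuple(slice(0, s) for s in shape)]
    peak = np.abs(fine).max()
    if peak > 0:
        fine = fine / peak
    return 1.0 + amplitude * fine


def generate_triplet(spec: PhantomSpec,
                     ct_table=None,
                     degradation: CbctDegradation | None = None,
                     mri_table=None,
                     mri_labels: LabelVolume | None = None) -> GroundTruthTriplet:
    """Full pipeline: labels -> CT -> CBCT -> MRI for one imaging session.

    ``mri_labels`` optionally renders the MRI from a different (earlier)
    anatomy, emulating a planning MRI acquired before anatomical change.
    """
    labels = generate_label_volume(spec)
    ct = render_ct(labels, ct_table, seed=spec.seed)
    cbct = simulate_cbct(ct, labels, degradation, seed=spec.seed)
    mri = simulate_t1_mri(mri_labels if mri_labels is not None else labels,
                          mri_table, seed=spec.seed)
    return GroundTruthTriplet(ct=ct, cbct=cbct, mri=mri, labels=labels)


def make_dataset(n_patients: int, triplets_per_patient: int,
                 spec_template: PhantomSpec | None = None,
                 out_dir: str | Path = "phantom_dataset",
                 compress: bool = False) -> pd.DataFrame:
    """Write a phantom cohort to disk and return its manifest.

    Per patient one MRI volume is rendered from the patient's baseline
    anatomy and reused across all of that patient's triplets, while each
    triplet's CT/CBCT get fresh anatomical jitter — emulating weekly CBCT/CT
    sessions evaluated against a single planning MRI.
    """
    if n_patients < 1 or triplets_per_patient < 1:
        raise ValueError("n_patients and triplets_per_patient must be >= 1")
    template = PhantomSpec() if spec_template is None else spec_template
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for p in range(n_patients):
        patient_seed = int(np.random.default_rng(
            np.random.SeedSequence([int(template.seed), p, 0x9A])).integers(0, 2**31 - 1))
        base_spec = replace(template, seed=patient_seed)
        base_labels = generate_label_volume(base_spec)
        mri = simulate_t1_mri(base_labels, seed=patient_seed)
        mri_path = out_dir / f"patient{p:03d}_mri{ext}"
        volio.write_volume(mri, mri_path)
        for k in range(triplets_per_patient):
            trip_seed = int(np.random.default_rng(
                np.random.SeedSequence([int(template.seed), p, k, 0x7])).integers(0, 2**31 - 1))
            spec = replace(template, seed=trip_seed)
            labels = generate_label_volume(spec)
            ct = render_ct(labels, seed=trip_seed)
            cbct = simulate_cbct(ct, labels, seed=trip_seed)
            stem = out_dir / f"patient{p:03d}_triplet{k:02d}"
            paths = {
                "ct_path": f"{stem}_ct{ext}",
                "cbct_path": f"{stem}_cbct{ext}",
                "labels_path": f"{stem}_labels{ext}",
            }
            volio.write_volume(ct, paths["ct_path"])
            volio.write_volume(cbct, paths["cbct_path"])
            volio.write_volume(labels.labels, paths["labels_path"], dtype=np.uint8)
            rows.append({"patient_id": f"patient{p:03d}", "triplet_id": k,
                         "mri_path": str(mri_path), **paths, "seed": trip_seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
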