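"""HU→SPR conversion and a simplified straight-ray proton range engine.

The engine replaces a clinical treatment-planning dose calculation with an
analytic depth-dose model: each 1×1 mm² beamlet of a monoenergetic lateral
field is traced as a straight ray, the water-equivalent path length (WEPL)
is accumulated from the stopping-power-ratio (SPR) volume, and an analytic
Bragg-shaped curve — whose distal 80% falloff in water sits exactly at the
configured ``r80_water_mm`` — is evaluated at each depth sample.  Range
geometry (distal R80 per beamlet, normalized range differences) is faithful
under this model; absolute dose is not (no lateral scatter, no nuclear
halo), which is sufficient for the range-difference and DVH mechanisms the
package evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grid import VolumeGrid

__all__ = [
    "SprCurve", "BeamSpec", "DoseLine", "R80Map", "DvhCurve", "InvalidLineError",
    "default_spr_curve", "hu_to_spr", "spr_relative_error",
    "wepl_profile", "bragg_curve", "compute_dose_line", "extract_distal_r80",
    "compute_r80_map", "r80_difference_histogram", "compute_dvh",
]


class InvalidLineError(ValueError):
    """A dose line with no usable Bragg peak / distal falloff."""


@dataclass
class SprCurve:
    """Piecewise-linear HU → stopping-power-ratio calibration.

    Nodes must have strictly increasing HU and non-decreasing, non-negative
    SPR, and the curve must pass through (0 HU, 1.0) within 1e-3 — the
    water anchor.  HU outside the node range clamp to the end SPR values.
    """

    nodes: tuple[tuple[float, float], ...]
    provenance: str = "package default (synthetic calibration)"

    def __post_init__(self) -> None:
        nodes = tuple((float(h), float(s)) for h, s in self.nodes)
        if len(nodes) < 2:
            raise ValueError("SPR curve needs at least two nodes")
        hu = np.array([n[0] for n in nodes])
        spr = np.array([n[1] for n in nodes])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("node HU values must be strictly increasing")
        if np.any(spr < 0):
            raise ValueError("SPR values must be non-negative")
        if np.any(np.diff(spr) < 0):
            raise ValueError("SPR must be monotone non-decreasing")
        water = float(np.interp(0.0, hu, spr))
        if abs(water - 1.0) > 1e-3:
            raise ValueError(f"curve violates the water anchor: SPR(0 HU) = {water}")
        self.nodes = nodes

    @property
    def hu(self) -> np.ndarray:
        return np.array([n[0] for n in self.nodes])

    @property
    def spr(self) -> np.ndarray:
        return np.array([n[1] for n in self.nodes])

    def __call__(self, hu_values: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(hu_values, dtype=float), self.hu, self.spr)

    @staticmethod
    def from_csv(path: str | Path) -> "SprCurve":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("SPR curve CSV needs two columns (HU, SPR) with a header")
        return SprCurve(tuple(zip(df.iloc[:, 0], df.iloc[:, 1])), provenance=str(path))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.nodes, columns=["hu", "spr"]).to_csv(path, index=False)


def default_spr_curve() -> SprCurve:
    """Small shipped calibration anchored at air, water and dense bone."""
    return SprCurve((
        (-1024.0, 0.001),
        (-200.0, 0.80),
        (0.0, 1.00),
        (60.0, 1.04),
        (1000.0, 1.52),
        (1500.0, 1.60),
        (3072.0, 2.20),
    ))


def hu_to_spr(vol: VolumeGrid, curve: SprCurve | None = None) -> VolumeGrid:
    """Voxelwise piecewise-linear HU → SPR conversion."""
    curve = curve or default_spr_curve()
    return vol.with_data(curve(vol.data))


def spr_relative_error(sct: VolumeGrid, ct: VolumeGrid,
                       curve: SprCurve | None = None, mask=None,
                       spr_floor: float = 0.1) -> tuple[float, VolumeGrid]:
    """Mean |SPR(sct) - SPR(ct)| / SPR(ct) × 100 over a mask.

    Voxels whose reference SPR falls below ``spr_floor`` are excluded so the
    ratio stays defined; returns (percent, relative-error map with NaN
    outside the evaluated region).
    """
    if not sct.same_grid_as(ct):
        raise ValueError("volumes are not aligned")
    curve = curve or default_spr_curve()
    spr_s = curve(sct.data)
    spr_c = curve(ct.data)
    m = np.ones(ct.shape, dtype=bool) if mask is None else np.asarray(
        mask.mask if hasattr(mask, "mask") else mask, dtype=bool)
    m = m & (spr_c >= spr_floor)
    if not m.any():
        raise ValueError("no voxels above the SPR floor in the mask")
    re_map = np.full(ct.shape, np.nan)
    re_map[m] = np.abs(spr_s[m] - spr_c[m]) / spr_c[m] * 100.0
    return float(np.nanmean(re_map[m])), ct.with_data(re_map)


# --------------------------------------------------------------------------
# beam geometry

@dataclass
class BeamSpec:
    """Monoenergetic lateral-beam geometry.

    The field is a square of side ``field_size_mm`` (80–100 mm) centred on
    the isocenter, perpendicular to ``direction``; beamlets sit on a
    ``beamlet_grid_mm`` lattice and depth-dose is sampled every
    ``dose_grid_mm``.  Beam energy is specified through its range in water,
    ``r80_water_mm``.
    """

    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_size_mm: float = 90.0
    spot_spacing_mm: float = 2.5
    beamlet_grid_mm: float = 1.0
    dose_grid_mm: float = 1.0
    r80_water_mm: float = 120.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("beam direction must be a nonzero vector")
        self.direction = tuple(d / n)
        if not 80.0 <= self.field_size_mm <= 100.0:
            raise ValueError(f"field_size_mm must lie in [80, 100], got {self.field_size_mm}")
        for name in ("spot_spacing_mm", "beamlet_grid_mm", "dose_grid_mm", "r80_water_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def lateral_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors spanning the field plane."""
        d = np.asarray(self.direction)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(d, helper)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(d, helper)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v


@dataclass
class DoseLine:
    """Depth-dose samples of one beamlet, normalized to its Bragg peak."""

    depths_mm: np.ndarray
    dose: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depths_mm.ndim != 1 or self.depths_mm.shape != self.dose.shape:
            raise ValueError("depths and dose must be matching 1D arrays")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ValueError("depths must be strictly increasing")


@dataclass
class R80Map:
    """2D lateral grid of distal-R80 depths (mm) with a validity mask."""

    r80_mm: np.ndarray
    valid: np.ndarray
    u_mm: np.ndarray
    v_mm: np.ndarray
    beam: BeamSpec

    def to_csv(self, path: str | Path) -> None:
        out = np.where(self.valid, self.r80_mm, np.nan)
        pd.DataFrame(out, index=self.u_mm, columns=self.v_mm).to_csv(path)


@dataclass
class DvhCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    structure: str = "structure"


# --------------------------------------------------------------------------
# depth-dose model

def _canonical_bragg_shape(u: np.ndarray) -> np.ndarray:
    """Unnormalized depth-dose shape on WEPL normalized to the nominal range:
    a slowly rising entrance plateau, a Gaussian Bragg peak and a sharp
    distal cutoff."""
    u = np.asarray(u, dtype=float)
    entrance = 0.35 + 0.10 * u
    peak = 0.65 * np.exp(-0.5 * ((u - 1.0) / 0.035) ** 2)
    cutoff = 1.0 / (1.0 + np.exp((u - 1.05) / 0.02))
    return (entrance + peak) * cutoff


def _shape_calibration() -> tuple[float, float]:
    """(max value, distal-0.8-crossing argument) of the canonical shape."""
    fine = np.linspace(0.0, 1.4, 14001)
    s = _canonical_bragg_shape(fine)
    smax = float(s.max())
    norm = s / smax
    above = norm >= 0.8
    last = np.max(np.nonzero(above))
    u80 = float(optimize.brentq(
        lambda u: _canonical_bragg_shape(u) / smax - 0.8, fine[last], fine[last + 1],
        xtol=1e-12))
    return smax, u80


_SHAPE_MAX, _SHAPE_U80 = _shape_calibration()


def bragg_curve(wepl_axis: np.ndarray, r80_water_mm: float) -> np.ndarray:
    """Normalized depth dose as a function of WEPL (mm).

    Peak value 1; the distal falloff crosses 0.8 exactly at
    ``wepl = r80_water_mm``; doubling the range stretches the whole curve
    by two.
    """
    if r80_water_mm <= 0:
        raise ValueError("r80_water_mm must be positive")
    u = np.asarray(wepl_axis, dtype=float) * (_SHAPE_U80 / r80_water_mm)
    return _canonical_bragg_shape(u) / _SHAPE_MAX


# --------------------------------------------------------------------------
# ray tracing

def _entry_and_span(vol: VolumeGrid, point: np.ndarray, direction: np.ndarray
                    ) -> tuple[float, float]:
    """Parametric [t_in, t_out] of the ray point + t·direction inside the
    volume bounding box (world mm; axis-aligned grids)."""
    lo = vol.origin_mm - 0.5 * vol.spacing_mm
    hi = vol.origin_mm + (np.asarray(vol.shape) - 0.5) * vol.spacing_mm
    t_in, t_out = -np.inf, np.inf
    for k in range(3):
        if abs(direction[k]) < 1e-12:
            if not (lo[k] <= point[k] <= hi[k]):
                return np.inf, -np.inf
            continue
        t0 = (lo[k] - point[k]) / direction[k]
        t1 = (hi[k] - point[k]) / direction[k]
        t_in = max(t_in, min(t0, t1))
        t_out = min(t_out, max(t0, t1))
    return t_in, t_out


def _sample_spr(spr_vol: VolumeGrid, points: np.ndarray, order: int = 1) -> np.ndarray:
    """SPR at world-mm points (linear or nearest lookup; outside → 0)."""
    idx = spr_vol.world_to_index(points.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(np.asarray(spr_vol.data, dtype=float), idx,
                                   order=order, mode="constant", cval=0.0)
    return vals.reshape(points.shape[:-1])


def wepl_profile(spr_vol: VolumeGrid, entry_mm, direction, step_mm: float = 1.0,
                 n_steps: int | None = None, interpolation: str = "linear"
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative water-equivalent depth along a straight ray.

    ``WEPL(k·step) = Σ_{i<k} SPR(midpoint_i) · step`` with SPR sampled at
    segment midpoints.  Returns (geometric depths, WEPL), both in mm.
    """
    entry = np.asarray(entry_mm, dtype=float)
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    if step_mm <= 0 or step_mm > float(spr_vol.spacing_mm.min()) + 1e-9:
        raise ValueError("step_mm must be positive and at most the voxel size")
    t_in, t_out = _entry_and_span(spr_vol, entry, d)
    if t_in > 1e-6 or t_out < 0:
        raise ValueError("entry point lies outside the volume")
    if n_steps is None:
        n_steps = int(np.floor(t_out / step_mm))
    order = {"linear": 1, "nearest": 0}[interpolation]
    mids = entry + (np.arange(n_steps)[:, None] + 0.5) * step_mm * d
    spr = _sample_spr(spr_vol, mids, order=order)
    depths = np.arange(n_steps + 1) * step_mm
    wepl = np.concatenate([[0.0], np.cumsum(spr) * step_mm])
    return depths, wepl


def extract_distal_r80(line: DoseLine) -> float:
    """Depth of the last downward 0.8 crossing beyond the Bragg peak,
    located by linear interpolation between bracketing depth samples."""
    dose = line.dose
    peak = int(np.argmax(dose))
    if peak >= dose.size - 1:
        raise InvalidLineError("peak at the domain boundary; no distal falloff")
    d = dose[peak:]
    crossing = (d[:-1] >= 0.8) & (d[1:] < 0.8)
    if not crossing.any():
        raise InvalidLineError("dose never falls below 80% beyond the peak")
    i = int(np.max(np.nonzero(crossing))) + peak
    frac = (dose[i] - 0.8) / (dose[i] - dose[i + 1])
    return float(line.depths_mm[i] + frac * (line.depths_mm[i + 1] - line.depths_mm[i]))


def compute_dose_line(spr_vol: VolumeGrid, beamlet_entry_mm, beam: BeamSpec) -> DoseLine:
    """Depth dose of one beamlet: Bragg curve evaluated at the WEPL of each
    ``dose_grid_mm`` depth sample, normalized to its own maximum."""
    step = min(beam.dose_grid_mm, float(spr_vol.spacing_mm.min()))
    depths, wepl = wepl_profile(spr_vol, beamlet_entry_mm, beam.direction, step_mm=step)
    # decimate to the dose grid
    stride = max(1, int(round(beam.dose_grid_mm / step)))
    depths = depths[::stride]
    wepl = wepl[::stride]
    dose = bragg_curve(wepl, beam.r80_water_mm)
    peak = dose.max()
    if peak <= 0:
        raise InvalidLineError("zero dose along the line")
    dose = dose / peak
    valid = True
    try:
        extract_distal_r80(DoseLine(depths, dose))
    except InvalidLineError:
        valid = False
    return DoseLine(depths, dose, valid=valid)


def compute_r80_map(spr_vol: VolumeGrid, beam: BeamSpec) -> R80Map:
    """Distal-R80 depth for every 1×1 mm beamlet of the field.

    Beamlets whose dose line has no Bragg peak followed by a distal 80%
    crossing inside the volume are masked invalid, never silently zero.
    """
    u, v = beam.lateral_axes()
    d = np.asarray(beam.direction)
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    half = beam.field_size_mm / 2.0
    offsets = np.arange(-half, half + 1e-9, beam.beamlet_grid_mm)
    step = min(beam.dose_grid_mm, float(spr_vol.spacing_mm.min()))

    # common parametric span covering the whole volume for every beamlet
    t_lo, t_hi = _entry_and_span(spr_vol, iso, d)
    if t_hi <= t_lo:
        raise ValueError("beam axis misses the volume")
    n_steps = int(np.floor((t_hi - t_lo) / step))
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")
    starts = iso + uu[..., None] * u + vv[..., None] * v + t_lo * d  # (U, V, 3)
    mids = starts[:, :, None, :] + (np.arange(n_steps)[None, None, :, None] + 0.5) * step * d
    spr = _sample_spr(spr_vol, mids)                                  # (U, V, n)
    wepl = np.concatenate([np.zeros((*spr.shape[:2], 1)), np.cumsum(spr, axis=-1) * step],
                          axis=-1)
    stride = max(1, int(round(beam.dose_grid_mm / step)))
    wepl = wepl[..., ::stride]
    dose = bragg_curve(wepl, beam.r80_water_mm)
    peak = dose.max(axis=-1, keepdims=True)
    ok = peak[..., 0] > 0
    dose = np.divide(dose, peak, out=np.zeros_like(dose), where=peak > 0)
    depths = np.arange(wepl.shape[-1]) * beam.dose_grid_mm

    nb, k = dose.shape[0] * dose.shape[1], dose.shape[2]
    flat = dose.reshape(nb, k)
    peak_idx = flat.argmax(axis=1)
    after_peak = np.arange(k - 1)[None, :] >= peak_idx[:, None]
    crossing = (flat[:, :-1] >= 0.8) & (flat[:, 1:] < 0.8) & after_peak
    has_cross = crossing.any(axis=1)
    last = (k - 2) - np.argmax(crossing[:, ::-1], axis=1)
    i = np.clip(last, 0, k - 2)
    frac = np.where(has_cross,
                    (flat[np.arange(nb), i] - 0.8)
                    / np.maximum(flat[np.arange(nb), i] - flat[np.arange(nb), i + 1], 1e-12),
                    0.0)
    r80 = depths[i] + frac * beam.dose_grid_mm
    valid = has_cross & (peak_idx > 0) & (peak_idx < k - 1) & ok.reshape(nb)
    if not valid.any():
        raise ValueError("no valid beamlets: the field misses the anatomy "
                         "or the beam range exceeds it")
    shape2d = dose.shape[:2]
    return R80Map(r80_mm=r80.reshape(shape2d), valid=valid.reshape(shape2d),
                  u_mm=offsets.copy(), v_mm=offsets.copy(), beam=beam)


def r80_difference_histogram(map_sct: R80Map, map_ct: R80Map, r80_water_mm: float,
                             bin_width_pct: float = 0.1, bin_span_pct: float = 5.0,
                             ) -> dict:
    """Per-beamlet R80 error of the sCT relative to the reference CT,
    expressed as a percentage of the range in water.

    Returns the histogram (overflow-capturing end bins), its bin edges and
    the summary statistics (mean, sd, fraction within ±1%).
    """
    if map_sct.r80_mm.shape != map_ct.r80_mm.shape:
        raise ValueError("R80 maps must share the beamlet grid")
    common = map_sct.valid & map_ct.valid
    if not common.any():
        raise ValueError("valid masks are disjoint")
    err_pct = (map_sct.r80_mm[common] - map_ct.r80_mm[common]) / r80_water_mm * 100.0
    edges = np.arange(-bin_span_pct, bin_span_pct + bin_width_pct / 2, bin_width_pct)
    counts, _ = np.histogram(err_pct, bins=np.concatenate([[-np.inf], edges, [np.inf]]))
    return {
        "errors_pct": err_pct,
        "counts": counts,
        "bin_edges": edges,
        "mean_pct": float(err_pct.mean()),
        "sd_pct": float(err_pct.std(ddof=0)),
        "frac_within_1pct": float(np.mean(np.abs(err_pct) <= 1.0)),
        "n_beamlets": int(common.sum()),
    }


def compute_dvh(dose_vol: VolumeGrid | np.ndarray, structure, dose_bins=None,
                name: str | None = None) -> DvhCurve:
    """Cumulative DVH: fraction of the structure receiving at least each
    dose level.  Starts at 1 for zero dose and reaches 0 beyond the
    maximum dose."""
    dose = np.asarray(dose_vol.data if isinstance(dose_vol, VolumeGrid) else dose_vol,
                      dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    mask = structure.mask if hasattr(structure, "mask") else np.asarray(structure, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure")
    vals = dose[mask]
    if dose_bins is None:
        top = float(vals.max())
        dose_bins = np.linspace(0.0, top * 1.05 if top > 0 else 1.0, 101)
    dose_bins = np.asarray(dose_bins, dtype=float)
    frac = np.array([np.mean(vals >= d) for d in dose_bins])
    if dose_bins[0] <= 0:
        frac[0] = 1.0  # every voxel receives >= 0 dose
    label = name or getattr(structure, "name", "structure")
    return DvhCurve(dose_axis=dose_bins, volume_fraction=frac, structure=label)
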