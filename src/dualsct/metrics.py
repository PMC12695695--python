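"""Image-quality and delineation metrics over tissue masks.

All intensity metrics operate in HU space on aligned volumes and are
evaluated only over an explicit region mask (brain tissue, skull, nasal
cavities, whole head, ...), never over the background.  Overlap metrics
(Dice, Hausdorff) compare binary segmentations on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import VolumeGrid
from .phantom import LABEL_NAMES, LabelVolume

__all__ = [
    "RegionMask", "region_from_labels", "brain_tissue_mask",
    "masked_mae", "masked_psnr", "masked_ssim",
    "hu_error_map", "hu_difference_histogram",
    "dice_coefficient", "hausdorff_distance", "delineation_report",
    "paired_model_comparison", "sharpness",
    "DEFAULT_DATA_RANGE",
]

#: Dynamic range of the clipped HU window [-1024, 3072], used as the default
#: PSNR/SSIM data range.
DEFAULT_DATA_RANGE = 4096.0


@dataclass
class RegionMask:
    """A named boolean region on the same grid as the volumes it gates."""

    mask: np.ndarray
    name: str = "region"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def region_from_labels(labels: LabelVolume, *codes: int, name: str | None = None) -> RegionMask:
    """Region covering the given organ codes of a label volume."""
    if name is None:
        name = "+".join(LABEL_NAMES.get(c, str(c)) for c in codes)
    return RegionMask(labels.mask(*codes), name)


def brain_tissue_mask(ct: VolumeGrid, head_mask: np.ndarray | None = None,
                      hu_floor: float = -200.0) -> RegionMask:
    """Default soft-tissue evaluation mask: head voxels with CT HU above a
    floor that excludes air.  Phantom pipelines normally use label-derived
    masks instead."""
    m = np.asarray(ct.data) > hu_floor
    if head_mask is not None:
        m &= np.asarray(head_mask, dtype=bool)
    return RegionMask(m, "brain_tissue")


def _as_mask(mask) -> np.ndarray:
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region mask")
    return m


def masked_mae(a: np.ndarray | VolumeGrid, b, mask) -> float:
    """Mean absolute difference over a mask (HU for CT-like inputs)."""
    a = np.asarray(a.data if isinstance(a, VolumeGrid) else a, dtype=float)
    b = np.asarray(b.data if isinstance(b, VolumeGrid) else b, dtype=float)
    m = _as_mask(mask)
    return float(np.mean(np.abs(a[m] - b[m])))


def masked_psnr(a, b, mask, data_range: float = DEFAULT_DATA_RANGE) -> float:
    """Peak signal-to-noise ratio, dB: ``10 log10(range^2 / masked MSE)``.

    Identical inputs return ``inf`` (the zero-MSE sentinel).
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    a = np.asarray(a.data if isinstance(a, VolumeGrid) else a, dtype=float)
    b = np.asarray(b.data if isinstance(b, VolumeGrid) else b, dtype=float)
    m = _as_mask(mask)
    mse = float(np.mean((a[m] - b[m]) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def masked_ssim(a, b, mask, window: int = 7, k1: float = 0.01, k2: float = 0.03,
                data_range: float = DEFAULT_DATA_RANGE) -> float:
    """Mean local structural similarity over window centres inside the mask.

    Local means/variances/covariance use a cubic ``window``^3 uniform
    filter; only centres whose full window lies inside the volume are
    eligible, and of those only the ones inside the mask contribute.
    """
    a = np.asarray(a.data if isinstance(a, VolumeGrid) else a, dtype=float)
    b = np.asarray(b.data if isinstance(b, VolumeGrid) else b, dtype=float)
    m = _as_mask(mask)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("volumes and mask must share a shape")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    r = window // 2
    if any(s < window for s in a.shape):
        raise ValueError(f"volume {a.shape} smaller than the {window}^3 window")
    mu_a = ndimage.uniform_filter(a, window)
    mu_b = ndimage.uniform_filter(b, window)
    mu_aa = ndimage.uniform_filter(a * a, window)
    mu_bb = ndimage.uniform_filter(b * b, window)
    mu_ab = ndimage.uniform_filter(a * b, window)
    var_a = mu_aa - mu_a ** 2
    var_b = mu_bb - mu_b ** 2
    cov = mu_ab - mu_a * mu_b
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
    interior = np.zeros_like(m)
    interior[r:-r or None, r:-r or None, r:-r or None] = True
    valid = m & interior
    if not valid.any():
        raise ValueError("mask has no window centres in the volume interior")
    return float(ssim_map[valid].mean())


def hu_error_map(sct: VolumeGrid, ct: VolumeGrid) -> VolumeGrid:
    """Signed voxelwise difference sct - ct (HU)."""
    if not sct.same_grid_as(ct):
        raise ValueError("volumes are not aligned on the same grid")
    return ct.with_data(np.asarray(sct.data, dtype=float) - np.asarray(ct.data, dtype=float))


def hu_difference_histogram(sct: VolumeGrid, ct: VolumeGrid, mask,
                            bin_edges: np.ndarray | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of sct - ct over a mask.

    Default bins: 50 HU wide spanning ±1000 HU, with unbounded end bins so
    the total count always equals the mask voxel count.
    """
    if bin_edges is None:
        bin_edges = np.arange(-1000.0, 1000.0 + 50.0, 50.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    m = _as_mask(mask)
    diff = hu_error_map(sct, ct).data[m]
    edges = np.concatenate([[-np.inf], bin_edges, [np.inf]])
    counts, _ = np.histogram(diff, bins=edges)
    return counts, bin_edges


def dice_coefficient(seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks score 1."""
    a = np.asarray(seg_a, dtype=bool)
    b = np.asarray(seg_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("segmentations must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def hausdorff_distance(seg_a: np.ndarray, seg_b: np.ndarray,
                       spacing=(1.0, 1.0, 1.0), percentile: float = 100.0) -> float:
    """(Percentile) Hausdorff distance in mm between two binary masks.

    Directed distances are measured from every voxel of one mask to the
    nearest voxel of the other via a Euclidean distance transform; the
    exact HD (percentile=100) takes the max, HD95 the 95th percentile, each
    symmetrized by the max of the two directions.
    """
    a = np.asarray(seg_a, dtype=bool)
    b = np.asarray(seg_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("segmentations must share a grid")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for empty masks")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    spacing = np.asarray(spacing, dtype=float)
    dist_to_b = ndimage.distance_transform_edt(~b, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~a, sampling=spacing)
    d_ab = dist_to_b[a]
    d_ba = dist_to_a[b]
    if percentile == 100:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def delineation_report(sct_labels: LabelVolume, ct_labels: LabelVolume,
                       organs: dict[str, int] | None = None,
                       percentile: float = 100.0) -> pd.DataFrame:
    """Per-organ DSC / HD table, prediction (sct) versus ground truth (ct).

    Organs missing from either volume are flagged (``present = False``)
    rather than silently scored.
    """
    if not sct_labels.labels.same_grid_as(ct_labels.labels):
        raise ValueError("label volumes must share a grid")
    if organs is None:
        organs = {name: code for code, name in LABEL_NAMES.items() if code != 0}
    spacing = ct_labels.labels.spacing_mm
    rows = []
    for name, code in organs.items():
        pred = sct_labels.mask(code)
        truth = ct_labels.mask(code)
        present = bool(pred.any()) and bool(truth.any())
        row = {"organ": name, "code": code, "present": present}
        if present:
            row["dsc"] = dice_coefficient(pred, truth)
            row["hd_mm"] = hausdorff_distance(pred, truth, spacing, percentile)
        else:
            row["dsc"] = np.nan
            row["hd_mm"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def paired_model_comparison(metric_values_model1, metric_values_model2) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-subject metrics.

    Uses the exact null distribution for n <= 25 (no ties); all-zero
    differences yield a degenerate report instead of a p-value.
    """
    x = np.asarray(metric_values_model1, dtype=float)
    y = np.asarray(metric_values_model2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D paired samples")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    diff = x - y
    if np.all(diff == 0):
        return {"statistic": 0.0, "p_value": np.nan, "n": int(x.size),
                "degenerate": True}
    method = "exact" if (x.size <= 25 and not np.any(diff == 0)) else "auto"
    res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
    # signed statistic: W+ - W- so swapping the models flips the sign
    ranks = stats.rankdata(np.abs(diff[diff != 0]))
    signed = float(np.sum(ranks[diff[diff != 0] > 0]) - np.sum(ranks[diff[diff != 0] < 0]))
    return {"statistic": signed, "p_value": float(res.pvalue), "n": int(x.size),
            "degenerate": False}


def sharpness(vol: VolumeGrid | np.ndarray, mask=None) -> float:
    """Mean absolute discrete Laplacian — a simple edge-content score used
    to compare adversarially trained output against smoother MAE-only
    output."""
    data = np.asarray(vol.data if isinstance(vol, VolumeGrid) else vol, dtype=float)
    lap = np.abs(ndimage.laplace(data))
    if mask is None:
        return float(lap.mean())
    return float(lap[_as_mask(mask)].mean())
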