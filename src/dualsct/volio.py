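"""Volume I/O and preprocessing.

Covers the standard conditioning applied to CT/CBCT/MRI volumes before
training: NIfTI round-tripping, rigid resampling into the CT grid, HU
clipping to [-1024, 3072], min-max normalization to [-1, 1], patient-level
train/val/test splitting, and axial slice batching for 2D models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import RigidTransform, VolumeGrid

__all__ = [
    "NormalizationBounds",
    "HU_BOUNDS",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "resample_rigid",
    "clip_hu",
    "normalize_minmax",
    "denormalize",
    "split_patients",
    "iter_axial_slices",
]


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a NIfTI volume."""


@dataclass(frozen=True)
class NormalizationBounds:
    """Intensity window (lo, hi) used for clipping and min-max scaling."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError(f"require hi > lo, got ({self.lo}, {self.hi})")

    @staticmethod
    def from_volume(vol: VolumeGrid) -> "NormalizationBounds":
        """Per-volume (min, max) bounds — the convention used for MRI."""
        lo = float(vol.data.min())
        hi = float(vol.data.max())
        if hi <= lo:
            raise ValueError("degenerate intensity range: volume is constant")
        return NormalizationBounds(lo, hi)


#: The fixed CT/CBCT Hounsfield window every HU volume is clipped to.
HU_BOUNDS = NormalizationBounds(-1024.0, 3072.0)


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume into a :class:`VolumeGrid`.

    The NIfTI affine is decomposed into spacing (column norms), direction
    (normalized columns) and origin (translation part).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        aff = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"{path}: degenerate affine (zero spacing column)")
    direction = lin / spacing
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-4):
        raise VolumeFormatError(f"{path}: affine is not rigid+scale (sheared direction)")
    return VolumeGrid(data, spacing, aff[:3, 3], direction)


def write_volume(vol: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    nib.save(img, str(path))


def resample_rigid(
    moving: VolumeGrid,
    reference: VolumeGrid,
    t: RigidTransform | None = None,
    interpolation: str = "linear",
    fill_value: float = -1024.0,
) -> VolumeGrid:
    """Resample ``moving`` onto the grid of ``reference``.

    ``t`` maps reference world coordinates into moving world coordinates
    (the registration transform); identity by default.  Out-of-support
    voxels receive ``fill_value`` (-1024 for HU images, 0 for MRI).
    """
    if t is None:
        t = RigidTransform.identity()
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")

    # index_m = A_m^-1 (R (A_r i + o_r) + tr - o_m), with A = direction @ diag(spacing)
    a_r = reference.direction @ np.diag(reference.spacing_mm)
    a_m = moving.direction @ np.diag(moving.spacing_mm)
    a_m_inv = np.linalg.inv(a_m)
    matrix = a_m_inv @ t.rotation @ a_r
    offset = a_m_inv @ (t.rotation @ reference.origin_mm + t.translation_mm - moving.origin_mm)
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=float),
        matrix,
        offset=offset,
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=fill_value,
    )
    return VolumeGrid(out, reference.spacing_mm.copy(), reference.origin_mm.copy(),
                      reference.direction.copy())


def clip_hu(vol: VolumeGrid, bounds: NormalizationBounds = HU_BOUNDS) -> VolumeGrid:
    """Clamp voxel values into ``[bounds.lo, bounds.hi]`` (idempotent)."""
    return vol.with_data(np.clip(vol.data, bounds.lo, bounds.hi))


def normalize_minmax(vol: VolumeGrid, bounds: NormalizationBounds) -> VolumeGrid:
    """Map ``[lo, hi] -> [-1, +1]`` linearly: ``v' = 2 (v - lo)/(hi - lo) - 1``."""
    lo, hi = bounds.lo, bounds.hi
    return vol.with_data(2.0 * (np.asarray(vol.data, dtype=float) - lo) / (hi - lo) - 1.0)


def denormalize(vol: VolumeGrid, bounds: NormalizationBounds) -> VolumeGrid:
    """Exact inverse of :func:`normalize_minmax`."""
    lo, hi = bounds.lo, bounds.hi
    return vol.with_data((np.asarray(vol.data, dtype=float) + 1.0) * (hi - lo) / 2.0 + lo)


def split_patients(
    patient_ids: Iterable,
    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Partition patient ids into (train, val, test) at the patient level.

    Validation and test sizes are ``floor(fraction * n)``; the remainder
    goes to training.  Deterministic for a given seed.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ids)
    n_val = int(np.floor(f_val * n))
    n_test = int(np.floor(f_test * n))
    n_nonzero = sum(f > 0 for f in fractions)
    if n < n_nonzero:
        raise ValueError(f"{n} patients cannot fill {n_nonzero} nonempty partitions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    val = shuffled[:n_val]
    test = shuffled[n_val:n_val + n_test]
    train = shuffled[n_val + n_test:]
    return train, val, test


def iter_axial_slices(
    triplet,
    batch: int = 3,
    with_mri: bool = True,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield axial (input stack, CT target) batches from a normalized triplet.

    Inputs are stacked channel-first, CBCT first then (optionally) MRI, so
    batches have shape ``(b, C, H, W)`` with ``C`` = 1 or 2 and targets
    ``(b, 1, H, W)``.  The final partial batch is yielded as-is.
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    ct = np.asarray(triplet.ct.data, dtype=float)
    cbct = np.asarray(triplet.cbct.data, dtype=float)
    n_slices = ct.shape[2]
    if with_mri:
        mri = np.asarray(triplet.mri.data, dtype=float)
        stack = np.stack([cbct, mri], axis=0)  # (2, H, W, K)
    else:
        stack = cbct[None]  # (1, H, W, K)
    for start in range(0, n_slices, batch):
        sl = slice(start, min(start + batch, n_slices))
        x = np.moveaxis(stack[:, :, :, sl], 3, 0)       # (b, C, H, W)
        y = np.moveaxis(ct[None, :, :, sl], 3, 0)       # (b, 1, H, W)
        yield np.ascontiguousarray(x), np.ascontiguousarray(y)
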