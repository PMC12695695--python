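"""Volume containers and rigid transforms.

A :class:`VolumeGrid` is the common currency of the package: a 3D scalar
array together with the geometric metadata (voxel spacing, world origin,
axis-direction matrix) needed to place every voxel in RAS world millimetre
coordinates.  Indexing is 0-based and the world coordinate of voxel index
``i`` is ``origin + direction @ (i * spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "RigidTransform"]

_ORTHO_TOL = 1e-6


@dataclass
class VolumeGrid:
    """A 3D scalar volume with voxel spacing, origin and orientation.

    Parameters
    ----------
    data
        3D array, indexed ``[i, j, k]``.  Axial slices are ``data[:, :, k]``.
    spacing_mm
        Per-axis voxel size in millimetres, strictly positive.
    origin_mm
        World (RAS, mm) coordinate of voxel ``(0, 0, 0)``.
    direction
        3x3 axis-direction matrix, orthonormal to within ``1e-6``.
    """

    data: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix is not orthonormal within 1e-6")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world(mm) affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return (self.direction @ (idx * self.spacing_mm).T).T + self.origin_mm

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (self.direction.T @ (xyz - self.origin_mm).T).T / self.spacing_mm

    def same_grid_as(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this grid's metadata with different voxel data."""
        if data.shape != self.data.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.data.shape}")
        return VolumeGrid(data, self.spacing_mm.copy(), self.origin_mm.copy(),
                          self.direction.copy())

    def copy(self) -> "VolumeGrid":
        return self.with_data(self.data.copy())

    def world_extent_mm(self) -> np.ndarray:
        """Physical side lengths of the grid bounding box, in mm."""
        return np.asarray(self.shape) * self.spacing_mm


@dataclass
class RigidTransform:
    """Proper rigid world transform ``x -> rotation @ x + translation_mm``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal within 1e-6")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (self.rotation @ xyz.T).T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation_mm + self.translation_mm)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_euler(angles_deg: np.ndarray, translation_mm: np.ndarray) -> "RigidTransform":
        """Rigid transform from x/y/z Euler angles (degrees, applied z·y·x)."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return RigidTransform(rz @ ry @ rx, translation_mm)
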