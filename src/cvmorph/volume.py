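"""Scalar 3D volumes with world geometry.

A :class:`Volume3D` is the package's in-memory image container: a scalar
intensity grid plus the affine pieces (voxel spacing in mm, origin, axis
direction matrix) needed to map 0-based voxel indices to world millimetre
coordinates.  World coordinates are RAS-like; the origin is the world
position of the corner voxel's *center*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume3D:
    """A 3D scalar image with voxel-to-world geometry.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar grid, axis order matching the direction matrix columns.
    spacing_mm : 3-tuple of float
        Voxel edge lengths in mm, all positive.
    origin_mm : 3-tuple of float
        World coordinate of the center of voxel (0, 0, 0).
    orientation : (3, 3) ndarray
        Orthonormal direction matrix; columns are the world directions of
        the voxel axes.  Identity by default.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation @ np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_world(self, idx) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm, shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.orientation @ np.diag(self.spacing_mm)).T + self.origin_mm

    def world_to_index(self, xyz) -> np.ndarray:
        """Map world mm to fractional voxel indices, shape (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.orientation @ np.diag(self.spacing_mm))
        return (xyz - np.asarray(self.origin_mm)) @ inv.T

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def like(self, intensities: np.ndarray) -> "Volume3D":
        """A new volume sharing this one's geometry."""
        if intensities.shape != self.shape:
            raise ValueError("shape mismatch")
        return Volume3D(intensities, self.spacing_mm, self.origin_mm, self.orientation.copy())
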