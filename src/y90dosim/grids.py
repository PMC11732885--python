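"""Voxel grid container and NIfTI round-tripping.

A :class:`VoxelGrid` holds a 3-D scalar field (SPECT-like counts, activity in
GBq per voxel, or absorbed dose in Gy) on an isotropic lattice.  World
coordinates are in millimetres; the affine written to NIfTI is diagonal with
the voxel pitch on the diagonal and the grid origin in the translation column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "load_mask", "save_mask"]


@dataclass
class VoxelGrid:
    """3-D scalar field with isotropic spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative finite voxel values.
    spacing_mm : float
        Isotropic voxel pitch in mm (> 0).
    origin_mm : tuple of 3 floats
        World position of voxel (0, 0, 0), mm.
    """

    values: np.ndarray
    spacing_mm: float = 4.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")
        if np.any(self.values < 0):
            raise ValueError("voxel values must be non-negative")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        self.origin_mm = tuple(float(c) for c in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (spacing^3 / 1000)."""
        return self.spacing_mm**3 / 1000.0

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry and different values."""
        return VoxelGrid(values, self.spacing_mm, self.origin_mm)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    # ---- NIfTI I/O -------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelGrid":
        img = nib.load(path)
        aff = img.affine
        spacings = np.abs(np.diag(aff)[:3])
        if not np.allclose(spacings, spacings[0], rtol=1e-5):
            raise ValueError("anisotropic NIfTI grids are not supported")
        return cls(
            np.asarray(img.dataobj, dtype=float),
            float(spacings[0]),
            tuple(aff[:3, 3]),
        )


def save_mask(mask: np.ndarray, grid: VoxelGrid, path: str) -> None:
    """Write a binary mask as 8-bit NIfTI sharing *grid*'s affine."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine)
    nib.save(img, path)


def load_mask(path: str) -> np.ndarray:
    img = nib.load(path)
    return np.asarray(img.dataobj) > 0
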