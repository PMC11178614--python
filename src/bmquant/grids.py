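"""Voxel-grid container and NIfTI I/O.

A :class:`VoxelGrid` is the single imaging substrate used throughout the
package: a 3D scalar field (SUV in the dimensionless g/mL convention, or CT
Hounsfield units) together with its voxel spacing in millimetres. PET and CT
grids are assumed co-registered on the same lattice; no resampling is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "read_volume", "write_volume"]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field. SUV grids are non-negative in practice but this is not
        enforced (noise may dip below zero); values must be finite.
    spacing_mm : tuple of 3 floats
        Voxel edge lengths in mm, strictly positive.
    origin_mm : tuple of 3 floats
        Position of voxel (0, 0, 0) in mm (carried through I/O, otherwise
        unused: all analysis is voxel-indexed).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values, self.spacing_mm, self.origin_mm)


def _affine(grid: VoxelGrid) -> np.ndarray:
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    return affine


def write_volume(grid: VoxelGrid, path: str, dtype=None) -> None:
    """Write a grid as NIfTI (.nii or .nii.gz); spacing goes into the affine."""
    data = grid.values if dtype is None else grid.values.astype(dtype)
    nib.save(nib.Nifti1Image(data, _affine(grid)), path)


def read_volume(path: str) -> VoxelGrid:
    """Read a NIfTI volume into a :class:`VoxelGrid`.

    Raises a descriptive error for non-3D images.
    """
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelGrid(np.asarray(data), tuple(float(z) for z in zooms), origin)
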