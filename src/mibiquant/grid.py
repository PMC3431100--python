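"""Voxel-grid container shared by the CT and SPECT sides of the pipeline.

A :class:`VoxelGrid` is a 3-D scalar array with physical spacing and origin.
The index convention throughout the package is ``(slice, row, col)`` with the
slice axis running chest-wall -> nipple; coordinates are voxel-centred,
0-based, in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class VoxelGrid:
    """3-D scalar volume with physical geometry.

    Parameters
    ----------
    values : ndarray
        3-D array; units depend on the carrier (cm^-1 for CT attenuation,
        counts or uCi/mL for SPECT).
    spacing : tuple of float
        Voxel edge lengths in mm per axis (slice, row, col).
    origin : tuple of float
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.508, 0.508, 0.508)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1 cm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N, 3) to physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates (N, 3) to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy_with(self, values: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry and different values."""
        return VoxelGrid(values=np.asarray(values), spacing=self.spacing,
                         origin=self.origin)

    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32),
                                 affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelGrid":
        img = nib.load(path)
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(o) for o in affine[:3, 3])
        return cls(values=np.asarray(img.dataobj, dtype=float),
                   spacing=spacing, origin=origin)


@dataclass
class BreastMask:
    """Boolean breast support on a voxel grid.

    ``provenance`` records whether the mask came from CT skin stripping or
    from the emission-defined attenuation support.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "skin_stripped"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("BreastMask requires a 3-D array")
        if self.provenance not in ("skin_stripped", "attenuation_mask"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "BreastMask":
        return BreastMask(self.mask.copy(), self.spacing, self.origin,
                          self.provenance)
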