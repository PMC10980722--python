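"""Volume grid: the spatial frame shared by every voxelwise analysis.

A :class:`VolumeGrid` bundles a 3D lattice shape, a voxel-to-mm affine and a
boolean grey-matter mask.  All maps in the pipeline (contrast maps,
prediction maps, coupling maps, stat maps) live on a grid and are stored as
flat vectors over the in-mask voxels; the grid provides the round trip to
full 3D volumes and NIfTI-1 images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid"]


@dataclass
class VolumeGrid:
    """3D lattice + voxel->mm affine + boolean analysis mask.

    Parameters
    ----------
    shape : tuple of 3 ints
        Lattice dimensions in voxels.
    affine : (4, 4) ndarray
        Voxel-index to mm (RAS) affine.
    mask : (shape) bool ndarray
        Analysis (grey-matter) mask; voxelwise results are only defined
        inside it.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    # -- constructors ----------------------------------------------------

    @classmethod
    def isotropic(
        cls,
        shape: tuple[int, int, int],
        voxel_size_mm: float = 3.0,
        mask: np.ndarray | None = None,
    ) -> "VolumeGrid":
        """Diagonal RAS affine with the mm origin at the grid center.

        When ``mask`` is omitted an inscribed ellipsoid is used as a
        desk-scale stand-in for a grey-matter mask.
        """
        if voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        shape = tuple(int(s) for s in shape)
        center = (np.asarray(shape) - 1) / 2.0
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = -center * voxel_size_mm
        if mask is None:
            mask = ellipsoid_mask(shape)
        return cls(shape=shape, affine=affine, mask=mask)

    # -- coordinates -----------------------------------------------------

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to mm coordinates (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates (n, 3) to fractional voxel indices (n, 3)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    # -- mask bookkeeping ------------------------------------------------

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def mask_ijk(self) -> np.ndarray:
        """(n_voxels, 3) integer indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    @property
    def mask_mm(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of in-mask voxel centers."""
        return self.voxel_to_mm(self.mask_ijk)

    def flat_index_volume(self) -> np.ndarray:
        """Volume of running in-mask indices; -1 outside the mask."""
        vol = np.full(self.shape, -1, dtype=np.int64)
        vol[self.mask] = np.arange(self.n_voxels)
        return vol

    def unmask(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a masked vector (..., n_voxels) back into a volume."""
        values = np.asarray(values)
        out = np.full(values.shape[:-1] + self.shape, fill, dtype=float)
        out[..., self.mask] = values
        return out

    def mask_values(self, volume: np.ndarray) -> np.ndarray:
        """Gather the in-mask voxels of a volume into a flat vector."""
        return np.asarray(volume)[..., self.mask] if volume.ndim > 3 else np.asarray(volume)[self.mask]

    # -- I/O ---------------------------------------------------------------

    def to_nifti(self, data: np.ndarray) -> nib.Nifti1Image:
        """Wrap a volume (3D/4D, or masked vector) as a NIfTI-1 image."""
        data = np.asarray(data)
        if data.ndim == 1 and data.shape[0] == self.n_voxels:
            data = self.unmask(data)
        if data.ndim == 2 and data.shape[-1] == self.n_voxels:
            # time/subject axis last in NIfTI convention
            data = np.moveaxis(self.unmask(data), 0, -1)
        return nib.Nifti1Image(np.asarray(data, dtype=np.float64), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, mask: np.ndarray | None = None) -> "VolumeGrid":
        shape = img.shape[:3]
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        return cls(shape=tuple(shape), affine=np.asarray(img.affine), mask=mask)


def ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Inscribed ellipsoid: a compact stand-in for a grey-matter mask."""
    ax = [(np.arange(s) - (s - 1) / 2.0) / (s / 2.0) for s in shape]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    return ii**2 + jj**2 + kk**2 <= 1.0
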