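"""Voxel grid geometry shared by all pipeline stages.

World coordinates are millimetres. A voxel with index ``i`` along an axis is
centred at ``origin + i * voxel_size`` and owns the half-open cell
``[origin + (i - 1/2) * voxel_size, origin + (i + 1/2) * voxel_size)``, so a
point landing exactly on a cell boundary belongs to the voxel with the larger
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """An axis-aligned isotropic voxel grid.

    Parameters
    ----------
    dims
        Number of voxels along each of the three axes.
    voxel_size
        Isotropic edge length in mm (default 2).
    origin
        World position (mm) of the centre of voxel (0, 0, 0).
    ap_axis
        Index of the anterior-posterior axis; slices of constant index along
        this axis play the role of coronal slices.
    """

    dims: tuple[int, int, int]
    voxel_size: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ap_axis: int = 1

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.ap_axis not in (0, 1, 2):
            raise ValueError(f"ap_axis must be 0, 1 or 2, got {self.ap_axis}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 voxel-to-world affine."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (``(..., 3)``) to world mm (voxel centres)."""
        return np.asarray(indices, dtype=float) * self.voxel_size + np.asarray(self.origin)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (``(..., 3)``) to integer voxel indices.

        Boundary points go to the larger index (half-open cells).
        """
        rel = (np.asarray(points, dtype=float) - np.asarray(self.origin)) / self.voxel_size
        return np.floor(rel + 0.5).astype(np.int64)

    def contains(self, indices: np.ndarray) -> np.ndarray:
        """Boolean mask of index rows that fall inside the grid."""
        idx = np.asarray(indices)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=-1)

    def ap_extent_mm(self) -> float:
        """Physical extent of the grid along the AP axis in mm."""
        return self.dims[self.ap_axis] * self.voxel_size

    def slice_center_mm(self, slice_index: np.ndarray | int) -> np.ndarray | float:
        """World AP coordinate (mm) of the centre of an AP slice."""
        return np.asarray(slice_index, dtype=float) * self.voxel_size + self.origin[self.ap_axis]

    def ap_to_slice(self, ap_mm: np.ndarray | float) -> np.ndarray | int:
        """AP slice index owning a world AP coordinate (half-open cells)."""
        rel = (np.asarray(ap_mm, dtype=float) - self.origin[self.ap_axis]) / self.voxel_size
        out = np.floor(rel + 0.5).astype(np.int64)
        return int(out) if out.ndim == 0 else out
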