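"""Common voxel space for all stimulation volumes.

Every binary volume of tissue activated (VTA) in a cohort lives on one
shared, axis-aligned voxel grid (the stand-in for a cohort-specific atlas
space).  World coordinates follow the voxel-center convention: the center
of voxel ``(0, 0, 0)`` sits at ``origin`` and voxel ``(i, j, k)`` at
``origin + index * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """An axis-aligned 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis (all >= 1).
    voxel_size
        Edge length of a voxel along each axis in mm (all > 0).
    origin
        World (mm) coordinates of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be three entries > 0, got {self.voxel_size}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a] for a in range(3)
        )

    def contains_point(self, point) -> bool:
        """Whether a world point lies inside the grid's physical extent.

        The extent spans half a voxel beyond the outermost voxel centers.
        """
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.voxel_size)
        hi = (
            np.asarray(self.origin)
            + (np.asarray(self.shape) - 0.5) * np.asarray(self.voxel_size)
        )
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def nearest_voxel(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to a world point."""
        p = np.asarray(point, dtype=float)
        idx = np.rint((p - np.asarray(self.origin)) / np.asarray(self.voxel_size)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def empty_mask(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=bool)
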