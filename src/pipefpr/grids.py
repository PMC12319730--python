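"""Voxel grid geometry shared by all modules.

A :class:`VolumeGrid` is the minimal geometry a contrast map needs: array
shape, voxel size in mm, and the world position of voxel (0, 0, 0). Axes are
assumed axis-aligned (no rotation/shear), which is all the synthetic cohort
and the harmonization steps require; maps are taken to live in a common
anatomical space already.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; every entry must be >= 8.
    voxel_size : tuple of float
        Voxel edge length in mm along each axis; strictly positive.
    origin_offset : tuple of float
        World-space (mm) position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(
            self, "origin_offset", tuple(float(v) for v in self.origin_offset)
        )
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ValueError("VolumeGrid is three-dimensional")
        if any(s < 8 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 8, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal scaling plus translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin_offset
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        """True if the two grids sample identical world locations."""
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin_offset, other.origin_offset, atol=tol)
        )


#: Desk-scale default used throughout tests and examples: 32 mm-cube brain
#: stand-in at 2 mm isotropic resolution.
DEFAULT_GRID = VolumeGrid(shape=(32, 32, 32), voxel_size=(2.0, 2.0, 2.0))
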