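"""Shared spatial primitives: image grids, world coordinates, NIfTI I/O.

All volumes in this package are numpy arrays indexed ``(i, j, k)`` together
with a 4x4 voxel-to-world affine in millimetres (RAS orientation for
phantom-generated data).  :class:`Grid` bundles shape and affine so that
every module can check geometric compatibility the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Grid", "load_volume", "save_volume"]


@dataclass(frozen=True)
class Grid:
    """A voxel lattice embedded in world (mm) space."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> world, mm

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_size: float = 2.0) -> "Grid":
        """Centred isotropic grid: world origin at the grid centre."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([voxel_size] * 3 + [1.0])
        affine[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
        return cls(shape, affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def world_coords(self) -> np.ndarray:
        """(3, *shape) array of world coordinates of voxel centres."""
        idx = np.indices(self.shape, dtype=float)
        hom = np.concatenate([idx, np.ones((1,) + self.shape)], axis=0)
        return np.einsum("ij,j...->i...", self.affine, hom)[:3]

    def matches(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "Grid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise ValueError(f"geometry mismatch between {what}: "
                             f"{self.shape} vs {other.shape} or differing affines")


def load_volume(path) -> tuple[np.ndarray, Grid]:
    """Read a 3-D or 4-D NIfTI file, returning (data, grid of the spatial axes)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = Grid(tuple(data.shape[:3]), np.asarray(img.affine))
    return data, grid


def save_volume(data: np.ndarray, grid: Grid, path) -> None:
    """Write data on ``grid`` as 32-bit float NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
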