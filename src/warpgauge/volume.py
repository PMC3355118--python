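"""The universal raster type: a 3D intensity grid with a voxel-to-world affine.

World coordinates are right-handed RAS millimetres throughout the package,
defined by the volume's voxel-to-world affine; voxel indices are 0-based.
This matches the NIfTI convention, so volumes round-trip losslessly through
nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D single-channel image on a regular grid.

    Parameters
    ----------
    data
        3D float array of intensities, indexed ``[i, j, k]``.
    affine
        4x4 voxel-to-world matrix: ``world = affine @ [i, j, k, 1]`` in mm.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """World position of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to fractional voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    @property
    def center_world(self) -> np.ndarray:
        """World coordinates of the geometric grid centre."""
        center_ijk = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.voxel_to_world(center_ijk)

    def grid_world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.moveaxis(idx, 0, -1)
        return self.voxel_to_world(ijk)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.affine.copy())

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume with the same grid but different intensities."""
        if data.shape != self.data.shape:
            raise ValueError("data shape mismatch")
        return ImageVolume(np.asarray(data, dtype=np.float64), self.affine.copy())

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )
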