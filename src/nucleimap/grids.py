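"""Reference grids and volume I/O.

All 3-D volumes in this package live on an explicit :class:`Grid` — a voxel
array shape plus a 4x4 affine mapping 0-based voxel indices to world
coordinates in millimetres (MNI-style RAS convention).  Orientation is always
taken from the affine, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "GridMismatchError", "save_volume", "load_volume"]


class GridMismatchError(ValueError):
    """Two volumes do not share a common grid (no silent resampling)."""


@dataclass(frozen=True)
class Grid:
    """A regular 3-D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Voxel array shape ``(nx, ny, nz)``.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm affine.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, shape, origin_mm=(0.0, 0.0, 0.0), voxel_size_mm=1.0) -> "Grid":
        """Axis-aligned grid with isotropic voxels and given world origin."""
        aff = np.eye(4)
        aff[:3, :3] *= float(voxel_size_mm)
        aff[:3, 3] = origin_mm
        return cls(tuple(shape), aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def matches(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "Grid") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape} vs {other.shape} or differing affines"
            )

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out

    def mm_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates for world points (no rounding)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def mm_to_nearest_voxel(self, xyz) -> tuple[np.ndarray, np.ndarray]:
        """Round world points to nearest voxel indices.

        Returns ``(indices, inside)`` where ``inside`` flags points whose
        nearest voxel lies within the grid.
        """
        cont = self.mm_to_voxel(xyz)
        idx = np.rint(cont).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        return idx, inside

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of every voxel centre, one array per axis."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        A, t = self.affine[:3, :3], self.affine[:3, 3]
        x = A[0, 0] * ii + A[0, 1] * jj + A[0, 2] * kk + t[0]
        y = A[1, 0] * ii + A[1, 1] * jj + A[1, 2] * kk + t[1]
        z = A[2, 0] * ii + A[2, 1] * jj + A[2, 2] * kk + t[2]
        return x, y, z


def save_volume(path, data: np.ndarray, grid: Grid) -> None:
    """Write a volume as NIfTI-1 with the grid's affine."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, grid.affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data, Grid(tuple(data.shape[:3]), img.affine)
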