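"""Voxel grids and image volumes.

The universal currency between all pipeline stages is a non-negative
activity image on a regular grid with a *center-origin* world frame:
world coordinate (0,0,0) sits at the geometric center of the grid, the
``y`` axis is normal to the detector panels and ``z`` is axial.  Grids
may be 2D (a single transaxial slice, used for desk-scale work) or 3D;
every operation in the package accepts both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "ImageVolume", "read_nifti", "write_nifti"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular (2D or 3D) voxel lattice centered on the world origin.

    Parameters
    ----------
    shape
        Grid dimensions ``(nx, ny)`` or ``(nx, ny, nz)``.
    voxel_size
        Edge length of a voxel in mm per axis.  A scalar is broadcast
        to all axes; default 1 mm isotropic.
    """

    shape: tuple
    voxel_size: tuple = field(default=None)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got shape {shape}")
        if any(s < 1 for s in shape):
            raise ValueError(f"all grid dims must be >= 1, got {shape}")
        vs = self.voxel_size
        if vs is None:
            vs = 1.0
        if np.isscalar(vs):
            vs = (float(vs),) * len(shape)
        else:
            vs = tuple(float(v) for v in vs)
        if len(vs) != len(shape):
            raise ValueError("voxel_size must match grid dimensionality")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be > 0, got {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent_mm(self) -> tuple:
        """Physical edge lengths of the grid in mm."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    @property
    def half_extent_mm(self) -> tuple:
        return tuple(e / 2.0 for e in self.extent_mm)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        v = self.voxel_size[axis]
        return (np.arange(n) - (n - 1) / 2.0) * v

    def coord_grids(self):
        """World-coordinate arrays of all voxel centers (open meshgrid)."""
        return np.meshgrid(
            *[self.axis_coords(a) for a in range(self.ndim)], indexing="ij", sparse=True
        )

    def index_to_world(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        n = np.asarray(self.shape, dtype=float)
        v = np.asarray(self.voxel_size, dtype=float)
        return (idx - (n - 1) / 2.0) * v

    def world_to_index(self, world) -> np.ndarray:
        """Continuous (fractional) index of a world point; inverse of
        :meth:`index_to_world` for any in-grid point."""
        w = np.asarray(world, dtype=float)
        n = np.asarray(self.shape, dtype=float)
        v = np.asarray(self.voxel_size, dtype=float)
        return w / v + (n - 1) / 2.0

    def contains_world(self, world) -> bool:
        idx = self.world_to_index(world)
        return bool(
            np.all(idx > -0.5) and np.all(idx < np.asarray(self.shape) - 0.5)
        )

    def affine(self) -> np.ndarray:
        """4x4 NIfTI affine mapping voxel indices to world mm (center origin)."""
        shape3 = self.shape + (1,) * (3 - self.ndim)
        vs3 = self.voxel_size + (1.0,) * (3 - self.ndim)
        aff = np.eye(4)
        for a in range(3):
            aff[a, a] = vs3[a]
            aff[a, 3] = -(shape3[a] - 1) / 2.0 * vs3[a]
        return aff


@dataclass
class ImageVolume:
    """A (2D or 3D) activity image bound to its :class:`VoxelGrid`."""

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: VoxelGrid) -> "ImageVolume":
        return cls(np.zeros(grid.shape), grid)

    @classmethod
    def full(cls, grid: VoxelGrid, value: float) -> "ImageVolume":
        return cls(np.full(grid.shape, float(value)), grid)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.grid)

    def total(self) -> float:
        return float(self.data.sum())

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.grid == other.grid


def write_nifti(vol: ImageVolume, path) -> None:
    data = vol.data
    if vol.grid.ndim == 2:  # store single-slice 3D
        data = data[:, :, None]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), vol.grid.affine())
    img.header.set_zooms(vol.grid.voxel_size + (1.0,) * (3 - vol.grid.ndim))
    nib.save(img, str(path))


def read_nifti(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    if data.ndim == 3 and data.shape[2] == 1 and abs(float(zooms[2]) - 1.0) < 1e-9:
        data = data[:, :, 0]
        grid = VoxelGrid(data.shape, tuple(float(z) for z in zooms[:2]))
    else:
        grid = VoxelGrid(data.shape, tuple(float(z) for z in zooms[: data.ndim]))
    return ImageVolume(data, grid)
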