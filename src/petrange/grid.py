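"""Voxelized volumes with millimetre geometry.

The scanner's axial direction (the B0 axis of the magnet) is the third
array axis, z.  World coordinates follow the voxel-center convention:
voxel index ``i`` (0-based) along an axis sits at ``origin + i * voxel_size``.
Voxels are isotropic throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError, FormatError

AXES = ("x", "y", "z")


@dataclass
class VoxelGrid:
    """A 3D non-negative intensity volume on an isotropic mm grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative intensities (arbitrary units: activity concentration,
        annihilation counts, or mass density depending on context).
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : ndarray, shape (3,)
        World (mm) coordinates of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: float = 0.5
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not self.voxel_size > 0:
            raise DataError(f"voxel_size must be > 0, got {self.voxel_size}")
        if np.any(self.values < 0):
            raise DataError("voxel values must be non-negative")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int | str) -> np.ndarray:
        """World (mm) coordinates of voxel centers along one axis."""
        ax = AXES.index(axis) if isinstance(axis, str) else axis
        n = self.shape[ax]
        return self.origin[ax] + np.arange(n) * self.voxel_size

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.voxel_size

    def world_to_index(self, point) -> np.ndarray:
        """Nearest voxel index of a world point; raises if outside the grid."""
        fidx = (np.asarray(point, float) - self.origin) / self.voxel_size
        idx = np.rint(fidx).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise DataError(f"point {point} outside grid of shape {self.shape}")
        return idx

    @property
    def center(self) -> np.ndarray:
        """World coordinates of the geometric center of the grid."""
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.voxel_size

    def congruent_with(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= atol
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.voxel_size, self.origin.copy())


def centered_grid(shape, voxel_size: float) -> VoxelGrid:
    """An all-zero grid whose world center is at the origin (0, 0, 0)."""
    shape = tuple(int(s) for s in shape)
    origin = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return VoxelGrid(np.zeros(shape), voxel_size, origin)


def write_volume(grid: VoxelGrid, path, sidecar: dict | None = None) -> None:
    """Write a grid as a NIfTI-1 volume; the affine encodes size and origin.

    If ``sidecar`` is given it is written as ``<path>.json`` next to the
    volume (provenance: generating spec, seeds, escape counts, ...).
    """
    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values.astype(np.float64), affine)
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_volume(path) -> VoxelGrid:
    """Read a NIfTI-1 volume written by :func:`write_volume`.

    Only isotropic voxels are supported; anisotropic files raise
    :class:`~petrange.errors.DataError` rather than being silently resampled.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = np.asarray(img.affine)
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise FormatError(f"could not read {path} as NIfTI-1: {exc}") from exc
    scales = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(scales, scales[0], atol=1e-6):
        raise DataError(f"anisotropic voxels {scales} are unsupported")
    if not np.allclose(affine[:3, :3], np.diag(scales), atol=1e-6):
        raise DataError("rotated/sheared affines are unsupported")
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    return VoxelGrid(data, float(scales[0]), affine[:3, 3])
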