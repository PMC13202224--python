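"""Digital twins of the physical resolution phantoms.

Two phantoms are modelled:

* a 25 mm cube of tissue-equivalent material pierced by three glass
  capillaries (inner bore filled with activity) arranged as an equilateral
  triangle in the transverse plane — used for line-profile resolution
  metrology in x, y and z;
* a microDerenzo phantom: six angular sectors of equal-diameter rods
  (1.5 down to 0.7 mm) on triangular lattices inside a cylindrical
  housing — used for rod-resolvability scoring.

Builders are deterministic (no RNG) and voxelize with in-plane subvoxel
supersampling so that partial-volume fractions are represented.  The rod
and capillary axes are the grid z axis (the B0 axis) at build time; the
perpendicular orientation is obtained with :func:`rotate_90`, a lossless
axis permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigError, GeometryError
from .grid import VoxelGrid, centered_grid
from .rangekernel import MaterialSpec

DENSITY_AIR = 0.0012  # g/cm^3
DENSITY_WATER = 1.0
DENSITY_GLASS = 2.2


@dataclass
class GridParams:
    """How to lay out the voxel grid around a phantom."""

    voxel_size: float = 0.5  # mm, isotropic
    margin: float = 5.0      # mm of air padding on every side
    supersample: int = 4     # in-plane subsamples per voxel edge

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be > 0")
        if self.supersample < 1:
            raise ConfigError("supersample must be >= 1")


@dataclass
class CapillaryPhantomSpec:
    """Three-capillary cube phantom (all lengths mm)."""

    cube_side: float = 25.0
    inner_diameter: float = 1.15
    outer_diameter: float = 1.5
    active_length: float = 39.0
    triangle_side: float = 8.0  # center-to-center capillary spacing
    material: MaterialSpec = dc_field(default_factory=lambda: MaterialSpec("PLA", 1.30))
    concentration: float = 1.0  # activity per mm^3 of bore, arbitrary units

    def __post_init__(self) -> None:
        if not self.inner_diameter < self.outer_diameter:
            raise ConfigError("inner_diameter must be < outer_diameter")
        if not self.triangle_side > self.outer_diameter:
            raise ConfigError("triangle_side must exceed outer_diameter (overlap)")

    def capillary_centers(self) -> np.ndarray:
        """(3, 2) transverse (x, y) centers, triangle centroid at (0, 0)."""
        circum = self.triangle_side / np.sqrt(3.0)
        angles = np.deg2rad([90.0, 210.0, 330.0])
        return circum * np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass
class DerenzoPhantomSpec:
    """MicroDerenzo phantom: one sector of rods per diameter."""

    rod_diameters: tuple[float, ...] = (1.5, 1.2, 1.0, 0.9, 0.8, 0.7)
    rod_length: float = 10.0
    housing_outer_diameter: float = 27.0
    center_spacing_factor: float = 2.0  # rod center spacing = factor * diameter
    keepout_radius: float = 4.0         # first rod row distance from center
    wall_margin: float = 1.5            # housing wall thickness kept rod-free
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.center_spacing_factor < 1.0:
            raise GeometryError(
                f"center_spacing_factor={self.center_spacing_factor} < 1 makes rods overlap"
            )
        if len(self.rod_diameters) < 1:
            raise ConfigError("at least one rod sector is required")


@dataclass
class Orientation:
    """Phantom orientation relative to B0 (the grid z axis)."""

    tag: str = "parallel"       # "parallel" | "perpendicular"
    rotation_axis: str = "x"    # transverse axis used for the 90 deg rotation

    def __post_init__(self) -> None:
        if self.tag not in ("parallel", "perpendicular"):
            raise ConfigError(f"unknown orientation {self.tag!r}")
        if self.rotation_axis not in ("x", "y"):
            raise ConfigError("rotation axis must be a transverse axis (x or y)")


# ---------------------------------------------------------------------------
# voxelization helpers

def _subvoxel_offsets(voxel_size: float, s: int) -> np.ndarray:
    """Centered subsample offsets covering one voxel edge."""
    return ((np.arange(s) + 0.5) / s - 0.5) * voxel_size


def _disk_occupancy(xc: np.ndarray, yc: np.ndarray, center, radius, s: int,
                    voxel_size: float) -> np.ndarray:
    """Fractional in-plane coverage of a disk over voxel cells.

    ``xc``/``yc`` are 1D voxel-center coordinate arrays; returns an
    (nx, ny) array of fractions in [0, 1] from an s x s subsample grid.
    """
    offs = _subvoxel_offsets(voxel_size, s)
    X = xc[:, None, None, None] + offs[None, None, :, None]
    Y = yc[None, :, None, None] + offs[None, None, None, :]
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius ** 2
    return inside.mean(axis=(2, 3))


def _axial_mask(zc: np.ndarray, length: float) -> np.ndarray:
    """Voxel centers with z in the half-open span [-L/2, L/2).

    The half-open convention makes the covered voxel count exactly
    length / voxel_size whenever that ratio is an integer, independent of
    grid phase.
    """
    return (zc >= -length / 2) & (zc < length / 2)


def _check_inside(xc, yc, cx, cy, radius, label: str) -> None:
    if (cx - radius < xc[0] or cx + radius > xc[-1]
            or cy - radius < yc[0] or cy + radius > yc[-1]):
        raise GeometryError(f"{label} (center {cx:.2f},{cy:.2f} mm, r={radius:.2f} mm) "
                            "does not fit inside the grid")


# ---------------------------------------------------------------------------
# builders

def build_capillary_phantom(
    spec: CapillaryPhantomSpec, grid_params: GridParams | None = None
) -> tuple[VoxelGrid, VoxelGrid]:
    """Voxelize the capillary cube phantom.

    Returns ``(activity, density)`` on congruent centered grids.  Activity
    is nonzero only inside the three inner bores (uniform concentration,
    partial-volume weighted at the bore edge).  The density grid carries
    glass in the capillary wall annulus, water in the bore, the cube
    material inside the cube and air (0.0012 g/cm^3) everywhere else —
    including the capillary overhang beyond the cube faces, where the
    glass tube passes through air.
    """
    gp = grid_params or GridParams()
    vs = gp.voxel_size
    extent_xy = spec.cube_side + 2 * gp.margin
    extent_z = max(spec.cube_side, spec.active_length) + 2 * gp.margin
    shape = (int(np.ceil(extent_xy / vs)),) * 2 + (int(np.ceil(extent_z / vs)),)
    activity = centered_grid(shape, vs)
    density = centered_grid(shape, vs)
    xc, yc, zc = (activity.axis_coords(a) for a in range(3))

    half = spec.cube_side / 2
    in_cube_xy = (np.abs(xc)[:, None] <= half) & (np.abs(yc)[None, :] <= half)
    in_cube_z = (np.abs(zc) <= half)
    dens = np.full(shape, DENSITY_AIR)
    dens[in_cube_xy[:, :, None] & in_cube_z[None, None, :]] = spec.material.density

    ax_mask = _axial_mask(zc, spec.active_length)
    for k, (cx, cy) in enumerate(spec.capillary_centers()):
        _check_inside(xc, yc, cx, cy, spec.outer_diameter / 2, f"capillary {k}")
        # density by voxel-center classification along the full tube length
        r2 = (xc[:, None] - cx) ** 2 + (yc[None, :] - cy) ** 2
        bore_c = r2 <= (spec.inner_diameter / 2) ** 2
        wall_c = (r2 <= (spec.outer_diameter / 2) ** 2) & ~bore_c
        dens[wall_c[:, :, None] & ax_mask[None, None, :]] = DENSITY_GLASS
        dens[bore_c[:, :, None] & ax_mask[None, None, :]] = DENSITY_WATER
        # activity: partial-volume bore occupancy
        if spec.inner_diameter > 0:
            frac = _disk_occupancy(xc, yc, (cx, cy), spec.inner_diameter / 2,
                                   gp.supersample, vs)
            activity.values[:, :, ax_mask] += (
                spec.concentration * frac[:, :, None]
            )
    density.values = dens
    return activity, density


def derenzo_rod_centers(spec: DerenzoPhantomSpec) -> dict[float, np.ndarray]:
    """Transverse (x, y) rod centers per diameter, mm, phantom center at 0.

    Each sector is a triangular ("apex toward the center") lattice with
    center spacing ``center_spacing_factor * d``, clipped so every rod
    keeps a clearance of one rod radius from the sector boundary lines and
    from the housing wall.
    """
    n_sectors = len(spec.rod_diameters)
    wedge_half = np.pi / n_sectors
    r_max = spec.housing_outer_diameter / 2 - spec.wall_margin
    out: dict[float, np.ndarray] = {}
    for i, d in enumerate(spec.rod_diameters):
        s = spec.center_spacing_factor * d
        pts = []
        j = 0
        while True:
            y = spec.keepout_radius + j * s * np.sqrt(3) / 2
            if y > r_max:
                break
            for k in range(j + 1):
                x = (k - j / 2) * s
                r = np.hypot(x, y)
                theta = np.arctan2(x, y)  # angle off the sector bisector
                if r + d / 2 > r_max:
                    continue
                if abs(theta) > wedge_half or r * np.sin(wedge_half - abs(theta)) < d / 2:
                    continue
                pts.append((x, y))
            j += 1
        bisector = (i + 0.5) * 2 * np.pi / n_sectors
        rot = np.array([[np.cos(bisector), np.sin(bisector)],
                        [-np.sin(bisector), np.cos(bisector)]])
        local = np.asarray(pts).reshape(-1, 2)
        out[d] = local @ rot
    return out


def build_derenzo_phantom(
    spec: DerenzoPhantomSpec, grid_params: GridParams | None = None
) -> VoxelGrid:
    """Voxelize the microDerenzo phantom activity (rods only)."""
    gp = grid_params or GridParams()
    vs = gp.voxel_size
    extent_xy = spec.housing_outer_diameter + 2 * gp.margin
    extent_z = spec.rod_length + 2 * gp.margin
    shape = (int(np.ceil(extent_xy / vs)),) * 2 + (int(np.ceil(extent_z / vs)),)
    activity = centered_grid(shape, vs)
    xc, yc, zc = (activity.axis_coords(a) for a in range(3))
    ax_mask = _axial_mask(zc, spec.rod_length)
    for d, centers in derenzo_rod_centers(spec).items():
        for cx, cy in centers:
            _check_inside(xc, yc, cx, cy, d / 2, f"rod d={d}")
            frac = _disk_occupancy(xc, yc, (cx, cy), d / 2, gp.supersample, vs)
            activity.values[:, :, ax_mask] += spec.concentration * frac[:, :, None]
    return activity


def rotate_90(grid: VoxelGrid, axis: str, k: int = 1) -> VoxelGrid:
    """Rotate a grid by exact 90-degree steps about a transverse axis.

    This is a pure axis permutation/flip — no interpolation, so intensity
    values and their sum are preserved exactly and four applications
    return the original array.  The world center of the grid is kept
    fixed.  Voxels are isotropic by construction, which is what makes the
    lossless permutation valid.
    """
    if axis not in ("x", "y"):
        raise ConfigError(f"rotation axis must be x or y, got {axis!r}")
    plane = (1, 2) if axis == "x" else (2, 0)
    vals = np.rot90(grid.values, k=k, axes=plane)
    center = grid.center
    shape = np.asarray(vals.shape)
    origin = center - (shape - 1) / 2.0 * grid.voxel_size
    return VoxelGrid(vals.copy(), grid.voxel_size, origin)
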