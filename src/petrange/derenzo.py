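"""Rod-resolvability scoring for Derenzo-style phantoms.

For every adjacent rod pair in a sector a line profile is sampled across
the two rods, the two peak intensities and the valley between them are
estimated with local 3-point parabolic fits, and the valley-to-peak
ratio VPR = valley / mean(peak_a, peak_b) is formed.  A sector is
*resolvable* when its mean VPR falls strictly below the Rayleigh
threshold 0.735 — the valley-to-peak ratio of two equal Airy diffraction
patterns at exactly the Rayleigh separation, which
:func:`airy_rayleigh_vpr` re-derives from first principles.

The smallest-resolvable-rod summary uses a contiguity rule: a diameter
counts only if its sector *and every larger-diameter sector* pass, which
guards against isolated noise-induced passes.

Rod centers are taken from the known synthetic phantom geometry;
automatic rod localization on measured images is out of scope.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.special import j1, jn_zeros

from .errors import DataError
from .grid import VoxelGrid
from .profiles import LineProfile, _parabola_vertex

RAYLEIGH_THRESHOLD = 0.735


# ---------------------------------------------------------------------------
# plane extraction

@dataclass
class PlaneImage:
    """A transverse (x, y) image plane with mm geometry."""

    values: np.ndarray      # (nx, ny)
    voxel_size: float
    origin: np.ndarray      # (2,) mm of pixel (0, 0) center

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise DataError("PlaneImage expects a 2D array")
        self.origin = np.asarray(self.origin, float).reshape(2)


def transverse_plane(volume: VoxelGrid, z_index: int | None = None,
                     n_average: int = 1) -> PlaneImage:
    """Extract (optionally axially averaged) transverse plane.

    Default is the central slice; ``n_average`` > 1 averages that many
    slices centered on ``z_index`` to trade axial information for counts.
    """
    nz = volume.shape[2]
    if z_index is None:
        z_index = nz // 2
    half = n_average // 2
    lo = max(0, z_index - half)
    hi = min(nz, lo + n_average)
    return PlaneImage(volume.values[:, :, lo:hi].mean(axis=2),
                      volume.voxel_size, volume.origin[:2])


# ---------------------------------------------------------------------------
# pair profiles and VPR

def pair_profile(plane: PlaneImage, center_a, center_b,
                 step: float | None = None) -> LineProfile:
    """Bilinear profile along the segment through two rod centers.

    The segment is extended by half the center distance beyond each
    center so both peaks are interior samples.
    """
    a = np.asarray(center_a, float)
    b = np.asarray(center_b, float)
    sep = np.linalg.norm(b - a)
    if sep == 0:
        raise DataError("rod centers coincide: degenerate profile segment")
    if step is None:
        step = plane.voxel_size / 2
    if step > plane.voxel_size / 2 + 1e-12:
        raise DataError("profile step must be <= half the pixel size")
    u = (b - a) / sep
    start = a - 0.5 * sep * u
    length = 2.0 * sep
    n = int(np.floor(length / step)) + 1
    s = np.arange(n) * step
    pts = start[None, :] + s[:, None] * u[None, :]
    fidx = (pts - plane.origin[None, :]) / plane.voxel_size
    nmax = np.asarray(plane.values.shape) - 1
    if np.any(fidx < -1e-9) or np.any(fidx > nmax[None, :] + 1e-9):
        raise DataError("extended pair segment leaves the image")
    vals = ndi.map_coordinates(plane.values, fidx.T, order=1, mode="nearest")
    return LineProfile(s, np.maximum(vals, 0.0), axis="x")


@dataclass
class VPRResult:
    vpr: float
    merged: bool = False
    peak_positions: tuple[float, float] | None = None
    valley_position: float | None = None


def pair_vpr(profile: LineProfile, peak_mode: str = "mean") -> VPRResult:
    """Valley-to-peak ratio of a two-rod profile.

    Peaks and the valley are 3-point parabolic vertices at the local
    argmax/argmin samples.  If no two distinct peaks with an interior
    valley exist the rods are merged and VPR = 1.0 is returned flagged.
    ``peak_mode`` selects the normalization: ``mean`` (default) or
    ``max`` of the two peak estimates.
    """
    if peak_mode not in ("mean", "max"):
        raise DataError(f"unknown peak_mode {peak_mode!r}")
    y = profile.intensities
    x = profile.positions
    idx, _ = find_peaks(y)
    if idx.size < 2:
        return VPRResult(1.0, merged=True)
    top = idx[np.argsort(y[idx])[-2:]]
    i, j = int(top.min()), int(top.max())
    if j - i < 2:
        return VPRResult(1.0, merged=True)
    seg = y[i + 1: j]
    v = i + 1 + int(np.argmin(seg))
    if y[v] >= min(y[i], y[j]):
        return VPRResult(1.0, merged=True)
    _, pa, _ = _parabola_vertex(x[i - 1: i + 2], y[i - 1: i + 2])
    _, pb, _ = _parabola_vertex(x[j - 1: j + 2], y[j - 1: j + 2])
    _, vv, _ = _parabola_vertex(x[v - 1: v + 2], y[v - 1: v + 2])
    peak = max(pa, pb) if peak_mode == "max" else 0.5 * (pa + pb)
    if peak <= 0:
        return VPRResult(1.0, merged=True)
    vpr = float(np.clip(vv / peak, 0.0, 1.0))
    return VPRResult(vpr, merged=False,
                     peak_positions=(float(x[i]), float(x[j])),
                     valley_position=float(x[v]))


# ---------------------------------------------------------------------------
# sectors and classification

@dataclass
class SectorLayout:
    """Known rod geometry of one sector."""

    rod_diameter: float
    centers: np.ndarray          # (n, 2) mm
    center_spacing: float        # design lattice spacing, mm

    def adjacent_pairs(self, tol: float = 1.05) -> list[tuple[int, int]]:
        tree = cKDTree(self.centers)
        return sorted(tree.query_pairs(self.center_spacing * tol))


@dataclass
class SectorResult:
    rod_diameter: float
    pair_vprs: list[float]
    mean_vpr: float
    resolvable: bool
    n_merged: int = 0


@dataclass
class VPRTable:
    """Per-sector VPR summary for one acquisition condition."""

    condition: str
    sectors: list[SectorResult]
    smallest_resolvable: float | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "rod_diameter_mm": [s.rod_diameter for s in self.sectors],
                "mean_vpr": [s.mean_vpr for s in self.sectors],
                "resolvable": [s.resolvable for s in self.sectors],
            }
        )


def sector_mean_vpr(plane: PlaneImage, layout: SectorLayout,
                    peak_mode: str = "mean",
                    threshold: float = RAYLEIGH_THRESHOLD) -> SectorResult:
    """Mean VPR over all adjacent rod pairs in one sector."""
    pairs = layout.adjacent_pairs()
    if not pairs:
        raise DataError(
            f"sector d={layout.rod_diameter}: fewer than one adjacent rod pair"
        )
    vprs, merged = [], 0
    for i, j in pairs:
        res = pair_vpr(pair_profile(plane, layout.centers[i], layout.centers[j]),
                       peak_mode)
        vprs.append(res.vpr)
        merged += res.merged
    mean = float(np.mean(vprs))
    return SectorResult(layout.rod_diameter, vprs, mean, mean < threshold, merged)


def classify_table(mean_vpr_by_diameter: dict[float, float],
                   condition: str = "",
                   threshold: float = RAYLEIGH_THRESHOLD) -> VPRTable:
    """Classify sector mean VPRs against the Rayleigh threshold.

    Resolvable means strictly below the threshold.  The smallest
    resolvable diameter obeys the contiguity rule (every larger sector
    must also pass); ``None`` when the largest sector already fails.
    """
    diameters = sorted(mean_vpr_by_diameter, reverse=True)
    sectors = [
        SectorResult(d, [], float(mean_vpr_by_diameter[d]),
                     float(mean_vpr_by_diameter[d]) < threshold)
        for d in diameters
    ]
    smallest = None
    for s in sectors:
        if s.resolvable:
            smallest = s.rod_diameter
        else:
            break
    return VPRTable(condition, sectors, smallest)


# ---------------------------------------------------------------------------
# packaged printed VPR rows

@functools.cache
def load_printed_vpr() -> pd.DataFrame:
    """Published per-sector mean VPRs for the seven acquisition conditions."""
    with resources.files("petrange.data").joinpath("table3_vpr.csv").open() as fh:
        return pd.read_csv(fh)


def printed_vpr_row(isotope: str, field_t: float,
                    orientation: str = "parallel") -> dict[float, float]:
    t = load_printed_vpr()
    row = t[(t.isotope == isotope) & (t.field_t == field_t)
            & (t.orientation == orientation)]
    if row.empty:
        raise DataError(f"no printed VPR row for {isotope} {field_t} T {orientation}")
    r = row.iloc[0]
    return {float(c.split("_")[1]): float(r[c]) for c in t.columns if c.startswith("vpr_")}


def classify_printed_rows(threshold: float = RAYLEIGH_THRESHOLD) -> dict[str, VPRTable]:
    """Classification of every packaged printed VPR row."""
    t = load_printed_vpr()
    out = {}
    for _, r in t.iterrows():
        label = f"{r.isotope} {r.field_t} T ({r.orientation})"
        row = printed_vpr_row(r.isotope, r.field_t, r.orientation)
        out[label] = classify_table(row, condition=label, threshold=threshold)
    return out


# ---------------------------------------------------------------------------
# Rayleigh criterion from first principles

def airy_intensity(x) -> np.ndarray:
    """Normalized Airy pattern intensity [2 J1(x)/x]^2 (x = pi kappa r)."""
    x = np.atleast_1d(np.asarray(x, float))
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
    return out


def airy_rayleigh_vpr(separation: float, n_samples: int = 20001) -> float:
    """VPR of two equal Airy patterns at ``separation`` Rayleigh units.

    One Rayleigh unit is the first-zero distance of the Airy pattern.
    The valley is the interior minimum of the densely evaluated 1D cut
    (at the midpoint, by symmetry); the peak is the total intensity at a
    source center.  ``separation`` = 1 reproduces the 0.735 threshold.
    """
    if separation < 0:
        raise DataError("separation must be >= 0")
    x0 = jn_zeros(1, 1)[0]  # 3.8317...
    d = separation * x0
    if d == 0:
        return 1.0
    xs = np.linspace(0.0, d, n_samples)
    prof = airy_intensity(xs) + airy_intensity(np.abs(xs - d))
    peak = float(prof[0])
    valley = float(prof[1:-1].min())
    return min(valley / peak, 1.0)
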