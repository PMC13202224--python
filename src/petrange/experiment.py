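"""End-to-end experiment orchestration and reporting.

A :class:`RunConfig` fully determines one acquisition condition
(phantom, isotope, material, field, orientation, kernel + seed,
reconstruction, analysis); every stochastic stage receives an explicit
seed, so any report can be regenerated bit-identically from its embedded
configuration.

Field comparisons are run with *matched seeds*: the 0 T and 9.4 T
conditions replay the same decay sample, so the percent changes isolate
the magnetic confinement effect rather than Monte Carlo noise.  (The
physical experiment this emulates compared two separate acquisitions;
matched seeds are the cleaner synthetic analogue.)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import __version__
from .derenzo import (RAYLEIGH_THRESHOLD, SectorLayout, VPRTable,
                      classify_table, sector_mean_vpr, transverse_plane)
from .errors import ConfigError
from .grid import VoxelGrid, centered_grid
from .phantoms import (CapillaryPhantomSpec, DerenzoPhantomSpec, GridParams,
                       build_capillary_phantom, build_derenzo_phantom,
                       derenzo_rod_centers, rotate_90, DENSITY_AIR)
from .profiles import FieldComparison, WidthMetrics, slice_averaged_metrics
from .rangekernel import (FieldSpec, MaterialSpec, RangeKernelConfig,
                          apply_range_blur, default_isotope, default_material)
from .recon import MLEMConfig, reconstruct_volume


@dataclass
class AnalysisConfig:
    n_adjacent_slices: int = 3      # slices averaged each side of center
    derenzo_axial_average: int = 1  # axial slices averaged into the VPR plane


@dataclass
class RunConfig:
    """One acquisition condition, fully seeded and serializable."""

    phantom: str = "capillary"  # "capillary" | "derenzo"
    isotope: str = "Ga-68"
    material: str = "PLA"
    field_t: float = 0.0
    orientation: str = "parallel"
    kernel: RangeKernelConfig = dc_field(default_factory=RangeKernelConfig)
    grid: GridParams = dc_field(default_factory=GridParams)
    recon: MLEMConfig = dc_field(default_factory=MLEMConfig)
    recon_bypass: bool = True
    analysis: AnalysisConfig = dc_field(default_factory=AnalysisConfig)
    capillary: dict = dc_field(default_factory=dict)  # CapillaryPhantomSpec overrides
    derenzo: dict = dc_field(default_factory=dict)    # DerenzoPhantomSpec overrides

    def __post_init__(self) -> None:
        if self.phantom not in ("capillary", "derenzo"):
            raise ConfigError(f"unknown phantom {self.phantom!r}")
        if self.orientation not in ("parallel", "perpendicular"):
            raise ConfigError(f"unknown orientation {self.orientation!r}")
        if self.field_t < 0:
            raise ConfigError("field_t must be >= 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("kernel", RangeKernelConfig), ("grid", GridParams),
                         ("recon", MLEMConfig), ("analysis", AnalysisConfig)):
            if key in d and isinstance(d[key], dict):
                try:
                    d[key] = sub(**d[key])
                except TypeError as exc:
                    raise ConfigError(f"bad {key!r} section: {exc}") from exc
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad run config: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        try:
            d = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable YAML config: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_field(self, field_t: float) -> "RunConfig":
        d = self.to_dict()
        d["field_t"] = field_t
        return RunConfig.from_dict(d)


def _require_matched(cfg0: RunConfig, cfg_b0: RunConfig) -> None:
    d0 = cfg0.to_dict()
    d1 = cfg_b0.to_dict()
    d0.pop("field_t")
    d1.pop("field_t")
    if d0 != d1:
        diff = [k for k in d0 if d0[k] != d1[k]]
        raise ConfigError(
            "field-comparison configs must be identical except field_t; "
            f"differing keys: {diff}"
        )


# ---------------------------------------------------------------------------
# capillary experiment

@dataclass
class ExperimentReport:
    """Container for one field-comparison experiment."""

    kind: str
    provenance: dict
    width_metrics: dict | None = None     # axis -> {"0T": WidthMetrics, "B0": ...}
    comparisons: dict | None = None       # axis -> {"fwhm"/"fwtm": FieldComparison}
    vpr_tables: dict | None = None        # condition label -> VPRTable

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, WidthMetrics):
                return {
                    "fwhm_mm": o.fwhm_mm, "fwtm_mm": o.fwtm_mm,
                    "fwhm_mean": o.fwhm_mean, "fwhm_sd": o.fwhm_sd,
                    "fwtm_mean": o.fwtm_mean, "fwtm_sd": o.fwtm_sd,
                    "n_slices_excluded": o.n_slices_excluded,
                }
            if isinstance(o, FieldComparison):
                return {"value_0t": o.value_0t, "value_b0": o.value_b0,
                        "percent_change": o.percent_change}
            if isinstance(o, VPRTable):
                return {
                    "condition": o.condition,
                    "smallest_resolvable_mm": o.smallest_resolvable,
                    "sectors": [dataclasses.asdict(s) for s in o.sectors],
                }
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(self.__dict__, default=enc, indent=2)


def _blur_and_reconstruct(activity: VoxelGrid, density: VoxelGrid,
                          cfg: RunConfig):
    iso = default_isotope(cfg.isotope)
    field = FieldSpec(cfg.field_t)
    rng = np.random.default_rng(cfg.kernel.seed)
    blur = apply_range_blur(activity, density, iso, field, cfg.kernel, rng)
    vol = reconstruct_volume(blur.annihilation, cfg.recon, bypass=cfg.recon_bypass)
    return vol, blur


def run_capillary_experiment(cfg0: RunConfig, cfg_b0: RunConfig) -> ExperimentReport:
    """Matched-seed 0 T vs B0 capillary width comparison.

    x/y profiles are taken from the capillary-parallel orientation, the z
    profile from the volume rotated 90 degrees about x (capillaries then
    along y), following the two-orientation acquisition scheme.
    """
    _require_matched(cfg0, cfg_b0)
    if cfg0.phantom != "capillary":
        raise ConfigError("run_capillary_experiment needs phantom='capillary'")
    mat = default_material(cfg0.material)
    spec = CapillaryPhantomSpec(material=mat, **cfg0.capillary)
    activity, density = build_capillary_phantom(spec, cfg0.grid)
    act_rot = rotate_90(activity, "x")
    den_rot = rotate_90(density, "x")

    cx, cy = spec.capillary_centers()[0]
    point_par = np.array([cx, cy, 0.0])
    # rotation about x by +90 deg maps world (x, y, z) -> (x, -z, y)
    point_rot = np.array([cx, 0.0, cy])

    metrics: dict[str, dict[str, WidthMetrics]] = {a: {} for a in ("x", "y", "z")}
    escapes = {}
    for label, cfg in (("0T", cfg0), ("B0", cfg_b0)):
        vol_par, blur_par = _blur_and_reconstruct(activity, density, cfg)
        vol_rot, blur_rot = _blur_and_reconstruct(act_rot, den_rot, cfg)
        n_adj = cfg.analysis.n_adjacent_slices
        for axis in ("x", "y"):
            metrics[axis][label] = slice_averaged_metrics(
                vol_par, axis, point_par, step_axis="z", n_adjacent=n_adj)
        metrics["z"][label] = slice_averaged_metrics(
            vol_rot, "z", point_rot, step_axis="y", n_adjacent=n_adj)
        escapes[label] = {"parallel": blur_par.escaped_fraction,
                          "perpendicular": blur_rot.escaped_fraction}

    comparisons = {
        axis: {
            "fwhm": FieldComparison(metrics[axis]["0T"].fwhm_mean,
                                    metrics[axis]["B0"].fwhm_mean),
            "fwtm": FieldComparison(metrics[axis]["0T"].fwtm_mean,
                                    metrics[axis]["B0"].fwtm_mean),
        }
        for axis in metrics
    }
    prov = {
        "package_version": __version__,
        "config_hash_0t": cfg0.config_hash(),
        "config_hash_b0": cfg_b0.config_hash(),
        "seed": cfg0.kernel.seed,
        "escaped_fraction": escapes,
    }
    return ExperimentReport("capillary", prov, width_metrics=metrics,
                            comparisons=comparisons)


# ---------------------------------------------------------------------------
# Derenzo experiment

def derenzo_density_grid(activity: VoxelGrid, spec: DerenzoPhantomSpec,
                         material: MaterialSpec) -> VoxelGrid:
    """Bulk-density grid for the Derenzo phantom: housing material inside
    the cylinder (over the rod length), air outside."""
    density = centered_grid(activity.shape, activity.voxel_size)
    xc, yc, zc = (activity.axis_coords(a) for a in range(3))
    r2 = xc[:, None] ** 2 + yc[None, :] ** 2
    inside = (r2 <= (spec.housing_outer_diameter / 2) ** 2)[:, :, None] & \
             ((zc >= -spec.rod_length / 2) & (zc < spec.rod_length / 2))[None, None, :]
    vals = np.full(activity.shape, DENSITY_AIR)
    vals[inside] = material.density
    density.values = vals
    return density


def derenzo_layouts(spec: DerenzoPhantomSpec) -> list[SectorLayout]:
    return [
        SectorLayout(d, centers, spec.center_spacing_factor * d)
        for d, centers in derenzo_rod_centers(spec).items()
    ]


def analyze_derenzo_volume(vol: VoxelGrid, spec: DerenzoPhantomSpec,
                           condition: str = "", axial_average: int = 1,
                           threshold: float = RAYLEIGH_THRESHOLD) -> VPRTable:
    """Sector VPR table of a reconstructed/blurred Derenzo volume."""
    plane = transverse_plane(vol, n_average=axial_average)
    means = {}
    for layout in derenzo_layouts(spec):
        means[layout.rod_diameter] = sector_mean_vpr(
            plane, layout, threshold=threshold).mean_vpr
    return classify_table(means, condition=condition, threshold=threshold)


def run_derenzo_experiment(configs: list[RunConfig]) -> ExperimentReport:
    """VPR tables and smallest-resolvable summary for a set of conditions."""
    tables: dict[str, VPRTable] = {}
    escapes = {}
    hashes = {}
    for cfg in configs:
        if cfg.phantom != "derenzo":
            raise ConfigError("run_derenzo_experiment needs phantom='derenzo'")
        mat = default_material(cfg.material)
        spec = DerenzoPhantomSpec(**cfg.derenzo)
        activity = build_derenzo_phantom(spec, cfg.grid)
        density = derenzo_density_grid(activity, spec, mat)
        vol, blur = _blur_and_reconstruct(activity, density, cfg)
        label = f"{cfg.isotope} {cfg.field_t} T ({cfg.orientation})"
        tables[label] = analyze_derenzo_volume(
            vol, spec, condition=label,
            axial_average=cfg.analysis.derenzo_axial_average)
        escapes[label] = blur.escaped_fraction
        hashes[label] = cfg.config_hash()
    prov = {
        "package_version": __version__,
        "config_hashes": hashes,
        "seeds": {lbl: c.kernel.seed for lbl, c in zip(tables, configs)},
        "escaped_fraction": escapes,
    }
    return ExperimentReport("derenzo", prov, vpr_tables=tables)
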