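# petrange

Positron-range blurring and its magnetic confinement in preclinical
PET/MRI, as a tested, reusable analysis pipeline.

PET spatial resolution is fundamentally limited by the positron range:
the distance a positron travels between its emission and its
annihilation. The blur grows with the emitter's endpoint energy
(E<sub>βmax</sub>: ¹⁸F 0.63 MeV, ⁸⁹Zr 0.90 MeV, ⁶⁸Ga 1.90 MeV) and
shrinks with the density of the surrounding medium. Inside an MR
magnet's static field B₀ the Lorentz force curls the transverse
component of the positron trajectory (gyroradius r = p/(0.29979 B₀),
p in GeV/c) while leaving the axial component untouched, so at high
field the blur becomes anisotropic: confined in the transverse plane,
unchanged along B₀.

`petrange` provides every stage needed to study this effect on
synthetic data at desk scale:

- **Digital phantoms** (`petrange.phantoms`) — a three-capillary cube
  (ID 1.15 mm / OD 1.5 mm line sources in materials of 0.20, 1.30 or
  1.70 g·cm⁻³, emulating lung, trabecular and cortical bone) and a
  six-sector microDerenzo phantom (rods 0.7–1.5 mm in a 27 mm housing),
  voxelized with partial-volume supersampling; exact lossless 90°
  reorientation relative to B₀.
- **Annihilation-displacement kernel** (`petrange.rangekernel`) — a
  stochastic positron-range model whose 3D displacement density is
  ∝ e^(−|d|/s), calibrated so the median |d| equals the configured
  median range for each (isotope, material) pair (e.g. ⁶⁸Ga in the
  1.30 g·cm⁻³ material: 1.97 mm); transverse-only confinement at B₀ > 0
  via a scale factor κ_t or a mechanistic helical model capped at the
  gyration diameter. Escaped positrons are counted, not deposited.
- **Reconstruction** (`petrange.recon`) — slice-by-slice parallel-beam
  MLEM (Shepp–Vardi multiplicative update) with an exactly adjoint
  sparse projector pair, optional Poisson resampling and projection-space
  detector blurring.
- **Resolution metrology** (`petrange.profiles`) — capillary
  profilometry: 3-point parabolic peak estimation, linearly interpolated
  FWHM/FWTM (first crossing outward from the peak), 7-slice averaging
  with sample SD, and percent change between field conditions.
- **Rod resolvability** (`petrange.derenzo`) — valley-to-peak ratios
  (VPR = valley / mean of the two peak parabolic fits) for every
  adjacent rod pair, sector means, and classification against the
  Rayleigh threshold 0.735 — a constant the package re-derives from two
  Airy patterns at the exact Rayleigh separation.
- **Orchestration** (`petrange.experiment`, CLI `petrange`) — YAML run
  configs, matched-seed 0 T / 9.4 T comparisons, JSON reports with full
  provenance, NIfTI-1 volume I/O.

## Worked example

A matched-seed field comparison for the worst-case emitter (⁶⁸Ga) in the
medium-density cube, with transverse confinement κ_t = 0.4 at 9.4 T:

```python
import petrange as pr

kernel = pr.RangeKernelConfig(kappa_t=0.4, seed=7, n_decays=2_000_000)
cfg0 = pr.RunConfig(isotope="Ga-68", material="PLA", field_t=0.0, kernel=kernel)
report = pr.run_capillary_experiment(cfg0, cfg0.with_field(9.4))
for axis in ("x", "y", "z"):
    c = report.comparisons[axis]["fwtm"]
    print(f"{axis}: FWTM {c.value_0t:.2f} -> {c.value_b0:.2f} mm "
          f"({c.percent_change:+.1f}%)")
```

prints

```
x: FWTM 5.69 -> 3.15 mm (-44.6%)
y: FWTM 5.68 -> 3.17 mm (-44.1%)
z: FWTM 5.80 -> 6.03 mm (+3.9%)
```

x and y are transverse to B₀: the 9.4 T condition shrinks their tenth-
maximum width by ~44% because the confinement factor scales every
transverse displacement. z lies along B₀ and moves by less than 5% —
the axial displacement stream is bit-identical between the two runs
(matched seeds), so the small residual is purely the re-binning of
transversely moved annihilations.

The Derenzo side of the same physics:

```python
row = pr.printed_vpr_row("Ga-68", 0.0)      # published sector mean VPRs
print(pr.classify_table(row).smallest_resolvable)   # -> None
print(pr.airy_rayleigh_vpr(1.0))                    # -> 0.7350316...
```

No sector of the high-energy emitter passes the 0.735 threshold at
0 T; the threshold itself is reproduced from first principles.

## Layout

```
src/petrange/          library (phantoms, kernel, recon, metrology, CLI)
src/petrange/data/     packaged physics tables (median ranges, printed VPRs)
tests/                 pytest suite (unit, property and end-to-end tests)
docs/methods.md        models, assumptions, parameter choices, limitations
scripts/acceptance.py  headline-number reproduction
```
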