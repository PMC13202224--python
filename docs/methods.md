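# Methods

This note documents the models behind `petrange`, the parameters that
matter, the numerical choices, and what the synthetic data can and
cannot say about real acquisitions.

## Scope and coordinate conventions

All geometry is in millimetres on isotropic voxel grids (default
0.5 mm), right-handed, with the scanner/magnet axis (B₀) along +z and a
voxel-center convention: voxel index *i* sits at `origin + i·voxel_size`.
Orientation changes are exact 90° axis permutations — never
interpolation — so reorienting a phantom relative to B₀ is lossless and
invertible.

## Digital phantoms

**Capillary cube.** A 25 mm cube of bulk density ρ ∈ {0.20, 1.30,
1.70} g·cm⁻³ (lung-, trabecular-bone- and cortical-bone-equivalent)
pierced by three glass capillaries (bore 1.15 mm, wall to 1.5 mm,
active length 39 mm) arranged as an equilateral triangle in the
transverse plane. The triangle side is not fixed by the physical
description ("approximately equilateral"); the default is 8 mm,
chosen so all three bores plus several millimetres of range blur stay
inside the cube, and it is a config parameter, not a claimed measured
value. The capillary overhang beyond the cube is surrounded by air
(0.0012 g·cm⁻³); bore water is 1.0 and glass 2.2 g·cm⁻³. Activity is
voxelized by in-plane sub-voxel supersampling (default 4×4 per voxel),
so partial-volume fractions at the bore edge are represented and the
total active volume matches the analytic cylinder volume to a few
percent at 0.5 mm voxels.

**MicroDerenzo.** Six 60° sectors of rods with diameters 1.5, 1.2,
1.0, 0.9, 0.8, 0.7 mm (length 10 mm) inside a 27 mm housing. The rod
lattice is triangular with center spacing 2·d (the conventional Derenzo
spacing; the physical model's true spacing is not published, so the
factor is exposed as `center_spacing_factor`). Rods keep one radius of
clearance from sector boundaries and the housing wall; the first row
sits at a configurable keep-out radius (default 4 mm) from the center.

## Annihilation-displacement kernel

The package's synthetic-data core generates the displacement between
positron emission and annihilation. No forward transport model is
published for the experiment this emulates; the kernel's mandate is to
produce displacements with the *statistical structure* the analysis
assumes:

1. at 0 T the distribution is isotropic and its median magnitude equals
   the configured median positron range for the (isotope, material)
   pair;
2. at B₀ > 0 the axial marginal is unchanged — bit-identically so under
   matched seeds — and the transverse spread is reduced;
3. everything is reproducible from an explicit seed.

**Radial-empirical model (default).** Directions are isotropic; the 3D
displacement density is proportional to e^(−|d|/s), so |d| ~
Gamma(shape = 3, scale = s), and s = R_median / 2.6740603 (the median
of Gamma(3,1)) makes the sample median exactly the calibration target.
This is the classic single-exponential empirical positron-range kernel
shape. It was chosen over the alternative reading (|d| itself
exponential) for a measured reason: an exponential magnitude couples
radius and direction so strongly that conditioning on the narrow
profile row used in capillary metrology distorts the *conditional*
axial distribution when the transverse scale changes (single-row z-FWTM
grew ≈ +29% under κ_t = 0.4 despite exact axial-marginal invariance).
With the Gamma(3) magnitude the conditional artifact is below the
percent level, consistent with the axial-invariance signature the
pipeline is designed to detect. The field effect is a pure transverse
contraction: d_perp → κ_t·d_perp, κ_t ∈ (0, 1], applied only when
B₀ > 0 (so one config serves matched field-on/field-off runs).
κ_t is a *configured* confinement strength, not derived from B₀.

**Helical model.** A positron kinetic energy is drawn from the allowed
β⁺ spectrum N(E) ∝ p·E_tot·(E_max − E)² by rejection sampling; the
range follows a power law r = c·E^1.5 with c calibrated so the median
range is exact (the median of a monotone function is the function of
the median, and the spectrum median is computed by dense CDF
inversion); the transverse excursion is capped at the per-positron
gyration diameter 2r_g(E, B₀), r_g = p/(0.29979·B₀) (p in GeV/c gives
r in meters). This is a mechanistic caricature — it curls, it does not
transport — but it makes the confinement energy-dependent instead of a
single factor.

**Calibration targets.** Median ranges ship in
`src/petrange/data/range_table.csv` for the nine (isotope, material)
pairs plus a back-derived water reference per isotope. The published
per-material medians embed a composition correction and are *not*
mutually consistent with pure 1/ρ density scaling (residuals up to
~8%); the packaged pair value therefore always wins over the scaling
law, which serves only as a fallback for unlisted densities (e.g. air,
where the range is effectively unbounded and positrons escape).
`scaling_residuals()` reports the inconsistency explicitly.

**Image-domain blurring.** `apply_range_blur` samples emission points
proportionally to activity (uniformly jittered within the voxel),
displaces each with the kernel calibrated for the density of the
*emission* voxel, and bins annihilations to the nearest voxel.
Displacements leaving the grid are counted as escaped and reported in
the result and the JSON sidecar; deposited + escaped = n_decays
exactly. Two consequences to keep in mind: (a) there is no per-step
boundary tracking, so a positron emitted in the water bore uses the
water-calibrated kernel even if it annihilates in the surrounding
material; (b) in the low-density cube a substantial fraction of
high-energy positrons escapes, which is the physically expected regime
and is asserted by test.

## Reconstruction

A desk-scale stand-in for 3D list-mode MLEM: each transverse slice is
projected into a parallel-beam sinogram (default 180 angles over
[0, π)) and reconstructed with the multiplicative update
f ← (f/s)·Aᵀ(g/(Af + ε)), ε = 1e-12, from a uniform positive start.
The projector is an explicit sparse matrix (pixel centers rotated per
angle and splat linearly into radial bins), which buys three exact
properties: forward/back projection are true adjoints; every pixel
contributes unit weight per angle, so the sensitivity is exactly
n_angles and total counts are conserved across iterations; and the
Poisson log-likelihood is non-decreasing (tracked numerically each
run). Iteration defaults follow the acquisition protocols emulated:
10 for capillary runs (FWTM degrades at high iteration counts), 150
for Derenzo runs. Optional detector blurring is a projection-space
Gaussian (default FWHM 0.9 mm, the intrinsic resolution class of
small-animal systems; zero-padded so the operator stays self-adjoint;
set 0 to disable). Because the geometry is a 2D stand-in, absolute
reconstructed widths are not comparable to any physical system's
published bars and are never asserted as such; analysis stages accept
either reconstructed volumes or the annihilation grid directly
(bypass mode, the experiment default).

## Capillary profilometry

Profiles are single voxel rows (no thick-slab averaging). The peak is
the exact vertex of the parabola through the discrete maximum and its
two neighbours; zero-curvature neighbourhoods fall back to the discrete
maximum with a flag. FWHM/FWTM are read from the linearly interpolated
profile at the first sample pair bracketing the level, scanning outward
from the peak on each side (NEMA-style first crossing, robust to tail
bumps); the parabola supplies only the peak position and amplitude.
Each metric is measured independently on the centre slice and three
slices either side (7 total) and reported as mean ± sample SD (n−1);
truncated slices are excluded and counted. x/y profiles come from the
capillary-parallel orientation, z from the volume rotated 90° about x,
with the 7-slice stepping re-oriented along the rotated capillary axis
(y) — the natural re-orientation of the parallel-case scheme, and a
package choice since the original stepping for z is not specified.

## Derenzo VPR analysis

Rod centers are known a priori from the synthetic geometry (blind rod
localization is out of scope). For every nearest-neighbour lattice pair
(distance ≤ 1.05× design spacing) a bilinear profile is sampled through
both centers, extended by half the separation beyond each so both peaks
are interior. The two highest interior local maxima are taken as the
rod peaks, the interior minimum between them as the valley, each
refined with a 3-point parabolic fit; VPR = valley / mean(peaks)
(a max-peak normalization is available behind a flag), clamped to
[0, 1]. Profiles with no two distinct peaks or no real dip flag the
pair as merged with VPR 1.0. Sector mean VPRs classify against the
Rayleigh threshold 0.735 with *strict* inequality (a published row
with 0.739 at the largest rod is not resolvable, which fixes the
convention), and the smallest-resolvable diameter uses a contiguity
rule: every larger sector must also pass, guarding against isolated
noise passes. The VPR plane is the central transverse slice by
default; an axial average over the rod extent is available
(`derenzo_axial_average`) and is what the Monte Carlo sweeps use,
since it trades no in-plane information for √n noise reduction.

The threshold constant itself is validated from first principles:
`airy_rayleigh_vpr(s)` evaluates the 1D cut through two equal Airy
intensity patterns I(x) = [2J₁(x)/x]² separated by s Rayleigh units
(first-zero distance 3.8317/π) on a dense grid; at s = 1 the
valley-to-peak ratio is 0.7350.

## Matched-seed field comparisons

The physical experiment compares two separate acquisitions; the
synthetic analogue replays the *same* decay stream at both fields.
Draw order is independent of B₀, so the axial displacement components
are equal element-wise between conditions, and percent changes isolate
the confinement effect from Monte Carlo noise. A null comparison
(κ_t = 1 at both fields) yields exactly 0% change on every axis — a
regression test of the whole chain.

## Problem sizes

The shipped tests and the acceptance script run at sizes chosen to keep
statistical error well inside the stated tolerances while remaining
desk-scale: 10⁵ displacement samples for median-recovery checks (sample
median SE ≈ 0.4%), 10⁶ for the transverse-FWHM scaling ratio (histogram
bins 0.02 mm, light smoothing against bin shot noise), 2×10⁶ decays for
capillary field comparisons at 0.5 mm voxels, and 4×10⁶ decays at
0.25 mm voxels with a 21-slice axial average for Derenzo confinement
sweeps. MLEM sanity checks use 32² slices and 60 angles.

## Known limitations

- No condensed-history transport: no energy loss along the path, no
  boundary crossing, no annihilation-photon acollinearity, no
  positronium physics. The kernel reproduces configured medians and the
  transverse/axial anisotropy structure — nothing finer.
- Emission-voxel material lookup (see above) biases capillary runs
  toward the bore-water kernel; this mirrors the escape-dominated
  regime discussed for low-density media but understates
  material-density contrast for thin sources in dense media.
- The 2D parallel-beam MLEM shares the update rule, not the geometry,
  of a real 3D list-mode reconstruction; absolute widths through it are
  stand-in numbers.
- Passing tests demonstrate correct metrology and the intended
  anisotropy structure on synthetic data; they do not validate the
  kernel against measured positron-range distributions.
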