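# Methods

## Physical model

A nacreous layer is idealized as a laterally uniform 1D stack of
alternating aragonite platelets (index n₁, thickness d₁) and interlamellar
gaps (index n₂, thickness d₂) between an air ambient and a bulk-aragonite
substrate. All media are lossless and non-dispersive. Aragonite is
birefringent (1.530 / 1.681 / 1.686 along the c/b/a axes) but is treated
with the single effective index 1.63 standard in nacre optics; the gap is
air (1.00) for fossil nacre with collapsed organic sheets and organic
(1.43) for living shells.

Reflectance is computed with the coherent 2×2 characteristic-matrix
(transfer-matrix) method per polarization, with Snell propagation angles
taken as complex square roots so oblique and near-evanescent cases remain
well defined. Unpolarized reflectance is the intensity mean of s and p
(identical at normal incidence, where only one is computed). For lossless
stacks the solver satisfies R + T = 1 to ~1e-15 and reproduces the Airy
single-film closed form to ~1e-16; both identities are enforced in the
test suite at 1e-8 and 1e-10 respectively.

For laterally uniform planar stacks this 1D solution is exact, so it
replaces grid-based (FDTD-type) field solvers for this geometry: same
physics, no grid dispersion, desk-scale runtime (~15 ms for a 600-layer
stack over the 401-point visible grid).

## Synthetic stacks

`StackSpec` is the generative recipe. Plate and gap thicknesses are drawn
independently per layer from truncated Gaussians — the field reports
mean ± SD only and plate-thickness histograms are unimodal; covariance
between plate and gap widths is unmeasured and taken as zero. Truncation
floors (1 nm plates, 0.5 nm gaps) only guard against non-physical layers:
at plate-like parameters they are many SDs below the mean and perturb the
moments negligibly. At gap-like parameters (4 ± 2 nm) the floor sits at
1.75 SD and shifts the gap mean upward by ~0.2 nm — intended behavior, as
negative or sub-ångström gaps are meaningless.

Defaults encode the measured study conditions: d₁ = 190/160/140 nm
(red/green/blue fossil nacre) with per-color SDs 15/8/18 nm, air gaps
d₂ = 4 ± 2 nm; abalone d₁ ≈ 250–300 nm with organic gaps 11 ± 3 nm. The
default period count 300 corresponds to ~50 µm of stack at a 164 nm
period — the depth of homogeneous periodicity associated with brilliant
color. Depth profiles are `constant`, `linear_drift` (rate in nm of period
per period, emulating the drifting periods of abalone and pale fossil
nacre) or `custom` (explicit per-period values).

What the generator does **not** emulate: lateral tablet tiling and surface
roughness, plate birefringence, absorption by organic residue, and any
plate–gap thickness correlation. Passing tests therefore demonstrate the
interference mechanism under these idealizations, not a quantitative match
to any individual shell's spectrum.

## Disorder averaging

Ensembles average intensity (not amplitude) over independent stack
realizations: distinct lateral patches within the measurement spot add
incoherently at the detector, while each patch is modelled fully
coherently — disorder, not partial coherence, supplies the band
broadening. Realization seeds are spawned from the spec seed via
`numpy.random.SeedSequence`, making runs reproducible and the realization
stream prefix-stable (the first k of n draws are the same draws). The
default 100 realizations puts the Monte-Carlo error of the mean spectrum
well below the band-shape differences the experiments compare.

## Band statistics

λ_max is the global maximum of the spectrum. FWHM is measured at half
maximum above baseline, taking the *outermost* half-crossings (linearly
interpolated): chirped-period stacks produce broad bands with coherent
ripple that dips below half maximum, and the outermost crossings measure
the band envelope rather than a single ripple lobe; for clean single bands
the outermost and nearest crossings coincide. The baseline is the median
reflectance outside λ_max ± 1.5×FWHM, refined once from an initial
whole-spectrum median. A flat spectrum has no peak; a band whose crossings
are not bracketed by the grid reports FWHM as undefined, as does a band in
`fwhm_vs_planes` whose contrast (peak − baseline) is below 0.05, the scale
of the bare ambient/plate interface fringes.

## Colorimetry

Tristimulus values integrate reflectance × illuminant × CIE 1931 2°
color-matching functions (embedded 5 nm table, linearly interpolated) over
the 380–780 nm overlap of the spectrum grid, by trapezoidal rule.
Chromaticity is (x, y, z) = (X, Y, Z)/(X+Y+Z); saturation is the Euclidean
(x, y) distance from the illuminant white point — the simplest measure of
"distance from the achromatic center"; CIE excitation purity would be an
alternative but is not the default. The default illuminant is E (equal
energy), matching reflectance measured against a white diffuse reference;
D65 (embedded 10 nm table) is available. White points are computed from
the same embedded tables on the same grid, so a flat spectrum maps to its
illuminant's white point exactly (saturation 0) rather than to within
table error.

One geometric caveat: saturation compared *across hues* inherits the shape
of the chromaticity diagram — the spectral locus is much farther from the
white point in the green than near 460 or 640 nm. In the homogeneity scan
the drifted band both broadens and shifts its centroid toward green, and
the hue shift can raise the distance-from-white measure even as the band
broadens; the scan therefore asserts bandwidth, which is the
hue-independent quantity. Saturation comparisons elsewhere (gap-width
scan, white-noise tests) are made at matched hue, where the measure is
unambiguous.

## Experiments and problem sizes

All full-scale experiments use 300-period stacks on the 380–780 nm × 1 nm
grid; stochastic conditions average 100 realizations (~10 s per 8-condition
sweep on one core). Per-condition seeds are spawned from the experiment
seed. The sweeps:

- **d1-scan** (d₁ ∈ {137, 157, 194} nm, paired SDs {18, 8, 15} nm, 4 nm air
  gap): λ_max rises with d₁ (blue→green→red); every measured SD broadens
  its band relative to SD = 0.
- **d2-scan** (d₁ = 150 ± 15 nm; d₂ ∈ {1, 4, 11, 20} nm × n₂ ∈ {1.0, 1.43}):
  for air gaps the band strengthens from 1→4 nm, the 20 nm gap lifts a
  wavelength-independent "white-noise" baseline, and saturation peaks at
  4 nm — the nanogap optimum; organic filling weakens the 11 nm band.
- **homogeneity-scan** (ordered stacks, drift rate ∈ {0, 0.05, 0.1} nm per
  period, drift centered so mean period is matched): FWHM grows
  monotonically with drift rate.
- **order-scan**: Bragg order and peak for the five canonical shell
  recipes, cross-checked against the solved spectra (< 2% disagreement).
- **angle-scan**: iridescent blue shift of the band, tracking
  2d√(n_eff² − sin²θ) to < 3% up to 45°.

## Numerical choices

- Wavelength grid 380–780 nm, 1 nm step (FWHM interpolation makes the
  effective resolution finer than the step).
- Per-wavelength 2×2 complex matrix products accumulated layer by layer in
  element-wise form (vectorized across the grid); singular products raise
  with layer diagnostics rather than propagating NaNs.
- Order selection returns the smallest order landing in 380–780 nm,
  scanning upward and stopping once peaks fall below the visible.
- Tie-breaks in saturation ranking: λ_max ascending, then input order
  (stable sort).
- Degenerate inputs: zero-thickness layers are dropped at stack
  construction; d₂ = 0 collapses the stack to a bare interface; index-
  matched gaps (n₂ = n₁) produce a flat spectrum at machine precision.

## Known limitations

- No absorption or dispersion; measured spectra of real shells include
  both, plus scattering from lateral microstructure, so simulated peak
  reflectances run higher than measured ones.
- The Bragg-Snell band centers computed from the measured thicknesses sit
  1–3% below the measured band centers (628/531/465 vs 640/540/460 nm) —
  within the joint uncertainty of the thickness statistics and the
  effective-index idealization.
- Measured angle dependence of real fossil nacre is weaker than the ideal
  model predicts (peaks shifted long of the calculation); this package
  documents but does not model that disorder-related offset.
- The penetration-depth plane count N_eff ∝ 1/√R is a qualitative ordering
  device, not a calibrated count; the quantitative bandwidth-vs-planes
  relation is always computed numerically from solved spectra.
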