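# Methods

This note records the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical choices a maintainer would want to
know.

## Coordinate and unit conventions

Image coordinates are 0-based `(row, col)` with the origin at the
top-left pixel center. The object-plane y axis is the particle-beam
(vertical) axis, increasing downstream with increasing row; x runs
along columns. A single configured scalar maps pixels to object-plane
micrometres (default 1.14 µm/px, the instrument's positional
resolution); the full optical magnification chain is not modeled
because the zoom setting is variable. The 25° angle between laser and
microscope axes is carried as metadata only: the dominant velocity
component (vertical) is perpendicular to both axes, so no parallax
correction is applied to speeds. Physics code works in SI; instrument
I/O uses µm, mm, nm, µs, mbar and mJ, with all conversions centralized
in `aerotrack.units`.

## Synthetic frames (forward model)

Each particle contributes, per flash, a pixel-integrated isotropic 2-D
Gaussian whose integral is `k · d⁶ · E · I_rel`: `k` the calibration
constant (default fixed by 157 photons for a 40 nm sphere at 50 mJ and
full illumination), `E` the flash energy and `I_rel` the Gaussian
illumination profile (0.5 mm FWHM default). Pixel integration uses
separable erf differences over a ±6σ window, so photon conservation
holds to better than 0.1% for spots inside the frame.

Defaults and rationale:

- **PSF σ = 2 px.** Not directly measured; the diffraction-limited
  spot of an NA 0.055 objective at 532 nm is a few pixels at
  1.14 µm/px, so an O(few-px) default is used and kept configurable.
- **Background**: Poisson with mean 0.12 photons/px/mJ × total pulse
  energy; **dark noise**: additive Gaussian, σ = 1.3 photons/px;
  **saturation**: hard clip at 30 700 photons. These are the measured
  camera characteristics.
- **Ghosts**: optional duplicate spots at a constant pixel offset with
  default 10% intensity, rendered only when they would exceed the dark
  noise. The offset magnitude is configurable with no claim of realism
  (only "faint, constant displacement" is known).
- **Clusters**: droplet occupancy is Poisson; observed (non-empty)
  droplets follow the zero-truncated distribution, and an n-monomer
  cluster has diameter `monomer × n^(1/3)` by volume conservation,
  hence 4× brightness for a dimer.
- Particle motion during one ~7 ns flash (≤ 0.6 px at 100 m/s) is not
  rendered; it is a sub-pixel blur source in the real instrument.

The generator does **not** emulate speckle, defocus aberrations,
depth-of-field variation across the 91 µm focal depth, droplet drying
dynamics, or non-Gaussian beam halos. Passing recovery tests therefore
demonstrates the correctness of the analysis chain, not robustness to
those real-data effects.

The pressure-scan generator draws transverse positions from Gaussians
whose FWHM follows the Gaussian-beam envelope with power-law
pressure scalings (defaults: waist exponent −3/2, focus −1/2,
divergence −1; the waist exponent is reported free by the fitting
stage because the two printed candidate values, −2/3 and −3/2,
disagree — the package takes no side). Axial speeds come from the jet
model below.

## Detection

Difference of Gaussians with σ = 3 and 6 px. The instrument
description prints 0.03/0.06 px, which would make both blurs numerical
identities; a DoG must act at the spot scale, so the package treats
the printed values as a ×100 unit misprint and uses 3/6 px,
configurable. The signed DoG image is thresholded (positive lobes);
the threshold is an explicit configuration value, with a helper
suggesting μ + 5σ of a particle-free DoG region. Clustering uses
4-connectivity by default (8 available). Centroids are computed from
the DoG values of the selected pixels; brightness integrates *raw*
pixel values within 10 px, with no background subtraction by default
(an annulus-median option exists). A peak is flagged saturated when
any pixel in its integration disk reaches the saturation level, since
sizing is invalid beyond the detector's linear range. Proximity
exclusion is strict (`< 21 px`) and mutual. Known bias: when two spot
images sit within ~4 σ_large of each other, the DoG negative lobes
repel the centroids by a few percent of the separation; the 21 px rule
removes most such cases in practice.

Ghost identification needs the constant offset: it is either
configured or estimated as the modal integer displacement among
bright→faint peak pairs across many frames (minimum pair count
enforced). The fainter member of a matching pair is flagged; equal
brightness ties flag the member displaced along the offset.

## Velocimetry

Which flash produced which image is not recoverable from a single
exposure, so pairing uses a flow-direction prior (downstream) and a
displacement gate `max_speed × delay` tied to the laser-spot extent
(0.5 mm / 0.5 µs → 1000 m/s). Matching is mutual nearest neighbour
among admissible pairs; speeds are reported as magnitudes. An
over-wide gate admits cross-particle mispairings when spacing is
comparable to the gate; the guarantee of 100% pairing accuracy holds
for spacings ≥ 2× the maximum displacement. A brightness-similarity
gate exists but is off by default.

## Sizing

Calibration fits `I^{1/6} = k^{1/6} d` through the origin (the
least-squares slope is `Σ d I^{1/6} / Σ d²`), matching the straight-
line presentation of the law in sixth-root space; a free-exponent
log–log fit is stored purely as a diagnostic of the d⁶ scaling.
Brightness is first rescaled to beam-center illumination and 1 mJ;
records below a relative-illumination floor (default 0.1) are
unsizable, as are saturated records and diameters outside the
40–125 nm window (background-limited below, detector-range-limited
above; the window is configuration, not hard-coded). Cluster flagging
uses cutoff factor 1.15 × the monomer mode — midway between the
monomer (1.0) and dimer (2^{1/3} ≈ 1.26) diameters. Per-standard mean
brightness may use a 5% trimmed mean to resist residual ghosts and
clusters.

## Beam characterization

All widths are FWHM. The transverse profile fit is the exact
maximum-likelihood Gaussian fit to the unbinned positions (sample mean
and standard deviation); histograms are display-only. The envelope fit
is nonlinear least squares of `w(z) = w₀√(1 + ((z−z₀)/z_R)²)`
initialized at the minimum-width point; divergence is reported as the
far-field *half*-angle θ = w₀/(2 z_R) of the FWHM envelope (half- vs
full-angle is a convention choice, documented and convertible by a
factor 2). Scaling laws are log–log linear regressions returning
exponent ± standard error.

Densities: the measured areal (column) density of an axisymmetric
Gaussian beam with line density λ and width σ peaks at
`λ/(√(2π)σ)`. The yield calculation converts the peak column density
to a peak volumetric density `n_v = σ_a/(√(2π)σ)` and multiplies by
the effective cross-section `2πσ²` and the particle speed — for a
Gaussian beam this product is exactly the flux integral
∫ n_v(r) v dA. Inflow is concentration × sample flow rate (reference
values 10¹² /ml and 1 µl/min are explicit arguments, not constants).
Hit-ratio prediction is `density × π(FWHM/2)²`, capped at 1; it is
exactly linear in density and quadratic in FWHM.

## Jet dynamics

- **Flow field.** Centerline Mach number from the Ashkenas–Sherman
  far-field correlation with the monatomic constants A = 3.26,
  x₀/d = 0.075 (the published values for γ = 5/3). The correlation is
  applied for x/d ≥ 0.5; below that the power law is outside its
  validity range (and the expression changes sign near x/d ≈ 0.36), so
  the code refuses rather than extrapolates. Gas T, p, ρ follow the
  isentropic relations from stagnation conditions; stagnation is the
  lens entrance pressure at room temperature (293.15 K — "standard
  conditions" for the 1008 m/s helium speed of sound).
- **Orifice flow.** Mass flow and orifice gas state come from an
  isentropic choked-orifice estimate through the *effective* orifice
  (physical 1.5 mm × a fitted contraction ratio, default 0.880, which
  absorbs the low-Reynolds boundary layer). This replaces a full
  internal-lens CFD treatment and is the main fidelity limitation of
  the module: absolute mass flows and hence Stokes numbers carry the
  uncertainty of that estimate.
- **Drag.** Henderson (1976) sphere correlation: subsonic branch,
  supersonic branch (M ≥ 1.75) and the prescribed linear bridge in
  Mach number, evaluated with the slip Reynolds and Mach numbers and a
  particle-surface/gas temperature ratio (default 1). In the low-speed
  free-molecular limit it agrees with the closed-form (Epstein-type)
  free-molecular drag within a few percent, which the tests verify
  independently.
- **Propagation.** `dv/dx = F/(mv)` integrated by adaptive embedded
  Runge–Kutta (rtol 10⁻⁷ default); the x-parameterization requires a
  strictly positive initial velocity (v = 0 is a singular point). The
  velocity at the end of the integration range (default 30 mm, ≫
  orifice diameter) is reported as terminal: gas density has fallen
  orders of magnitude by then and tolerance-halving changes the result
  by < 0.1%.
- **Stokes number.** `St = τu/(d_f/2)`, `τ = C_c ρ_p d_p²/(18µ)`,
  `u = 4F_m/(ρ_l π d_f²)`, with C_c the Cunningham slip correction
  `1 + Kn(1.257 + 0.4 e^{−1.1/Kn})` at the throat state (the quantity
  that belongs in the relaxation time, even though the surrounding
  literature sometimes labels the symbol a "discharge coefficient").
  Under these compositions u is pressure-independent for choked flow,
  and in the free-molecular limit the particle dynamics depend on
  pressure and diameter only through p/d_p while St ∝ d_p/p — which is
  why terminal velocities at equal St collapse (the tests confirm
  agreement within 2% across (d_p, p) pairs).
- **Collapse fit.** The three-parameter model
  `v/c = A(1 − e^{−C·St}) + B·St` (saturating rise plus a weak linear
  tail) is the package default; the literature form it stands in for
  is not printed in any accessible source, so the model is pluggable
  and the default was chosen to be monotone and well-conditioned at
  parameter values of interest (A ≈ 0.5, B ≈ 0.002, C ≈ 0.09).
- **Entrance-parameter fit.** Joint least squares over propagated
  velocity profiles with one entrance velocity per condition and a
  shared effective-diameter ratio (bounded to (0.5, 1]); synthetic
  recovery of the ratio is verified within 2%.

## Problem sizes used in the test and acceptance runs

Rendered-frame tests use 256×256 sensors with the full-size
photometric parameters; detection recall/false-discovery statistics
use 100 seeded frames with four particles each; pressure-scan
parameter recovery uses 4–5 pressures × 8 distances × 400 particles
drawn directly from the position model (rendering is exercised
separately); the velocity-collapse checks use two to four (d_p, p)
conditions. These sizes make every statistical tolerance comfortably
resolvable while keeping the whole suite fast.

## Known limitations

- The Rayleigh d⁶ law is applied up to 200 nm; larger particles (Mie
  regime) are detected but not sized, and the code only warns.
- The choked-orifice estimate ignores the internal lens geometry; the
  effective-diameter ratio soaks up part, not all, of that error.
- One-dimensional jet dynamics: no barrel shock, Mach disk, or radial
  particle trajectories; terminal velocity is insensitive to these on
  the centerline but off-axis particles are not modeled.
- Ghost-offset auto-estimation needs multiple frames with coexisting
  main/ghost pairs; single sparse frames must configure the offset.
- The illumination correction does not model the 25° oblique viewing
  geometry of the laser sheet.
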