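# Methods

This note records the model, the numerical choices and their rationale, and
what the desk-scale tests do and do not demonstrate.

## Units and conventions

Lengths are in micrometres, times in femtoseconds (c = 0.299792458 μm/fs),
fields dimensionless; the stored magnetic field is impedance-scaled
(Z₀H), so a plane wave in a medium of index n has |H| = n|E| and the
time-averaged Poynting vector is S = ½ℜ{E×H*} in consistent relative
units.  The time convention is exp(−iωt); running discrete Fourier
transforms accumulate exp(+iωt), so outgoing waves carry exp(+ikz).
Wavelengths quoted anywhere are vacuum wavelengths; the in-medium
wavelength λ/n enters size parameters and cross-section prefactors
explicitly.  Grid cell (i, j, k) is centred at ((i+½)Δ, (j+½)Δ, (k+½)Δ);
z is the optical axis.

## PSTD solver

The update is leapfrog in time (E at integer, H at half-integer steps) with
spectral spatial derivatives: forward FFT, multiplication by ik (Nyquist
mode zeroed), inverse FFT, on a collocated grid.  Stability requires
ωΔt ≤ 2 at the largest resolvable |k| = π√D/Δ (D non-singleton
dimensions), giving Δt ≤ 2Δ/(c/n_min · π√D); the default step is 0.95× the
bound, reference full-scale runs use 0.252 fs on a λ₀/6 grid (bound
≈ 0.266 fs).  Leapfrog admits an exactly conserved discrete energy
½Σε_r E(τ)² + ½ΣH(τ−Δt/2)·H(τ+Δt/2); the solver tracks it on request and
the vacuum-periodic test holds it to machine precision over 10³ steps.

Accuracy, not stability, dictates the step in quantitative runs: leapfrog
phase velocity errs by ≈ (ωΔt)²/24 and group velocity by
1/√(1−(ωΔt/2)²) − 1.  Pulse-speed tests and the 1D OCT pipeline therefore
run at Δt well under the bound (safety 0.3–0.5); characterization runs use
safety 0.7 where sub-percent phase error suffices.

The PML is a Berenger-style split-field absorber adapted to the spectral
update: each field component is stored as sub-fields per contributing
derivative axis, damped at a rate σ_a(r) graded as a cubic polynomial over
the layer, with exponential (exactly integrated) damping factors.  The peak
σ is set from the standard round-trip formula for a target theoretical
reflection (−60 dB power by default; measured amplitude reflection of the
10-cell default layer is ≈ 2×10⁻³, comfortably below the −40 dB power
budget; −100 dB/16-cell settings reach ≈ 2×10⁻⁵ and are used by the 1D
detection pipeline).  Periodic FFT wraparound is absorbed by the same
layers.

Two source mechanisms exist:

* a planar magnetic current density J*(t) = ℜ{−k̂×e_ill exp(−iω₀(t−t₀))}
  exp(−π((t−t₀)/W)²) for focused-beam OCT runs (t₀ = 5W keeps the t = 0
  amplitude below 10⁻⁶ of peak; W is chosen so the amplitude spectrum is
  ≥ 0.1 of peak at both band edges, ≈ 36.5 fs for 1180–1420 nm);
* a scattered-field formulation for plane-wave characterization: the
  incident pulse is analytic and enters as the polarization drive
  (ε_b/ε − 1)∂E_inc/∂t inside the scatterer only, so the solver advances
  the purely outgoing scattered field and the PML terminates it on all
  faces.  This avoids transverse truncation of the plane wave and gives
  the cleanest cross-section measurements.

All spectral probes are normalized by the source amplitude spectrum
evaluated on the same discrete time lattice, making recorded fields
per-unit-incident-amplitude and coupling spectra flat for a unit mirror.

## Focused illumination

The fiber mode is the weakly-guiding Gaussian approximation with 1/e²
intensity radius w₀ = MFD/2 (4.6 μm for the 9.2 μm fiber).  Its Fourier
relay through L1 gives a collimated Gaussian of 1/e² radius λf₁/(πw₀)
(2.25 mm at 1300 nm), hard-truncated at Rₐ = 3.5 mm.  The focal field
follows from the Richards–Wolf form of the Debye–Wolf integral with
aplanatic √cosθ apodization, reduced for linear polarization to the I₀/I₁/I₂
Bessel integrals and evaluated by Gauss–Legendre quadrature over the
aperture cone (NA = Rₐ/f₂ ≈ 0.097).  Consistency checks: plane-to-plane
energy conservation at the 10⁻⁶ level, agreement with angular-spectrum
propagation away from focus to < 2% RMS, and ≤ 5% RMS agreement between the
solver-propagated source field and the Debye–Wolf focus (the cross-module
source-injection test).

A note on the carrier frequency: the source definition uses ω₀ = c k₀, the
only dimensionally consistent reading of the carrier relation.

## Mie reference

Coefficients aₙ, bₙ come from Riccati–Bessel recurrences with the
logarithmic derivative evaluated by downward recurrence; truncation at
n_max = ⌈x + 4x^{1/3} + 2⌉.  Exterior fields use the outgoing vector
spherical harmonic expansion (degree m = 1) for a unit x-polarized +z
plane wave, validated internally by the optical theorem (10⁻⁸), by
equality of the coefficient-series g with quadrature of the phase function
(10⁻⁶), and by closed-surface flux equal to σ_s (0.5%).  The test suite
additionally cross-checks against an independent direct Riccati–Bessel
formulation (no recurrence) at m ∈ {1.1, 1.5, 1.84}, x ∈ {0.5, 3.4, 10}.

For the modelled phantom (d = 1 μm, rutile n = 2.609 in silicone 1.42,
ρ = 4.5×10⁻³ μm⁻³) the package computes μ_s(1300 nm) = 10.56 mm⁻¹ and a
Hann-spectrum-weighted 11.49 mm⁻¹; the rutile index is adopted because the
anatase value (2.488) yields 12.9/13.1 mm⁻¹, inconsistent with the design
values the phantom was built to.  The particle index is treated as
wavelength-independent across the band.

## Discrete-scatterer characterization and design

σ_s of an arbitrary cell-set scatterer is the net scattered Poynting flux
through a closed cubic reference surface (triangulated, vertices on the
cell-centre lattice, two triangles per square patch), divided by the
incident intensity ½n_b; the flux quadrature is the vertex-sum facet rule
Σ v̂·(A/3)Σ_{l∈facet} S_l.  g comes from the surface-equivalence
near-to-far-field transform of the scattered fields (equivalent currents
J_s = n̂×H, M_s = −n̂×E, phase-weighted facet sums) integrated over a
Gauss–Legendre × uniform-azimuth direction set.  The transform reproduces
the Mie phase function to < 0.5% when fed analytic surface fields.

The design objective is the spectrum-weighted Poynting-flux mismatch

ε(n) = Σ_m S(λ_m) · Σ_facets |v̂·(A/3)Σ_l (S̃_l − S_l)|² /
Σ_facets |v̂·(A/3)Σ_l S_l|²

between total-field Poynting vectors S̃ of the discrete scatterer (one
broadband PSTD run probed at all λ_m) and the Mie total field S of the
target sphere, on the same surface.  ε = 0 for a perfect match, Σ_m S(λ_m)
for zero field, and is invariant to common rescaling.  The 7³ bounding cube
is reduced to 4³ = 64 free refractive indices (bounds [1, 3.5]) by mirror
symmetry about the three bisecting cell planes; cube(i,j,k) =
octant(|i|,|j|,|k|).  Optimization is Nelder–Mead (initial simplex step
0.05, relative tolerance 10⁻⁴, bounds enforced by projection before
evaluation) with a monotone best-so-far trace; desk-scale problems free
2–8 parameters, the full 64-parameter problem is supported but
long-running.  Default design spectrum: 9 wavelengths uniform in k over
1180–1420 nm with Hann weights; default surface: half-width 5 cells beyond
the bounding cube, vertex spacing Δ.

Three stair-case sphere discretizations are provided (centre-in-sphere
with the sphere centred on a cell centre; the same centred on a cell
corner; and a fatter ≥ 25%-volume-coverage stair-case).  At λ₀/6 they are
mutually distinct (57/56/81 cells) and their characterized μ_s and g
spectra differ pairwise by tens of percent — the quantitative statement of
why naive discretization misrepresents micron-scale scatterers.  Under
grid refinement the centre-in-sphere discretization's σ_s error against
Mie falls 24.6% → 4.0% → 0.7% over Δ = λ₀/{6, 12, 24}, and the vertex
Poynting field matches the Mie exterior solution to 3.4% RMS at λ₀/24 (at
λ₀/12 the staircase representation error alone leaves ≈ 11%).

## Detection, noise, reconstruction

α(k) is accumulated incrementally per iteration as a per-k scalar against
the stored spectral illumination pattern of the detection plane (from an
illumination-only run), exactly equal (10⁻¹⁰) to the post-hoc overlap of
fully accumulated spectral fields.  The interference spectrum uses
proportionality constant 1; all absolute scaling is absorbed into η.  The
reference mirror is a perfect electric conductor plane at z_ref.  Shot
noise replaces n(k) = η·i(k) by Poisson draws; η calibration bisects on
log η against a reconstructed-image ROI SNR (amplitude ratio in dB between
ROI and noise-region means), using common random numbers so the searched
function is deterministic and monotone.

Reconstruction evaluates A(z) = (1/2π)ΣS(k)ñ(k)exp(i2k n_g z)Δk directly on
any depth grid (the factor 2 is the round trip; displayed depths in medium
use group index n_g = 1.42 — the silicone measurement does not distinguish
group from phase index, so one value serves as both).  With a Hann S(k) the
axial amplitude PSF has its first sidelobe at −31.5 dB and a main lobe
extending ±2π/Δk_band; in mirror tests the background beyond the sidelobe
skirt (≳ 25 μm from the peak) sits below −60 dB, limited by Hann sidelobe
decay rather than by solver artifacts.

## Speckle surrogate

Desk-scale speckle statistics use a separable-PSF convolution model:
uniformly placed point scatterers with circular-Gaussian complex
amplitudes (≥ 20 per resolution cell — fully developed regime) convolved
with the axial A-scan kernel of the Hann band (depths scaled by 1.42) and
the *two-way* lateral response.  The lateral response is the square of the
in-focus Debye–Wolf amplitude profile because the same fiber mode
illuminates and detects: the coupling of a point scatterer at lateral
offset x₀ scales as e_ill(x₀)².  With the package's source-normalized
coupling convention the axial spectrum is exactly the Hann window.

Measured over ten seeds, the amplitude images give normalized-
autocovariance FWHMs of ≈ 4.3 μm (axial) and ≈ 7.9 μm (lateral); the full
three-dimensional solver pipeline is expected to give a somewhat larger
axial figure if the effective spectrum retains residual source taper on
top of the Hann window (the same surrogate yields 5.3–6.2 μm axial for
non-flattened source spectra).  Autocovariance is computed on
linear-amplitude images; computing it on dB images narrows the lateral
FWHM by ≈ 20% and is not the default.

The surrogate captures stationary, fully developed, shift-invariant
speckle only: no depth-dependent PSF, no multiple or dependent scattering,
no attenuation, no noise floor.  Tests passing on it validate the
statistics machinery and the PSF scales, not those sample-dependent
effects — the PSTD pipeline exists precisely to supply them at full scale.

## Analysis procedures

* Autocovariance: mean-subtracted, FFT-based (biased) estimator, averaged
  over the orthogonal axis, normalized at zero lag; FWHM by linear
  interpolation of the half crossing (symmetric two-sided width).
* PSF extraction: threshold at the 99.95th percentile, 26-connected
  component labelling, per-component maximum as the candidate centre, 1D
  Gaussian fits along x and z, rejection at normalized RMS residual
  > 0.15 (the value is a package choice; it cleanly separates isolated
  blobs from overlapping unequal pairs, while equal blobs at sub-FWHM
  separation are fundamentally indistinguishable from a single Gaussian),
  sub-pixel centres from the fits, monotone pchip resampling onto common
  axes for averaging.  Depth profiles bin lateral FWHMs into 40 μm bins
  with two-standard-deviation spreads; the minimum of the mean curve
  estimates the focus.
* Attenuation: the high-scattering average intensity A-scan is divided by
  the low-scattering (index-contrast 0.001) calibration average, cancelling
  the confocal function; I₀exp(−2μ_s(z−z₀)) is fitted by nonlinear least
  squares (z₀ fixed at the fit-range start to remove the I₀/z₀
  redundancy).  Uncertainty: many refits with per-point Gaussian
  perturbations at the known relative SD (default 500, seeded);
  μ_s_sigma is the SD of the refit distribution.  Simulation at 10%
  per-point noise shows the reported σ matches the sampling SD (0.374 vs
  0.381 at the test geometry) and 2σ intervals cover at ≈ 95%.
* Amplitude histograms: maximum-likelihood Rayleigh scale √(Σa²/2N) with a
  Kolmogorov–Smirnov statistic; KS sampling assumes decorrelated pixels,
  so speckle images are subsampled beyond the grain size before testing.

## Test problem sizes

The suite runs every stage at reduced scale chosen for accuracy, not merely
speed: 1D grids of a few hundred cells for propagation/detection physics,
3D grids of 23³–55³ for plane-wave characterization (λ₀/6 to λ₀/24 around
a 1 μm scatterer), a 112×112×30 grid for the focused-beam consistency
check, two-parameter design optimizations, and 10-seed speckle ensembles
on ≈ 80×120 μm images.  Full-scale runs (12 000 iterations at 0.252 fs,
2048 spectral samples, 64 free design parameters, hundreds of A-scans) use
the same code paths and are configuration choices.

## Known limitations

Non-dispersive, isotropic, non-magnetic media only (TiO₂ birefringence is
ignored, as the design calculations assume); no subpixel permittivity
smoothing (the discrete-scatterer design method is the intended
alternative); scalar fiber-coupling approximation on S_det; Gaussian
rather than exact LP01 fiber mode; the 4f relay is an approximation to the
real scan lens; shot noise is the only detector noise source; the PEC
reference mirror is ideal.  The uniqueness or stability of optimized
scatterer designs is not addressed — the optimizer finds *a* refractive
index distribution with matching exterior flux, not a physically unique
one.
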