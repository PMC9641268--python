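# Methods

## Model and scope

`sfdot` implements the two-step spatial-frequency-domain fluorescence
reconstruction for a **semi-infinite, homogeneous** scattering medium in
reflection geometry, under the **first-order (Born) approximation**: the
demodulated emission spectrum is linear in the fluorophore concentration,
coupled through the two-point diffusion Green's-function kernel

γ(q, z; k) = (ℓ_ex ℓ_em / D_ex D_em) · e^{−[Q_ex(k)+Q_em(q)] z} /
([Q_ex(k) ℓ_ex + 1][Q_em(q) ℓ_em + 1]),  Q(q) = √(3 μ_a (μ_a+μ_s′) + q²).

Modulation is along x only (k = (k, 0), k = 2πf).  Out of scope by design:
heterogeneous or layered backgrounds, surface curvature/profilometry, full
3D inversion, absolute concentration quantification, and nonlinear
(beyond-Born) excitation depletion inside thick targets.

Two derived scalars are not specified by the measurement protocol and are
fixed by standard diffusion-optics conventions:

* **Diffusion length** D = 1/(3(μ_a + μ_s′)) (mm) — the CW convention.  Any
  constant speed factor would cancel: only ℓ/D ratios and Q enter the
  kernel, and the depth fit absorbs overall scale into its amplitude A.
* **Extrapolation distance** ℓ = 2·A(n)·D with the Groenhuis/Egan
  effective-reflection polynomial A(n) = (1+R_eff)/(1−R_eff),
  R_eff = 0.0636 n + 0.668 + 0.710/n − 1.440/n².  Default n_rel = 1.33
  (water-based phantom), configurable.  Depth estimation is insensitive to
  this choice since ℓ only enters the slowly varying (Qℓ+1) factors.

Default background properties (breast-tissue-like): μ_a/μ_s′ =
0.004/0.8 mm⁻¹ at 808 nm excitation and 0.006/0.76 mm⁻¹ at 850 nm emission.

## Forward simulator

The synthetic-data generator reproduces the reference acquisition protocol:
31 spatial frequencies from 0 to 0.15 mm⁻¹, phases (0, 2π/3, 4π/3), a
256×256 grid over a 100×100 mm field (pitch 0.390625 mm, ~17 px per period
of the finest modulation), and a 12-bit camera whose gain (exposure
surrogate) is set per dataset so the unmodulated frame peaks at ~4000 of
4095 counts.  Frames are synthesized in the frequency domain: per
wavenumber k, the emission field under unit complex illumination e^{ikx} is
one FFT of the concentration map, a pointwise multiplication by the
(±k-shifted) kernel, and an inverse FFT — exact under the linear model.
Slab targets use the analytic z-integral of the kernel; the slab remains
linear (no excitation depletion).  Noise: Poisson shot noise on expected
counts, Gaussian read noise (sd 2 counts), rounding, clipping.  The
instrument's nominal-vs-actual frequency mismatch (magnification error) can
be injected via a frequency scale; bright-field frames carry the actual
frequency for the calibration step.

What the generator does **not** emulate — hence what passing tests do not
show about real data: model mismatch (the inverse model is the same
diffusion kernel the forward model uses, so forward–inverse consistency is
near-exact by construction), thick-target nonlinearity, background
heterogeneity, surface curvature, stray/ambient light beyond a constant
offset (which three-phase demodulation cancels exactly), and background
autofluorescence (an optional uniform background-fluorophore slab is
available but defaults to zero; see "Weak positivity" below).

## Demodulation and spectra

Three-phase demodulation uses real part (1/3)(2F₀ − F₁ − F₂) and, by
default, imaginary part (1/√3)(F₂ − F₁) — the "consistent" convention for
which |Φ| equals the modulation amplitude exactly.  A "literal"
variant with coefficient 1/3 (as sometimes printed for this method) is kept
behind a flag; it leaks a conjugate −k component that slightly rescales
k-dependent amplitudes.  Spectra are evaluated two ways: FFT on the grid's
frequency lattice (with physical scaling, pixel area × sum, and
pixel-center phase), and exact direct summation at arbitrary continuous q —
the latter is used at the measured modulation frequency, which generally
falls between lattice frequencies.  Coordinates: pixel centers at
(i+0.5)·pitch, origin at the field corner.

Frequency calibration averages the bright-field rows into a 1D profile,
locates the spectral peak near the nominal bin, then refines by
variable-projection least squares (fit of offset + cosine + sine amplitudes
with the frequency as the only nonlinear parameter) — unbiased by window
leakage, recovering noise-free frequencies to ~1e−9 mm⁻¹.  Frequencies with
fewer than two periods across the field fall back to nominal (the peak
cannot be separated from the DC lobe); so does any profile without a peak
5× above the median spectral floor.

## Depth fit

y(k) uses the **magnitude** of Φ̂(k; k): the model requires a real positive
response, Φ̂ is complex, and the magnitude is exact for noise-free targets
while robust under noise (the Rician floor it creates is absorbed by the
fitted offset y_o).  All y are normalized by y at the smallest |k| present;
that same point is then excluded from the fit (for thick targets the
linearized model is poorest at k = 0; on an exact exponential the removal
is a no-op).  Fitting: trust-region least squares with analytic Jacobian,
bounds A, z, y_o ≥ 0, fixed starts (5.0, 1.0, 0.1).  The reported
uncertainty is the square root of the z-diagonal of the residual-variance
scaled covariance (JᵀJ)⁻¹s².  Degenerate inputs (constant response) yield a
flagged, non-converged result — never a silent depth.

## Margin reconstruction

The k = 0 demodulated spectrum is divided by γ(q, z; 0) on the FFT lattice,
multiplied by the Gaussian filter f_σ(q) = (1/2πσ²)e^{−q²/2σ²} (prefactor
kept as written; normalization removes it), and inverse-transformed with
the mathematically consistent inverse sign — the printed single-sign
convention would mirror asymmetric scenes.  The real part is taken; the map
is max-normalized.  FWHM mask: pixels ≥ 0.5 (ties included), 8-connected
components, area = pixel count × pixel area.

### Weak positivity (σ selection)

σ is scanned over a grid (default 0.01–5.0 mm⁻¹, step 0.01, bracketing all
plausible optima) and the selected σ* is the **largest** value for which
the map's mean exceeds one **noise** standard deviation, the noise sd being
estimated by mirroring the negative-pixel population
(σ_n = √mean(C²|C<0); for zero-mean Gaussian noise around the background
this equals the noise sd, and mean ≥ σ_n bounds the negative-pixel fraction
near Φ(−1) ≈ 16%).  Comparing the mean against the *total* pixel standard
deviation instead would be scale-free but unusable: any sparse
max-normalized blob has mean/std ≈ 2√π·s_blur/L < 1 unless the blur radius
approaches a third of the field, which would force absurdly small σ for
every scene.  The noise-referenced criterion reproduces the expected
behavior: σ* decreases with target depth (lower SNR at longer pathlengths)
and never increases with added noise.

Two caveats, both consequences of the ideal zero-background phantom:
(1) noise-free maps trip the criterion only where the discrete Gaussian
filter becomes Nyquist-truncated (ringing), so σ* sits near the top of the
*resolvable* band (~1.4 mm⁻¹ at the default pitch) rather than at the grid
top; (2) the negative-pixel *fraction* on noisy zero-background scenes is
~0.5·(1 − support fraction) ≈ 50%, because the empty background is a
zero-mean noise field — a real acquisition's diffuse background offset is
what pushes this figure toward the 16% mark.  The fraction is reported as a
diagnostic; pixels within 1e−9 of zero are not counted as negative.

### Projection comparison

The same FWHM measure applied to the raw unmodulated fluorescence image
(no inversion) gives the traditional 2D-projection margin estimate; it
exceeds 1 at all depths and grows roughly linearly with depth, while the
reconstructed width stays near 1 — the quantitative argument for the
inversion step.

## Multiple targets

Lateral segmentation smooths the unmodulated image (Gaussian, 2 px), finds
profile peaks along the row through the detected maxima with prominence
≥ 5× the robust (MAD-based) noise sd, and splits at the inter-peak profile
minima.  Each segment is apodized with a Tukey window (taper 10% of segment
width; 0 reproduces a hard split, which would inject spectral leakage into
the per-segment response) and analyzed independently.  A single detected
peak yields one full-field segment with no window, making the single-target
path identical to the unsegmented pipeline.  Per-segment failures are
flagged entries, not exceptions.

## Problem sizes and numerics

Test and acceptance sweeps use the full default protocol (256² grid, 31
frequencies): 5 depths × 5 noisy runs for depth/margin accuracy and 5
depths × 4 perturbation combinations (noise-free, 12-bit quantization on —
quantization is part of the instrument, not a noise source) for the ±10%
optical-property robustness.  Oracle-grade unit tests (kernel-division
identity, direct-DFT agreement) use small grids and an unquantized camera,
and condition the kernel division (z = 1.5 mm, σ = 1.5 mm⁻¹) so that the
e^{Qz} amplification of float round-off stays far below the 1e−8
tolerances; at large z·σ the division amplifies double-precision noise by
many orders of magnitude, which is exactly the instability the Gaussian
filter exists to regularize.

## Known limitations

* Forward and inverse share the diffusion kernel, so simulation-based
  accuracy figures are upper bounds on real-data performance; they validate
  the algorithmic chain, not the diffusion model itself.
* The exponential depth model assumes emission from a single plane; thick
  targets are summarized by their top surface, and the simulator's linear
  slab option spreads emission in z without excitation depletion.
* Joint ±10% scaling of μ_a and μ_s′ at both wavelengths produces depth
  errors up to ~0.83 mm at 10 mm depth — slightly above the ~0.8 mm quoted
  for single-coefficient-style perturbations; margin changes stay < 1%.
* Segmentation splits along x only and assumes laterally disjoint targets;
  laterally coincident targets at different depths are out of scope.
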