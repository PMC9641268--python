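# sfdot — rapid SFD fluorescence depth and margin estimation

`sfdot` estimates the **depth** and **transverse margins** of fluorescent
inclusions (e.g. ICG-labelled tumors) buried in turbid media, from wide-field
images acquired under sinusoidally modulated illumination — the spatial
frequency domain (SFD) variant of fluorescence diffuse optical tomography.
It is aimed at image-guided-surgery research: instead of a full, ill-posed 3D
inversion it uses a rapid two-step algorithm, and it ships with a
diffusion-theory forward simulator so the entire pipeline runs and is tested
with no instrument and no downloads.

## The method

Illumination patterns `S_i = (S0/2)[1 + cos(k x + θ_i)]` with phases
θ = 0, 2π/3, 4π/3 are projected at spatial frequencies f = 0 … 0.15 mm⁻¹
(k = 2πf).  Each frame triplet is demodulated into the complex emission field
Φ(ρ; k), whose Fourier transform Φ̂(q; k) is linear in the fluorophore
concentration under the first-order (Born) diffusion model, with the
semi-infinite two-point kernel

    γ(q, z; k) = (ℓ_ex ℓ_em / D_ex D_em) · exp(−[Q_ex(k) + Q_em(q)] z)
                 / ([Q_ex(k) ℓ_ex + 1][Q_em(q) ℓ_em + 1]),
    Q(q) = sqrt(3 μ_a (μ_a + μ_s′) + q²).

**Step 1 — depth.**  For a thin layer at depth z, the boundary-corrected
response `y(k) = |Φ̂(k; k)| (Q_ex ℓ_ex + 1)(Q_em ℓ_em + 1)` decays as a single
exponential in `x(k) = Q_ex(k) + Q_em(k)`:

    y(k)/y(0) = A exp(−z_target · x(k)) + y_o.

A bounded nonlinear fit (starts A, z, y_o = 5.0, 1.0, 0.1; smallest-|k| point
excluded) returns z_target with its standard error.

**Step 2 — margins.**  At the fitted depth, the lateral concentration follows
by analytic Fourier inversion of the unmodulated (k = 0) data,

    C(ρ) = InvFT[ Φ̂(q; 0) / γ(q, z; 0) · f_σ(q) ],
    f_σ(q) = (1/2πσ²) exp(−q²/2σ²),

with σ chosen automatically by a weak-positivity rule (largest σ for which
the map's mean exceeds one noise standard deviation).  The margin is the
FWHM contour of the max-normalized map; the **relative width**
`sqrt(FWHM area / true area)` equals 1 for perfect recovery.

## Worked example

```python
from sfdot import (fit_depth, modulation_response, simulate_acquisition,
                   single_target_phantom)

dataset = simulate_acquisition(single_target_phantom(6.0), seed=7)  # 6 mm deep
fit = fit_depth(modulation_response(dataset))
print(fit.z_target, fit.z_std)
```

Running `python examples/simulate_and_estimate_depth.py` prints

```
frames: 31 frequencies x 3 phases, 256x256 px, peak count 4089
x range: 0.2156 .. 1.8973 mm^-1 (twice the reciprocal penetration depth)
fitted depth: 6.035 +/- 0.019 mm (true 6.0 mm, error 0.035 mm)
amplitude A = 3.674, noise floor yo = 0.0017, converged = True
```

i.e. a 10 × 10 mm fluorescent layer 6 mm below the surface, imaged with shot
noise at ~4000 peak counts, is localized to 0.035 mm.  Margin reconstruction
(`python examples/margin_reconstruction.py`, target at 4 mm) prints

```
fitted depth:        4.014 +/- 0.012 mm
selected sigma:      0.60 mm^-1 (weak-positivity rule)
FWHM margin area:    75.7 mm^2 (true 100)
relative width:      0.870 (reconstruction)
relative width:      1.104 (raw 2D projection, no inversion)
```

— the inverted margin is within ~13% of the true width while the raw 2D
projection, blurred by diffusion, reads wider (and gets rapidly worse with
depth).  Further examples cover two-target segmentation
(`examples/two_targets.py`) and robustness to ±10% optical-property errors
(`examples/optical_property_robustness.py`).

A thin CLI mirrors the library: `sfdot simulate`, `sfdot reconstruct`,
`sfdot depth`, `sfdot margin`, `sfdot report` (datasets travel as multi-page
16-bit TIFF stacks with a JSON sidecar; see `sfdot.io`).

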