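"""Recover the lateral margins of a buried target by Fourier inversion.

After the depth fit, the unmodulated (k = 0) demodulated image is divided
by the diffusion kernel at the fitted depth and Gaussian-low-pass filtered
(Eqs. of the two-step method); the regularization parameter sigma is chosen
automatically by weak positivity.  The FWHM contour of the max-normalized
map estimates the target's margins; the relative width
sqrt(FWHM area / true area) is 1 for perfect recovery.  For comparison the
same margin measure is applied to the raw 2D projection image, which
overestimates margins increasingly with depth.
"""

import numpy as np

from sfdot import (
    fit_depth,
    modulation_response,
    projection_width,
    reconstruct_margin,
    simulate_acquisition,
    single_target_phantom,
    three_phase_demodulate,
)
from sfdot.demodulate import Spectrum

TRUE_DEPTH_MM = 4.0
TRUE_AREA_MM2 = 100.0

dataset = simulate_acquisition(single_target_phantom(TRUE_DEPTH_MM), seed=11)
fit = fit_depth(modulation_response(dataset))

dc_field = three_phase_demodulate(*dataset.triplet(0))
recon = reconstruct_margin(
    Spectrum(dc_field, dataset.pixel_pitch), fit.z_target, dataset.medium
)
proj = projection_width(np.clip(dc_field.real, 0, None), dataset.pixel_pitch)

print(f"fitted depth:        {fit.z_target:.3f} +/- {fit.z_std:.3f} mm")
print(f"selected sigma:      {recon.sigma:.2f} mm^-1 (weak-positivity rule)")
print(f"FWHM margin area:    {recon.area_mm2:.1f} mm^2 (true {TRUE_AREA_MM2:.0f})")
print(f"relative width:      {recon.relative_width:.3f} (reconstruction)")
print(f"relative width:      {proj:.3f} (raw 2D projection, no inversion)")
# The reconstructed margin is close to the true 10 mm square; the raw
# projection is blurred by diffusion and reads wider.
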