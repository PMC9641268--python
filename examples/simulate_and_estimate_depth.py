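"""Simulate a buried fluorescent target and estimate its depth.

A 10 x 10 mm thin fluorescent layer is placed 6 mm below the surface of a
breast-tissue-like scattering medium and imaged under 31 sinusoidal
illumination frequencies (0-0.15 mm^-1, three phases each) with a noisy
12-bit camera.  The demodulated emission response y(k), normalized and
plotted against x(k) = Q_ex(k) + Q_em(k), decays as exp(-z x); fitting
A exp(-z x) + yo recovers the depth.
"""

import numpy as np

from sfdot import fit_depth, modulation_response, simulate_acquisition, single_target_phantom

TRUE_DEPTH_MM = 6.0

dataset = simulate_acquisition(single_target_phantom(TRUE_DEPTH_MM), seed=7)
print(f"frames: {dataset.frames.shape[0]} frequencies x {dataset.frames.shape[1]} phases, "
      f"{dataset.frames.shape[2]}x{dataset.frames.shape[3]} px, "
      f"peak count {dataset.frames[0].max()}")

response = modulation_response(dataset)
fit = fit_depth(response)

print(f"x range: {response.x[0]:.4f} .. {response.x[-1]:.4f} mm^-1 "
      "(twice the reciprocal penetration depth)")
print(f"fitted depth: {fit.z_target:.3f} +/- {fit.z_std:.3f} mm "
      f"(true {TRUE_DEPTH_MM} mm, error {abs(fit.z_target - TRUE_DEPTH_MM):.3f} mm)")
print(f"amplitude A = {fit.A:.3f}, noise floor yo = {fit.y_offset:.4f}, "
      f"converged = {fit.converged}")
# The depth error on noisy simulated data is typically well under the
# ~1 mm accuracy reported for phantom experiments with this protocol.
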