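"""Shared fixtures: media, cameras, and cached simulation sweeps.

The expensive pipeline sweeps (noisy depth series, optical-property
perturbation series) are session-scoped so the depth- and margin-accuracy
tests can share one set of simulated acquisitions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sfdot import (
    AcquisitionConfig,
    CameraModel,
    analyze_targets,
    default_medium,
    simulate_acquisition,
    single_target_phantom,
)

DEPTHS_MM = (2.0, 4.0, 6.0, 8.0, 10.0)
N_SEEDS = 5


@pytest.fixture(scope="session")
def medium():
    return default_medium()


@pytest.fixture(scope="session")
def noiseless_camera():
    return CameraModel(shot_noise=False, read_noise_sd=0.0, quantize=False)


@pytest.fixture(scope="session")
def small_config():
    """Coarser grid for exactness-oriented unit tests (keeps FFTs tiny)."""
    return AcquisitionConfig(grid=(128, 128))


@pytest.fixture(scope="session")
def noisy_single_target_sweep():
    """Full two-step pipeline on noisy acquisitions: depths 2-10 mm x 5 seeds.

    Returns a list of dicts with true depth, fitted depth, relative width,
    selected sigma and negative fraction.
    """
    out = []
    for iz, z in enumerate(DEPTHS_MM):
        for i in range(N_SEEDS):
            ds = simulate_acquisition(single_target_phantom(z), seed=10 * iz + i)
            res = analyze_targets(ds, segment=False)[0]
            assert res.error is None, res.error
            out.append(
                {
                    "z_true": z,
                    "seed": 10 * iz + i,
                    "z_hat": res.depth.z_target,
                    "z_std": res.depth.z_std,
                    "relative_width": res.reconstruction.relative_width,
                    "sigma": res.reconstruction.sigma,
                    "negative_fraction": res.reconstruction.negative_fraction,
                }
            )
    return out


@pytest.fixture(scope="session")
def perturbed_optics_sweep():
    """Noise-free acquisitions analyzed with +/-10% perturbed optical
    properties (all four sign combinations, both wavelengths jointly).

    "Noise-free" means shot and read noise off; the 12-bit quantization of
    the camera is part of the instrument and stays on.
    """
    quiet_camera = CameraModel(shot_noise=False, read_noise_sd=0.0)
    from sfdot.demodulate import Spectrum, three_phase_demodulate
    from sfdot.depth import fit_depth, modulation_response
    from sfdot.margins import reconstruct_margin

    rows = []
    for z in DEPTHS_MM:
        ds = simulate_acquisition(
            single_target_phantom(z), camera=quiet_camera, seed=None
        )
        dc = three_phase_demodulate(*ds.triplet(0))
        spec = Spectrum(dc, ds.pixel_pitch)
        fit0 = fit_depth(modulation_response(ds))
        rec0 = reconstruct_margin(spec, fit0.z_target, ds.medium)
        for fa, fs in itertools.product((0.9, 1.1), repeat=2):
            wrong = ds.medium.scaled(fa, fs)
            fit = fit_depth(modulation_response(ds, wrong))
            row = {
                "z_true": z,
                "factor_mu_a": fa,
                "factor_mu_s": fs,
                "z_hat": fit.z_target,
                "z_hat_ref": fit0.z_target,
                "relative_width_ref": rec0.relative_width,
            }
            if z <= 6.0:
                rec = reconstruct_margin(spec, fit.z_target, wrong)
                row["relative_width"] = rec.relative_width
            rows.append(row)
    return rows
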