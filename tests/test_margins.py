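"""Regularized Fourier inversion, sigma selection, FWHM margin measures."""

import math

import numpy as np
import pytest

from sfdot import (
    CameraModel,
    default_medium,
    fwhm_margin,
    invert_transverse,
    projection_width,
    reconstruct_margin,
    relative_width,
    select_sigma,
    simulate_acquisition,
    single_target_phantom,
)
from sfdot.demodulate import Spectrum, three_phase_demodulate
from sfdot.diffusion import kernel_gamma
from sfdot.margins import default_sigma_grid


def kernel_division_spectrum(conc, pitch, z, medium):
    """Forward-synthesized demodulated field gamma * C_hat for k = 0."""
    ny, nx = conc.shape
    qx = 2 * math.pi * np.fft.fftfreq(nx, d=pitch)
    qy = 2 * math.pi * np.fft.fftfreq(ny, d=pitch)
    q = np.sqrt(qx[None, :] ** 2 + qy[:, None] ** 2)
    field = np.fft.ifft2(kernel_gamma(q, z, 0.0, medium) * np.fft.fft2(conc))
    return Spectrum(field, pitch), q


class TestInvertTransverse:
    def test_kernel_division_identity(self, medium):
        # inversion of a forward-synthesized spectrum returns the
        # sigma-low-passed concentration exactly (the module's core oracle)
        # depth and sigma chosen so exp(Q z) amplification of float
        # round-off stays far below the 1e-8 tolerance at the Nyquist corner
        rng = np.random.default_rng(11)
        conc = rng.random((64, 64))
        pitch, z, sigma = 0.5, 1.5, 1.5
        spec, q = kernel_division_spectrum(conc, pitch, z, medium)
        recon = invert_transverse(spec, z, sigma, medium)
        filt = np.exp(-(q**2) / (2 * sigma**2)) / (2 * math.pi * sigma**2)
        expected = np.fft.ifft2(np.fft.fft2(conc) * filt).real
        assert np.max(np.abs(recon - expected)) < 1e-8 * np.max(np.abs(expected))

    def test_linearity(self, medium):
        rng = np.random.default_rng(12)
        conc = rng.random((32, 32))
        spec, _ = kernel_division_spectrum(conc, 0.5, 3.0, medium)
        a = invert_transverse(spec, 3.0, 1.0, medium)
        spec2 = Spectrum(2.0 * spec.field, spec.pixel_pitch)
        b = invert_transverse(spec2, 3.0, 1.0, medium)
        assert np.allclose(b, 2.0 * a, rtol=1e-12)

    def test_real_projection_close_to_full_complex_inverse(self, medium):
        conc = np.zeros((64, 64))
        conc[28:36, 28:36] = 1.0
        spec, q = kernel_division_spectrum(conc, 0.5, 3.0, medium)
        recon = invert_transverse(spec, 3.0, 1.5, medium)
        filt = np.exp(-(q**2) / (2 * 1.5**2)) / (2 * math.pi * 1.5**2)
        full = np.fft.ifft2(np.fft.fft2(spec.field) / kernel_gamma(q, 3.0, 0.0, medium) * filt)
        assert np.max(np.abs(full.imag)) < 1e-8 * np.max(np.abs(full.real))
        assert np.allclose(recon, full.real)

    def test_shallow_noise_free_width_near_unity(self, noiseless_camera, medium):
        ds = simulate_acquisition(single_target_phantom(2.0), camera=noiseless_camera, seed=None)
        dc = three_phase_demodulate(*ds.triplet(0))
        recon = invert_transverse(Spectrum(dc, ds.pixel_pitch), 2.0, 3.0, medium)
        m = fwhm_margin(recon / recon.max(), ds.pixel_pitch)
        assert relative_width(m.area_mm2) == pytest.approx(1.0, abs=0.1)

    def test_invalid_sigma_rejected(self, medium):
        spec = Spectrum(np.zeros((8, 8)), 0.5)
        with pytest.raises(ValueError, match="sigma"):
            invert_transverse(spec, 2.0, 0.0, medium)


class TestSelectSigma:
    def test_noise_free_selects_resolvable_top(self, noiseless_camera, medium):
        # without noise the constraint only trips where the discrete Gaussian
        # filter becomes Nyquist-truncated, so sigma* sits at the top of the
        # resolvable band rather than at tiny values
        ds = simulate_acquisition(single_target_phantom(4.0), camera=noiseless_camera, seed=None)
        dc = three_phase_demodulate(*ds.triplet(0))
        sel = select_sigma(Spectrum(dc, ds.pixel_pitch), 4.0, medium)
        assert sel.satisfied
        assert sel.sigma > 1.0

    def test_noisier_data_never_increases_sigma(self, medium):
        for seed in range(2):
            sigmas = []
            for peak in (4000.0, 400.0, 40.0):
                ds = simulate_acquisition(
                    single_target_phantom(4.0),
                    camera=CameraModel(target_peak=peak),
                    seed=seed,
                )
                dc = three_phase_demodulate(*ds.triplet(0))
                sigmas.append(select_sigma(Spectrum(dc, ds.pixel_pitch), 4.0, medium).sigma)
            assert sigmas[0] >= sigmas[1] >= sigmas[2]

    def test_bad_grid_rejected(self, medium):
        spec = Spectrum(np.ones((8, 8)), 0.5)
        with pytest.raises(ValueError, match="sigma_grid"):
            select_sigma(spec, 2.0, medium, np.array([0.5, 0.4]))

    def test_default_grid_brackets_reported_values(self):
        grid = default_sigma_grid()
        assert grid[0] <= 0.11 and grid[-1] >= 3.77
        assert np.all(np.diff(grid) > 0)


class TestFwhmMargin:
    def test_gaussian_blob_area_closed_form(self):
        # FWHM area of an isotropic Gaussian of scale s is pi (1.1774 s)^2
        n, pitch, s = 256, 0.5, 4.0  # s = 8 px
        x = (np.arange(n) - n / 2) * pitch
        g = np.exp(-(x[None, :] ** 2 + x[:, None] ** 2) / (2 * s**2))
        m = fwhm_margin(g, pitch)
        assert m.area_mm2 == pytest.approx(math.pi * (1.1774 * s) ** 2, rel=0.03)

    def test_plateau_area(self):
        n, pitch = 128, 0.5
        img = np.zeros((n, n))
        img[30:50, 40:60] = 1.0  # 10 x 10 mm at 0.5 mm pitch
        m = fwhm_margin(img, pitch)
        assert m.area_mm2 == pytest.approx(100.0, rel=0.02)
        assert m.n_components == 1

    def test_two_blobs_two_components(self):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 1.0
        img[40:50, 40:50] = 0.8
        m = fwhm_margin(img, 1.0)
        assert m.n_components == 2
        assert sorted(m.component_areas_mm2) == [100.0, 100.0]

    def test_all_zero_map(self):
        m = fwhm_margin(np.zeros((16, 16)), 1.0)
        assert m.area_mm2 == 0.0 and m.component_areas_mm2 == []

    def test_half_maximum_ties_included(self):
        img = np.zeros((8, 8))
        img[2, 2] = 1.0
        img[2, 3] = 0.5
        m = fwhm_margin(img, 1.0)
        assert m.mask[2, 3]
        assert m.area_mm2 == 2.0


class TestRelativeWidth:
    @pytest.mark.parametrize("area, true, expected", [(169.0, 100.0, 1.3), (100.0, 100.0, 1.0)])
    def test_arithmetic(self, area, true, expected):
        assert relative_width(area, true) == pytest.approx(expected)

    def test_invalid_true_area(self):
        with pytest.raises(ValueError):
            relative_width(10.0, 0.0)


class TestProjectionWidth:
    def test_monotone_in_depth_and_dominates_reconstruction(self, noiseless_camera, medium):
        widths = []
        recon_widths = []
        for z in (2.0, 4.0, 6.0, 8.0, 10.0):
            ds = simulate_acquisition(single_target_phantom(z), camera=noiseless_camera, seed=None)
            dc = three_phase_demodulate(*ds.triplet(0))
            dc_int = np.clip(dc.real, 0.0, None)
            widths.append(projection_width(dc_int, ds.pixel_pitch))
            rec = reconstruct_margin(Spectrum(dc, ds.pixel_pitch), z, medium)
            recon_widths.append(rec.relative_width)
        assert all(b > a for a, b in zip(widths, widths[1:]))
        assert widths[0] > 1.0  # any diffusion blur widens a plateau's FWHM
        for z, pw, rw in zip((2.0, 4.0, 6.0, 8.0, 10.0), widths, recon_widths):
            if z >= 4.0:
                assert pw >= rw

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            projection_width(np.zeros((8, 8)), 1.0)
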