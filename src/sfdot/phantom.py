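"""Forward simulator for structured-illumination fluorescence acquisitions.

Generates complete synthetic datasets — one fluorescence frame per
(spatial frequency, phase) pair plus bright-field frames — from a
declarative phantom description, under the first-order (Born) diffusion
model: the demodulated emission spectrum is linear in the fluorophore
concentration, with the semi-infinite two-point kernel of
:mod:`sfdot.diffusion` coupling illumination and emission.

Synthesis is done in the frequency domain: for each modulation wavenumber
``k`` the emission field under unit complex illumination ``exp(i k x)`` is
obtained by one FFT of the concentration map, a pointwise multiplication by
the (shifted) kernel, and one inverse FFT.  A frame at phase ``theta`` is
then ``(S0/2) E_0 + (S0/2) Re{exp(i theta) E_k}``, which is exact for the
linear model and fast.

Coordinates: pixel centers at ``(i + 0.5) * pitch``, origin at the
field-of-view corner, x (last array axis) is the modulation axis.
Intensity modulation is along x only; ``k = 2 pi f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diffusion import MediumPair, default_medium, kernel_gamma, slab_kernel

__all__ = [
    "TargetSpec",
    "PhantomSpec",
    "AcquisitionConfig",
    "CameraModel",
    "AcquisitionDataset",
    "AUTOFLUORESCENCE_FLOOR",
    "rasterize_targets",
    "emission_envelope",
    "simulate_frame",
    "simulate_brightfield",
    "simulate_acquisition",
    "single_target_phantom",
    "multi_target_phantom",
]

#: Relative background-fluorophore concentration that puts the uniform
#: background's contribution to the unmodulated emission response near 1% of
#: a shallow (2 mm) reference target's — an optional stand-in for the weak
#: diffuse autofluorescence floor of real NIR acquisitions.  The reference
#: scenes default to zero background (ideal phantom).
AUTOFLUORESCENCE_FLOOR = 1.4e-5


@dataclass(frozen=True)
class TargetSpec:
    """One fluorescent inclusion.

    ``center`` (mm), ``width``/``height`` (mm) describe the lateral
    footprint (axis-aligned rectangle by default, disc when
    ``shape='disc'`` with ``width`` the diameter); ``z_top`` is the depth of
    the top surface (mm); ``thickness`` 0 means an ideal thin layer;
    ``concentration`` is relative (arbitrary units).
    """

    center: tuple[float, float]
    width: float = 10.0
    height: float = 10.0
    z_top: float = 2.0
    thickness: float = 0.0
    concentration: float = 1.0
    shape: str = "rect"

    def __post_init__(self) -> None:
        if self.z_top < 0:
            raise ValueError("z_top must be non-negative")
        if self.thickness < 0:
            raise ValueError("thickness must be non-negative")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.shape not in ("rect", "disc"):
            raise ValueError(f"unknown footprint shape {self.shape!r}")

    @property
    def footprint_area(self) -> float:
        if self.shape == "disc":
            return math.pi * (self.width / 2.0) ** 2
        return self.width * self.height


@dataclass(frozen=True)
class PhantomSpec:
    """Fluorophore layout plus fluorophore constants.

    ``epsilon`` (extinction coefficient) and ``eta`` (quantum efficiency)
    enter only as the product ``epsilon * eta`` scaling the emission;
    absolute values are arbitrary because the pipeline normalizes.
    ``background`` is a uniform semi-infinite background-fluorophore
    concentration emulating the diffuse autofluorescence floor (0 = none).
    """

    targets: tuple[TargetSpec, ...] = ()
    medium: MediumPair = field(default_factory=default_medium)
    epsilon: float = 1.0
    eta: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.epsilon * self.eta <= 0:
            raise ValueError("epsilon * eta must be positive")
        if self.background < 0:
            raise ValueError("background concentration must be non-negative")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Illumination and sampling geometry.

    Defaults follow the reference protocol: 31 spatial frequencies from 0 to
    0.15 mm^-1, phases (0, 2pi/3, 4pi/3), a 100 x 100 mm field of view on a
    256 x 256 grid (pitch 0.390625 mm, resolving the finest modulation
    period of ~6.7 mm with ~17 px).  ``frequency_scale`` applies a
    multiplicative offset between nominal and actual on-surface frequencies
    (emulating magnification error); the bright-field frames carry the
    actual frequencies, which the calibration step recovers.
    """

    frequencies: tuple[float, ...] = tuple(np.linspace(0.0, 0.15, 31))
    phases: tuple[float, ...] = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)
    field_of_view: tuple[float, float] = (100.0, 100.0)
    grid: tuple[int, int] = (256, 256)
    S0: float = 1.0
    frequency_scale: float = 1.0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        if any(f < 0 for f in freqs):
            raise ValueError("frequencies must be non-negative")
        if list(freqs) != sorted(freqs):
            raise ValueError("frequencies must be sorted ascending")
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "phases", tuple(float(p) for p in self.phases))
        px = self.field_of_view[0] / self.grid[0]
        py = self.field_of_view[1] / self.grid[1]
        if not math.isclose(px, py, rel_tol=1e-12):
            raise ValueError("pixels must be square (Lx/Nx == Ly/Ny)")

    @property
    def pixel_pitch(self) -> float:
        return self.field_of_view[0] / self.grid[0]

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x of shape (Nx,), y of shape (Ny,)), mm."""
        nx, ny = self.grid
        p = self.pixel_pitch
        return (np.arange(nx) + 0.5) * p, (np.arange(ny) + 0.5) * p


@dataclass(frozen=True)
class CameraModel:
    """12-bit camera with shot noise.

    The per-dataset gain (an exposure surrogate) is set so the unmodulated
    (f = 0) frame peaks at ``target_peak`` counts, mirroring the practice of
    raising exposure until the brightest pixel nears 4000 on a 4095 scale.
    ``quantize=False`` keeps frames as floats (useful for numerically exact
    forward-inverse checks).
    """

    bit_depth: int = 12
    full_scale: int = 4095
    target_peak: float = 4000.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    quantize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.target_peak <= self.full_scale):
            raise ValueError("target_peak must lie in (0, full_scale]")

    def apply(self, expected: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        """Turn an expected-intensity image (counts) into a recorded frame."""
        out = np.clip(expected, 0.0, None)
        if self.shot_noise or self.read_noise_sd > 0:
            if rng is None:
                raise ValueError("noise enabled but no RNG supplied")
        if self.shot_noise:
            out = rng.poisson(out).astype(float)
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        if self.quantize:
            out = np.clip(np.rint(out), 0, self.full_scale)
        return out

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise_sd == 0


@dataclass
class AcquisitionDataset:
    """Ordered synthetic (or loaded) acquisition.

    ``frames[i, j]`` is the fluorescence frame at ``frequencies[i]`` (nominal,
    ascending) and ``phases[j]``; ``brightfield[i]`` is the excitation
    reflection pattern at ``frequencies[i]``.
    """

    frequencies: np.ndarray
    phases: np.ndarray
    frames: np.ndarray
    brightfield: np.ndarray
    pixel_pitch: float
    medium: MediumPair
    exposure: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        nf, nph = len(self.frequencies), len(self.phases)
        if self.frames.shape[:2] != (nf, nph):
            raise ValueError(
                f"frames shape {self.frames.shape} inconsistent with "
                f"{nf} frequencies x {nph} phases"
            )
        if self.brightfield.shape[0] != nf:
            raise ValueError("one bright-field frame per frequency required")

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies)

    def triplet(self, i_freq: int) -> tuple[np.ndarray, ...]:
        """The three phase frames at frequency index ``i_freq``, as floats."""
        return tuple(self.frames[i_freq, j].astype(float) for j in range(len(self.phases)))


# ----------------------------------------------------------------- rasterize


def rasterize_targets(
    spec: PhantomSpec, config: AcquisitionConfig
) -> list[tuple[np.ndarray, float, float]]:
    """Discretize each target's lateral concentration onto the pixel grid.

    Returns one ``(map, z_top, thickness)`` tuple per target; a pixel belongs
    to a footprint when its center lies inside.  Raises if a footprint
    extends outside the field of view.
    """
    x, y = config.coords()
    lx, ly = config.field_of_view
    xx, yy = np.meshgrid(x, y)
    out = []
    for t in spec.targets:
        cx, cy = t.center
        if t.shape == "disc":
            r = t.width / 2.0
            inside_fov = (cx - r >= 0) and (cx + r <= lx) and (cy - r >= 0) and (cy + r <= ly)
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        else:
            hw, hh = t.width / 2.0, t.height / 2.0
            inside_fov = (cx - hw >= 0) and (cx + hw <= lx) and (cy - hh >= 0) and (cy + hh <= ly)
            mask = (np.abs(xx - cx) <= hw) & (np.abs(yy - cy) <= hh)
        if not inside_fov:
            raise ValueError(f"target footprint at {t.center} extends outside the field of view")
        out.append((t.concentration * mask.astype(float), t.z_top, t.thickness))
    return out


# ------------------------------------------------------------------ envelopes


def _q_shifted_mag(config: AcquisitionConfig, k_signed: float) -> np.ndarray:
    """|q + k e_x| on the FFT lattice, shape (Ny, Nx)."""
    ny, nx = config.grid[1], config.grid[0]
    p = config.pixel_pitch
    qx = 2.0 * math.pi * np.fft.fftfreq(nx, d=p)
    qy = 2.0 * math.pi * np.fft.fftfreq(ny, d=p)
    return np.sqrt((qx[None, :] + k_signed) ** 2 + qy[:, None] ** 2)


def emission_envelope(
    conc_map: np.ndarray,
    z_top: float,
    thickness: float,
    k_signed: float,
    phantom: PhantomSpec,
    config: AcquisitionConfig,
    conc_spectrum: np.ndarray | None = None,
) -> np.ndarray:
    """Emission field (complex) for unit complex illumination exp(i k x).

    Multiplies the concentration spectrum by the kernel evaluated at the
    shifted frequency |q + k e_x| and inverse-transforms; the returned field
    carries the exp(i k x) plane-wave factor, so a laterally uniform layer
    yields exactly ``eps*eta*gamma(|k|, z; |k|) * C * exp(i k x)``.
    """
    q_mag = _q_shifted_mag(config, k_signed)
    k_mag = abs(k_signed)
    if thickness > 0:
        kern = slab_kernel(q_mag, z_top, thickness, k_mag, phantom.medium)
    else:
        kern = kernel_gamma(q_mag, z_top, k_mag, phantom.medium)
    c_hat = np.fft.fft2(conc_map) if conc_spectrum is None else conc_spectrum
    envelope = np.fft.ifft2(phantom.epsilon * phantom.eta * kern * c_hat)
    x, _ = config.coords()
    return envelope * np.exp(1j * k_signed * x)[None, :]


def _total_envelope(
    phantom: PhantomSpec,
    config: AcquisitionConfig,
    k_signed: float,
    rasters: list[tuple[np.ndarray, float, float]] | None = None,
    spectra: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Sum of per-target emission envelopes plus the uniform background term."""
    ny, nx = config.grid[1], config.grid[0]
    total = np.zeros((ny, nx), dtype=complex)
    if rasters is None:
        rasters = rasterize_targets(phantom, config)
    for idx, (cmap, z_top, thickness) in enumerate(rasters):
        spec = None if spectra is None else spectra[idx]
        total += emission_envelope(cmap, z_top, thickness, k_signed, phantom, config, spec)
    if phantom.background > 0:
        k_mag = abs(k_signed)
        amp = (
            phantom.epsilon
            * phantom.eta
            * phantom.background
            * slab_kernel(k_mag, 0.0, np.inf, k_mag, phantom.medium)
        )
        x, _ = config.coords()
        total += amp * np.exp(1j * k_signed * x)[None, :]
    return total


def _noiseless_frame(
    e_dc: np.ndarray, e_k: np.ndarray, theta: float, s0: float
) -> np.ndarray:
    return 0.5 * s0 * e_dc.real + 0.5 * s0 * (np.exp(1j * theta) * e_k).real


def _dc_gain(phantom: PhantomSpec, config: AcquisitionConfig, camera: CameraModel) -> float:
    """Gain making the noiseless f=0 frame peak at camera.target_peak."""
    e_dc = _total_envelope(phantom, config, 0.0)
    peak = float(np.max(config.S0 * e_dc.real))
    return 1.0 if peak <= 0 else camera.target_peak / peak


# -------------------------------------------------------------------- frames


def simulate_frame(
    phantom: PhantomSpec,
    f: float,
    theta: float,
    config: AcquisitionConfig | None = None,
    camera: CameraModel | None = None,
    rng: np.random.Generator | None = None,
    gain: float | None = None,
) -> np.ndarray:
    """One fluorescence frame under illumination (S0/2)(1 + cos(k x + theta)).

    Returns camera counts.  ``gain`` overrides the peak-normalizing gain
    (pass the dataset-level gain when building frames individually).
    """
    config = config or AcquisitionConfig()
    camera = camera or CameraModel()
    if not any(math.isclose(f, fc, abs_tol=1e-12) for fc in config.frequencies):
        raise ValueError(f"frequency {f} not in the configured set")
    if not any(math.isclose(theta, t, abs_tol=1e-12) for t in config.phases):
        raise ValueError(f"phase {theta} not in the configured set")
    if gain is None:
        gain = _dc_gain(phantom, config, camera)
    k = 2.0 * math.pi * f * config.frequency_scale
    e_dc = _total_envelope(phantom, config, 0.0)
    e_k = e_dc if k == 0 else _total_envelope(phantom, config, k)
    expected = gain * _noiseless_frame(e_dc, e_k, theta, config.S0)
    if camera.noiseless and not camera.quantize:
        return expected
    if not camera.noiseless and rng is None:
        rng = np.random.default_rng(0)
    return camera.apply(expected, rng)


def simulate_brightfield(
    f: float,
    config: AcquisitionConfig | None = None,
    camera: CameraModel | None = None,
    f_actual: float | None = None,
) -> np.ndarray:
    """Excitation reflection pattern at phase 0 (no diffusion blur).

    Proportional to (1 + cos(k_actual x)) / 2, scaled to the camera's target
    peak; ``f_actual`` injects a known frequency offset to exercise the
    calibration step (defaults to f * config.frequency_scale).
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    config = config or AcquisitionConfig()
    camera = camera or CameraModel()
    fa = f * config.frequency_scale if f_actual is None else f_actual
    x, _ = config.coords()
    ny = config.grid[1]
    pattern = 0.5 * camera.target_peak * (1.0 + np.cos(2.0 * math.pi * fa * x))
    img = np.broadcast_to(pattern[None, :], (ny, len(x))).copy()
    if camera.quantize:
        img = np.clip(np.rint(img), 0, camera.full_scale)
    return img


def simulate_acquisition(
    phantom: PhantomSpec,
    config: AcquisitionConfig | None = None,
    camera: CameraModel | None = None,
    seed: int | None = 0,
) -> AcquisitionDataset:
    """Full synthetic acquisition: one frame per (frequency, phase) pair plus
    one bright-field frame per frequency, reproducible under a fixed seed."""
    config = config or AcquisitionConfig()
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    nf, nph = len(config.frequencies), len(config.phases)
    ny, nx = config.grid[1], config.grid[0]

    rasters = rasterize_targets(phantom, config)
    spectra = [np.fft.fft2(cmap) for cmap, _, _ in rasters]
    gain = _dc_gain_cached(phantom, config, camera, rasters, spectra)

    dtype = float if not camera.quantize else np.uint16
    frames = np.zeros((nf, nph, ny, nx), dtype=dtype)
    bright = np.zeros((nf, ny, nx), dtype=dtype)
    e_dc = _total_envelope(phantom, config, 0.0, rasters, spectra)
    for i, f in enumerate(config.frequencies):
        k = 2.0 * math.pi * f * config.frequency_scale
        e_k = e_dc if k == 0 else _total_envelope(phantom, config, k, rasters, spectra)
        for j, theta in enumerate(config.phases):
            expected = gain * _noiseless_frame(e_dc, e_k, theta, config.S0)
            if camera.noiseless and not camera.quantize:
                frames[i, j] = expected
            else:
                frames[i, j] = camera.apply(expected, rng)
        bright[i] = simulate_brightfield(f, config, camera)

    provenance = {
        "schema": "sfdot-dataset v1",
        "seed": seed,
        "gain": gain,
        "config": {
            "frequencies": list(config.frequencies),
            "phases": list(config.phases),
            "field_of_view": list(config.field_of_view),
            "grid": list(config.grid),
            "S0": config.S0,
            "frequency_scale": config.frequency_scale,
        },
        "camera": {
            "bit_depth": camera.bit_depth,
            "full_scale": camera.full_scale,
            "target_peak": camera.target_peak,
            "shot_noise": camera.shot_noise,
            "read_noise_sd": camera.read_noise_sd,
            "quantize": camera.quantize,
        },
    }
    return AcquisitionDataset(
        frequencies=np.array(config.frequencies),
        phases=np.array(config.phases),
        frames=frames,
        brightfield=bright,
        pixel_pitch=config.pixel_pitch,
        medium=phantom.medium,
        exposure=gain,
        provenance=provenance,
    )


def _dc_gain_cached(phantom, config, camera, rasters, spectra) -> float:
    e_dc = _total_envelope(phantom, config, 0.0, rasters, spectra)
    peak = float(np.max(config.S0 * e_dc.real))
    return 1.0 if peak <= 0 else camera.target_peak / peak


# -------------------------------------------------------------- conveniences


def single_target_phantom(
    z_top: float,
    side: float = 10.0,
    center: tuple[float, float] | None = None,
    thickness: float = 0.0,
    medium: MediumPair | None = None,
    background: float = 0.0,
) -> PhantomSpec:
    """Reference scene: one square thin target (default 10 x 10 mm) centered
    in the default field of view, over the default background medium."""
    if center is None:
        center = (50.0, 50.0)
    return PhantomSpec(
        targets=(
            TargetSpec(center=center, width=side, height=side, z_top=z_top, thickness=thickness),
        ),
        medium=medium or default_medium(),
        background=background,
    )


def multi_target_phantom(
    specs: list[tuple[tuple[float, float], float]],
    side: float = 10.0,
    medium: MediumPair | None = None,
    background: float = 0.0,
) -> PhantomSpec:
    """Scene with several square thin targets given as (center, z_top) pairs."""
    return PhantomSpec(
        targets=tuple(
            TargetSpec(center=c, width=side, height=side, z_top=z) for c, z in specs
        ),
        medium=medium or default_medium(),
        background=background,
    )
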