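"""Closed-form diffusion-theory quantities for a semi-infinite turbid medium.

Everything downstream of the forward model and the analytic inversion rests
on four scalar quantities:

* the diffusion coefficient ``D = 1 / (3 (mu_a + mu_s'))`` (mm),
* the extrapolation distance ``ell = 2 A(n) D`` (mm) at which the diffuse
  fluence extrapolates to zero outside the boundary,
* the depth-penetration factor ``Q(q) = sqrt(3 mu_a (mu_a + mu_s') + q^2)``
  (mm^-1), whose reciprocal is the decay depth of a spatial-frequency
  component of diffuse light, and
* the two-point Green's-function kernel ``gamma(q, z; k)`` coupling a
  sinusoidally modulated excitation pattern (wavenumber ``k``) to the
  demodulated emission spectrum at transverse frequency ``q`` from a thin
  fluorescent layer at depth ``z``.

All lengths are millimetres, all wavenumbers are angular (mm^-1,
``k = 2 pi f``). Kernel outputs are in arbitrary units: absolute radiometric
calibration is out of scope because the depth fit absorbs scale into its
amplitude and the margin map is max-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "MediumPair",
    "boundary_reflection_factor",
    "diffusion_coefficient",
    "extrapolation_length",
    "penetration_factor",
    "kernel_gamma",
    "slab_kernel",
]


def boundary_reflection_factor(n_rel: float) -> float:
    """Internal-reflection boundary factor A(n) for the extrapolated boundary.

    Uses the Groenhuis/Egan effective-reflection polynomial
    ``R_eff = 0.0636 n + 0.668 + 0.710 / n - 1.440 / n**2`` and
    ``A = (1 + R_eff) / (1 - R_eff)``.  At ``n = 1`` this gives A ~ 1
    (index-matched boundary, ell ~ 2D).
    """
    if n_rel < 1.0:
        raise ValueError(f"relative refractive index must be >= 1, got {n_rel}")
    r_eff = 0.0636 * n_rel + 0.668 + 0.710 / n_rel - 1.440 / n_rel**2
    if not -1.0 < r_eff < 1.0:
        raise ValueError(f"effective reflection coefficient out of range for n={n_rel}")
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass(frozen=True)
class OpticalProperties:
    """Background optical properties at a single wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.
    n_rel : float
        Refractive index of the medium relative to the outside (air),
        dimensionless.  Default 1.33 (water-based liquid phantom).
    """

    mu_a: float
    mu_s_prime: float
    n_rel: float = 1.33

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and math.isfinite(self.mu_a)):
            raise ValueError(f"mu_a must be positive and finite, got {self.mu_a}")
        if not (self.mu_s_prime > 0 and math.isfinite(self.mu_s_prime)):
            raise ValueError(f"mu_s_prime must be positive, got {self.mu_s_prime}")
        if self.n_rel < 1.0:
            raise ValueError(f"n_rel must be >= 1, got {self.n_rel}")

    @property
    def D(self) -> float:
        """Diffusion length scale 1 / (3 (mu_a + mu_s')), mm."""
        return diffusion_coefficient(self)

    @property
    def ell(self) -> float:
        """Extrapolation distance 2 A(n) D, mm."""
        return extrapolation_length(self)

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3 mu_a (mu_a + mu_s')), mm^-1."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))

    def scaled(self, factor_mu_a: float = 1.0, factor_mu_s: float = 1.0) -> "OpticalProperties":
        """Return a copy with mu_a and mu_s' multiplied by the given factors."""
        return OpticalProperties(
            mu_a=self.mu_a * factor_mu_a,
            mu_s_prime=self.mu_s_prime * factor_mu_s,
            n_rel=self.n_rel,
        )


@dataclass(frozen=True)
class MediumPair:
    """Optical properties at the excitation and emission wavelengths."""

    ex: OpticalProperties
    em: OpticalProperties

    def scaled(self, factor_mu_a: float = 1.0, factor_mu_s: float = 1.0) -> "MediumPair":
        return MediumPair(
            ex=self.ex.scaled(factor_mu_a, factor_mu_s),
            em=self.em.scaled(factor_mu_a, factor_mu_s),
        )


def default_medium() -> MediumPair:
    """Breast-tissue-like liquid-phantom background: 808 nm excitation
    (mu_a = 0.004, mu_s' = 0.8 mm^-1), 850 nm emission (0.006, 0.76 mm^-1)."""
    return MediumPair(
        ex=OpticalProperties(mu_a=0.004, mu_s_prime=0.8),
        em=OpticalProperties(mu_a=0.006, mu_s_prime=0.76),
    )


def diffusion_coefficient(props: OpticalProperties) -> float:
    """D = 1 / (3 (mu_a + mu_s')), mm (standard CW diffusion convention)."""
    return 1.0 / (3.0 * (props.mu_a + props.mu_s_prime))


def extrapolation_length(props: OpticalProperties) -> float:
    """ell = 2 A(n_rel) D, mm."""
    return 2.0 * boundary_reflection_factor(props.n_rel) * diffusion_coefficient(props)


def penetration_factor(q_mag, props: OpticalProperties):
    """Depth-penetration factor Q(q) = sqrt(3 mu_a (mu_a + mu_s') + q^2), mm^-1.

    ``q_mag`` is the magnitude of an angular spatial frequency (mm^-1); may be
    a scalar or an ndarray.  Strictly increasing in q; Q(0) = mu_eff.
    """
    q = np.asarray(q_mag, dtype=float)
    if np.any(q < 0):
        raise ValueError("spatial frequency magnitude must be non-negative")
    out = np.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s_prime) + q * q)
    return float(out) if np.isscalar(q_mag) or out.ndim == 0 else out


def kernel_gamma(q_mag, z, k_mag, medium: MediumPair):
    """Two-point Green's-function kernel gamma(q, z; k) of the semi-infinite
    medium (arbitrary units).

    gamma = (ell_ex ell_em / (D_ex D_em))
            * exp(-(Q_ex(k) + Q_em(q)) z)
            / ((Q_ex(k) ell_ex + 1) (Q_em(q) ell_em + 1))

    Broadcasts over ndarray arguments.  Strictly positive, strictly
    decreasing in z, q and k; log gamma is affine in z with slope
    -(Q_ex(k) + Q_em(q)).
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("depth z must be non-negative")
    ell_ex, ell_em = medium.ex.ell, medium.em.ell
    d_ex, d_em = medium.ex.D, medium.em.D
    q_ex = penetration_factor(k_mag, medium.ex)
    q_em = penetration_factor(q_mag, medium.em)
    pref = (ell_ex * ell_em) / (d_ex * d_em)
    out = pref * np.exp(-(q_ex + q_em) * z_arr) / ((q_ex * ell_ex + 1.0) * (q_em * ell_em + 1.0))
    return float(out) if np.ndim(out) == 0 else out


def slab_kernel(q_mag, z_top, thickness, k_mag, medium: MediumPair):
    """Analytic z-integral of the kernel over a slab [z_top, z_top + thickness].

    Equals gamma(q, z_top; k) * (1 - exp(-S t)) / S with
    S = Q_ex(k) + Q_em(q); supports laterally-uniform-in-depth slab targets.
    thickness = 0 gives 0 (a genuinely thin layer is modelled with
    :func:`kernel_gamma` directly); thickness -> inf gives gamma / S.
    """
    z_arr = np.asarray(z_top, dtype=float)
    t_arr = np.asarray(thickness, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("z_top must be non-negative")
    if np.any(t_arr < 0):
        raise ValueError("thickness must be non-negative")
    s = penetration_factor(k_mag, medium.ex) + penetration_factor(q_mag, medium.em)
    out = kernel_gamma(q_mag, z_top, k_mag, medium) * -np.expm1(-s * t_arr) / s
    return float(out) if np.ndim(out) == 0 else out
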