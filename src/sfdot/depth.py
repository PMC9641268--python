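"""Target-depth estimation from the modulation-frequency decay.

For a thin fluorescent layer at depth ``z`` in a semi-infinite medium, the
normalized emission response at the modulation wavenumber ``k`` decays as a
single exponential in

    x(k) = Q_ex(k) + Q_em(k)        (twice the reciprocal penetration depth)

with

    y(k) = |Phi_hat(k; k)| (Q_ex(k) l_ex + 1) (Q_em(k) l_em + 1)
    y(k) / y(0) = A exp(-z x(k)) + yo.

``Phi_hat(k; k)`` is the demodulated emission spectrum evaluated at the
(measured) modulation wavenumber itself; the boundary factors remove the
kernel's slowly varying denominator so only the ``exp(-z x)`` decay and a
noise floor ``yo`` remain.  Depth is recovered by bounded trust-region
least squares from fixed starting values (A, z, yo) = (5.0, 1.0, 0.1).

Protocol details follow the reference procedure: y is normalized by its
value at the smallest |k| present, and that smallest-|k| point is excluded
from the fit (for thick targets the linear model is poorest at k = 0).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .demodulate import Spectrum, calibrate_frequency, three_phase_demodulate
from .diffusion import MediumPair, penetration_factor
from .phantom import AcquisitionDataset

__all__ = ["ModulationResponse", "DepthFit", "modulation_response", "fit_depth"]

log = logging.getLogger(__name__)

FIT_START = (5.0, 1.0, 0.1)  # (A, z_target, yo)


@dataclass
class ModulationResponse:
    """Paired samples (x(k), y(k)) ready for the exponential depth fit.

    ``y`` is already normalized by ``y0`` (the raw response at the smallest
    retained |k|); ``excluded`` lists indices of the original frequency set
    dropped for non-positive response.
    """

    k: np.ndarray
    x: np.ndarray
    y: np.ndarray
    y0: float
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.k) == len(self.x) == len(self.y)):
            raise ValueError("k, x, y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing with k")
        if np.any(self.y <= 0):
            raise ValueError("retained y values must be positive")


@dataclass
class DepthFit:
    """Result of the exponential depth fit."""

    z_target: float
    A: float
    y_offset: float
    z_std: float
    converged: bool
    residual_norm: float
    n_points: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "z_mm": self.z_target,
                "z_std_mm": self.z_std,
                "A": self.A,
                "y_offset": self.y_offset,
                "n_points": self.n_points,
                "converged": self.converged,
                "residual_norm": self.residual_norm,
            }
        )


def modulation_response(
    dataset: AcquisitionDataset,
    medium: MediumPair | None = None,
    convention: str = "consistent",
    calibrate: bool = True,
    window: np.ndarray | None = None,
) -> ModulationResponse:
    """Build (x(k), y(k)) from an acquisition.

    Per frequency: demodulate the phase triplet, measure the actual
    frequency from the bright-field frame (optional), evaluate the spectrum
    at q = (k_measured, 0) by direct summation, take the magnitude and apply
    the boundary factors; normalize all y by the value at the smallest |k|.
    ``window`` (2D, broadcastable) apodizes each demodulated field before the
    spectral evaluation — used by the multi-target segmentation.

    Non-positive responses are excluded with a warning; at least four
    frequencies are required.
    """
    medium = medium or dataset.medium
    if dataset.n_frequencies < 4:
        raise ValueError("at least 4 frequencies are required")
    ks, xs, ys, excluded = [], [], [], []
    for i, f_nom in enumerate(dataset.frequencies):
        F0, F1, F2 = dataset.triplet(i)
        fld = three_phase_demodulate(F0, F1, F2, convention=convention)
        if window is not None:
            fld = fld * window
        if calibrate:
            f_meas = calibrate_frequency(
                dataset.brightfield[i].astype(float), f_nom, dataset.pixel_pitch
            )
        else:
            f_meas = f_nom
        k = 2.0 * math.pi * f_meas
        q_ex = penetration_factor(k, medium.ex)
        q_em = penetration_factor(k, medium.em)
        y_raw = abs(Spectrum(fld, dataset.pixel_pitch).at(k, 0.0))
        y_val = y_raw * (q_ex * medium.ex.ell + 1.0) * (q_em * medium.em.ell + 1.0)
        if y_val <= 0:
            log.warning("non-positive response at f=%.4g mm^-1; point excluded", f_nom)
            excluded.append(i)
            continue
        ks.append(k)
        xs.append(q_ex + q_em)
        ys.append(y_val)
    if len(ys) < 2:
        raise ValueError("too few usable frequencies for a modulation response")
    i0 = int(np.argmin(np.abs(ks)))
    y0 = ys[i0]
    return ModulationResponse(
        k=np.array(ks), x=np.array(xs), y=np.array(ys) / y0, y0=y0, excluded=excluded
    )


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, z, yo = params
    return a * np.exp(-z * x) + yo


def _jacobian(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, z, _ = params
    e = np.exp(-z * x)
    return np.column_stack([e, -a * x * e, np.ones_like(x)])


def fit_depth(resp: ModulationResponse, drop_smallest_k: bool = True) -> DepthFit:
    """Fit y = A exp(-z x) + yo and return the depth estimate.

    The smallest-|k| point is removed before fitting (default); bounds
    A, z, yo >= 0 prevent sign-flip degeneracy.  The standard error is the
    square root of the z-diagonal of the residual-variance-scaled parameter
    covariance.  Non-convergence or an unidentifiable depth is flagged, not
    raised.
    """
    keep = np.ones(len(resp.x), dtype=bool)
    if drop_smallest_k:
        keep[int(np.argmin(np.abs(resp.k)))] = False
    x, y = resp.x[keep], resp.y[keep]
    if len(x) < 4:
        raise ValueError(f"need at least 4 points after exclusion, got {len(x)}")

    res = least_squares(
        lambda p: _model(p, x) - y,
        x0=np.array(FIT_START),
        jac=lambda p: _jacobian(p, x),
        bounds=(np.zeros(3), np.full(3, np.inf)),
        method="trf",
    )
    a_hat, z_hat, yo_hat = res.x
    dof = max(len(x) - 3, 1)
    s_sq = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s_sq
        z_var = cov[1, 1]
    except np.linalg.LinAlgError:
        z_var = np.inf
    z_std = float(np.sqrt(z_var)) if z_var >= 0 else float("inf")
    converged = bool(res.success) and math.isfinite(z_std)
    if not converged:
        log.warning("depth fit did not converge cleanly (status %s)", res.status)
    return DepthFit(
        z_target=float(z_hat),
        A=float(a_hat),
        y_offset=float(yo_hat),
        z_std=z_std,
        converged=converged,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_points=int(len(x)),
    )
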