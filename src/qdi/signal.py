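"""Quasi-diffusion forward model and its log-log analytic structure.

The normalized decay is ``S(b)/S0 = E_alpha(-(D12*b)**alpha)``, interpolating
a stretched exponential at low b and a ``b**-alpha`` power law at high b.
Logarithms of b are taken relative to b0 = 1 s/mm^2, i.e. b is treated as a
unitless number of s/mm^2.  D12 is always in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, gamma as gamma_fn

from .mlf import mlf

__all__ = [
    "QDIParams",
    "StickParams",
    "qdi_attenuation",
    "qdi_asymptote",
    "log_slope",
    "log_curvature",
    "stick_attenuation",
    "effective_coefficient",
]


@dataclass(frozen=True)
class QDIParams:
    """Quasi-diffusion parameter pair.

    Attributes
    ----------
    d12 : float
        Quasi-diffusion coefficient, mm^2/s (> 0).
    alpha : float
        Fractional exponent, unitless, in (0, 1]; 1 is Gaussian decay.
    """

    d12: float
    alpha: float

    def __post_init__(self):
        if not (np.isfinite(self.d12) and self.d12 > 0.0):
            raise ValueError(f"d12 must be finite and > 0, got {self.d12!r}")
        if not (np.isfinite(self.alpha) and 0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha!r}")


@dataclass(frozen=True)
class StickParams:
    """Axially symmetric impermeable-cylinder (stick) reference model."""

    d_par: float
    d_perp: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.d_par) and np.isfinite(self.d_perp)):
            raise ValueError("stick coefficients must be finite")
        if self.d_perp < 0.0 or self.d_par <= self.d_perp:
            raise ValueError(f"require d_par > d_perp >= 0, got d_par={self.d_par!r}, d_perp={self.d_perp!r}")


def _as_b(b, positive: bool = False) -> tuple[np.ndarray, bool]:
    arr = np.asarray(b, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError("b must be finite")
    if positive:
        if np.any(arr <= 0.0):
            raise ValueError("b must be > 0")
    elif np.any(arr < 0.0):
        raise ValueError("b must be >= 0")
    return arr, scalar


def _z_of(b: np.ndarray, params: QDIParams) -> np.ndarray:
    return -((params.d12 * b) ** params.alpha)


def qdi_attenuation(b, params: QDIParams):
    """Normalized signal ``E_alpha(-(d12*b)**alpha)`` for b >= 0 (s/mm^2)."""
    b_arr, scalar = _as_b(b)
    out = mlf(_z_of(b_arr, params), params.alpha, 1.0)
    out = np.atleast_1d(out)
    return float(out[0]) if scalar else out


def qdi_asymptote(b, params: QDIParams, regime: str = "low_b"):
    """Low-b stretched-exponential or high-b power-law limit of the decay.

    ``low_b``:  exp(-(d12*b)**alpha / Gamma(alpha+1))
    ``high_b``: sin(alpha*pi)/pi * Gamma(alpha) / (d12*b)**alpha
    """
    b_arr, scalar = _as_b(b, positive=True)
    u = (params.d12 * b_arr) ** params.alpha
    if regime == "low_b":
        out = np.exp(-u / gamma_fn(params.alpha + 1.0))
    elif regime == "high_b":
        if params.alpha >= 1.0:
            raise ValueError("high_b asymptote undefined for alpha = 1 (no power-law tail)")
        out = np.sin(params.alpha * np.pi) / np.pi * gamma_fn(params.alpha) / u
    else:
        raise ValueError(f"regime must be 'low_b' or 'high_b', got {regime!r}")
    return float(out[0]) if scalar else out


def log_slope(b, params: QDIParams):
    """d ln S / d ln b = E_{a,0}(z)/E_{a,1}(z) with z = -(d12*b)**alpha.

    Negative for all b > 0 and tends to -alpha as b -> infinity (alpha < 1).
    """
    b_arr, scalar = _as_b(b, positive=True)
    z = _z_of(b_arr, params)
    out = mlf(z, params.alpha, 0.0) / mlf(z, params.alpha, 1.0)
    out = np.atleast_1d(out)
    return float(out[0]) if scalar else out


def _log_curvature_z(z, alpha: float):
    """Second log-log derivative as a function of z = -(d12*b)**alpha."""
    e1 = np.atleast_1d(mlf(z, alpha, 1.0))
    e0 = np.atleast_1d(mlf(z, alpha, 0.0))
    em1 = np.atleast_1d(mlf(z, alpha, -1.0))
    return ((em1 + e0) * e1 - e0**2) / e1**2


def log_curvature(b, params: QDIParams):
    """d^2 ln S / d(ln b)^2; crosses zero (- to +) at the inflection point."""
    b_arr, scalar = _as_b(b, positive=True)
    out = _log_curvature_z(_z_of(b_arr, params), params.alpha)
    return float(out[0]) if scalar else out


def stick_attenuation(b, params: StickParams):
    """Directionally averaged impermeable-cylinder signal.

    ``exp(-d_perp*b) * (sqrt(pi)/2) * erf(sqrt(b*dd)) / sqrt(b*dd)`` with
    ``dd = d_par - d_perp``; continuous limit 1 at b = 0.  High-b log-log
    slope tends to -1/2 when d_perp = 0.
    """
    b_arr, scalar = _as_b(b)
    dd = params.d_par - params.d_perp
    x = np.sqrt(b_arr * dd)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(x > 0.0, np.sqrt(np.pi) / 2.0 * erf(x) / np.where(x > 0.0, x, 1.0), 1.0)
    out = np.exp(-params.d_perp * b_arr) * factor
    return float(out[0]) if scalar else out


def effective_coefficient(params: QDIParams) -> float:
    """Normal effective coefficient ``d12**alpha`` (units mm^(2a)/s^a)."""
    return params.d12**params.alpha
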