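"""Two-parameter Mittag-Leffler function on the negative real axis.

Evaluates ``E_{alpha,gamma}(z) = sum_k z**k / Gamma(alpha*k + gamma)`` for
``z <= 0`` and fractional orders ``0 < alpha <= 1``, which is the regime
required by the quasi-diffusion signal representation (``gamma`` in
``{-1, 0, 1}`` in practice, any real ``gamma`` accepted for ``alpha < 1``).

Three regimes are stitched together, each validated against an
extended-precision series oracle (:func:`mlf_series_oracle`):

* ``|z| <= 1`` -- the defining Taylor series in double precision (no
  cancellation in this range; terms at non-positive-integer gamma arguments
  vanish through the entire reciprocal gamma).
* ``1 < |z| < 1e4`` -- numerical inversion of the Laplace transform
  ``s**(alpha-gamma) / (s**alpha - z)`` on a parabolic Hankel contour
  ``s = mu*(1+iu)**2`` with the trapezoidal rule.  For ``z < 0`` and
  ``alpha < 1`` the poles of the integrand lie off the principal sheet, so
  the contour parameters can be held fixed.
* ``|z| >= 1e4`` -- the algebraic asymptotic expansion
  ``-sum_{k>=1} z**-k / Gamma(gamma - alpha*k)``.

``alpha == 1`` is dispatched to exact exponential closed forms (the contour
representation degenerates: the pole sits on the branch cut).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import rgamma

from .errors import ConvergenceError

__all__ = ["mlf", "mlf_derivative", "mlf_series_oracle"]

# |z| thresholds between the Taylor / contour / asymptotic branches.
_TAYLOR_MAX = 1.0
_ASYM_MIN = 1.0e4

# Parabolic contour parameters: s = _MU*(1+iu)**2, trapezoid step _H,
# truncation at |u| = _UMAX.  Discretization error ~ exp(-2*pi/_H) and
# truncation error ~ exp(_MU*(1-_UMAX**2)); roundoff ~ eps*exp(_MU).
_MU = 7.0
_H = 0.08
_UMAX = 4.0

_ASYM_TERMS = 10


def _validate(z: np.ndarray, alpha: float, gamma: float) -> None:
    if not np.isfinite(alpha) or alpha <= 0.0:
        raise ValueError(f"alpha must be a finite positive real, got {alpha!r}")
    if alpha > 1.0:
        raise ValueError(f"alpha > 1 (superdiffusive orders) is unsupported, got {alpha!r}")
    if not np.isfinite(gamma):
        raise ValueError(f"gamma must be finite, got {gamma!r}")
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    if np.any(z > 0.0):
        raise ValueError("z must satisfy z <= 0")


def _taylor(z: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    # Enough terms that alpha*k + gamma is deep into the Gamma growth regime.
    n = max(60, int(math.ceil(40.0 / alpha)))
    coeffs = rgamma(alpha * np.arange(n) + gamma)
    return np.polynomial.polynomial.polyval(z, coeffs)


def _contour(z: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    n = int(_UMAX / _H)
    u = _H * np.arange(n + 1)
    s = _MU * (1.0 + 1j * u) ** 2
    pref = (_MU / np.pi) * (1.0 + 1j * u) * np.exp(s) * s ** (alpha - gamma)
    g = pref / (s**alpha - z[..., None])
    return _H * (g[..., 0].real + 2.0 * np.sum(g[..., 1:].real, axis=-1))


def _asymptotic(z: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    k = np.arange(1, _ASYM_TERMS + 1, dtype=float)
    coeffs = rgamma(gamma - alpha * k)
    return -np.sum(z[..., None] ** -k * coeffs, axis=-1)


def _exp_closed_form(z: np.ndarray, gamma: float) -> np.ndarray:
    """E_{1,m}(z) for integer m: z**(1-m)*exp(z) for m <= 1, else
    (exp(z) - sum_{j<m-1} z**j/j!) / z**(m-1)."""
    m = int(round(gamma))
    if abs(gamma - m) > 1e-12:
        raise ValueError("alpha == 1 supports integer gamma only; use alpha < 1 or the series oracle")
    if m <= 1:
        return z ** float(1 - m) * np.exp(z)
    out = np.exp(z)
    for j in range(m - 1):
        out = out - z**j / math.factorial(j)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(z != 0.0, out / z ** float(m - 1), rgamma(float(m)))
    return out


def mlf(z, alpha: float, gamma: float = 1.0):
    """Evaluate ``E_{alpha,gamma}(z)`` elementwise for ``z <= 0``.

    Parameters
    ----------
    z : float or array_like
        Argument(s), each ``<= 0``.  Magnitudes up to ~1e10 and beyond are
        supported through the asymptotic branch.
    alpha : float
        Fractional order in ``(0, 1]``.
    gamma : float, optional
        Second parameter (default 1, the one-parameter function).

    Returns
    -------
    float or ndarray
        ``E_{alpha,gamma}(z)``, same shape as ``z``.
    """
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    _validate(z_arr, alpha, gamma)

    out = np.empty_like(z_arr)
    if alpha == 1.0:
        out[:] = _exp_closed_form(z_arr, gamma)
    else:
        az = np.abs(z_arr)
        small = az <= _TAYLOR_MAX
        large = az >= _ASYM_MIN
        mid = ~small & ~large
        if np.any(small):
            out[small] = _taylor(z_arr[small], alpha, gamma)
        if np.any(mid):
            out[mid] = _contour(z_arr[mid], alpha, gamma)
        if np.any(large):
            out[large] = _asymptotic(z_arr[large], alpha, gamma)
        if gamma == 1.0:
            # E_{alpha,1} is completely monotone on z <= 0: clip quadrature
            # noise so downstream logarithms are always defined.
            np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def mlf_derivative(z, alpha: float, gamma: float = 1.0):
    """d/dz ``E_{alpha,gamma}(z)`` for strictly negative ``z``.

    Uses the recurrence
    ``E'_{a,g}(z) = [E_{a,g-1}(z) - (g-1) E_{a,g}(z)] / (a z)``,
    which requires ``z != 0``; the ``z -> 0`` limit is never needed on the
    quasi-diffusion code paths, so ``z == 0`` raises.
    """
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    _validate(z_arr, alpha, gamma)
    if np.any(z_arr == 0.0):
        raise ValueError("mlf_derivative requires z < 0 strictly (recurrence divides by z)")
    num = mlf(z_arr, alpha, gamma - 1.0) - (gamma - 1.0) * mlf(z_arr, alpha, gamma)
    out = num / (alpha * z_arr)
    return float(out[0]) if scalar else out


def mlf_series_oracle(z, alpha: float, gamma: float = 1.0, n_terms: int = 100_000,
                      precision_digits: int | None = None):
    """Extended-precision partial sum of the defining series (test oracle).

    Computed with mpmath; independent of the production branches in
    :func:`mlf`.  Restricted to ``|z| <= 50`` where the alternating series is
    tractable at the requested precision (cancellation grows like
    ``exp(|z|**(1/alpha))``, which sets the automatic default precision).

    Parameters
    ----------
    z : float
        Scalar argument, ``-50 <= z <= 0``.
    n_terms : int
        Maximum number of series terms before a convergence error is raised.
    precision_digits : int, optional
        Working decimal precision (>= 50).  Default scales with the expected
        cancellation.

    Returns
    -------
    float
        The converged partial sum rounded to double precision.
    """
    import mpmath as mp

    zf = float(z)
    if not np.isfinite(zf) or zf > 0.0:
        raise ValueError("oracle requires finite z <= 0")
    if abs(zf) > 50.0:
        raise ValueError("oracle is restricted to |z| <= 50")
    _validate(np.atleast_1d(zf), alpha, gamma)
    if precision_digits is None:
        precision_digits = 60 + int(abs(zf) ** (1.0 / alpha) / 2.0)
    if precision_digits < 50:
        raise ValueError("precision_digits must be >= 50")

    with mp.workdps(precision_digits):
        total = mp.mpf(0)
        zm = mp.mpf(zf)
        am = mp.mpf(alpha)
        gm = mp.mpf(gamma)
        zk = mp.mpf(1)
        tiny = mp.mpf(10) ** (-precision_digits + 10)
        small_run = 0
        runs_needed = int(2.0 / alpha) + 3
        prev_mag = mp.inf
        growing = 0
        for k in range(n_terms):
            a = alpha * k + gamma
            if abs(a - round(a)) < 1e-12 and round(a) <= 0:
                term = mp.mpf(0)  # 1/Gamma at a pole: reciprocal gamma is entire
            else:
                term = zk / mp.gamma(am * k + gm)
            total += term
            zk *= zm
            mag = abs(term)
            growing = growing + 1 if mag > prev_mag else 0
            prev_mag = mag
            if mag < tiny * (1 + abs(total)):
                small_run += 1
                if small_run > runs_needed:
                    return float(total)
            else:
                small_run = 0
        raise ConvergenceError(
            f"series did not converge within {n_terms} terms at z={zf}, alpha={alpha}, gamma={gamma}"
        )
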