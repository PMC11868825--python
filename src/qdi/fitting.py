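"""Voxelwise parameter estimation.

Pipeline: orientationally average each b-shell (the powder average),
normalize by the mean b = 0 signal, then fit (d12, alpha) per voxel by
bounded trust-region least squares on residuals in ln-signal space --
logarithmic residuals give balanced weighting across the several decades of
decay spanned by ultra-high-b protocols.  The inflection-point map is filled
from the analytic IP solver (via the lookup table when possible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionScheme, SHELL_TOLERANCE
from .errors import GeometryError, InsufficientDataError
from .inflection import IP_UNDEFINED, IPTable, default_ip_table, find_ip, lookup_ip
from .errors import IPTableRangeError
from .signal import QDIParams, qdi_attenuation

__all__ = [
    "DecayCurve", "DecayCurveSet", "FitResult", "ParameterMaps", "FitBounds",
    "powder_average", "fit_decay", "fit_volume", "mse_log",
]

_MODEL_FLOOR = 1e-300  # guards ln() against exp-underflow at alpha = 1


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the fit (wide enough for CSF, ex vivo tissue and
    the Gaussian limit)."""

    d12_min: float = 1e-5
    d12_max: float = 1e-2
    alpha_min: float = 0.05
    alpha_max: float = 1.0


@dataclass(frozen=True)
class DecayCurve:
    """Orientationally averaged normalized decay for one voxel."""

    b: np.ndarray
    s_norm: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        s = np.asarray(self.s_norm, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if not (b.shape == s.shape == v.shape) or b.ndim != 1:
            raise ValueError("b, s_norm, valid must be 1-D arrays of equal length")
        if np.any(np.diff(b) < 0.0):
            raise ValueError("b must be ascending")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "s_norm", s)
        object.__setattr__(self, "valid", v)

    def truncated(self, bmax: float) -> "DecayCurve":
        keep = self.b <= bmax
        return DecayCurve(b=self.b[keep], s_norm=self.s_norm[keep], valid=self.valid[keep])


@dataclass(frozen=True)
class DecayCurveSet:
    """Per-voxel decay curves over a volume: shared shell b-values plus
    spatial arrays of normalized signal and validity flags."""

    b: np.ndarray                 # (m,)
    s_norm: np.ndarray            # (..., m)
    valid: np.ndarray             # (..., m)

    def curve(self, index) -> DecayCurve:
        return DecayCurve(b=self.b, s_norm=self.s_norm[index], valid=self.valid[index])


@dataclass(frozen=True)
class FitResult:
    params: QDIParams
    mse_log: float
    ip: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class ParameterMaps:
    """Co-registered 3-D maps; NaN outside the mask / at failed voxels."""

    d12_map: np.ndarray
    alpha_map: np.ndarray
    ip_map: np.ndarray
    mse_map: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in (self.d12_map, self.alpha_map, self.ip_map,
                                    self.mse_map, self.mask)}
        if len(shapes) != 1:
            raise GeometryError(f"map shapes differ: {shapes}")


def powder_average(dwi, scheme: AcquisitionScheme, clamped=None,
                   max_clamped_fraction: float = 1.0,
                   shell_tolerance: float = SHELL_TOLERANCE) -> DecayCurveSet:
    """Orientationally average a 4-D volume into per-voxel decay curves.

    Per voxel and b-shell, the arithmetic mean of the signal over the
    shell's directions; S0 is the mean over all b = 0 volumes and
    ``s_norm = shell mean / S0``.  A shell point is marked invalid (excluded
    from log-space fitting) when its mean or S0 is non-positive, or when the
    fraction of its samples flagged in ``clamped`` (the Rician floor clamp)
    exceeds ``max_clamped_fraction``.  Clamped samples still enter the mean
    as their corrected value of zero -- dropping them would bias the shell
    mean upward.

    Parameters
    ----------
    dwi : ndarray, shape (..., n_volumes)
    scheme : AcquisitionScheme
    clamped : ndarray of bool, same shape as ``dwi``, optional
    max_clamped_fraction : float
        Validity threshold; 1.0 (default) invalidates only fully clamped
        shell points (whose mean is 0 regardless).
    """
    data = np.asarray(dwi, dtype=float)
    if data.shape[-1] != len(scheme):
        raise GeometryError(f"volume count {data.shape[-1]} != scheme length {len(scheme)}")
    shells = scheme.shells(shell_tolerance)
    if shells[0][0] != 0.0:
        raise InsufficientDataError("no b=0 volume: cannot normalize")

    b_centers = np.array([b for b, _ in shells])
    spatial = data.shape[:-1]
    means = np.empty(spatial + (len(shells),))
    clamped_ok = np.ones(spatial + (len(shells),), dtype=bool)
    for k, (_, idx) in enumerate(shells):
        means[..., k] = data[..., idx].mean(axis=-1)
        if clamped is not None:
            frac = np.asarray(clamped, dtype=bool)[..., idx].mean(axis=-1)
            clamped_ok[..., k] = frac <= max_clamped_fraction + 1e-12

    s0 = means[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s_norm = means / s0[..., None]
    valid = clamped_ok & np.isfinite(s_norm) & (s_norm > 0.0) & (s0[..., None] > 0.0)
    s_norm = np.where(valid, s_norm, np.nan)
    return DecayCurveSet(b=b_centers, s_norm=s_norm, valid=valid)


def _log_model(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = qdi_attenuation(b, QDIParams(d12=float(x[0]), alpha=float(x[1])))
    return np.log(np.maximum(np.atleast_1d(s), _MODEL_FLOOR))


def _init_guess(b: np.ndarray, logs: np.ndarray, bounds: FitBounds) -> np.ndarray:
    # d12 from the monoexponential slope of the two lowest non-zero b points
    if b.size >= 2 and b[1] > b[0]:
        d0 = (logs[0] - logs[1]) / (b[1] - b[0])
    else:
        d0 = 1e-3
    d0 = float(np.clip(d0, bounds.d12_min * 1.01, bounds.d12_max * 0.99))
    return np.array([d0, 0.9])


def fit_decay(curve: DecayCurve, bounds: FitBounds | None = None,
              init: QDIParams | None = None, ip_table: IPTable | None = None) -> FitResult:
    """Fit (d12, alpha) to one decay curve in ln-signal space.

    Requires a b = 0 anchor and >= 3 valid non-zero-b points.  Non-converged
    optimizations return ``converged=False`` with the best iterate rather
    than raising.
    """
    bounds = bounds or FitBounds()
    has_b0 = np.any((curve.b == 0.0) & curve.valid)
    sel = curve.valid & (curve.b > 0.0)
    if not has_b0 or sel.sum() < 3:
        raise InsufficientDataError(
            f"need a b=0 anchor plus >= 3 valid non-zero points, got b0={has_b0}, n={int(sel.sum())}")
    b = curve.b[sel]
    logs = np.log(curve.s_norm[sel])

    if init is not None:
        x0 = np.array([init.d12, init.alpha])
    else:
        x0 = _init_guess(b, logs, bounds)
    x0 = np.clip(x0, [bounds.d12_min, bounds.alpha_min], [bounds.d12_max, bounds.alpha_max])

    def residuals(x):
        return _log_model(x, b) - logs

    lo = [bounds.d12_min, bounds.alpha_min]
    hi = [bounds.d12_max, bounds.alpha_max]
    solver_opts = dict(bounds=(lo, hi), method="trf", x_scale=[1e-3, 0.1],
                       ftol=1e-12, xtol=1e-10, gtol=1e-14, max_nfev=1500)
    res = least_squares(residuals, x0, **solver_opts)

    x_best = res.x
    cost_best = 2.0 * res.cost  # scipy cost = 0.5 * sum(r**2)
    converged = bool(res.status > 0)

    # The Gaussian corner alpha = 1 is unreachable by the interior trf path
    # (and just below 1 the model's high-b power-law floor
    # ~ 1/(Gamma(1-alpha)*(d12*b)^alpha) is far above exponential decay), so
    # the monoexponential model is fitted as an explicit closed-form
    # candidate: ln s = -d12*b is linear with minimizer -sum(b*logs)/sum(b^2).
    if bounds.alpha_max >= 1.0:
        d_gauss = float(np.clip(-np.sum(b * logs) / np.sum(b * b),
                                bounds.d12_min, bounds.d12_max))
        x_gauss = np.array([d_gauss, 1.0])
        cost_gauss = float(np.sum(residuals(x_gauss) ** 2))
        if cost_gauss < cost_best:
            x_best, cost_best, converged = x_gauss, cost_gauss, True

    params = QDIParams(d12=float(x_best[0]), alpha=float(x_best[1]))
    mse = float(cost_best / b.size)

    if ip_table is not None:
        try:
            ip = lookup_ip(ip_table, params)
        except IPTableRangeError:
            ip = find_ip(params)
    else:
        ip = find_ip(params)
    return FitResult(params=params, mse_log=mse, ip=ip,
                     converged=converged, n_points=int(sel.sum()))


def mse_log(params: QDIParams, curve: DecayCurve) -> float:
    """Mean squared ln-space error of ``params`` against a curve's valid
    non-zero-b points (supports scoring a truncated-range fit on the full
    range)."""
    sel = curve.valid & (curve.b > 0.0)
    if sel.sum() < 1:
        raise InsufficientDataError("curve has no valid b > 0 point")
    model = np.log(np.maximum(np.atleast_1d(qdi_attenuation(curve.b[sel], params)), _MODEL_FLOOR))
    return float(np.mean((model - np.log(curve.s_norm[sel])) ** 2))


def fit_volume(dwi, scheme: AcquisitionScheme, mask=None, clamped=None,
               max_clamped_fraction: float = 1.0,
               bounds: FitBounds | None = None, ip_table: IPTable | None = None,
               shell_tolerance: float = SHELL_TOLERANCE) -> ParameterMaps:
    """Powder-average and fit every masked voxel of a 4-D volume.

    Deterministic given its inputs (no randomness in fitting).  Voxels whose
    curves are unusable get NaN in all maps; the run continues.
    """
    data = np.asarray(dwi, dtype=float)
    spatial = data.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise GeometryError(f"mask shape {mask.shape} != spatial dims {spatial}")
    if not mask.any():
        raise ValueError("mask is empty")
    if ip_table is None:
        ip_table = default_ip_table()

    curves = powder_average(data, scheme, clamped=clamped,
                            max_clamped_fraction=max_clamped_fraction,
                            shell_tolerance=shell_tolerance)
    nan = np.full(spatial, np.nan)
    maps = ParameterMaps(d12_map=nan.copy(), alpha_map=nan.copy(), ip_map=nan.copy(),
                         mse_map=nan.copy(), mask=mask)
    for index in np.ndindex(spatial):
        if not mask[index]:
            continue
        try:
            result = fit_decay(curves.curve(index), bounds=bounds, ip_table=ip_table)
        except InsufficientDataError:
            continue
        maps.d12_map[index] = result.params.d12
        maps.alpha_map[index] = result.params.alpha
        maps.ip_map[index] = result.ip
        maps.mse_map[index] = result.mse_log
    return maps
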