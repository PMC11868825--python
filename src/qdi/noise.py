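"""Rician noise estimation, floor correction and simulation.

Magnitude MRI has a positive noise floor: in signal-free regions the mean
magnitude is mu_R = sigma*sqrt(pi/2) where sigma is the Gaussian
channel-noise standard deviation.  sigma is estimated from pairwise
differences of the signal across gradient directions inside a signal-free
ROI; a difference of two i.i.d. draws has standard deviation sigma*sqrt(2),
so the pooled difference SD is divided by sqrt(2) by default.  (Whether the
original processing applied that divisor is not documented; pass
``sqrt2_correction=False`` to reproduce the raw pooled SD -- this changes
mu_R by 41%.)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import InsufficientDataError

__all__ = ["NoiseEstimate", "estimate_sigma", "correct_rician", "add_rician_noise"]

_MU_R_FACTOR = np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class NoiseEstimate:
    """Gaussian noise SD and the implied mean Rician floor (signal units)."""

    sigma: float
    mu_r: float

    def __post_init__(self):
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")


def estimate_sigma(roi_signals, sqrt2_correction: bool = True) -> NoiseEstimate:
    """Estimate the Gaussian noise SD from a signal-free ROI.

    Parameters
    ----------
    roi_signals : array_like, shape (n_voxels, n_directions)
        Magnitude signal per ROI voxel and gradient direction (>= 2 of each).
    sqrt2_correction : bool
        Divide the pooled difference SD by sqrt(2) (default True).

    Returns
    -------
    NoiseEstimate
    """
    arr = np.asarray(roi_signals, dtype=float)
    if arr.ndim != 2:
        raise ValueError("roi_signals must be 2-D (voxel x direction)")
    n_vox, n_dir = arr.shape
    if n_dir < 2:
        raise InsufficientDataError(f"need >= 2 directions, got {n_dir}")
    if n_vox < 2:
        raise InsufficientDataError(f"need >= 2 ROI voxels, got {n_vox}")
    diffs = [arr[:, i] - arr[:, j] for i, j in combinations(range(n_dir), 2)]
    sd = float(np.std(np.concatenate(diffs), ddof=1))
    sigma = sd / np.sqrt(2.0) if sqrt2_correction else sd
    return NoiseEstimate(sigma=sigma, mu_r=sigma * _MU_R_FACTOR)


def correct_rician(S, mu_r: float):
    """Remove the Rician floor: ``sqrt(max(S**2 - mu_r**2, 0))`` elementwise.

    Returns
    -------
    corrected : ndarray
        Floor-corrected signal (same shape as ``S``).
    clamped : ndarray of bool
        True where ``S < mu_r`` forced a clamp to zero; these points should
        be excluded from log-space fitting.
    """
    if mu_r < 0.0:
        raise ValueError("mu_r must be >= 0")
    arr = np.asarray(S, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("magnitude signal must be >= 0")
    clamped = arr < mu_r
    corrected = np.sqrt(np.maximum(arr**2 - mu_r**2, 0.0))
    return corrected, clamped


def add_rician_noise(signal, sigma: float, seed=None):
    """Simulate magnitude (Rician) noise: ``sqrt((S+g1)**2 + g2**2)``.

    ``g1``, ``g2`` are independent zero-mean Gaussians with SD ``sigma``
    drawn from ``numpy.random.default_rng(seed)`` (a Generator is accepted);
    identical seeds give identical output.
    """
    if sigma < 0.0:
        raise ValueError("sigma must be >= 0")
    arr = np.asarray(signal, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("signal must be >= 0")
    if sigma == 0.0:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, size=arr.shape)
    g2 = rng.normal(0.0, sigma, size=arr.shape)
    return np.sqrt((arr + g1) ** 2 + g2**2)
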