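"""Synthetic multi-shell phantoms with known (d12, alpha) ground truth.

Scheme presets mirror three published ultra-high-b protocols (b-value lists
and per-shell direction counts as printed; the actual gradient tables are
not public, so directions are synthesized by seeded electrostatic repulsion
on the sphere).  Phantoms are isotropic -- identical decay in every
direction -- since fitting operates on orientational averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionScheme
from .fitting import ParameterMaps
from .inflection import find_ip
from .noise import add_rician_noise
from .signal import QDIParams, qdi_attenuation

__all__ = ["PhantomSpec", "PhantomRegion", "make_scheme", "make_phantom",
           "default_phantom_spec", "sphere_points"]

_PRESETS = {"dataset1", "dataset1_short", "dataset2", "dataset3"}

# dataset1: 6 x b=0 plus 11 shells with the published direction counts
_DS1_B = [400, 800, 1200, 2000, 3000, 4000, 6000, 8000, 10000, 12000, 15000]
_DS1_NDIR = [16, 16, 21, 31, 21, 21, 31, 31, 31, 31, 46]
# dataset2: 50 x b=0; 32 directions below b=2400, 64 at/above
_DS2_B = [200, 950, 2300, 4250, 6750, 9850, 13500, 17800]
# dataset3: single direction per b
_DS3_B = [1000, 2000, 3000, 6000, 9000, 12000, 15000, 18000, 21000, 25000]


def sphere_points(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """n approximately uniform unit vectors via electrostatic repulsion.

    Antipodally symmetric energy (gradient directions are sign-invariant);
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    if n == 1:
        return pts
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            force += np.sum(diff / (dist2[..., None] ** 1.5 + 1e-12), axis=1)
        pts = pts + step * force / n
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_scheme(preset: str, seed: int = 0) -> AcquisitionScheme:
    """Build one of the acquisition-scheme presets.

    ``dataset1``: b = 0 (x6), 400...15000 s/mm^2 (11 shells, published
    direction counts); ``dataset1_short``: the 4-b-value subset
    {0, 1200, 4000, 15000}; ``dataset2``: b = 0 (x50), 200...17800;
    ``dataset3``: b = 0, 1000...25000, one direction per b.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")

    if preset in ("dataset1", "dataset1_short"):
        if preset == "dataset1_short":
            keep = {0, 1200, 4000, 15000}
            shells = [(b, n) for b, n in zip(_DS1_B, _DS1_NDIR) if b in keep]
            n_b0 = 1
        else:
            shells = list(zip(_DS1_B, _DS1_NDIR))
            n_b0 = 6
        bvals = [0.0] * n_b0
        bvecs = [np.zeros(3)] * n_b0
        for i, (b, ndir) in enumerate(shells):
            dirs = sphere_points(ndir, seed=seed + 11 * i + 1)
            bvals.extend([float(b)] * ndir)
            bvecs.extend(dirs)
        return AcquisitionScheme(bvals=np.array(bvals), bvecs=np.array(bvecs),
                                 delta_small=12.0, delta_big=23.0)
    if preset == "dataset2":
        bvals = [0.0] * 50
        bvecs = [np.zeros(3)] * 50
        for i, b in enumerate(_DS2_B):
            ndir = 32 if b < 2400 else 64
            dirs = sphere_points(ndir, seed=seed + 11 * i + 1)
            bvals.extend([float(b)] * ndir)
            bvecs.extend(dirs)
        return AcquisitionScheme(bvals=np.array(bvals), bvecs=np.array(bvecs),
                                 delta_small=8.0, delta_big=49.0)
    # dataset3
    bvals = [0.0] + [float(b) for b in _DS3_B]
    bvecs = [np.zeros(3)] + [np.array([0.0, 1.0, 0.0])] * len(_DS3_B)
    return AcquisitionScheme(bvals=np.array(bvals), bvecs=np.array(bvecs),
                             delta_small=3.5, delta_big=17.5)


@dataclass(frozen=True)
class PhantomRegion:
    label: str
    voxels: np.ndarray  # boolean mask over the phantom shape
    d12: float
    alpha: float


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant ground-truth phantom description.

    ``snr_b0`` is the b = 0 SNR defining the Rician sigma (= s0/snr_b0);
    ``numpy.inf`` means noiseless.
    """

    shape: tuple
    regions: tuple
    snr_b0: float = 50.0
    seed: int = 0
    s0: float = 1000.0

    def __post_init__(self):
        occupied = np.zeros(self.shape, dtype=int)
        for r in self.regions:
            if r.voxels.shape != tuple(self.shape):
                raise ValueError(f"region {r.label!r} mask shape {r.voxels.shape} != {self.shape}")
            QDIParams(d12=r.d12, alpha=r.alpha)  # validates truth values
            occupied += r.voxels.astype(int)
        if np.any(occupied > 1):
            raise ValueError("regions must be disjoint")
        if not (self.snr_b0 > 0.0):
            raise ValueError("snr_b0 must be > 0 (use numpy.inf for noiseless)")


def default_phantom_spec(shape=(9, 9, 3), snr_b0: float = 50.0, seed: int = 0,
                         s0: float = 1000.0) -> PhantomSpec:
    """Three-slab phantom with GM-, WM- and CSF-like truth values
    (defaults near reported in vivo tissue medians)."""
    nx = shape[0]
    third = nx // 3
    gm = np.zeros(shape, dtype=bool); gm[:third] = True
    wm = np.zeros(shape, dtype=bool); wm[third:2 * third] = True
    csf = np.zeros(shape, dtype=bool); csf[2 * third:] = True
    regions = (
        PhantomRegion("gm", gm, d12=0.8e-3, alpha=0.88),
        PhantomRegion("wm", wm, d12=0.7e-3, alpha=0.75),
        PhantomRegion("csf", csf, d12=3.0e-3, alpha=1.0),
    )
    return PhantomSpec(shape=tuple(shape), regions=regions, snr_b0=snr_b0, seed=seed, s0=s0)


def make_phantom(spec: PhantomSpec, scheme: AcquisitionScheme):
    """Synthesize a 4-D dataset plus ground-truth maps.

    Per voxel the signal is ``s0 * qdi_attenuation(b; truth)`` in every
    direction (isotropic), with Rician noise at ``sigma = s0/snr_b0``.
    Fully reproducible from ``spec.seed``.

    Returns
    -------
    data : ndarray, shape ``spec.shape + (len(scheme),)``
    truth : ParameterMaps
        Ground-truth d12/alpha/analytic-IP maps (mse map is all zero inside
        the phantom); mask covers the union of regions.
    sigma : float
        The Gaussian noise SD that was applied (0 for noiseless).
    """
    shape = tuple(spec.shape)
    nvol = len(scheme)
    data = np.zeros(shape + (nvol,))
    nan = np.full(shape, np.nan)
    d12_map, alpha_map, ip_map = nan.copy(), nan.copy(), nan.copy()
    mask = np.zeros(shape, dtype=bool)

    for region in spec.regions:
        params = QDIParams(d12=region.d12, alpha=region.alpha)
        profile = spec.s0 * np.atleast_1d(qdi_attenuation(scheme.bvals, params))
        data[region.voxels] = profile
        d12_map[region.voxels] = region.d12
        alpha_map[region.voxels] = region.alpha
        ip_map[region.voxels] = find_ip(params)
        mask |= region.voxels

    sigma = 0.0 if np.isinf(spec.snr_b0) else spec.s0 / spec.snr_b0
    if sigma > 0.0:
        data = add_rician_noise(data, sigma, seed=spec.seed)
    mse_map = np.where(mask, 0.0, np.nan)
    truth = ParameterMaps(d12_map=d12_map, alpha_map=alpha_map, ip_map=ip_map,
                          mse_map=mse_map, mask=mask)
    return data, truth, sigma
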