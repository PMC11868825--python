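"""Protocol-evaluation experiments: bmax truncation sweeps, short- vs
full-protocol agreement (bias, uncertainty, ICC) and ROI summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .fitting import DecayCurve, FitBounds, FitResult, ParameterMaps, fit_decay, mse_log

__all__ = ["ProtocolComparison", "bmax_sweep", "compare_protocols", "icc", "roi_stats"]


@dataclass(frozen=True)
class ProtocolComparison:
    """Voxelwise agreement of one parameter between two protocols.

    bias = mean(subset - full); uncertainty = SD of the difference;
    icc = two-way random-effects absolute-agreement single-measurement ICC;
    pearson is reported alongside for transparency.
    """

    bias: float
    uncertainty: float
    icc: float
    pearson: float
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.uncertainty < 0.0:
            raise ValueError("uncertainty must be >= 0")


def bmax_sweep(curves, bmax_list, bounds: FitBounds | None = None,
               ip_table=None) -> dict[float, list[FitResult]]:
    """Fit curves truncated at each bmax; score mse on the full range.

    Parameters
    ----------
    curves : DecayCurve or iterable of DecayCurve
    bmax_list : ascending b-values (s/mm^2)

    Returns
    -------
    dict mapping bmax -> list of FitResult, where each result's ``mse_log``
    is the full-range score of the truncated-range fit.  bmax values that
    leave fewer than 3 valid non-zero points are skipped with a warning.
    """
    if isinstance(curves, DecayCurve):
        curves = [curves]
    curves = list(curves)
    out: dict[float, list[FitResult]] = {}
    for bmax in bmax_list:
        usable = [c for c in curves
                  if (c.valid & (c.b > 0.0) & (c.b <= bmax)).sum() >= 3]
        if not usable:
            warnings.warn(f"bmax={bmax:g} leaves < 3 valid non-zero points; skipped", stacklevel=2)
            continue
        results = []
        for c in usable:
            r = fit_decay(c.truncated(bmax), bounds=bounds, ip_table=ip_table)
            results.append(FitResult(params=r.params, mse_log=mse_log(r.params, c),
                                     ip=r.ip, converged=r.converged, n_points=r.n_points))
        out[float(bmax)] = results
    return out


def icc(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed longhand from the two-column ANOVA decomposition of the paired
    table (n subjects x 2 raters); bounded above by 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = xa.size
    if n < 2:
        raise ValueError("need >= 2 pairs")
    table = np.stack([xa, ya], axis=1)
    k = 2
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((table - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0.0:
        return 0.0
    return float((msr - mse) / denom)


def _pairwise(a: np.ndarray, b: np.ndarray, mask: np.ndarray):
    sel = mask & np.isfinite(a) & np.isfinite(b)
    return a[sel], b[sel]


def compare_protocols(maps_full: ParameterMaps, maps_subset: ParameterMaps,
                      mask=None) -> dict[str, ProtocolComparison]:
    """Bias/uncertainty/ICC of subset-protocol maps against full-protocol
    maps, per parameter (``d12``, ``alpha``, ``ip``).

    Voxels with a NaN sentinel in either map of a given parameter are
    excluded pairwise (so IP-undefined voxels do not void the d12/alpha
    comparisons).
    """
    pairs = {
        "d12": (maps_full.d12_map, maps_subset.d12_map),
        "alpha": (maps_full.alpha_map, maps_subset.alpha_map),
        "ip": (maps_full.ip_map, maps_subset.ip_map),
    }
    shapes = {a.shape for pair in pairs.values() for a in pair}
    if len(shapes) != 1:
        raise GeometryError(f"map geometries differ: {shapes}")
    if mask is None:
        mask = maps_full.mask & maps_subset.mask
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != maps_full.d12_map.shape:
            raise GeometryError("mask shape mismatch")
    if not mask.any():
        raise ValueError("mask is empty")

    out = {}
    for name, (full, subset) in pairs.items():
        f, s = _pairwise(full, subset, mask)
        if f.size < 2:
            continue
        diff = s - f
        out[name] = ProtocolComparison(
            bias=float(diff.mean()),
            uncertainty=float(diff.std(ddof=1)),
            icc=icc(f, s),
            pearson=float(np.corrcoef(f, s)[0, 1]) if f.std() > 0 and s.std() > 0 else float("nan"),
            n_voxels=int(f.size),
        )
    return out


def roi_stats(map_3d, roi) -> dict[str, float]:
    """Median and quartiles of defined (non-NaN) voxels inside an ROI.

    Quartiles use linear interpolation between order statistics.  Returns
    ``median``, ``q25``, ``q75``, ``n``, ``n_excluded``.
    """
    arr = np.asarray(map_3d, dtype=float)
    roi_arr = np.asarray(roi, dtype=bool)
    if roi_arr.shape != arr.shape:
        raise GeometryError(f"roi shape {roi_arr.shape} != map shape {arr.shape}")
    if not roi_arr.any():
        raise ValueError("empty ROI")
    values = arr[roi_arr]
    defined = values[np.isfinite(values)]
    if defined.size == 0:
        raise ValueError("ROI contains no defined voxels")
    q25, med, q75 = np.percentile(defined, [25.0, 50.0, 75.0], method="linear")
    return {"median": float(med), "q25": float(q25), "q75": float(q75),
            "n": int(defined.size), "n_excluded": int(values.size - defined.size)}
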