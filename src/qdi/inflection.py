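"""Signal inflection-point (IP) location and lookup tables.

The IP is the b-value where the second derivative of ln S with respect to
ln b crosses zero, i.e. where

    E_{a,-1}(z)*E_{a,1}(z) + E_{a,0}(z)*E_{a,1}(z) - E_{a,0}(z)**2 = 0

with z = -(d12*b)**alpha.  Because the model depends on b and d12 only
through their product u = d12*b, the root is located once in u for each
alpha (a sign-change scan in ln u refined by a bracketed root solve) and
rescaled -- mathematically identical to scanning ln b for each (d12, alpha)
pair, and it makes d12 * IP(d12, alpha) exactly constant in d12.

The public contract keeps the scan-window semantics: a result is defined
only when 0 < ln(IP) < 50; otherwise the undefined sentinel (NaN) is
returned.  alpha within 1e-6 of 1 (Gaussian decay: curvature < 0
everywhere) is likewise undefined.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import IPTableRangeError
from .signal import QDIParams, _log_curvature_z
from . import __about__

__all__ = ["IP_UNDEFINED", "IPTable", "find_ip", "build_ip_table", "lookup_ip",
           "save_ip_table", "load_ip_table", "default_ip_table"]

#: Sentinel for "no inflection point in the scan window" (serialized as NaN).
IP_UNDEFINED = float("nan")

_ALPHA_GAUSSIAN = 1.0 - 1e-6

# ln u window for the internal scale-invariant solve; covers ln b in (0, 50)
# for every d12 in (4e-18, 2e4) mm^2/s.
_V_LO, _V_HI = -40.0, 60.0
_V_COARSE = 0.01

_root_cache: dict[float, float] = {}


def _curvature_v(v, alpha: float):
    """Curvature as a function of v = ln(d12*b)."""
    z = -np.exp(alpha * np.asarray(v, dtype=float))
    return _log_curvature_z(z, alpha)


def _root_u(alpha: float) -> float:
    """u = d12*b at the curvature zero crossing for this alpha (NaN if none
    in the search window)."""
    if alpha in _root_cache:
        return _root_cache[alpha]
    v = np.arange(_V_LO, _V_HI, _V_COARSE)
    g = _curvature_v(v, alpha)
    sign_change = np.nonzero((g[:-1] < 0.0) & (g[1:] >= 0.0))[0]
    if sign_change.size == 0:
        u = float("nan")
    else:
        i = sign_change[0]
        u = np.exp(brentq(lambda w: float(_curvature_v(w, alpha)[0]),
                          v[i], v[i + 1], xtol=1e-12, rtol=8.9e-16))
    _root_cache[alpha] = u
    return u


def find_ip(params: QDIParams) -> float:
    """b-value of the signal inflection point, or NaN when undefined.

    Defined results satisfy ``log_curvature(ip, params) == 0`` to ~1e-9 and
    lie inside the scan window ``0 < ln(ip) < 50``.
    """
    if params.alpha >= _ALPHA_GAUSSIAN:
        return IP_UNDEFINED
    u = _root_u(params.alpha)
    if not np.isfinite(u):
        return IP_UNDEFINED
    b = u / params.d12
    lnb = np.log(b)
    if not (0.0 < lnb < 50.0):
        return IP_UNDEFINED
    return float(b)


@dataclass(frozen=True)
class IPTable:
    """Precomputed IP b-values over a (d12, alpha) grid.

    ``ip_values[i, j]`` is the IP for ``d12_grid[i]``, ``alpha_grid[j]``;
    NaN marks the undefined sentinel.
    """

    d12_grid: np.ndarray
    alpha_grid: np.ndarray
    ip_values: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.d12_grid, dtype=float)
        a = np.asarray(self.alpha_grid, dtype=float)
        v = np.asarray(self.ip_values, dtype=float)
        if d.ndim != 1 or a.ndim != 1 or d.size == 0 or a.size == 0:
            raise ValueError("grids must be non-empty 1-D arrays")
        if np.any(np.diff(d) <= 0.0) or np.any(np.diff(a) <= 0.0):
            raise ValueError("grids must be strictly ascending")
        if v.shape != (d.size, a.size):
            raise ValueError(f"ip_values shape {v.shape} != {(d.size, a.size)}")
        defined = v[np.isfinite(v)]
        if np.any(defined <= 0.0):
            raise ValueError("defined IP entries must be > 0")
        object.__setattr__(self, "d12_grid", d)
        object.__setattr__(self, "alpha_grid", a)
        object.__setattr__(self, "ip_values", v)


def build_ip_table(d12_range=(1e-5, 3e-3), alpha_range=(0.30, 0.995),
                   d12_step: float | None = None, alpha_step: float | None = None,
                   n_d12: int = 60, n_alpha: int = 140) -> IPTable:
    """Tabulate :func:`find_ip` over a (d12, alpha) grid.

    If explicit steps are given the grids are linear; otherwise d12 nodes are
    log-spaced (``n_d12`` of them) and alpha nodes linear (``n_alpha``),
    matching the default table used for map generation.
    """
    d_lo, d_hi = map(float, d12_range)
    a_lo, a_hi = map(float, alpha_range)
    if not (0.0 < d_lo < d_hi) or not (0.0 < a_lo < a_hi < 1.0 + 1e-12):
        raise ValueError("ranges must satisfy 0 < lo < hi (alpha hi < 1)")
    if d12_step is not None:
        d_grid = np.arange(d_lo, d_hi + 0.5 * d12_step, d12_step)
    else:
        d_grid = np.geomspace(d_lo, d_hi, n_d12)
    if alpha_step is not None:
        a_grid = np.arange(a_lo, a_hi + 0.5 * alpha_step, alpha_step)
    else:
        a_grid = np.linspace(a_lo, a_hi, n_alpha)
    if d_grid.size == 0 or a_grid.size == 0:
        raise ValueError("empty grid")

    ip = np.empty((d_grid.size, a_grid.size))
    for j, a in enumerate(a_grid):
        if a >= _ALPHA_GAUSSIAN:
            ip[:, j] = IP_UNDEFINED
            continue
        for i, d in enumerate(d_grid):
            ip[i, j] = find_ip(QDIParams(d12=float(d), alpha=float(a)))
    return IPTable(d12_grid=d_grid, alpha_grid=a_grid, ip_values=ip)


_default_table: IPTable | None = None


def default_ip_table() -> IPTable:
    """The package-default table (built once per process, then cached)."""
    global _default_table
    if _default_table is None:
        _default_table = build_ip_table()
    return _default_table


def lookup_ip(table: IPTable, params: QDIParams) -> float:
    """Bilinear interpolation of ln(IP) over (ln d12, alpha).

    Raises :class:`IPTableRangeError` outside the grid; propagates the NaN
    sentinel if any surrounding node is undefined.
    """
    d, a = params.d12, params.alpha
    dg, ag = table.d12_grid, table.alpha_grid
    if not (dg[0] <= d <= dg[-1]) or not (ag[0] <= a <= ag[-1]):
        raise IPTableRangeError(
            f"(d12={d:g}, alpha={a:g}) outside table range "
            f"[{dg[0]:g}, {dg[-1]:g}] x [{ag[0]:g}, {ag[-1]:g}]")
    i = min(int(np.searchsorted(dg, d, side="right") - 1), dg.size - 2)
    j = min(int(np.searchsorted(ag, a, side="right") - 1), ag.size - 2)
    corners = table.ip_values[i:i + 2, j:j + 2]
    if not np.all(np.isfinite(corners)):
        return IP_UNDEFINED
    td = (np.log(d) - np.log(dg[i])) / (np.log(dg[i + 1]) - np.log(dg[i]))
    ta = (a - ag[j]) / (ag[j + 1] - ag[j])
    ln_ip = np.log(corners)
    top = ln_ip[0, 0] * (1 - ta) + ln_ip[0, 1] * ta
    bot = ln_ip[1, 0] * (1 - ta) + ln_ip[1, 1] * ta
    return float(np.exp(top * (1 - td) + bot * td))


def save_ip_table(table: IPTable, path) -> None:
    """Write the table as plain text: a metadata header plus a TSV matrix."""
    with open(path, "w") as fh:
        fh.write("# qdi IP lookup table\n")
        fh.write(f"# version: {__about__.__version__}\n")
        fh.write("# units: d12 mm^2/s, alpha unitless, ip s/mm^2\n")
        fh.write("# sentinel: nan (no inflection point in scan window)\n")
        fh.write("# rows: d12 grid; columns: alpha grid\n")
        fh.write("d12_grid\t" + "\t".join(f"{v:.17g}" for v in table.d12_grid) + "\n")
        fh.write("alpha_grid\t" + "\t".join(f"{v:.17g}" for v in table.alpha_grid) + "\n")
        for row in table.ip_values:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_ip_table(path) -> IPTable:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = dict()
    for key in ("d12_grid", "alpha_grid"):
        ln = lines.pop(0).rstrip("\n").split("\t")
        if ln[0] != key:
            raise ValueError(f"malformed IP table: expected {key!r} line, got {ln[0]!r}")
        header[key] = np.array([float(v) for v in ln[1:]])
    values = np.loadtxt(io.StringIO("".join(lines)))
    values = np.atleast_2d(values)
    return IPTable(d12_grid=header["d12_grid"], alpha_grid=header["alpha_grid"], ip_values=values)
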