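"""Bimodality diagnostics: Hartigan-style dip statistic and KDE mode counting.

The dip statistic of a sample is the smallest uniform (sup-norm) distance
between its empirical CDF and any unimodal CDF.  Here the unimodal class is
the atomless one: continuous nondecreasing functions that are convex up to a
mode and concave after it (a piecewise-linear representative always attains
the optimum).  The statistic is computed by bisecting on the band half-width
d and checking, in one forward and one backward sweep, whether a
convex-then-concave function can thread the ECDF band

    G(x_j) in [ C_j/n - d,  C_{j-1}/n + d ]

(C_j the cumulative count at the j-th distinct order statistic).  Each sweep
propagates, node by node, the convex piecewise-linear function
psi_j(value) = minimal arrival slope of a convex nondecreasing in-band
function reaching that value, which is exactly representable by its
breakpoints; unimodal feasibility holds iff at some node the forward
(convex-side) and backward (concave-side) feasible value intervals overlap.

Because the class is atomless the statistic can exceed the classical dip by
at most the effect of an atom at the mode (O(1/n) for continuous data); the
test calibrates p-values by Monte Carlo against the *same* statistic under
the uniform null, so the test is exact regardless.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "dip_statistic",
    "dip_test",
    "kde_mode_locations",
    "generate_dip_null",
]


def _dedupe(x):
    """Distinct sorted values with cumulative counts."""
    x = np.sort(np.asarray(x, dtype=float))
    vals, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    return vals, cum, x.size


def _lower_hull(c, s):
    """Lower convex hull of points (c, s) as a function of c (c sorted)."""
    hc: list[float] = []
    hs: list[float] = []
    for ci, si in zip(c, s):
        if hc and ci == hc[-1]:
            if si < hs[-1]:
                hc.pop(), hs.pop()
            else:
                continue
        while len(hc) >= 2:
            # drop middle point if it lies above the chord
            c1, s1 = hc[-2], hs[-2]
            c2, s2 = hc[-1], hs[-1]
            if (s2 - s1) * (ci - c1) >= (si - s1) * (c2 - c1):
                hc.pop(), hs.pop()
            else:
                break
        hc.append(ci)
        hs.append(si)
    return np.array(hc), np.array(hs)


def _insert_zero_crossings(c, s):
    """Add breakpoints where the PL function crosses zero, then clip at 0."""
    sign = s > 0
    if np.all(sign) or np.all(~sign):
        return c, np.maximum(s, 0.0)
    cs_out = [c[0]]
    ss_out = [max(s[0], 0.0)]
    for i in range(1, len(c)):
        if (s[i - 1] > 0) != (s[i] > 0) and s[i - 1] != s[i]:
            t = s[i - 1] / (s[i - 1] - s[i])
            cz = c[i - 1] + t * (c[i] - c[i - 1])
            if cs_out[-1] < cz < c[i]:
                cs_out.append(cz)
                ss_out.append(0.0)
        cs_out.append(c[i])
        ss_out.append(max(s[i], 0.0))
    return np.array(cs_out), np.array(ss_out)


def _eval_pl(c, s, q):
    return float(np.interp(q, c, s))


def _forward_domains(x, lo_band, hi_band):
    """Feasible end-value intervals of convex nondecreasing in-band functions
    on each prefix.  Returns a list of (lo, hi) or None once infeasible."""
    n = len(x)
    domains: list[tuple[float, float] | None] = [None] * n
    lo0, hi0 = lo_band[0], hi_band[0]
    if lo0 > hi0:
        return domains
    c = np.array([lo0, hi0])
    s = np.array([0.0, 0.0])
    domains[0] = (lo0, hi0)
    for j in range(1, n):
        h = x[j] - x[j - 1]
        c, s = _insert_zero_crossings(c, s)
        pc = c + h * s
        ps = s
        target_hi = hi_band[j]
        if pc[-1] < target_hi:
            pc = np.append(pc, target_hi)
            ps = np.append(ps, ps[-1] + (target_hi - pc[-2]) / h)
        order = np.argsort(pc, kind="stable")
        pc, ps = _lower_hull(pc[order], ps[order])
        new_lo = max(lo_band[j], pc[0])
        new_hi = min(hi_band[j], pc[-1])
        if new_lo > new_hi:
            return domains
        s_lo = _eval_pl(pc, ps, new_lo)
        s_hi = _eval_pl(pc, ps, new_hi)
        keep = (pc > new_lo) & (pc < new_hi)
        c = np.concatenate([[new_lo], pc[keep], [new_hi]])
        s = np.concatenate([[s_lo], ps[keep], [s_hi]])
        domains[j] = (new_lo, new_hi)
    return domains


def _unimodal_band_feasible(x, cum_frac_lo, cum_frac_hi, d):
    """Can a convex-then-concave nondecreasing function thread the band?"""
    lo = cum_frac_lo - d
    hi = cum_frac_hi + d
    if np.any(lo > hi):
        return False
    fwd = _forward_domains(x, lo, hi)
    # concave side: mirror.  g concave nondecr on x  <=>  -g(-x) convex nondecr
    bwd = _forward_domains(-x[::-1], -hi[::-1], -lo[::-1])
    n = len(x)
    for j in range(n):
        f = fwd[j]
        b = bwd[n - 1 - j]
        if f is None or b is None:
            continue
        b_lo, b_hi = -b[1], -b[0]
        if max(f[0], b_lo) <= min(f[1], b_hi) + 1e-15:
            return True
    return False


def dip_statistic(x, tol: float = 1e-5) -> float:
    """Dip statistic: sup-distance from the ECDF to the nearest unimodal CDF.

    At least 1/(2n) for any sample; small for unimodal data; large when the
    ECDF has two well-separated rises.  Ties are handled through cumulative
    counts at distinct values.
    """
    vals, cum, n = _dedupe(x)
    if n < 4 or len(vals) < 2:
        return 0.0
    frac_lo = cum / n            # G(x_j) >= C_j/n - d
    frac_hi = (cum - np.diff(np.concatenate([[0], cum]))) / n  # C_{j-1}/n + d
    lo_d, hi_d = 0.5 / n, 0.5
    if _unimodal_band_feasible(vals, frac_lo, frac_hi, lo_d):
        return lo_d
    while hi_d - lo_d > tol:
        mid = 0.5 * (lo_d + hi_d)
        if _unimodal_band_feasible(vals, frac_lo, frac_hi, mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


def generate_dip_null(n: int, n_draws: int, seed: int = 0) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the dip for uniform samples."""
    rng = np.random.default_rng(seed)
    out = np.array([dip_statistic(rng.random(n)) for _ in range(n_draws)])
    out.sort()
    return out


_NULL_TABLE_SIZES = (200, 500, 1000)


def _frozen_null(n: int) -> np.ndarray | None:
    try:
        from . import _dip_null
    except ImportError:  # table not generated
        return None
    table = getattr(_dip_null, f"DIP_NULL_N{n}", None)
    return None if table is None else np.asarray(table)


def dip_test(x, n_boot: int | None = None,
             rng: np.random.Generator | None = None,
             n_max: int = 500):
    """Dip statistic with a Monte-Carlo p-value for the unimodal null.

    Samples larger than ``n_max`` are subsampled (reproducibly via ``rng``);
    for subsample sizes with a frozen uniform-null table (n = 200, 500) the
    table is used, otherwise the null is simulated live.  Pass ``n_boot`` to
    force a live Monte-Carlo calibration.  Returns (dip, p_value); small p
    rejects unimodality.
    """
    x = np.asarray(x, dtype=float).ravel()
    if rng is None:
        rng = np.random.default_rng(0)
    if x.size > n_max:
        x = rng.choice(x, size=n_max, replace=False)
    dip = dip_statistic(x)
    null = None
    if n_boot is None and x.size in _NULL_TABLE_SIZES:
        null = _frozen_null(x.size)
    if null is None:
        draws = n_boot if n_boot is not None else 199
        null = generate_dip_null(x.size, draws, seed=int(rng.integers(2**31)))
    p = (1.0 + np.sum(null >= dip - 1e-12)) / (1.0 + null.size)
    return float(dip), float(p)


def kde_mode_locations(x, grid_size: int = 512, rel_prominence: float = 0.05):
    """Locations of local density maxima (Gaussian KDE, Scott bandwidth),
    ordered by density; secondary modes must rise ``rel_prominence`` of the
    peak density above the intervening valley."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 5 or np.ptp(x) == 0:
        return [float(np.median(x))]
    kde = gaussian_kde(x)
    pad = 0.1 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peak = dens.max()
    cand = [i for i in range(1, grid_size - 1)
            if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    cand.sort(key=lambda i: -dens[i])
    modes: list[int] = []
    for i in cand:
        ok = True
        for j in modes:
            a, b = min(i, j), max(i, j)
            valley = dens[a:b + 1].min()
            if min(dens[i], dens[j]) - valley < rel_prominence * peak:
                ok = False
                break
        if ok:
            modes.append(i)
    return [float(grid[i]) for i in modes]
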