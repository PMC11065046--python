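"""Dynamic-shift statistics of the joint FRET-efficiency / lifetime distribution.

A static (single-state) FRET system obeys E = 1 - tau in the plane spanned by
the intensity efficiency E and the normalized donor lifetime
tau = tau_D(A)/tau_D(0).  Mixing of transfer rates within a burst lifts the
burst's coordinate above that static line (Jensen's inequality: the mean of
1/K exceeds 1/mean(K)), and the *dynamic shift* Delta quantifies the signed
deviation.  Two variants of the signed distance are provided:

* ``printed``:        Delta = (E + tau - 1) / sqrt(E^2 + tau^2)
* ``perpendicular``:  Delta = (E + tau - 1) / sqrt(2)

Both vanish exactly on the static line and are positive above it.  The
moment-difference view compares (E, E_tau (1 - E_tau)) against the parabola
y = x (1 - x), with mixing pushing points below the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .photophysics import PhotophysicsParams

__all__ = [
    "ShiftConfig",
    "ShiftResult",
    "RateMixture",
    "TwoStateSpec",
    "dynamic_shift",
    "shift_distribution",
    "moment_difference_shift",
    "parabola_signed_distance",
    "jensen_bounds",
    "two_state_reference",
    "two_state_arc",
    "kappa_path_statistics",
]

_VARIANTS = ("printed", "perpendicular")


@dataclass(frozen=True)
class ShiftConfig:
    """Choice of the shift denominator; both variants are 0 on E + tau = 1."""

    variant: str = "printed"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")


@dataclass(frozen=True)
class ShiftResult:
    values: np.ndarray
    mean: float
    std: float
    variant: str
    n_bursts: int

    @classmethod
    def from_values(cls, values: np.ndarray, variant: str) -> "ShiftResult":
        values = np.asarray(values, dtype=float)
        return cls(values=values, mean=float(np.mean(values)),
                   std=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
                   variant=variant, n_bursts=int(values.size))


def dynamic_shift(E, tau, config: ShiftConfig = ShiftConfig()):
    """Signed distance of (E, tau) from the static line E + tau = 1.

    Positive above the line.  The printed variant is undefined at the origin.
    """
    E = np.asarray(E, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any((E < 0) | (E > 1)) or np.any((tau < 0) | (tau > 1)):
        raise ValueError("(E, tau) must lie in the unit square")
    num = E + tau - 1.0
    if config.variant == "printed":
        denom_sq = E * E + tau * tau
        if np.any(denom_sq == 0.0):
            raise ValueError("printed shift variant is undefined at (0, 0)")
        out = num / np.sqrt(denom_sq)
    else:
        out = num / math.sqrt(2.0)
    return float(out) if out.ndim == 0 else out


def shift_distribution(bursts, config: ShiftConfig = ShiftConfig()) -> ShiftResult:
    """Per-burst dynamic shifts and their mean / standard deviation.

    ``bursts`` is an :class:`~fretshift.experiment.ExperimentResult` or a
    DataFrame with columns E_intensity and tau_norm (rows with NaN
    coordinates or ``usable == False`` are dropped).
    """
    df = getattr(bursts, "bursts", bursts)
    if "usable" in df:
        df = df[df["usable"]]
    df = df.dropna(subset=["E_intensity", "tau_norm"])
    if len(df) < 2:
        raise ValueError("need at least 2 usable bursts")
    E = np.clip(df["E_intensity"].to_numpy(), 0.0, 1.0)
    tau = np.clip(df["tau_norm"].to_numpy(), 0.0, 1.0)
    values = dynamic_shift(E, tau, config)
    return ShiftResult.from_values(values, config.variant)


# ---------------------------------------------------------------------------
# moment-difference shift


def parabola_signed_distance(x, y, tol: float = 1e-10):
    """Signed orthogonal distance from (x, y) to the curve y = x(1 - x).

    The nearest point is found by bracketed 1-D minimization of the squared
    distance along the curve parameter; the sign is negative below the curve
    (y < x(1 - x)), where dynamic mixing pushes the moment difference.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.empty(np.broadcast(x_arr, y_arr).shape)
    x_b, y_b = np.broadcast_arrays(x_arr, y_arr)
    for i, (xi, yi) in enumerate(zip(x_b.ravel(), y_b.ravel())):
        res = optimize.minimize_scalar(
            lambda t: (t - xi) ** 2 + (t * (1.0 - t) - yi) ** 2,
            bounds=(-1.0, 2.0), method="bounded",
            options={"xatol": tol})
        t = res.x
        dist = math.sqrt(res.fun)
        sign = 1.0 if yi > xi * (1.0 - xi) else (-1.0 if yi < xi * (1.0 - xi) else 0.0)
        out.ravel()[i] = sign * dist
    return float(out[0]) if np.ndim(x) == 0 and np.ndim(y) == 0 else out


def moment_difference_shift(bursts, config: ShiftConfig = ShiftConfig()):
    """Per-burst signed distance of (E_I, E_tau(1 - E_tau)) to y = x(1 - x).

    E_tau = 1 - tau_norm is the lifetime-based efficiency.  For a static
    single state E_I = E_tau and the distance is zero; within-burst mixing
    makes the mean distance negative.
    """
    df = getattr(bursts, "bursts", bursts)
    if "usable" in df:
        df = df[df["usable"]]
    df = df.dropna(subset=["E_intensity", "tau_norm"])
    if len(df) < 1:
        raise ValueError("no usable bursts")
    E_I = np.clip(df["E_intensity"].to_numpy(), 0.0, 1.0)
    E_tau = np.clip(1.0 - df["tau_norm"].to_numpy(), 0.0, 1.0)
    return parabola_signed_distance(E_I, E_tau * (1.0 - E_tau))


# ---------------------------------------------------------------------------
# Jensen bounds for rate mixtures


@dataclass(frozen=True)
class RateMixture:
    """Finite mixture of fluorescence rates K with weights pi."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if rates.shape != weights.shape or rates.ndim != 1 or rates.size == 0:
            raise ValueError("rates and weights must be equal-length 1-D arrays")
        if np.any(rates <= 0):
            raise ValueError("rates must be positive")
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0,
                                                   rel_tol=0, abs_tol=1e-9):
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)


def jensen_bounds(mix: RateMixture):
    """(mean lifetime, lifetime of the mean rate, nonnegative gap).

    mean lifetime   tau_bar = sum pi_i / K_i,
    harmonic value  1 / E[K] = 1 / sum pi_i K_i,
    gap = tau_bar - 1/E[K] >= 0 by convexity of 1/x -- the average lifetime
    of a mixture exceeds the lifetime of the averaged state, which is the
    origin of the dynamic shift.
    """
    tau_bar = float(np.sum(mix.weights / mix.rates))
    harmonic = float(1.0 / np.sum(mix.weights * mix.rates))
    return tau_bar, harmonic, tau_bar - harmonic


# ---------------------------------------------------------------------------
# two-state mixing reference


@dataclass(frozen=True)
class TwoStateSpec:
    """Two FRET states E1 != E2 exchanging at symmetric rate lambda (1/ns)."""

    efficiency_1: float
    efficiency_2: float
    exchange_rate: float

    def __post_init__(self) -> None:
        for e in (self.efficiency_1, self.efficiency_2):
            if not 0.0 < e < 1.0:
                raise ValueError("state efficiencies must lie in (0, 1)")
        if self.efficiency_1 == self.efficiency_2:
            raise ValueError("states must differ")
        if self.exchange_rate < 0:
            raise ValueError("exchange rate must be >= 0")


def two_state_arc(spec: TwoStateSpec, tau):
    """Closed-form mixing arc E(tau) = 1 - tau1 tau2 / (tau1 + tau2 - tau).

    tau_i = 1 - E_i are the normalized state lifetimes.  For any within-burst
    occupancy fraction f of state 1, the burst coordinate
    (E, tau) = (f E1 + (1-f) E2,  (f tau1^2 + (1-f) tau2^2)/(f tau1 + (1-f) tau2))
    lies exactly on this arc: writing u = f tau1 + (1-f) tau2 = 1 - E and
    v = f tau1^2 + (1-f) tau2^2 = tau u, one checks
    u (tau1 + tau2) - v = tau1 tau2 identically, which rearranges to the arc.
    """
    t1 = 1.0 - spec.efficiency_1
    t2 = 1.0 - spec.efficiency_2
    tau = np.asarray(tau, dtype=float)
    return 1.0 - t1 * t2 / (t1 + t2 - tau)


def two_state_reference(spec: TwoStateSpec, *, photophysics: PhotophysicsParams,
                        rng: np.random.Generator, n_bursts: int = 500,
                        photons_per_burst: int = 400,
                        excitation_period: float = 50.0):
    """Simulate bursts of a two-state switching system and return per-burst
    (E_I, tau_norm) together with the closed-form arc.

    Each burst is a telegraph process between the two efficiency states,
    sampled at the pulse times (exact two-state transition probabilities over
    a pulse period); each pulse resolves homogeneously within the occupied
    state.  Returns a dict with 'E', 'tau', 'occupancy' arrays and an 'arc'
    callable.
    """
    kD = photophysics.donor_decay
    k_et = np.array([kD * e / (1.0 - e)
                     for e in (spec.efficiency_1, spec.efficiency_2)])
    lam = spec.exchange_rate
    # symmetric telegraph: P(stay) over dt = (1 + exp(-2 lam dt)) / 2
    p_flip = 0.5 * (1.0 - math.exp(-2.0 * lam * excitation_period))

    state = (rng.random(n_bursts) < 0.5).astype(int)
    I_D = np.zeros(n_bursts, dtype=np.int64)
    I_A = np.zeros(n_bursts, dtype=np.int64)
    dwell_sum = np.zeros(n_bursts)
    occ1 = np.zeros(n_bursts)
    for _ in range(photons_per_burst):
        rate_et = k_et[state]
        k_tot = kD + rate_et
        dwell = rng.exponential(1.0, n_bursts) / k_tot
        acceptor = rng.random(n_bursts) * k_tot < rate_et
        I_A += acceptor
        I_D += ~acceptor
        dwell_sum += np.where(acceptor, 0.0, dwell)
        occ1 += state == 0
        flip = rng.random(n_bursts) < p_flip
        state = np.where(flip, 1 - state, state)

    ok = I_D > 0
    E = I_A[ok] / (I_A[ok] + I_D[ok])
    tau = (dwell_sum[ok] / I_D[ok]) * kD
    return {
        "E": E,
        "tau": tau,
        "occupancy": occ1[ok] / photons_per_burst,
        "arc": lambda t: two_state_arc(spec, t),
    }


# ---------------------------------------------------------------------------
# kappa^2 path statistics


def kappa_path_statistics(times: np.ndarray, kappa_sq: np.ndarray,
                          *, max_lag: float | None = 1.0,
                          n_boot: int = 200,
                          rng: np.random.Generator | None = None) -> dict:
    """Summaries of an ensemble of kappa^2(t) trajectories.

    Returns the distribution of per-path time-mean kappa^2, its grand mean
    and standard error, the principal mode location (kernel density), a
    bimodality diagnostic (Hartigan dip statistic with a Monte-Carlo
    unimodal-null p-value), and the lag-autocorrelation of kappa^2(t)
    averaged over paths.
    """
    from .stats import dip_test, kde_mode_locations

    kappa_sq = np.asarray(kappa_sq, dtype=float)
    if kappa_sq.ndim != 2 or kappa_sq.shape[0] < 100:
        raise ValueError("need >= 100 paths (n_paths, n_times)")
    times = np.asarray(times, dtype=float)

    path_means = np.trapezoid(kappa_sq, times, axis=1) / (times[-1] - times[0])
    dip, p_value = dip_test(path_means, n_boot=n_boot, rng=rng)
    modes = kde_mode_locations(path_means)

    dt = times[1] - times[0]
    if max_lag is None:
        max_lag = times[-1]
    n_lags = min(int(round(max_lag / dt)), kappa_sq.shape[1] - 1)
    # center at the grand (stationary) mean: per-path centering would force
    # spuriously negative long-lag correlations
    centered = kappa_sq - kappa_sq.mean()
    var = np.mean(centered**2)
    acf = np.empty(n_lags + 1)
    for lag in range(n_lags + 1):
        if lag == 0:
            acf[0] = 1.0
        else:
            acf[lag] = np.mean(centered[:, :-lag] * centered[:, lag:]) / var

    return {
        "path_means": path_means,
        "mean": float(path_means.mean()),
        "sem": float(path_means.std(ddof=1) / math.sqrt(path_means.size)),
        "principal_mode": float(modes[0]) if len(modes) else float("nan"),
        "n_kde_modes": len(modes),
        "dip": dip,
        "dip_p_value": p_value,
        "acf_lags": np.arange(n_lags + 1) * dt,
        "acf": acf,
    }
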