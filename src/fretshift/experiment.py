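"""Confocal smFRET burst simulation and per-burst FRET coordinates.

A burst is one molecule's transit through the confocal volume (default 1 ms).
During a burst the donor is excited by a pulsed laser (default every 50 ns);
each excitation event resolves into a donor or an acceptor photon with a
delay, photons are detected with a per-channel efficiency, and the burst is
summarized by

* the intensity-based FRET efficiency  E_I = I_A / (I_A + I_D),
* the normalized donor lifetime        tau = mean donor delay * k_D,

which together give one point in the FRET-efficiency / lifetime plane.  The
dye translational state persists across excitation events within a burst
(propagated between pulses) and is redrawn from the stationary law at every
burst start (each burst is a fresh molecule); dipole orientations are redrawn
from their uniform equilibrium at every excitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import named_streams
from .models import DyePairModel
from .photophysics import (
    KAPPA_SQ_ISOTROPIC_MEAN,
    PhotophysicsParams,
    sample_dynamic_events,
    sample_static_events,
)

__all__ = [
    "BurstConfig",
    "BurstRecord",
    "ExperimentResult",
    "scheduled_burst_count",
    "run_burst",
    "run_experiment",
    "estimate_intensity_fret",
    "estimate_lifetime_fret",
]

BURST_COLUMNS = ["burst_id", "I_D", "I_A", "E_intensity", "tau_norm",
                 "mean_kappa_sq", "n_events", "usable"]


@dataclass(frozen=True)
class BurstConfig:
    """Burst schedule and detection.

    Times within a burst are in ns; the experiment schedule is in seconds.
    ``detection_efficiency`` is the per-channel probability that an emitted
    photon is recorded; give a (donor, acceptor) pair for unequal channels.
    """

    burst_duration: float = 1.0e6  # ns (1 ms)
    excitation_period: float = 50.0  # ns
    detection_efficiency: float | tuple[float, float] = 0.005
    bursts_per_second: float = 1.0
    total_duration: float = 7.0 * 3600.0  # s
    min_photons: int = 10

    def __post_init__(self) -> None:
        eta = self.efficiencies
        if not all(0.0 <= e <= 1.0 for e in eta):
            raise ValueError("detection efficiencies must lie in [0, 1]")
        if self.burst_duration <= 0 or self.excitation_period <= 0:
            raise ValueError("burst duration and excitation period must be > 0")
        if self.bursts_per_second <= 0 or self.total_duration <= 0:
            raise ValueError("schedule rates and durations must be > 0")
        if self.burst_duration >= 1.0e9 / self.bursts_per_second:
            raise ValueError("burst_duration must be shorter than the burst spacing")
        if self.min_photons < 0:
            raise ValueError("min_photons must be >= 0")

    @property
    def efficiencies(self) -> tuple[float, float]:
        e = self.detection_efficiency
        if np.ndim(e) == 0:
            return (float(e), float(e))
        if len(e) != 2:
            raise ValueError("detection_efficiency must be scalar or a pair")
        return (float(e[0]), float(e[1]))

    @property
    def pulses_per_burst(self) -> int:
        return int(self.burst_duration // self.excitation_period)


@dataclass(frozen=True)
class BurstRecord:
    burst_id: int
    I_D: int
    I_A: int
    E_intensity: float
    tau_norm: float
    mean_kappa_sq: float
    n_events: int
    usable: bool


@dataclass(frozen=True)
class ExperimentResult:
    """Burst table plus the provenance needed to reproduce it bit-exactly."""

    bursts: pd.DataFrame
    config: BurstConfig
    photophysics: PhotophysicsParams
    model_kind: str
    kappa_mode: str
    seed: int
    photons: pd.DataFrame | None = None
    rng_algorithm: str = "numpy PCG64 via SeedSequence-spawned named streams"

    @property
    def usable(self) -> pd.DataFrame:
        return self.bursts[self.bursts["usable"]]


def scheduled_burst_count(config: BurstConfig) -> int:
    """Number of bursts scheduled at ``bursts_per_second`` over the
    experiment; burst k starts at k / bursts_per_second."""
    return int(math.floor(config.total_duration * config.bursts_per_second))


def estimate_intensity_fret(I_A, I_D):
    """Intensity-based efficiency E_I = I_A / (I_A + I_D)."""
    I_A = np.asarray(I_A, dtype=float)
    I_D = np.asarray(I_D, dtype=float)
    total = I_A + I_D
    if np.any(total <= 0):
        raise ValueError("undefined estimate: no detected photons")
    out = I_A / total
    return float(out) if out.ndim == 0 else out


def estimate_lifetime_fret(tau_DA, tau_D0):
    """Lifetime-based efficiency 1 - tau_D(A) / tau_D(0)."""
    if np.any(np.asarray(tau_D0) <= 0):
        raise ValueError("tau_D0 must be > 0")
    out = 1.0 - np.asarray(tau_DA, dtype=float) / np.asarray(tau_D0, dtype=float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# engine


def _detected_event_times(config: BurstConfig, n_bursts: int,
                          rng: np.random.Generator):
    """Pulse times (ns) of detected excitation events per burst.

    Valid only for equal channel efficiencies: detection is then independent
    of photon color, so pulses can be thinned before their outcome is
    simulated.  Gaps between detected pulses are geometric.
    """
    eta = config.efficiencies[0]
    n_pulses = config.pulses_per_burst
    mean = n_pulses * eta
    max_ev = int(mean + 8.0 * math.sqrt(max(mean * (1 - eta), 1.0)) + 16)
    max_ev = min(max_ev, n_pulses)
    gaps = rng.geometric(eta, size=(n_bursts, max_ev))
    pulse_idx = np.cumsum(gaps, axis=1) - 1
    valid = pulse_idx < n_pulses
    times = pulse_idx * config.excitation_period
    return times, valid


def run_experiment(model: DyePairModel, photophysics: PhotophysicsParams,
                   config: BurstConfig, *, n_bursts: int | None = None,
                   seed: int = 0, kappa_sq_override: float | None = None,
                   donor_only: bool = False,
                   store_photons: bool = False) -> ExperimentResult:
    """Simulate an smFRET experiment and return the burst table.

    ``n_bursts`` defaults to the scheduled count (total_duration *
    bursts_per_second).  ``kappa_sq_override`` freezes kappa^2 at the given
    value regardless of the model's mode; ``donor_only`` removes the acceptor
    (k_ET = 0), the donor-only control used for lifetime normalization.
    The same (model, config, seed) always reproduces the same table.
    """
    if n_bursts is None:
        n_bursts = scheduled_burst_count(config)
    if n_bursts < 1:
        raise ValueError("need at least one burst")
    eta_d, eta_a = config.efficiencies
    if eta_d != eta_a:
        raise NotImplementedError(
            "unequal channel efficiencies require per-pulse simulation; "
            "set detection_efficiency to a scalar")

    streams = named_streams(seed)
    trans_rngs = (streams["donor-trans"], streams["acceptor-trans"])
    phot_rng = streams["photophysics"]
    det_rng = streams["detection"]

    if donor_only:
        kappa_sq_override = 0.0
    dynamic = (model.kappa_mode == "dynamic") and kappa_sq_override is None
    kappa_static = (KAPPA_SQ_ISOTROPIC_MEAN if kappa_sq_override is None
                    else float(kappa_sq_override))

    times, valid = _detected_event_times(config, n_bursts, det_rng)
    n_events_total = valid.sum(axis=1)

    # Pendulum gaps between detected pulses are always >= the excitation
    # period; when that is at least the relaxation horizon (several
    # relaxation times of every pendulum coordinate), the between-event
    # transition kernel is stationary to within e^(-horizon * rate), so the
    # state at each event can be drawn from a pre-equilibrated stationary
    # pool instead of being Heun-stepped through the full gap.
    pool = None
    if (model.kind == "pendulum"
            and config.excitation_period >= model.relaxation_horizon):
        pool_n = max(8192, 16 * n_bursts)
        pool = model.initial_translational_states(pool_n, trans_rngs)
        pool_rng = streams["schedule"]

    states = model.initial_translational_states(n_bursts, trans_rngs)
    I_D = np.zeros(n_bursts, dtype=np.int64)
    I_A = np.zeros(n_bursts, dtype=np.int64)
    dwell_sum = np.zeros(n_bursts)
    kappa_sum = np.zeros(n_bursts)
    prev_time = np.zeros(n_bursts)
    photon_rows = [] if store_photons else None

    max_ev = times.shape[1]
    for j in range(max_ev):
        active = valid[:, j]
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        if pool is not None:
            states[idx] = pool[pool_rng.integers(len(pool), size=idx.size)]
        else:
            gap = times[idx, j] - prev_time[idx]
            states[idx] = model.propagate_translational(states[idx], gap,
                                                        trans_rngs)
        prev_time[idx] = times[idx, j]

        r_vec = model.inter_dye_vectors(states[idx])
        dist = np.linalg.norm(r_vec, axis=-1)
        if dynamic:
            with np.errstate(divide="ignore"):
                r_hat = np.where(dist[:, None] > 0, r_vec / dist[:, None],
                                 [1.0, 0.0, 0.0])
            acc, dwell, delay, kbar2 = sample_dynamic_events(
                dist, photophysics, model.donor_rotation,
                model.acceptor_rotation, phot_rng, r_hat=r_hat)
        else:
            acc, dwell, delay = sample_static_events(
                dist, kappa_static, photophysics, phot_rng)
            kbar2 = np.full(idx.size, kappa_static)

        I_A[idx] += acc
        I_D[idx] += ~acc
        dwell_sum[idx] += np.where(acc, 0.0, dwell)
        kappa_sum[idx] += kbar2
        if photon_rows is not None:
            for b, a, dl in zip(idx, acc, delay):
                photon_rows.append((int(b), float(times[b, j] + dl),
                                    "acceptor" if a else "donor"))

    total = I_D + I_A
    with np.errstate(invalid="ignore", divide="ignore"):
        e_int = np.where(total > 0, I_A / np.maximum(total, 1), np.nan)
        tau_da = np.where(I_D > 0, dwell_sum / np.maximum(I_D, 1), np.nan)
        tau_norm = tau_da * photophysics.donor_decay
        mean_k2 = np.where(n_events_total > 0,
                           kappa_sum / np.maximum(n_events_total, 1), np.nan)
    usable = (total >= config.min_photons) & (I_D > 0)

    bursts = pd.DataFrame({
        "burst_id": np.arange(n_bursts),
        "I_D": I_D,
        "I_A": I_A,
        "E_intensity": e_int,
        "tau_norm": tau_norm,
        "mean_kappa_sq": mean_k2,
        "n_events": n_events_total,
        "usable": usable,
    })
    photons = None
    if photon_rows is not None:
        photons = pd.DataFrame(photon_rows,
                               columns=["burst_id", "delay_ns", "channel"])
        photons = photons.sort_values(["burst_id", "delay_ns"],
                                      kind="stable").reset_index(drop=True)
    return ExperimentResult(
        bursts=bursts, config=config, photophysics=photophysics,
        model_kind=model.kind, kappa_mode=model.kappa_mode, seed=seed,
        photons=photons,
    )


def run_burst(config: BurstConfig, model: DyePairModel,
              photophysics: PhotophysicsParams, seed: int = 0,
              **kwargs) -> BurstRecord:
    """Simulate a single burst and return its record.

    A burst with zero detected photons (or none in the donor channel, so no
    lifetime estimate) comes back with ``usable=False`` and NaN coordinates.
    """
    result = run_experiment(model, photophysics, config, n_bursts=1,
                            seed=seed, **kwargs)
    row = result.bursts.iloc[0]
    return BurstRecord(
        burst_id=0, I_D=int(row.I_D), I_A=int(row.I_A),
        E_intensity=float(row.E_intensity), tau_norm=float(row.tau_norm),
        mean_kappa_sq=float(row.mean_kappa_sq), n_events=int(row.n_events),
        usable=bool(row.usable),
    )
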