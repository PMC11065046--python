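"""Orientation factor, Forster transfer rates, and excitation-event sampling.

An excitation event is one laser-pulse excitation of the donor and its
stochastic resolution.  The photophysics is a four-state continuous-time
Markov chain on S = {D, A, FD, FA}: from the excited donor D the system
either fluoresces (D -> FD, rate k_D) or transfers energy to the acceptor
(D -> A, rate k_ET), after which the acceptor fluoresces (A -> FA, rate k_A).
FD and FA are absorbing.  When the dipoles reorient during the excited-state
dwell the transfer rate k_ET(t) = k_D C kappa^2(t) / r^6 is time-dependent
and the chain is time-inhomogeneous; exit times from D then follow the
integrated hazard k_D t + H(t), H(t) = int_0^t k_ET(s) ds.

Production sampling uses Lewis-Shedler thinning with the rigorous bound
kappa^2 <= 4 (exact, no grid bias); a fine-grid inversion sampler is kept as
an independent oracle for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import RotationParams, sphere_propagate, uniform_unit_vectors

__all__ = [
    "PhotophysicsParams",
    "KappaPath",
    "ExcitationRecord",
    "KAPPA_SQ_ISOTROPIC_MEAN",
    "kappa_factor",
    "forster_radius6",
    "transfer_rate",
    "static_efficiency",
    "time_dependent_efficiency",
    "integrated_hazard",
    "build_rate_matrix",
    "sample_excitation_event",
    "sample_static_events",
    "sample_dynamic_events",
    "sample_event_by_inversion",
    "sample_kappa_sq_static",
    "simulate_kappa_paths",
]

#: Dynamic-averaging value of kappa^2 for uniformly distributed dipoles.
KAPPA_SQ_ISOTROPIC_MEAN = 2.0 / 3.0

STATES = ("D", "A", "FD", "FA")


@dataclass(frozen=True)
class PhotophysicsParams:
    """Rates and the Forster constant.

    ``forster_constant`` C is defined by R0^6(t) = C kappa^2(t); the
    reference Forster radius is the dynamic-averaging one,
    R0_ref = (2C/3)^(1/6).  Constructing from R0_ref is usually more
    convenient: C = 3 R0_ref^6 / 2.
    """

    donor_decay: float = 0.25  # k_D, 1/ns
    acceptor_decay: float = 0.5  # k_A, 1/ns
    forster_constant: float = 1.5 * 40.0**6  # C, A^6

    def __post_init__(self) -> None:
        for name in ("donor_decay", "acceptor_decay", "forster_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def from_forster_radius(cls, R0_ref: float, donor_decay: float = 0.25,
                            acceptor_decay: float = 0.5) -> "PhotophysicsParams":
        if R0_ref <= 0:
            raise ValueError("R0_ref must be > 0")
        return cls(donor_decay, acceptor_decay,
                   R0_ref**6 / KAPPA_SQ_ISOTROPIC_MEAN)

    @property
    def reference_forster_radius(self) -> float:
        return (self.forster_constant * KAPPA_SQ_ISOTROPIC_MEAN) ** (1.0 / 6.0)


@dataclass(frozen=True)
class KappaPath:
    """kappa^2 samples on an increasing time grid starting at 0, with the
    (frozen or slowly varying) inter-dye distance."""

    times: np.ndarray
    kappa_sq: np.ndarray
    distance: float | np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        k2 = np.asarray(self.kappa_sq, dtype=float)
        if t.shape != k2.shape:
            raise ValueError("times and kappa_sq must have equal length")
        if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing from 0")
        if np.any(k2 < 0) or np.any(k2 > 4.0):
            raise ValueError("kappa^2 must lie in [0, 4]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "kappa_sq", k2)


@dataclass(frozen=True)
class ExcitationRecord:
    outcome: str  # 'donor_photon' | 'acceptor_photon'
    donor_dwell: float
    emission_delay: float
    path_mean_kappa_sq: float

    def __post_init__(self) -> None:
        if self.outcome not in ("donor_photon", "acceptor_photon"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.donor_dwell < 0 or self.emission_delay < self.donor_dwell:
            raise ValueError("times must be nonnegative and delay >= dwell")


# ---------------------------------------------------------------------------
# elementary quantities


def kappa_factor(mu_D, mu_A, r_hat):
    """Orientation factor kappa = muD.muA - 3 (r.muD)(r.muA).

    All inputs must be unit vectors (checked to 1e-6); broadcasting over
    leading dimensions is supported.  kappa^2 = kappa**2 lies in [0, 4]:
    it vanishes when the three vectors are mutually orthogonal and reaches 4
    when both dipoles are collinear with the separation.
    """
    mu_D = np.asarray(mu_D, dtype=float)
    mu_A = np.asarray(mu_A, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    for v, name in ((mu_D, "mu_D"), (mu_A, "mu_A"), (r_hat, "r_hat")):
        if np.any(np.abs(np.linalg.norm(v, axis=-1) - 1.0) > 1e-6):
            raise ValueError(f"{name} must be a unit vector")
    return (np.sum(mu_D * mu_A, axis=-1)
            - 3.0 * np.sum(r_hat * mu_D, axis=-1) * np.sum(r_hat * mu_A, axis=-1))


def forster_radius6(C: float, kappa_sq):
    """R0^6 = C kappa^2 (linear in the orientation factor)."""
    if C <= 0:
        raise ValueError("C must be > 0")
    kappa_sq = np.asarray(kappa_sq, dtype=float)
    if np.any(kappa_sq < 0) or np.any(kappa_sq > 4.0):
        raise ValueError("kappa^2 must lie in [0, 4]")
    return C * kappa_sq


def transfer_rate(r, kappa_sq, params: PhotophysicsParams):
    """k_ET = k_D R0^6 / r^6 = k_D C kappa^2 / r^6.

    ``r`` must be positive; the r = 0 degenerate case is the caller's
    responsibility (the chain collapses to the acceptor two-state system).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0 (r = 0 is handled by the event sampler)")
    return params.donor_decay * forster_radius6(params.forster_constant, kappa_sq) / r**6


def static_efficiency(r, params: PhotophysicsParams):
    """Time-homogeneous efficiency 1 / (1 + (r/R0_ref)^6); 1 at r = 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    return 1.0 / (1.0 + (r / params.reference_forster_radius) ** 6)


def _hazard_grid(path: KappaPath, params: PhotophysicsParams):
    """Cumulative transfer hazard H on the path grid (trapezoidal)."""
    k_et = transfer_rate(path.distance, path.kappa_sq, params)
    dt = np.diff(path.times)
    increments = 0.5 * (k_et[1:] + k_et[:-1]) * dt
    H = np.concatenate([[0.0], np.cumsum(increments)])
    return k_et, H


def integrated_hazard(path: KappaPath, t: float, params: PhotophysicsParams):
    """H(t) = int_0^t k_ET(s) ds by trapezoidal quadrature on the path grid."""
    t = float(t)
    if t < 0 or t > path.times[-1] + 1e-12:
        raise ValueError("t outside the path support")
    k_et, H = _hazard_grid(path, params)
    return float(np.interp(t, path.times, H))


def time_dependent_efficiency(path: KappaPath, T: float,
                              params: PhotophysicsParams):
    """Path-dependent efficiency H(T) / (H(T) + k_D T); 0 at T = 0 taken as
    the k_ET(0)/(k_ET(0)+k_D) limit."""
    if T > path.times[-1] + 1e-12:
        raise ValueError("path does not cover [0, T]")
    if T == 0.0:
        k0 = float(transfer_rate(path.distance, path.kappa_sq[0], params))
        return k0 / (k0 + params.donor_decay)
    H = integrated_hazard(path, T, params)
    return H / (H + params.donor_decay * T)


def build_rate_matrix(k_ET: float, params: PhotophysicsParams) -> np.ndarray:
    """Generator of the four-state chain, states ordered (D, A, FD, FA)."""
    if k_ET < 0:
        raise ValueError("k_ET must be >= 0")
    kD, kA = params.donor_decay, params.acceptor_decay
    Q = np.array([
        [-(kD + k_ET), k_ET, kD, 0.0],
        [0.0, -kA, 0.0, kA],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    return Q


# ---------------------------------------------------------------------------
# event sampling


def sample_static_events(r, kappa_sq, params: PhotophysicsParams,
                         rng: np.random.Generator):
    """Vectorized homogeneous events (kappa^2 and r frozen for the dwell).

    Returns (acceptor: bool array, dwell, delay).  Exit from D occurs at
    Exp(k_D + k_ET); the branch is acceptor with probability
    k_ET/(k_D + k_ET); acceptor photons add an independent Exp(k_A) dwell.
    r = 0 entries collapse to the acceptor-only two-state chain.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    kappa_sq = np.broadcast_to(np.asarray(kappa_sq, dtype=float), r.shape)
    kD, kA = params.donor_decay, params.acceptor_decay
    k_et = np.zeros_like(r)
    zero = r == 0.0
    pos = ~zero
    k_et[pos] = transfer_rate(r[pos], kappa_sq[pos], params)
    k_tot = kD + k_et
    dwell = rng.exponential(1.0, size=r.shape) / k_tot
    acceptor = rng.random(r.shape) * k_tot < k_et
    if np.any(zero):
        acceptor[zero] = True
        dwell[zero] = 0.0
    delay = dwell.copy()
    n_acc = int(acceptor.sum())
    if n_acc:
        delay[acceptor] += rng.exponential(1.0 / kA, size=n_acc)
    return acceptor, dwell, delay


def sample_dynamic_events(r, params: PhotophysicsParams,
                          donor_rotation: RotationParams | None = None,
                          acceptor_rotation: RotationParams | None = None,
                          rng: np.random.Generator = None, r_hat=None,
                          mu_D0=None, mu_A0=None, kappa_path=None):
    """Vectorized exact thinning of the inhomogeneous donor-exit hazard.

    For each event the inter-dye distance is frozen at ``r`` (translational
    motion is slow on the dwell timescale) while both dipoles, initialized
    uniformly on the sphere unless given, diffuse during the dwell.  Proposals
    come from the homogeneous bound k_D (1 + 4 C / r^6) (kappa^2 <= 4); at an
    accepted exit the branch is acceptor with instantaneous probability
    k_ET(t)/(k_D + k_ET(t)).

    ``kappa_path`` replaces the dipole simulation with a prescribed
    deterministic kappa^2(t) (a vectorized callable of the time since
    excitation), so the thinning sampler can be checked against the
    integrated-hazard inversion oracle on a known hazard.

    Returns (acceptor, dwell, delay, path_mean_kappa_sq).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n = r.shape[0]
    kD, kA = params.donor_decay, params.acceptor_decay
    C = params.forster_constant
    if kappa_path is None and (donor_rotation is None or acceptor_rotation is None):
        raise ValueError("give rotation parameters or a kappa_path")

    if r_hat is None:
        r_hat = np.zeros((n, 3))
        r_hat[:, 0] = 1.0
    else:
        r_hat = np.broadcast_to(np.asarray(r_hat, dtype=float), (n, 3)).copy()

    acceptor = np.zeros(n, dtype=bool)
    dwell = np.zeros(n)
    kbar2 = np.zeros(n)  # time-integrated kappa^2 (trapezoid over proposals)

    zero = r == 0.0
    if np.any(zero):
        acceptor[zero] = True

    active = np.flatnonzero(~zero)
    if active.size:
        if kappa_path is None:
            mu_D = (uniform_unit_vectors(rng, active.size) if mu_D0 is None
                    else np.asarray(mu_D0, dtype=float)[active].copy())
            mu_A = (uniform_unit_vectors(rng, active.size) if mu_A0 is None
                    else np.asarray(mu_A0, dtype=float)[active].copy())
            DD = donor_rotation.diffusion
            DA = acceptor_rotation.diffusion
        idx = active.copy()
        r_act = r[idx]
        rh = r_hat[idx]
        bound = kD * (1.0 + 4.0 * C / r_act**6)
        t = np.zeros(idx.size)
        if kappa_path is None:
            k2_prev = kappa_factor(mu_D, mu_A, rh) ** 2
        else:
            k2_prev = np.asarray(kappa_path(t), dtype=float)
        while idx.size:
            dt_prop = rng.exponential(1.0, size=idx.size) / bound
            if kappa_path is None:
                mu_D = sphere_propagate(mu_D, DD, dt_prop, rng)
                mu_A = sphere_propagate(mu_A, DA, dt_prop, rng)
                k2 = kappa_factor(mu_D, mu_A, rh) ** 2
            else:
                k2 = np.asarray(kappa_path(t + dt_prop), dtype=float)
            rate = kD * (1.0 + C * k2 / r_act**6)
            if np.any(rate > bound * (1.0 + 1e-12)):
                raise AssertionError("thinning bound violated (kappa^2 > 4?)")
            t = t + dt_prop
            kbar2 = kbar2.copy()
            kbar2[idx] += 0.5 * (k2 + k2_prev) * dt_prop
            accept = rng.random(idx.size) * bound < rate
            if np.any(accept):
                sel = idx[accept]
                dwell[sel] = t[accept]
                k_et_exit = rate[accept] - kD
                acceptor[sel] = rng.random(sel.size) * rate[accept] < k_et_exit
            keep = ~accept
            idx = idx[keep]
            if kappa_path is None:
                mu_D, mu_A = mu_D[keep], mu_A[keep]
            rh, r_act = rh[keep], r_act[keep]
            bound, t = bound[keep], t[keep]
            k2_prev = k2[keep]

    pos_dwell = dwell > 0
    kbar2[pos_dwell] /= dwell[pos_dwell]
    delay = dwell.copy()
    n_acc = int(acceptor.sum())
    if n_acc:
        delay[acceptor] += rng.exponential(1.0 / kA, size=n_acc)
    return acceptor, dwell, delay, kbar2


def sample_event_by_inversion(path: KappaPath, params: PhotophysicsParams,
                              rng: np.random.Generator, size: int = 1):
    """Oracle sampler: invert the donor-exit survival on a fine path grid.

    S(t) = exp(-k_D t - H(t)).  Draws exit times by inverting the cumulative
    hazard on the path's time grid (linear interpolation of the cumulative
    hazard between grid nodes).  Draws beyond the path support are clipped to
    the endpoint and flagged by returning NaN for those entries.
    """
    k_et, H = _hazard_grid(path, params)
    total = params.donor_decay * path.times + H
    u = rng.exponential(1.0, size=size)
    out = np.interp(u, total, path.times, right=np.nan)
    return out if size != 1 else float(out[0])


def sample_excitation_event(r: float, params: PhotophysicsParams,
                            rng: np.random.Generator, *,
                            donor_rotation: RotationParams | None = None,
                            acceptor_rotation: RotationParams | None = None,
                            kappa_sq: float = KAPPA_SQ_ISOTROPIC_MEAN,
                            r_hat=None) -> ExcitationRecord:
    """One excitation event for a dye pair at frozen inter-dye distance ``r``.

    With rotation parameters given, the dipoles start from the uniform
    equilibrium and evolve during the dwell (time-inhomogeneous chain, exact
    thinning); otherwise kappa^2 is held at ``kappa_sq``.
    """
    if donor_rotation is not None and acceptor_rotation is not None:
        acc, dwell, delay, kbar2 = sample_dynamic_events(
            np.array([r]), params, donor_rotation, acceptor_rotation, rng,
            r_hat=None if r_hat is None else np.asarray(r_hat)[None, :])
        k2 = float(kbar2[0])
    else:
        acc, dwell, delay = sample_static_events(
            np.array([r]), kappa_sq, params, rng)
        k2 = float(kappa_sq)
    return ExcitationRecord(
        outcome="acceptor_photon" if acc[0] else "donor_photon",
        donor_dwell=float(dwell[0]),
        emission_delay=float(delay[0]),
        path_mean_kappa_sq=k2,
    )


# ---------------------------------------------------------------------------
# kappa^2 utilities


def sample_kappa_sq_static(rng: np.random.Generator, size=None):
    """kappa^2 under independent uniform dipoles and separation direction.

    This is the classical static (isotropic-average) kappa^2 distribution,
    with mean 2/3.
    """
    n = 1 if size is None else int(np.prod(np.atleast_1d(size)))
    mu_D = uniform_unit_vectors(rng, n)
    mu_A = uniform_unit_vectors(rng, n)
    r_hat = uniform_unit_vectors(rng, n)
    k2 = kappa_factor(mu_D, mu_A, r_hat) ** 2
    return float(k2[0]) if size is None else k2.reshape(np.atleast_1d(size))


def simulate_kappa_paths(donor_rotation: RotationParams,
                         acceptor_rotation: RotationParams,
                         rng: np.random.Generator, *,
                         n_paths: int = 200, duration: float = 1.0,
                         dt: float = 0.001, r_hat=None):
    """Ensembles of kappa^2(t) trajectories during an excitation window.

    Both dipoles start uniform and diffuse on the sphere; the separation
    direction is held fixed (x by default).  Returns (times, kappa_sq) with
    kappa_sq of shape (n_paths, n_times).
    """
    n_t = int(round(duration / dt)) + 1
    times = np.arange(n_t) * dt
    if r_hat is None:
        r_hat = np.array([1.0, 0.0, 0.0])
    r_hat = np.broadcast_to(np.asarray(r_hat, dtype=float), (n_paths, 3))
    mu_D = uniform_unit_vectors(rng, n_paths)
    mu_A = uniform_unit_vectors(rng, n_paths)
    out = np.empty((n_paths, n_t))
    out[:, 0] = kappa_factor(mu_D, mu_A, r_hat) ** 2
    for i in range(1, n_t):
        mu_D = sphere_propagate(mu_D, donor_rotation.diffusion, dt, rng)
        mu_A = sphere_propagate(mu_A, acceptor_rotation.diffusion, dt, rng)
        out[:, i] = kappa_factor(mu_D, mu_A, r_hat) ** 2
    return times, out
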