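"""Stochastic propagation of dye translational states and dipole orientations.

Three stochastic processes are provided:

* an Ornstein-Uhlenbeck (OU) spring for the dye position, propagated with the
  exact Gaussian transition kernel (the noise coefficient is constant, so the
  Stratonovich and Ito readings coincide);
* an elastic pendulum -- a point mass on a spring free to swing -- written in
  spherical coordinates and integrated with a Stratonovich-Heun
  predictor-corrector;
* spherical Brownian motion of the transition-dipole unit vector, whose
  stationary law is uniform on S2.

All lengths are in Angstrom, times in ns, rates in 1/ns.  Random numbers come
from caller-supplied ``numpy.random.Generator`` objects; ``named_streams``
derives independent per-process streams from one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpringParams",
    "PendulumParams",
    "RotationParams",
    "TimescaleConfig",
    "IntegratorConfig",
    "named_streams",
    "ou_propagate",
    "spring_equilibrium_sample",
    "pendulum_step",
    "pendulum_drift_root",
    "sphere_step",
    "sphere_propagate",
    "uniform_unit_vectors",
    "unit_vector_from_angles",
    "angles_from_unit_vector",
    "rotational_diffusion_coefficient",
    "simulate_dye_pair",
]

_POLE_TOL = 1e-6


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SpringParams:
    """Diagonal OU spring: dX = -K (X - X_eq) dt + sigma dB.

    ``rates`` are the diagonal entries of K interpreted as relaxation rates
    (1/ns); ``sigma`` is the common volatility (Angstrom / sqrt(ns));
    ``equilibrium`` is X_eq.  The per-axis stationary variance is
    sigma^2 / (2 k_i).
    """

    rates: tuple[float, float, float]
    sigma: float
    equilibrium: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.rates) != 3 or any(k <= 0 for k in self.rates):
            raise ValueError(f"spring rates must be 3 positive values, got {self.rates}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @classmethod
    def from_matrix(cls, K: np.ndarray, sigma: float,
                    equilibrium=(0.0, 0.0, 0.0)) -> "SpringParams":
        K = np.asarray(K, dtype=float)
        if K.shape != (3, 3):
            raise ValueError("spring matrix must be 3x3")
        if not np.allclose(K, np.diag(np.diag(K))):
            raise ValueError("only diagonal spring matrices are supported")
        return cls(tuple(np.diag(K)), sigma, tuple(equilibrium))

    @classmethod
    def isotropic(cls, rate: float, sigma: float,
                  equilibrium=(0.0, 0.0, 0.0)) -> "SpringParams":
        return cls((rate, rate, rate), sigma, tuple(equilibrium))

    @classmethod
    def from_stationary_sd(cls, sd: float, rate: float,
                           equilibrium=(0.0, 0.0, 0.0)) -> "SpringParams":
        """Isotropic spring with a prescribed per-axis stationary sd."""
        return cls.isotropic(rate, sd * math.sqrt(2.0 * rate), tuple(equilibrium))

    @classmethod
    def anisotropic_equal_volume(cls, sd: float, p: float, rate: float,
                                 stiff_axis: int = 0,
                                 equilibrium=(0.0, 0.0, 0.0)) -> "SpringParams":
        """Anisotropic ellipsoid with the same accessible volume as the
        isotropic cloud of per-axis sd ``sd``.

        The soft/stiff stationary-variance ratio is 1/p and the determinant of
        the stationary covariance is preserved, so the per-axis variances are
        sd^2 * p^(-1/3) (two soft axes) and sd^2 * p^(2/3) (stiff axis).
        """
        if not 0 < p <= 1:
            raise ValueError(f"anisotropy p must be in (0, 1], got {p}")
        var = np.full(3, sd * sd * p ** (-1.0 / 3.0))
        var[stiff_axis] = sd * sd * p ** (2.0 / 3.0)
        sigma = sd * math.sqrt(2.0 * rate)  # shared volatility
        rates = tuple(sigma**2 / (2.0 * v) for v in var)
        return cls(rates, sigma, tuple(equilibrium))

    @property
    def stationary_sd(self) -> np.ndarray:
        return self.sigma / np.sqrt(2.0 * np.asarray(self.rates))

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.rates)) == 1


@dataclass(frozen=True)
class PendulumParams:
    """Elastic pendulum in spherical coordinates (r, theta, phi).

    dr     = [-k_r (r - r_eq) + c_r / r] dt + sigma_r o dB
    dtheta = [-k_theta sin(theta) + sigma_theta^2/(2 r^2 tan(theta))] dt
             + (sigma_theta / r) o dB
    dphi   = sigma_phi / (r sin(theta)) o dB

    ``c_r`` is the dimensionless-in-spirit coefficient of the 1/r radial
    drift (units A^2/ns); the literal reading of the model is c_r = 1, the
    noise-induced-drift alternative is c_r = sigma_r^2.
    """

    radial_spring: float = 0.2
    polar_spring: float = 0.2
    equilibrium_radius: float = 18.0
    sigma_r: float = 0.9
    sigma_theta: float = 9.0
    sigma_phi: float = 9.0
    radial_correction_coefficient: float = 1.0

    def __post_init__(self) -> None:
        for name in ("radial_spring", "polar_spring", "equilibrium_radius",
                     "sigma_r", "sigma_theta", "sigma_phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class RotationParams:
    """Rotational diffusion of a spherical dye.

    Either give ``diffusion`` (rad^2/ns) directly, or the physical inputs
    (thermal energy kT, dynamic viscosity nu, hydrodynamic radius R_h) from
    which D = kT / (8 pi nu R_h^3).
    """

    diffusion: float | None = None
    thermal_energy: float | None = None
    viscosity: float | None = None
    hydrodynamic_radius: float | None = None

    def __post_init__(self) -> None:
        if self.diffusion is None:
            if None in (self.thermal_energy, self.viscosity, self.hydrodynamic_radius):
                raise ValueError(
                    "give either diffusion or all of thermal_energy, viscosity, "
                    "hydrodynamic_radius"
                )
            object.__setattr__(self, "diffusion",
                               rotational_diffusion_coefficient(self))
        if self.diffusion <= 0:
            raise ValueError(f"rotational diffusion must be > 0, got {self.diffusion}")

    @property
    def sigma(self) -> float:
        """Angular volatility sqrt(2 D) of the spherical Langevin equations."""
        return math.sqrt(2.0 * self.diffusion)


def rotational_diffusion_coefficient(params: RotationParams) -> float:
    """Stokes-Einstein-Debye rotational diffusion, D = kT / (8 pi nu R_h^3)."""
    kT, nu, Rh = params.thermal_energy, params.viscosity, params.hydrodynamic_radius
    if kT is None or nu is None or Rh is None:
        if params.diffusion is not None:
            return params.diffusion
        raise ValueError("insufficient physical inputs for rotational diffusion")
    if kT <= 0 or nu <= 0 or Rh <= 0:
        raise ValueError("kT, viscosity and hydrodynamic radius must be > 0")
    return kT / (8.0 * math.pi * nu * Rh**3)


@dataclass(frozen=True)
class TimescaleConfig:
    """Declared integration steps: orientational faster than translational."""

    translational_step: float = 0.1  # ns
    orientational_step: float = 0.001  # ns

    def __post_init__(self) -> None:
        if self.translational_step <= 0 or self.orientational_step <= 0:
            raise ValueError("time steps must be positive")
        if not self.orientational_step < self.translational_step:
            raise ValueError(
                "orientational step must be smaller than translational step "
                f"(got {self.orientational_step} >= {self.translational_step})"
            )


@dataclass(frozen=True)
class IntegratorConfig:
    scheme: str = "exact-ou"
    step: float = 0.1
    seed: int = 0
    pole_tolerance: float = _POLE_TOL

    _SCHEMES = ("exact-ou", "heun-stratonovich", "euler-maruyama")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"scheme must be one of {self._SCHEMES}")
        if self.step <= 0:
            raise ValueError("step must be positive")


_STREAM_NAMES = ("donor-trans", "donor-rot", "acceptor-trans", "acceptor-rot",
                 "photophysics", "detection", "schedule")


def named_streams(master_seed: int, names=_STREAM_NAMES) -> dict[str, np.random.Generator]:
    """Independent named RNG streams derived from one master seed.

    Streams are spawned from a single ``SeedSequence`` in the fixed order of
    ``names``, so runs are bit-reproducible given (seed, names).
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# OU spring


def ou_propagate(x: np.ndarray, params: SpringParams, dt: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Exact OU transition over a step of any length.

    Per axis i: mean X_eq,i + (x_i - X_eq,i) e^(-k_i dt), variance
    (sigma^2 / 2 k_i)(1 - e^(-2 k_i dt)).  ``dt`` may be a scalar or an array
    broadcastable against the leading dimensions of ``x``; dt = 0 entries
    return the state unchanged (the kernel degenerates to the identity).
    """
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be nonnegative")
    x = np.asarray(x, dtype=float)
    k = np.asarray(params.rates)
    eq = np.asarray(params.equilibrium)
    dt = np.asarray(dt, dtype=float)[..., None] if np.ndim(dt) else dt
    decay = np.exp(-k * dt)
    var = params.sigma**2 / (2.0 * k) * (1.0 - np.exp(-2.0 * k * dt))
    mean = eq + (x - eq) * decay
    return mean + np.sqrt(var) * rng.standard_normal(x.shape)


def spring_equilibrium_sample(params: SpringParams, rng: np.random.Generator,
                              size: int | tuple | None = None) -> np.ndarray:
    """Draw from the stationary Gaussian N(X_eq, diag(sigma^2 / 2 k_i))."""
    sd = params.stationary_sd
    shape = (3,) if size is None else (tuple(np.atleast_1d(size)) + (3,))
    return np.asarray(params.equilibrium) + sd * rng.standard_normal(shape)


def _ou_euler_step(x, params: SpringParams, dt, rng):
    """Plain Euler-Maruyama step; kept as the independent fine-step oracle."""
    k = np.asarray(params.rates)
    eq = np.asarray(params.equilibrium)
    drift = -k * (np.asarray(x) - eq)
    return x + drift * dt + params.sigma * math.sqrt(dt) * rng.standard_normal(np.shape(x))


# ---------------------------------------------------------------------------
# elastic pendulum


def pendulum_drift_root(params: PendulumParams) -> float:
    """Radial rest point: positive root of k_r r^2 - k_r r_eq r - c_r = 0."""
    k, req, c = (params.radial_spring, params.equilibrium_radius,
                 params.radial_correction_coefficient)
    return 0.5 * (req + math.sqrt(req * req + 4.0 * c / k))


def _reflect_polar(th, ph):
    """Fold theta back into (0, pi), shifting phi by pi when crossing a pole."""
    th = np.mod(th, 2.0 * np.pi)
    over = th > np.pi
    th = np.where(over, 2.0 * np.pi - th, th)
    ph = np.where(over, ph + np.pi, ph)
    return th, ph


def pendulum_step(state: np.ndarray, params: PendulumParams, dt: float,
                  rng: np.random.Generator, *, pole_tol: float = _POLE_TOL,
                  _depth: int = 0) -> np.ndarray:
    """One step of the elastic pendulum; ``state`` is (..., 3) = (r, theta, phi).

    The radial coordinate takes a Stratonovich-Heun predictor-corrector step
    of  dr = [-k_r (r - r_eq) + c_r/r] dt + sigma_r dB.  The angular pair is
    advanced coordinate-free: the swing direction takes a tangent-plane
    diffusion step with per-direction volatilities sigma_theta/r (polar) and
    sigma_phi/r (azimuthal) followed by the deterministic polar restoring
    rotation -k_theta sin(theta) dt.  The geodesic step generates the metric
    drift (the cot(theta) term of the coordinate form) exactly and has no
    pole singularity; for sigma_theta = sigma_phi the two forms describe the
    same diffusion.  A step driving r <= 0 is rejected and re-taken as two
    half steps (up to 8 halvings).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = np.asarray(state, dtype=float)
    r, th, ph = state[..., 0], state[..., 1], state[..., 2]
    if np.any(r <= 0):
        raise ValueError("pendulum radius must be positive")
    th = np.clip(th, pole_tol, np.pi - pole_tol)

    # radial Heun step
    sq = math.sqrt(dt)
    dBr = rng.standard_normal(r.shape) * sq

    def a_r(rr):
        return (-params.radial_spring * (rr - params.equilibrium_radius)
                + params.radial_correction_coefficient / rr)

    r1 = r + a_r(r) * dt + params.sigma_r * dBr
    r1s = np.maximum(r1, 1e-6)  # guard for evaluating drift at the predictor
    r_new = r + 0.5 * (a_r(r) + a_r(r1s)) * dt + params.sigma_r * dBr

    bad = (r_new <= 0) | (r1 <= 0)
    if np.any(bad):
        if _depth >= 8:
            raise RuntimeError("pendulum step failed after 8 dt halvings")
        redo = np.stack([r, th, ph], axis=-1)[bad]
        half = pendulum_step(redo, params, dt / 2.0, rng,
                             pole_tol=pole_tol, _depth=_depth + 1)
        half = pendulum_step(half, params, dt / 2.0, rng,
                             pole_tol=pole_tol, _depth=_depth + 1)
        r_bad, th_bad, ph_bad = half[..., 0], half[..., 1], half[..., 2]

    # Angular step on the sphere of (instantaneous) radius r, by Strang
    # splitting: half-step exact restoring flow, tangent diffusion step,
    # half-step restoring.  The polar drift ODE d(theta)/dt = -k sin(theta)
    # integrates exactly to tan(theta/2) -> tan(theta/2) exp(-k t).
    decay = math.exp(-params.polar_spring * dt / 2.0)
    th_half = np.clip(2.0 * np.arctan(np.tan(0.5 * th) * decay),
                      pole_tol, np.pi - pole_tol)
    u = unit_vector_from_angles(th_half, ph)
    e1, e2 = _polar_tangent_basis(u)
    xi_th = rng.standard_normal(r.shape) * (params.sigma_theta / r) * sq
    xi_ph = rng.standard_normal(r.shape) * (params.sigma_phi / r) * sq
    step = xi_th[..., None] * e1 + xi_ph[..., None] * e2
    alpha = np.linalg.norm(step, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(alpha[..., None] > 0,
                             step / np.where(alpha[..., None] == 0, 1.0,
                                             alpha[..., None]), e1)
    u = np.cos(alpha)[..., None] * u + np.sin(alpha)[..., None] * direction
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    th_new, ph_new = angles_from_unit_vector(u)
    th_new = np.clip(2.0 * np.arctan(np.tan(0.5 * th_new) * decay),
                     pole_tol, np.pi - pole_tol)

    if np.any(bad):
        r_new = np.where(bad, 0.0, r_new)  # placeholders, overwritten below
        out = np.stack([r_new, th_new, ph_new], axis=-1)
        out[bad] = np.stack([r_bad, th_bad, ph_bad], axis=-1)
        return out
    return np.stack([r_new, th_new, ph_new], axis=-1)


def _polar_tangent_basis(u: np.ndarray):
    """(e_theta, e_phi) tangent directions at u (polar axis = local z)."""
    th, ph = angles_from_unit_vector(u)
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(ph), np.sin(ph)
    e_th = np.stack([ct * cp, ct * sp, -st], axis=-1)
    e_ph = np.stack([-sp, cp, np.zeros_like(sp)], axis=-1)
    return e_th, e_ph


def pendulum_position(state: np.ndarray) -> np.ndarray:
    """Cartesian position (..., 3) in the pendulum's local frame.

    theta = 0 is the local polar axis (+z of the local frame)."""
    state = np.asarray(state, dtype=float)
    r, th, ph = state[..., 0], state[..., 1], state[..., 2]
    s = np.sin(th)
    return np.stack([r * s * np.cos(ph), r * s * np.sin(ph), r * np.cos(th)], axis=-1)


# ---------------------------------------------------------------------------
# spherical Brownian motion of dipoles


def unit_vector_from_angles(theta, phi) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    s = np.sin(theta)
    return np.stack([s * np.cos(phi), s * np.sin(phi), np.cos(theta)], axis=-1)


def angles_from_unit_vector(mu: np.ndarray):
    mu = np.asarray(mu, dtype=float)
    theta = np.arccos(np.clip(mu[..., 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(mu[..., 1], mu[..., 0]), 2.0 * np.pi)
    return theta, phi


def uniform_unit_vectors(rng: np.random.Generator, size=None) -> np.ndarray:
    shape = (3,) if size is None else (tuple(np.atleast_1d(size)) + (3,))
    v = rng.standard_normal(shape)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _tangent_basis(mu: np.ndarray):
    """Two orthonormal tangent vectors at each point mu of S2."""
    helper = np.zeros_like(mu)
    small_z = np.abs(mu[..., 2]) < 0.9
    helper[..., 2] = np.where(small_z, 1.0, 0.0)
    helper[..., 0] = np.where(small_z, 0.0, 1.0)
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(mu, e1)
    return e1, e2


def _geodesic_step(mu, D, dt, rng):
    """One geodesic (great-circle) diffusion step; exact small-dt MSD 4 D dt."""
    e1, e2 = _tangent_basis(mu)
    sd = np.asarray(np.sqrt(2.0 * D * dt))
    if sd.ndim:
        sd = sd[..., None]
    xi = rng.standard_normal(mu.shape[:-1] + (2,)) * sd
    alpha = np.sqrt(xi[..., 0] ** 2 + xi[..., 1] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = (xi[..., 0:1] * e1 + xi[..., 1:2] * e2)
        norm = np.linalg.norm(direction, axis=-1, keepdims=True)
        direction = np.where(norm > 0, direction / np.where(norm == 0, 1.0, norm), e1)
    out = np.cos(alpha)[..., None] * mu + np.sin(alpha)[..., None] * direction
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def sphere_propagate(mu: np.ndarray, D, dt, rng: np.random.Generator, *,
                     max_step_var: float = 0.02,
                     uniform_cutoff: float = 15.0) -> np.ndarray:
    """Propagate unit dipoles by spherical Brownian motion over time ``dt``.

    Internally sub-steps so that each geodesic step has angular variance
    2 D dt_sub <= ``max_step_var``.  When 2 D dt exceeds ``uniform_cutoff``
    the l=1 relaxation factor e^(-2 D dt) is below 3e-7 and an exact uniform
    draw is returned instead.  ``D`` and ``dt`` may be arrays broadcastable
    over the leading dimensions of ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    D = np.broadcast_to(np.asarray(D, dtype=float), mu.shape[:-1]).copy()
    dt = np.broadcast_to(np.asarray(dt, dtype=float), mu.shape[:-1]).copy()
    if np.any(dt < 0):
        raise ValueError("dt must be nonnegative")
    out = mu.copy()

    spread = 2.0 * D * dt
    uni = spread >= uniform_cutoff
    if np.any(uni):
        out[uni] = uniform_unit_vectors(rng, size=int(uni.sum()))

    active = (~uni) & (dt > 0)
    if np.any(active):
        n_sub = np.ceil(spread[active] / max_step_var).astype(int)
        n_sub = np.maximum(n_sub, 1)
        dt_sub = dt[active] / n_sub
        sub_mu = out[active]
        sub_D = D[active]
        remaining = n_sub.copy()
        while True:
            todo = remaining > 0
            if not np.any(todo):
                break
            sub_mu[todo] = _geodesic_step(sub_mu[todo], sub_D[todo],
                                          dt_sub[todo], rng)
            remaining[todo] -= 1
        out[active] = sub_mu
    return out


def sphere_step(state: np.ndarray, params: RotationParams, dt: float,
                rng: np.random.Generator, *, pole_tol: float = _POLE_TOL) -> np.ndarray:
    """One spherical-Brownian step of a unit dipole (angle-coordinate form).

    Away from the poles the polar/azimuthal Langevin pair
    d(theta) = (sigma^2 / 2) cot(theta) dt + sigma o dB,
    d(phi)   = (sigma / sin(theta)) o dB,  sigma = sqrt(2 D),
    is advanced with a Heun predictor-corrector; within ``pole_tol`` of a pole
    the step is taken in the local tangent plane instead, which removes the
    coordinate singularity without biasing the uniform stationary law.
    Input/output are unit 3-vectors, renormalized after every step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = np.asarray(state, dtype=float)
    scalar = mu.ndim == 1
    mu = np.atleast_2d(mu)
    norm = np.linalg.norm(mu, axis=-1)
    if np.any(np.abs(norm - 1.0) > 1e-6):
        raise ValueError("dipole must be a unit vector")
    sigma = params.sigma
    th, ph = angles_from_unit_vector(mu)
    # take tangent-plane steps in a band around the poles wide enough that
    # the coordinate form's cot(theta) drift stays bounded over one step
    guard = max(pole_tol, 0.1, 4.0 * sigma * math.sqrt(dt))
    near_pole = (th < guard) | (th > np.pi - guard)

    out = mu.copy()
    if np.any(near_pole):
        out[near_pole] = _geodesic_step(mu[near_pole], params.diffusion, dt, rng)
    reg = ~near_pole
    if np.any(reg):
        t0 = th[reg]
        p0 = ph[reg]
        sq = math.sqrt(dt)
        dBt = rng.standard_normal(t0.shape) * sq
        dBp = rng.standard_normal(t0.shape) * sq
        drift0 = 0.5 * sigma * sigma / np.tan(t0)
        g0 = sigma / np.sin(t0)
        t1 = np.clip(t0 + drift0 * dt + sigma * dBt, 0.5 * guard,
                     np.pi - 0.5 * guard)
        drift1 = 0.5 * sigma * sigma / np.tan(t1)
        g1 = sigma / np.sin(t1)
        t_new = t0 + 0.5 * (drift0 + drift1) * dt + sigma * dBt
        p_new = p0 + 0.5 * (g0 + g1) * dBp
        t_new, p_new = _reflect_polar(t_new, p_new)
        out[reg] = unit_vector_from_angles(t_new, p_new)
    out /= np.linalg.norm(out, axis=-1, keepdims=True)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# paired-dye trajectory generation


def simulate_dye_pair(model, duration: float, timescales: TimescaleConfig,
                      streams: dict[str, np.random.Generator]) -> dict:
    """Synchronized donor/acceptor translational + orientational trajectories.

    ``model`` is a :class:`fretshift.models.DyePairModel`.  Translational
    states are advanced on the ``translational_step`` grid; dipoles on the
    ``orientational_step`` grid.  The four stochastic processes use the four
    named streams (donor-trans, donor-rot, acceptor-trans, acceptor-rot) and
    never share random numbers.

    Returns a dict with 'times_trans', 'positions' (n_t, 2, 3) in the global
    frame, 'times_rot', and 'dipoles' (n_r, 2, 3).
    """
    from .models import DyePairModel  # local import to avoid a cycle

    if not isinstance(model, DyePairModel):
        raise TypeError("model must be a DyePairModel")
    dt_t = timescales.translational_step
    dt_r = timescales.orientational_step
    n_t = int(round(duration / dt_t)) + 1
    n_r = int(round(duration / dt_r)) + 1

    trans_rngs = (streams["donor-trans"], streams["acceptor-trans"])
    rot_rngs = (streams["donor-rot"], streams["acceptor-rot"])

    states = model.initial_translational_states(1, trans_rngs)
    positions = np.empty((n_t, 2, 3))
    positions[0] = model.global_positions(states)[0]
    for i in range(1, n_t):
        states = model.propagate_translational(states, dt_t, trans_rngs)
        positions[i] = model.global_positions(states)[0]

    dipoles = np.empty((n_r, 2, 3))
    mu = np.stack([uniform_unit_vectors(rot_rngs[0], 1)[0],
                   uniform_unit_vectors(rot_rngs[1], 1)[0]])
    dipoles[0] = mu
    D = (model.donor_rotation.diffusion, model.acceptor_rotation.diffusion)
    for i in range(1, n_r):
        for d in range(2):
            mu[d] = sphere_propagate(mu[d], D[d], dt_r, rot_rngs[d])
        dipoles[i] = mu

    return {
        "times_trans": np.arange(n_t) * dt_t,
        "positions": positions,
        "times_rot": np.arange(n_r) * dt_r,
        "dipoles": dipoles,
    }
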