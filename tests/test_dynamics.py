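"""SDE propagators: OU springs, elastic pendulum, spherical Brownian motion."""

import math

import numpy as np
import pytest
from scipy import stats

from fretshift.dynamics import (
    IntegratorConfig,
    PendulumParams,
    RotationParams,
    SpringParams,
    TimescaleConfig,
    _ou_euler_step,
    named_streams,
    ou_propagate,
    pendulum_drift_root,
    pendulum_step,
    rotational_diffusion_coefficient,
    simulate_dye_pair,
    sphere_propagate,
    sphere_step,
    spring_equilibrium_sample,
    uniform_unit_vectors,
    unit_vector_from_angles,
    angles_from_unit_vector,
)
from fretshift.models import DyePairModel, table1_model


class TestOUPropagation:
    def test_stationary_limit_moments(self, rng):
        p = SpringParams.isotropic(rate=2.0, sigma=1.5, equilibrium=(1.0, -2.0, 0.5))
        x0 = np.zeros((100_000, 3))
        x1 = ou_propagate(x0, p, dt=50.0, rng=rng)  # k dt = 100 >> 1
        sd = 1.5 / math.sqrt(2 * 2.0)
        for axis in range(3):
            mean_se = sd / math.sqrt(100_000)
            assert x1[:, axis].mean() == pytest.approx(p.equilibrium[axis],
                                                       abs=4 * mean_se)
            assert x1[:, axis].std() == pytest.approx(sd, rel=0.02)

    def test_diffusive_small_dt_variance(self, rng):
        p = SpringParams.isotropic(rate=1.0, sigma=2.0)
        dt = 1e-4  # k dt = 1e-4
        x1 = ou_propagate(np.zeros((200_000, 3)), p, dt, rng)
        assert x1.var() == pytest.approx(p.sigma**2 * dt, rel=0.01)

    def test_autocorrelation_recovers_rate(self, rng):
        k_true = 0.8
        p = SpringParams.isotropic(rate=k_true, sigma=1.0)
        n_chains, n_steps, dt = 200, 5000, 0.1
        x = spring_equilibrium_sample(p, rng, size=n_chains)
        traj = np.empty((n_steps, n_chains))
        for i in range(n_steps):
            traj[i] = x[:, 0]
            x = ou_propagate(x, p, dt, rng)
        lags = np.arange(1, 11)
        acf = np.array([np.mean(traj[:-l] * traj[l:]) for l in lags])
        acf /= np.mean(traj * traj)
        slope = np.polyfit(lags * dt, np.log(acf), 1)[0]
        assert -slope == pytest.approx(k_true, rel=0.05)

    @pytest.mark.parametrize("k_dt", [0.01, 0.1, 1.0])
    def test_exact_transition_matches_fine_euler_oracle(self, k_dt):
        p = SpringParams.isotropic(rate=1.0, sigma=1.0, equilibrium=(0.5, 0, 0))
        dt = k_dt
        rng1 = np.random.default_rng(10)
        rng2 = np.random.default_rng(20)
        x0 = np.full((10_000, 3), 2.0)
        exact = ou_propagate(x0, p, dt, rng1)[:, 0]
        euler = x0.copy()
        n_sub = 200
        for _ in range(n_sub):
            euler = _ou_euler_step(euler, p, dt / n_sub, rng2)
        res = stats.ks_2samp(exact, euler[:, 0])
        assert res.pvalue > 0.01

    def test_zero_dt_is_identity(self, rng):
        p = SpringParams.isotropic(rate=1.0, sigma=1.0)
        x0 = np.ones((5, 3))
        assert np.array_equal(ou_propagate(x0, p, 0.0, rng), x0)

    def test_non_diagonal_matrix_rejected(self):
        K = np.array([[1.0, 0.2, 0], [0.2, 1.0, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            SpringParams.from_matrix(K, sigma=1.0)


class TestSpringEquilibrium:
    def test_isotropic_moments(self, rng):
        p = SpringParams.isotropic(rate=0.5, sigma=1.0, equilibrium=(3, 0, 0))
        s = spring_equilibrium_sample(p, rng, size=100_000)
        sd = p.stationary_sd[0]
        assert s.mean(axis=0) == pytest.approx([3, 0, 0], abs=4 * sd / 316)
        v = s.var(axis=0)
        assert v.max() / v.min() < 1.05  # symmetry of the three axes

    def test_anisotropic_variance_ratio_p_half(self, rng):
        p = SpringParams.anisotropic_equal_volume(sd=2.0, p=0.5, rate=1.0,
                                                  stiff_axis=2)
        s = spring_equilibrium_sample(p, rng, size=200_000)
        v = s.var(axis=0)
        assert v[0] / v[2] == pytest.approx(2.0, rel=0.03)
        assert v[1] / v[2] == pytest.approx(2.0, rel=0.03)
        # accessible volume preserved: geometric mean of variances = sd^2
        assert np.prod(v) ** (1 / 3) == pytest.approx(4.0, rel=0.03)

    def test_stationarity_under_propagation(self, rng):
        # one long propagation step leaves the stationary ensemble invariant
        p = SpringParams.anisotropic_equal_volume(sd=1.0, p=0.3, rate=1.0)
        s0 = spring_equilibrium_sample(p, rng, size=50_000)
        s1 = ou_propagate(s0, p, dt=0.7, rng=rng)
        for axis in range(3):
            assert stats.ks_2samp(s0[:, axis], s1[:, axis]).pvalue > 0.01


class TestPendulum:
    def test_drift_root_golden_ratio(self):
        p = PendulumParams(radial_spring=1.0, polar_spring=1.0,
                           equilibrium_radius=1.0, sigma_r=1.0,
                           sigma_theta=1.0, sigma_phi=1.0,
                           radial_correction_coefficient=1.0)
        assert pendulum_drift_root(p) == pytest.approx((1 + math.sqrt(5)) / 2)

    def test_drift_root_is_fixed_point_without_noise(self, rng):
        p = PendulumParams(radial_spring=1.0, polar_spring=1.0,
                           equilibrium_radius=1.0, sigma_r=1e-9,
                           sigma_theta=1e-9, sigma_phi=1e-9)
        r_star = pendulum_drift_root(p)
        state = np.array([[r_star, 1e-8, 0.0]])
        for _ in range(100):
            state = pendulum_step(state, p, 0.01, rng)
        assert state[0, 0] == pytest.approx(r_star, abs=1e-6)

    def test_polar_angle_decays_monotonically(self, rng):
        p = PendulumParams(radial_spring=1.0, polar_spring=2.0,
                           equilibrium_radius=1.0, sigma_r=1e-9,
                           sigma_theta=1e-9, sigma_phi=1e-9)
        state = np.array([[1.0, 1.2, 0.3]])
        thetas = [1.2]
        for _ in range(50):
            state = pendulum_step(state, p, 0.05, rng)
            thetas.append(state[0, 1])
        assert all(b < a + 1e-12 for a, b in zip(thetas, thetas[1:]))
        assert thetas[-1] < 0.1

    def test_radius_stays_positive_under_strong_noise(self, rng):
        p = PendulumParams(radial_spring=0.5, polar_spring=0.1,
                           equilibrium_radius=1.0, sigma_r=2.0,
                           sigma_theta=1.0, sigma_phi=1.0)
        state = np.column_stack([np.full(500, 0.3), np.full(500, 1.0),
                                 np.zeros(500)])
        for _ in range(200):
            state = pendulum_step(state, p, 0.05, rng)
            assert np.all(state[:, 0] > 0)

    def test_polar_marginal_matches_stationary_density(self):
        # theta-marginal of the default-like pendulum against the analytic
        # stationary law  p(theta) ~ sin(theta)^m exp(beta cos theta)
        p = PendulumParams(radial_spring=0.2, polar_spring=3.0,
                           equilibrium_radius=18.0, sigma_r=0.9,
                           sigma_theta=9.0, sigma_phi=9.0)
        m = DyePairModel(kind="pendulum", donor_pendulum=p, acceptor_pendulum=p,
                         separation=60.0)
        streams = named_streams(42)
        st_ = m.initial_translational_states(
            4000, (streams["donor-trans"], streams["acceptor-trans"]))
        th = st_[:, 0, 1]
        r_bar = st_[:, 0, 0].mean()
        beta = 2 * p.polar_spring * r_bar**2 / p.sigma_theta**2
        grid = np.linspace(1e-6, np.pi, 4000)
        pdf = np.sin(grid) * np.exp(beta * (np.cos(grid) - 1.0))
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        res = stats.ks_1samp(th, lambda q: np.interp(q, grid, cdf))
        assert res.pvalue > 0.01


class TestSphereDiffusion:
    def test_long_run_cos_theta_uniform(self, rng):
        rot = RotationParams(diffusion=1.0)
        mu = np.tile([0.0, 0.0, 1.0], (5000, 1))  # worst-case start: a pole
        samples = []
        for _ in range(20):
            mu = sphere_propagate(mu, rot.diffusion, 2.0, rng)  # 2D*dt = 4
            samples.append(mu[:, 2].copy())
        cos = np.concatenate(samples)
        assert stats.kstest(cos, stats.uniform(loc=-1, scale=2).cdf).pvalue > 0.01

    def test_one_step_preserves_uniform_law(self, rng):
        mu = uniform_unit_vectors(rng, 100_000)
        out = sphere_step(mu, RotationParams(diffusion=0.5), 0.05, rng)
        assert stats.kstest(out[:, 2],
                            stats.uniform(loc=-1, scale=2).cdf).pvalue > 0.01
        phi = np.mod(np.arctan2(out[:, 1], out[:, 0]), 2 * np.pi)
        assert stats.kstest(phi,
                            stats.uniform(scale=2 * np.pi).cdf).pvalue > 0.01

    def test_step_from_exact_pole_is_finite(self, rng):
        out = sphere_step(np.array([0.0, 0.0, 1.0]),
                          RotationParams(diffusion=1.0), 0.01, rng)
        assert np.all(np.isfinite(out))
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)

    def test_small_step_mean_square_displacement(self, rng):
        D, dt = 1.0, 1e-4  # D dt = 1e-4
        mu = uniform_unit_vectors(rng, 1_000_000)
        out = sphere_propagate(mu, D, dt, rng)
        ang = np.arccos(np.clip(np.sum(mu * out, axis=-1), -1, 1))
        assert np.mean(ang**2) == pytest.approx(4 * D * dt, rel=0.02)

    def test_norm_preserved_over_many_steps(self, rng):
        rot = RotationParams(diffusion=2.0)
        mu = uniform_unit_vectors(rng, 1000)
        worst = 0.0
        for _ in range(1000):  # 10^6 total steps
            mu = sphere_step(mu, rot, 0.01, rng)
            worst = max(worst, float(np.abs(np.linalg.norm(mu, axis=-1) - 1).max()))
        assert worst <= 1e-9

    def test_angle_vector_round_trip(self, rng):
        mu = uniform_unit_vectors(rng, 1000)
        th, ph = angles_from_unit_vector(mu)
        back = unit_vector_from_angles(th, ph)
        assert np.abs(back - mu).max() < 1e-10


class TestRotationalDiffusionCoefficient:
    def test_stokes_einstein_debye_normalization(self):
        p = RotationParams(thermal_energy=1.0, viscosity=1.0 / (8 * math.pi),
                           hydrodynamic_radius=1.0)
        assert p.diffusion == pytest.approx(1.0)

    def test_cubic_radius_scaling(self):
        small = RotationParams(thermal_energy=4.0, viscosity=1e-3,
                               hydrodynamic_radius=5.0)
        large = RotationParams(thermal_energy=4.0, viscosity=1e-3,
                               hydrodynamic_radius=10.0)
        assert small.diffusion / large.diffusion == pytest.approx(8.0)

    def test_positive_and_validated(self):
        assert rotational_diffusion_coefficient(
            RotationParams(diffusion=0.3)) == 0.3
        with pytest.raises(ValueError):
            RotationParams(diffusion=-1.0)
        with pytest.raises(ValueError):
            RotationParams(thermal_energy=1.0)


class TestTimescalesAndStreams:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            TimescaleConfig(translational_step=0.001, orientational_step=0.1)
        cfg = TimescaleConfig()
        assert cfg.orientational_step < cfg.translational_step

    def test_integrator_config_validation(self):
        with pytest.raises(ValueError):
            IntegratorConfig(scheme="milstein")

    def test_named_streams_reproducible_and_distinct(self):
        a = named_streams(77)
        b = named_streams(77)
        for name in a:
            assert a[name].random() == b[name].random()
        draws = {name: named_streams(77)[name].random() for name in a}
        assert len(set(draws.values())) == len(draws)


class TestSimulateDyePair:
    def test_near_zero_volatility_states_constant(self):
        spring = SpringParams.isotropic(rate=1.0, sigma=1e-12)
        model = DyePairModel(kind="isotropic", donor_spring=spring,
                             acceptor_spring=spring, separation=50.0)
        out = simulate_dye_pair(model, duration=1.0,
                                timescales=TimescaleConfig(0.1, 0.01),
                                streams=named_streams(3))
        drift = np.abs(out["positions"] - out["positions"][0]).max()
        assert drift < 1e-5

    def test_seed_swap_preserves_stationary_statistics(self):
        model = table1_model("isotropic")
        d = []
        for seed in (101, 202):
            streams = named_streams(seed)
            st_ = model.initial_translational_states(
                20_000, (streams["donor-trans"], streams["acceptor-trans"]))
            d.append(model.inter_dye_distances(st_))
        assert not np.allclose(d[0][:100], d[1][:100])  # different paths
        assert stats.ks_2samp(d[0], d[1]).pvalue > 0.01  # same law

    def test_translational_and_rotational_grids(self):
        model = table1_model("isotropic")
        out = simulate_dye_pair(model, duration=0.5,
                                timescales=TimescaleConfig(0.1, 0.005),
                                streams=named_streams(5))
        assert len(out["times_trans"]) == 6
        assert len(out["times_rot"]) == 101
        norms = np.linalg.norm(out["dipoles"], axis=-1)
        assert np.abs(norms - 1).max() < 1e-9

    def test_spring_distance_unimodal_pendulum_bimodal(self):
        from fretshift.stats import dip_test
        streams = named_streams(11)
        rngs = (streams["donor-trans"], streams["acceptor-trans"])
        iso = table1_model("isotropic")
        d_iso = iso.inter_dye_distances(
            iso.initial_translational_states(4000, rngs))
        _, p_iso = dip_test(d_iso, rng=np.random.default_rng(3), n_max=1000)
        assert p_iso > 0.05  # Rayleigh-like: unimodality not rejected
        pend = table1_model("pendulum-static")
        d_pend = pend.inter_dye_distances(
            pend.initial_translational_states(4000, rngs))
        _, p_pend = dip_test(d_pend, rng=np.random.default_rng(3), n_max=1000)
        assert p_pend < 0.05  # two swing configurations: bimodal
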