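"""Orientation factor, transfer rates, and CTMC event sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.linalg import expm

from fretshift.dynamics import RotationParams, uniform_unit_vectors
from fretshift.photophysics import (
    KAPPA_SQ_ISOTROPIC_MEAN,
    ExcitationRecord,
    KappaPath,
    PhotophysicsParams,
    build_rate_matrix,
    forster_radius6,
    integrated_hazard,
    kappa_factor,
    sample_dynamic_events,
    sample_event_by_inversion,
    sample_excitation_event,
    sample_kappa_sq_static,
    sample_static_events,
    static_efficiency,
    time_dependent_efficiency,
    transfer_rate,
)

X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


class TestKappaFactor:
    def test_collinear_maximum(self):
        assert kappa_factor(X, X, X) == pytest.approx(-2.0)
        assert kappa_factor(X, X, X) ** 2 == pytest.approx(4.0)

    def test_mutually_orthogonal_no_transfer(self):
        assert kappa_factor(X, Y, Z) == pytest.approx(0.0)

    def test_parallel_perpendicular_to_separation(self):
        assert kappa_factor(Y, Y, X) == pytest.approx(1.0)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            kappa_factor(2 * X, Y, Z)

    def test_monte_carlo_mean_two_thirds(self):
        rng = np.random.default_rng(8)
        k2 = sample_kappa_sq_static(rng, 1_000_000)
        se = k2.std() / 1000.0
        assert k2.mean() == pytest.approx(2.0 / 3.0, abs=3 * se)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_in_zero_four(self, seed):
        rng = np.random.default_rng(seed)
        k2 = kappa_factor(uniform_unit_vectors(rng, 100),
                          uniform_unit_vectors(rng, 100),
                          uniform_unit_vectors(rng, 100)) ** 2
        assert np.all(k2 >= 0.0) and np.all(k2 <= 4.0)


class TestRatesAndEfficiencies:
    def test_forster_radius6_linearity(self, photo):
        C = photo.forster_constant
        assert forster_radius6(C, 0.0) == 0.0
        assert forster_radius6(C, 2.0 / 3.0) == pytest.approx(
            photo.reference_forster_radius**6)
        assert forster_radius6(C, 1.0) == pytest.approx(2 * forster_radius6(C, 0.5))

    def test_transfer_rate_at_reference_radius(self, photo):
        R0 = photo.reference_forster_radius
        assert transfer_rate(R0, 2 / 3, photo) == pytest.approx(photo.donor_decay)
        assert transfer_rate(R0 / 2, 2 / 3, photo) == pytest.approx(
            64 * photo.donor_decay)
        assert transfer_rate(1e6, 2 / 3, photo) == pytest.approx(0.0, abs=1e-12)

    def test_transfer_rate_rejects_nonpositive_distance(self, photo):
        with pytest.raises(ValueError):
            transfer_rate(0.0, 2 / 3, photo)

    def test_static_efficiency_landmarks(self, photo):
        R0 = photo.reference_forster_radius
        assert static_efficiency(R0, photo) == 0.5
        assert static_efficiency(0.0, photo) == 1.0
        assert static_efficiency(2 * R0, photo) == pytest.approx(1.0 / 65.0)


class TestPathEfficiency:
    def test_constant_rate_equal_to_donor_decay(self, photo):
        # k_ET = k_D throughout => efficiency 1/2 for every horizon
        R0 = photo.reference_forster_radius
        path = KappaPath(np.linspace(0, 10, 101), np.full(101, 2 / 3), R0)
        for T in (0.5, 2.0, 10.0):
            assert time_dependent_efficiency(path, T, photo) == pytest.approx(0.5)

    def test_zero_path_zero_efficiency(self, photo):
        path = KappaPath(np.linspace(0, 5, 51), np.zeros(51), 45.0)
        assert time_dependent_efficiency(path, 5.0, photo) == 0.0

    def test_half_interval_transfer_gives_one_third(self, photo):
        R0 = photo.reference_forster_radius
        t = np.linspace(0, 2, 200_001)
        k2 = np.where(t <= 1.0, 2 / 3, 0.0)
        path = KappaPath(t, k2, R0)
        assert time_dependent_efficiency(path, 2.0, photo) == pytest.approx(
            1.0 / 3.0, abs=1e-4)

    def test_equals_static_efficiency_in_homogeneous_regime(self, photo):
        # with kappa^2 pinned at 2/3 the path formula collapses to Eq.-5 form
        for r in (30.0, 40.0, 55.0):
            path = KappaPath(np.linspace(0, 8, 81), np.full(81, 2 / 3), r)
            assert time_dependent_efficiency(path, 8.0, photo) == pytest.approx(
                float(static_efficiency(r, photo)), rel=1e-9)

    def test_path_shorter_than_horizon_rejected(self, photo):
        path = KappaPath(np.linspace(0, 1, 11), np.full(11, 2 / 3), 40.0)
        with pytest.raises(ValueError):
            time_dependent_efficiency(path, 2.0, photo)


class TestIntegratedHazard:
    def test_zero_and_constant_paths(self, photo):
        t = np.linspace(0, 4, 41)
        assert integrated_hazard(KappaPath(t, np.zeros(41), 40.0), 4.0,
                                 photo) == 0.0
        const = KappaPath(t, np.full(41, 2 / 3), photo.reference_forster_radius)
        assert integrated_hazard(const, 3.0, photo) == pytest.approx(
            photo.donor_decay * 3.0)

    def test_matches_refined_grid_oracle(self, photo):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 5, 501)
        k2 = np.interp(t, np.linspace(0, 5, 11), rng.uniform(0, 4, 11))
        coarse = KappaPath(t, k2, 42.0)
        t_fine = np.linspace(0, 5, 5001)
        fine = KappaPath(t_fine, np.interp(t_fine, t, k2), 42.0)
        for horizon in (1.3, 2.7, 5.0):
            a = integrated_hazard(coarse, horizon, photo)
            b = integrated_hazard(fine, horizon, photo)
            assert a == pytest.approx(b, rel=1e-6)

    def test_monotone_nondecreasing(self, photo):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 3, 301)
        path = KappaPath(t, rng.uniform(0, 4, 301), 45.0)
        vals = [integrated_hazard(path, h, photo) for h in np.linspace(0, 3, 30)]
        assert vals[0] == 0.0
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestRateMatrix:
    def test_generator_structure(self, photo):
        Q = build_rate_matrix(0.7, photo)
        assert Q.shape == (4, 4)
        assert np.allclose(Q.sum(axis=1), 0.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.all(off >= 0)
        assert np.all(Q[2] == 0) and np.all(Q[3] == 0)  # FD, FA absorbing

    def test_no_transfer_exits_only_to_fd(self, photo):
        Q = build_rate_matrix(0.0, photo)
        assert Q[0, 1] == 0.0
        assert Q[0, 2] == photo.donor_decay

    def test_negative_rate_rejected(self, photo):
        with pytest.raises(ValueError):
            build_rate_matrix(-0.1, photo)

    def test_matrix_exponential_matches_sampler_occupation(self, photo):
        # k_ET = k_D; occupation probabilities at t = 1/k_D from expm vs the
        # empirical state frequencies of the homogeneous event sampler
        kD = photo.donor_decay
        R0 = photo.reference_forster_radius
        Q = build_rate_matrix(kD, photo)
        t_obs = 1.0 / kD
        probs = expm(Q * t_obs)[0]
        rng = np.random.default_rng(9)
        n = 100_000
        acc, dwell, delay = sample_static_events(np.full(n, R0), 2 / 3, photo, rng)
        state = np.full(n, 2)  # FD
        still_d = dwell > t_obs
        state[still_d] = 0
        to_a = acc & ~still_d
        state[to_a & (delay > t_obs)] = 1
        state[to_a & (delay <= t_obs)] = 3
        for s in range(4):
            freq = np.mean(state == s)
            se = math.sqrt(max(probs[s] * (1 - probs[s]), 1e-9) / n)
            assert freq == pytest.approx(probs[s], abs=max(3 * se, 1e-3))


class TestStaticEventSampler:
    def test_homogeneous_branching_and_dwell(self, photo):
        rng = np.random.default_rng(10)
        r = 1.1 * photo.reference_forster_radius
        k_et = float(transfer_rate(r, 2 / 3, photo))
        k_tot = photo.donor_decay + k_et
        n = 100_000
        acc, dwell, delay = sample_static_events(np.full(n, r), 2 / 3, photo, rng)
        p_acc = k_et / k_tot
        assert acc.mean() == pytest.approx(p_acc, abs=3 * math.sqrt(p_acc / n))
        assert stats.kstest(dwell, stats.expon(scale=1 / k_tot).cdf).pvalue > 0.01
        # competing exponentials: branch and exit time are independent
        assert stats.ks_2samp(dwell[acc], dwell[~acc]).pvalue > 0.01

    def test_zero_distance_reduces_to_acceptor_chain(self, photo):
        rng = np.random.default_rng(11)
        acc, dwell, delay = sample_static_events(np.zeros(50_000), 2 / 3,
                                                 photo, rng)
        assert np.all(acc)
        assert np.all(dwell == 0.0)
        assert stats.kstest(delay, stats.expon(
            scale=1 / photo.acceptor_decay).cdf).pvalue > 0.01

    def test_donor_only_mean_delay(self, photo):
        rng = np.random.default_rng(12)
        n = 50_000
        acc, dwell, delay = sample_static_events(
            np.full(n, 40.0), 0.0, photo, rng)  # kappa^2 = 0: no transfer
        assert not np.any(acc)
        tau = 1.0 / photo.donor_decay
        assert delay.mean() == pytest.approx(tau, abs=3 * tau / math.sqrt(n))


class TestDynamicEventSampler:
    def test_thinning_matches_inversion_oracle(self, photo):
        rng = np.random.default_rng(13)
        n = 10_000
        rejections = 0
        for trial in range(20):
            r0 = float(rng.uniform(30, 55))
            nodes = np.linspace(0, 100, int(rng.integers(4, 12)))
            vals = rng.uniform(0, 4, nodes.size)
            k2_fn = lambda t: np.interp(t, nodes, vals)
            grid = np.linspace(0, 100, 8001)
            path = KappaPath(grid, k2_fn(grid), r0)
            inv = sample_event_by_inversion(path, photo,
                                            np.random.default_rng(1000 + trial),
                                            size=n)
            inv = inv[~np.isnan(inv)]
            acc, dwell, _, _ = sample_dynamic_events(
                np.full(n, r0), photo, rng=np.random.default_rng(2000 + trial),
                kappa_path=k2_fn)
            if stats.ks_2samp(inv, dwell).pvalue < 0.001:
                rejections += 1
        assert rejections == 0

    def test_zero_distance_acceptor_only(self, photo):
        rot = RotationParams(diffusion=0.1)
        rng = np.random.default_rng(14)
        acc, dwell, delay, _ = sample_dynamic_events(
            np.zeros(20_000), photo, rot, rot, rng)
        assert np.all(acc)
        assert stats.kstest(delay, stats.expon(
            scale=1 / photo.acceptor_decay).cdf).pvalue > 0.01

    def test_fast_rotation_approaches_dynamic_averaging(self, photo):
        # very fast reorientation averages the hazard to its kappa^2 = 2/3
        # value, so the acceptor fraction approaches the static efficiency
        rot = RotationParams(diffusion=500.0)
        rng = np.random.default_rng(15)
        r0 = photo.reference_forster_radius
        acc, dwell, _, kbar = sample_dynamic_events(
            np.full(30_000, r0), photo, rot, rot, rng)
        assert acc.mean() == pytest.approx(0.5, abs=0.01)
        assert kbar[dwell > 0].mean() == pytest.approx(2 / 3, abs=0.02)

    def test_path_mean_kappa_bounded(self, photo):
        rot = RotationParams(diffusion=0.05)
        rng = np.random.default_rng(16)
        acc, dwell, _, kbar = sample_dynamic_events(
            np.full(5000, 40.0), photo, rot, rot, rng)
        assert np.all(kbar >= 0) and np.all(kbar <= 4.0)


class TestExcitationRecord:
    def test_static_event_record(self, photo):
        rec = sample_excitation_event(40.0, photo, np.random.default_rng(1))
        assert rec.outcome in ("donor_photon", "acceptor_photon")
        assert rec.emission_delay >= rec.donor_dwell >= 0
        assert rec.path_mean_kappa_sq == pytest.approx(2 / 3)

    def test_dynamic_event_record(self, photo):
        rot = RotationParams(diffusion=0.1)
        rec = sample_excitation_event(40.0, photo, np.random.default_rng(2),
                                      donor_rotation=rot, acceptor_rotation=rot)
        assert 0.0 <= rec.path_mean_kappa_sq <= 4.0

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            ExcitationRecord("lost_photon", 1.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            ExcitationRecord("donor_photon", 2.0, 1.0, 0.5)


class TestKappaPathContainer:
    def test_validation(self):
        with pytest.raises(ValueError):
            KappaPath(np.array([0.0, 1.0]), np.array([0.0, 5.0]), 40.0)
        with pytest.raises(ValueError):
            KappaPath(np.array([1.0, 2.0]), np.array([1.0, 1.0]), 40.0)
        with pytest.raises(ValueError):
            KappaPath(np.array([0.0, 1.0, 1.0]), np.ones(3), 40.0)
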