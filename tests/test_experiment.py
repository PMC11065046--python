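"""Burst simulation: controls, estimators, determinism, and schedules."""

import math

import numpy as np
import pandas as pd
import pytest

from fretshift.dynamics import SpringParams
from fretshift.experiment import (
    BurstConfig,
    estimate_intensity_fret,
    estimate_lifetime_fret,
    run_burst,
    run_experiment,
    scheduled_burst_count,
)
from fretshift.models import DyePairModel, table1_model


def rigid_model(separation, sd=1e-8):
    """Dye pair with (numerically) frozen positions at a given separation."""
    spring = SpringParams.from_stationary_sd(sd, rate=1.0)
    return DyePairModel(kind="isotropic", donor_spring=spring,
                        acceptor_spring=spring, separation=separation)


SMALL = BurstConfig(burst_duration=1.0e5, detection_efficiency=0.02)


class TestEstimators:
    def test_intensity_examples(self):
        assert estimate_intensity_fret(3, 1) == pytest.approx(0.75)
        assert estimate_intensity_fret(0, 17) == 0.0
        with pytest.raises(ValueError):
            estimate_intensity_fret(0, 0)

    def test_intensity_unbiased_under_binomial_sampling(self, rng):
        counts = rng.binomial(100, 0.4, size=10_000)
        est = estimate_intensity_fret(counts, 100 - counts)
        assert est.mean() == pytest.approx(0.4, abs=3 * 0.049 / 100)

    def test_lifetime_examples(self):
        assert estimate_lifetime_fret(4.0, 4.0) == 0.0
        assert estimate_lifetime_fret(2.0, 4.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            estimate_lifetime_fret(1.0, 0.0)

    def test_lifetime_recovers_homogeneous_efficiency(self, rng, photo):
        # tau' = 1/(k_D + k_ET)  =>  1 - tau'/tau_0 = k_ET/(k_D + k_ET)
        k_et = 0.4
        n = 50_000
        dwells = rng.exponential(1.0 / (photo.donor_decay + k_et), n)
        est = estimate_lifetime_fret(dwells.mean(), 1.0 / photo.donor_decay)
        truth = k_et / (photo.donor_decay + k_et)
        assert est == pytest.approx(truth, abs=3 * truth / math.sqrt(n))


class TestBurstSchedule:
    def test_seven_hours_at_one_per_second(self):
        cfg = BurstConfig()
        assert cfg.total_duration == 7 * 3600
        assert 24_900 <= scheduled_burst_count(cfg) <= 25_200

    def test_burst_must_fit_in_schedule_slot(self):
        with pytest.raises(ValueError):
            BurstConfig(burst_duration=2e9, bursts_per_second=1.0)

    def test_detection_efficiency_validated(self):
        with pytest.raises(ValueError):
            BurstConfig(detection_efficiency=1.5)
        pair = BurstConfig(detection_efficiency=(0.1, 0.2))
        assert pair.efficiencies == (0.1, 0.2)


class TestControls:
    def test_donor_only_no_fret_unit_lifetime(self, photo):
        model = rigid_model(40.0)
        res = run_experiment(model, photo, SMALL, n_bursts=200, seed=4,
                             donor_only=True)
        df = res.usable
        assert (df["I_A"] == 0).all()
        assert df["E_intensity"].mean() == pytest.approx(0.0, abs=1e-12)
        assert df["tau_norm"].mean() == pytest.approx(1.0, abs=0.02)

    def test_lifetime_normalization_tightens_with_photons(self, photo):
        model = rigid_model(40.0)
        spreads = []
        for eta in (0.01, 0.2):
            cfg = BurstConfig(burst_duration=1.0e5, detection_efficiency=eta)
            res = run_experiment(model, photo, cfg, n_bursts=150, seed=5,
                                 donor_only=True)
            spreads.append(res.usable["tau_norm"].std())
        assert spreads[1] < 0.5 * spreads[0]

    def test_coincident_dyes_transfer_every_photon(self, photo):
        model = rigid_model(1e-5, sd=1e-9)
        res = run_experiment(model, photo, SMALL, n_bursts=100, seed=6)
        df = res.bursts
        assert (df["I_D"] == 0).all()
        assert (df["I_A"] > 0).all()
        # no donor photons: no lifetime estimate, bursts excluded from shift
        assert not df["usable"].any()

    def test_static_system_scatters_on_static_line(self, photo):
        # frozen distance + kappa^2 = 2/3: mean perpendicular shift must sit
        # at the shot-noise floor (zero within 2 SE over the bursts)
        from fretshift.shift import ShiftConfig, shift_distribution
        model = rigid_model(photo.reference_forster_radius)
        cfg = BurstConfig(burst_duration=1.0e6, detection_efficiency=0.5)
        res = run_experiment(model, photo, cfg, n_bursts=400, seed=7)
        shift = shift_distribution(res, ShiftConfig("perpendicular"))
        se = shift.std / math.sqrt(shift.n_bursts)
        assert abs(shift.mean) < 2 * se + 1e-4


class TestEngineInvariants:
    def test_same_seed_identical_tables(self, photo):
        model = table1_model("pendulum-dynamic")
        a = run_experiment(model, photo, SMALL, n_bursts=40, seed=9)
        b = run_experiment(model, photo, SMALL, n_bursts=40, seed=9)
        pd.testing.assert_frame_equal(a.bursts, b.bursts)

    def test_different_seed_different_tables(self, photo):
        model = table1_model("isotropic")
        a = run_experiment(model, photo, SMALL, n_bursts=40, seed=9)
        b = run_experiment(model, photo, SMALL, n_bursts=40, seed=10)
        assert not a.bursts["E_intensity"].equals(b.bursts["E_intensity"])

    def test_halving_detection_halves_counts_not_fret(self, photo):
        model = table1_model("isotropic")
        means = {}
        for eta in (0.04, 0.02):
            cfg = BurstConfig(burst_duration=1.0e6, detection_efficiency=eta)
            res = run_experiment(model, photo, cfg, n_bursts=400, seed=11)
            df = res.usable
            means[eta] = (df["I_D"].add(df["I_A"]).mean(),
                          df["E_intensity"].mean(),
                          df["E_intensity"].sem())
        assert means[0.04][0] / means[0.02][0] == pytest.approx(2.0, rel=0.05)
        se = math.hypot(means[0.04][2], means[0.02][2])
        assert abs(means[0.04][1] - means[0.02][1]) < 2 * se

    def test_photon_conservation_and_counts(self, photo):
        model = table1_model("pendulum-static")
        res = run_experiment(model, photo, SMALL, n_bursts=60, seed=12)
        df = res.bursts
        assert ((df["I_D"] + df["I_A"]) <= df["n_events"]).all() or \
               ((df["I_D"] + df["I_A"]) == df["n_events"]).all()
        assert (df["n_events"] <= SMALL.pulses_per_burst).all()

    def test_photon_table_consistent_with_counts(self, photo):
        model = table1_model("isotropic")
        res = run_experiment(model, photo, SMALL, n_bursts=20, seed=13,
                             store_photons=True)
        counts = res.photons.groupby(["burst_id", "channel"]).size()
        for b in range(20):
            row = res.bursts.iloc[b]
            assert counts.get((b, "donor"), 0) == row["I_D"]
            assert counts.get((b, "acceptor"), 0) == row["I_A"]

    def test_min_photon_exclusion(self, photo):
        model = table1_model("isotropic")
        cfg = BurstConfig(burst_duration=2e4, detection_efficiency=0.005,
                          min_photons=10)
        res = run_experiment(model, photo, cfg, n_bursts=200, seed=14)
        df = res.bursts
        assert (df.loc[df["usable"], "I_D"] + df.loc[df["usable"], "I_A"]
                >= 10).all()
        assert (~df.loc[df["I_D"] + df["I_A"] < 10, "usable"]).all()

    def test_unequal_channel_efficiencies_not_silently_wrong(self, photo):
        model = table1_model("isotropic")
        cfg = BurstConfig(detection_efficiency=(0.01, 0.02))
        with pytest.raises(NotImplementedError):
            run_experiment(model, photo, cfg, n_bursts=5, seed=1)

    def test_run_burst_single_record(self, photo):
        rec = run_burst(SMALL, table1_model("isotropic"), photo, seed=15)
        assert rec.I_D + rec.I_A == pytest.approx(
            SMALL.pulses_per_burst * 0.02, rel=0.5)
        assert 0.0 <= rec.E_intensity <= 1.0

    def test_stationary_pool_path_matches_propagation_path(self, photo):
        # pendulum bursts via the stationary-pool fast path must have the
        # same burst statistics as explicit gap propagation (horizon larger
        # than the pulse period forces the slow path)
        from scipy.stats import ks_2samp
        from dataclasses import replace
        fast_model = table1_model("pendulum-static")
        slow_model = replace(fast_model, relaxation_horizon=51.0)
        cfg = BurstConfig(burst_duration=2.0e5, detection_efficiency=0.02)
        a = run_experiment(fast_model, photo, cfg, n_bursts=150, seed=16)
        b = run_experiment(slow_model, photo, cfg, n_bursts=150, seed=16)
        res = ks_2samp(a.usable["E_intensity"], b.usable["E_intensity"])
        assert res.pvalue > 0.01
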