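"""Generator contracts: point-process validity, determinism, known moments."""

import numpy as np
import pandas as pd
import pytest

import spikepert as sp
from spikepert.loads import LoadCondition, all_conditions, loaded_conditions
from spikepert.simulate import (
    AreaSpec,
    SimConfig,
    simulate_unit,
    simulate_population,
    simulate_kinematics,
    kinematic_trajectory,
    simulate_emg,
    evoked_profile,
    epoch_evoked_factor,
)


def _area(**kw):
    base = dict(area_name="test", n_units=2, baseline_rate=20.0,
                true_onset_latency=20.0, peak_amplitude=100.0)
    base.update(kw)
    return AreaSpec(**base)


def _config(**kw):
    base = dict(areas=[_area()], seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestLoadGeometry:
    def test_nine_conditions_one_null(self):
        conds = all_conditions()
        assert len(conds) == 9
        assert sum(c.is_null for c in conds) == 1
        assert len(loaded_conditions()) == 8

    def test_eight_distinct_directions(self):
        angles = sorted(c.angle_rad for c in loaded_conditions())
        assert len(set(np.round(angles, 12))) == 8


class TestSimulateUnit:
    def test_homogeneous_poisson_limit(self):
        # no evoked component: pooled rate must match the baseline
        spec = _area(peak_amplitude=0.0, baseline_rate=20.0)
        cfg = _config(areas=[spec], trial_window=(-200.0, 800.0),
                      n_trials_posture=200)
        rng = np.random.default_rng(0)
        rec = simulate_unit(spec, [("posture", loaded_conditions()[0])], cfg, rng)
        trials = rec.trials[("posture", loaded_conditions()[0].key)]
        total = sum(len(t) for t in trials)
        t_total_s = 200 * 1.0
        rate = total / t_total_s
        se = np.sqrt(20.0 / t_total_s)
        assert abs(rate - 20.0) < 3 * se

    def test_spikes_sorted_and_within_window(self):
        spec = _area()
        cfg = _config(areas=[spec])
        rng = np.random.default_rng(1)
        rec = simulate_unit(spec, [("posture", c) for c in all_conditions()], cfg, rng)
        for trains in rec.trials.values():
            for t in trains:
                assert np.all(np.diff(t) >= 0)
                assert t.size == 0 or (t[0] >= -300.0 and t[-1] <= 300.0)

    def test_thinning_matches_time_rescaling_oracle(self):
        """Empirical intensity of the thinning sampler matches an independent
        inverse-CDF (time-rescaling) sampler binwise."""
        spec = _area(baseline_rate=10.0, peak_amplitude=80.0,
                     unit_latency_jitter_sd=0.0, tuning_width=1.0)
        cfg = _config(areas=[spec], n_trials_posture=3000)
        load = loaded_conditions()[0]
        rng = np.random.default_rng(7)
        rec = simulate_unit(spec, [("posture", load)], cfg, rng,
                            unit_id="u")
        trains = rec.trials[("posture", load.key)]
        # oracle: inhomogeneous sampling by inverting the cumulative intensity
        truth = rec.truth
        from spikepert.loads import condition_tuning
        tun = condition_tuning(load, truth.preferred_angle_rad)
        grid = np.arange(-300.0, 300.0, 0.5)
        lam = 10.0 + tun * 80.0 * evoked_profile(grid - truth.latency_ms, 1.0, 40.0)
        cum = np.concatenate([[0.0], np.cumsum(lam) * 0.5 / 1000.0])
        rng2 = np.random.default_rng(8)
        oracle_counts = np.zeros(grid.size)
        n_rep = 3000
        total_mass = cum[-1]
        n_events = rng2.poisson(total_mass, size=n_rep)
        for n in n_events:
            u = rng2.uniform(0, total_mass, size=n)
            idx = np.searchsorted(cum, u) - 1
            np.add.at(oracle_counts, np.clip(idx, 0, grid.size - 1), 1)
        # compare binned (10 ms) empirical rates of the two samplers
        edges = np.arange(-300.0, 301.0, 10.0)
        thin_all = np.concatenate(trains)
        h_thin, _ = np.histogram(thin_all, bins=edges)
        h_thin = h_thin / (3000 * 0.01)
        h_orc = oracle_counts.reshape(-1, 20).sum(axis=1) / (n_rep * 0.01)
        expected = lam.reshape(-1, 20).mean(axis=1)
        se = np.sqrt(expected / (3000 * 0.01)) + 1e-6
        assert np.all(np.abs(h_thin - expected) < 5 * se)
        assert np.all(np.abs(h_thin - h_orc) < 6 * se)

    def test_task_gain_scales_epoch_counts_linearly(self):
        spec = _area(peak_amplitude=120.0, unit_latency_jitter_sd=0.0,
                     task_gain={"posture": 1.0, "movie": 0.5, "in": 1.0, "out": 1.0})
        cfg = _config(areas=[spec], n_trials_posture=1000, n_trials_movie=1000)
        load = loaded_conditions()[0]
        rng = np.random.default_rng(11)
        rec = simulate_unit(spec, [("posture", load), ("movie", load)], cfg, rng)

        def evoked_count(task):
            trains = rec.trials[(task, load.key)]
            resp = np.mean([((t >= 50) & (t < 100)).sum() for t in trains])
            base = np.mean([((t >= -100) & (t < 0)).sum() for t in trains]) / 2.0
            return resp - base

        ep, em = evoked_count("posture"), evoked_count("movie")
        assert ep > 0
        assert abs(em / ep - 0.5) < 0.12

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_unit(_area(), [], _config(), np.random.default_rng(0))

    def test_negative_intensity_config_rejected(self):
        # movie gain < 1 dips the intensity below zero at tiny baselines
        spec = _area(baseline_rate=0.5, peak_amplitude=200.0,
                     task_gain={"posture": 1.0, "movie": 0.0, "in": 1.0, "out": 1.0},
                     task_delay_ms={"posture": 0.0, "movie": 30.0, "in": 0.0, "out": 0.0})
        with pytest.raises(ValueError, match="negative intensity"):
            simulate_unit(spec, [("posture", loaded_conditions()[0])],
                          _config(areas=[spec]), np.random.default_rng(0))


class TestSimulatePopulation:
    def test_same_seed_identical_datasets(self):
        cfg = _config(areas=[_area(n_units=3)])
        a = simulate_population(cfg, tasks=("posture",))
        b = simulate_population(cfg, tasks=("posture",))
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        pd.testing.assert_frame_equal(a.reversal_times, b.reversal_times)
        assert a.ground_truth == b.ground_truth

    def test_unit_bookkeeping(self):
        areas = [_area(area_name=f"a{i}", n_units=5) for i in range(3)]
        ds = simulate_population(_config(areas=areas), tasks=("posture",),
                                 with_kinematics=False)
        assert ds.spikes["unit_id"].nunique() == 15
        assert set(ds.ground_truth) == set(ds.spikes["unit_id"].unique())

    def test_sidecar_latencies_sample_mean(self):
        spec = _area(n_units=60, true_onset_latency=25.0, unit_latency_jitter_sd=1.5)
        ds = simulate_population(_config(areas=[spec]), tasks=("posture",),
                                 with_kinematics=False)
        lats = np.array([v["latency_ms"] for v in ds.ground_truth.values()])
        assert abs(lats.mean() - 25.0) < 2 * 1.5 / np.sqrt(60)

    def test_duplicate_area_names_rejected(self):
        areas = [_area(area_name="x"), _area(area_name="x")]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_population(_config(areas=areas))

    def test_in_out_use_preferred_load_only(self, small_dataset):
        cfg = _config(areas=[_area(n_units=2)])
        ds = simulate_population(cfg, tasks=("in", "out"), with_kinematics=False)
        for uid, g in ds.spikes.groupby("unit_id"):
            loads = g[["shoulder_load", "elbow_load"]].drop_duplicates()
            assert len(loads) == 1
            truth = ds.ground_truth[uid]
            assert loads.iloc[0]["shoulder_load"] == truth["ptd_shoulder"]


class TestKinematics:
    def test_zero_target_correlation_gives_independence(self):
        cfg = _config(target_unit_kinematic_correlation=0.0)
        rng = np.random.default_rng(2)
        counts = rng.poisson(5.0, size=5000)
        revs = np.array([simulate_kinematics(c, 5.0, cfg, rng) for c in counts])
        r = np.corrcoef(counts, revs)[0, 1]
        assert abs(r) < 0.05

    def test_generative_correlation_recovered(self):
        """Median per-unit correlation targets the configured rho."""
        cfg = _config(target_unit_kinematic_correlation=-0.11)
        rng = np.random.default_rng(3)
        med = []
        for _ in range(500):
            counts = rng.poisson(8.0, size=200)
            revs = np.array([simulate_kinematics(c, 8.0, cfg, rng) for c in counts])
            med.append(np.corrcoef(counts, revs)[0, 1])
        assert abs(np.median(med) - (-0.11)) < 0.03

    def test_trajectory_argmax_equals_reversal_time(self):
        cfg = _config()
        rng = np.random.default_rng(4)
        for _ in range(100):
            t_rev = float(rng.integers(60, 280))
            traj = kinematic_trajectory(t_rev, cfg, direction_rad=rng.uniform(0, 6.28))
            d = traj.distance_from_start()
            assert traj.time_ms[int(np.argmax(d))] == t_rev


class TestEMG:
    def test_zero_gain_never_crosses_threshold(self):
        cfg = _config()
        rng = np.random.default_rng(5)
        envs = []
        for _ in range(200):
            t, raw = simulate_emg(cfg, rng, gain=0.0)
            envs.append(sp.preprocess_emg(raw, cfg.emg_fs_hz, time_ms=t).envelope)
        res = sp.onset_threshold(t, np.mean(envs, axis=0))
        assert res.onset_ms is None

    def test_doubling_envelope_doubles_rectified_output(self):
        cfg = _config()
        t, a = simulate_emg(_config(emg_baseline=1.0), np.random.default_rng(6), gain=2.0)
        _, b = simulate_emg(_config(emg_baseline=2.0), np.random.default_rng(6), gain=4.0)
        assert np.allclose(np.abs(b), 2.0 * np.abs(a))

    def test_low_sampling_rate_rejected(self):
        cfg = _config(emg_fs_hz=250.0)
        with pytest.raises(ValueError):
            simulate_emg(cfg, np.random.default_rng(0))
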