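"""Onset detectors and bootstrap rank-ordering."""

import numpy as np
import pytest

from spikepert.latency import (
    baseline_stats,
    onset_threshold,
    onset_running_ttest,
    bootstrap_rank,
)


def smooth_noise(rng, n, scale=1.0, tau=10):
    """Correlated Gaussian noise resembling kernel-smoothed baseline activity."""
    w = np.exp(-np.arange(4 * tau) / tau)
    w /= w.sum()
    x = np.convolve(rng.normal(size=n + w.size), w, mode="full")[w.size:n + w.size]
    return scale * x / x.std()


class TestBaselineStats:
    def test_constant(self):
        t = np.arange(-150.0, 50.0)
        m, s = baseline_stats(t, np.full_like(t, 10.0))
        assert (m, s) == (10.0, 0.0)

    def test_alternating_hand_formula(self):
        t = np.arange(-99.5, 0.0)  # exactly 100 points inside [-100, 0]
        x = np.where(np.arange(t.size) % 2 == 0, 0.0, 20.0)
        m, s = baseline_stats(t, x)
        assert m == pytest.approx(10.0)
        assert s == pytest.approx(10.0 * np.sqrt(100 / 99))  # ~10.05

    def test_large_sample_consistency(self, rng):
        t = np.linspace(-100.0, 0.0, 100_000)
        x = rng.normal(5.0, 2.0, t.size)
        m, s = baseline_stats(t, x)
        assert abs(m - 5.0) < 0.05 and abs(s - 2.0) < 0.02


class TestOnsetThreshold:
    def test_step_detected_at_step_time(self):
        t = np.arange(-100.0, 200.0)
        x = np.where(t >= 30.0, 20.0, 10.0)
        res = onset_threshold(t, x, baseline=(10.0, 1.0))
        assert res.onset_ms == 30.0

    def test_short_excursion_rejected_by_persistence(self):
        t = np.arange(-100.0, 200.0)
        x = np.full_like(t, 10.0)
        x[(t >= 40) & (t < 50)] = 30.0  # 10 ms wide only
        res = onset_threshold(t, x, baseline=(10.0, 1.0))
        assert res.onset_ms is None

    def test_zero_sd_baseline_flagged(self):
        t = np.arange(-100.0, 200.0)
        x = np.where(t >= 25.0, 11.0, 10.0)
        res = onset_threshold(t, x)
        assert res.sd_was_zero
        assert res.onset_ms == 25.0

    def test_threshold_monotone_in_k(self, rng):
        t = np.arange(-100.0, 300.0)
        for _ in range(200):
            x = 10.0 + smooth_noise(rng, t.size) + np.where(
                t > rng.integers(10, 150), rng.uniform(1, 6), 0.0)
            o3 = onset_threshold(t, x, k=3).onset_ms
            o4 = onset_threshold(t, x, k=4).onset_ms
            assert o4 is None or (o3 is not None and o3 <= o4)

    def test_translation_equivariance(self, rng):
        t = np.arange(-100.0, 300.0)
        x = 10.0 + smooth_noise(rng, t.size) + np.where(t > 60, 8.0, 0.0)
        base = onset_threshold(t, x).onset_ms
        shift = 37.0
        shifted = onset_threshold(t + shift, x,
                                  baseline_window=(-100.0 + shift, 0.0 + shift),
                                  search_start_ms=shift).onset_ms
        assert shifted == base + shift


class TestRunningTTest:
    def test_no_departure_gives_none(self):
        t = np.arange(-100.0, 200.0)
        traces = np.full((10, t.size), 3.0)
        res = onset_running_ttest(t, traces, reference_level=3.0)
        assert res.onset_ms is None

    def test_step_ensemble_detected(self, rng):
        t = np.arange(-100.0, 200.0)
        traces = rng.normal(0, 1.0, size=(50, t.size))
        traces[:, t >= 40.0] += 5.0
        res = onset_running_ttest(t, traces, reference_level=0.0)
        assert abs(res.onset_ms - 40.0) <= 2.0

    def test_alpha_monotonicity(self, rng):
        t = np.arange(-100.0, 200.0)
        for _ in range(50):
            traces = rng.normal(0, 1.0, size=(12, t.size))
            traces[:, t >= rng.integers(20, 120)] += rng.uniform(0.3, 1.5)
            loose = onset_running_ttest(t, traces, alpha=0.05).onset_ms
            strict = onset_running_ttest(t, traces, alpha=0.01).onset_ms
            assert strict is None or (loose is not None and loose <= strict)

    def test_directional_gate(self):
        # a significant *decrease* must not register as an onset
        t = np.arange(-100.0, 200.0)
        traces = np.zeros((20, t.size))
        traces[:, t >= 30.0] = -5.0
        traces += np.linspace(-0.005, 0.005, 20)[:, None]  # tiny, zero-mean variance
        res = onset_running_ttest(t, traces, reference_level=0.0)
        assert res.onset_ms is None


class TestBootstrapRank:
    def test_single_area_always_first(self, rng):
        t = np.arange(-100.0, 200.0)
        traces = 10.0 + rng.normal(0, 1, size=(6, t.size))
        traces[:, t >= 50] += 20.0
        m = bootstrap_rank({"only": traces}, t, rng, n_iter=50)
        assert m.proportions.loc["only", 1] == 1.0

    def test_well_separated_onsets_rank_cleanly(self, rng):
        t = np.arange(-100.0, 200.0)
        early = 10.0 + rng.normal(0, 1, size=(200, t.size))
        early[:, t >= 20] += 30.0
        late = 10.0 + rng.normal(0, 1, size=(200, t.size))
        late[:, t >= 60] += 30.0
        m = bootstrap_rank({"early": early, "late": late}, t, rng, n_iter=1000)
        assert m.proportions.loc["early", 1] > 0.99
        assert m.proportions.loc["late", 2] > 0.99

    def test_matrix_doubly_stochastic(self, rng):
        t = np.arange(-100.0, 200.0)
        areas = {}
        for i, onset in enumerate((20, 25, 60)):
            tr = 10.0 + rng.normal(0, 2, size=(8, t.size))
            tr[:, t >= onset] += 6.0
            areas[f"a{i}"] = tr
        m = bootstrap_rank(areas, t, rng, n_iter=200)
        assert np.allclose(m.proportions.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(m.proportions.sum(axis=0), 1.0, atol=1e-12)

    def test_no_crossing_ranks_last_and_counted(self, rng):
        t = np.arange(-100.0, 200.0)
        flat = 10.0 + rng.normal(0, 1, size=(20, t.size))
        resp = 10.0 + rng.normal(0, 1, size=(20, t.size))
        resp[:, t >= 30] += 30.0
        m = bootstrap_rank({"flat": flat, "resp": resp}, t, rng, n_iter=100)
        assert m.none_count["flat"] > 80
        assert m.proportions.loc["flat", 2] > 0.9

    def test_independent_seeds_agree_within_binomial_error(self, rng):
        t = np.arange(-100.0, 200.0)
        a = 10.0 + rng.normal(0, 1.5, size=(30, t.size))
        a[:, t >= 25] += 8.0
        b = 10.0 + rng.normal(0, 1.5, size=(30, t.size))
        b[:, t >= 32] += 8.0
        traces = {"a": a, "b": b}
        n = 600
        p1 = bootstrap_rank(traces, t, np.random.default_rng(10), n_iter=n)
        p2 = bootstrap_rank(traces, t, np.random.default_rng(99), n_iter=n)
        v1, v2 = p1.proportions.loc["a", 1], p2.proportions.loc["a", 1]
        se = np.sqrt(0.25 / n) * 2
        assert abs(v1 - v2) < 4 * se

    def test_running_ttest_method_supported(self, rng):
        t = np.arange(-100.0, 200.0)
        a = rng.normal(0, 1, size=(30, t.size))
        a[:, t >= 25] += 5.0
        b = rng.normal(0, 1, size=(30, t.size))
        b[:, t >= 60] += 5.0
        m = bootstrap_rank({"a": a, "b": b}, t, rng, method="running_ttest", n_iter=100)
        assert m.proportions.loc["a", 1] > 0.95
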