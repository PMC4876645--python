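"""Response-onset detection and bootstrap rank-ordering of cortical areas.

Two onset detectors are provided:

* the threshold rule — the earliest post-perturbation time at which a
  signal exceeds its baseline mean + k baseline SDs (k = 3 by default) and
  stays above for at least a persistence window (20 ms), guarding against
  transient excursions;
* a running one-sample t-test across units (1 ms steps) against a
  reference level (0, or the baseline difference when baselines already
  differ between conditions), with the same persistence rule and a
  directional gate (the across-unit mean must exceed the reference).

Onset order across areas is assessed by resampling units with replacement
within each area, rebuilding the population (or differential) signal,
re-detecting the onset, and rank-ordering areas in every iteration.
Iterations where a signal never crosses threshold are kept, ranked last
(ties broken uniformly at random), so the rank-proportion matrix stays
doubly stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .population import _baseline_stats

BASELINE_WINDOW = (-100.0, 0.0)
_SD_EPS = 1e-6


@dataclass
class OnsetResult:
    """A detected (or absent) response onset."""

    onset_ms: float | None
    method: str
    area: str = ""
    label: str = ""
    threshold_k: float = 3.0
    persistence_ms: float = 20.0
    alpha: float | None = None
    reference_level: float = 0.0
    sd_was_zero: bool = False


def baseline_stats(
    time_ms: np.ndarray, signal: np.ndarray, window: tuple[float, float] = BASELINE_WINDOW
) -> tuple[float, float]:
    """Sample mean and SD (ddof=1) of a signal over the baseline window."""
    time_ms = np.asarray(time_ms, dtype=float)
    mask = (time_ms >= window[0]) & (time_ms <= window[1])
    if not mask.any():
        raise ValueError("baseline window outside the signal grid")
    return _baseline_stats(time_ms, np.asarray(signal, dtype=float), window)


def _first_persistent_run(flags: np.ndarray, run_len: int) -> int | None:
    """Index of the first position opening >= run_len consecutive True flags."""
    if run_len <= 0:
        raise ValueError("persistence must be positive")
    f = np.asarray(flags, dtype=bool)
    if f.size < run_len:
        return None
    window_all = np.convolve(f.astype(int), np.ones(run_len, dtype=int), mode="valid")
    hits = np.nonzero(window_all == run_len)[0]
    return int(hits[0]) if hits.size else None


def onset_threshold(
    time_ms: np.ndarray,
    signal: np.ndarray,
    k: float = 3.0,
    persistence_ms: float = 20.0,
    baseline: tuple[float, float] | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    search_start_ms: float = 0.0,
    area: str = "",
    label: str = "",
) -> OnsetResult:
    """Earliest t >= search_start with ``signal > mean + k*sd`` sustained
    for the persistence window.

    ``baseline`` supplies precomputed (mean, sd); otherwise the stats are
    taken from the signal's own baseline window.  ``search_start_ms`` is
    the event time the search begins at (0 = perturbation onset).  A zero
    baseline SD (constant baseline) degrades the threshold to
    mean + epsilon and flags the result.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if baseline is None:
        mean, sd = baseline_stats(time_ms, signal, baseline_window)
    else:
        mean, sd = baseline
    sd_zero = sd == 0.0
    threshold = mean + (k * sd if not sd_zero else _SD_EPS)
    dt = time_ms[1] - time_ms[0]
    run_len = max(1, math.ceil(persistence_ms / dt))
    post = time_ms >= search_start_ms
    above = signal[post] > threshold
    idx = _first_persistent_run(above, run_len)
    onset = float(time_ms[post][idx]) if idx is not None else None
    return OnsetResult(
        onset_ms=onset, method="threshold_3sd", area=area, label=label,
        threshold_k=k, persistence_ms=persistence_ms,
        reference_level=mean, sd_was_zero=sd_zero,
    )


def _running_ttest_flags(
    traces: np.ndarray, reference: float, alpha: float
) -> np.ndarray:
    """Per-timepoint significance of the across-unit one-sample t-test.

    Two-sided test with a directional gate (mean above reference).  At
    degenerate time points (zero across-unit variance) the test is
    significant iff the mean differs from the reference.
    """
    n = traces.shape[0]
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0, ddof=1)
    flags = np.zeros(traces.shape[1], dtype=bool)
    degen = sd == 0.0
    flags[degen] = mean[degen] > reference
    ok = ~degen
    if ok.any():
        t = (mean[ok] - reference) / (sd[ok] / math.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        flags[ok] = (p < alpha) & (mean[ok] > reference)
    return flags


def onset_running_ttest(
    time_ms: np.ndarray,
    unit_traces: np.ndarray,
    reference_level: float = 0.0,
    alpha: float = 0.05,
    persistence_ms: float = 20.0,
    area: str = "",
    label: str = "",
) -> OnsetResult:
    """Earliest t >= 0 where across-unit activity departs from a reference.

    ``unit_traces`` is (n_units, n_time); the test runs at every grid step
    and the departure must stay significant for the persistence window.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    traces = np.atleast_2d(np.asarray(unit_traces, dtype=float))
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 units")
    if traces.shape[1] != time_ms.size:
        raise ValueError("trace length does not match the time grid")
    dt = time_ms[1] - time_ms[0]
    run_len = max(1, math.ceil(persistence_ms / dt))
    post = time_ms >= 0.0
    flags = _running_ttest_flags(traces[:, post], reference_level, alpha)
    idx = _first_persistent_run(flags, run_len)
    onset = float(time_ms[post][idx]) if idx is not None else None
    return OnsetResult(
        onset_ms=onset, method="running_ttest", area=area, label=label,
        alpha=alpha, persistence_ms=persistence_ms, reference_level=reference_level,
    )


@dataclass
class RankProportionMatrix:
    """Areas x ranks matrix of bootstrap rank frequencies."""

    proportions: pd.DataFrame  # index: areas, columns: 1..n_areas
    n_iterations: int
    none_count: dict[str, int] = field(default_factory=dict)
    onsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows = self.proportions.sum(axis=1).to_numpy()
        cols = self.proportions.sum(axis=0).to_numpy()
        if not (np.allclose(rows, 1.0, atol=1e-9) and np.allclose(cols, 1.0, atol=1e-9)):
            raise ValueError("rank-proportion matrix must be doubly stochastic")


def bootstrap_rank(
    traces_by_area: dict[str, np.ndarray],
    time_ms: np.ndarray,
    rng: np.random.Generator,
    method: str = "threshold_3sd",
    n_iter: int = 10_000,
    k: float = 3.0,
    persistence_ms: float = 20.0,
    alpha: float = 0.05,
    reference: str = "zero",
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    reuse_baseline: bool = False,
) -> RankProportionMatrix:
    """Bootstrap the rank order of per-area onset times.

    Each iteration resamples every area's units with replacement (keeping
    the area's unit count), rebuilds its signal from the resampled traces,
    detects the onset, and ranks areas by ascending onset; a missing onset
    counts as latest.  For ``method="threshold_3sd"`` the signal is the
    across-unit mean and baseline stats are recomputed per iteration unless
    ``reuse_baseline`` (then the full-sample stats are reused).  For
    ``method="running_ttest"`` the resampled unit matrix is tested against
    the reference (``"zero"`` or the iteration's own ``"baseline"`` mean).

    For differential contrasts pass per-unit *difference* traces: the same
    resampled unit then contributes both conditions (paired resampling).
    """
    if method not in ("threshold_3sd", "running_ttest"):
        raise ValueError(f"unknown onset method {method!r}")
    areas = list(traces_by_area)
    if len(areas) == 0:
        raise ValueError("no areas")
    time_ms = np.asarray(time_ms, dtype=float)
    mats = {a: np.atleast_2d(np.asarray(t, dtype=float)) for a, t in traces_by_area.items()}
    for a, m in mats.items():
        if m.shape[0] < 2:
            raise ValueError(f"area {a!r} has fewer than 2 units")
    full_baseline = {
        a: baseline_stats(time_ms, m.mean(axis=0), baseline_window)
        for a, m in mats.items()
    }
    dt = time_ms[1] - time_ms[0]
    run_len = max(1, math.ceil(persistence_ms / dt))
    post = time_ms >= 0.0
    t_post = time_ms[post]
    base_mask = (time_ms >= baseline_window[0]) & (time_ms <= baseline_window[1])

    n_areas = len(areas)
    counts = np.zeros((n_areas, n_areas), dtype=np.int64)
    none_count = {a: 0 for a in areas}
    onset_records: dict[str, list[float]] = {a: [] for a in areas}

    for _ in range(n_iter):
        onsets = np.empty(n_areas)
        for ai, a in enumerate(areas):
            m = mats[a]
            idx = rng.integers(0, m.shape[0], size=m.shape[0])
            sample = m[idx]
            if method == "threshold_3sd":
                sig = sample.mean(axis=0)
                if reuse_baseline:
                    b_mean, b_sd = full_baseline[a]
                else:
                    b = sig[base_mask]
                    b_mean, b_sd = float(b.mean()), float(b.std(ddof=1))
                thr = b_mean + (k * b_sd if b_sd > 0 else _SD_EPS)
                flags = sig[post] > thr
            else:
                if reference == "zero":
                    ref = 0.0
                elif reference == "baseline":
                    ref = float(sample.mean(axis=0)[base_mask].mean())
                else:
                    raise ValueError(f"unknown reference {reference!r}")
                flags = _running_ttest_flags(sample[:, post], ref, alpha)
            hit = _first_persistent_run(flags, run_len)
            if hit is None:
                onsets[ai] = np.inf
                none_count[a] += 1
            else:
                onsets[ai] = t_post[hit]
            onset_records[a].append(onsets[ai])
        # ascending rank, random tie-break (incl. the +inf "no onset" ties)
        order = np.lexsort((rng.random(n_areas), onsets))
        for rank, ai in enumerate(order):
            counts[ai, rank] += 1

    props = pd.DataFrame(
        counts / float(n_iter), index=areas, columns=np.arange(1, n_areas + 1)
    )
    return RankProportionMatrix(
        proportions=props,
        n_iterations=n_iter,
        none_count=none_count,
        onsets={a: np.asarray(v) for a, v in onset_records.items()},
    )
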