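"""Per-area population signals and task-differential signals.

The population signal of an area is the unweighted across-unit mean (with
SEM) of trial-averaged spike densities, each responsive unit contributing
its preferred-torque-direction activity.  Differential signals are
across-unit means of per-unit condition differences (Posture - Movie,
OUT - IN), optionally with the sign reversed for units whose epoch
modulation is significantly negative — the control for bidirectionally
modulated populations whose raw mean difference washes out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .loads import LoadCondition
from .preprocessing import Kernel, RateSeries
from .tuning import RESPONSE_WINDOW, BASELINE_WINDOW


def unit_trial_averaged_density(
    unit_spikes: pd.DataFrame,
    task: str,
    load: LoadCondition,
    kernel: Kernel,
    window: tuple[float, float],
    n_trials: int | None = None,
) -> RateSeries:
    """Trial-averaged spike density of one unit in one (task, load) cell.

    Pooling spikes across trials and dividing by the trial count equals the
    mean of per-trial densities (the kernel sum is linear), so the average
    is computed in one convolution.
    """
    from .preprocessing import spike_density  # local to avoid cycle at import

    sel = unit_spikes[
        (unit_spikes["task"] == task)
        & (unit_spikes["shoulder_load"] == load.shoulder)
        & (unit_spikes["elbow_load"] == load.elbow)
    ]
    if n_trials is None:
        n_trials = int(sel["trial"].nunique()) if len(sel) else 0
    if n_trials == 0:
        raise ValueError("no trials for this (task, load) cell")
    pooled = spike_density(sel["spike_time_ms"].to_numpy(), window, kernel)
    return RateSeries(
        pooled.time_ms, pooled.rate / n_trials, n_trials_averaged=n_trials
    )


@dataclass
class PopulationSignal:
    """Across-unit mean rate of one area in one condition."""

    area: str
    label: str
    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_units: int
    baseline_mean: float
    baseline_sd: float


def _baseline_stats(
    time_ms: np.ndarray, trace: np.ndarray, window: tuple[float, float]
) -> tuple[float, float]:
    mask = (time_ms >= window[0]) & (time_ms <= window[1])
    vals = trace[mask]
    return float(vals.mean()), float(vals.std(ddof=1))


def population_signal(
    unit_traces: np.ndarray,
    time_ms: np.ndarray,
    area: str = "",
    label: str = "",
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> PopulationSignal:
    """Unweighted mean ± SEM across units at each time point.

    ``unit_traces`` is (n_units, n_time); baseline statistics are computed
    on the mean trace over the baseline window.
    """
    traces = np.atleast_2d(np.asarray(unit_traces, dtype=float))
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 units")
    mean = traces.mean(axis=0)
    sem = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
    b_mean, b_sd = _baseline_stats(time_ms, mean, baseline_window)
    return PopulationSignal(
        area=area, label=label, time_ms=np.asarray(time_ms, dtype=float),
        mean=mean, sem=sem, n_units=traces.shape[0],
        baseline_mean=b_mean, baseline_sd=b_sd,
    )


@dataclass
class DifferentialSignal:
    """Across-unit mean of per-unit condition-difference traces."""

    area: str
    pair_label: str
    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_units: int
    reference_level: float
    sign_flip_applied: bool
    n_flipped: int = 0


def sign_flip_calls(
    epoch_a: np.ndarray,
    epoch_b: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> np.ndarray:
    """Which units significantly *decrease* from condition b to condition a.

    ``epoch_a`` and ``epoch_b`` are per-unit lists/arrays of trial-wise
    epoch means.  Returns a boolean array: True where the unit's a-b epoch
    difference is negative and significant by a two-sample t-test.
    """
    flags = np.zeros(len(epoch_a), dtype=bool)
    for i, (a, b) in enumerate(zip(epoch_a, epoch_b)):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        if np.std(a) == 0.0 and np.std(b) == 0.0:
            sig = a.mean() != b.mean()
        else:
            sig = stats.ttest_ind(a, b, equal_var=equal_var).pvalue < alpha
        flags[i] = bool(sig) and (a.mean() < b.mean())
    return flags


def differential_signal(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    time_ms: np.ndarray,
    area: str = "",
    pair_label: str = "",
    sign_flip: bool = False,
    flip_mask: np.ndarray | None = None,
    reference: str = "zero",
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> DifferentialSignal:
    """Mean ± SEM of per-unit difference traces (a - b), paired by row.

    With ``sign_flip`` the rows selected by ``flip_mask`` (units whose
    epoch modulation is significantly negative) contribute negated
    difference traces.  ``reference="baseline"`` sets the signal's
    reference level to the mean differential over the baseline window
    (used when baseline activity already differs between conditions)
    instead of 0.
    """
    a = np.atleast_2d(np.asarray(traces_a, dtype=float))
    b = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired trace matrices must have identical shape")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 paired units")
    diff = a - b
    n_flipped = 0
    if sign_flip:
        if flip_mask is None:
            raise ValueError("sign_flip requires a flip_mask of per-unit calls")
        flip_mask = np.asarray(flip_mask, dtype=bool)
        diff = np.where(flip_mask[:, None], -diff, diff)
        n_flipped = int(flip_mask.sum())
    mean = diff.mean(axis=0)
    sem = diff.std(axis=0, ddof=1) / np.sqrt(diff.shape[0])
    if reference == "zero":
        ref = 0.0
    elif reference == "baseline":
        ref, _ = _baseline_stats(np.asarray(time_ms, dtype=float), mean, baseline_window)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return DifferentialSignal(
        area=area, pair_label=pair_label, time_ms=np.asarray(time_ms, dtype=float),
        mean=mean, sem=sem, n_units=diff.shape[0],
        reference_level=float(ref), sign_flip_applied=sign_flip, n_flipped=n_flipped,
    )


def change_ratio(evoked_a: np.ndarray, evoked_b: np.ndarray) -> tuple[float, np.ndarray]:
    """Relative change of the population evoked response between conditions.

    ``(mean(evoked_a) - mean(evoked_b)) / mean(evoked_a)`` over paired
    per-unit evoked responses (epoch minus baseline); also returns per-unit
    ratios.  Undefined (nan) when the condition-a population mean is <= 0.
    """
    a = np.asarray(evoked_a, dtype=float)
    b = np.asarray(evoked_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired evoked arrays must have identical shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_unit = np.where(a > 0, (a - b) / a, np.nan)
    denom = a.mean()
    ratio = (denom - b.mean()) / denom if denom > 0 else float("nan")
    return float(ratio), per_unit


@dataclass
class AbsoluteChangeDistribution:
    abs_changes: np.ndarray
    mean: float
    sd: float
    ecdf: ECDF


def absolute_change_distribution(
    epoch_a: np.ndarray, epoch_b: np.ndarray
) -> AbsoluteChangeDistribution:
    """Per-unit |a - b| epoch changes with summary stats and their ECDF."""
    a = np.asarray(epoch_a, dtype=float)
    b = np.asarray(epoch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired epoch arrays must have identical shape")
    abs_d = np.abs(a - b)
    return AbsoluteChangeDistribution(
        abs_changes=abs_d,
        mean=float(abs_d.mean()),
        sd=float(abs_d.std(ddof=1)) if abs_d.size > 1 else 0.0,
        ecdf=ECDF(abs_d),
    )
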