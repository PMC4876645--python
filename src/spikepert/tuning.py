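"""Per-unit perturbation response quantification and preferred-direction selection.

Each unit's evoked response is its trial-mean firing rate in the
long-latency epoch (50-100 ms post-perturbation) minus its baseline rate
(-100 to 0 ms).  The loaded condition with the largest evoked response in
the Posture task is the unit's preferred torque direction (PTD), and the
unit counts as perturbation-responsive when its PTD-epoch activity differs
from the unloaded catch condition by a two-sample t-test.

Epoch means are computed from raw spike counts (count / duration), not
from the smoothed density, so that kernel smearing cannot leak activity
from after the epoch into it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loads import LoadCondition, all_conditions, loaded_conditions
from .preprocessing import RateSeries

RESPONSE_WINDOW = (50.0, 100.0)
BASELINE_WINDOW = (-100.0, 0.0)


def epoch_mean(rate_or_spikes, window: tuple[float, float]) -> float:
    """Mean firing rate (sp/s) of one trial over an epoch.

    For an array of spike times the estimate is count / duration; for a
    :class:`~spikepert.preprocessing.RateSeries` it is the mean of the rate
    samples falling inside the window.
    """
    a, b = window
    if b <= a:
        raise ValueError("empty epoch window")
    if isinstance(rate_or_spikes, RateSeries):
        mask = (rate_or_spikes.time_ms >= a) & (rate_or_spikes.time_ms < b)
        if not mask.any():
            raise ValueError("window outside the series grid")
        return float(rate_or_spikes.rate[mask].mean())
    spikes = np.asarray(rate_or_spikes, dtype=float)
    count = int(((spikes >= a) & (spikes < b)).sum())
    return 1000.0 * count / (b - a)


def unit_epoch_table(
    unit_spikes: pd.DataFrame,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    n_trials: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Trial-wise response- and baseline-epoch means for one unit.

    ``unit_spikes`` is the tidy spike table restricted to one unit.  A
    trial with zero spikes anywhere never appears in a spike table; when
    the true trial counts are known, pass ``n_trials`` (task -> count) and
    missing trials are filled in with zero rates.
    """
    rows = []
    seen: set[tuple[str, str, str]] = set()
    grouped = unit_spikes.groupby(
        ["task", "shoulder_load", "elbow_load", "trial"], sort=True
    )
    present: dict[tuple[str, str, str], set[int]] = {}
    for (task, s_load, e_load, trial), g in grouped:
        t = g["spike_time_ms"].to_numpy()
        rows.append(
            (task, s_load, e_load, int(trial),
             epoch_mean(t, response_window), epoch_mean(t, baseline_window))
        )
        present.setdefault((task, s_load, e_load), set()).add(int(trial))
        seen.add((task, s_load, e_load))
    if n_trials is not None:
        for (task, s_load, e_load) in seen:
            expected = n_trials.get(task)
            if expected is None:
                continue
            for trial in range(expected):
                if trial not in present[(task, s_load, e_load)]:
                    rows.append((task, s_load, e_load, trial, 0.0, 0.0))
    return pd.DataFrame(
        rows,
        columns=["task", "shoulder_load", "elbow_load", "trial",
                 "response_sp_s", "baseline_sp_s"],
    )


@dataclass
class PTDResult:
    """Preferred torque direction and responsiveness call for one unit."""

    unit_id: str
    ptd: LoadCondition
    response_magnitude: float  # evoked = response - baseline, trial-mean, sp/s
    responsive: bool
    p_value: float
    tied: bool = False


def select_ptd(
    epoch_table: pd.DataFrame,
    unit_id: str = "",
    task: str = "posture",
    magnitude_nm: float = 0.24,
) -> PTDResult:
    """Pick the loaded condition with the largest trial-mean evoked response.

    Requires all nine conditions of the given task to be present.  Exact
    ties are broken by the canonical condition ordering (shoulder axis
    fastest) and flagged.  The responsiveness fields are left unset
    (``p_value = nan``) until :func:`test_responsive` fills them.
    """
    sub = epoch_table[epoch_table["task"] == task]
    present = set(map(tuple, sub[["shoulder_load", "elbow_load"]].drop_duplicates().values))
    needed = {c.key for c in all_conditions()}
    if present < needed:
        missing = sorted(needed - present)
        raise ValueError(f"missing conditions for task {task!r}: {missing}")
    evoked = {}
    for cond in loaded_conditions(magnitude_nm):
        g = sub[(sub["shoulder_load"] == cond.shoulder) & (sub["elbow_load"] == cond.elbow)]
        evoked[cond] = g["response_sp_s"].mean() - g["baseline_sp_s"].mean()
    best = max(evoked.values())
    winners = [c for c in loaded_conditions(magnitude_nm) if evoked[c] == best]
    return PTDResult(
        unit_id=unit_id,
        ptd=winners[0],
        response_magnitude=float(best),
        responsive=False,
        p_value=math.nan,
        tied=len(winners) > 1,
    )


def test_responsive(
    epoch_table: pd.DataFrame,
    ptd: LoadCondition,
    alpha: float = 0.05,
    task: str = "posture",
    equal_var: bool = True,
) -> tuple[bool, float]:
    """Two-sample t-test of PTD vs catch-trial response-epoch activity.

    Student's pooled-variance test by default (``equal_var=False`` gives
    Welch).  With zero variance in both groups the p-value is 1 when the
    means agree and 0 when they differ (a deterministic difference).
    """
    sub = epoch_table[epoch_table["task"] == task]
    ptd_vals = sub[
        (sub["shoulder_load"] == ptd.shoulder) & (sub["elbow_load"] == ptd.elbow)
    ]["response_sp_s"].to_numpy()
    null_vals = sub[
        (sub["shoulder_load"] == "null") & (sub["elbow_load"] == "null")
    ]["response_sp_s"].to_numpy()
    if ptd_vals.size < 2 or null_vals.size < 2:
        raise ValueError("need at least 2 trials per group")
    if np.std(ptd_vals) == 0.0 and np.std(null_vals) == 0.0:
        p = 1.0 if np.mean(ptd_vals) == np.mean(null_vals) else 0.0
    else:
        p = float(stats.ttest_ind(ptd_vals, null_vals, equal_var=equal_var).pvalue)
    return bool(p < alpha), p


def analyze_units(
    spikes: pd.DataFrame,
    alpha: float = 0.05,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    equal_var: bool = True,
    ptd_task: str = "posture",
    magnitude_nm: float = 0.24,
) -> pd.DataFrame:
    """PTD selection and responsiveness screening for every unit.

    The PTD is chosen from Posture-task data and reused for the same unit
    across tasks.  Returns one row per unit: unit_id, area, ptd_shoulder,
    ptd_elbow, evoked_sp_s, p_value, responsive, tied.
    """
    rows = []
    for unit_id, unit_spikes in spikes.groupby("unit_id", sort=True):
        area = unit_spikes["area"].iloc[0]
        table = unit_epoch_table(unit_spikes, response_window, baseline_window)
        try:
            res = select_ptd(table, unit_id, task=ptd_task, magnitude_nm=magnitude_nm)
        except ValueError:
            continue  # unit lacks the full Posture condition grid
        responsive, p = test_responsive(
            table, res.ptd, alpha=alpha, task=ptd_task, equal_var=equal_var
        )
        rows.append(
            (unit_id, area, res.ptd.shoulder, res.ptd.elbow,
             res.response_magnitude, p, responsive, res.tied)
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "area", "ptd_shoulder", "ptd_elbow",
                 "evoked_sp_s", "p_value", "responsive", "tied"],
    )
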