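"""Trial-by-trial coupling between neural activity and the corrective movement.

The behavioral read-out of each Posture trial is the joint-reversal time:
the moment of maximum joint-space excursion from the start posture before
the hand turns back toward the central target.  Each unit's trial-wise
evoked response (50-100 ms epoch mean in its preferred torque direction)
is correlated against these reversal times, and per-unit coefficients are
summarized per area with a Wilcoxon signed-rank test against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TrialKinematics:
    """Two-joint trajectory of one trial (angles in rad, time in ms)."""

    time_ms: np.ndarray
    shoulder_rad: np.ndarray
    elbow_rad: np.ndarray
    start: tuple[float, float]
    reversal_time_ms: float | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.shoulder_rad = np.asarray(self.shoulder_rad, dtype=float)
        self.elbow_rad = np.asarray(self.elbow_rad, dtype=float)

    def distance_from_start(self) -> np.ndarray:
        return np.hypot(
            self.shoulder_rad - self.start[0], self.elbow_rad - self.start[1]
        )


def joint_reversal_time(
    trajectory: TrialKinematics,
    return_fraction: float = 0.2,
) -> tuple[float, bool]:
    """Time of maximum joint-space excursion before the corrective return.

    The trajectory's Euclidean distance from the start posture is scanned;
    the search for the maximum is restricted to the segment before the
    path first re-enters a return radius (``return_fraction`` of the peak
    excursion) after having left it.  If the path never returns, the global
    argmax is used and the result is flagged.

    Returns
    -------
    (reversal_ms, returned) : tuple
        ``returned`` is False when the monotone-outward fallback fired.
    """
    if not 0.0 < return_fraction < 1.0:
        raise ValueError("return_fraction must lie in (0, 1)")
    d = trajectory.distance_from_start()
    peak = float(d.max())
    if peak <= 1e-12:
        raise ValueError("flat trajectory: no perturbation excursion")
    radius = return_fraction * peak
    outside = d > radius
    if not outside.any():
        raise ValueError("flat trajectory: no perturbation excursion")
    first_out = int(np.argmax(outside))
    back_in = np.nonzero(~outside[first_out:])[0]
    if back_in.size == 0:
        return float(trajectory.time_ms[int(np.argmax(d))]), False
    end = first_out + int(back_in[0])
    idx = int(np.argmax(d[:end]))
    return float(trajectory.time_ms[idx]), True


def unit_trial_correlation(
    epoch_means: np.ndarray,
    reversal_times: np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between a unit's trial-wise activity and reversal time.

    Returns ``(r, p)``; ``(nan, nan)`` when either side has zero variance
    (the caller excludes such units).
    """
    x = np.asarray(epoch_means, dtype=float)
    y = np.asarray(reversal_times, dtype=float)
    if x.size != y.size:
        raise ValueError("unequal numbers of trials")
    if x.size < 5:
        raise ValueError("need at least 5 paired trials")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return (math.nan, math.nan)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationSummary:
    median_r: float
    wilcoxon_p: float
    n_units: int
    n_significant: int


def population_correlation_summary(
    r_values: np.ndarray,
    p_values: np.ndarray | None = None,
    alpha: float = 0.05,
) -> CorrelationSummary:
    """Median per-unit correlation and a signed-rank test against zero.

    The Wilcoxon test uses the exact null distribution for n <= 25 and the
    normal approximation with continuity correction above.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 5:
        raise ValueError("need at least 5 units with a defined correlation")
    nonzero = r[r != 0.0]
    if nonzero.size == 0:
        p = 1.0
    else:
        method = "exact" if nonzero.size <= 25 else "approx"
        try:
            res = stats.wilcoxon(nonzero, method=method, correction=(method == "approx"))
        except ValueError:  # ties defeat the exact distribution
            res = stats.wilcoxon(nonzero, method="approx", correction=True)
        p = float(res.pvalue)
    n_sig = 0
    if p_values is not None:
        pv = np.asarray(p_values, dtype=float)
        n_sig = int(np.sum(pv[~np.isnan(pv)] < alpha))
    return CorrelationSummary(
        median_r=float(np.median(r)),
        wilcoxon_p=p,
        n_units=int(r.size),
        n_significant=n_sig,
    )
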