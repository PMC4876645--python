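"""Synthetic multi-area perturbation datasets with known ground truth.

Spike trains are drawn from inhomogeneous Poisson processes whose intensity
is a baseline plus a tuned, task-gated evoked transient:

    lambda(t) = baseline
              + tuning(load) * peak * [ b(t - l_u) + (g_task - 1) * b(t - l_u - d_task) ]

where ``b`` is a peak-normalized difference-of-exponentials bump
(fast rise, slow decay), ``l_u`` the unit's response latency (area latency
plus per-unit jitter, fixed across that unit's trials), ``g_task`` a
multiplicative task gain relative to the reference Posture task, and
``d_task`` a divergence delay that lets the task effect start later than
the perturbation response itself (late target-selection divergence).

Sampling uses exact thinning against an analytic intensity bound.  A
hierarchical seed tree (one child stream per unit, split again for spikes
and kinematics) makes the whole dataset reproducible independent of
iteration order.

Each simulated Posture trial also carries a joint-kinematics record: a
two-joint trajectory whose maximum joint-space excursion occurs exactly at
a per-trial reversal time coupled (negatively) to the trial's evoked spike
count, and an EMG generator produces amplitude-modulated broadband noise
with a configurable evoked-burst onset (default 34 ms).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .loads import LoadCondition, all_conditions, loaded_conditions, condition_tuning
from .kinematics import TrialKinematics

TASKS = ("posture", "movie", "in", "out")

__all__ = [
    "AreaSpec",
    "SimConfig",
    "UnitRecording",
    "Dataset",
    "default_sim_config",
    "simulate_unit",
    "simulate_population",
    "simulate_kinematics",
    "kinematic_trajectory",
    "simulate_emg",
    "evoked_profile",
]


def evoked_profile(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Peak-normalized causal bump ``(1 - e^(-t/rise)) * e^(-t/decay)``.

    Zero for t < 0; equals 1 at its peak ``t* = rise * ln(1 + decay/rise)``.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    mask = t > 0
    tm = t[mask]
    out[mask] = (1.0 - np.exp(-tm / rise_tau)) * np.exp(-tm / decay_tau)
    t_peak = rise_tau * math.log1p(decay_tau / rise_tau)
    peak = (1.0 - math.exp(-t_peak / rise_tau)) * math.exp(-t_peak / decay_tau)
    return out / peak


@dataclass
class AreaSpec:
    """Generative parameters for one cortical area.

    ``task_gain`` maps task name to the multiplicative gain on the evoked
    component relative to Posture (gain 1.0); ``task_delay_ms`` maps task
    name to the divergence delay of that gain change relative to the
    response latency.  Units flagged as sign-flipped swap their IN and OUT
    gains (negative OUT-IN modulation).
    """

    area_name: str
    n_units: int
    baseline_rate: float
    true_onset_latency: float
    peak_amplitude: float
    unit_latency_jitter_sd: float = 1.0
    profile_rise_tau: float = 1.0
    profile_decay_tau: float = 40.0
    tuning_width: float = 1.0
    fraction_sign_flipped: float = 0.0
    task_gain: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TASKS}
    )
    task_delay_ms: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TASKS}
    )

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.baseline_rate < 0 or self.peak_amplitude < 0:
            raise ValueError("rates must be nonnegative")
        if self.true_onset_latency <= 0:
            raise ValueError("true_onset_latency must be positive")
        if self.unit_latency_jitter_sd < 0:
            raise ValueError("latency jitter SD must be nonnegative")
        if not 0.0 <= self.fraction_sign_flipped <= 1.0:
            raise ValueError("fraction_sign_flipped must lie in [0, 1]")
        for task in TASKS:
            self.task_gain.setdefault(task, 1.0)
            self.task_delay_ms.setdefault(task, 0.0)
            if self.task_gain[task] < 0:
                raise ValueError("task gains must be nonnegative")


@dataclass
class SimConfig:
    """Global simulation settings (times in ms, rates in sp/s)."""

    areas: list[AreaSpec]
    dt: float = 1.0
    trial_window: tuple[float, float] = (-300.0, 300.0)
    n_trials_posture: int = 10
    n_trials_movie: int = 10
    n_trials_per_target: int = 20
    seed: int = 0
    load_magnitude_nm: float = 0.24
    # kinematics
    kinematics_noise_sd: float = 30.0
    target_unit_kinematic_correlation: float = -0.11
    reversal_base_ms: float = 220.0
    excursion_rad: float = 0.15
    # EMG
    emg_fs_hz: float = 2000.0
    emg_onset_ms: float = 34.0
    emg_baseline: float = 1.0
    emg_evoked_gain: float = 2.0
    emg_rise_tau: float = 3.0
    emg_decay_tau: float = 30.0

    def __post_init__(self) -> None:
        t_min, t_max = self.trial_window
        if not (t_min < -100.0 <= 0.0 < t_max):
            raise ValueError("trial window must contain [-100, 0] and extend past 0")
        for n in (self.n_trials_posture, self.n_trials_movie, self.n_trials_per_target):
            if n < 2:
                raise ValueError("trial counts must be >= 2")
        n_steps = (t_max - t_min) / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt must divide the trial window length")
        if not -1.0 <= self.target_unit_kinematic_correlation <= 0.0:
            raise ValueError("target correlation must lie in [-1, 0]")

    def n_trials(self, task: str) -> int:
        if task == "posture":
            return self.n_trials_posture
        if task == "movie":
            return self.n_trials_movie
        if task in ("in", "out"):
            return self.n_trials_per_target
        raise ValueError(f"unknown task {task!r}")


def epoch_evoked_factor(
    latency_ms: float,
    rise_tau: float = 1.0,
    decay_tau: float = 40.0,
    epoch: tuple[float, float] = (50.0, 100.0),
) -> float:
    """Mean of the peak-normalized evoked bump over the long-latency epoch.

    Converts between the profile's peak amplitude and the epoch-mean evoked
    response it produces: ``epoch_evoked = peak * epoch_evoked_factor``.
    """
    t = np.arange(epoch[0], epoch[1], 0.1) + 0.05
    return float(evoked_profile(t - latency_ms, rise_tau, decay_tau).mean())


def default_sim_config(seed: int = 0, n_units_per_area: int = 100) -> SimConfig:
    """The default five-area dataset.

    Areas mirror the latency and amplitude gradients of primate
    sensorimotor cortex under mechanical arm perturbations: primary
    somatosensory cortex responds first and strongest, premotor cortex last
    and weakest; a movie-watching (disengaged) condition scales evoked
    responses down with area-specific divergence delays, and a
    target-selection contrast (OUT vs IN) boosts motor areas late, with a
    bidirectionally modulated (partially sign-flipped) population.

    The per-area ``evoked`` values are the target *epoch-mean* evoked
    responses (50-100 ms minus baseline, sp/s, in the preferred direction);
    the profile peak is calibrated from them via
    :func:`epoch_evoked_factor`, so the measured long-latency responses of
    well-tuned units land on the configured values.
    """
    # area_name, latency, epoch evoked, movie change ratio, movie_delay,
    # out_gain, out_delay, flip_frac
    table = [
        ("S1", 17.0, 68.5, 0.09, 22.0, 1.10, 133.0, 0.50),
        ("A2", 18.0, 38.7, 0.15, 50.0, 1.00, 0.0, 0.50),
        ("A5", 21.0, 30.3, 0.36, 0.0, 1.15, 129.0, 0.50),
        ("M1", 22.0, 43.3, 0.36, 15.0, 1.30, 44.0, 0.20),
        ("PMd", 25.0, 26.9, 0.40, 17.0, 1.25, 73.0, 0.45),
    ]
    areas = []
    for name, lat, evoked, ratio, d_mov, g_out, d_out, flip in table:
        # movie gain such that the *epoch-mean* suppression equals the target
        # change ratio; the divergence-delayed term sits nearer its peak in
        # the epoch, so the gain must be rescaled by the shifted epoch factor
        delta = ratio * epoch_evoked_factor(lat) / epoch_evoked_factor(lat + d_mov)
        areas.append(AreaSpec(
            area_name=name,
            n_units=n_units_per_area,
            baseline_rate=15.0,
            true_onset_latency=lat,
            peak_amplitude=evoked / epoch_evoked_factor(lat),
            fraction_sign_flipped=flip,
            task_gain={"posture": 1.0, "movie": 1.0 - delta, "in": 1.0, "out": g_out},
            task_delay_ms={"posture": 0.0, "movie": d_mov, "in": 0.0, "out": d_out},
        ))
    return SimConfig(areas=areas, seed=seed)


@dataclass
class UnitGroundTruth:
    """Sidecar record of one unit's generative parameters."""

    unit_id: str
    area: str
    latency_ms: float
    preferred_angle_rad: float
    ptd_shoulder: str
    ptd_elbow: str
    sign_flipped: bool
    baseline_rate: float
    peak_amplitude: float
    task_gain: dict[str, float]
    task_delay_ms: dict[str, float]


@dataclass
class UnitRecording:
    """All trials for one simulated neuron."""

    unit_id: str
    area: str
    truth: UnitGroundTruth
    # (task, (shoulder, elbow)) -> list of per-trial sorted spike arrays (ms)
    trials: dict[tuple[str, tuple[str, str]], list[np.ndarray]]


def _unit_gains(spec: AreaSpec, sign_flipped: bool) -> dict[str, float]:
    gains = dict(spec.task_gain)
    if sign_flipped:
        gains["in"], gains["out"] = gains["out"], gains["in"]
    return gains


def _intensity_factory(
    spec: AreaSpec,
    latency: float,
    preferred_angle: float,
    gains: dict[str, float],
):
    """Return ``lambda(t, task, load)`` for one unit, in sp/s (t in ms)."""

    def intensity(t_ms: np.ndarray, task: str, load: LoadCondition) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        lam = np.full_like(t, spec.baseline_rate)
        if load.is_null:
            return lam
        tun = condition_tuning(load, preferred_angle, spec.tuning_width)
        if tun == 0.0:
            return lam
        g = gains[task]
        d = spec.task_delay_ms[task]
        bump = evoked_profile(t - latency, spec.profile_rise_tau, spec.profile_decay_tau)
        if g != 1.0:
            bump = bump + (g - 1.0) * evoked_profile(
                t - latency - d, spec.profile_rise_tau, spec.profile_decay_tau
            )
        lam += tun * spec.peak_amplitude * bump
        return lam

    return intensity


def _intensity_bound(spec: AreaSpec, task_gain: float) -> float:
    return spec.baseline_rate + spec.peak_amplitude * (1.0 + max(0.0, task_gain - 1.0))


def _validate_nonnegative_intensity(
    spec: AreaSpec, latency: float, gains: dict[str, float], window: tuple[float, float]
) -> None:
    """Reject configurations whose intensity dips below zero anywhere.

    Checking at full tuning (tun = 1) covers every load condition, since
    the evoked term scales linearly with tuning in [0, 1].
    """
    t = np.arange(window[0], window[1] + 0.25, 0.25)
    bump = evoked_profile(t - latency, spec.profile_rise_tau, spec.profile_decay_tau)
    for task in TASKS:
        g, d = gains[task], spec.task_delay_ms[task]
        if g >= 1.0:
            continue
        shifted = evoked_profile(
            t - latency - d, spec.profile_rise_tau, spec.profile_decay_tau
        )
        lam = spec.baseline_rate + spec.peak_amplitude * (bump + (g - 1.0) * shifted)
        if lam.min() < 0.0:
            raise ValueError(
                f"negative intensity for area {spec.area_name!r}, task {task!r}"
            )


def _sample_trials_thinning(
    intensity,
    bound: float,
    window: tuple[float, float],
    n_trials: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Exact inhomogeneous-Poisson sampling by thinning a bounding process."""
    t0, t1 = window
    duration_s = (t1 - t0) / 1000.0
    counts = rng.poisson(bound * duration_s, size=n_trials)
    total = int(counts.sum())
    times = rng.uniform(t0, t1, size=total)
    accept = rng.uniform(0.0, bound, size=total) < intensity(times)
    trial_idx = np.repeat(np.arange(n_trials), counts)
    out: list[np.ndarray] = []
    for i in range(n_trials):
        sel = times[(trial_idx == i) & accept]
        out.append(np.sort(sel))
    return out


def nearest_loaded_condition(
    preferred_angle: float, magnitude_nm: float = 0.24
) -> LoadCondition:
    """The loaded condition whose torque direction is closest to an angle."""
    conds = loaded_conditions(magnitude_nm)
    gaps = [
        abs(math.remainder(c.angle_rad - preferred_angle, 2 * math.pi)) for c in conds
    ]
    return conds[int(np.argmin(gaps))]


def simulate_unit(
    area_spec: AreaSpec,
    conditions: list[tuple[str, LoadCondition | None]],
    sim_config: SimConfig,
    rng: np.random.Generator,
    unit_id: str = "unit_000",
) -> UnitRecording:
    """Simulate all trials of one neuron for the given (task, load) cells.

    The unit's preferred torque direction, latency jitter, and sign-flip
    status are drawn once from ``rng`` and held fixed across trials.  A
    ``None`` load stands for the unit's own preferred loaded condition
    (used by the IN/OUT target task, where the perturbation is chosen per
    neuron).
    """
    if not conditions:
        raise ValueError("condition list is empty")
    preferred = float(rng.uniform(0.0, 2.0 * math.pi))
    latency = float(
        area_spec.true_onset_latency
        + rng.normal(0.0, area_spec.unit_latency_jitter_sd)
    )
    latency = max(latency, 1.0)
    flipped = bool(rng.uniform() < area_spec.fraction_sign_flipped)
    gains = _unit_gains(area_spec, flipped)
    _validate_nonnegative_intensity(area_spec, latency, gains, sim_config.trial_window)
    intensity = _intensity_factory(area_spec, latency, preferred, gains)
    ptd = nearest_loaded_condition(preferred, sim_config.load_magnitude_nm)

    trials: dict[tuple[str, tuple[str, str]], list[np.ndarray]] = {}
    for task, load in conditions:
        if load is None:
            load = ptd
        bound = _intensity_bound(area_spec, gains[task])
        lam = lambda t, task=task, load=load: intensity(t, task, load)
        trials[(task, load.key)] = _sample_trials_thinning(
            lam, bound, sim_config.trial_window, sim_config.n_trials(task), rng
        )
    truth = UnitGroundTruth(
        unit_id=unit_id,
        area=area_spec.area_name,
        latency_ms=latency,
        preferred_angle_rad=preferred,
        ptd_shoulder=ptd.shoulder,
        ptd_elbow=ptd.elbow,
        sign_flipped=flipped,
        baseline_rate=area_spec.baseline_rate,
        peak_amplitude=area_spec.peak_amplitude,
        task_gain=gains,
        task_delay_ms=dict(area_spec.task_delay_ms),
    )
    return UnitRecording(unit_id=unit_id, area=area_spec.area_name, truth=truth, trials=trials)


def simulate_kinematics(
    evoked_count: float,
    expected_count: float,
    sim_config: SimConfig,
    rng: np.random.Generator,
) -> float:
    """Per-trial joint-reversal time (ms) coupled to the evoked spike count.

    ``T = base - slope * z + noise`` with ``z`` the Poisson-standardized
    evoked count and the slope calibrated so the activity/reversal-time
    correlation targets ``target_unit_kinematic_correlation``.  The result
    is snapped to the kinematic grid and clamped inside the trial window.
    """
    if evoked_count < 0:
        raise ValueError("evoked count must be nonnegative")
    rho = abs(sim_config.target_unit_kinematic_correlation)
    sigma = sim_config.kinematics_noise_sd
    slope = sigma * rho / math.sqrt(1.0 - rho**2) if rho < 1.0 else math.inf
    z = 0.0
    if expected_count > 0:
        z = (evoked_count - expected_count) / math.sqrt(expected_count)
    t = sim_config.reversal_base_ms - slope * z + rng.normal(0.0, sigma)
    t_max = sim_config.trial_window[1]
    t = min(max(t, 60.0), t_max - 20.0)
    return float(round(t / sim_config.dt) * sim_config.dt)


def kinematic_trajectory(
    reversal_time_ms: float,
    sim_config: SimConfig,
    direction_rad: float = 0.7,
    start: tuple[float, float] = (0.55, 1.25),
) -> TrialKinematics:
    """Two-joint out-and-back trajectory peaking exactly at the reversal time.

    Joint-space distance from the start posture follows a quarter-sine rise
    to the configured excursion at ``reversal_time_ms`` and a quarter-cosine
    return to the start by the end of the window, so the argmax of the
    distance equals the reversal time on the grid by construction.
    """
    t_max = sim_config.trial_window[1]
    grid = np.arange(0.0, t_max + sim_config.dt / 2, sim_config.dt)
    T = reversal_time_ms
    if not 0.0 < T < t_max:
        raise ValueError("reversal time must lie inside (0, t_max)")
    d = np.empty_like(grid)
    rising = grid <= T
    d[rising] = np.sin(0.5 * np.pi * grid[rising] / T)
    d[~rising] = np.cos(0.5 * np.pi * (grid[~rising] - T) / (t_max - T))
    d *= sim_config.excursion_rad
    shoulder = start[0] + d * math.cos(direction_rad)
    elbow = start[1] + d * math.sin(direction_rad)
    return TrialKinematics(
        time_ms=grid,
        shoulder_rad=shoulder,
        elbow_rad=elbow,
        start=start,
        reversal_time_ms=float(T),
    )


def simulate_emg(
    sim_config: SimConfig,
    rng: np.random.Generator,
    gain: float | None = None,
    onset_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One raw EMG trial: broadband noise amplitude-modulated by an envelope.

    ``raw(t) = (baseline + gain * b(t - onset)) * n(t)`` with ``n`` unit
    white Gaussian noise at ``emg_fs_hz`` and ``b`` the peak-normalized
    evoked bump.  Returns ``(time_ms, values)``.
    """
    fs = sim_config.emg_fs_hz
    if fs < 2 * 150.0:
        raise ValueError("EMG sampling rate must be at least twice the 150 Hz band edge")
    if gain is None:
        gain = sim_config.emg_evoked_gain
    if onset_ms is None:
        onset_ms = sim_config.emg_onset_ms
    t0, t1 = sim_config.trial_window
    n = int(round((t1 - t0) * fs / 1000.0)) + 1
    time_ms = t0 + np.arange(n) * 1000.0 / fs
    envelope = sim_config.emg_baseline + gain * evoked_profile(
        time_ms - onset_ms, sim_config.emg_rise_tau, sim_config.emg_decay_tau
    )
    return time_ms, envelope * rng.standard_normal(n)


@dataclass
class Dataset:
    """A complete simulated (or loaded) multi-area recording.

    ``spikes`` is tidy: one row per spike with columns (unit_id, area,
    task, shoulder_load, elbow_load, trial, spike_time_ms).
    ``reversal_times`` holds one row per Posture trial with the trial's
    evoked spike count and ground-truth joint-reversal time.
    ``ground_truth`` maps unit_id to its generative sidecar record.
    """

    spikes: pd.DataFrame
    reversal_times: pd.DataFrame
    ground_truth: dict[str, dict]
    config: SimConfig | None = None

    def units(self) -> pd.DataFrame:
        return (
            self.spikes[["unit_id", "area"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.csv", index=False, float_format="%.4f")
        self.reversal_times.to_csv(
            out / "reversal_times.csv", index=False, float_format="%.4f"
        )
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "Dataset":
        src = Path(in_dir)
        # keep_default_na: the torque level "null" is a literal, not missing data
        spikes = pd.read_csv(src / "spikes.csv", keep_default_na=False)
        spikes["spike_time_ms"] = spikes["spike_time_ms"].astype(float)
        spikes["trial"] = spikes["trial"].astype(int)
        rev_path = src / "reversal_times.csv"
        reversal = (
            pd.read_csv(rev_path, keep_default_na=False)
            if rev_path.exists()
            else pd.DataFrame()
        )
        gt_path = src / "ground_truth.json"
        truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
        return cls(spikes=spikes, reversal_times=reversal, ground_truth=truth)


def _expected_epoch_count(
    intensity, task: str, load: LoadCondition, window: tuple[float, float]
) -> float:
    t = np.arange(window[0], window[1], 0.25)
    lam = intensity(t + 0.125, task, load)
    return float(lam.sum() * 0.25 / 1000.0)


def simulate_population(
    sim_config: SimConfig,
    tasks: tuple[str, ...] = TASKS,
    with_kinematics: bool = True,
) -> Dataset:
    """Simulate every unit of every area across the requested tasks.

    Posture and Movie present all nine load conditions; the IN/OUT target
    task presents only the load that drives the unit best (its generative
    preferred direction), as in a recording session where the perturbation
    is chosen per neuron.  Deterministic given ``sim_config.seed``.
    """
    names = [a.area_name for a in sim_config.areas]
    if len(set(names)) != len(names):
        raise ValueError("duplicate area names")
    conds = all_conditions(sim_config.load_magnitude_nm)
    root = np.random.SeedSequence(sim_config.seed)
    area_seqs = root.spawn(len(sim_config.areas))

    spike_rows: list[tuple] = []
    rev_rows: list[tuple] = []
    truth: dict[str, dict] = {}
    epoch = (50.0, 100.0)

    if not tasks:
        raise ValueError("no tasks requested")
    for spec, area_seq in zip(sim_config.areas, area_seqs):
        unit_seqs = area_seq.spawn(spec.n_units)
        for u, unit_seq in enumerate(unit_seqs):
            spike_seq, kin_seq = unit_seq.spawn(2)
            rng = np.random.default_rng(spike_seq)
            unit_id = f"{spec.area_name}_{u:03d}"
            unit_conditions: list[tuple[str, LoadCondition | None]] = []
            for task in tasks:
                if task in ("posture", "movie"):
                    unit_conditions += [(task, c) for c in conds]
                else:  # IN/OUT at the unit's own preferred load
                    unit_conditions.append((task, None))
            rec = simulate_unit(spec, unit_conditions, sim_config, rng, unit_id=unit_id)
            truth[unit_id] = asdict(rec.truth)
            for (task, (s_load, e_load)), trial_list in rec.trials.items():
                for trial_i, spikes in enumerate(trial_list):
                    for t_spike in spikes:
                        spike_rows.append(
                            (unit_id, spec.area_name, task, s_load, e_load,
                             trial_i, float(t_spike))
                        )
            # kinematics for Posture trials
            if with_kinematics and "posture" in tasks:
                intensity = _intensity_factory(
                    spec, rec.truth.latency_ms, rec.truth.preferred_angle_rad,
                    rec.truth.task_gain,
                )
                kin_rng = np.random.default_rng(kin_seq)
                for load in conds:
                    mu = _expected_epoch_count(intensity, "posture", load, epoch)
                    for trial_i, spikes in enumerate(rec.trials[("posture", load.key)]):
                        count = int(((spikes >= epoch[0]) & (spikes < epoch[1])).sum())
                        t_rev = simulate_kinematics(count, mu, sim_config, kin_rng)
                        rev_rows.append(
                            (unit_id, spec.area_name, "posture", load.shoulder,
                             load.elbow, trial_i, count, t_rev)
                        )

    spikes_df = pd.DataFrame(
        spike_rows,
        columns=["unit_id", "area", "task", "shoulder_load", "elbow_load",
                 "trial", "spike_time_ms"],
    )
    rev_df = pd.DataFrame(
        rev_rows,
        columns=["unit_id", "area", "task", "shoulder_load", "elbow_load",
                 "trial", "evoked_count", "reversal_time_ms"],
    )
    return Dataset(spikes=spikes_df, reversal_times=rev_df,
                   ground_truth=truth, config=sim_config)
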