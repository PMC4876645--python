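"""End-to-end analysis pipeline: simulate/load -> tune -> population -> latency -> correlate.

``run_pipeline`` executes the full perturbation-response analysis from one
:class:`RunConfig` and emits tidy report tables (per-unit tuning calls,
per-area population and differential signals, onset reports for both
detection methods and all three contrasts, bootstrap rank matrices, and a
trial-by-trial kinematics correlation summary) plus a machine-readable run
manifest.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .loads import LoadCondition
from .preprocessing import Kernel, make_kernel, spike_density
from .tuning import analyze_units, unit_epoch_table
from .population import (
    population_signal,
    differential_signal,
    sign_flip_calls,
    change_ratio,
    absolute_change_distribution,
)
from .latency import onset_threshold, onset_running_ttest, bootstrap_rank
from .kinematics import unit_trial_correlation, population_correlation_summary
from .simulate import Dataset, SimConfig, AreaSpec, default_sim_config, simulate_population

log = logging.getLogger("spikepert")


@dataclass
class RunConfig:
    """One pipeline run: input mode, analysis parameters, output paths.

    Defaults follow the analysis conventions this pipeline implements:
    50-100 ms response epoch, -100-0 ms baseline, 3 SD threshold with
    20 ms persistence, alpha 0.05, 10,000 bootstrap iterations.
    """

    mode: str = "simulate"                 # "simulate" | "load"
    data_dir: str | None = None            # required in load mode
    out_dir: str = "spikepert_out"
    seed: int = 0
    sim: SimConfig | None = None
    tasks: tuple[str, ...] = ("posture", "movie", "in", "out")
    response_window: tuple[float, float] = (50.0, 100.0)
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    kernel_rise_tau: float = 1.0
    kernel_fall_tau: float = 20.0
    threshold_k: float = 3.0
    persistence_ms: float = 20.0
    alpha: float = 0.05
    n_iter: int = 10_000
    equal_var: bool = True
    correlation_method: str = "pearson"
    window: tuple[float, float] = (-300.0, 300.0)
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load" and not self.data_dir:
            raise ValueError("load mode requires data_dir")
        if self.mode == "simulate" and self.sim is None:
            self.sim = default_sim_config(seed=self.seed)
        if self.sim is not None:
            self.window = tuple(self.sim.trial_window)
            self.dt = self.sim.dt

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw is not None:
            areas = [AreaSpec(**a) for a in sim_raw.pop("areas", [])]
            for key in ("trial_window",):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimConfig(areas=areas, **sim_raw)
        for key in ("tasks", "response_window", "baseline_window", "window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)


def validate_dataset(
    spikes: pd.DataFrame,
    window: tuple[float, float] = (-300.0, 300.0),
    baseline_window: tuple[float, float] = (-100.0, 0.0),
) -> pd.DataFrame:
    """Structural diagnostics for a tidy spike table.

    Checks the schema, spike times against the trial window, per-cell trial
    counts, baseline coverage, and cross-task pairing of units.  Returns a
    table of issues (empty when the dataset is clean); raises only on a
    table missing required columns.
    """
    required = {"unit_id", "area", "task", "shoulder_load", "elbow_load",
                "trial", "spike_time_ms"}
    missing = required - set(spikes.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    issues: list[tuple[str, str]] = []
    bad = spikes[(spikes["spike_time_ms"] < window[0]) | (spikes["spike_time_ms"] > window[1])]
    for row_idx in bad.index[:100]:
        issues.append(("spike_outside_window", f"row {row_idx}"))
    if spikes["spike_time_ms"].min() > baseline_window[0]:
        issues.append(("no_baseline_coverage",
                       f"earliest spike at {spikes['spike_time_ms'].min():.1f} ms"))
    counts = (
        spikes.groupby(["unit_id", "task", "shoulder_load", "elbow_load"])["trial"]
        .nunique()
    )
    for (unit, task), g in counts.groupby(level=["unit_id", "task"]):
        if g.nunique() > 1:
            issues.append(("uneven_trial_counts", f"{unit}/{task}"))
    tasks_by_unit = spikes.groupby("unit_id")["task"].agg(lambda s: frozenset(s))
    all_tasks = set(spikes["task"].unique())
    for pair, label in ((("posture", "movie"), "posture/movie"),
                        (("in", "out"), "in/out")):
        if set(pair) <= all_tasks:
            for unit, tasks in tasks_by_unit.items():
                have = set(pair) & tasks
                if have and have != set(pair):
                    issues.append(("unpaired_unit", f"{unit} lacks {set(pair) - have}"))
    return pd.DataFrame(issues, columns=["issue", "where"])


def _unit_trace(
    unit_spikes: pd.DataFrame,
    task: str,
    kernel: Kernel,
    window: tuple[float, float],
    load: LoadCondition | None = None,
    n_trials: int | None = None,
) -> np.ndarray | None:
    """Trial-averaged spike-density trace of one unit in one task.

    ``load=None`` pools whatever single load the task was run at (the
    IN/OUT task presents only the unit's preferred load).
    """
    sel = unit_spikes[unit_spikes["task"] == task]
    if load is not None:
        sel = sel[(sel["shoulder_load"] == load.shoulder)
                  & (sel["elbow_load"] == load.elbow)]
    if len(sel) == 0:
        return None
    if n_trials is None:
        n_trials = int(sel["trial"].nunique())
    series = spike_density(sel["spike_time_ms"].to_numpy(), window, kernel)
    return series.rate / n_trials


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage and write the report bundle.

    Returns the bundle as a dict of DataFrames / objects; the same tables
    are written as CSV/JSON under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_boot_pert, rng_boot_task, rng_boot_target = _spawn_rngs(config.seed, 3)

    # ---- stage 1: data -------------------------------------------------
    if config.mode == "simulate":
        sim = config.sim
        assert sim is not None
        dataset = simulate_population(sim, tasks=config.tasks)
        n_trials = {t: sim.n_trials(t) for t in config.tasks}
    else:
        dataset = Dataset.from_dir(config.data_dir)
        n_trials = {}
    spikes = dataset.spikes
    log.info("stage=data n_spikes=%d n_units=%d", len(spikes), spikes["unit_id"].nunique())

    diagnostics = validate_dataset(spikes, window=config.window,
                                   baseline_window=config.baseline_window)
    if len(diagnostics):
        log.warning("stage=validate issues=%d", len(diagnostics))

    # ---- stage 2: tuning ----------------------------------------------
    units = analyze_units(
        spikes, alpha=config.alpha,
        response_window=config.response_window,
        baseline_window=config.baseline_window,
        equal_var=config.equal_var,
    )
    units.to_csv(out / "units.csv", index=False)
    log.info("stage=tuning n_units=%d n_responsive=%d", len(units),
             int(units["responsive"].sum()))

    kernel = make_kernel(config.kernel_rise_tau, config.kernel_fall_tau, dt=config.dt)
    responsive = units[units["responsive"]]
    areas = sorted(spikes["area"].unique())
    grid = np.arange(config.window[0], config.window[1] + config.dt / 2, config.dt)
    base_mask = (grid >= config.baseline_window[0]) & (grid <= config.baseline_window[1])
    tasks_present = set(spikes["task"].unique())

    # ---- stage 3: per-unit traces -------------------------------------
    # PTD (from Posture) for posture/movie; the task's own single load for in/out
    unit_traces: dict[str, dict[str, np.ndarray]] = {t: {} for t in tasks_present}
    epoch_tables: dict[str, pd.DataFrame] = {}
    spikes_by_unit = dict(tuple(spikes.groupby("unit_id")))
    for _, row in responsive.iterrows():
        uid = row["unit_id"]
        usp = spikes_by_unit[uid]
        ptd = LoadCondition(row["ptd_shoulder"], row["ptd_elbow"])
        epoch_tables[uid] = unit_epoch_table(
            usp, config.response_window, config.baseline_window,
            n_trials=n_trials or None,
        )
        for task in tasks_present:
            load = ptd if task in ("posture", "movie") else None
            tr = _unit_trace(usp, task, kernel, config.window, load=load,
                             n_trials=n_trials.get(task))
            if tr is not None:
                unit_traces[task][uid] = tr

    # ---- stage 4: population signals + perturbation onsets -------------
    pop_rows, onset_rows = [], []
    pert_traces_by_area: dict[str, np.ndarray] = {}
    evoked_traces_by_area: dict[str, np.ndarray] = {}
    for area in areas:
        uids = [u for u in responsive[responsive["area"] == area]["unit_id"]
                if u in unit_traces.get("posture", {})]
        if len(uids) < 2:
            continue
        mat = np.vstack([unit_traces["posture"][u] for u in uids])
        pert_traces_by_area[area] = mat
        evoked = mat - mat[:, base_mask].mean(axis=1, keepdims=True)
        evoked_traces_by_area[area] = evoked
        sig = population_signal(mat, grid, area=area, label="posture",
                                baseline_window=config.baseline_window)
        pop_rows.append(pd.DataFrame({
            "area": area, "label": "posture", "time_ms": grid,
            "mean_sp_s": sig.mean, "sem_sp_s": sig.sem, "n_units": sig.n_units,
        }))
        res3 = onset_threshold(grid, sig.mean, k=config.threshold_k,
                               persistence_ms=config.persistence_ms,
                               baseline=(sig.baseline_mean, sig.baseline_sd),
                               area=area, label="perturbation")
        rest = onset_running_ttest(grid, evoked, reference_level=0.0,
                                   alpha=config.alpha,
                                   persistence_ms=config.persistence_ms,
                                   area=area, label="perturbation")
        onset_rows += [res3, rest]

    # ---- stage 5: task engagement (Posture - Movie) --------------------
    summary_rows = []
    diff_rows = []
    eng_traces_by_area: dict[str, np.ndarray] = {}
    if "movie" in tasks_present and "posture" in tasks_present:
        for area in areas:
            uids = [u for u in responsive[responsive["area"] == area]["unit_id"]
                    if u in unit_traces["posture"] and u in unit_traces["movie"]]
            if len(uids) < 2:
                continue
            a = np.vstack([unit_traces["posture"][u] for u in uids])
            b = np.vstack([unit_traces["movie"][u] for u in uids])
            # evoked traces so shared baseline rate cancels exactly in the diff
            diff = differential_signal(a, b, grid, area=area,
                                       pair_label="posture-movie")
            eng_traces_by_area[area] = a - b
            diff_rows.append(pd.DataFrame({
                "area": area, "pair": "posture-movie", "time_ms": grid,
                "mean_sp_s": diff.mean, "sem_sp_s": diff.sem,
                "n_units": diff.n_units,
            }))
            onset_rows.append(onset_threshold(
                grid, diff.mean, k=config.threshold_k,
                persistence_ms=config.persistence_ms,
                baseline_window=config.baseline_window,
                area=area, label="posture-movie"))
            onset_rows.append(onset_running_ttest(
                grid, a - b, reference_level=0.0, alpha=config.alpha,
                persistence_ms=config.persistence_ms,
                area=area, label="posture-movie"))
            ev_a = _evoked_epochs(epoch_tables, uids, "posture",
                                  lambda uid: _ptd_of(responsive, uid))
            ev_b = _evoked_epochs(epoch_tables, uids, "movie",
                                  lambda uid: _ptd_of(responsive, uid))
            ratio, _ = change_ratio(ev_a.mean(axis=1), ev_b.mean(axis=1))
            summary_rows.append({
                "area": area, "n_units": len(uids),
                "evoked_posture_mean": float(np.mean(ev_a.mean(axis=1))),
                "evoked_posture_sd": float(np.std(ev_a.mean(axis=1), ddof=1)),
                "differential_movie_mean": float(np.mean(ev_a.mean(axis=1) - ev_b.mean(axis=1))),
                "differential_movie_sd": float(np.std(ev_a.mean(axis=1) - ev_b.mean(axis=1), ddof=1)),
                "change_ratio_movie": ratio,
            })

    # ---- stage 6: target selection (OUT - IN) --------------------------
    sel_traces_by_area: dict[str, np.ndarray] = {}
    abs_change = {}
    if "in" in tasks_present and "out" in tasks_present:
        for area in areas:
            uids = [u for u in responsive[responsive["area"] == area]["unit_id"]
                    if u in unit_traces["out"] and u in unit_traces["in"]]
            if len(uids) < 2:
                continue
            a = np.vstack([unit_traces["out"][u] for u in uids])
            b = np.vstack([unit_traces["in"][u] for u in uids])
            ep_out = [_task_epochs(epoch_tables[u], "out") for u in uids]
            ep_in = [_task_epochs(epoch_tables[u], "in") for u in uids]
            flips = sign_flip_calls(ep_out, ep_in, alpha=config.alpha,
                                    equal_var=config.equal_var)
            for flip_on in (False, True):
                diff = differential_signal(
                    a, b, grid, area=area, pair_label="out-in",
                    sign_flip=flip_on, flip_mask=flips if flip_on else None,
                    reference="baseline", baseline_window=config.baseline_window)
                label = "out-in-flipped" if flip_on else "out-in"
                diff_rows.append(pd.DataFrame({
                    "area": area, "pair": label, "time_ms": grid,
                    "mean_sp_s": diff.mean, "sem_sp_s": diff.sem,
                    "n_units": diff.n_units,
                }))
                onset_rows.append(onset_threshold(
                    grid, diff.mean, k=config.threshold_k,
                    persistence_ms=config.persistence_ms,
                    baseline_window=config.baseline_window,
                    area=area, label=label))
                traces = np.where(flips[:, None], -(a - b), a - b) if flip_on else a - b
                ref = float(traces.mean(axis=0)[base_mask].mean())
                onset_rows.append(onset_running_ttest(
                    grid, traces, reference_level=ref, alpha=config.alpha,
                    persistence_ms=config.persistence_ms,
                    area=area, label=label))
                if not flip_on:
                    sel_traces_by_area[area] = a - b
            mean_out = np.array([np.mean(e) for e in ep_out])
            mean_in = np.array([np.mean(e) for e in ep_in])
            abs_change[area] = absolute_change_distribution(mean_out, mean_in)
            summary_rows.append({
                "area": area, "n_units": len(uids),
                "differential_out_in_mean": float(np.mean(mean_out - mean_in)),
                "differential_out_in_sd": float(np.std(mean_out - mean_in, ddof=1)),
                "abs_change_mean": abs_change[area].mean,
                "abs_change_sd": abs_change[area].sd,
            })

    # ---- stage 7: bootstrap rank matrices ------------------------------
    rank_matrices = {}
    if config.n_iter > 0:
        contrasts = [
            ("perturbation", pert_traces_by_area, rng_boot_pert, "zero"),
            ("posture-movie", eng_traces_by_area, rng_boot_task, "zero"),
            ("out-in", sel_traces_by_area, rng_boot_target, "baseline"),
        ]
        for name, traces, rng, ref in contrasts:
            if len(traces) >= 2:
                rank_matrices[name] = bootstrap_rank(
                    traces, grid, rng, method="threshold_3sd",
                    n_iter=config.n_iter, k=config.threshold_k,
                    persistence_ms=config.persistence_ms, alpha=config.alpha,
                    reference=ref, baseline_window=config.baseline_window)
                rank_matrices[name].proportions.to_csv(
                    out / f"rank_matrix_{name}.csv")
    else:
        log.warning("stage=bootstrap skipped (n_iter=0)")

    # ---- stage 8: kinematics correlation -------------------------------
    corr_df = pd.DataFrame(
        columns=["unit_id", "area", "r", "p", "n_trials"])
    corr_summaries = {}
    if len(dataset.reversal_times):
        corr_rows = []
        rev = dataset.reversal_times
        for _, row in responsive.iterrows():
            uid = row["unit_id"]
            tab = epoch_tables.get(uid)
            if tab is None:
                continue
            sub = tab[(tab["task"] == "posture")
                      & (tab["shoulder_load"] == row["ptd_shoulder"])
                      & (tab["elbow_load"] == row["ptd_elbow"])]
            rsub = rev[(rev["unit_id"] == uid)
                       & (rev["shoulder_load"] == row["ptd_shoulder"])
                       & (rev["elbow_load"] == row["ptd_elbow"])]
            merged = sub.merge(rsub[["trial", "reversal_time_ms"]], on="trial")
            if len(merged) < 5:
                continue
            r, p = unit_trial_correlation(
                merged["response_sp_s"].to_numpy(),
                merged["reversal_time_ms"].to_numpy(),
                method=config.correlation_method)
            if not np.isnan(r):
                corr_rows.append((uid, row["area"], r, p, len(merged)))
        corr_df = pd.DataFrame(
            corr_rows, columns=["unit_id", "area", "r", "p", "n_trials"])
        for area in areas:
            sub = corr_df[corr_df["area"] == area]
            if len(sub) >= 5:
                s = population_correlation_summary(
                    sub["r"].to_numpy(), sub["p"].to_numpy(), alpha=config.alpha)
                corr_summaries[area] = asdict(s)
        corr_df.to_csv(out / "correlations.csv", index=False)
        with open(out / "correlation_summary.json", "w") as fh:
            json.dump(corr_summaries, fh, indent=1, sort_keys=True)

    # ---- outputs -------------------------------------------------------
    onsets_df = pd.DataFrame([{
        "area": r.area, "signal": r.label, "method": r.method,
        "onset_ms": r.onset_ms, "k": r.threshold_k,
        "persistence_ms": r.persistence_ms, "alpha": r.alpha,
        "reference_level": r.reference_level,
    } for r in onset_rows])
    onsets_df.to_csv(out / "onsets.csv", index=False)
    if pop_rows:
        pd.concat(pop_rows).to_csv(out / "population_signals.csv", index=False)
    if diff_rows:
        pd.concat(diff_rows).to_csv(out / "differential_signals.csv", index=False)
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out / "area_summary.csv", index=False)
    diagnostics.to_csv(out / "diagnostics.csv", index=False)

    manifest = {
        "spikepert_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_units": int(spikes["unit_id"].nunique()),
        "n_spikes": int(len(spikes)),
        "config_hash": hashlib.sha256(
            repr(sorted(asdict(config).items(), key=lambda kv: kv[0])).encode()
        ).hexdigest()[:16],
        "parameters": {
            "response_window": list(config.response_window),
            "baseline_window": list(config.baseline_window),
            "threshold_k": config.threshold_k,
            "persistence_ms": config.persistence_ms,
            "alpha": config.alpha,
            "n_iter": config.n_iter,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "dataset": dataset,
        "units": units,
        "onsets": onsets_df,
        "population_signals": pd.concat(pop_rows) if pop_rows else pd.DataFrame(),
        "differential_signals": pd.concat(diff_rows) if diff_rows else pd.DataFrame(),
        "area_summary": summary_df,
        "rank_matrices": rank_matrices,
        "correlations": corr_df,
        "correlation_summaries": corr_summaries,
        "diagnostics": diagnostics,
        "manifest": manifest,
    }


def _ptd_of(units: pd.DataFrame, unit_id: str) -> LoadCondition:
    row = units[units["unit_id"] == unit_id].iloc[0]
    return LoadCondition(row["ptd_shoulder"], row["ptd_elbow"])


def _task_epochs(epoch_table: pd.DataFrame, task: str,
                 load: LoadCondition | None = None) -> np.ndarray:
    sub = epoch_table[epoch_table["task"] == task]
    if load is not None:
        sub = sub[(sub["shoulder_load"] == load.shoulder)
                  & (sub["elbow_load"] == load.elbow)]
    return sub["response_sp_s"].to_numpy()


def _evoked_epochs(epoch_tables: dict[str, pd.DataFrame], uids: list[str],
                   task: str, ptd_lookup) -> np.ndarray:
    """(n_units, n_trials) matrix of trial-wise evoked (response - baseline)."""
    rows = []
    for uid in uids:
        tab = epoch_tables[uid]
        ptd = ptd_lookup(uid)
        sub = tab[(tab["task"] == task)
                  & (tab["shoulder_load"] == ptd.shoulder)
                  & (tab["elbow_load"] == ptd.elbow)]
        rows.append(sub["response_sp_s"].to_numpy() - sub["baseline_sp_s"].to_numpy())
    n = min(len(r) for r in rows)
    return np.vstack([r[:n] for r in rows])
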