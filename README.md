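# spikepert

Perturbation-response analysis of multi-area cortical spike trains.

When a brief mechanical torque is applied to the arm, somatosensory
feedback sweeps through sensory and motor cortex within tens of
milliseconds, and the response in each area depends on what the limb is
being used for. Quantifying that sweep — *when* each area's population
responds, *how strongly*, and *when* responses start to differ between
behavioral contexts — requires a chain of estimators: spike-density
functions, preferred-direction tuning, population averaging, onset
detection, and resampling statistics for onset order. `spikepert`
implements that chain as a tested, reusable pipeline for anyone analyzing
peri-event spike data from perturbation (or other event-aligned)
experiments, together with a ground-truth-known synthetic multi-area
dataset generator for validating every stage.

## What it computes

With spike times `t_s` aligned to perturbation onset (t = 0, ms):

* **Spike density** — `r(t) = Σ_s k(t − t_s)` with a causal asymmetric
  double-exponential kernel `k(t) ∝ (1 − e^(−t/τ_r)) e^(−t/τ_f)`
  (τ_r = 1 ms, τ_f = 20 ms), unit area, output in sp/s.
* **Tuning** — each unit's preferred torque direction (PTD) is the
  shoulder × elbow load combination (of 3 × 3, one unloaded catch)
  maximizing the 50–100 ms evoked response (epoch minus −100–0 ms
  baseline); responsiveness is a two-sample t-test of PTD vs catch epoch
  rates.
* **Population signal** — unweighted across-unit mean ± SEM of
  trial-averaged PTD densities over responsive units; **differential
  signals** are means of per-unit condition differences
  (engaged − disengaged; OUT − IN target), with an optional sign-flip
  control for bidirectionally modulated units.
* **Onset latency** — earliest t ≥ 0 where the signal exceeds baseline
  mean + 3 SD and stays above for ≥ 20 ms; alternatively a running
  one-sample t-test across units against the baseline reference at 1 ms
  steps with the same persistence rule.
* **Onset order** — bootstrap resampling of units within each area
  (10,000 reference iterations), re-detecting onsets and accumulating an
  areas × ranks proportion matrix (no-crossing iterations rank last; ties
  split at random).
* **Behavioral coupling** — trial-by-trial correlation between epoch
  rates and the joint-reversal time of the corrective movement, with
  per-area median and Wilcoxon signed-rank summary.
* **EMG** — 10–150 Hz zero-phase third-order Butterworth band-pass plus
  full-wave rectification, feeding the same onset detector.

## Worked example

Simulate the default five-area dataset (100 units/area, baseline
15 sp/s, configured onset latencies S1 17, A2 18, A5 21, M1 22,
PMd 25 ms) and run the perturbation-response analysis:

```python
import spikepert as sp
from spikepert.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    mode="simulate",
    sim=sp.default_sim_config(seed=0, n_units_per_area=100),
    tasks=("posture",),
    n_iter=1000,
    out_dir="out",
)
bundle = run_pipeline(cfg)

onsets = bundle["onsets"]
pert = onsets[onsets.signal == "perturbation"]
print(pert.pivot(index="area", columns="method", values="onset_ms"))
print(bundle["rank_matrices"]["perturbation"].proportions.round(3))
```

Output (≈ 25 s on one core):

```
method  running_ttest  threshold_3sd
area
A2               18.0           18.0
A5               22.0           22.0
M1               24.0           24.0
PMd              27.0           25.0
S1               18.0           18.0

         1      2      3      4      5
A2   0.218  0.712  0.067  0.003  0.000
A5   0.003  0.011  0.811  0.163  0.012
M1   0.000  0.000  0.072  0.819  0.109
PMd  0.081  0.004  0.021  0.015  0.879
S1   0.698  0.273  0.029  0.000  0.000
```

The detected onsets recover the configured latencies to within 0–2 ms
(the residual lag comes from causal-kernel smoothing), and the bootstrap
rank matrix shows the configured order: S1 first in ~70% of resamples
(its 1 ms lead over A2 sits at the grid resolution, so ties and the
threshold rule's noise tail take the rest), premotor cortex last in 88%.
`out/` additionally contains the per-unit tuning table, population and
differential signal traces, the onset report, rank matrices, and a run
manifest. The same stages run from the shell:

```sh
spikepert simulate --seed 0 --out data/
spikepert all --config cfg.yaml --seed 0 --out out/
```

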