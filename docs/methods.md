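# Methods

This note documents the models, estimators, and design choices behind
`spikepert`, and what its synthetic-data tests do and do not establish
about real recordings.

## Analysis pipeline

**Spike-density estimation.** Spike trains (ms, aligned to perturbation
onset at t = 0) are convolved with a causal asymmetric double-exponential
kernel, `k(t) ∝ (1 − e^(−t/τ_rise)) · e^(−t/τ_fall)` for t ≥ 0, with
τ_rise = 1 ms and τ_fall = 20 ms. The exact algebraic form behind the
"1 ms rise / 20 ms fall" convention is not unique in the literature
(product form vs difference of exponentials); we use the product form
above. At these time constants the two differ negligibly for onset
estimation, but the choice is stated here because it is a choice. The
kernel is truncated at 8·τ_fall and renormalized to unit area over time
measured in seconds, so that each spike contributes one spike of
integrated rate and the convolution output reads directly in sp/s.
Density values are computed by direct evaluation of the continuous kernel
at `t_grid − t_spike` (no binning), so the estimator is exactly the
kernel-sum definition; spikes shortly before the analysis window still
contribute through the kernel tail, avoiding an artificial edge transient.

**Epoch quantification and tuning.** A unit's evoked response is its
trial-mean firing rate in the long-latency epoch (50–100 ms) minus its
baseline (−100–0 ms). Epoch means are computed from raw spike counts
(count/duration), not from the smoothed trace, so kernel smearing cannot
leak post-epoch activity into the epoch. The preferred torque direction
(PTD) is the loaded condition (of 8) with the largest trial-mean evoked
response in the Posture task; exact ties go to the canonical condition
ordering (shoulder axis fastest) and are flagged. Responsiveness is a
two-sample Student t-test (pooled variance; Welch available) of PTD vs
catch-trial epoch rates at α = 0.05. The PTD chosen from Posture data is
reused for the same unit across tasks.

*Selection bias.* Because the PTD is the argmax over eight noisy
condition estimates, evoked responses measured at the PTD are biased
upward by roughly +5–10 sp/s at 10 trials/condition (largest for
high-rate units). This bias propagates into every Table-2-style output
(evoked magnitudes, task differentials, change ratios), in the synthetic
data exactly as it would in real recordings analyzed with the same
procedure. The generator's amplitude targets are *pre-selection*
quantities; measured outputs sit above them by this bias.

**Population and differential signals.** The population signal of an area
is the unweighted across-unit mean (± SEM) of trial-averaged PTD spike
densities over its responsive units. Task contrasts are across-unit means
of per-unit difference traces (Posture − Movie; OUT − IN), computed only
over units recorded in both conditions. For OUT − IN, where baseline
activity may already differ between targets, the reference level is the
mean differential over the baseline window rather than 0. The sign-flip
control negates the difference trace of units whose 50–100 ms epoch
difference is significantly negative (independent two-sample t-test at
α = 0.05 — trials in the two target conditions are interleaved but not
matched, so a paired test is not applicable) before averaging.

**Onset detection.** Two detectors, both requiring persistence of
`ceil(20 ms / dt)` consecutive grid points (the onset is the first point
of the run):

* *Threshold rule:* earliest t ≥ 0 with signal > baseline mean + k·SD
  (k = 3), baseline statistics being the sample mean and SD (ddof = 1)
  over the signal's own −100–0 ms grid points. A zero baseline SD
  degrades the threshold to mean + 1e−6 sp/s and flags the result.
* *Running t-test:* earliest t ≥ 0 where the across-unit one-sample
  t-test against the reference level is two-sided significant at α with
  the across-unit mean above the reference (directional gate), stepping
  every 1 ms. Degenerate time points (zero across-unit variance) count as
  significant iff the mean differs from the reference.

Known behavior of the threshold rule at high SNR: when the threshold sits
at a few percent of the evoked amplitude, baseline noise excursions
within one noise-correlation time (~20 ms, set by the kernel) before the
true rise can merge with it and satisfy the persistence requirement,
producing occasional detections a few ms early. This left tail is
intrinsic to the rule, not to the data generator; it is visible in the
bootstrap onset distributions.

**Bootstrap rank ordering.** Units are resampled with replacement within
each area (preserving the area's unit count), the population or
differential signal is rebuilt, the onset re-detected (baseline
statistics recomputed per iteration — reusing full-sample statistics was
measured to be strictly worse, since resampling shifts the baseline level
relative to a fixed threshold), and areas are ranked by ascending onset.
A signal that never crosses counts as latest; all ties (finite or not)
are broken uniformly at random within the iteration, which keeps the
rank-proportion matrix doubly stochastic and retains no-crossing
iterations. For differential contrasts the same resampled unit
contributes both conditions (paired resampling).

**Kinematics correlation.** The joint-reversal time of a trial is the
time of maximum Euclidean distance from the start posture in
(shoulder, elbow) angle space, restricted to the segment before the
trajectory first re-enters a return radius (default 20% of peak
excursion — the task's hand-space tolerance cannot be mapped to joint
space without limb geometry, so the radius is relative and configurable);
a trajectory that never returns falls back to the global argmax with a
flag. Per unit, trial-wise PTD epoch rates are correlated with reversal
times (Pearson by default, Spearman optional); per-area summaries report
the median correlation, a Wilcoxon signed-rank test against zero (exact
null for n ≤ 25, normal approximation with continuity correction above),
and the count of units significant at 0.05.

**EMG.** Raw traces are band-pass filtered 10–150 Hz with a third-order
Butterworth applied forward and backward (zero phase, effective order 6)
and full-wave rectified. Zero-phase filtering preserves onset alignment
on average but smears energy acausally: on very deeply averaged traces
(≥ 500 trials) the 3 SD threshold shrinks enough that the filter's
acausal tail is detected a few ms before the true envelope onset. At
session-scale averaging (~100 trials) detection is unbiased to within the
grid step.

## Synthetic data generator

Spikes are drawn from an inhomogeneous Poisson process by exact thinning
against an analytic intensity bound,

    λ(t) = baseline + tuning(load) · peak · [ b(t − ℓ_u) + (g_task − 1) · b(t − ℓ_u − d_task) ],

where `b` is the peak-normalized difference-of-exponentials bump
(rise 1 ms, decay 40 ms by default), `ℓ_u` the unit latency (area latency
+ N(0, 1 ms) per-unit jitter, fixed across trials), `g_task` the
multiplicative task gain relative to Posture, and `d_task` a divergence
delay allowing late task effects. Tuning over the eight loaded torque
directions is a raised cosine `((1 + cos Δθ)/2)^(1/width)` of the angle
between the condition's shoulder–elbow torque vector and the unit's
preferred angle (uniformly drawn); the catch condition gets tuning 0.
Configurations whose intensity would go negative anywhere are rejected.
Randomness comes from one seed split hierarchically (area → unit →
{spikes, kinematics}), so datasets are byte-reproducible independent of
iteration order.

Defaults emulate five sensorimotor areas under mechanical arm
perturbations: latencies S1 17, A2 18, A5 21, M1 22, PMd 25 ms; baseline
15 sp/s; 10 trials per load condition (Posture and Movie, 9 conditions
each), 20 trials per target (IN/OUT at the unit's preferred load only);
trial window −300–300 ms at dt = 1 ms. Amplitudes are specified as
target *epoch-mean* evoked responses (S1 68.5, A2 38.7, A5 30.3,
M1 43.3, PMd 26.9 sp/s) and converted to profile peaks by the epoch
factor of the evoked bump at the area's latency. Movie gains are derived
the same way from target change ratios (S1 9%, A2 15%, A5 36%, M1 36%,
PMd 40%) using the delay-shifted epoch factor, with divergence delays
(S1 22, A2 50, A5 0, M1 15, PMd 17 ms) so the engagement effect starts
immediately in A5 and later elsewhere. Target-selection gains boost OUT
responses in motor areas with late delays (M1 +30% at 44 ms, PMd +25% at
73 ms, parietal areas small and very late, A2 none), and a configurable
fraction of units is "sign-flipped" (their IN/OUT gains swapped),
emulating bidirectionally modulated populations.

The evoked rise constant (1 ms) and latency jitter (SD 1 ms) are the
package's own choices — the single-unit response shape and inter-unit
latency dispersion are not published quantities. They are set so that the
configured area latency is identifiable: the population rise must be
sharp relative to the causal kernel's smoothing for a threshold detector
to localize it to within the ~2 ms detection lag; broader jitter or
slower rises shift detected onsets later by the corresponding smear.

Each Posture trial carries a joint-kinematics record: the reversal time
is `base − slope·z + noise` with `z` the Poisson-standardized evoked
count and the slope set from the target activity–kinematics correlation
(default −0.11, noise SD 30 ms, base 220 ms), and the emitted two-joint
trajectory attains its maximum joint-space excursion exactly at that
time (quarter-sine out, quarter-cosine back, 0.15 rad excursion). EMG
trials are unit-variance white noise at 2 kHz amplitude-modulated by
`baseline + gain · b(t − 34 ms)` (rise 3 ms, decay 30 ms, gain 2×
baseline by default).

What the generator does *not* emulate: non-Poisson spiking (refractory
periods, bursting), rate drift across trials, correlated noise across
simultaneously recorded units, heterogeneous baseline rates, realistic
EMG physiology, or biomechanical limb dynamics. Passing parameter-recovery
tests on this generator therefore establishes correctness of the
estimators under the stated model, not robustness to those features of
real data.

## Numerical choices and problem sizes

* dt = 1 ms everywhere (matching the 1 ms stepping of the running test);
  onsets are therefore quantized to 1 ms.
* Kernel truncation at 8 fall-times; unit area enforced after truncation.
* Thinning bound: `baseline + tuning·peak·(1 + max(0, g − 1))`, exact
  because the bump is peak-normalized.
* Bootstrap iterations: tests use 1,000 and the acceptance script 2,000
  (scaled down from the reference 10,000); rank proportions at these
  sizes carry binomial noise of ~1–2 points.
* The responsiveness/correlation calibration checks use 10,000 simulated
  null units/pairs, giving a ±0.6-point binomial band around α = 5%.
* Degenerate inputs: empty spike trains yield zero-rate series; constant
  baselines flag the onset result; zero-variance correlation inputs are
  excluded and logged; change ratios with non-positive denominators are
  reported as undefined.

## Known limitations

* Rank-order recovery between areas whose configured latencies differ by
  a single grid step (S1 vs A2, 1 ms apart) is capped around 70–90%
  first-place proportion depending on the dataset draw: exact onset ties
  are split randomly, and the threshold rule's merge-assisted left tail
  occasionally awards first place elsewhere. This mirrors the behavior of
  the rule itself rather than an estimator defect.
* The threshold detector's baseline SD is estimated from 101 strongly
  autocorrelated samples (~10 effective degrees of freedom); in a few
  percent of bootstrap iterations the underestimated SD produces a
  spuriously early onset. Iterations are kept (and visible in the onset
  distributions) by design.
* Differential onsets for weak, late effects (e.g. a 9% suppression
  starting 22 ms after a 17 ms response) are detected with several ms of
  lag, since the differential amplitude crosses 3 baseline SDs well after
  divergence begins.
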