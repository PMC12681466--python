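# Methods

This note documents the models, numerical choices and open design
decisions behind `erfp`, in the spirit of a statistics package's methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The measurement chain

### Filtering

The continuous moment signals are low-pass filtered with a Butterworth
design applied forward and backward (`scipy.signal.sosfiltfilt`), giving
zero phase shift and an effective magnitude response of twice the design
order.  Defaults: cut-off 10 Hz, design order 4 (`dual_pass_4`).  The
acquisition convention "4th-order dual-pass" is ambiguous between a
4th-order design passed twice and a 2nd-order design whose two passes sum
to fourth order; both readings are available (`filter.mode =
dual_pass_4 | dual_pass_2x2`), the former is the default.  With a 10-Hz
cut-off the shortest oscillation left in the signal (100 ms) matches the
integration-window length, restricting the analysis to supraspinal balance
control.

Filtering happens on the continuous recording *before* segmentation so
that the dual-pass edge transients fall at the recording boundaries, not
inside every 3.5-s epoch.  A unit test verifies that filtering and
segmentation commute away from epoch edges.

### Epoching

Epochs are aligned at the fixation-cross/cue onset (t = 0) and nominally
span −500…+3,000 ms.  Conventions: 0-based sample indices; epoch windows
inclusive at both ends in milliseconds, so the default window holds
3,501 samples at 1 kHz; sample-index ↔ millisecond conversion is exact at
integer milliseconds.  Because the sliding window is centered, the
pipeline actually cuts padded epochs (−550…+3,050 ms) and crops the
variability series back to the analysis window, so every output time has
full window support and no shortened-window bias exists at the bounds.

### Sliding-window variability

`sliding_sd` computes the sample SD (denominator n−1, matching the R
default) in a 100-ms window moving in 1-ms steps.  Windows are centered —
the value at t summarises [t − w/2, t + w/2), keeping variability
temporally aligned with its cause — with a trailing mode available in
config.  Values are reported in mN·m (×1000 from N·m); raw files stay in
physical units (N, N·m) and the conversion happens only at this stage.
The implementation uses cumulative sums (O(n) per epoch) after de-meaning
the series for numerical stability, and is tested against a naive
per-window recomputation to 1e-9.

Axis combination averages the ML and AP *variabilities* pointwise
(SD first, then average), not the raw signals.  Per-trial order:
SD per axis → combine axes → average across a participant's included
trials → participant × condition time course.

### Trial exclusions

Flags are computed in a fixed order:

1. **RT outliers** — responded trials deviating more than 3 SD from the
   participant's mean RT, mean and SD computed over *all* responded trials
   (whether the criterion should instead be computed after removing error
   trials is not determinable from the source conventions; this order is a
   documented choice).
2. **Errors and post-error trials** — analysis-specific: the memory-task
   error analysis excludes RT-task errors, the RT-task error analysis
   excludes memory errors, and the RT analysis excludes both; trials
   immediately following any error are excluded throughout.  The
   force-plate analysis reuses the RT analysis' trial set.
3. **First remaining trial of each block** (the experimenter started
   blocks for the participant).

The pass is idempotent: flags depend only on the base columns, so
re-running on a flagged table reproduces itself.

### Cluster-based permutation test

Pointwise paired t (df = N−1; t ≡ 0 where the difference variance
vanishes); cluster-forming threshold = two-sided critical t at
`cluster_alpha` = .05 — the field-standard choice where only "a predefined
threshold" is specified; a sign change splits otherwise contiguous
suprathreshold runs.  The permutation scheme flips the sign of each
participant's whole difference series independently (equivalent to
exchanging condition labels within participants).  The null statistic is
the **maximum |cluster mass| per permutation**, which controls the
familywise error rate jointly over the time base and both signs; p-values
use the +1-corrected estimator (1 + #{null ≥ observed})/(n_perm + 1), ties
counting as exceedances, and the observed labeling is not forced into the
null sample (the +1 correction plays that role).  An exhaustive mode
enumerates all 2^N sign patterns and returns exact p = #{≥}/2^N; the
randomized p is tested to converge to it within Monte-Carlo error.
Multi-factor designs are handled as separate paired contrasts (four in the
two-factor experiment), not as a factorial cluster test.

### Behavioral statistics

Paired t with Cohen's d on difference scores (d_z) — the variant is not
uniquely determined by convention; d_z is the natural companion of the
paired t.  The 2×2 within-subject ANOVA is evaluated through paired
contrasts: each 1-df effect is a per-participant contrast score, F = t²,
partial η² = t²/(t² + N − 1); this is algebraically identical to the
classical SS decomposition (tested against a hand-computed SS oracle and
against `pingouin.rm_anova`).  Grand means are unweighted means of
participant cell means.  Two-sided p-values throughout; no normality
screening — the parametric tests are run unconditionally.

## 2. The synthetic generators

### Behavior

RT = base(load) + max(0, C(load) − SOA) + ε, with ε ex-Gaussian
(Gaussian σ = 60 ms plus exponential τ = 80 ms, shifted to zero mean) —
right-skewed RT noise is standard; the scale gives plausible within-cell
SDs (~100 ms) and was not fitted.  Calibrated defaults solve the printed
condition means of the two experiments:

| design | base (ms) | C (ms) | expected cells (ms) |
|---|---|---|---|
| SOA only | 613 | 338 | 851 / 613 |
| report | 649 | 296 | 845 / 649 |
| ignore | 624 | 194 | 718 / 624 |

Errors are Bernoulli (2% manual, 2% vocal; no vocal response in ignore
trials).  Block structure: every SOA × tone × orientation (× load) cell
appears `trials_per_cell` times per block in quasi-random order; the five
visual objects appear equally often with no immediate repetition
(repair-based shuffle); the tone-key mapping alternates across
participants.  Counterbalancing beyond that is simplified to the
quasi-random shuffle.

*Known gap:* there is no between-participant variance in base or C, so
simulated group-level t and F statistics are far larger than typical
empirical ones; grand-mean effects — the quantities the calibration
targets — are unaffected.

### Sway

Intermittent-control stand-in: per axis, a stationary Ornstein–Uhlenbeck
baseline (SD 0.02 N·m, time constant 300 ms; AR(1) discretisation with a
10-τ burn-in) plus corrective impulses — Gaussian bumps of amplitude
0.02 N·m and total width 150 ms (SD = width/5), truncated at ±width/2 —
at event times drawn from an inhomogeneous Poisson process discretised to
the 1-kHz sample grid (per-sample Bernoulli thinning of λ(t)/fs).  Event
times are shared between axes; each axis gets an independent random sign,
keeping the moment signal zero-mean (sliding SD is sign-invariant, so this
choice does not affect any tested quantity).

λ(t) = λ0 · phase(t) · condition, with λ0 = 2 impulses/s and default phase
multipliers pre-fixation 1.0, fixation-to-target 1.2, suppression (visual
target → response) 0.6, rebound (response → epoch end) 1.4 — emulating
variability that is elevated around the fixation cross and suppressed
before the manual response.  Between trials the rate is λ0.  Condition
multipliers (per SOA/load, scalar or per-phase) and fixed condition
windows (start, end, multiplier relative to cue onset) allow embedding
effects at known times.  No quantitative sway effect sizes are available
to calibrate against, so these magnitudes are stated, not estimated, and
the simulator is validated by error control and recovery, not by
reproducing empirical cluster masses.

Forces are placeholders (Fz ≈ 687 N body weight, Fx = Fy = Mz = 0): only
the moments are analysed.  Trials are laid out 4.5 s apart (cue to cue),
comfortably exceeding the 3.6-s padded epoch span; overlapping layouts
raise an error.  The generator does **not** emulate inverted-pendulum
dynamics, center-of-pressure geometry, drift, or vocal-response timing —
a green pipeline test establishes correct statistics and bookkeeping, not
biomechanical fidelity.

## 3. Validation simulations

`erfp.validation` builds paired designs in which the two conditions of
every participant have *identical trial timing* (same SOA, same response
latency, interleaved trials in one recording), so condition differences
can only come from an embedded rate manipulation — never from event-time
confounds:

* **Null FWER** (`null_fwer`): 200 datasets × 24 participants × 10
  trials/condition, 1,000 permutations; the fraction of datasets with any
  significant cluster is compared to the one-sided 95% binomial bound
  around α = .05 (≈ .075 at 200 datasets).  10 trials per condition keeps
  the 200-dataset run near two minutes on one CPU; the FWER of the test
  does not depend on the trial count, which only scales the variance of
  the condition means.
* **Recovery** (`recovery_rate`): 20 replicates × 24 participants × 80
  trials/condition with the impulse rate scaled ×0.4 inside
  1,600–2,000 ms in one condition; a replicate succeeds when its most
  significant cluster overlaps that window with temporal Jaccard ≥ 0.3.
  500 permutations per replicate (minimum attainable p ≈ .002 ≪ .05)
  keep the 20-replicate run under two minutes.

## 4. Known limitations

* The cluster test implements one defensible configuration
  (max-|mass| null, two-sided t threshold at .05); other permutation
  packages' defaults may differ, so cluster masses from re-analyses of
  real data need not match published values obtained with other tools.
* Epoch times assume an exactly uniform sample clock; irregular exports
  are rejected rather than resampled.
* The within-subject CI (Cousineau centering with the Morey correction)
  is a plotting aid, not an inferential device; the cluster test is the
  inference.
* `rm_anova_2x2` is restricted to 2×2 within designs — by construction
  every effect has 1 df, which is what the F = t² formulation requires.
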