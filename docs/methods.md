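# Methods

This note documents the models, conventions and numerical choices behind
`rewardops`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, what the synthetic cohorts do and do not emulate,
and where genuinely open design points were fixed by decision.

## Behavioural tasks and measures

**DRLM (discriminative reward learning-memory).** Each session presents up
to 40 tone-DS trials. A DS lasts at most 30 s; one feeder response within
the DS triggers pellet delivery and tone termination 1 s later.
Consecutive DS presentations are separated by variable inter-trial
intervals (ITIs) with mean 50 s and range 20–80 s; ITI feeder responses are
counted but have no consequence. Analysis uses the first 20 trials of each
test. Per test and mouse: pellets = responded DS trials; median DS
response latency over all analysed trials with 30 s imputed for
non-responders (the imputation applies only to the latency median —
non-responded trials never enter DS-on photometry analyses); median ITI
response interval = median over ITIs of (ITI duration / responses in that
ITI); learning ratio = median ITI interval / median DS latency.

Two conventions needed fixing:

* *Zero-response ITIs.* The per-ITI interval is undefined when an ITI has
  no responses; such ITIs are excluded from the median. If **no** ITI has
  a response the interval is imputed to the 80-s maximum ITI duration and
  a warning is logged.
* *Ratio mode.* The learning ratio is reported as the ratio of medians by
  default; a per-trial mode (median over trials of interval/latency) is
  also computed and emitted in the metrics tables
  (`learning_ratio_per_trial`), since both formulations appear in the
  literature on this task.

**REV (reward-to-effort valuation).** Nose-pokes are reinforced on the
progressive-ratio schedule r(k) = 4·⌊(k−1)/5⌋+1. Ratio completion elicits
a 1-s tone DS plus pellet delivery; retrieval is followed by a 5-s timeout.
Sessions end at the time limit (no breakpoint criterion) or, in the
generator, when the quitting hazard fires. Measures: total operant
responses, pellets earned, final ratio attained, median retrieval latency
(ratio completion → feeder response), median post-reinforcement pause
(feeder response → next operant response), and per-PR-block medians of the
operant phase (first → last poke) and post-operant phase (DS onset →
feeder response). Trials are delimited in the log by pellet deliveries; a
trailing run of pokes without delivery forms one incomplete trial.

Trial indices are 1-based; all time windows are half-open [start, end);
times are seconds from session start.

## Photometry model

**Down-sampling.** The 970 → 20 Hz factor is non-integer (48.5). The
package uses window-mean resampling: each 20-Hz output sample is the mean
of the raw samples in its half-open 50-ms window. This is deterministic,
mean-preserving and free of filter-design ambiguity; it is one of several
defensible readings of "down-sampled to 20 Hz" and is fixed here as a
documented convention (a sensitivity-analysis hook, not a claim about the
original acquisition code).

**Per-trial z-scoring.** For each trial the baseline is the 10 s
immediately before phase onset — DS onset in DRLM, the trial's first
operant response in REV. z(t) = (F(t) − F₀)/SD₀ with F₀, SD₀ the mean and
**population** SD (divisor N; the divisor is not dictated by the formula,
so it is fixed and documented) of the baseline samples at 20 Hz. By
construction the baseline window itself has mean z = 0 and SD 1; this is
asserted to 1e−9 in the tests. Degenerate trials (baseline extending
before the trace, SD₀ = 0) are excluded and counted in a QC report.

**Binning.** Variable-length phases are time-normalized: the phase is
split into 10 equal-duration sub-windows and each bin is the mean of the
samples falling in it. The minimum phase duration is 0.5 s (≥ 10 samples
at 20 Hz, one per sub-window); shorter phases are excluded per phase and
counted in QC. Should a sub-window still be empty, it is filled by linear
interpolation between neighbouring non-empty bins (never extrapolated —
edge gaps copy the nearest non-empty bin). Fixed phases span 5 s binned
into 10 × 0.5-s intervals and require full sample coverage. The ITI
feeder phase starts at the first feeder response of the ITI after the 5-s
post-DS feeder window and is normalized against the **preceding** trial's
pre-DS baseline.

**Aggregation.** Per-trial bins are averaged per mouse × test with
selections for trial windows (1–20, 1–10, 11–20), responded/completed
trials only, and PR block. A non-binned phase mean (grand mean z over the
phase) is carried alongside. Mice with no qualifying trials simply have
no row; the imbalance propagates to the statistics stage.

## Statistics

Screening uses the boxplot rule (outside Q1 − 1.5·IQR, Q3 + 1.5·IQR, per
group; groups of < 4 are not screened). Normality (Shapiro–Wilk per
group) and variance homogeneity (Levene) are advisory: the pipeline
proceeds and retains the report.

The mixed-design ANOVA is the classical univariate decomposition with one
between-subjects factor and one or two fully-crossed within-subjects
factors. Between effects are tested against subjects-within-groups;
each within-factor family (main effect and its group interaction) against
its subject × factor stratum. With unequal group sizes the conventional
weighted-means solution is used; on balanced designs the decomposition is
exact (the strata partition the total SS) and the implementation is
checked to 1e−8 against a brute-force oracle and against `pingouin` for
the 1-within case. Subjects with missing within cells are dropped
listwise per analysis and counted. No sphericity correction is applied by
default, matching the classical reporting style for these designs; the
group main effect — the primary contrast — does not depend on sphericity.
Post-hocs are Tukey–Kramer via the studentized-range distribution; Sidak
adjustment is provided for small planned families. The two-step planned
contrast first compares the two control groups (pooled-variance t test);
at p > 0.05 they are combined and a single pooled-control vs experimental
contrast is run, otherwise pooling is refused and per-control contrasts
are reported. Significance is two-sided at p ≤ 0.05.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuning
knobs.

* **ITI schedule**: uniform on [20, 80] s. Only the mean (50 s) and range
  are specified by the task; the uniform family matches both with the
  fewest assumptions and is the one distributional choice made here.
* **Responding**: each DS trial is responded with probability p —
  CON 24.4/40, CSS 18.4/40, the published per-test means. A per-mouse
  logit-normal random effect (σ = 0.4) reproduces the published
  between-animal spread (per-test SD ≈ 5.4 simulated vs 5.6 reported).
  Responding declines within a session (first half p·1.45, second half
  p·0.55, marginal preserved), reflecting the observed concentration of
  responses in the analysed first 20 trials; this is what makes the
  test-1 learning ratio start near 1.
* **Latencies**: log-normal (σ = 0.5 in log space) truncated at 30 s by
  inverse-CDF sampling. Medians: CON 8 → 5 → 3 s across tests (learning),
  CSS flat at 8 s. ITI responses: Poisson at 0.125 Hz (CON) / 0.10 Hz
  (CSS), skipping the 5-s retrieval window. These choices produce the
  phenotype the analysis must recover: control learning ratios rising
  from ≈ 1 to ≈ 2.5 across tests while CSS stays near 1.
* **REV**: log-normal inter-poke intervals (median 2 s CON, 4 s CSS),
  retrieval latencies (1.5 / 2.5 s), pauses (5 / 10 s), and a pre-trial
  quitting hazard proportional to the trial's required ratio (0.01 CON,
  0.03 CSS per ratio unit). Under these rates ≈ 85–90 % of CSS mice reach
  PR 5, matching the reported 15/17, and control breakpoints land around
  PR 9–13.
* **Traces**: each labelled event adds a peak-normalized
  difference-of-exponentials kernel (rise 0.1 s, decay 1.0 s) scaled by a
  group × phase amplitude onto a constant baseline (10 a.u.) with white
  Gaussian noise (SD 0.5) and optional linear drift. DS-onset amplitudes:
  CON 1.0 (trials 1–10) rising to 2.0 (trials 11+), CSS flat 1.0 — hence
  CSS < CON DS-on activity in late trials. REV amplitudes at the operant
  run and ratio completion: CON −0.6 (suppression below baseline),
  CSS +0.6 — hence CSS > CON at PR 5. Reward-retrieval transients are
  +2.0 in both groups. A per-mouse log-normal amplitude factor (σ = 0.2)
  adds animal-level variability. The analysis pipeline is deliberately
  independent of these kernel details.

What the generator does **not** emulate: photobleaching, hemodynamic or
motion artefacts, an isosbestic control channel, correlated (1/f) noise,
within-session amplitude drift, or any coupling between behavioural
vigour and transient amplitude beyond the phase labels. Passing tests
therefore validate the event-log and signal-processing arithmetic and the
statistical calibration of the pipeline — not robustness to real-world
artefacts, which would require the excluded corrections.

**Randomness.** All draws flow from the single cohort seed through named
substreams keyed by (seed, group, mouse, session-kind, test), so cohorts
are byte-identical across runs and generation order.

## Simulation-study problem sizes

The end-to-end calibration studies in the test suite run the full
generator → trace → segmentation → z-score → ANOVA path on scaled-down
cohorts chosen once for desk-scale runtime: raw rate 100 Hz (five times
the 20-Hz analysis rate, so the down-sampling path is still exercised),
20-trial DRLM sessions, one test day. The type-I study uses 1,000 null
cohorts at n = 6/group (both groups given identical parameters) and
checks that the group-main-effect rejection rate's 95 % CI covers 0.05;
the power study uses 60 cohorts at the calibrated CSS effect with
n = 13/group and requires ≥ 80 % detection. Directional checks
(CSS DS-on < CON in trials 11–20; CSS operant > CON at PR 5) use one
13/group cohort.

## Known limitations

* The weighted-means mixed ANOVA assumes missing within-cells are handled
  by listwise deletion; no REML/mixed-effects alternative is provided.
* Interval (within-factor) F tests inherit the usual sphericity
  sensitivity; Greenhouse–Geisser-style correction is not applied by
  default.
* The downsampler is a window-mean, not an anti-aliased decimator; for
  signals with strong content near 10 Hz the two differ.
* ROUT-style regression-based outlier detection is not implemented; only
  the boxplot rule is.
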