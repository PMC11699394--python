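# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `pupilsync`, in the spirit of a package methods appendix:
what is computed, why the defaults are what they are, and what passing the
test suite does and does not establish about real recordings.

## Tapping measures

**Spontaneous motor tempo (SMT).** Per unpaced trial, the mean inter-tap
interval after discarding the first ten taps (warm-up/stabilization); the
participant's SMT is the mean of the per-trial means. Metronome intervals
for the three tempo conditions are the SMT interval scaled by 0.8 (Faster)
and 1.2 (Slower). "20 % faster" is read as a 20 % shorter interval — the
symmetric-interval reading; the rate-based alternative (ITI/1.2) would give
an asymmetric design and is not used.

**Matching and cleaning.** Each tap is matched to its nearest cue; the
signed asynchrony is tap − cue, so anticipation is negative. Deterministic
tie-breaks: a tap exactly midway between cues goes to the earlier cue; when
several taps land on one cue, the smallest |asynchrony| is kept and the rest
are dropped as extras. The first four matched taps are discarded, trials
with fewer than 40 remaining recorded taps are flagged excluded (a flag,
never an error), and asynchronies more than 3 within-trial SDs from the
within-trial mean (computed after the four-tap discard) are removed.
Cleaning is idempotent: a cleaned series passes through unchanged, so
re-running a stage never re-discards taps. The outlier SD is computed per
trial, not per condition.

**Circular summary.** Asynchronies map to phases on the cue-interval circle
(360° = one ITI); the mean resultant vector's modulus is synchronization
consistency and its argument, reported in (−180°, 180°], is accuracy
(negative = taps precede cues). R is invariant to shifting all asynchronies
by whole intervals, and for Gaussian jitter σ approximates the
wrapped-normal expectation exp(−(2πσ/ITI)²/2) — both are property-tested.

## Pupil cleaning chain

Fixed order: blink padding → smoothing + interpolation → baseline
correction → dilation-speed rejection → range screen → missing-data screen.
No stage ever re-validates a sample except interpolation.

- **Blink padding (±100 ms).** Every sample within 100 ms of an invalid
  sample is invalidated (binary dilation of the invalid mask), removing the
  partial-occlusion ramps flanking blinks.
- **Smoothing (4 ms) and interpolation (< 1000 ms).** The moving-average
  window is `round(window·rate)` samples — 2 samples at 500 Hz, i.e. nearly
  minimal smoothing, which is documented rather than "fixed". The window is
  centered, leaning one sample earlier when even. Gaps strictly shorter
  than 1000 ms with ≥ 2 valid samples on each side are filled by a cubic
  spline fit through the valid samples (linear fallback below 4 points);
  edge gaps and longer gaps stay invalid.
- **Baseline correction.** Subtract the median valid value of the 1000 ms
  pre-stimulus window; an empty window excludes the trial ("no baseline").
  Subtraction only shifts the scale, so downstream means are relative to
  the pre-stimulus level.
- **Dilation speed (median + 16·MAD).** The speed of each valid sample is
  the larger absolute slope to its valid neighbors; samples above
  median + 16·MAD are invalidated in a single pass (the cited procedure
  permits iterating; one pass is used because nothing more is specified).
  When MAD = 0 (e.g. constant signal plus one spike) the threshold floor
  median + 16·ε·max(1, |median|) keeps constant traces intact while still
  catching the spike. Note the filter assumes a noisy speed distribution;
  on noiseless smooth signals with long quiescent stretches the MAD
  degenerates and the floor makes it aggressive — irrelevant for real or
  generated (noisy) data.
- **Range screen.** The histogram an experimenter would inspect is written
  as a text table; an optional [low, high] range invalidates outliers. Off
  by default — the study's equivalent step is a visual inspection.
- **Missing-data screen (strict 33 %).** Exclusion if *more than* 33 % of
  samples are missing; exactly 33 % is retained. The fraction counts
  samples invalid *before* interpolation fills plus anything invalidated
  later, so interpolation cannot rescue an unusable trial. The published
  chain lists interpolation before the screen without saying which count is
  used; both are implemented (`missing_before_interp`), with the
  conservative reading as default. The trial mean is over valid samples of
  the entire trial window, on the baseline-corrected scale.

## Phase coherence

Entrainment is estimated per trial: (1) restrict to [cue 5, end of the
60th cue interval) — the first four intervals carry the orienting response;
(2) zero-phase third-order Butterworth high-pass at 0.05 Hz (forward–
backward; a single pass would rotate phases frequency-dependently and bias
coherence), with remaining invalid runs bridged linearly for filtering only
and re-masked afterward, and padding of ~3 filter time constants so the
edge transient of the very low cutoff does not leak into the trace;
(3) z-score over valid samples (per trial, before epoching, per the
published order); (4) cut into phrases of four cue intervals starting at
cue 5 — phrases are time-locked to cues, not taps, so listening trials are
computable; a 60-cue trial gives exactly 14 phrases; phrases with > 50 %
invalid samples are dropped, and fewer than two retained phrases is an
error; (5) FFT per rectangular-windowed phrase. Because the phrase spans
exactly four periods, the metronome frequency is bin 4 with no leakage for
a stationary sinusoid; the phrase sample count is `round(4·ITI·rate)`, a
≤ 0.5-sample truncation negligible at 500 Hz.

PC is the modulus of the mean unit phasor of the bin-4 coefficients across
retained phrases; zero coefficients are dropped (logged). "Normalization"
is exactly this division by phrase count of unit phasors — PC is already in
[0, 1] and amplitude-blind, hence comparable across tempi; no further
scaling is applied. Coherence at neighboring bins (−1, +1, +2 by default)
is reported purely as a spectral-leakage diagnostic; an alternative that
averages the kept coefficients before phase extraction exists behind
`average_neighbor_coeffs` (off by default — the diagnostic reading keeps
the reported statistic bin-exact). For unpaced trials the tap onsets play
the role of cues and the trial's mean inter-tap interval sets the target
frequency, which is what makes the movement-only control computable.

The null expectation for N independent uniform phases is
E[PC] ≈ √π/(2√N) ≈ 0.237 for N = 14; the Monte-Carlo suite checks this to
2 %.

## Inference

Condition tables hold one value per participant × condition cell (mean over
retained trials). Participants missing any cell for a measure are dropped
from that measure's analysis with a logged reason, keeping the design
balanced — unbalanced input to the ANOVA is an error by contract.

The 3 × 2 within-subject ANOVA reports F with uncorrected df (no sphericity
correction by default; Greenhouse–Geisser p values are available) and
generalized eta squared, ges = SS_effect / (SS_effect + SS_subjects +
Σ within-error SS), computed via pingouin and verified in the tests against
an independent hand-written sum-of-squares partition to 1e-10. Post-hoc
contrasts are standard paired t-tests (df = n − 1) — the "Welch" label
sometimes attached to paired designs is a misnomer, as Welch's correction
applies to independent samples — adjusted by Benjamini–Hochberg FDR across
the family of task contrasts at each tempo. The paired effect size is
d = mean(diff)/SD(diff), which satisfies d = t/√n exactly (e.g. t = 4.434,
n = 23 → d = 0.92); a pooled-SD variant is available. Zero-variance
differences are flagged degenerate and reported with infinite-magnitude t
and p = 0 rather than NaN. The tapping-performance ANOVA over tempo uses
the standard one-way within df (2, 2(n−1)).

## Synthetic data

The generator is the test bed: it produces data with the structure the
pipeline assumes, plus ground truth.

- **Cohort.** Participant SMTs are drawn from N(692.34, 190.34) ms clipped
  to [462, 1192] ms — the distribution of spontaneous tempi this kind of
  cohort shows. Each synthetic participant's metronomes are derived from
  the *measured* SMT of their simulated unpaced trials, exactly as an
  experimenter would.
- **Taps.** Paced taps are cue + N(−30, 25) ms (anticipatory mean, values
  typical of paced finger tapping); each tap is unrecorded with p = 0.02,
  and ~4.5 % of trials are "soft-tapping" trials missing taps at rate 0.35
  — these are the trials the 40-tap minimum screens out (≈ 4 % of trials
  end-to-end). Asynchrony jitter is Gaussian in time, not von Mises in
  phase, because asynchronies are small relative to the interval; its SD
  scales with the cue interval (Weber-like), so synchronization consistency
  is comparable across tempi — matching the equivalence observed in this
  paradigm. Unpaced inter-tap intervals follow smt·exp(random walk, scale
  0.01) plus the same jitter.
- **Pupil.** baseline (≈ 4000 au, per-participant offset SD 200) + slow
  sinusoidal drift (60 au at 0.02 Hz, random phase) + evoked dilations —
  an Erlang/gamma impulse response `(t/tₘ)^s e^{−s(t/tₘ−1)}` with shape
  s = 10.1 and unit peak at tₘ = 900 ms, the canonical pupil-response
  parameterization, inside the 500–1200 ms latency band — at every event +
  an entrained sinusoid at the metronome frequency (20 au) whose phase is
  redrawn per four-cue phrase from von Mises(0, κ), so κ maps directly onto
  the coherence statistic + white noise (10 au). Blinks are a Poisson
  process (0.2 Hz, 150 ms) marked invalid with sharp edge deflections that
  exercise the dilation-speed filter. The evoked amplitude scales with the
  cue interval so the tonic dilation load (events/s × amplitude) is
  tempo-neutral, keeping the zero-effect null exchangeable across tempi.
- **Effects.** `study_effects()` raises the evoked amplitude by 30 au in
  the Tap × Faster and Tap × Slower cells — calibrated once by simulation
  to a paired d near 0.9 for the off-tempo task contrasts at n = 23 — and
  the phase concentration from κ = 1 (modest entrainment even while
  listening) to κ = 2 in all tapping cells. The entrainment contrast is
  deliberately clear-cut rather than an estimate of any real effect size.
  `null_effects()` makes all conditions exchangeable.

What the generator does *not* emulate: gaze-position/foreshortening
artifacts, luminance responses, non-stationary tempo drift within paced
trials, heavy-tailed asynchrony distributions, or between-participant
variability in entrainment strength. Passing tests therefore demonstrates
the pipeline's correctness on data satisfying its assumptions, not the
empirical effect sizes of any real experiment.

## Calibration and problem sizes

Two simulation suites check the inference layer end-to-end (simulate →
clean → measure → infer):

- **Null calibration:** 200 experiments with zero injected effects,
  10 participants; the task-effect rejection rate at α = 0.05 must fall
  within binomial 99 % bounds. Trials are scaled down (20 cues, 100 Hz,
  one unpaced trial) but the design's 3 trials per condition is kept:
  condition cells are means over trials, and single-trial cells inherit
  the drift component's non-Gaussian trial-average distribution, which
  mildly inflates the small-sample F test (measured ≈ 11 % with one trial
  per cell vs. 4.5 % with three).
- **Power:** 200 experiments at n = 23 with `study_effects()`; the task
  effect on phase coherence must reject in > 80 % of runs.

All randomness flows from per-call seeds or generators; datasets,
pipeline outputs and the acceptance script are byte-reproducible for a
fixed seed.

## Known limitations

- The reader parses delimited-text exports only, not binary eye-tracker
  files; column names and the missing token are configurable because
  export layouts vary between labs.
- The dilation-speed filter is single-pass and assumes a noisy speed
  distribution (see above).
- The interpolation spline is fit through all valid samples of a trial;
  with very long traces a local fit around each gap would be cheaper, but
  at trial scale (~45 s at 500 Hz) the global fit is exact for the tested
  contracts and simpler.
- Phase coherence is a cross-phrase statistic within trials; cross-trial
  coherence and Hilbert/wavelet alternatives are out of scope.
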