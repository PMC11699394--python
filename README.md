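# pupilsync

Analysis pipeline for finger-tapping synchronization and pupillometry
experiments in which participants either tap along with, or passively listen
to, metronomes placed at their own spontaneous motor tempo (SMT) and ±20 %
around it, while pupil size is recorded at 500 Hz. The package turns raw
tap/pupil time series into:

- **spontaneous motor tempo** — mean inter-tap interval of unpaced tapping
  trials (first ten warm-up taps discarded), and the three metronome
  intervals derived from it;
- **circular synchronization statistics** — each tap's signed asynchrony
  (tap − cue, ms) mapped onto the cue-interval circle,
  `θᵢ = 360°·aᵢ/ITI`; the mean resultant vector
  `R·e^{iφ} = (1/n)Σ e^{iθᵢ}` gives consistency (R ∈ [0, 1]) and accuracy
  (φ, negative = anticipatory);
- **trial-averaged evoked pupil size** — after the standard cleaning chain
  (blink removal with ±100 ms padding, 4 ms moving average, cubic-spline
  interpolation of gaps < 1000 ms, subtractive baseline correction by the
  median of the 1000 ms pre-stimulus window, dilation-speed artifact
  rejection at median + 16·MAD, optional range screen, and exclusion of
  trials with > 33 % missing data);
- **pupillary phase coherence** — the trial is trimmed past the orienting
  response (first four cues), high-pass filtered (third-order zero-phase
  Butterworth, 0.05 Hz), z-scored, cut into 14 four-cue phrases, and
  Fourier-transformed per phrase; the statistic is
  `PC = |(1/N) Σₖ cₖ/|cₖ||` over the per-phrase coefficients `cₖ` at the
  metronome frequency (exactly DFT bin 4, since each phrase spans four
  periods). PC ∈ [0, 1] is amplitude-blind and comparable across tempi;
- **repeated-measures inference** — 3 (tempo) × 2 (task) within-subject
  ANOVA with generalized eta squared, post-hoc paired t-tests with
  Benjamini–Hochberg FDR and paired d = mean(diff)/SD(diff) (= t/√n), and
  the one-way control analysis comparing listening, paced tapping and
  unpaced tapping at the preferred tempo.

A first-class synthetic-data generator (`pupilsync.simulate`) produces tap
sequences and pupil traces with known ground truth — per-participant tempi,
anticipatory asynchronies, evoked dilation kernels, an entrained oscillation
whose cross-phrase phase concentration is a dial, blinks and noise — so
every stage is testable without any recordings.

## Worked example

```python
import pupilsync as ps

# one paced trial at a 600 ms metronome
tap = ps.TapSimParams(smt_ms=600.0, async_mean_ms=-30.0, async_sd_ms=25.0, seed=7)
trial = ps.simulate_paced_trial(tap, iti_ms=600.0, n_cues=60)

series = ps.clean_tap_trial(ps.match_taps_to_cues(trial))
summ = ps.circular_summary(series)
print(f"taps analyzed: {summ.n}, R = {summ.vector_length:.3f}, "
      f"direction = {summ.direction_deg:.1f} deg")

pup = ps.PupilSimParams(phase_kappa=2.0, seed=8)
trace, truth = ps.simulate_pupil_trace(
    pup, trial, duration_ms=trial.cue_onsets_ms[-1] + 2600.0)
clean = ps.preprocess_trial(trace, stimulus_onset_ms=1500.0)
print(f"missing data: {clean.missing_frac:.1%}, "
      f"mean evoked pupil = {clean.mean_pupil_au:.1f} au")

res = ps.compute_entrainment(clean.trace, trial.cue_onsets_ms, trial.iti_ms)
print(f"phase coherence = {res.phase_coherence:.3f} "
      f"over {res.n_phrases_used} phrases")
```

prints

```
taps analyzed: 54, R = 0.973, direction = -21.7 deg
missing data: 6.2%, mean evoked pupil = -35.2 au
phase coherence = 0.504 over 14 phrases
```

The 60 cues yield 54 analyzable taps after discarding the four
tempo-stabilization taps and unrecorded ones; R near 1 with a negative
direction means tight, anticipatory synchronization. The trial-mean pupil is
on the baseline-corrected scale (arbitrary units relative to the
pre-stimulus median, so its sign reflects slow drift). A coherence of 0.50
over 14 phrases sits clearly above the chance level for 14 random phases
(≈ 0.24), as expected for the moderate phase concentration simulated here.

## Command line

Each stage is also a CLI subcommand over delimited-text files
(`design.csv`, per-trial `*_events.csv` and `*_pupil.csv`):

```bash
pupilsync run-all --config config.yaml --seed 1 --outdir out/
pupilsync simulate --seed 1 --outdir out/          # synthetic dataset only
pupilsync tapping --data-dir out/data --outdir out/
pupilsync pupil-clean --data-dir out/data --outdir out/
pupilsync entrainment --data-dir out/data --outdir out/
pupilsync stats --outdir out/
```

`run-all` writes tidy per-trial tables, ANOVA/post-hoc tables with
significance stars, and a `manifest.json` reconciling every exclusion.
Outputs are byte-identical for a fixed config and seed.

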