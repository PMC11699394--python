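"""Core data containers shared across the pipeline.

Timestamps are milliseconds from recording start throughout. Missing pupil
samples are represented by an explicit validity mask (never by sentinel
numerics); the numeric array holds NaN at invalid positions purely for
safety, so an accidental use of a masked sample propagates loudly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TASKS = ("Listen", "Tap", "SMT")
TEMPI = ("Faster", "SMT", "Slower", "none")

#: relative tolerance on inter-sample spacing vs. the nominal sampling period
SPACING_RTOL = 0.01


@dataclass(frozen=True)
class SessionDesign:
    """One trial's slot in the 3 (tempo) x 2 (task) within-subject design.

    ``task='SMT'`` denotes unpaced spontaneous-tempo tapping, which has no
    metronome, hence ``tempo='none'``.
    """

    participant_id: str
    trial_id: str
    task: str
    tempo: str = "none"
    n_cues: int = 60
    stimulus_onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.tempo not in TEMPI:
            raise ValueError(f"unknown tempo {self.tempo!r}; expected one of {TEMPI}")
        if self.task == "SMT" and self.tempo != "none":
            raise ValueError("unpaced SMT trials have no metronome; tempo must be 'none'")
        if self.task != "SMT" and self.tempo == "none":
            raise ValueError("paced trials require a tempo")
        if self.n_cues < 0:
            raise ValueError("n_cues must be non-negative")


@dataclass
class PupilTrace:
    """Uniformly sampled pupil time series with a validity mask.

    Parameters
    ----------
    timestamps_ms
        Strictly increasing sample times, ms from recording start. Spacing
        must be consistent with ``sample_rate_hz`` to within 1 %.
    pupil
        Pupil size in arbitrary units; NaN at invalid samples.
    sample_rate_hz
        Nominal sampling rate (500 Hz in the study design this emulates).
    valid_mask
        False where the sample is missing (blink, artifact, tracker loss).
    meta
        Free-form labels (participant, trial, stage notes).
    """

    timestamps_ms: np.ndarray
    pupil: np.ndarray
    sample_rate_hz: float
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = self.timestamps_ms.size
        if self.pupil.size != n or self.valid_mask.size != n:
            raise ValueError("timestamps, pupil and valid_mask must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if n > 1:
            dt = np.diff(self.timestamps_ms)
            if np.any(dt <= 0):
                raise ValueError("non-monotonic timestamps")
            nominal = 1000.0 / self.sample_rate_hz
            if np.any(np.abs(dt - nominal) > SPACING_RTOL * nominal):
                raise ValueError(
                    "sample spacing inconsistent with sample_rate_hz (>1% deviation)"
                )
        # mask is authoritative: a missing numeric value implies invalid
        self.valid_mask = self.valid_mask & ~np.isnan(self.pupil)
        self.pupil = np.where(self.valid_mask, self.pupil, np.nan)

    @property
    def n_samples(self) -> int:
        return self.timestamps_ms.size

    @property
    def duration_ms(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.timestamps_ms[-1] - self.timestamps_ms[0]) + 1000.0 / self.sample_rate_hz

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            self.timestamps_ms.copy(),
            self.pupil.copy(),
            self.sample_rate_hz,
            self.valid_mask.copy(),
            dict(self.meta),
        )

    def window(self, t0_ms: float, t1_ms: float) -> "PupilTrace":
        """Return the sub-trace with ``t0_ms <= t < t1_ms`` (half-open)."""
        sel = (self.timestamps_ms >= t0_ms) & (self.timestamps_ms < t1_ms)
        return PupilTrace(
            self.timestamps_ms[sel],
            self.pupil[sel],
            self.sample_rate_hz,
            self.valid_mask[sel],
            dict(self.meta),
        )

    def with_mask(self, valid_mask: np.ndarray) -> "PupilTrace":
        """Copy with a replaced validity mask (numeric values untouched where valid)."""
        out = self.copy()
        out.valid_mask = np.asarray(valid_mask, dtype=bool)
        out.pupil = np.where(out.valid_mask, out.pupil, np.nan)
        return out


# cue grids are generated on an exact lattice; 1% of the ITI is generous
CUE_SPACING_RTOL = 0.01


@dataclass
class TapTrial:
    """Cue and tap onset times for one trial.

    ``cue_onsets_ms`` is empty for unpaced (SMT) trials; ``iti_ms`` is the
    metronome inter-cue interval and is None when there is no metronome.
    """

    cue_onsets_ms: np.ndarray
    tap_onsets_ms: np.ndarray
    design: Optional[SessionDesign] = None
    iti_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.cue_onsets_ms = np.sort(np.asarray(self.cue_onsets_ms, dtype=float))
        self.tap_onsets_ms = np.sort(np.asarray(self.tap_onsets_ms, dtype=float))
        if self.cue_onsets_ms.size >= 2:
            d = np.diff(self.cue_onsets_ms)
            if self.iti_ms is None:
                self.iti_ms = float(np.median(d))
            if np.any(np.abs(d - self.iti_ms) > CUE_SPACING_RTOL * self.iti_ms):
                raise ValueError("metronome cues are not equally spaced at iti_ms")
        elif self.cue_onsets_ms.size == 0 and self.iti_ms is not None:
            # allowed: virtual target interval for unpaced trials
            pass

    @property
    def n_cues(self) -> int:
        return self.cue_onsets_ms.size

    @property
    def n_taps(self) -> int:
        return self.tap_onsets_ms.size


def replace_design(trial: TapTrial, design: SessionDesign) -> TapTrial:
    return TapTrial(trial.cue_onsets_ms, trial.tap_onsets_ms, design, trial.iti_ms)
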