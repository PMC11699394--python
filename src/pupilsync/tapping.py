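"""Tapping analysis: spontaneous motor tempo, tap-cue matching, trial
cleaning, and circular synchronization statistics.

The circular summary represents the metronome period as a 360 deg cycle:
each tap's signed asynchrony (tap onset minus nearest-cue onset, ms) maps to
a phase angle, taps become unit vectors, and the mean resultant vector gives
synchronization consistency (its length, in [0, 1]) and accuracy (its
direction; negative angles mean the tap preceded the cue).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .containers import TapTrial

logger = logging.getLogger("pupilsync")


@dataclass
class SmtResult:
    """Spontaneous motor tempo: mean inter-tap interval across unpaced trials."""

    smt_ms: float
    per_trial_means_ms: List[float]
    n_taps_used: int


@dataclass
class AsynchronySeries:
    """Signed asynchronies (tap - cue, ms) of a trial after matching.

    ``cleaned`` marks a series that has been through :func:`clean_tap_trial`;
    cleaning is idempotent, so a cleaned series passes through unchanged.
    """

    asynchronies_ms: np.ndarray
    matched_cue_indices: np.ndarray
    iti_ms: float
    n_extra_taps: int = 0
    cleaned: bool = False
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    n_outliers_removed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.asynchronies_ms = np.asarray(self.asynchronies_ms, dtype=float)
        self.matched_cue_indices = np.asarray(self.matched_cue_indices, dtype=int)

    @property
    def n(self) -> int:
        return self.asynchronies_ms.size


@dataclass
class CircularSummary:
    """Resultant vector of tap phases: length = consistency, direction = accuracy."""

    vector_length: float
    direction_deg: float
    n: int


def compute_smt(smt_trials: Sequence[TapTrial], n_discard: int = 10) -> SmtResult:
    """Mean inter-tap interval across unpaced trials, first ``n_discard``
    taps of each trial dropped as warm-up.
    """
    per_trial: List[float] = []
    n_used = 0
    for i, trial in enumerate(smt_trials):
        label = trial.design.trial_id if trial.design is not None else f"trial {i}"
        taps = trial.tap_onsets_ms[n_discard:]
        if taps.size < 2:
            raise ValueError(
                f"{label}: needs more than {n_discard + 1} taps to estimate SMT "
                f"(has {trial.n_taps})")
        itis = np.diff(taps)
        per_trial.append(float(np.mean(itis)))
        n_used += taps.size
    return SmtResult(float(np.mean(per_trial)), per_trial, n_used)


def derive_tempi(smt_ms: float, fraction: float = 0.2) -> Dict[str, float]:
    """Metronome inter-cue intervals for the three tempo conditions.

    '20% faster' shortens the interval by the fraction (ITI x 0.8) and
    '20% slower' lengthens it (ITI x 1.2).
    """
    if smt_ms <= 0:
        raise ValueError("smt_ms must be positive")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    return {
        "Faster": (1.0 - fraction) * smt_ms,
        "SMT": smt_ms,
        "Slower": (1.0 + fraction) * smt_ms,
    }


def match_taps_to_cues(trial: TapTrial) -> AsynchronySeries:
    """Assign each tap to its nearest metronome cue.

    Signed asynchrony = tap onset - cue onset, so negative values are
    anticipatory taps. Deterministic tie-breaks: a tap exactly midway between
    two cues goes to the earlier cue; when several taps share a cue, the one
    with the smallest absolute asynchrony is kept (first wins on an exact
    tie) and the rest are flagged extra and excluded.
    """
    cues = trial.cue_onsets_ms
    taps = trial.tap_onsets_ms
    if cues.size == 0 or taps.size == 0:
        raise ValueError("matching requires at least one cue and one tap")
    iti = trial.iti_ms if trial.iti_ms is not None else float(np.median(np.diff(cues)))

    right = np.searchsorted(cues, taps)
    left = np.clip(right - 1, 0, cues.size - 1)
    right = np.clip(right, 0, cues.size - 1)
    d_left = np.abs(taps - cues[left])
    d_right = np.abs(taps - cues[right])
    nearest = np.where(d_left <= d_right, left, right)  # tie -> earlier cue
    asyncs = taps - cues[nearest]

    keep = np.ones(taps.size, dtype=bool)
    for cue_idx in np.unique(nearest):
        members = np.flatnonzero(nearest == cue_idx)
        if members.size > 1:
            best = members[np.argmin(np.abs(asyncs[members]))]
            keep[members] = False
            keep[best] = True
    n_extra = int((~keep).sum())
    if n_extra:
        logger.info("matching: %d extra taps excluded (multiple taps per cue)", n_extra)
    return AsynchronySeries(asyncs[keep], nearest[keep], iti, n_extra_taps=n_extra)


def clean_tap_trial(series: AsynchronySeries, n_discard: int = 4,
                    min_taps: int = 40, sd_cut: float = 3.0) -> AsynchronySeries:
    """Discard warm-up taps, apply the minimum-tap criterion, and remove
    asynchrony outliers.

    The first ``n_discard`` matched taps are dropped (tempo stabilization);
    the trial is flagged excluded - not an error - if fewer than ``min_taps``
    remain; asynchronies more than ``sd_cut`` within-trial standard
    deviations from the within-trial mean (computed after the discard) are
    removed. Cleaning an already-cleaned series is a no-op.
    """
    if series.cleaned:
        return series
    asyncs = series.asynchronies_ms[n_discard:]
    cues = series.matched_cue_indices[n_discard:]
    excluded = asyncs.size < min_taps
    reason = f"fewer than {min_taps} recorded taps" if excluded else None
    n_out = 0
    if asyncs.size >= 2:
        sd = float(np.std(asyncs, ddof=0))
        if sd > 0:
            z = np.abs(asyncs - np.mean(asyncs)) / sd
            inliers = z <= sd_cut
            n_out = int((~inliers).sum())
            asyncs, cues = asyncs[inliers], cues[inliers]
    if n_out:
        logger.info("cleaning: removed %d asynchrony outliers (>%g SD)", n_out, sd_cut)
    return AsynchronySeries(
        asyncs, cues, series.iti_ms, n_extra_taps=series.n_extra_taps,
        cleaned=True, excluded=excluded, exclusion_reason=reason,
        n_outliers_removed=n_out, meta=dict(series.meta))


def circular_summary(series: AsynchronySeries) -> CircularSummary:
    """Mean resultant vector of tap phases on the cue-interval circle.

    Phase_i = 360 deg x asynchrony_i / iti; the resultant vector length lies
    in [0, 1] (1 = perfectly consistent) and its direction, reported in
    (-180, 180] degrees, is negative when taps precede cues on average.
    """
    if series.n == 0:
        raise ValueError("circular summary requires at least one asynchrony")
    phases = 2.0 * np.pi * series.asynchronies_ms / series.iti_ms
    z = np.mean(np.exp(1j * phases))
    r = float(np.abs(z))
    direction = float(np.degrees(np.angle(z)))  # in (-180, 180]
    if direction <= -180.0:
        direction += 360.0
    return CircularSummary(min(r, 1.0), direction, series.n)
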