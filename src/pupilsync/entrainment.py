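"""Pupillary phase coherence at the metronome frequency.

A cleaned trial is trimmed past the orienting response (first four cues),
high-pass filtered (zero-phase Butterworth) and z-scored, epoched into
four-cue phrases, and Fourier-transformed per phrase. Because a phrase
spans exactly four metronome periods, the metronome frequency falls exactly
on DFT bin 4; phase coherence is the modulus of the mean unit phasor of the
bin-4 coefficients across phrases. It is amplitude-blind and bounded in
[0, 1] (1 = the pupil oscillation keeps the same phase relative to every
phrase start), hence comparable across tempi. Neighboring bins are kept as
spectral-leakage diagnostics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import PupilTrace

logger = logging.getLogger("pupilsync")

DEFAULT_NEIGHBOR_OFFSETS = (-1, 1, 2)


@dataclass
class PhraseSet:
    """Equal-length sample windows, one per four-cue phrase."""

    phrases: np.ndarray          # (n_phrases, phrase_len) values
    valid: np.ndarray            # same shape, validity of each sample
    phrase_len_samples: int
    start_times_ms: np.ndarray
    iti_ms: float
    sample_rate_hz: float
    retained_mask: np.ndarray    # phrases with <= max invalid fraction

    @property
    def n_phrases(self) -> int:
        return int(self.phrases.shape[0])


@dataclass
class SpectralEstimate:
    """DFT coefficients of one phrase at the target and neighbor bins."""

    target_bin: int
    coefficients: Dict[int, complex]  # bin offset -> coefficient
    bin_freqs_hz: Dict[int, float]
    neighbor_offsets: Tuple[int, ...]


@dataclass
class CoherenceResult:
    phase_coherence: float
    n_phrases_used: int
    neighbor_coherence: Dict[int, float]
    mean_phase_deg: float


def drop_onset_window(trace: PupilTrace, cues: Sequence[float],
                      iti_ms: Optional[float] = None) -> PupilTrace:
    """Trim the trace to [cue_5, end of the last cue interval).

    The first four cue intervals carry the orienting response to stimulus
    onset and are discarded before spectral analysis.
    """
    cues = np.asarray(cues, dtype=float)
    if cues.size < 5:
        raise ValueError("onset trimming requires at least 5 cues")
    if iti_ms is None:
        iti_ms = float(np.median(np.diff(cues)))
    t0 = cues[4]
    t1 = cues[0] + cues.size * iti_ms
    return trace.window(t0, t1)


def _butter_highpass_sos(sample_rate_hz: float, cutoff_hz: float, order: int):
    return butter(order, cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")


def highpass_zscore(trace: PupilTrace, cutoff_hz: float = 0.05,
                    order: int = 3) -> PupilTrace:
    """Zero-phase Butterworth high-pass (drift removal), then z-score.

    Remaining invalid runs are bridged by linear interpolation for the
    filter only and re-masked afterward. Zero-phase (forward-backward)
    filtering is used so the filter cannot rotate phases and bias the
    coherence estimate. The z-score uses the valid samples (mean 0, SD 1).
    """
    valid = trace.valid_mask
    if int(valid.sum()) < 2:
        raise ValueError("degenerate trace: fewer than 2 valid samples")
    t = trace.timestamps_ms
    vi = np.flatnonzero(valid)
    if float(np.std(trace.pupil[vi])) == 0.0:
        raise ValueError("degenerate trace: constant signal")
    x = np.interp(t, t[vi], trace.pupil[vi])  # linear bridge incl. edges
    sos = _butter_highpass_sos(trace.sample_rate_hz, cutoff_hz, order)
    # pad by ~3 filter time constants so the edge transient of the very low
    # cutoff does not leak into the trace
    padlen = int(min(x.size - 1, 3.0 * trace.sample_rate_hz / cutoff_hz))
    y = sosfiltfilt(sos, x, padlen=padlen)
    mu = float(np.mean(y[valid]))
    sd = float(np.std(y[valid]))
    if sd == 0.0:
        raise ValueError("degenerate trace: zero variance after filtering")
    # bridged values stay on the numeric grid (the phrase FFT needs a full
    # grid) but remain masked invalid for phrase-retention decisions;
    # PupilTrace normally NaNs masked values, so bypass the constructor mask
    # coupling by building the object and restoring the numeric array.
    out = trace.copy()
    out.pupil = (y - mu) / sd
    out.valid_mask = valid.copy()
    return out


def epoch_phrases(trace: PupilTrace, cues: Sequence[float],
                  taps_per_phrase: int = 4,
                  max_invalid_frac: float = 0.5,
                  iti_ms: Optional[float] = None) -> PhraseSet:
    """Cut an onset-trimmed trace into equal-length four-cue phrases.

    Phrase k starts at cue ``5 + taps_per_phrase*(k-1)`` and spans
    ``taps_per_phrase x iti`` (``round(4 x iti x rate)`` samples).
    Incomplete final phrases are dropped; phrases with more than half their
    samples invalid are excluded via ``retained_mask``. Fewer than two
    retained phrases is an error.
    """
    cues = np.asarray(cues, dtype=float)
    if iti_ms is None:
        iti_ms = float(np.median(np.diff(cues)))
    n_len = int(round(taps_per_phrase * iti_ms * trace.sample_rate_hz / 1000.0))
    starts = cues[4::taps_per_phrase]
    t = trace.timestamps_ms
    phrases, valid, kept_starts = [], [], []
    for s in starts:
        i = int(np.searchsorted(t, s - 1e-9))
        if i + n_len > trace.n_samples:
            continue  # incomplete final phrase
        phrases.append(trace.pupil[i:i + n_len])
        valid.append(trace.valid_mask[i:i + n_len])
        kept_starts.append(s)
    if not phrases:
        raise ValueError("insufficient phrases: none fit inside the trace")
    phrases = np.asarray(phrases)
    valid = np.asarray(valid)
    invalid_frac = 1.0 - valid.mean(axis=1)
    retained = invalid_frac <= max_invalid_frac
    if int(retained.sum()) < 2:
        raise ValueError("insufficient phrases: fewer than 2 retained")
    n_drop = int((~retained).sum())
    if n_drop:
        logger.info("epoching: dropped %d phrases with >%.0f%% invalid samples",
                    n_drop, 100 * max_invalid_frac)
    return PhraseSet(phrases, valid, n_len, np.asarray(kept_starts),
                     iti_ms, trace.sample_rate_hz, retained)


def phrase_spectrum(phrase: np.ndarray, iti_ms: float, sample_rate_hz: float,
                    neighbor_offsets: Sequence[int] = DEFAULT_NEIGHBOR_OFFSETS,
                    taps_per_phrase: int = 4) -> SpectralEstimate:
    """DFT of one rectangular-windowed phrase, keeping the metronome bin
    and its leakage-diagnostic neighbors.

    The target bin index equals ``taps_per_phrase`` because the phrase spans
    exactly that many metronome periods, so the bin frequency is
    ``1000/iti_ms`` Hz by construction.
    """
    phrase = np.asarray(phrase, dtype=float)
    n = phrase.size
    expected = int(round(taps_per_phrase * iti_ms * sample_rate_hz / 1000.0))
    if n != expected:
        raise ValueError(f"phrase length {n} != expected {expected} samples")
    coeffs = np.fft.rfft(phrase)
    target = taps_per_phrase
    kept = {0: complex(coeffs[target])}
    freqs = {0: target * sample_rate_hz / n}
    for off in neighbor_offsets:
        b = target + off
        if 0 <= b < coeffs.size:
            kept[off] = complex(coeffs[b])
            freqs[off] = b * sample_rate_hz / n
    return SpectralEstimate(target, kept, freqs, tuple(neighbor_offsets))


def coherence_of_coefficients(coeffs: Sequence[complex]) -> Tuple[float, float, int]:
    """Phase coherence of a set of complex coefficients.

    Each nonzero coefficient is normalized to a unit phasor; the coherence
    is the modulus of their complex mean and the mean phase its argument
    (degrees). Returns (coherence, mean_phase_deg, n_used).
    """
    c = np.asarray(coeffs, dtype=complex)
    mag = np.abs(c)
    nonzero = mag > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("coherence: dropped %d zero coefficients", n_dropped)
    c = c[nonzero]
    if c.size < 2:
        raise ValueError("phase coherence requires at least 2 nonzero coefficients")
    z = np.mean(c / np.abs(c))
    return float(np.abs(z)), float(np.degrees(np.angle(z))), int(c.size)


def phase_coherence(spectra: Sequence[SpectralEstimate]) -> CoherenceResult:
    """Cross-phrase phase coherence at the metronome bin, with the same
    statistic per neighbor offset as a leakage diagnostic."""
    target = [s.coefficients[0] for s in spectra]
    pc, mean_phase, n_used = coherence_of_coefficients(target)
    neighbor: Dict[int, float] = {}
    offsets = spectra[0].neighbor_offsets if spectra else ()
    for off in offsets:
        cs = [s.coefficients[off] for s in spectra if off in s.coefficients]
        try:
            neighbor[off], _, _ = coherence_of_coefficients(cs)
        except ValueError:
            neighbor[off] = float("nan")
    return CoherenceResult(pc, n_used, neighbor, mean_phase)


def compute_entrainment(trace: PupilTrace, cues: Sequence[float],
                        iti_ms: Optional[float] = None,
                        cutoff_hz: float = 0.05, order: int = 3,
                        taps_per_phrase: int = 4,
                        max_invalid_frac: float = 0.5,
                        neighbor_offsets: Sequence[int] = DEFAULT_NEIGHBOR_OFFSETS,
                        average_neighbor_coeffs: bool = False) -> CoherenceResult:
    """Full entrainment chain for one cleaned trial.

    ``cues`` are metronome onsets for paced trials; for unpaced trials pass
    the tap onsets and the participant's mean inter-tap interval as
    ``iti_ms`` (the target frequency). With ``average_neighbor_coeffs`` the
    target and kept neighbor coefficients are averaged per phrase before
    phase extraction (alternative leakage treatment, off by default).
    """
    cues = np.asarray(cues, dtype=float)
    if iti_ms is None:
        iti_ms = float(np.median(np.diff(cues)))
    trimmed = drop_onset_window(trace, cues, iti_ms)
    filtered = highpass_zscore(trimmed, cutoff_hz, order)
    phrases = epoch_phrases(filtered, cues, taps_per_phrase,
                            max_invalid_frac, iti_ms)
    spectra = [
        phrase_spectrum(phrases.phrases[i], iti_ms, phrases.sample_rate_hz,
                        neighbor_offsets, taps_per_phrase)
        for i in np.flatnonzero(phrases.retained_mask)
    ]
    if average_neighbor_coeffs:
        pooled = [np.mean(list(s.coefficients.values())) for s in spectra]
        pc, mean_phase, n_used = coherence_of_coefficients(pooled)
        return CoherenceResult(pc, n_used, {}, mean_phase)
    return phase_coherence(spectra)
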