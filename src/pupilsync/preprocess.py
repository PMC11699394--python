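"""Pupil cleaning chain: blink padding, smoothing + spline interpolation,
subtractive baseline correction, dilation-speed artifact rejection, optional
range screening, and the trial-level missing-data screen.

Stage order is fixed: blinks -> smooth/interpolate -> baseline -> speed MAD
-> range screen -> finalize. No stage ever re-validates a sample except
interpolation, which only fills invalid runs strictly shorter than the gap
threshold. The missing-data fraction used for the 33 % screen is counted
*before* interpolation fills (configurable), so interpolation cannot rescue
an unusable trial.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation

from .containers import PupilTrace

logger = logging.getLogger("pupilsync")


@dataclass
class PreprocessConfig:
    blink_pad_ms: float = 100.0
    smooth_window_ms: float = 4.0
    max_gap_interp_ms: float = 1000.0
    baseline_window_ms: float = 1000.0
    max_missing_frac: float = 0.33
    mad_constant: float = 16.0
    plausible_range_au: Optional[Tuple[float, float]] = None
    missing_before_interp: bool = True
    histogram_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must be in (0, 1)")
        for name in ("blink_pad_ms", "smooth_window_ms", "max_gap_interp_ms",
                     "baseline_window_ms", "mad_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CleanTrial:
    """Outcome of the cleaning chain for one trial."""

    trace: PupilTrace
    missing_frac: float
    excluded: bool
    reason: Optional[str]
    mean_pupil_au: Optional[float]
    stage_log: dict


class BaselineMissingError(ValueError):
    """No valid sample in the pre-stimulus baseline window."""


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal invalid runs (half-open)."""
    inv = ~valid
    if not inv.any():
        return
    padded = np.concatenate([[False], inv, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def remove_blinks(trace: PupilTrace, pad_ms: float = 100.0) -> PupilTrace:
    """Invalidate every sample within ``pad_ms`` of an invalid (blink) sample.

    Pads both sides to drop the partial-occlusion artifacts flanking a
    blink; after this stage no valid sample remains within ``pad_ms`` of any
    originally invalid sample.
    """
    if trace.valid_mask.all():
        return trace.copy()
    k = int(round(pad_ms * trace.sample_rate_hz / 1000.0))
    inv = binary_dilation(~trace.valid_mask, structure=np.ones(2 * k + 1, dtype=bool))
    return trace.with_mask(~inv)


def smooth_and_interpolate(trace: PupilTrace, window_ms: float = 4.0,
                           max_gap_ms: float = 1000.0) -> PupilTrace:
    """Centered moving average over valid samples, then cubic-spline filling
    of short gaps.

    The window is ``round(window_ms x rate)`` samples (2 at 500 Hz - nearly
    minimal smoothing), centered and leaning one sample earlier when even.
    Invalid runs strictly shorter than ``max_gap_ms`` with at least two valid
    samples on each side are filled by a cubic spline through the valid
    samples; longer or edge gaps stay invalid.
    """
    out = trace.copy()
    valid = out.valid_mask
    n = out.n_samples
    if n == 0:
        return out
    w = max(1, int(round(window_ms * trace.sample_rate_hz / 1000.0)))
    if w > 1:
        vals = np.where(valid, out.pupil, 0.0)
        cnt = valid.astype(float)
        kernel = np.ones(w)
        num = np.convolve(vals, kernel, mode="full")
        den = np.convolve(cnt, kernel, mode="full")
        # output sample i averages inputs [i - w//2, i + (w-1)//2]
        lo = (w - 1) // 2
        num, den = num[lo:lo + n], den[lo:lo + n]
        smoothed = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out.pupil = np.where(valid, smoothed, np.nan)

    t = out.timestamps_ms
    vi = np.flatnonzero(valid)
    if vi.size >= 2:
        if vi.size >= 4:
            spline = CubicSpline(t[vi], out.pupil[vi])
        else:  # too few points for a cubic; fall back to linear
            spline = lambda x: np.interp(x, t[vi], out.pupil[vi])
        new_valid = valid.copy()
        filled = 0
        for s, e in _invalid_runs(valid):
            gap_ms = (e - s) * 1000.0 / trace.sample_rate_hz
            n_before = int(valid[:s].sum())
            n_after = int(valid[e:].sum())
            if gap_ms < max_gap_ms and n_before >= 2 and n_after >= 2:
                out.pupil[s:e] = spline(t[s:e])
                new_valid[s:e] = True
                filled += e - s
        out.valid_mask = new_valid
        if filled:
            logger.info("interpolation: filled %d samples", filled)
    return out


def baseline_correct(trace: PupilTrace, stimulus_onset_ms: float,
                     window_ms: float = 1000.0) -> PupilTrace:
    """Subtract the median valid pupil value of the pre-stimulus window
    ``[onset - window_ms, onset)``.

    Raises :class:`BaselineMissingError` when the window holds no valid
    sample; callers flag the trial excluded with reason "no baseline".
    """
    t = trace.timestamps_ms
    sel = (t >= stimulus_onset_ms - window_ms) & (t < stimulus_onset_ms) & trace.valid_mask
    if not sel.any():
        raise BaselineMissingError("no valid sample in baseline window")
    med = float(np.median(trace.pupil[sel]))
    out = trace.copy()
    out.pupil = out.pupil - med
    out.meta["baseline_au"] = med
    return out


def dilation_speed(trace: PupilTrace) -> np.ndarray:
    """Per-valid-sample dilation speed (au/ms).

    For each valid sample the speed is the larger absolute slope to its
    valid neighbors (edge samples use their single neighbor); returned
    aligned to the valid-sample subsequence.
    """
    vi = np.flatnonzero(trace.valid_mask)
    p = trace.pupil[vi]
    t = trace.timestamps_ms[vi]
    if vi.size < 3:
        raise ValueError("dilation speed needs at least 3 valid samples")
    slopes = np.abs(np.diff(p) / np.diff(t))
    d = np.empty(vi.size)
    d[0] = slopes[0]
    d[-1] = slopes[-1]
    d[1:-1] = np.maximum(slopes[:-1], slopes[1:])
    return d


def reject_speed_artifacts(trace: PupilTrace, mad_constant: float = 16.0) -> PupilTrace:
    """Invalidate samples whose dilation speed exceeds
    ``median(d) + mad_constant x MAD(d)`` (single pass).

    With a degenerate MAD of zero (e.g. a constant trace with one spike) the
    threshold floor ``median + mad_constant x eps x max(1, |median|)`` keeps
    constant traces intact while still catching the spike.
    """
    d = dilation_speed(trace)
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    eps = np.finfo(float).eps
    thr = med + mad_constant * max(mad, eps * max(1.0, abs(med)))
    vi = np.flatnonzero(trace.valid_mask)
    bad = vi[d > thr]
    if bad.size:
        logger.info("speed filter: removed %d samples above %.4g au/ms", bad.size, thr)
    mask = trace.valid_mask.copy()
    mask[bad] = False
    return trace.with_mask(mask)


def screen_range(trace: PupilTrace,
                 plausible_range_au: Optional[Tuple[float, float]] = None,
                 histogram_path: Optional[str] = None) -> PupilTrace:
    """Invalidate samples outside a plausible size range (no-op when absent).

    Automates the final visual-inspection step: the histogram an
    experimenter would inspect is written as a small text table (bin edges
    and counts) when ``histogram_path`` is given.
    """
    out = trace.copy()
    if histogram_path is not None and trace.valid_mask.any():
        counts, edges = np.histogram(trace.pupil[trace.valid_mask], bins=50)
        with open(histogram_path, "w") as fh:
            fh.write("bin_left,bin_right,count\n")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo},{hi},{c}\n")
    if plausible_range_au is None:
        return out
    lo, hi = plausible_range_au
    mask = out.valid_mask & (out.pupil >= lo) & (out.pupil <= hi)
    n_cut = int(out.valid_mask.sum() - mask.sum())
    if n_cut:
        logger.info("range screen: removed %d samples outside [%g, %g]", n_cut, lo, hi)
    return out.with_mask(mask)


def finalize_trial(trace: PupilTrace, max_missing_frac: float = 0.33,
                   missing_frac: Optional[float] = None,
                   stage_log: Optional[dict] = None) -> CleanTrial:
    """Apply the missing-data screen and compute the trial-mean pupil size.

    A trial is excluded when strictly more than ``max_missing_frac`` of its
    samples are missing (exactly at the threshold is retained); otherwise
    the trial mean is the mean of the valid, baseline-corrected samples over
    the entire trial window.
    """
    if missing_frac is None:
        missing_frac = float((~trace.valid_mask).mean()) if trace.n_samples else 1.0
    excluded = missing_frac > max_missing_frac
    if excluded:
        return CleanTrial(trace, missing_frac, True,
                          f"missing data {missing_frac:.1%} > {max_missing_frac:.0%}",
                          None, stage_log or {})
    mean = float(np.mean(trace.pupil[trace.valid_mask])) if trace.valid_mask.any() else None
    return CleanTrial(trace, missing_frac, False, None, mean, stage_log or {})


def preprocess_trial(trace: PupilTrace, stimulus_onset_ms: float,
                     config: Optional[PreprocessConfig] = None) -> CleanTrial:
    """Run the full cleaning chain on one trial.

    Returns a :class:`CleanTrial`; the stage log records how many samples
    each stage invalidated or filled.
    """
    cfg = config or PreprocessConfig()
    log: dict = {"n_samples": trace.n_samples,
                 "invalid_raw": int((~trace.valid_mask).sum())}

    t1 = remove_blinks(trace, cfg.blink_pad_ms)
    log["invalid_after_blink_pad"] = int((~t1.valid_mask).sum())
    ever_missing = ~t1.valid_mask  # pre-fill snapshot for the missing screen

    t2 = smooth_and_interpolate(t1, cfg.smooth_window_ms, cfg.max_gap_interp_ms)
    log["filled_by_interpolation"] = int((t2.valid_mask & ~t1.valid_mask).sum())

    try:
        t3 = baseline_correct(t2, stimulus_onset_ms, cfg.baseline_window_ms)
    except BaselineMissingError:
        logger.info("trial excluded: no baseline")
        return CleanTrial(t2, float(ever_missing.mean()), True, "no baseline", None, log)

    if int(t3.valid_mask.sum()) >= 3:
        t4 = reject_speed_artifacts(t3, cfg.mad_constant)
    else:
        t4 = t3
    log["removed_by_speed_filter"] = int((t3.valid_mask & ~t4.valid_mask).sum())

    t5 = screen_range(t4, cfg.plausible_range_au, cfg.histogram_path)
    log["removed_by_range_screen"] = int((t4.valid_mask & ~t5.valid_mask).sum())

    ever_missing |= ~t5.valid_mask
    frac = float(ever_missing.mean()) if cfg.missing_before_interp \
        else float((~t5.valid_mask).mean())
    return finalize_trial(t5, cfg.max_missing_frac, frac, log)
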