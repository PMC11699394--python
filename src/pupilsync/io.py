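"""Readers and writers for the delimited-text formats the pipeline touches.

The pupil reader emulates an eye-tracker "sample report" export: one row per
sample with a timestamp, a pupil size in arbitrary units, and a validity /
blink flag. The event reader emulates a MIDI note-on log: one row per event
with an onset time and an event type (``cue`` or ``tap``). Column names,
delimiter and the missing-value token are configurable because exported
layouts vary between labs; defaults match the synthetic datasets written by
:mod:`pupilsync.simulate`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .containers import PupilTrace, SessionDesign, TapTrial

logger = logging.getLogger("pupilsync")

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


@dataclass
class ReaderConfig:
    """Column map and dialect for sample/event exports."""

    time_col: str = "time_ms"
    pupil_col: str = "pupil"
    valid_col: str = "valid"
    event_time_col: str = "time_ms"
    event_type_col: str = "type"
    delimiter: Optional[str] = None  # None -> sniffed from the header line
    missing_token: str = "."
    sample_rate_hz: float = 500.0


class ParseError(ValueError):
    """A row of an input file could not be interpreted."""


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for cand in (",", "\t", ";"):
        if cand in header:
            return cand
    return ","


def _read_table(path: Union[str, Path], config: ReaderConfig) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = config.delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _to_float(series: pd.Series, colname: str, path: Path) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        line = int(np.flatnonzero(bad.values)[0]) + 2
        raise ParseError(f"{path}: unparseable value {series[bad].iloc[0]!r} "
                         f"in column {colname!r} at line {line}")
    return out.to_numpy(dtype=float)


def _to_bool(series: pd.Series, colname: str, path: Path) -> np.ndarray:
    toks = series.astype(str).str.strip().str.lower()
    out = np.empty(len(toks), dtype=bool)
    for i, tok in enumerate(toks):
        if tok in _TRUE_TOKENS:
            out[i] = True
        elif tok in _FALSE_TOKENS:
            out[i] = False
        else:
            raise ParseError(f"{path}: unparseable value {series.iloc[i]!r} "
                             f"in column {colname!r} at line {i + 2}")
    return out


def read_pupil_samples(path: Union[str, Path],
                       format_config: Optional[ReaderConfig] = None) -> PupilTrace:
    """Read a pupil sample export into a :class:`PupilTrace`.

    Samples are flagged invalid where the validity column marks a blink
    (false) or where the pupil field equals the configured missing token.
    Raises :class:`ParseError` naming the offending line for unparseable
    rows, and ``ValueError("non-monotonic timestamps")`` for a reversed or
    concatenated export.
    """
    cfg = format_config or ReaderConfig()
    path = Path(path)
    df = _read_table(path, cfg)
    for col in (cfg.time_col, cfg.pupil_col, cfg.valid_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    n_in = len(df)
    t = _to_float(df[cfg.time_col], cfg.time_col, path)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotonic timestamps")
    raw = df[cfg.pupil_col].astype(str).str.strip()
    missing = (raw == cfg.missing_token) | df[cfg.pupil_col].isna()
    pupil = np.full(n_in, np.nan)
    if (~missing).any():
        pupil[~missing.values] = _to_float(
            df.loc[~missing, cfg.pupil_col], cfg.pupil_col, path)
    valid = _to_bool(df[cfg.valid_col], cfg.valid_col, path) & ~missing.values
    trace = PupilTrace(t, pupil, cfg.sample_rate_hz, valid)
    logger.info("%s: read %d samples (%d invalid)", path.name, n_in, int((~valid).sum()))
    return trace


def read_tap_events(path: Union[str, Path],
                    format_config: Optional[ReaderConfig] = None,
                    design: Optional[SessionDesign] = None) -> TapTrial:
    """Read a cue/tap event log into a :class:`TapTrial`.

    Event types must be ``cue`` or ``tap`` (case-insensitive); anything else
    is an error, as is an empty file.
    """
    cfg = format_config or ReaderConfig()
    path = Path(path)
    df = _read_table(path, cfg)
    for col in (cfg.event_time_col, cfg.event_type_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise ParseError(f"{path}: empty event file")
    t = _to_float(df[cfg.event_time_col], cfg.event_time_col, path)
    kinds = df[cfg.event_type_col].astype(str).str.strip().str.lower()
    unknown = ~kinds.isin(["cue", "tap"])
    if unknown.any():
        line = int(np.flatnonzero(unknown.values)[0]) + 2
        raise ParseError(f"{path}: unknown event type "
                         f"{df[cfg.event_type_col][unknown].iloc[0]!r} at line {line}")
    cues = t[(kinds == "cue").values]
    taps = t[(kinds == "tap").values]
    return TapTrial(cues, taps, design=design)


TIDY_COLUMNS = ("participant", "trial", "task", "tempo", "measure", "value")


def write_tidy_results(records, path: Union[str, Path]) -> None:
    """Write result rows to one delimited text file (lossless round trip).

    ``records`` is a DataFrame or a sequence of mappings sharing a schema;
    an empty input yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=TIDY_COLUMNS if not records else None)
    df.to_csv(path, index=False)


def read_tidy_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration

def default_config() -> dict:
    """All numeric constants of the pipeline, at their published defaults."""
    return {
        "reader": {
            "time_col": "time_ms", "pupil_col": "pupil", "valid_col": "valid",
            "event_time_col": "time_ms", "event_type_col": "type",
            "delimiter": None, "missing_token": ".", "sample_rate_hz": 500.0,
        },
        "tapping": {
            "smt_discard_taps": 10,   # warm-up taps dropped from each SMT trial
            "tempo_fraction": 0.2,    # +/-20% metronome tempi
            "clean_discard_taps": 4,  # tempo-stabilization taps dropped per paced trial
            "min_taps": 40,           # fewer recorded taps -> trial excluded
            "outlier_sd": 3.0,        # asynchrony outlier cut, within-trial z
        },
        "preprocess": {
            "blink_pad_ms": 100.0,
            "smooth_window_ms": 4.0,
            "max_gap_interp_ms": 1000.0,
            "baseline_window_ms": 1000.0,
            "max_missing_frac": 0.33,
            "mad_constant": 16.0,
            "plausible_range_au": None,
            "missing_before_interp": True,
        },
        "entrainment": {
            "highpass_cutoff_hz": 0.05,
            "filter_order": 3,
            "taps_per_phrase": 4,
            "max_invalid_phrase_frac": 0.5,
            "neighbor_offsets": [-1, 1, 2],
            "average_neighbor_coeffs": False,
        },
        "stats": {
            "alpha": 0.05,
            "effect_size": "mean_diff_sd",  # d = mean(diff)/SD(diff)
            "sphericity_correction": False,
        },
    }


def load_config(path: Union[str, Path, None]) -> dict:
    """Load a YAML config file merged over :func:`default_config`."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section in cfg and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def reader_config_from(cfg: dict) -> ReaderConfig:
    return ReaderConfig(**cfg.get("reader", {}))
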