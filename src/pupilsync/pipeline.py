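"""End-to-end orchestration: simulate -> tapping -> pupil-clean ->
entrainment -> stats, with persisted delimited-text intermediates so each
stage can be re-run and inspected independently, and a manifest recording
every exclusion.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .containers import SessionDesign, TapTrial
from .io import (ReaderConfig, load_config, read_pupil_samples, read_tap_events,
                 reader_config_from)
from .preprocess import PreprocessConfig, preprocess_trial
from .entrainment import compute_entrainment
from .simulate import (PupilSimParams, TapSimParams, null_effects,
                       simulate_experiment, study_effects)
from .stats import (aggregate_conditions, control_analysis, posthoc_paired,
                    rm_anova, significance_stars)
from .tapping import (circular_summary, clean_tap_trial, compute_smt,
                      match_taps_to_cues)

logger = logging.getLogger("pupilsync")

TIDY_COLS = ["participant", "trial", "task", "tempo", "measure", "value",
             "excluded", "reason"]


def _load_design(data_dir: Path) -> pd.DataFrame:
    path = data_dir / "design.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing dataset: {path}")
    return pd.read_csv(path)


def _design_of(row: pd.Series) -> SessionDesign:
    return SessionDesign(str(row["participant_id"]), str(row["trial_id"]),
                         str(row["task"]), str(row["tempo"]),
                         int(row["n_cues"]), float(row["stimulus_onset_ms"]))


def stage_simulate(config: dict, seed: Optional[int], outdir: Path) -> Path:
    """Write a synthetic dataset according to the config's simulate block."""
    sim = dict(config.get("simulate", {}))
    effects_name = sim.pop("effects", "study")
    effect_spec = {"study": study_effects, "null": null_effects}[effects_name]()
    tap_params = TapSimParams(**sim.pop("tap_params", {}))
    pupil_params = PupilSimParams(**sim.pop("pupil_params", {}))
    if seed is not None:
        sim["seed"] = seed
    exp = simulate_experiment(tap_params=tap_params, pupil_params=pupil_params,
                              effect_spec=effect_spec, **sim)
    data_dir = outdir / "data"
    exp.write(data_dir)
    logger.info("simulated %d trials -> %s", len(exp.trials), data_dir)
    return data_dir


def _base_of(design: SessionDesign) -> dict:
    return {"participant": design.participant_id, "trial": design.trial_id,
            "task": design.task, "tempo": design.tempo}


def tapping_rows(trial: TapTrial, cfg: dict) -> List[dict]:
    """Tidy measure rows (vector_length, direction_deg, n_taps) for one
    paced tapping trial, with exclusion flag and reason."""
    base = _base_of(trial.design)
    if trial.n_taps == 0:
        return [{**base, "measure": m, "value": np.nan,
                 "excluded": True, "reason": "no recorded taps"}
                for m in ("vector_length", "direction_deg")]
    series = clean_tap_trial(match_taps_to_cues(trial),
                             cfg["clean_discard_taps"],
                             cfg["min_taps"], cfg["outlier_sd"])
    if series.excluded or series.n == 0:
        return [{**base, "measure": m, "value": np.nan,
                 "excluded": True, "reason": series.exclusion_reason}
                for m in ("vector_length", "direction_deg")]
    summ = circular_summary(series)
    return [{**base, "measure": m, "value": v, "excluded": False, "reason": None}
            for m, v in (("vector_length", summ.vector_length),
                         ("direction_deg", summ.direction_deg),
                         ("n_taps", summ.n))]


def pupil_rows(clean, design: SessionDesign) -> List[dict]:
    """Tidy measure rows for one cleaned pupil trial."""
    base = _base_of(design)
    return [
        {**base, "measure": "mean_pupil",
         "value": clean.mean_pupil_au if not clean.excluded else np.nan,
         "excluded": clean.excluded, "reason": clean.reason},
        {**base, "measure": "missing_frac", "value": clean.missing_frac,
         "excluded": clean.excluded, "reason": clean.reason},
    ]


def entrainment_events(trial: TapTrial):
    """Events and target interval for the coherence analysis of a trial.

    Paced trials lock to their metronome cues; unpaced trials lock to the
    taps, with the trial's mean inter-tap interval as the target frequency.
    """
    if trial.n_cues:
        return trial.cue_onsets_ms, float(trial.iti_ms)
    if trial.n_taps < 6:
        raise ValueError("too few taps for entrainment")
    events = trial.tap_onsets_ms
    return events, float(np.mean(np.diff(events)))


def entrainment_rows(clean, trial: TapTrial, ecfg: dict) -> List[dict]:
    """Tidy coherence rows for one trial from its cleaned trace."""
    base = _base_of(trial.design)
    if clean.excluded:
        return [{**base, "measure": "phase_coherence", "value": np.nan,
                 "excluded": True, "reason": clean.reason}]
    try:
        events, iti = entrainment_events(trial)
        res = compute_entrainment(
            clean.trace, events, iti,
            cutoff_hz=ecfg["highpass_cutoff_hz"], order=ecfg["filter_order"],
            taps_per_phrase=ecfg["taps_per_phrase"],
            max_invalid_frac=ecfg["max_invalid_phrase_frac"],
            neighbor_offsets=tuple(ecfg["neighbor_offsets"]),
            average_neighbor_coeffs=ecfg["average_neighbor_coeffs"])
    except ValueError as err:
        return [{**base, "measure": "phase_coherence", "value": np.nan,
                 "excluded": True, "reason": str(err)}]
    rows = [{**base, "measure": "phase_coherence", "value": res.phase_coherence,
             "excluded": False, "reason": None},
            {**base, "measure": "n_phrases", "value": res.n_phrases_used,
             "excluded": False, "reason": None},
            {**base, "measure": "mean_phase_deg", "value": res.mean_phase_deg,
             "excluded": False, "reason": None}]
    rows += [{**base, "measure": f"coherence_bin{off:+d}", "value": pc,
              "excluded": False, "reason": None}
             for off, pc in res.neighbor_coherence.items()]
    return rows


def stage_tapping(data_dir: Path, outdir: Path, config: dict) -> pd.DataFrame:
    """Per-trial tapping measures and per-participant spontaneous tempi."""
    cfg = config["tapping"]
    rcfg = reader_config_from(config)
    design = _load_design(data_dir)
    rows: List[dict] = []
    smt_rows: List[dict] = []
    for pid, sub in design.groupby("participant_id", sort=True):
        smt_trials = []
        for _, r in sub[sub["task"] == "SMT"].iterrows():
            trial = read_tap_events(data_dir / r["events_file"], rcfg,
                                    design=_design_of(r))
            smt_trials.append(trial)
        if smt_trials:
            res = compute_smt(smt_trials, cfg["smt_discard_taps"])
            smt_rows.append({"participant": pid, "smt_ms": res.smt_ms,
                             "n_taps_used": res.n_taps_used,
                             **{f"trial_{i + 1}_mean_ms": m
                                for i, m in enumerate(res.per_trial_means_ms)}})
        for _, r in sub[sub["task"] == "Tap"].iterrows():
            trial = read_tap_events(data_dir / r["events_file"], rcfg,
                                    design=_design_of(r))
            rows.extend(tapping_rows(trial, cfg))
    out = pd.DataFrame(rows, columns=TIDY_COLS)
    out.to_csv(outdir / "tapping.csv", index=False)
    pd.DataFrame(smt_rows).to_csv(outdir / "smt.csv", index=False)
    return out


def analyze_experiment(exp, config: Optional[dict] = None) -> pd.DataFrame:
    """In-memory per-trial measures for a :class:`SyntheticExperiment`.

    Computes the same tidy rows the file-based stages produce, without
    touching disk - convenient for simulation studies (calibration, power).
    """
    cfg = load_config(None) if config is None else config
    pcfg = _preprocess_cfg(cfg)
    rows: List[dict] = []
    for st in exp.trials:
        clean = preprocess_trial(st.pupil, st.design.stimulus_onset_ms, pcfg)
        rows.extend(pupil_rows(clean, st.design))
        rows.extend(entrainment_rows(clean, st.taps, cfg["entrainment"]))
        if st.design.task == "Tap":
            rows.extend(tapping_rows(st.taps, cfg["tapping"]))
    return pd.DataFrame(rows, columns=TIDY_COLS)


def _reader_for(r: pd.Series, rcfg: ReaderConfig) -> ReaderConfig:
    # a design row may carry its own sampling rate (e.g. simulated datasets)
    if "sample_rate_hz" in r and pd.notna(r["sample_rate_hz"]):
        return dataclasses.replace(rcfg, sample_rate_hz=float(r["sample_rate_hz"]))
    return rcfg


def _clean_one(data_dir: Path, r: pd.Series, rcfg: ReaderConfig, pcfg: PreprocessConfig):
    trace = read_pupil_samples(data_dir / r["pupil_file"], _reader_for(r, rcfg))
    return preprocess_trial(trace, float(r["stimulus_onset_ms"]), pcfg)


def _preprocess_cfg(config: dict) -> PreprocessConfig:
    p = dict(config["preprocess"])
    rng = p.get("plausible_range_au")
    if rng is not None:
        p["plausible_range_au"] = tuple(rng)
    return PreprocessConfig(**p)


def stage_pupil(data_dir: Path, outdir: Path, config: dict) -> pd.DataFrame:
    """Clean every trial's pupil trace and report the trial-mean pupil size."""
    rcfg = reader_config_from(config)
    pcfg = _preprocess_cfg(config)
    design = _load_design(data_dir)
    rows: List[dict] = []
    for _, r in design.iterrows():
        clean = _clean_one(data_dir, r, rcfg, pcfg)
        rows.extend(pupil_rows(clean, _design_of(r)))
    out = pd.DataFrame(rows, columns=TIDY_COLS)
    out.to_csv(outdir / "pupil.csv", index=False)
    return out


def stage_entrainment(data_dir: Path, outdir: Path, config: dict) -> pd.DataFrame:
    """Phase coherence at the metronome frequency for every usable trial.

    Paced trials are time-locked to their cues; unpaced (SMT) trials use the
    tap onsets with the trial's mean inter-tap interval as the target
    frequency, which makes the movement-only control computable.
    """
    rcfg = reader_config_from(config)
    pcfg = _preprocess_cfg(config)
    ecfg = config["entrainment"]
    design = _load_design(data_dir)
    rows: List[dict] = []
    for _, r in design.iterrows():
        clean = _clean_one(data_dir, r, rcfg, pcfg)
        trial = read_tap_events(data_dir / r["events_file"], rcfg,
                                design=_design_of(r))
        rows.extend(entrainment_rows(clean, trial, ecfg))
    out = pd.DataFrame(rows, columns=TIDY_COLS)
    out.to_csv(outdir / "entrainment.csv", index=False)
    return out


MAIN_CELLS = [(t, g) for t in ("Listen", "Tap") for g in ("Faster", "SMT", "Slower")]
CONTROL_CELLS = [("Listen", "SMT"), ("Tap", "SMT"), ("SMT", "none")]


def _write_anova(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    df["stars"] = [significance_stars(p) for p in df["p"]]
    df.to_csv(path, index=False)


def stage_stats(outdir: Path, config: dict) -> Dict[str, pd.DataFrame]:
    """Inference layer over the per-trial tidy tables."""
    scfg = config["stats"]
    trial_rows = pd.concat(
        [pd.read_csv(outdir / f) for f in ("tapping.csv", "pupil.csv",
                                           "entrainment.csv")
         if (outdir / f).exists()],
        ignore_index=True)
    results: Dict[str, pd.DataFrame] = {}

    for measure, stem in (("mean_pupil", "pupil"),
                          ("phase_coherence", "coherence")):
        table = aggregate_conditions(trial_rows, measure, cells=MAIN_CELLS)
        if table.empty or table["participant"].nunique() < 2:
            logger.info("stats: skipping %s (insufficient data)", measure)
            continue
        anova = rm_anova(table, within=("task", "tempo"),
                         sphericity_correction=scfg["sphericity_correction"])
        _write_anova(anova, outdir / f"anova_{stem}.csv")
        results[f"anova_{stem}"] = anova
        post = posthoc_paired(table, effect_size=scfg["effect_size"])
        pdf = pd.DataFrame([vars(p) for p in post])
        pdf["stars"] = [significance_stars(p) for p in pdf["p_fdr"]]
        pdf.to_csv(outdir / f"posthoc_{stem}.csv", index=False)
        results[f"posthoc_{stem}"] = pdf

    for measure in ("vector_length", "direction_deg"):
        cells = [("Tap", g) for g in ("Faster", "SMT", "Slower")]
        table = aggregate_conditions(trial_rows, measure, cells=cells)
        if table.empty or table["participant"].nunique() < 2:
            continue
        anova = rm_anova(table, within=("tempo",))
        _write_anova(anova, outdir / f"anova_{measure}.csv")
        results[f"anova_{measure}"] = anova

    for measure, stem in (("mean_pupil", "pupil"),
                          ("phase_coherence", "coherence")):
        table = aggregate_conditions(trial_rows, measure, cells=CONTROL_CELLS)
        if table.empty or table["participant"].nunique() < 2:
            continue
        anova = control_analysis(table)
        _write_anova(anova, outdir / f"control_{stem}.csv")
        results[f"control_{stem}"] = anova
    return results


def run_pipeline(config: Union[str, Path, dict, None], seed: Optional[int],
                 outdir: Union[str, Path]) -> Dict[str, pd.DataFrame]:
    """Run every stage from a config; deterministic under config + seed.

    The config either names an existing ``data_dir`` or contains a
    ``simulate`` block; outputs (tidy per-trial tables, ANOVA and post-hoc
    tables, manifest) land in ``outdir``.
    """
    cfg = load_config(config) if not isinstance(config, dict) else \
        {**load_config(None), **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if "simulate" in cfg:
        data_dir = stage_simulate(cfg, seed, outdir)
    else:
        data_dir = Path(cfg.get("data_dir", ""))
        if not (data_dir / "design.csv").exists():
            raise FileNotFoundError(f"missing data directory or design.csv "
                                    f"under {data_dir!s}")

    tap = stage_tapping(data_dir, outdir, cfg)
    pup = stage_pupil(data_dir, outdir, cfg)
    ent = stage_entrainment(data_dir, outdir, cfg)
    results = stage_stats(outdir, cfg)

    design = _load_design(data_dir)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "counts": {
            "trials_total": int(len(design)),
            "tap_trials": int((design["task"] == "Tap").sum()),
            "tap_trials_excluded": int(
                tap[tap["measure"] == "vector_length"]["excluded"].sum()),
            "pupil_trials_excluded": int(
                pup[pup["measure"] == "mean_pupil"]["excluded"].sum()),
            "entrainment_trials_excluded": int(
                ent[ent["measure"] == "phase_coherence"]["excluded"].sum()),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
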