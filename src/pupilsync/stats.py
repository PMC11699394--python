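"""Repeated-measures inference layer.

Condition tables hold one value per participant x condition cell (the mean
over that cell's retained trials). The 3 (tempo) x 2 (task) within-subject
ANOVA reports F, uncorrected degrees of freedom, p, and generalized eta
squared (SS_effect / (SS_effect + SS_subjects + sum of within-error SS)),
computed via pingouin. Post-hoc paired t-tests (df = n - 1) are adjusted by
Benjamini-Hochberg FDR across the comparison family, with the paired effect
size d = mean(difference) / SD(difference) - which reproduces the identity
d = t / sqrt(n). A pooled-SD variant of d is available behind a flag.

No sphericity correction is applied by default (uncorrected df are
reported); Greenhouse-Geisser-corrected p values are available as an option.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("pupilsync")


@dataclass
class PosthocResult:
    comparison: str
    t: float
    df: int
    p_raw: float
    p_fdr: float
    d: float
    degenerate: bool = False


def aggregate_conditions(trial_rows: pd.DataFrame,
                         measure: str,
                         cells: Optional[Sequence[Tuple[str, str]]] = None
                         ) -> pd.DataFrame:
    """Per-participant condition means over retained trials.

    ``trial_rows`` is a tidy table with columns participant, task, tempo,
    measure, value and an optional boolean ``excluded`` column. Participants
    missing any design cell (all trials excluded there) are dropped for this
    measure, with a logged reason - keeping the design balanced.
    """
    df = trial_rows[trial_rows["measure"] == measure].copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=["value"])
    cell = (df.groupby(["participant", "task", "tempo"], as_index=False)["value"]
            .mean())
    if cells is None:
        cells = sorted({(t, g) for t, g in zip(cell["task"], cell["tempo"])})
    n_cells = len(cells)
    keep = []
    for pid, sub in cell.groupby("participant"):
        have = {(t, g) for t, g in zip(sub["task"], sub["tempo"])}
        if all(c in have for c in cells):
            keep.append(pid)
        else:
            missing = [c for c in cells if c not in have]
            logger.info("%s: participant %s dropped for measure %r "
                        "(missing cells %s, unbalances the design)",
                        "aggregate", pid, measure, missing)
    out = cell[cell["participant"].isin(keep)]
    out = out[[(t, g) in set(cells) for t, g in zip(out["task"], out["tempo"])]]
    out = out.reset_index(drop=True)
    out.attrs["measure"] = measure
    out.attrs["n_cells"] = n_cells
    return out


def _check_balanced(table: pd.DataFrame, within: Sequence[str],
                    subject: str) -> None:
    counts = table.groupby([subject, *within], observed=True).size()
    if (counts != 1).any():
        raise ValueError("unbalanced condition table: expected exactly one value "
                         "per participant x condition cell")
    per_subj = table.groupby(subject, observed=True).size()
    if per_subj.nunique() != 1:
        raise ValueError("unbalanced condition table: participants differ in "
                         "their condition cells")


def rm_anova(table: pd.DataFrame, within: Sequence[str] = ("task", "tempo"),
             dv: str = "value", subject: str = "participant",
             sphericity_correction: bool = False) -> pd.DataFrame:
    """Within-subjects ANOVA with generalized eta squared.

    Returns one row per effect with columns effect, F, df_num, df_den, p,
    ges. One- and two-factor designs are supported; the input must be
    balanced (aggregate first).
    """
    within = list(within)
    _check_balanced(table, within, subject)

    def col(row, *names):
        for name in names:  # pingouin spells p columns differently by path
            if name in row.index:
                return row[name]
        raise KeyError(names)

    def sanitize(row: dict) -> dict:
        # zero effect variance (e.g. constant dv) -> F = 0, not 0/0
        if not np.isfinite(row["F"]):
            row.update(F=0.0, p=1.0)
        if not np.isfinite(row["ges"]):
            row["ges"] = 0.0
        return row

    if len(within) == 1:
        res = pg.rm_anova(data=table, dv=dv, within=within[0], subject=subject,
                          detailed=True, effsize="ng2")
        eff = res[res["Source"] != "Error"].iloc[0]
        err = res[res["Source"] == "Error"].iloc[0]
        if "F" not in res.columns:  # all-zero variance: pingouin omits F
            return pd.DataFrame([{"effect": within[0], "F": 0.0,
                                  "df_num": int(eff["DF"]),
                                  "df_den": int(err["DF"]),
                                  "p": 1.0, "ges": 0.0}])
        rows = [sanitize({
            "effect": within[0], "F": float(eff["F"]),
            "df_num": int(eff["DF"]), "df_den": int(err["DF"]),
            "p": float(col(eff, "p-unc", "p_unc")), "ges": float(eff["ng2"]),
        })]
        return pd.DataFrame(rows)
    res = pg.rm_anova(data=table, dv=dv, within=within, subject=subject,
                      detailed=True, effsize="ng2")
    pcols = ("p-GG-corr", "p_GG_corr") if sphericity_correction else \
        ("p-unc", "p_unc")
    rows = []
    for _, r in res.iterrows():
        rows.append(sanitize({
            "effect": str(r["Source"]).replace(" * ", ":"),
            "F": float(r["F"]),
            "df_num": int(r["ddof1"]), "df_den": int(r["ddof2"]),
            "p": float(col(r, *pcols)), "ges": float(r["ng2"]),
        }))
    return pd.DataFrame(rows)


def paired_tests(pairs: Iterable[Tuple[str, np.ndarray, np.ndarray]],
                 effect_size: str = "mean_diff_sd") -> List[PosthocResult]:
    """Paired t-tests over aligned per-participant arrays with BH-FDR.

    Each pair is ``(label, x, y)``; the test is on ``x - y`` with
    df = n - 1. A zero-variance difference is flagged degenerate and
    reported with infinite-magnitude t and p = 0.
    """
    labels, ts, dfs, ps, ds, degen = [], [], [], [], [], []
    for label, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 2:
            raise ValueError(f"{label}: paired test needs >= 2 aligned pairs")
        diff = x - y
        n = diff.size
        sd = float(np.std(diff, ddof=1))
        if sd == 0.0:
            m = float(np.mean(diff))
            t = math.inf if m > 0 else (-math.inf if m < 0 else 0.0)
            p = 0.0 if m != 0 else 1.0
            d = t if m != 0 else 0.0
            degen.append(True)
        else:
            t, p = sps.ttest_rel(x, y)
            t, p = float(t), float(p)
            if effect_size == "mean_diff_sd":
                d = float(np.mean(diff) / sd)
            elif effect_size == "pooled_sd":
                pooled = math.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
                d = float(np.mean(diff) / pooled)
            else:
                raise ValueError(f"unknown effect_size {effect_size!r}")
            degen.append(False)
        labels.append(label)
        ts.append(t)
        dfs.append(n - 1)
        ps.append(p)
        ds.append(d)
    p_fdr = bh_adjust(ps)
    return [PosthocResult(l, t, df, p, q, d, dg)
            for l, t, df, p, q, d, dg in zip(labels, ts, dfs, ps, p_fdr, ds, degen)]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def posthoc_paired(table: pd.DataFrame,
                   comparisons: Optional[Sequence[Tuple[str, dict, dict]]] = None,
                   dv: str = "value", subject: str = "participant",
                   effect_size: str = "mean_diff_sd") -> List[PosthocResult]:
    """Post-hoc paired contrasts on a condition table.

    ``comparisons`` is a list of ``(label, selector_a, selector_b)`` where
    each selector is a column->value dict identifying one condition cell.
    The default family is the task contrast (Tap - Listen) at each tempo,
    the set that follows the task x tempo interaction.
    """
    if comparisons is None:
        tempi = sorted(table["tempo"].unique())
        comparisons = [(f"Tap-Listen@{g}", {"task": "Tap", "tempo": g},
                        {"task": "Listen", "tempo": g}) for g in tempi]
    pairs = []
    for label, sel_a, sel_b in comparisons:
        a = table.loc[np.logical_and.reduce(
            [table[k] == v for k, v in sel_a.items()])]
        b = table.loc[np.logical_and.reduce(
            [table[k] == v for k, v in sel_b.items()])]
        a = a.set_index(subject)[dv]
        b = b.set_index(subject)[dv]
        common = a.index.intersection(b.index)
        pairs.append((label, a.loc[common].to_numpy(), b.loc[common].to_numpy()))
    return paired_tests(pairs, effect_size=effect_size)


def paired_d_from_t(t: float, n: int) -> float:
    """Identity linking the paired t statistic to d = mean(diff)/SD(diff)."""
    return t / math.sqrt(n)


def control_analysis(table: pd.DataFrame, dv: str = "value",
                     subject: str = "participant") -> pd.DataFrame:
    """One-way within-subjects ANOVA over task levels at the preferred
    tempo only (Listen, paced Tap, unpaced tapping) - the movement-only
    control comparison."""
    return rm_anova(table, within=("task",), dv=dv, subject=subject)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
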