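import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupilsync.stats import (aggregate_conditions, bh_adjust, control_analysis,
                             paired_d_from_t, paired_tests, posthoc_paired,
                             rm_anova, significance_stars)


def long_table(values):
    """values: dict (participant, task, tempo) -> value."""
    return pd.DataFrame([{"participant": p, "task": a, "tempo": b, "value": v}
                         for (p, a, b), v in values.items()])


def ss_partition_oracle(cube):
    """Independent balanced within-subjects SS partition.

    cube: (n_subjects, a, b) array. Returns per-effect (F, ges, df) computed
    from first principles, independent of the implementation under test.
    """
    n, a, b = cube.shape
    gm = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    ss_s = a * b * ((m_s - gm) ** 2).sum()
    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    m_ab = cube.mean(axis=0)
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_tot = ((cube - gm) ** 2).sum()
    ss_sab = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb
    err_all = ss_sa + ss_sb + ss_sab
    out = {}
    for name, ss_e, ss_err, df1 in (
            ("task", ss_a, ss_sa, a - 1),
            ("tempo", ss_b, ss_sb, b - 1),
            ("task:tempo", ss_ab, ss_sab, (a - 1) * (b - 1))):
        df2 = df1 * (n - 1)
        f = (ss_e / df1) / (ss_err / df2)
        out[name] = (f, ss_e / (ss_e + ss_s + err_all), df1, df2)
    return out


class TestAggregate:
    def rows(self, triples):
        return pd.DataFrame([{"participant": p, "task": a, "tempo": b,
                              "measure": "m", "value": v, "excluded": e}
                             for p, a, b, v, e in triples])

    def test_cell_mean_over_trials(self):
        df = self.rows([("P1", "Tap", "SMT", v, False) for v in (1, 2, 3)]
                       + [("P1", "Listen", "SMT", 5, False)])
        out = aggregate_conditions(df, "m")
        got = out.set_index(["task", "tempo"]).loc[("Tap", "SMT"), "value"]
        assert got == pytest.approx(2.0)

    def test_excluded_trials_ignored(self):
        df = self.rows([("P1", "Tap", "SMT", 1, False),
                        ("P1", "Tap", "SMT", 99, True),
                        ("P1", "Listen", "SMT", 0, False)])
        out = aggregate_conditions(df, "m")
        got = out.set_index(["task", "tempo"]).loc[("Tap", "SMT"), "value"]
        assert got == pytest.approx(1.0)

    def test_participant_missing_cell_dropped(self):
        df = self.rows([("P1", "Tap", "SMT", 1, False),
                        ("P1", "Listen", "SMT", 2, False),
                        ("P2", "Tap", "SMT", 3, False)])
        out = aggregate_conditions(df, "m",
                                   cells=[("Tap", "SMT"), ("Listen", "SMT")])
        assert set(out["participant"]) == {"P1"}

    def test_all_trials_excluded_in_cell_drops_participant(self):
        df = self.rows([("P1", "Tap", "SMT", 1, False),
                        ("P1", "Listen", "SMT", 2, True),
                        ("P2", "Tap", "SMT", 3, False),
                        ("P2", "Listen", "SMT", 4, False)])
        out = aggregate_conditions(df, "m",
                                   cells=[("Tap", "SMT"), ("Listen", "SMT")])
        assert set(out["participant"]) == {"P2"}


class TestRmAnova:
    def test_constant_dv_gives_zero_f(self):
        vals = {(p, a, b): 7.0 for p in "XYZ" for a in ("Listen", "Tap")
                for b in ("Faster", "SMT", "Slower")}
        res = rm_anova(long_table(vals)).set_index("effect")
        assert (res["F"] == 0.0).all()
        assert (res["ges"] == 0.0).all()

    def test_toy_table_matches_ss_partition_oracle(self):
        rng = np.random.default_rng(5)
        cube = rng.normal(size=(3, 2, 3))
        vals = {}
        for i, p in enumerate("UVW"):
            for j, a in enumerate(("Listen", "Tap")):
                for k, b in enumerate(("Faster", "SMT", "Slower")):
                    vals[(p, a, b)] = cube[i, j, k]
        res = rm_anova(long_table(vals)).set_index("effect")
        oracle = ss_partition_oracle(cube)
        for effect, (f, ges, df1, df2) in oracle.items():
            assert res.loc[effect, "F"] == pytest.approx(f, abs=1e-10)
            assert res.loc[effect, "ges"] == pytest.approx(ges, abs=1e-10)
            assert res.loc[effect, "df_num"] == df1
            assert res.loc[effect, "df_den"] == df2

    def test_design_degrees_of_freedom(self):
        rng = np.random.default_rng(9)
        n = 23
        vals = {(f"P{i}", a, b): rng.normal()
                for i in range(n) for a in ("Listen", "Tap")
                for b in ("Faster", "SMT", "Slower")}
        res = rm_anova(long_table(vals)).set_index("effect")
        assert (res.loc["task", "df_num"], res.loc["task", "df_den"]) == (1, 22)
        assert (res.loc["tempo", "df_num"], res.loc["tempo", "df_den"]) == (2, 44)
        assert (res.loc["task:tempo", "df_num"],
                res.loc["task:tempo", "df_den"]) == (2, 44)

    def test_unbalanced_table_rejected(self):
        vals = {(p, a, b): 1.0 for p in "XY" for a in ("Listen", "Tap")
                for b in ("Faster", "SMT")}
        del vals[("Y", "Tap", "SMT")]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(long_table(vals))


class TestPosthoc:
    def test_bh_step_up_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bh_permutation_invariant_and_monotone(self, ps):
        base = dict(zip(ps, bh_adjust(ps)))
        rng = np.random.default_rng(0)
        perm = list(ps)
        rng.shuffle(perm)
        for p, q in zip(perm, bh_adjust(perm)):
            assert q == pytest.approx(base[p], abs=1e-12)
            assert q >= p - 1e-12

    def test_degenerate_zero_variance_contract(self):
        res = paired_tests([("c", np.array([1.0, 1.0, 1.0]),
                             np.array([0.0, 0.0, 0.0]))])
        assert res[0].degenerate
        assert math.isinf(res[0].t) and res[0].t > 0
        assert res[0].p_raw == 0.0

    def test_d_equals_t_over_sqrt_n(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = paired_tests([("c", x, y)])[0]
        assert res.d == pytest.approx(paired_d_from_t(res.t, 30), abs=1e-12)

    def test_reported_effect_size_identities(self):
        # published t/d pairs at n = 23 follow d = t/sqrt(n) to 2 decimals
        assert round(paired_d_from_t(4.434, 23), 2) == 0.92
        assert round(paired_d_from_t(3.301, 23), 2) == 0.69

    def test_default_family_is_task_by_tempo(self):
        rng = np.random.default_rng(2)
        vals = {(f"P{i}", a, b): rng.normal() + (1.0 if a == "Tap" else 0.0)
                for i in range(12) for a in ("Listen", "Tap")
                for b in ("Faster", "SMT", "Slower")}
        res = posthoc_paired(long_table(vals))
        assert [r.comparison for r in res] == \
            ["Tap-Listen@Faster", "Tap-Listen@SMT", "Tap-Listen@Slower"]
        for r in res:
            assert r.p_fdr >= r.p_raw - 1e-12
            assert (r.d > 0) == (r.t > 0)


class TestControlAnalysis:
    def table(self, fn):
        rows = []
        for i in range(5):
            for task in ("Listen", "Tap", "SMT"):
                rows.append({"participant": f"P{i}", "task": task,
                             "tempo": "SMT" if task != "SMT" else "none",
                             "value": fn(i, task)})
        return pd.DataFrame(rows)

    def test_identical_values_give_zero_f(self):
        res = control_analysis(self.table(lambda i, t: 3.0))
        assert res.loc[0, "F"] == 0.0

    def test_one_way_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        res = control_analysis(self.table(lambda i, t: rng.normal()))
        assert res.loc[0, "df_num"] == 2
        assert res.loc[0, "df_den"] == 2 * (5 - 1)

    def test_matches_two_level_partition_oracle(self):
        # one-way within ANOVA on 3 participants vs direct SS computation
        rng = np.random.default_rng(4)
        cube = rng.normal(size=(3, 3))
        rows = [{"participant": f"P{i}", "task": t, "tempo": "none",
                 "value": cube[i, j]}
                for i in range(3) for j, t in enumerate(("A", "B", "C"))]
        res = control_analysis(pd.DataFrame(rows))
        n, k = cube.shape
        gm = cube.mean()
        ss_t = n * ((cube.mean(0) - gm) ** 2).sum()
        ss_s = k * ((cube.mean(1) - gm) ** 2).sum()
        ss_err = ((cube - gm) ** 2).sum() - ss_t - ss_s
        f = (ss_t / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        ges = ss_t / (ss_t + ss_s + ss_err)
        assert res.loc[0, "F"] == pytest.approx(f, abs=1e-10)
        assert res.loc[0, "ges"] == pytest.approx(ges, abs=1e-10)


def test_significance_star_convention():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
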