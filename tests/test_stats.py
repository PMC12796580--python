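"""Repeated-measures ANOVA, Bonferroni, ROUT, t tests and trend contrasts."""

import numpy as np
import pandas as pd
import pytest

from whiskloop import build_fixture
from whiskloop.stats import (
    bonferroni_adjust,
    linear_trend_contrast,
    rout_outliers,
    t_tests,
    two_way_rm_anova,
)


def _fixture_long_table():
    fx = build_fixture("anova_2x2_hand")
    rows = []
    for s in fx.inputs["subjects"]:
        for i, a in enumerate(fx.inputs["row_levels"]):
            for j, b in enumerate(fx.inputs["col_levels"]):
                rows.append(
                    {"subject": s, "row": a, "col": b, "value": fx.inputs["values"][s][i][j]}
                )
    return pd.DataFrame(rows), fx


def _brute_force_ss(table):
    """Independent oracle: sums of squares by explicit summation over cells."""
    subs = sorted(table["subject"].unique())
    rows = sorted(table["row"].unique())
    cols = sorted(table["col"].unique())
    n, a, b = len(subs), len(rows), len(cols)
    y = {}
    for _, r in table.iterrows():
        y[(r["subject"], r["row"], r["col"])] = float(r["value"])
    g = sum(y.values()) / len(y)
    ms = {s: sum(y[(s, i, j)] for i in rows for j in cols) / (a * b) for s in subs}
    ma = {i: sum(y[(s, i, j)] for s in subs for j in cols) / (n * b) for i in rows}
    mb = {j: sum(y[(s, i, j)] for s in subs for i in rows) / (n * a) for j in cols}
    mab = {(i, j): sum(y[(s, i, j)] for s in subs) / n for i in rows for j in cols}
    mas = {(i, s): sum(y[(s, i, j)] for j in cols) / b for i in rows for s in subs}
    mbs = {(j, s): sum(y[(s, i, j)] for i in rows) / a for j in cols for s in subs}
    ss = {
        "total": sum((v - g) ** 2 for v in y.values()),
        "subject": a * b * sum((ms[s] - g) ** 2 for s in subs),
        "row": n * b * sum((ma[i] - g) ** 2 for i in rows),
        "col": n * a * sum((mb[j] - g) ** 2 for j in cols),
        "interaction": n
        * sum((mab[(i, j)] - ma[i] - mb[j] + g) ** 2 for i in rows for j in cols),
        "row_x_subject": b
        * sum((mas[(i, s)] - ma[i] - ms[s] + g) ** 2 for i in rows for s in subs),
        "col_x_subject": a
        * sum((mbs[(j, s)] - mb[j] - ms[s] + g) ** 2 for j in cols for s in subs),
    }
    ss["residual"] = ss["total"] - sum(
        ss[k] for k in ("subject", "row", "col", "interaction", "row_x_subject", "col_x_subject")
    )
    return ss


class TestTwoWayRmAnova:
    def test_matches_brute_force_oracle_on_hand_fixture(self):
        table, fx = _fixture_long_table()
        oracle = _brute_force_ss(table)
        res = two_way_rm_anova(table, design="both_within")
        get = lambda e: float(res.table.loc[res.table["effect"] == e, "SS"].iloc[0])  # noqa: E731
        for effect, key in [("row", "row"), ("col", "col"), ("interaction", "interaction"),
                            ("subject", "subject"), ("total", "total")]:
            assert get(effect) == pytest.approx(oracle[key], rel=1e-9)
        for effect in ("row", "col", "interaction"):
            f = float(res.table.loc[res.table["effect"] == effect, "F"].iloc[0])
            assert f == pytest.approx(fx.expected[f"F_{effect}"], rel=1e-9)
            p = float(res.table.loc[res.table["effect"] == effect, "p"].iloc[0])
            assert p == pytest.approx(fx.expected[f"p_{effect}"], rel=1e-9)

    def test_total_ss_conserved(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(7):
            for a in ("r1", "r2"):
                for b in ("c1", "c2"):
                    rows.append(
                        {"subject": s, "row": a, "col": b, "value": rng.normal()}
                    )
        table = pd.DataFrame(rows)
        res = two_way_rm_anova(table)
        oracle = _brute_force_ss(table)
        parts = (
            oracle["subject"] + oracle["row"] + oracle["col"] + oracle["interaction"]
            + oracle["row_x_subject"] + oracle["col_x_subject"] + oracle["residual"]
        )
        assert parts == pytest.approx(oracle["total"], rel=1e-9)
        got_total = float(res.table.loc[res.table["effect"] == "total", "SS"].iloc[0])
        assert got_total == pytest.approx(oracle["total"], rel=1e-9)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        rows = []
        for s in range(9):
            for a in ("r1", "r2"):
                for b in ("c1", "c2"):
                    rows.append(
                        {"subject": f"s{s}", "row": a, "col": b,
                         "value": rng.normal(loc=(a == "r2") * 1.5)}
                    )
        table = pd.DataFrame(rows)
        res = two_way_rm_anova(table, design="both_within")
        ref = pg.rm_anova(
            data=table, dv="value", within=["row", "col"], subject="subject", detailed=True
        )
        for mine, theirs in [("row", "row"), ("col", "col"), ("interaction", "row * col")]:
            f_mine = float(res.table.loc[res.table["effect"] == mine, "F"].iloc[0])
            f_ref = float(ref.loc[ref["Source"] == theirs, "F"].iloc[0])
            assert f_mine == pytest.approx(f_ref, rel=1e-6)

    def test_mixed_design_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for s in range(16):
            group = "c1" if s < 8 else "c2"
            for a in ("r1", "r2"):
                rows.append(
                    {"subject": f"s{s}", "row": a, "col": group,
                     "value": rng.normal(loc=(group == "c2") * 0.8)}
                )
        table = pd.DataFrame(rows)
        res = two_way_rm_anova(table, design="mixed")
        ref = pg.mixed_anova(
            data=table, dv="value", within="row", subject="subject", between="col"
        )
        pairs = [("col", "col"), ("row", "row"), ("interaction", "Interaction")]
        for mine, theirs in pairs:
            f_mine = float(res.table.loc[res.table["effect"] == mine, "F"].iloc[0])
            f_ref = float(ref.loc[ref["Source"] == theirs, "F"].iloc[0])
            assert f_mine == pytest.approx(f_ref, rel=1e-6)

    def test_identical_values_all_effect_ss_zero(self):
        rows = [
            {"subject": s, "row": a, "col": b, "value": 3.0}
            for s in range(4)
            for a in ("r1", "r2")
            for b in ("c1", "c2")
        ]
        res = two_way_rm_anova(pd.DataFrame(rows))
        for effect in ("row", "col", "interaction"):
            assert float(res.table.loc[res.table["effect"] == effect, "SS"].iloc[0]) == 0.0

    def test_incomplete_design_rejected(self):
        table, _ = _fixture_long_table()
        with pytest.raises(ValueError):
            two_way_rm_anova(table.iloc[:-1])

    def test_null_column_factor_type_i_error(self):
        # true row effect, no column effect: rejection rate of the column
        # test stays near alpha (binomial 99% band at 1000 replicates)
        rng = np.random.default_rng(12)
        alpha, reps, n = 0.05, 1000, 8
        rejections = 0
        for _ in range(reps):
            base = rng.normal(0, 1, n)
            vals = {
                ("r1", "c1"): base + rng.normal(0, 1, n),
                ("r1", "c2"): base + rng.normal(0, 1, n),
                ("r2", "c1"): base + 2.0 + rng.normal(0, 1, n),
                ("r2", "c2"): base + 2.0 + rng.normal(0, 1, n),
            }
            rows = [
                {"subject": s, "row": a, "col": b, "value": vals[(a, b)][s]}
                for s in range(n)
                for a in ("r1", "r2")
                for b in ("c1", "c2")
            ]
            res = two_way_rm_anova(pd.DataFrame(rows))
            rejections += res.p_value("col") < alpha
        rate = rejections / reps
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= half + 0.01


class TestBonferroni:
    @pytest.mark.parametrize("case", build_fixture("bonferroni_cases").inputs["cases"])
    def test_cases(self, case):
        assert bonferroni_adjust([case["p"]], case["m"])[0] == pytest.approx(
            case["adjusted"]
        )

    def test_monotone_and_idempotent_at_m1(self):
        ps = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = bonferroni_adjust(ps, 3)
        assert adj == sorted(adj)
        assert bonferroni_adjust(ps, 1) == ps

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], 2)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5], 0)


class TestRout:
    def test_single_contaminant_flagged(self):
        fx = build_fixture("rout_single_contaminant")
        mask = rout_outliers(fx.inputs["values"], fx.inputs["q_percent"])
        assert list(np.flatnonzero(mask)) == fx.expected["outlier_indices"]

    def test_tight_cluster_no_outliers(self):
        assert not rout_outliers([1.0, 1.01, 0.99, 1.02, 0.98]).any()

    def test_affine_invariance(self):
        fx = build_fixture("rout_single_contaminant")
        x = np.asarray(fx.inputs["values"])
        base = rout_outliers(x)
        np.testing.assert_array_equal(base, rout_outliers(3.7 * x - 12.0))
        np.testing.assert_array_equal(base, rout_outliers(-0.2 * x + 5.0))

    def test_q_monotonicity(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 40), [8.0, -6.0, 15.0]])
        counts = [rout_outliers(x, q).sum() for q in (0.1, 0.5, 1.0, 5.0, 10.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0])


class TestTTests:
    def test_paired_identical_no_difference(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_tests(x, x, mode="paired")
        assert res["t"] == 0.0
        assert res["p"] == 1.0

    def test_paired_hand_example(self):
        # five paired differences d = (1, 2, 0, 3, 4): mean 2, sd 1.5811,
        # t = 2 / (1.5811/sqrt(5)) = 2.8284, df 4
        x = np.array([5.0, 7.0, 4.0, 9.0, 10.0])
        y = np.array([4.0, 5.0, 4.0, 6.0, 6.0])
        res = t_tests(x, y, mode="paired")
        assert res["t"] == pytest.approx(2.0 / (np.std(x - y, ddof=1) / np.sqrt(5)))
        assert res["t"] == pytest.approx(2.8284, abs=1e-4)
        assert res["df"] == 4

    def test_one_sample_symmetric_zero(self):
        res = t_tests(np.array([-2.0, 2.0, -1.0, 1.0]), mode="one_sample")
        assert res["t"] == pytest.approx(0.0)

    def test_unpaired_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = t_tests(x, y, mode="unpaired")
        ref = sps.ttest_ind(x, y)
        assert res["t"] == pytest.approx(float(ref.statistic))
        assert res["p"] == pytest.approx(float(ref.pvalue))


class TestLinearTrend:
    def test_equal_means_zero_statistic(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        res = linear_trend_contrast(g)
        assert res["t"] == pytest.approx(0.0)

    def test_increasing_means_tiny_variance(self):
        g = [
            np.array([1.0, 1.001, 0.999]),
            np.array([2.0, 2.001, 1.999]),
            np.array([3.0, 3.001, 2.999]),
        ]
        res = linear_trend_contrast(g)
        assert res["t"] > 0
        assert res["p"] < 1e-3

    def test_hand_built_table_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1.0, 4) for m in (0.0, 1.0, 3.0)]
        res = linear_trend_contrast(groups)
        coef = np.array([-1.0, 0.0, 1.0])
        means = np.array([g.mean() for g in groups])
        L = float(coef @ means)
        ss_c = L**2 / float((coef**2 / 4).sum())
        ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups) / (12 - 3)
        assert res["F"] == pytest.approx(ss_c / ms_w, rel=1e-12)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            linear_trend_contrast([np.array([1.0, 2.0]), np.array([2.0, 3.0])])
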