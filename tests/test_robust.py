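import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import mstats

from vwmstats.robust import (
    akp_delta,
    chi2_2x2,
    eta_squared,
    mixed_anova,
    rm_anova_2within,
    trimmed_mean,
    winsorized_variance,
    yuen_independent,
    yuen_paired,
)


class TestTrimmedMean:
    def test_basic(self):
        assert trimmed_mean(np.arange(1, 11), 0.2) == pytest.approx(5.5)

    def test_zero_trim_is_mean(self, rng):
        x = rng.normal(size=17)
        assert trimmed_mean(x, 0.0) == pytest.approx(x.mean())

    def test_robust_to_outlier(self):
        x = np.arange(1, 11, dtype=float)
        y = x.copy()
        y[-1] = 1e6
        assert trimmed_mean(y, 0.2) == trimmed_mean(x, 0.2)

    def test_invalid_trim(self):
        with pytest.raises(ValueError):
            trimmed_mean([1, 2, 3], 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([], 0.2)

    def test_winsorized_variance_zero_trim(self, rng):
        x = rng.normal(size=12)
        assert winsorized_variance(x, 0.0) == pytest.approx(x.var(ddof=1))


class TestYuenIndependent:
    def test_identical_samples(self, rng):
        x = rng.normal(size=20)
        res = yuen_independent(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_trim_equals_welch(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(loc=0.4, size=31)
        res = yuen_independent(x, y, tr=0.0)
        welch = stats.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(welch.statistic, rel=1e-12)
        assert res.p == pytest.approx(welch.pvalue, rel=1e-10)
        assert res.df == pytest.approx(welch.df, rel=1e-12)

    def test_textbook_formula_oracle(self, rng):
        # independent step-by-step evaluation using scipy's winsorize
        x = rng.normal(size=30)
        y = rng.normal(loc=0.5, scale=1.4, size=34)
        tr = 0.2
        g1, g2 = math.floor(tr * 30), math.floor(tr * 34)
        h1, h2 = 30 - 2 * g1, 34 - 2 * g2
        sw1 = np.asarray(mstats.winsorize(np.sort(x), (tr, tr))).var(ddof=1)
        sw2 = np.asarray(mstats.winsorize(np.sort(y), (tr, tr))).var(ddof=1)
        d1 = (30 - 1) * sw1 / (h1 * (h1 - 1))
        d2 = (34 - 1) * sw2 / (h2 * (h2 - 1))
        xt = np.sort(x)[g1 : 30 - g1].mean()
        yt = np.sort(y)[g2 : 34 - g2].mean()
        t_expected = (xt - yt) / math.sqrt(d1 + d2)
        df_expected = (d1 + d2) ** 2 / (d1**2 / (h1 - 1) + d2**2 / (h2 - 1))
        res = yuen_independent(x, y, tr=tr)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.df == pytest.approx(df_expected, rel=1e-12)
        assert 28 <= res.df <= 38

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            yuen_independent(np.ones(10), np.ones(12))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(2000):
            ps.append(yuen_independent(rng.normal(size=30), rng.normal(size=34)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestYuenPaired:
    @pytest.mark.parametrize("n,df", [(30, 17), (34, 21)])
    def test_printed_dfs(self, rng, n, df):
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        assert yuen_paired(x, y).df == df
        assert n - 2 * math.floor(0.2 * n) - 1 == df

    def test_identical(self, rng):
        x = rng.normal(size=20)
        res = yuen_paired(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            yuen_paired(np.zeros(5), np.zeros(6))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(2000):
            x = rng.normal(size=30)
            y = x * 0.5 + rng.normal(size=30)
            ps.append(yuen_paired(x, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAkpDelta:
    def test_equal_trimmed_means(self, rng):
        x = rng.normal(size=25)
        assert akp_delta(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("a", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, rng, a):
        x = rng.normal(size=25)
        y = rng.normal(loc=0.8, size=30)
        assert akp_delta(a * x, a * y) == pytest.approx(akp_delta(x, y), rel=1e-10)

    def test_step_by_step_oracle(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(loc=0.6, size=34)
        sw1 = np.asarray(mstats.winsorize(np.sort(x), (0.2, 0.2))).var(ddof=1)
        sw2 = np.asarray(mstats.winsorize(np.sort(y), (0.2, 0.2))).var(ddof=1)
        pooled = math.sqrt(((30 - 1) * sw1 + (34 - 1) * sw2) / (30 + 34 - 2))
        xt = np.sort(x)[6:24].mean()
        yt = np.sort(y)[6:28].mean()
        expected = 0.642 * (xt - yt) / pooled
        assert akp_delta(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            akp_delta(np.ones(10), np.ones(10))


class TestChi2:
    def test_demographics_table(self):
        res = chi2_2x2([[8, 22], [17, 17]])
        assert round(res.statistic, 2) == 2.73
        assert res.p == pytest.approx(0.098, abs=5e-4)
        assert res.df == 1.0

    def test_proportional_table_zero(self):
        assert chi2_2x2([[10, 20], [20, 40]]).statistic == 0.0

    def test_row_swap_invariance(self):
        a = chi2_2x2([[8, 22], [17, 17]]).statistic
        b = chi2_2x2([[17, 17], [8, 22]]).statistic
        assert a == pytest.approx(b, rel=1e-14)

    def test_transpose_invariance(self):
        t = np.array([[5, 9], [12, 3]])
        assert chi2_2x2(t).statistic == pytest.approx(chi2_2x2(t.T).statistic, rel=1e-14)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [5, 5]])

    def test_uncorrected_matches_scipy(self):
        t = np.array([[11, 4], [7, 13]])
        res = chi2_2x2(t, correction=False)
        ref = stats.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)


def _mixed_data(rng, n1=32, n2=32, k=2, effect=0.0):
    rows = []
    for i in range(n1 + n2):
        grp = "experimental" if i < n1 else "control"
        base = rng.normal()
        for t in range(k):
            bump = effect * t if grp == "experimental" else 0.0
            rows.append(
                dict(participant_id=f"s{i:03d}", group=grp, time=f"t{t}",
                     value=base + bump + rng.normal())
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_printed_dfs_64_participants(self, rng):
        df = _mixed_data(rng, n1=30, n2=34)
        res = mixed_anova(df)
        for effect in ("group", "time", "interaction"):
            assert res[effect].df == (1.0, 62.0)

    def test_group_f_equals_t_squared_without_change(self, rng):
        df = _mixed_data(rng, n1=12, n2=15)
        wide = df.pivot_table(index=["participant_id", "group"], columns="time",
                              values="value").reset_index()
        wide["t1"] = wide["t0"]  # no within-subject change
        long = wide.melt(id_vars=["participant_id", "group"], value_vars=["t0", "t1"],
                         var_name="time", value_name="value")
        res = mixed_anova(long)
        means = wide.groupby("group")["t0"].apply(list)
        t = stats.ttest_ind(means["experimental"], means["control"], equal_var=True)
        assert res["group"].statistic == pytest.approx(t.statistic**2, rel=1e-10)

    def test_ss_additive(self, rng):
        df = _mixed_data(rng, n1=9, n2=11, k=3, effect=0.4)
        res = mixed_anova(df)
        y = df["value"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert sum(res.ss.values()) == pytest.approx(ss_total, abs=1e-8)

    def test_missing_cell_listed(self, rng):
        df = _mixed_data(rng, n1=5, n2=5).iloc[:-1]
        with pytest.raises(ValueError, match="s009"):
            mixed_anova(df)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _mixed_data(rng, n1=10, n2=13, k=3, effect=0.3)
        res = mixed_anova(df)
        ref = pg.mixed_anova(df, dv="value", within="time", between="group",
                             subject="participant_id")
        ref = ref.set_index("Source")
        assert res["group"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res["time"].statistic == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert res["interaction"].statistic == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)
        assert res["time"].effect_sizes["eta_p_sq"] == pytest.approx(ref.loc["time", "np2"], rel=1e-8)


def _rm_data(rng, n=30, a=4, b=3):
    rows = []
    for i in range(n):
        base = rng.normal()
        for s in range(a):
            for z in range(b):
                rows.append(
                    dict(participant_id=f"s{i:03d}", time=f"a{s}", set_size=z,
                         value=base + 0.2 * s - 0.3 * z + rng.normal())
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_printed_training_dfs(self, rng):
        res = rm_anova_2within(_rm_data(rng, n=30, a=4, b=3))
        assert res["time"].df == (3.0, 87.0)
        assert res["set_size"].df == (2.0, 58.0)
        assert res["interaction"].df == (6.0, 174.0)

    def test_incomplete_crossing_rejected(self, rng):
        df = _rm_data(rng, n=6).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_2within(df)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _rm_data(rng, n=9, a=3, b=3)
        res = rm_anova_2within(df)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(df, dv="value", within=["time", "set_size"],
                              subject="participant_id", detailed=True).set_index("Source")
        assert res["time"].statistic == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert res["set_size"].statistic == pytest.approx(ref.loc["set_size", "F"], rel=1e-8)
        assert res["interaction"].statistic == pytest.approx(
            ref.loc["time * set_size", "F"], rel=1e-8)
        assert res["time"].effect_sizes["eta_g_sq"] == pytest.approx(
            ref.loc["time", "ng2"], rel=1e-8)

    def test_hand_worked_eta_oracle(self):
        # 2 subjects x 2 x 2 cube worked out by hand with exact fractions:
        # SS: subj=18, A=18, B=4.5, AB=0.5, AS=2, BS=0.5, ABS=0.5, total=44
        rows = []
        cube = {("s1", "a1", "b1"): 1, ("s1", "a1", "b2"): 2,
                ("s1", "a2", "b1"): 3, ("s1", "a2", "b2"): 4,
                ("s2", "a1", "b1"): 2, ("s2", "a1", "b2"): 5,
                ("s2", "a2", "b1"): 7, ("s2", "a2", "b2"): 8}
        for (s, a, b), v in cube.items():
            rows.append(dict(participant_id=s, time=a, set_size=b, value=float(v)))
        res = rm_anova_2within(pd.DataFrame(rows))
        assert res.ss["subject"] == pytest.approx(18.0, abs=1e-10)
        assert res.ss["time"] == pytest.approx(18.0, abs=1e-10)
        assert res.ss["set_size"] == pytest.approx(4.5, abs=1e-10)
        assert res.ss["interaction"] == pytest.approx(0.5, abs=1e-10)
        assert res["time"].effect_sizes == pytest.approx(
            {"eta_p_sq": 0.9, "eta_g_sq": 6 / 13})
        assert res["set_size"].effect_sizes == pytest.approx(
            {"eta_p_sq": 0.9, "eta_g_sq": 3 / 17})
        assert res["interaction"].effect_sizes == pytest.approx(
            {"eta_p_sq": 0.5, "eta_g_sq": 1 / 43})


class TestEtaSquared:
    def test_partial_at_least_generalized(self, rng):
        res = rm_anova_2within(_rm_data(rng, n=8, a=3, b=2))
        for effect in res.effects.values():
            assert effect.effect_sizes["eta_p_sq"] >= effect.effect_sizes["eta_g_sq"]

    def test_single_error_term_equality(self):
        eta_g, eta_p = eta_squared(4.0, 6.0, 6.0)
        assert eta_g == eta_p == pytest.approx(0.4)

    def test_negative_ss_rejected(self):
        with pytest.raises(ValueError):
            eta_squared(-1.0, 2.0, 2.0)
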