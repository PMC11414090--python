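import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from callimorph.exceptions import DegenerateDataError
from callimorph.stats_core import (
    GroupSummary,
    games_howell,
    levene_test,
    manova_pillai,
    one_sample_t,
    studentized_range_cdf,
    studentized_range_ppf,
    summarize,
    welch_anova,
    welch_t,
)
from conftest import make_summary


class TestSummarize:
    def test_two_values(self):
        flat = pd.DataFrame({"taxon": ["J", "J"], "BODY": [2.0, 4.0]})
        (s,) = summarize(flat)
        assert (s.n, s.mean) == (2, 3.0)
        assert s.sd == pytest.approx(math.sqrt(2))

    def test_single_value_degenerate(self):
        flat = pd.DataFrame({"taxon": ["J"], "BODY": [5.0]})
        (s,) = summarize(flat)
        assert (s.n, s.mean, s.sd) == (1, 5.0, None)

    def test_missing_values_not_counted(self):
        flat = pd.DataFrame({"taxon": ["J"] * 3, "BODY": [2.0, np.nan, 4.0]})
        (s,) = summarize(flat)
        assert s.n == 2

    def test_all_missing_group_omitted(self):
        flat = pd.DataFrame({"taxon": ["J", "P"], "BODY": [np.nan, 3.0]})
        assert [s.group for s in summarize(flat)] == ["P"]

    def test_synthetic_recovery_within_sampling_error(self):
        # parental spec mean 19.9, sd 1.6 at n=29 (published magnitudes)
        from callimorph.synthetic_data import SyntheticScenario, generate_traits
        from callimorph.schema import TRAIT_NAMES

        spec = {"J": {t: (19.9, 1.6) for t in TRAIT_NAMES}}
        synth = generate_traits(
            SyntheticScenario(parental_specs=spec, group_sizes={"J": 29}, seed=5)
        )
        flat = synth.table.to_flat_frame()
        s = next(x for x in summarize(flat) if x.trait == "BODY")
        assert abs(s.mean - 19.9) < 3 * 1.6 / math.sqrt(29)


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        res = levene_test([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mean_centered_equals_anova_on_deviations(self):
        # brute-force oracle: classic ANOVA on |x - group mean|
        res = levene_test([[1, 2, 3], [10, 20, 30]], center="mean")
        oracle = sps.f_oneway([1.0, 0.0, 1.0], [10.0, 0.0, 10.0])
        assert res.statistic == pytest.approx(oracle.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-12)

    @pytest.mark.parametrize("center", ["median", "mean"])
    def test_matches_scipy(self, center, rng):
        groups = [rng.normal(0, s, n) for s, n in [(1, 10), (2, 15), (1.5, 8)]]
        res = levene_test(groups, center=center)
        oracle = sps.levene(*groups, center=center)
        assert res.statistic == pytest.approx(oracle.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-10)

    def test_scale_invariance(self, rng):
        groups = [rng.normal(0, 1, 12), rng.normal(0, 3, 9)]
        a = levene_test(groups).statistic
        b = levene_test([g * 7.5 for g in groups]).statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_constant_groups_flagged(self):
        with pytest.raises(DegenerateDataError):
            levene_test([[1.0, 1.0], [2.0, 2.0]])


class TestWelchAnova:
    def test_k2_equals_squared_welch_t(self):
        a = make_summary("A", 12, 1.3, 2.1)
        b = make_summary("B", 30, 0.2, 0.9)
        f_res = welch_anova([a, b])
        t_res = welch_t(a, b)
        assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert f_res.df2 == pytest.approx(t_res.df1, rel=1e-10)
        assert f_res.p_value == pytest.approx(t_res.p_value, rel=1e-10)

    def test_equal_means(self):
        ss = [make_summary(g, 10, 5.0, s) for g, s in [("A", 1.0), ("B", 2.0), ("C", 0.5)]]
        res = welch_anova(ss)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_three_group_formula_term_by_term(self):
        ss = [
            make_summary("A", 10, 0.0, 1.0),
            make_summary("B", 10, 0.5, 1.0),
            make_summary("C", 10, 1.0, 2.0),
        ]
        res = welch_anova(ss)
        # independent term-by-term evaluation of the published statistic
        w = [10 / 1.0, 10 / 1.0, 10 / 4.0]
        W = sum(w)
        mbar = sum(wj * m for wj, m in zip(w, [0.0, 0.5, 1.0])) / W
        num = sum(wj * (m - mbar) ** 2 for wj, m in zip(w, [0.0, 0.5, 1.0])) / 2
        lam = sum((1 - wj / W) ** 2 / 9 for wj in w)
        f_star = num / (1 + 2 * 1 / 8 * lam)
        df2 = 8 / (3 * lam)
        assert res.statistic == pytest.approx(f_star, rel=1e-12)
        assert res.df2 == pytest.approx(df2, rel=1e-12)
        assert res.p_value == pytest.approx(sps.f.sf(f_star, 2, df2), rel=1e-12)

    def test_matches_pingouin_on_raw_data(self, rng):
        pg = pytest.importorskip("pingouin")
        values, labels = [], []
        for g, (mu, sd, n) in {"a": (0, 1, 12), "b": (1, 2, 20), "c": (0.5, 1.5, 9)}.items():
            values.extend(rng.normal(mu, sd, n))
            labels.extend([g] * n)
        frame = pd.DataFrame({"y": values, "g": labels})
        ss = [
            make_summary(g, len(sub), float(sub["y"].mean()), float(sub["y"].std(ddof=1)))
            for g, sub in frame.groupby("g")
        ]
        res = welch_anova(ss)
        oracle = pg.welch_anova(data=frame, dv="y", between="g").iloc[0]
        assert res.statistic == pytest.approx(oracle["F"], rel=1e-9)
        assert res.df2 == pytest.approx(oracle["ddof2"], rel=1e-9)
        assert res.p_value == pytest.approx(oracle["p_unc"], rel=1e-9)

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            welch_anova([make_summary("A", 5, 1.0, 0.0), make_summary("B", 5, 2.0, 1.0)])


class TestStudentizedRange:
    @pytest.mark.parametrize("k,df,q", [(3, 50, 3.0), (8, 12, 4.5), (2, 5, 1.2), (4, 200, 6.0)])
    def test_cdf_matches_scipy_to_1e6(self, k, df, q):
        assert studentized_range_cdf(q, k, df) == pytest.approx(
            sps.studentized_range.cdf(q, k, df), abs=1e-6
        )

    def test_ppf_inverts_cdf(self):
        q = studentized_range_ppf(0.95, 3, 40)
        assert studentized_range_cdf(q, 3, 40) == pytest.approx(0.95, abs=1e-8)


class TestGamesHowell:
    def test_equal_means_p_one(self):
        ss = [make_summary(g, 10, 5.0, 1.0) for g in "ABC"]
        res = games_howell(ss)
        pair = next(r for r in res if set(r.groups) == {"A", "B"})
        assert pair.statistic == 0.0
        assert pair.p_value == pytest.approx(1.0)

    def test_k2_matches_welch_decision(self):
        a = make_summary("A", 15, 10.0, 2.0)
        b = make_summary("B", 20, 11.5, 3.0)
        (gh,) = games_howell([a, b])
        wt = welch_t(a, b)
        # studentized-range transform of the Welch t at k=2
        expected = 1 - studentized_range_cdf(abs(wt.statistic) * math.sqrt(2), 2, wt.df1)
        assert gh.p_value == pytest.approx(expected, rel=1e-9)
        assert (gh.p_value < 0.05) == (wt.p_value < 0.05)

    def test_monotone_in_mean_difference(self):
        ps = []
        for dm in [0.5, 1.0, 1.5, 2.0]:
            ss = [
                make_summary("A", 12, 0.0, 1.0),
                make_summary("B", 12, dm, 1.0),
                make_summary("C", 12, 5.0, 1.0),
            ]
            pair = next(r for r in games_howell(ss) if set(r.groups) == {"A", "B"})
            ps.append(pair.p_value)
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_ci_excludes_zero_iff_significant(self):
        ss = [
            make_summary("A", 20, 0.0, 1.0),
            make_summary("B", 20, 1.2, 1.0),
            make_summary("C", 20, 0.1, 1.0),
        ]
        for r in games_howell(ss, alpha=0.05):
            excludes = r.conf_low > 0 or r.conf_high < 0
            assert excludes == (r.p_value < 0.05)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        values, labels = [], []
        for g, (mu, sd, n) in {"a": (0, 1, 14), "b": (1.2, 2, 18), "c": (0.4, 1.5, 11)}.items():
            values.extend(rng.normal(mu, sd, n))
            labels.extend([g] * n)
        frame = pd.DataFrame({"y": values, "g": labels})
        ss = [
            make_summary(g, len(sub), float(sub["y"].mean()), float(sub["y"].std(ddof=1)))
            for g, sub in frame.groupby("g")
        ]
        mine = {frozenset(r.groups): r for r in games_howell(ss)}
        oracle = pg.pairwise_gameshowell(data=frame, dv="y", between="g")
        for _, row in oracle.iterrows():
            r = mine[frozenset((row["A"], row["B"]))]
            assert r.p_value == pytest.approx(row["pval"], abs=1e-4)


class TestTTests:
    def test_one_sample_null(self):
        res = one_sample_t(make_summary("H", 10, 3.0, 1.0), 3.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_one_sample_published_cell(self):
        # hybrid body length vs its mid-parent value
        res = one_sample_t(make_summary("PJ", 54, 21.3, 2.7), 20.4)
        assert res.statistic == pytest.approx(2.449, abs=1e-3)
        assert res.p_value == pytest.approx(0.018, abs=1e-3)
        assert res.p_value < 0.05

    def test_one_sample_scaling_law(self):
        t1 = one_sample_t(make_summary("H", 25, 1.0, 2.0), 0.0).statistic
        t2 = one_sample_t(make_summary("H", 50, 1.0, 2.0), 0.0).statistic
        assert t2 == pytest.approx(t1 * math.sqrt(2), rel=1e-12)

    def test_welch_identical_summaries(self):
        a = make_summary("A", 10, 4.0, 1.5)
        res = welch_t(a, make_summary("B", 10, 4.0, 1.5))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_welch_equal_var_equal_n_df(self):
        res = welch_t(make_summary("A", 12, 1.0, 2.0), make_summary("B", 12, 3.0, 2.0))
        assert res.df1 == pytest.approx(22.0, rel=1e-12)

    def test_welch_published_cell_significant(self):
        # hybrid vs first-species hand length
        res = welch_t(make_summary("AH", 9, 39.0, 3.7), make_summary("A", 21, 30.5, 15.1))
        assert res.p_value < 0.05

    def test_welch_matches_scipy_from_stats(self):
        a = make_summary("A", 9, 39.0, 3.7)
        b = make_summary("B", 21, 30.5, 15.1)
        res = welch_t(a, b)
        t, p = sps.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
        )
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)


class TestManova:
    def test_duplicated_groups_null(self, rng):
        X = rng.normal(size=(20, 3))
        X2 = np.vstack([X, X])
        labels = ["a"] * 20 + ["b"] * 20
        res = manova_pillai(X2, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_univariate_reduction_equals_anova_f(self, rng):
        y = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        y[10:20] += 1.0
        res = manova_pillai(y[:, None], labels)
        p = 1
        k = 3
        s = min(p, k - 1)
        m = (abs(p - k + 1) - 1) / 2
        n_p = (30 - k - p - 1) / 2
        f_pillai = (2 * n_p + s + 1) / (2 * m + s + 1) * res.statistic / (s - res.statistic)
        oracle = sps.f_oneway(y[:10], y[10:20], y[20:])
        assert f_pillai == pytest.approx(oracle.statistic, rel=1e-9)

    def test_pillai_trace_eigen_oracle(self, rng):
        # V equals the sum of eigenvalues of (E+H)^{-1} H
        X = rng.normal(size=(24, 2))
        labels = np.repeat(["a", "b", "c"], 8)
        X[8:16] += [1.0, 0.0]
        res = manova_pillai(X, labels)
        grand = X.mean(axis=0)
        H = np.zeros((2, 2))
        E = np.zeros((2, 2))
        for g in "abc":
            sub = X[labels == g]
            d = (sub.mean(axis=0) - grand)[:, None]
            H += len(sub) * d @ d.T
            E += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
        eig = np.linalg.eigvals(np.linalg.inv(E + H) @ H)
        assert res.statistic == pytest.approx(float(np.real(eig.sum())), rel=1e-10)

    def test_matches_statsmodels(self, rng):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        X = rng.normal(size=(40, 4))
        labels = np.repeat(["a", "b", "c", "d"], 10)
        X[:10] += 0.8
        res = manova_pillai(X, labels)
        frame = pd.DataFrame(X, columns=[f"y{i}" for i in range(4)])
        frame["g"] = labels
        mv = sm_manova.MANOVA.from_formula("y0 + y1 + y2 + y3 ~ g", data=frame)
        tbl = mv.mv_test().results["g"]["stat"]
        row = tbl.loc["Pillai's trace"]
        assert res.statistic == pytest.approx(row["Value"], rel=1e-8)
        assert res.df1 == pytest.approx(row["Num DF"], rel=1e-8)
        assert res.df2 == pytest.approx(row["Den DF"], rel=1e-8)
        assert res.p_value == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_singular_within_sscp(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * X[:, 0]  # collinear traits
        with pytest.raises(DegenerateDataError, match="singular"):
            manova_pillai(X, ["a"] * 5 + ["b"] * 5)
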