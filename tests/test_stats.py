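"""Statistical battery: exactness against closed forms, enumeration oracles,
and reference implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from efferentquant.stats import (
    anova_oneway_posthoc,
    anova_twoway,
    correlation_table,
    friedman_statistic,
    friedman_with_posthoc,
    mann_whitney,
)


class TestFriedman:
    def test_identical_subjects_give_zero(self):
        data = np.tile([1.0, 1.0, 1.0], (5, 1))
        stat, df, p = friedman_statistic(data)
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_perfectly_consistent_ranks_reach_2n_for_k3(self, n):
        data = np.tile([1.0, 2.0, 3.0], (n, 1)) + np.arange(n)[:, None] * 10
        stat, _, _ = friedman_statistic(data)
        assert stat == pytest.approx(2.0 * n)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            data = rng.normal(size=(rng.integers(4, 10), rng.integers(3, 6)))
            stat, _, p = friedman_statistic(data)
            ref = sps.friedmanchisquare(*data.T)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 4))
        s1, _, _ = friedman_statistic(data)
        s2, _, _ = friedman_statistic(np.exp(data))
        assert s1 == pytest.approx(s2)

    def test_posthoc_table_and_incomplete_blocks(self):
        rows = [
            {"animal": a, "timepoint_day": d, "value": v}
            for a, vals in {"a": (1, 5, 2), "b": (2, 6, 1), "c": (1, 7, 3)}.items()
            for d, v in zip((0, 13, 26), vals)
        ]
        res = friedman_with_posthoc(pd.DataFrame(rows))
        assert set(res.posthoc["level_b"]) == {13, 26}
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()
        with pytest.raises(ValueError, match="missing cells"):
            friedman_with_posthoc(pd.DataFrame(rows[:-1]))

    def test_wilcoxon_posthoc_variant_runs(self):
        rng = np.random.default_rng(2)
        rows = [
            {"animal": f"a{i}", "timepoint_day": d, "value": rng.normal()}
            for i in range(8)
            for d in (0, 13, 26)
        ]
        res = friedman_with_posthoc(pd.DataFrame(rows), method="wilcoxon")
        assert ((res.posthoc["p_adj"] >= 0) & (res.posthoc["p_adj"] <= 1)).all()


class TestMannWhitney:
    def test_canonical_separated_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2
        assert res.p_value == 1.0

    def test_all_tied_values(self):
        assert mann_whitney([5, 5, 5], [5, 5]).p_value == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            # disjoint value pools: scipy's exact method assumes no ties
            a = rng.permutation(20)[: rng.integers(2, 7)].astype(float)
            b = (rng.permutation(20) + 20)[: rng.integers(2, 7)].astype(float)
            ours = mann_whitney(a, b, mode="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            b = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            ours = mann_whitney(a, b, mode="exact").p_value
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            n_a = len(a)
            u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
            us = np.array(
                [
                    ranks[list(c)].sum() - n_a * (n_a + 1) / 2
                    for c in itertools.combinations(range(len(pooled)), n_a)
                ]
            )
            oracle = min(
                1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
            )
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=5), rng.normal(size=6)
        p1 = mann_whitney(a, b).p_value
        p2 = mann_whitney(np.exp(a), np.exp(b)).p_value
        assert p1 == p2


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 12)
        res = anova_oneway_posthoc({"a": a, "b": b}, posthoc="bonferroni")
        t = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-12)

    def test_identical_groups_give_zero(self):
        res = anova_oneway_posthoc({"a": [2, 2, 2], "b": [2, 2, 2]}, posthoc="bonferroni")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_within_variance_flagged(self):
        res = anova_oneway_posthoc({"a": [1, 1, 1], "b": [2, 2, 2]})
        assert np.isinf(res.statistic) and res.extras["degenerate"]

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(i * 0.3, 1 + i * 0.2, 5 + i) for i, g in enumerate("abcd")}
        res = anova_oneway_posthoc(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(size=6) for g in "abc"}
        f1 = anova_oneway_posthoc(groups).statistic
        f2 = anova_oneway_posthoc(
            {g: 3.0 * v - 7.0 for g, v in groups.items()}
        ).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_bonferroni_adjustment_bounds(self):
        rng = np.random.default_rng(9)
        groups = {g: rng.normal(size=7) for g in "abc"}
        ph = anova_oneway_posthoc(groups, posthoc="bonferroni").posthoc
        assert (ph["p_adj"] >= ph["p_raw"] - 1e-15).all()
        assert (ph["p_adj"] <= 1.0).all()

    def test_games_howell_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        groups = {
            "g1": rng.normal(0, 1, 8),
            "g2": rng.normal(0.8, 2, 6),
            "g3": rng.normal(0.2, 0.5, 10),
        }
        ours = anova_oneway_posthoc(groups, posthoc="games_howell").posthoc
        df = pd.DataFrame(
            [(g, v) for g, vals in groups.items() for v in vals], columns=["g", "y"]
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        merged = ours.merge(ref, left_on=["group_a", "group_b"], right_on=["A", "B"])
        assert len(merged) == 3
        for _, r in merged.iterrows():
            assert r["p_adj"] == pytest.approx(r["pval"], abs=1e-6)


class TestTwoWayAnova:
    def test_balanced_2x2_hand_computed(self):
        # cells: a1b1={1,3}, a1b2={2,4}, a2b1={5,7}, a2b2={10,12}
        df = pd.DataFrame(
            {
                "y": [1, 3, 2, 4, 5, 7, 10, 12],
                "fa": ["a1"] * 4 + ["a2"] * 4,
                "fb": ["b1", "b1", "b2", "b2"] * 2,
            }
        )
        # hand sums of squares (balanced, type II == type I):
        # cell means 2, 3, 6, 11; grand mean 5.5
        # SS_A = 4*(2.5-5.5)^2 + 4*(8.5-5.5)^2 = 72
        # SS_B = 4*(4-5.5)^2 + 4*(7-5.5)^2 = 18
        # SS_cells = 2*sum((cell-5.5)^2) = 98 -> SS_AB = 98-72-18 = 8
        # SS_E = sum within cells = 8 on 4 df
        res = anova_twoway(df, "y", "fa", "fb")
        tab = res.extras["table"]
        assert tab.loc["fa", "sum_sq"] == pytest.approx(72.0)
        assert tab.loc["fb", "sum_sq"] == pytest.approx(18.0)
        assert tab.loc["fa:fb", "sum_sq"] == pytest.approx(8.0)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert res.statistic == pytest.approx((72.0 / 1) / (8.0 / 4))

    def test_pure_second_factor_effect(self):
        rng = np.random.default_rng(11)
        n = 40
        fb = np.tile(["f1", "f2"], n)
        y = np.where(fb == "f1", 0.0, 5.0) + rng.normal(0, 0.5, 2 * n)
        df = pd.DataFrame({"y": y, "fa": np.repeat(["g1", "g2"], n), "fb": fb})
        res = anova_twoway(df, "y", "fa", "fb")
        assert res.extras["p_values"]["fb"] < 1e-6
        assert res.extras["p_values"]["fa"] > 0.05

    def test_empty_cells_are_listed(self):
        df = pd.DataFrame(
            {"y": [1, 2, 3, 4], "fa": ["a", "a", "b", "b"], "fb": ["x", "x", "x", "y"]}
        )
        with pytest.raises(ValueError, match="empty design cells"):
            anova_twoway(df, "y", "fa", "fb")


class TestCorrelationTable:
    def test_perfectly_anti_monotone_pairs(self):
        df = pd.DataFrame(
            {
                "condition": "SC",
                "area_um2": [1.0, 2.0, 3.0, 4.0, 5.0],
                "norm_od": [10.0, 8.0, 5.0, 2.0, 1.0],
            }
        )
        row = correlation_table(df).iloc[0]
        assert row["spearman_rho"] == pytest.approx(-1.0)

    def test_independent_pairs_have_small_coefficient(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "condition": "SC",
                "area_um2": rng.normal(size=1000),
                "norm_od": rng.normal(size=1000),
            }
        )
        row = correlation_table(df).iloc[0]
        assert abs(row["pearson_r"]) < 0.1

    def test_imposed_negative_correlation_recovered(self):
        rho = -0.58
        rng = np.random.default_rng(13)
        n = 180
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        df = pd.DataFrame({"condition": "AT+1d", "area_um2": x, "norm_od": y})
        row = correlation_table(df).iloc[0]
        assert row["pearson_r"] == pytest.approx(rho, abs=0.1)
        assert row["pearson_p"] < 0.001

    def test_zero_variance_flagged_not_crashed(self):
        df = pd.DataFrame(
            {"condition": "SC", "area_um2": [1.0, 1.0, 1.0], "norm_od": [1, 2, 3]}
        )
        row = correlation_table(df).iloc[0]
        assert row["degenerate"] and np.isnan(row["coefficient"])

    def test_table_mirrors_published_layout(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "condition": np.repeat(["SC", "AT+1d"], 30),
                "area_um2": rng.normal(10, 3, 60),
                "norm_od": rng.normal(4, 1, 60),
            }
        )
        tab = correlation_table(df)
        assert list(tab["group"]) == ["SC", "AT+1d"]
        for col in ("n", "mean_od", "sd_od", "mean_area", "sd_area", "coefficient"):
            assert col in tab.columns
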