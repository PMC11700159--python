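import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from clampkit.group_stats import (
    GroupSample,
    StatsError,
    kruskal_dunn,
    line_f_test,
    mann_whitney,
    one_phase_f_test,
    rm_anova_gg,
    rout_outliers,
    tukey_posthoc,
)

from _oracles import gg_epsilon_formula, kruskal_h_by_hand, mann_whitney_exact_p


class TestRout:
    def test_homogeneous_gaussian_sample_is_untouched(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100.0, 10.0, size=40)
        kept, removed = rout_outliers(vals)
        assert removed.size == 0
        assert kept.size == 40

    def test_single_gross_outlier_is_removed(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(10.0, 1.0, size=20), [60.0]])
        kept, removed = rout_outliers(vals)
        assert removed.tolist() == [60.0]
        assert kept.size == 20

    def test_all_identical_values_are_kept(self):
        kept, removed = rout_outliers(np.full(10, 7.0))
        assert removed.size == 0
        assert kept.size == 10

    def test_partition_is_order_invariant(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0.0, 1.0, size=25), [12.0, -9.0]])
        kept_a, rem_a = rout_outliers(vals)
        kept_b, rem_b = rout_outliers(vals[::-1])
        assert sorted(rem_a) == sorted(rem_b)
        assert sorted(kept_a) == sorted(kept_b)

    def test_removal_fraction_is_capped(self):
        # half the points far away: at most 30% may be removed
        vals = np.concatenate([np.zeros(10), np.full(10, 1e6)])
        kept, removed = rout_outliers(vals)
        assert removed.size <= 6

    def test_tiny_sample_is_returned_unchanged_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed = rout_outliers([1.0, 2.0, 300.0])
        assert removed.size == 0


class TestKruskalDunn:
    def test_h_statistic_matches_hand_ranking(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = kruskal_dunn([GroupSample(str(i), g) for i, g in enumerate(groups)])
        assert res["H"] == pytest.approx(kruskal_h_by_hand(groups))
        assert res["H"] == pytest.approx(7.2)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1.0, size=12) for loc in (0.0, 0.3, 1.0)]
        res = kruskal_dunn([GroupSample(str(i), g) for i, g in enumerate(groups)])
        h, p = sps.kruskal(*groups)
        assert res["H"] == pytest.approx(h)
        assert res["p"] == pytest.approx(p)

    def test_identical_groups_give_h_zero(self):
        g = [GroupSample(l, [5.0] * 6) for l in "abc"]
        res = kruskal_dunn(g)
        assert res["H"] == 0.0
        assert res["p"] == 1.0

    def test_pairwise_table_covers_all_pairs(self):
        rng = np.random.default_rng(4)
        g = [GroupSample(l, rng.normal(size=10)) for l in ("WT", "Tau", "Tau+AR")]
        res = kruskal_dunn(g)
        pw = res["pairwise"]
        assert len(pw) == 3
        assert set(zip(pw["group_a"], pw["group_b"])) == {
            ("WT", "Tau"), ("WT", "Tau+AR"), ("Tau", "Tau+AR")
        }
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-12).all()


class TestMannWhitney:
    def test_exact_p_matches_full_enumeration(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [5.0, 6.0, 7.0, 8.0]
        u, p = mann_whitney(a, b)
        assert u in (0.0, 16.0)  # complete separation
        assert p == pytest.approx(mann_whitney_exact_p(a, b))
        assert p == pytest.approx(2.0 / 70.0)

    def test_exact_p_on_interleaved_sample(self):
        a = [1.0, 4.0, 5.0, 9.0]
        b = [2.0, 3.0, 7.0, 8.0]
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mann_whitney_exact_p(a, b))

    def test_large_samples_match_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, size=30)
        b = rng.normal(0.6, 1.0, size=25)
        u, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


def _long_frame(y, groups):
    n, k = y.shape
    rows = []
    for s in range(n):
        for j in range(k):
            rows.append({"subject": f"s{s}", "group": str(groups[s]),
                         "level": f"l{j}", "value": y[s, j]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_epsilon_is_one_for_two_levels(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(12, 2))
        res = rm_anova_gg(_long_frame(y, [0] * 6 + [1] * 6))
        assert res.epsilon == 1.0

    def test_epsilon_matches_classical_formula(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(16, 4)) + rng.normal(size=(16, 1))
        groups = [0] * 8 + [1] * 8
        res = rm_anova_gg(_long_frame(y, groups))
        assert res.epsilon == pytest.approx(
            gg_epsilon_formula(y, groups), rel=1e-9
        )

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        y = rng.normal(size=(20, 3))
        y[10:] += np.array([0.0, 0.5, 1.0])
        df = _long_frame(y, [0] * 10 + [1] * 10)
        res = rm_anova_gg(df)
        ref = pg.mixed_anova(data=df, dv="value", within="level",
                            subject="subject", between="group")
        for effect, ref_row in (("group", 0), ("within", 1), ("interaction", 2)):
            mine = res.table.set_index("effect").loc[effect]
            assert mine["F"] == pytest.approx(float(ref["F"][ref_row]), rel=1e-6)
            assert mine["p"] == pytest.approx(float(ref["p_unc"][ref_row]), rel=1e-6)
        # pingouin's eps ignores the between-group structure (it centers the
        # whole sample at once), so compare our pooled-within-group epsilon
        # to pingouin's only loosely; the exact oracle is
        # test_epsilon_matches_classical_formula
        assert res.epsilon == pytest.approx(float(ref["eps"][1]), abs=0.02)

    def test_strong_interaction_is_detected(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0.0, 0.5, size=(24, 4))
        y[12:] += np.arange(4) * 2.0  # group 1 gains strongly with level
        res = rm_anova_gg(_long_frame(y, [0] * 12 + [1] * 12))
        p_int = float(res.table.set_index("effect").loc["interaction", "p_gg"])
        assert p_int < 1e-6

    def test_incomplete_subject_is_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(10, 3))
        df = _long_frame(y, [0] * 5 + [1] * 5)
        df = df[~((df["subject"] == "s0") & (df["level"] == "l2"))]
        with pytest.warns(UserWarning):
            res = rm_anova_gg(df)
        assert res.n_subjects == 9

    def test_tukey_flags_the_separated_group(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0.0, 0.5, size=(30, 3))
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        y[20:] += 5.0  # group c far from a and b
        table = tukey_posthoc(_long_frame(y, groups))
        sig = table[table["reject"]]
        pairs = set(map(tuple, sig[["group_a", "group_b"]].to_numpy()))
        assert pairs == {("a", "c"), ("b", "c")}


class TestCurveComparisons:
    def test_noiseless_one_phase_parameters_are_recovered(self):
        x = np.linspace(0.0, 10.0, 24)
        res = one_phase_f_test(
            np.concatenate([x, x]),
            np.concatenate([
                3.0 * (1.0 - np.exp(-0.8 * x)),
                3.0 * (1.0 - np.exp(-0.8 * x)),
            ]),
            ["a"] * 24 + ["b"] * 24,
        )
        for g in ("a", "b"):
            assert res["groups"][g]["plateau"] == pytest.approx(3.0, rel=1e-6)
            assert res["groups"][g]["k"] == pytest.approx(0.8, rel=1e-6)
        # identical curves: residuals are pure optimizer round-off, so the
        # extra-sum-of-squares F-test must not flag a difference
        assert res["p"] > 0.05

    def test_different_plateaus_are_detected(self):
        rng = np.random.default_rng(12)
        x = np.tile(np.linspace(0.0, 10.0, 20), 2)
        y = np.concatenate([
            2.0 * (1.0 - np.exp(-0.7 * x[:20])),
            4.0 * (1.0 - np.exp(-0.7 * x[:20])),
        ]) + rng.normal(0.0, 0.05, size=40)
        res = one_phase_f_test(x, y, ["a"] * 20 + ["b"] * 20)
        assert res["p"] < 1e-9

    def test_line_f_test_recovers_slopes_and_detects_difference(self):
        rng = np.random.default_rng(13)
        x = np.tile(np.arange(1.0, 11.0), 2)
        y = np.concatenate([0.5 * x[:10], 1.5 * x[:10]])
        y += rng.normal(0.0, 0.05, size=20)
        res = line_f_test(x, y, ["a"] * 10 + ["b"] * 10)
        assert res["groups"]["a"]["slope"] == pytest.approx(0.5, abs=0.02)
        assert res["groups"]["b"]["slope"] == pytest.approx(1.5, abs=0.02)
        assert res["p"] < 1e-9

    def test_identical_lines_are_not_flagged(self):
        rng = np.random.default_rng(14)
        x = np.tile(np.arange(1.0, 11.0), 2)
        y = 0.8 * x + rng.normal(0.0, 0.1, size=20)
        res = line_f_test(x, y, ["a"] * 10 + ["b"] * 10)
        assert res["p"] > 0.05

    def test_single_group_is_an_error(self):
        with pytest.raises(StatsError):
            line_f_test([1.0, 2.0], [1.0, 2.0], ["a", "a"])
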