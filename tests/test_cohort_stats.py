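"""Rank-based comparative statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_mannwhitney_u, chi_square_oracle, hand_holm
from dietnet.cohort_stats import (
    build_cohort_summary,
    bmi_spearman_screen,
    chi_square,
    dunn_posthoc,
    holm_adjust,
    kruskal_wallis,
    mann_whitney,
    median_iqr,
)


class TestMedianIQR:
    def test_odd_symmetric(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_constant(self):
        assert median_iqr([7.0] * 9) == (7.0, 7.0, 7.0)

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        med, q1, q3 = median_iqr(x)
        s = np.sort(x)

        def interp(q):  # linear interpolation between order statistics
            h = q * (len(s) - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert (med, q1, q3) == pytest.approx((interp(0.5), interp(0.25), interp(0.75)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestMannWhitney:
    def test_identical_samples_give_half_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 8, 6).astype(float)
        y = rng.integers(0, 8, 6).astype(float)
        u, _ = mann_whitney(x, y)
        assert u == pytest.approx(brute_force_mannwhitney_u(x, y))

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(1.0, 1.0, size=12)
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(np.exp(x), np.exp(y))
        assert u1 == pytest.approx(u2) and p1 == pytest.approx(p2)


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        h, p = kruskal_wallis({"a": np.ones(5), "b": np.ones(5)})
        assert h == pytest.approx(0.0)

    def test_two_group_case_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(9)
        x = rng.permutation(np.arange(20.0))[:10]  # no ties across pooled data
        y = np.setdiff1d(np.arange(20.0), x)
        _, p_kw = kruskal_wallis({"x": x, "y": y})
        _, p_mw = mann_whitney(x, y)
        assert p_kw == pytest.approx(p_mw, abs=1e-6)

    def test_matches_rank_sum_formula(self):
        groups = {"a": np.array([1.0, 3.0, 5.0]), "b": np.array([2.0, 4.0, 6.0]),
                  "c": np.array([7.0, 8.0, 9.0])}
        h, _ = kruskal_wallis(groups)
        pooled = np.concatenate(list(groups.values()))
        from scipy.stats import rankdata
        ranks = rankdata(pooled)
        n = len(pooled)
        off, h_manual = 0, 0.0
        for g in groups.values():
            r = ranks[off:off + len(g)]
            h_manual += r.sum() ** 2 / len(g)
            off += len(g)
        h_manual = 12.0 / (n * (n + 1)) * h_manual - 3 * (n + 1)
        assert h == pytest.approx(h_manual)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        groups = {k: rng.normal(size=10) for k in "abc"}
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis({k: 3 * v + 2 for k, v in groups.items()})
        assert h1 == pytest.approx(h2)


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        g = {"a": np.arange(6.0), "b": np.arange(6.0), "c": np.arange(6.0)}
        out = dunn_posthoc(g)
        assert np.allclose(out["z"], 0.0)
        assert np.allclose(out["p_adj"], 1.0)

    def test_separated_pair_has_largest_z(self):
        g = {"lo": np.arange(10.0), "mid": np.arange(5.0, 15.0),
             "hi": np.arange(50.0, 60.0)}
        out = dunn_posthoc(g)
        row = out.loc[out["z"].abs().idxmax()]
        assert {row.group_a, row.group_b} == {"lo", "hi"}

    def test_matches_hand_computed_statistic(self):
        """No-tie fixture: mean ranks 2/5/8, S=N(N+1)/12, se=sqrt(5)."""
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0]),
             "c": np.array([7.0, 8.0, 9.0])}
        out = dunn_posthoc(g, adjust="none").set_index(["group_a", "group_b"])
        se = np.sqrt((9 * 10 / 12) * (2 / 3))
        assert out.loc[("a", "b"), "z"] == pytest.approx((2 - 5) / se)
        assert out.loc[("a", "c"), "z"] == pytest.approx((2 - 8) / se)


class TestChiSquare:
    def test_independent_table(self):
        table = np.outer([10, 20], [5, 5])  # O == E exactly
        stat, df, p = chi_square(table)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_anthropometric_status_by_sex_counts(self):
        """Published 4x2 status-by-sex counts: df 3, p ~ 0.0055."""
        obs = np.array([[67, 471, 59, 45], [53, 684, 73, 44]])
        stat, df, p = chi_square(obs)
        o_stat, o_df = chi_square_oracle(obs)
        assert df == o_df == 3
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert p == pytest.approx(0.00553, abs=5e-4)

    def test_2x2_hand_computation(self):
        obs = np.array([[10, 20], [20, 10]])
        stat, df, p = chi_square(obs)
        assert df == 1
        assert stat == pytest.approx(chi_square_oracle(obs)[0], abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(1, 60, size=(rng.integers(2, 5), rng.integers(2, 5)))
        stat, _, _ = chi_square(obs)
        assert stat == pytest.approx(chi_square_oracle(obs)[0], abs=1e-10)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04]) == pytest.approx([0.04])

    def test_printed_fixture(self):
        assert holm_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_hand_step_down_and_dominates_raw(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert adj == pytest.approx(hand_holm(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestBMIScreen:
    def test_bmi_duplicated_as_food_group_gives_rho_one(self, small_cohort):
        roster = small_cohort.roster.copy()
        roster.index = roster["id"].astype(str)
        cons = small_cohort.consumption.copy()
        cons["Coffee"] = roster["bmi"].to_numpy()
        out = bmi_spearman_screen(cons, roster).set_index("food_group")
        assert out.loc["Coffee", "rho_all"] == pytest.approx(1.0)
        for s in ("underweight", "eutrophy", "overweight", "obesity"):
            assert out.loc["Coffee", f"rho_{s}"] == pytest.approx(1.0)

    def test_tiny_stratum_marked_not_computable(self, small_cohort):
        roster = small_cohort.roster.copy()
        roster.index = roster["id"].astype(str)
        roster.loc[roster.index[:2], "anthro_class"] = "tiny"
        roster.loc[roster.index[2:], "anthro_class"] = "rest"
        out = bmi_spearman_screen(small_cohort.consumption, roster)
        assert out["rho_tiny"].isna().all()
        assert out["rho_rest"].notna().all()


class TestCohortSummary:
    def test_default_cohort_reproduces_published_percentages(self, default_cohort):
        """Stratum sizes 120/1155/132/89 give 77.2% eutrophy; sex split 42.9/57.1."""
        roster = default_cohort.roster
        rows = {r.variable: r for r in build_cohort_summary(roster, None)}
        anthro = rows["anthro_class"].per_group["total"]
        assert round(anthro["eutrophy"]["pct"], 1) == 77.2
        assert round(anthro["overweight"]["pct"], 1) == 8.8
        assert round(anthro["obesity"]["pct"], 1) == 5.9
        sex = rows["sex"].per_group["total"]
        assert round(sex["male"]["pct"], 1) == 42.9
        assert round(sex["female"]["pct"], 1) == 57.1

    def test_food_group_family_is_holm_adjusted(self, small_cohort):
        roster = small_cohort.roster
        rows = build_cohort_summary(roster, small_cohort.consumption)
        food = [r for r in rows if r.variable in small_cohort.consumption.columns]
        assert len(food) == 14
        tested = [r for r in food if r.p_raw is not None]
        for r in tested:
            assert r.p_adj is not None and r.p_adj >= r.p_raw - 1e-12

    def test_single_participant_cohort_counts_only(self):
        roster = pd.DataFrame(
            [{"id": "p1", "sex": "male", "age": 14.0, "ses": "good",
              "pubertal_stage": "pubertal", "bmi": 19.0, "anthro_class": "eutrophy"}]
        )
        rows = build_cohort_summary(roster, None)
        assert all(r.p_raw is None for r in rows)

    def test_unknown_stratifier_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown stratifier"):
            build_cohort_summary(small_cohort.roster, None, stratify_by="zodiac")


def test_mann_whitney_type_one_error_rate():
    """Null rejection rate at alpha=0.05 stays near nominal (1000 reps)."""
    rng = np.random.default_rng(2024)
    rejections = 0
    for _ in range(1000):
        x, y = rng.normal(size=25), rng.normal(size=25)
        _, p = mann_whitney(x, y)
        rejections += p < 0.05
    assert 0.035 <= rejections / 1000 <= 0.065
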