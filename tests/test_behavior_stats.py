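import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from swimtrack.behavior_stats import (
    GenotypeCounts,
    bmi,
    fulton_k,
    genotype_percent,
    mendelian_chi2,
    select_active_frames,
    sidak_adjust,
    summarize_fish,
    two_way_anova,
)
from swimtrack.tracking import SpeedSeries

from test_tracking import make_track


class TestSelectActiveFrames:
    def test_forced_block(self):
        speeds = np.zeros(200)
        speeds[50:150] = 10.0
        sel = select_active_frames(speeds, n=100)
        np.testing.assert_array_equal(sel.indices, np.arange(50, 150))
        assert not sel.short_series

    def test_short_series_flag(self):
        sel = select_active_frames(np.ones(80), n=100)
        assert len(sel.indices) == 80
        assert sel.short_series

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(4)
        speeds = rng.uniform(0, 20, 500)
        sel = select_active_frames(speeds, n=100)
        oracle = sorted(range(500), key=lambda i: (-speeds[i], i))[:100]
        assert set(sel.indices) == set(oracle)

    def test_ties_break_to_earlier_frames(self):
        speeds = np.array([5.0, 5.0, 5.0, 5.0])
        sel = select_active_frames(speeds, n=2)
        np.testing.assert_array_equal(sel.indices, [0, 1])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_active_frames([], n=10)


class TestSummarizeFish:
    def test_constant_speed_constant_curvature(self):
        track = make_track(0, [(5.0 * i, 0.0) for i in range(60)])
        speeds = SpeedSeries(track_id=0, speeds=np.full(59, 5.0), fps=24.96)
        summary = summarize_fish(track, speeds, np.full(60, 0.1), n_active=100)
        assert summary.mean_velocity == pytest.approx(5.0)
        assert summary.range_of_movement == 0.0
        assert summary.short_series  # only 59 activity frames available

    def test_exactly_100_active_frames(self):
        track = make_track(0, [(2.0 * i, 0.0) for i in range(101)])
        speeds = SpeedSeries(track_id=0, speeds=np.full(100, 2.0), fps=24.96)
        curv = np.linspace(-0.05, 0.05, 101)
        summary = summarize_fish(track, speeds, curv, n_active=100)
        assert summary.n_frames_used == 100
        assert not summary.short_series
        assert summary.range_of_movement == pytest.approx(
            curv[100] - curv[1]
        )

    def test_no_finite_curvature_error(self):
        track = make_track(0, [(float(i), 0.0) for i in range(10)])
        speeds = SpeedSeries(track_id=0, speeds=np.ones(9), fps=24.96)
        with pytest.raises(ValueError, match="curvature"):
            summarize_fish(track, speeds, np.full(10, np.nan))


def anova_oracle(data):
    """Cell-means decomposition for a balanced two-way layout."""
    levels_a = sorted({a for a, _, _ in data})
    levels_b = sorted({b for _, b, _ in data})
    cells = {
        (a, b): [v for aa, bb, v in data if (aa, bb) == (a, b)]
        for a in levels_a
        for b in levels_b
    }
    r = len(next(iter(cells.values())))
    grand = np.mean([v for _, _, v in data])
    mean_a = {a: np.mean([v for aa, _, v in data if aa == a]) for a in levels_a}
    mean_b = {b: np.mean([v for _, bb, v in data if bb == b]) for b in levels_b}
    cell_mean = {k: np.mean(v) for k, v in cells.items()}
    ss_a = r * len(levels_b) * sum((mean_a[a] - grand) ** 2 for a in levels_a)
    ss_b = r * len(levels_a) * sum((mean_b[b] - grand) ** 2 for b in levels_b)
    ss_ab = r * sum(
        (cell_mean[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in levels_a
        for b in levels_b
    )
    ss_res = sum(
        (v - cell_mean[(a, b)]) ** 2 for (a, b), vals in cells.items() for v in vals
    )
    return ss_a, ss_b, ss_ab, ss_res


class TestTwoWayAnova:
    def test_no_effect_balanced_2x2(self):
        data = []
        for a in "xy":
            for b in "uv":
                data += [(a, b, 1.0), (a, b, 3.0)]  # all cell means equal
        res = two_way_anova(data)
        for effect in ("factor_a", "factor_b", "interaction"):
            assert res.table.loc[effect, "F"] == pytest.approx(0.0, abs=1e-12)
            assert res.table.loc[effect, "p"] > 0.99

    def test_matches_cell_means_oracle_2x3(self):
        rng = np.random.default_rng(7)
        data = [
            (a, b, float(v))
            for a in "pq"
            for b in "xyz"
            for v in rng.integers(0, 20, 4)
        ]
        res = two_way_anova(data)
        ss_a, ss_b, ss_ab, ss_res = anova_oracle(data)
        assert res.table.loc["factor_a", "sum_sq"] == pytest.approx(ss_a, abs=1e-10)
        assert res.table.loc["factor_b", "sum_sq"] == pytest.approx(ss_b, abs=1e-10)
        assert res.table.loc["interaction", "sum_sq"] == pytest.approx(ss_ab, abs=1e-10)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-10)
        assert res.table.loc["factor_a", "df"] == 1
        assert res.table.loc["factor_b", "df"] == 2
        assert res.table.loc["interaction", "df"] == 2
        assert res.table.loc["residual", "df"] == 24 - 6
        f_exp = (ss_a / 1) / (ss_res / 18)
        assert res.table.loc["factor_a", "F"] == pytest.approx(f_exp, rel=1e-10)
        # total df and SS decomposition (balanced design)
        assert res.table["df"].sum() == len(data) - 1
        total_ss = sum((v - np.mean([x[2] for x in data])) ** 2 for _, _, v in data)
        assert res.table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-10)

    def test_single_observation_per_cell_drops_interaction(self):
        data = [("a", "u", 1.0), ("a", "v", 2.0), ("b", "u", 3.0), ("b", "v", 5.0)]
        res = two_way_anova(data)
        assert "interaction" not in res.table.index
        assert res.note is not None

    def test_unbalanced_rejected(self):
        data = [("a", "u", 1.0), ("a", "v", 2.0), ("b", "u", 3.0)]
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(data)

    def test_single_level_rejected(self):
        data = [("a", "u", 1.0), ("a", "v", 2.0)]
        with pytest.raises(ValueError, match="levels"):
            two_way_anova(data)

    def test_additive_effect_detected_at_n6(self):
        # injected effect of 2 residual SDs, n = 6 per cell -> p < 0.01
        rng = np.random.default_rng(42)
        data = []
        for a, shift in (("het", 0.0), ("hom", 2.0)):
            for b in ("s1", "s2"):
                for _ in range(6):
                    data.append((a, b, shift + rng.normal(0.0, 1.0)))
        res = two_way_anova(data)
        assert res.table.loc["factor_a", "p"] < 0.01


class TestSidak:
    def test_identity_at_m1(self):
        assert sidak_adjust([0.05], 1)[0] == pytest.approx(0.05)

    def test_forced_arithmetic(self):
        assert sidak_adjust([0.01], 3)[0] == pytest.approx(1 - 0.99**3)
        assert sidak_adjust([0.01], 3)[0] == pytest.approx(0.029701)

    def test_p_one_stays_one(self):
        assert sidak_adjust([1.0], 7)[0] == 1.0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            sidak_adjust([1.5], 2)

    @given(
        st.floats(0, 1),
        st.floats(0, 1),
        st.integers(1, 50),
        st.integers(1, 50),
    )
    def test_monotone_in_p_and_m(self, p1, p2, m1, m2):
        lo_p, hi_p = min(p1, p2), max(p1, p2)
        lo_m, hi_m = min(m1, m2), max(m1, m2)
        assert sidak_adjust([lo_p], lo_m)[0] <= sidak_adjust([hi_p], lo_m)[0] + 1e-12
        assert sidak_adjust([lo_p], lo_m)[0] <= sidak_adjust([lo_p], hi_m)[0] + 1e-12


class TestMorphometricFormulas:
    def test_bmi_forced(self):
        assert bmi(0.5, 3.0) == pytest.approx(0.05556, abs=1e-5)
        assert bmi(1.0, 1.0) == 1.0

    def test_fulton_forced(self):
        assert fulton_k(0.5, 3.0) == pytest.approx(1.85185, abs=1e-5)
        assert fulton_k(1.0, 10.0) == pytest.approx(0.1)

    def test_nonpositive_rejected(self):
        for fn in (bmi, fulton_k):
            with pytest.raises(ValueError):
                fn(0.0, 1.0)
            with pytest.raises(ValueError):
                fn(1.0, -1.0)

    @given(st.floats(0.01, 100), st.floats(0.1, 100))
    def test_bmi_inverse_square_scaling(self, w, l):
        assert bmi(w, 2 * l) == pytest.approx(bmi(w, l) / 4, rel=1e-9)

    @given(st.floats(0.01, 100), st.floats(0.1, 100))
    def test_fulton_isometric_invariance(self, w, l):
        assert fulton_k(8 * w, 2 * l) == pytest.approx(fulton_k(w, l), rel=1e-9)


def chi2_p_oracle_df1(stat):
    """Closed-form upper tail for 1 df: erfc(sqrt(x/2))."""
    return math.erfc(math.sqrt(stat / 2.0))


class TestMendelianChi2:
    def test_double_mutant_survival(self):
        res = mendelian_chi2(GenotypeCounts(observed=(7, 131), expected_ratio=(1, 15)))
        assert res.statistic == pytest.approx(0.32657, abs=1e-4)
        assert res.df == 1
        np.testing.assert_allclose(res.expected, [138 / 16, 138 * 15 / 16])
        assert res.p_value == pytest.approx(chi2_p_oracle_df1(res.statistic), abs=1e-12)
        # printed as 0.567 in the source; exact value is 0.56769
        assert res.p_value == pytest.approx(0.5677, abs=5e-4)

    def test_combined_lethality(self):
        res = mendelian_chi2(GenotypeCounts(observed=(0, 104), expected_ratio=(1, 15)))
        assert res.statistic == pytest.approx(6.9333, abs=1e-3)
        assert round(res.p_value, 3) == 0.008
        assert res.p_value == pytest.approx(chi2_p_oracle_df1(res.statistic), abs=1e-12)

    def test_exact_proportions_give_zero(self):
        res = mendelian_chi2(GenotypeCounts(observed=(10, 150), expected_ratio=(1, 15)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_p_monotone_in_deviation(self):
        ps = []
        for k in (10, 13, 16, 19, 22):
            res = mendelian_chi2(
                GenotypeCounts(observed=(k, 160 - k), expected_ratio=(1, 15))
            )
            ps.append(res.p_value)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            GenotypeCounts(observed=(-1, 5), expected_ratio=(1, 15))
        with pytest.raises(ValueError):
            GenotypeCounts(observed=(1,), expected_ratio=(1,))
        with pytest.raises(ValueError):
            GenotypeCounts(observed=(1, 2), expected_ratio=(0, 1))


class TestGenotypePercent:
    def test_printed_values(self):
        assert genotype_percent(28, 107) == 26
        assert genotype_percent(9, 39) == 23
        assert genotype_percent(22, 533, decimals=1) == 4.1

    def test_zero(self):
        assert genotype_percent(0, 41) == 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            genotype_percent(1, 0)
        with pytest.raises(ValueError):
            genotype_percent(5, 4)
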