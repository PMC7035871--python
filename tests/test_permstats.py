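"""Locality-blocked permutation regression framework."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_analysis_frame
from grazescape.permstats import (
    compare_seasons,
    format_report,
    ols_fit,
    permutation_regression,
    table3_report,
)


class TestOLSFit:
    def test_noiseless_line_recovered_exactly(self):
        g = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        fit = ols_fit(g, 2.0 + 0.1 * g)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.slope == pytest.approx(0.1)
        assert fit.p_value == pytest.approx(0.0)

    def test_constant_response_has_zero_slope_and_r2(self):
        fit = ols_fit([0.0, 1.0, 2.0, 3.0], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.r2 == 0.0
        assert fit.p_value == 1.0

    def test_five_point_dataset_matches_normal_equations_oracle(self):
        g = np.array([10.0, 40.0, 25.0, 70.0, 55.0])
        y = np.array([12.0, 30.0, 14.0, 48.0, 41.0])
        # independent oracle: scipy's closed-form regression
        oracle = stats.linregress(g, y)
        fit = ols_fit(g, y)
        assert fit.slope == pytest.approx(oracle.slope, rel=1e-12)
        assert fit.intercept == pytest.approx(oracle.intercept, rel=1e-12)
        assert fit.r2 == pytest.approx(oracle.rvalue**2, rel=1e-12)
        assert fit.p_value == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            ols_fit([1.0, 2.0], [1.0, 2.0])

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


def _singleton_frame():
    """Five units, one specimen each, exact line y = 2 + 0.1 g."""
    rows = [
        ("L1", "2003-01", "wet", 0.0, 2.0),
        ("L2", "2003-01", "wet", 100.0, 12.0),
        ("L3", "2003-01", "wet", 200.0, 22.0),
        ("L4", "2003-01", "wet", 300.0, 32.0),
        ("L5", "2003-01", "wet", 400.0, 42.0),
    ]
    return make_analysis_frame(rows)


def _replicated_frame(seed=0, n_loc=30, reps=4, slope=0.1, noise=5.0):
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_loc):
        g = rng.uniform(100.0, 400.0)
        for _ in range(int(rng.integers(1, reps + 1))):
            rows.append(
                (f"L{k}", "2003-06", "dry", g, 10.0 + slope * g + rng.normal(0, noise))
            )
    return make_analysis_frame(rows)


class TestPermutationRegression:
    def test_degenerate_resampling_equals_single_ols_fit(self):
        df = _singleton_frame()
        summary = permutation_regression(df, iterations=50, rng=0)
        fit = ols_fit(df["grassiness"], df["pct_c4"])
        assert summary.means["slope"] == pytest.approx(fit.slope, rel=1e-13)
        assert summary.means["intercept"] == pytest.approx(fit.intercept, rel=1e-13)
        assert summary.means["r2"] == pytest.approx(fit.r2, rel=1e-13)
        np.testing.assert_array_equal(summary.draws["slope"], fit.slope)
        for lo, hi in summary.cl.values():
            assert hi - lo == 0.0

    def test_p_hat_is_zero_when_every_iteration_significant(self):
        df = _replicated_frame(noise=0.5)
        summary = permutation_regression(df, iterations=200, rng=1)
        assert (summary.draws["p"] < 0.05).all()
        assert summary.p_hat == 0.0

    def test_p_hat_matches_printed_formula(self):
        df = _replicated_frame(seed=3, slope=0.01, noise=20.0)
        summary = permutation_regression(df, iterations=400, rng=2)
        expected = 1.0 - np.count_nonzero(summary.draws["p"] < 0.05) / 400
        assert summary.p_hat == pytest.approx(expected)

    def test_determinism_under_fixed_seed(self):
        df = _replicated_frame()
        a = permutation_regression(df, iterations=100, rng=42)
        b = permutation_regression(df, iterations=100, rng=42)
        for k in ("r2", "intercept", "slope"):
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_seed_sensitivity_within_monte_carlo_error(self):
        df = _replicated_frame(seed=9, noise=8.0)
        a = permutation_regression(df, iterations=800, rng=1)
        b = permutation_regression(df, iterations=800, rng=2)
        for k in ("r2", "intercept", "slope"):
            se = np.hypot(a.se(k), b.se(k))
            assert abs(a.means[k] - b.means[k]) < 3.0 * se

    def test_n_counts_distinct_locality_interval_units(self):
        rows = [
            ("L1", "2003-01", "wet", 10.0, 1.0),
            ("L1", "2003-01", "wet", 10.0, 2.0),  # same unit, second specimen
            ("L1", "2003-02", "wet", 10.5, 3.0),
            ("L2", "2003-01", "wet", 20.0, 4.0),
        ]
        summary = permutation_regression(make_analysis_frame(rows), iterations=10, rng=0)
        assert summary.n_units == 3

    def test_blocked_resampling_resists_overcollected_outlier_locality(self):
        # an extreme locality sampled 30x should not dominate the fit
        rng = np.random.default_rng(7)
        rows = []
        for k in range(20):
            g = 100.0 + 15.0 * k
            rows.append((f"L{k}", "m", "dry", g, 0.1 * g + rng.normal(0, 2.0)))
        for _ in range(30):  # repeated collections at one aberrant locality
            rows.append(("L_out", "m", "dry", 400.0, 0.0 + rng.normal(0, 2.0)))
        df = make_analysis_frame(rows)
        naive = ols_fit(df["grassiness"], df["pct_c4"])
        summary = permutation_regression(df, iterations=500, rng=1)
        assert abs(summary.means["slope"] - 0.1) < abs(naive.slope - 0.1)

    def test_subset_too_small_rejected(self):
        rows = [("L1", "m", "dry", 1.0, 1.0), ("L2", "m", "dry", 2.0, 2.0)]
        with pytest.raises(ValueError, match="at least 3"):
            permutation_regression(make_analysis_frame(rows), iterations=10, rng=0)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            permutation_regression(_singleton_frame(), iterations=0, rng=0)

    def test_inconsistent_season_within_unit_rejected(self):
        rows = [
            ("L1", "m", "dry", 1.0, 1.0),
            ("L1", "m", "wet", 1.0, 2.0),
            ("L2", "m", "dry", 2.0, 2.0),
            ("L3", "m", "dry", 3.0, 3.0),
        ]
        with pytest.raises(ValueError, match="season is inconsistent"):
            permutation_regression(make_analysis_frame(rows), iterations=10, rng=0)

    def test_season_filter_selects_subset(self):
        rows = [
            ("L1", "a", "dry", 0.0, 1.0),
            ("L2", "a", "dry", 100.0, 11.0),
            ("L3", "a", "dry", 200.0, 21.0),
            ("L4", "a", "wet", 0.0, 5.0),
            ("L5", "a", "wet", 100.0, 6.0),
            ("L6", "a", "wet", 200.0, 7.0),
        ]
        df = make_analysis_frame(rows)
        dry = permutation_regression(df, season="dry", iterations=5, rng=0)
        assert dry.n_units == 3 and dry.season == "dry"
        assert dry.means["slope"] == pytest.approx(0.1)

    def test_shuffle_scheme_keeps_all_specimens(self):
        df = _replicated_frame(seed=2)
        summary = permutation_regression(df, iterations=50, rng=0, scheme="shuffle")
        assert summary.scheme == "shuffle"
        assert np.isfinite(list(summary.means.values())).all()

    def test_percentile_confidence_limits_bracket_the_mean(self):
        df = _replicated_frame(seed=4)
        s = permutation_regression(df, iterations=300, rng=5, cl_mode="percentile")
        for k in ("r2", "intercept", "slope"):
            lo, hi = s.cl[k]
            assert lo <= s.means[k] <= hi


class TestCompareSeasons:
    def test_complete_separation_reports_floor_p(self):
        dry = np.full(100, 0.2)
        wet = np.full(100, 0.1)
        c = compare_seasons(dry, wet, "slope")
        assert c.at_floor
        assert 0.0 < c.p_one_tailed < 1.0 / 100

    def test_identical_draws_give_exact_null_p_half(self):
        draws = np.linspace(0.0, 1.0, 50)
        c = compare_seasons(draws, draws.copy(), "r2")
        assert c.p_one_tailed == pytest.approx(0.5)

    def test_mismatched_iteration_counts_rejected(self):
        with pytest.raises(ValueError, match="iteration counts"):
            compare_seasons(np.zeros(10), np.zeros(11), "slope")

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="parameter"):
            compare_seasons(np.zeros(5), np.zeros(5), "intercept")

    def test_strong_seasonal_difference_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for k in range(40):
            g = rng.uniform(100, 400)
            rows.append((f"L{k}", "jun", "dry", g, 0.12 * g + rng.normal(0, 5)))
            rows.append((f"L{k}", "jan", "wet", g, 40.0 + 0.01 * g + rng.normal(0, 5)))
        df = make_analysis_frame(rows)
        dry = permutation_regression(df, season="dry", iterations=300, rng=1)
        wet = permutation_regression(df, season="wet", iterations=300, rng=2)
        assert compare_seasons(dry, wet, "slope").p_one_tailed < 0.05
        assert compare_seasons(dry, wet, "r2").p_one_tailed < 0.05


def _multi_radius_frame(seed=0, n_loc=25):
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_loc):
        for interval, season in (("2003-06", "dry"), ("2003-12", "wet")):
            g = rng.uniform(100, 400, size=4)
            for _ in range(int(rng.integers(1, 4))):
                y = 5.0 + 0.1 * g[1] + rng.normal(0, 8)
                rows.append({
                    "locality_id": f"L{k}", "interval": interval, "season": season,
                    "pct_c4": float(np.clip(y, 0, 100)),
                    "grassiness_2000": g[0], "grassiness_4000": g[1],
                    "grassiness_8000": g[2], "grassiness_12000": g[3],
                })
    return pd.DataFrame(rows)


class TestTable3Report:
    def test_emits_12_summary_rows_and_8_comparisons(self):
        summaries, comparisons = table3_report(
            _multi_radius_frame(), iterations=50, seed=0
        )
        assert len(summaries) == 12  # 4 radii x both/dry/wet
        assert len(comparisons) == 8  # 4 radii x {r2, slope}
        assert set(summaries["season"]) == {"both", "dry", "wet"}

    def test_subset_n_equals_unit_counts(self):
        df = _multi_radius_frame(seed=1)
        summaries, _ = table3_report(df, iterations=20, seed=0)
        units = df.groupby(["locality_id", "interval"]).ngroups
        dry_units = df[df.season == "dry"].groupby(["locality_id", "interval"]).ngroups
        row = summaries.set_index(["radius_km", "season"])
        assert row.loc[(4.0, "both"), "n"] == units
        assert row.loc[(4.0, "dry"), "n"] == dry_units

    def test_bit_reproducible_under_one_seed(self):
        df = _multi_radius_frame(seed=2)
        a = table3_report(df, iterations=30, seed=9)
        b = table3_report(df, iterations=30, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_missing_radius_column_rejected(self):
        df = _multi_radius_frame().drop(columns=["grassiness_8000"])
        with pytest.raises(ValueError, match="grassiness_8000"):
            table3_report(df, iterations=10, seed=0)

    def test_formatted_report_shape(self):
        summaries, comparisons = table3_report(
            _multi_radius_frame(), radii=[4000.0], iterations=20, seed=0
        )
        formatted = format_report(summaries, comparisons)
        assert len(formatted) == 3
        assert "(" in formatted.loc[0, "r2"]
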