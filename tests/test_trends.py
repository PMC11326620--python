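import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from medaqua import (
    AnnualSeries,
    SyntheticConfig,
    carrying_capacity,
    correlation_matrix,
    fit_trend,
    forecast,
    generate_panel,
    growth_rate_series,
    mean_growth_rate,
    pearson,
    ratio_series,
    series_from_panel,
)


def series(years, values, label=""):
    return AnnualSeries(np.asarray(years), np.asarray(values), label=label)


class TestFitTrend:
    def test_exact_line_recovered(self):
        years = np.arange(2000, 2010)
        s = series(years, 2.0 * (years - 2000) + 1.0)
        m = fit_trend(s, kind="linear")
        np.testing.assert_allclose(m.coefficients, [2.0, 1.0], atol=1e-9)
        assert m.r2 == pytest.approx(1.0)

    def test_exact_quadratic_recovered(self):
        years = np.arange(2000, 2005)
        x = years - 2000.0
        s = series(years, x**2)
        m = fit_trend(s, kind="polynomial", degree=2)
        assert m.coefficients[0] == pytest.approx(1.0, abs=1e-9)
        assert m.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_noiseless_degree_d_fit_is_exact(self, degree):
        years = np.arange(1980, 2000)
        rng = np.random.default_rng(degree)
        coeffs = rng.uniform(-2, 2, degree + 1)
        s = series(years, np.polyval(coeffs, years - 1980.0))
        m = fit_trend(s, kind="polynomial", degree=degree)
        np.testing.assert_allclose(m.coefficients, coeffs, atol=1e-9)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exponential_fit_recovers_continuous_rate(self):
        years = np.arange(1990, 2010)
        s = series(years, 100.0 * np.exp(0.07 * (years - 1990)))
        m = fit_trend(s, kind="exponential")
        assert m.coefficients[0] == pytest.approx(0.07, abs=1e-10)

    def test_exponential_fit_rejects_nonpositive_values(self):
        s = series([2000, 2001, 2002], [1.0, 0.0, 2.0])
        with pytest.raises(ValueError):
            fit_trend(s, kind="exponential")

    def test_insufficient_points_rejected(self):
        s = series([2000, 2001, 2002], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_trend(s, kind="polynomial", degree=2)


class TestForecast:
    def test_interpolation_identity_at_observed_years(self):
        years = np.arange(2000, 2011)
        vals = 3.0 + 0.5 * (years - 2000) ** 2
        m = fit_trend(series(years, vals), kind="polynomial", degree=2)
        for y, v in zip(years, vals):
            assert forecast(m, int(y)) == pytest.approx(v, abs=1e-9)

    def test_linear_extrapolation_by_hand(self):
        years = np.arange(2000, 2006)
        m = fit_trend(series(years, 2.0 * (years - 2000) + 1.0), kind="linear")
        with pytest.warns(UserWarning, match="extrapolat"):
            assert forecast(m, 2010) == pytest.approx(21.0)

    def test_exponential_decade_growth_factor(self):
        years = np.arange(2000, 2011)
        s = series(years, 50.0 * 1.05 ** (years - 2000))
        m = fit_trend(s, kind="exponential")
        assert forecast(m, 2010) / forecast(m, 2000) == pytest.approx(
            1.05 ** 10, rel=1e-9)
        assert 1.05 ** 10 == pytest.approx(1.6289, abs=1e-4)


class TestGrowthRates:
    def test_constant_series_all_zero(self):
        g = growth_rate_series(series(range(2000, 2005), [7.0] * 5))
        assert np.allclose(g.values, 0.0)

    def test_single_step_five_percent(self):
        g = growth_rate_series(series([2000, 2001], [100.0, 105.0]))
        assert g.values.tolist() == [pytest.approx(5.0)]

    def test_zero_previous_year_skipped(self):
        g = growth_rate_series(series([2000, 2001, 2002], [0.0, 10.0, 20.0]))
        assert g.years.tolist() == [2002]

    def test_mean_growth_of_geometric_series_both_methods(self):
        years = np.arange(2000, 2015)
        s = series(years, 100.0 * 1.05 ** (years - 2000))
        assert mean_growth_rate(s, window=10, method="arithmetic") == pytest.approx(5.0)
        assert mean_growth_rate(s, window=10, method="cagr") == pytest.approx(5.0)
        assert mean_growth_rate(s, window=5, method="cagr") == pytest.approx(5.0)

    def test_arithmetic_mean_by_hand(self):
        s = series([2000, 2001, 2002], [100.0, 110.0, 99.0])
        assert mean_growth_rate(s, window=3) == pytest.approx(0.0)

    def test_cagr_square_root_case(self):
        # 21% over two elapsed years → 10%/yr compound
        s = series([2000, 2002], [100.0, 121.0])
        assert mean_growth_rate(s, window=3, method="cagr") == pytest.approx(10.0)

    def test_cagr_rejects_nonpositive_start(self):
        s = series([2000, 2001], [0.0, 5.0])
        with pytest.raises(ValueError):
            mean_growth_rate(s, window=2, method="cagr")


class TestCapacityAndRatios:
    def test_constant_series_mean_is_the_constant(self):
        s = series(range(1985, 2021), [4.15] * 36)
        assert carrying_capacity(s, (1985, 2020)) == pytest.approx(4.15)

    def test_two_point_mean(self):
        s = series([2000, 2001], [3.0, 5.0])
        assert carrying_capacity(s, (2000, 2001)) == pytest.approx(4.0)

    def test_windowed_mean_matches_hand_sum(self):
        years = np.arange(2000, 2010)
        vals = np.arange(10.0, 20.0)
        s = series(years, vals)
        assert carrying_capacity(s, (2003, 2006)) == pytest.approx(
            (13 + 14 + 15 + 16) / 4)

    def test_disjoint_window_rejected(self):
        with pytest.raises(ValueError):
            carrying_capacity(series([2000], [1.0]), (1990, 1995))

    def test_ratio_identity_and_hand_division(self):
        aqua = series([1950, 2019], [1.0, 2.0])
        fish = series([1950, 2019], [130.0, 4.0])
        r = ratio_series(fish, aqua)
        assert r.values.tolist() == [130.0, 2.0]
        same = ratio_series(aqua, aqua)
        assert np.allclose(same.values, 1.0)

    def test_disjoint_years_rejected(self):
        with pytest.raises(ValueError):
            ratio_series(series([2000], [1.0]), series([2001], [1.0]))


class TestCorrelations:
    def test_perfect_linear_relationships(self):
        x = series(range(2000, 2010), np.arange(10.0))
        up = series(range(2000, 2010), 3 * np.arange(10.0) + 2)
        down = series(range(2000, 2010), -np.arange(10.0))
        assert pearson(x, up) == pytest.approx(1.0)
        assert pearson(x, down) == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        x = series([2000, 2001, 2002, 2003], [1.0, 2.0, 3.0, 4.0])
        y = series([2000, 2001, 2002, 2003], [1.0, 3.0, 2.0, 4.0])
        assert pearson(x, y) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        x = series([2000, 2001, 2002], [1.0, 1.0, 1.0])
        y = series([2000, 2001, 2002], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson(x, y)

    def test_matrix_symmetric_unit_diagonal_duplicate_columns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=8)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=8)
        corr = correlation_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_matrix_matches_elementwise_pearson(self):
        df = pd.DataFrame(
            {"gdp": [1.0, 2, 3, 5], "cons": [2.0, 1, 4, 4], "coast": [9.0, 7, 3, 1]},
            index=["it", "fr", "eg", "gr"])
        corr = correlation_matrix(df)
        for a in df.columns:
            for b in df.columns:
                expected = np.corrcoef(df[a], df[b])[0, 1]
                assert corr.loc[a, b] == pytest.approx(expected)

    def test_exclusion_list_drops_outlier_row(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 100], "y": [1.0, 2, 3, -50]},
                          index=["a", "b", "c", "egypt"])
        full = correlation_matrix(df)
        trimmed = correlation_matrix(df, exclude=["egypt"])
        assert trimmed.loc["x", "y"] == pytest.approx(1.0)
        assert full.loc["x", "y"] < 0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.1, max_value=100), st.floats(-100, 100))
    def test_affine_invariance_of_matrix(self, scale, shift):
        df = pd.DataFrame({"x": [1.0, 2, 4, 8, 9], "y": [2.0, 1, 5, 3, 9]})
        base = correlation_matrix(df)
        df2 = df.assign(x=df["x"] * scale + shift)
        np.testing.assert_allclose(correlation_matrix(df2).values, base.values,
                                   atol=1e-9)


class TestPanelSeries:
    def test_total_and_species_selectors(self, tiny_panel):
        total = series_from_panel(tiny_panel, "total")
        assert total.values.sum() == pytest.approx(
            tiny_panel.df["quantity_t"].sum())
        carp = series_from_panel(tiny_panel, "species:carp")
        assert carp.values.tolist() == [150.0, 110.0]

    def test_unknown_selector_errors(self, tiny_panel):
        with pytest.raises(KeyError):
            series_from_panel(tiny_panel, "species:kraken")
        with pytest.raises(ValueError):
            series_from_panel(tiny_panel, "per-basin")

    def test_logistic_early_window_exponential_recovery(self):
        cfg = SyntheticConfig(n_species=1, n_countries=1, years=(1950, 2020),
                              noise_cv=0.0, midpoint_offset=55, seed=2)
        panel = generate_panel(cfg)
        s = series_from_panel(panel, "total")
        m = fit_trend(s, kind="exponential", window=(1950, 1959))
        assert m.coefficients[0] == pytest.approx(cfg.growth_rate, abs=1e-3)
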