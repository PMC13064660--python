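"""Weighted window aggregation, correlation scales, p_ex inversion, grids."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoring.analysis import (
    PexFits,
    UndefinedMeanError,
    clear_sky_weight,
    correlations_by_scale,
    fit_pex_functions,
    invert_apparent_pex,
    sd_ratio,
    season_of_center,
    sensitivity_grid,
    sw_variability_scenarios,
    window_weighted_mean,
    window_weights,
)
from isoring.chronology import TimeWindow, shift_window
from isoring.transport import run_forward


def _series(values, start="2015-06-01"):
    idx = pd.date_range(start, periods=len(values), freq="30min")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestWeightedMean:
    def test_three_point_toy(self):
        s = _series([10.0, 20.0, 30.0])
        w = TimeWindow(2015, 152, 152)
        an = _series([1.0, 2.0, 1.0])
        out = window_weighted_mean(s, w, "an_weighted", an=an)
        assert out == pytest.approx(20.0, abs=1e-12)

    def test_constant_series_any_scheme(self):
        idx = pd.date_range("2015-06-01", periods=96, freq="30min")
        s = pd.Series(7.5, index=idx)
        an = pd.Series(np.random.default_rng(0).uniform(0, 5, 96), index=idx)
        w = TimeWindow(2015, 152, 153)
        for scheme, kw in [("an_weighted", {"an": an}),
                           ("daytime_9_to_15", {}),
                           ("clear_sky_radiation", {"latitude_deg": 61.85})]:
            assert window_weighted_mean(s, w, scheme, **kw) == pytest.approx(7.5)

    def test_all_zero_weights_error(self):
        s = _series([1.0, 2.0, 3.0])
        an = _series([-1.0, -2.0, 0.0])  # negative A_n clamps to zero weight
        with pytest.raises(UndefinedMeanError):
            window_weighted_mean(s, TimeWindow(2015, 152, 152), "an_weighted", an=an)

    def test_weighted_mean_bounded(self, dataset, windows):
        rh = dataset.drivers["rh_pct"]
        an = dataset.drivers["an_umol_m2_s"]
        for w in windows:
            out = window_weighted_mean(rh, w, "an_weighted", an=an)
            sel = rh[(rh.index.dayofyear >= w.start_doy)
                     & (rh.index.dayofyear <= w.end_doy)]
            assert sel.min() <= out <= sel.max()


class TestClearSky:
    def test_night_is_zero(self):
        idx = pd.DatetimeIndex(["2015-06-15 00:00", "2015-12-15 12:00"])
        w = clear_sky_weight(idx, 67.77)
        assert w[0] == 0.0 or w[0] < 0.05  # midnight sun edge is nearly dark
        assert clear_sky_weight(pd.DatetimeIndex(["2015-01-15 01:00"]), 61.85)[0] == 0.0

    def test_noon_dominates_day(self):
        idx = pd.date_range("2015-06-15", periods=48, freq="30min")
        w = clear_sky_weight(idx, 61.85)
        assert w.argmax() == 24  # 12:00 local solar time

    def test_symmetry_about_noon(self):
        idx = pd.date_range("2015-03-21", periods=48, freq="30min")
        w = clear_sky_weight(idx, 45.0)
        assert np.allclose(w[1:24], w[25:48][::-1], atol=1e-6)


class TestCorrelationScales:
    def _frame(self, x, years, centers):
        return pd.DataFrame({"x": x, "y": -np.asarray(x), "year": years,
                             "center_doy": centers})

    def test_perfect_anticorrelation(self):
        df = self._frame([1.0, 2.0, 3.0, 4.0], [2015] * 4, [150, 170, 190, 210])
        r, p, n = correlations_by_scale(df, "intra_annual")
        assert r == pytest.approx(-1.0)
        assert n == 4

    def test_identity_correlation(self):
        df = self._frame([1.0, 2.0, 3.0], [2015] * 3, [150, 170, 190])
        df["y"] = df["x"]
        r, _, _ = correlations_by_scale(df, "intra_annual")
        assert r == pytest.approx(1.0)

    def test_ten_point_toy_against_direct_pearson(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        df = pd.DataFrame({"x": x, "y": y, "year": [2010 + i for i in range(10)],
                           "center_doy": np.full(10, 180.0)})
        r, p, n = correlations_by_scale(df, "intra_annual")
        r_ref, p_ref = stats.pearsonr(x, y)
        assert (r, p) == pytest.approx((r_ref, p_ref))

    def test_interannual_averages_years_first(self):
        df = pd.DataFrame({
            "x": [1.0, 3.0, 10.0, 12.0], "y": [5.0, 7.0, 2.0, 4.0],
            "year": [2015, 2015, 2016, 2016],
            "center_doy": [150.0, 200.0, 150.0, 200.0],
        })
        df = pd.concat([df, pd.DataFrame({"x": [20.0], "y": [0.0],
                                          "year": [2017], "center_doy": [180.0]})])
        r, _, n = correlations_by_scale(df, "interannual")
        ref = stats.pearsonr([2.0, 11.0, 20.0], [6.0, 3.0, 0.0])[0]
        assert n == 3
        assert r == pytest.approx(ref)

    def test_degenerate_equivalence_one_subsection_per_year(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        df = pd.DataFrame({"x": x, "y": y, "year": 2010 + np.arange(8),
                           "center_doy": np.full(8, 180.0)})
        r_intra, _, _ = correlations_by_scale(df, "intra_annual")
        r_inter, _, _ = correlations_by_scale(df, "interannual")
        assert r_intra == pytest.approx(r_inter)

    def test_seasonal_filter_and_boundary_rule(self):
        bounds = (135, 166, 227, 273)
        assert season_of_center(166.0, bounds) == "EGS"  # boundary -> earlier
        assert season_of_center(166.5, bounds) == "MGS"
        assert season_of_center(227.0, bounds) == "MGS"
        assert season_of_center(130.0, bounds) is None

    def test_insufficient_data(self):
        df = self._frame([1.0, 2.0], [2015, 2015], [150, 160])
        with pytest.raises(ValueError):
            correlations_by_scale(df, "interannual")


class TestPexInversion:
    def test_endmembers(self, forward):
        acc = forward.archive.entries[3]
        from isoring.transport import cellulose_delta_O, wood_from_cellulose

        for p_true in (0.0, 1.0, 0.36):
            wood = wood_from_cellulose(cellulose_delta_O(acc, p_true), "O")
            est = invert_apparent_pex(wood, acc.mean_sw_term, acc.mean_ps_o)
            assert est.p_ex == pytest.approx(p_true, abs=1e-10)

    def test_band_contains_point(self, forward):
        acc = forward.archive.entries[0]
        est = invert_apparent_pex(22.0, acc.mean_sw_term, acc.mean_ps_o)
        assert est.lower <= est.p_ex <= est.upper

    def test_out_of_range_flagged_not_clipped(self, forward):
        acc = forward.archive.entries[0]
        est = invert_apparent_pex(40.0, acc.mean_sw_term, acc.mean_ps_o)
        assert est.out_of_range
        assert not 0.0 <= est.p_ex <= 1.0

    def test_near_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            invert_apparent_pex(22.0, 2.0052e-3, 2.0052e-3)


class TestPexFits:
    def test_exact_linear_recovery(self):
        doy = np.linspace(150, 260, 20)
        table = pd.DataFrame({
            "center_doy": doy,
            "rh_pct": np.linspace(60, 80, 20),
            "p_ex": 0.9 - 0.002 * doy,
        })
        fits = fit_pex_functions(table)
        assert fits.doy_slope == pytest.approx(-0.002, abs=1e-12)
        assert fits.doy_intercept == pytest.approx(0.9, abs=1e-9)
        assert abs(fits.doy_r) == pytest.approx(1.0, abs=1e-9)

    def test_exponential_rh_recovery(self):
        rng = np.random.default_rng(5)
        rh = rng.uniform(50, 90, 60)
        pex = 1.8 * np.exp(-0.025 * rh) + rng.normal(0, 0.005, 60)
        table = pd.DataFrame({"center_doy": rng.uniform(150, 260, 60),
                              "rh_pct": rh, "p_ex": pex})
        fits = fit_pex_functions(table)
        assert fits.rh_a == pytest.approx(1.8, rel=0.15)
        assert fits.rh_b == pytest.approx(0.025, rel=0.15)
        assert fits.pex_of_rh(70.0) == pytest.approx(1.8 * np.exp(-1.75), abs=0.02)

    def test_degenerate_covariate(self):
        table = pd.DataFrame({"center_doy": np.full(12, 180.0),
                              "rh_pct": np.linspace(60, 80, 12),
                              "p_ex": np.linspace(0.3, 0.4, 12)})
        with pytest.raises(ValueError):
            fit_pex_functions(table)


class TestSensitivityGrid:
    def test_center_cell_is_baseline(self, dataset, windows, forward):
        an = dataset.drivers["an_umol_m2_s"]
        w = window_weights(dataset.drivers.index, "an_weighted", an=an.to_numpy())
        ring = forward.table["d18o_wood_permil"].to_numpy()
        grid = sensitivity_grid(ring, windows, dataset.drivers["rh_pct"], w,
                                shifts=np.arange(-4, 5, 2))
        base = [window_weighted_mean(dataset.drivers["rh_pct"], win,
                                     "an_weighted", an=an) for win in windows]
        r_ref = np.corrcoef(ring, base)[0, 1]
        i = list(grid.d_formation).index(0)
        assert grid.r[i, i] == pytest.approx(r_ref, abs=1e-9)

    def test_peak_is_grid_argmax(self, dataset, windows, forward):
        an = dataset.drivers["an_umol_m2_s"].to_numpy()
        w = window_weights(dataset.drivers.index, "an_weighted", an=an)
        ring = forward.table["d18o_wood_permil"].to_numpy()
        grid = sensitivity_grid(ring, windows, dataset.drivers["rh_pct"], w)
        ia = list(grid.d_formation).index(grid.peak_d_formation)
        ib = list(grid.d_maturation).index(grid.peak_d_maturation)
        assert abs(grid.r[ia, ib]) == pytest.approx(np.nanmax(np.abs(grid.r)))
        assert grid.contour_inner == pytest.approx(abs(grid.r_peak) - 0.01)

    def test_planted_shift_recovered(self, dataset, windows):
        """A +10-day dating misalignment planted into synthetic ring data is
        recovered by the grid peak within one cell."""
        an = dataset.drivers["an_umol_m2_s"]
        w = window_weights(dataset.drivers.index, "an_weighted", an=an.to_numpy())
        rh = dataset.drivers["rh_pct"]
        ring = np.array([
            -window_weighted_mean(rh, shift_window(win, 10, 10), "an_weighted", an=an)
            for win in windows
        ])
        grid = sensitivity_grid(ring, windows, rh, w, shifts=np.arange(-20, 21, 2))
        assert abs(grid.peak_d_formation - 10) <= 2
        assert abs(grid.peak_d_maturation - 10) <= 2

    def test_inverted_cells_marked_missing(self, dataset):
        short = [TimeWindow(2015, 180, 190)]
        an = dataset.drivers["an_umol_m2_s"].to_numpy()
        w = window_weights(dataset.drivers.index, "an_weighted", an=an)
        with pytest.raises(ValueError):
            # one window and one value: correlation is undefined everywhere
            sensitivity_grid(np.array([22.0]), short, dataset.drivers["rh_pct"], w)


class TestSdRatioAndScenarios:
    def test_identity_and_scaling(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert sd_ratio(x, x) == pytest.approx(1.0)
        assert sd_ratio(2.0 * x, x) == pytest.approx(2.0)
        assert sd_ratio(x, 2.0 * x) == pytest.approx(0.5)

    def test_hand_value(self):
        enr = np.array([10.0, 14.0])   # SD = 2*sqrt(2)
        sw = np.array([-12.0, -10.0])  # SD = sqrt(2)
        assert sd_ratio(enr, sw) == pytest.approx(2.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            sd_ratio(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_unit_scale_reproduces_baseline(self, dataset, windows, params, forward):
        table = sw_variability_scenarios(dataset, windows, params, [1.0])
        r_ref = stats.pearsonr(forward.table["d18o_wood_permil"],
                               forward.table["rh_an_weighted_pct"])[0]
        # s = 1 reproduces the baseline bit-identically
        assert table["r_ring_rh"].iloc[0] == r_ref

    def test_scenario_sweep_with_independent_source_water(self, params):
        """With source-water d18O independent of RH (slowly varying AR noise,
        as rootzone water is), killing its variability (s = 0) leaves the RH
        pathway carrying the whole signal, and the two correlations trade
        off monotonically in s.  Three seasons give the sample size the
        monotonicity needs."""
        from scipy.signal import lfilter

        from isoring.chronology import window_for_subsection
        from isoring.synthetic import SOUTHERN_BOREAL, build_dataset

        base = build_dataset(SOUTHERN_BOREAL, (2014, 2016), seed=7)
        windows3 = [
            window_for_subsection(base.growth_curves[y], i / 10, (i + 1) / 10)
            for y in (2014, 2015, 2016) for i in range(10)
        ]
        rng = np.random.default_rng(123)
        n = len(base.drivers)
        rho = 0.95  # ~20-day correlation, like rootzone water
        ar = lfilter([np.sqrt(1 - rho**2)], [1, -rho],
                     rng.standard_normal(n // 48 + 1))
        ds = base.replace_source_water(-11.5 + np.repeat(1.2 * ar, 48)[:n])
        table = sw_variability_scenarios(ds, windows3, params,
                                         [0.0, 0.5, 1.0, 2.0, 4.0])
        zero = table[table.s == 0.0].iloc[0]
        assert zero["r_sw_undefined"]
        assert np.isnan(zero["r_ring_sw"])
        assert abs(zero["r_ring_rh"]) == pytest.approx(
            table["r_ring_rh"].abs().max())
        sub = table[table.s > 0].sort_values("s")
        assert sub["r_ring_sw"].abs().is_monotonic_increasing
        assert sub["r_ring_rh"].abs().is_monotonic_decreasing
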