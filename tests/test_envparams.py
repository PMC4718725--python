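"""ED-parameter engineering: windowed averages, nonlinear solar transforms,
recent-change and fluctuation features, developmental stage, merging and
finalization."""

import numpy as np
import pandas as pd
import pytest

from climexp.envparams import (DELTA_FACTORS, DELTA_LAGS, EPS_WINDOWS,
                               CLIMATE_FACTORS, DevAnchors, L_WINDOWS,
                               NL_WINDOWS, build_raw_parameters, dev_stage,
                               field_indicator, finalize, fluctuation_residual,
                               merge_similar, nl_transform, recent_change,
                               seasonal_remainder, soil_moisture_params,
                               window_average)
from climexp.simulate import WeatherConfig, WeatherSeries, simulate_weather


def _flat_weather(value=25.0, slope_per_hour=0.0, days=20):
    idx = pd.date_range("2013-01-01", periods=days * 288, freq="5min")
    hours = (idx - idx[0]).total_seconds() / 3600.0
    vals = value + slope_per_hour * hours
    frame = pd.DataFrame({f: vals for f in CLIMATE_FACTORS}, index=idx)
    return WeatherSeries(frames={"dry": frame}, resolution_min=5)


class TestNLTransform:
    def test_anchor_point(self):
        assert nl_transform(400.0, "+") == pytest.approx(1.0)
        assert nl_transform(400.0, "-") == pytest.approx(1.0)

    def test_printed_formula_values(self):
        assert nl_transform(600.0, "+") == pytest.approx(np.e, rel=1e-12)
        assert nl_transform(0.0, "-") == pytest.approx(np.exp(2.0), rel=1e-12)

    def test_product_identity_and_monotonicity(self):
        x = np.linspace(0, 1000, 101)
        assert np.allclose(nl_transform(x, "+") * nl_transform(x, "-"), 1.0,
                           rtol=1e-12)
        assert (np.diff(nl_transform(x, "+")) > 0).all()
        assert (np.diff(nl_transform(x, "-")) < 0).all()

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            nl_transform(1.0, "x")


class TestWindowAverage:
    def test_constant_series_any_window(self):
        w = _flat_weather(25.0)
        t = pd.Timestamp("2013-01-18 10:00")
        for window in L_WINDOWS.values():
            assert window_average(w, "tp", window, t) == pytest.approx(25.0)

    def test_linear_ramp_window_midpoint(self):
        w = _flat_weather(0.0, slope_per_hour=1.0)
        t = pd.Timestamp("2013-01-18 10:00")
        val = window_average(w, "tp", pd.Timedelta(hours=4), t)
        expected = window_average(w, "tp", pd.Timedelta(minutes=5) * 0,
                                  t - pd.Timedelta(hours=2))
        assert val == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_summation(self, weather):
        frame = weather.frames["wet"]
        t = frame.index[288 * 16]   # 16 days in: every window covered
        for label, window in L_WINDOWS.items():
            got = window_average(weather, "ra", window, t)
            mask = (frame.index >= t - window) & (frame.index <= t)
            assert got == pytest.approx(
                frame.loc[mask, "ra"].sum() / mask.sum(), rel=1e-10)

    def test_window_before_start_raises(self):
        w = _flat_weather()
        with pytest.raises(ValueError, match="outside"):
            window_average(w, "tp", pd.Timedelta(days=15),
                           pd.Timestamp("2013-01-02"))


class TestRecentChange:
    def test_constant_series_zero(self):
        w = _flat_weather(30.0)
        t = pd.Timestamp("2013-01-18 10:00")
        for lag in DELTA_LAGS:
            assert recent_change(w, "tp", lag, t) == pytest.approx(0.0)

    def test_linear_ramp_equals_lag_times_slope(self):
        w = _flat_weather(0.0, slope_per_hour=1.0)
        t = pd.Timestamp("2013-01-18 10:00")
        assert recent_change(w, "tp", "1hr", t) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_sinusoid_matches_two_average_brute_force(self, weather):
        t = weather.frames["dry"].index[4000]
        for factor in DELTA_FACTORS:
            for lag_label, (lag, base) in DELTA_LAGS.items():
                got = recent_change(weather, factor, lag_label, t)
                expected = (window_average(weather, factor, base, t)
                            - window_average(weather, factor, base, t - lag))
                assert got == pytest.approx(expected, abs=1e-12)


class TestFluctuation:
    def test_noiseless_sinusoid_plus_trend_remainder_near_zero(self):
        idx = pd.date_range("2013-01-01", periods=20 * 288, freq="5min")
        hours = (idx - idx[0]).total_seconds() / 3600.0
        series = pd.Series(27 + 4 * np.sin(2 * np.pi * hours / 24)
                           + 0.01 * hours, index=idx)
        frame = pd.DataFrame({f: series for f in CLIMATE_FACTORS}, index=idx)
        w = WeatherSeries(frames={"dry": frame}, resolution_min=5)
        for t in idx[288 * 5::288 * 3][:4]:
            for label in EPS_WINDOWS:
                assert abs(fluctuation_residual(w, label, t)) < 0.05

    def test_injected_pulse_recovered_in_window_mean(self):
        idx = pd.date_range("2013-01-01", periods=20 * 288, freq="5min")
        hours = (idx - idx[0]).total_seconds() / 3600.0
        base = 27 + 4 * np.sin(2 * np.pi * hours / 24)
        series = pd.Series(base, index=idx)
        # 2 degC square pulse lasting 1 h, ending at the sampling time
        t = idx[288 * 10]
        pulse = (idx > t - pd.Timedelta(hours=1)) & (idx <= t)
        series[pulse] += 2.0
        frame = pd.DataFrame({f: series for f in CLIMATE_FACTORS}, index=idx)
        w = WeatherSeries(frames={"dry": frame}, resolution_min=5)
        got = fluctuation_residual(w, "4hr", t)
        expected = 2.0 * pulse.sum() / (4 * 12 + 1)
        # the trend and daily-cycle components absorb ~1/5 of an isolated
        # pulse, so the remainder recovers the rest of the anomaly mass
        assert got == pytest.approx(expected, rel=0.25)
        assert got > 0.5 * expected

    def test_short_series_rejected(self):
        idx = pd.date_range("2013-01-01", periods=300, freq="5min")
        with pytest.raises(ValueError, match="two periods"):
            seasonal_remainder(pd.Series(np.zeros(300), index=idx), 288)


class TestDevStage:
    def test_anchor_values_and_midpoints(self, anchors):
        d = anchors.anchors[("dry", "irrigated")]
        assert dev_stage(anchors, "dry", "irrigated", d[0]) == 0.0
        assert dev_stage(anchors, "dry", "irrigated", d[1]) == 40.0
        assert dev_stage(anchors, "dry", "irrigated", d[2]) == 100.0
        mid = d[1] + (d[2] - d[1]) / 2
        assert dev_stage(anchors, "dry", "irrigated",
                         mid) == pytest.approx(70.0)

    def test_monotone_over_sampling_span(self, anchors):
        ts = pd.date_range("2013-01-05", "2013-02-20", freq="12h")
        vals = [dev_stage(anchors, "dry", "irrigated", t) for t in ts]
        assert (np.diff(vals) >= 0).all()

    def test_before_transplanting_raises(self, anchors):
        with pytest.raises(ValueError, match="transplanting"):
            dev_stage(anchors, "dry", "irrigated", "2012-12-01")

    def test_nonincreasing_anchors_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            DevAnchors(anchors={("dry", "irrigated"):
                                ("2013-02-01", "2013-01-01", "2013-03-01")})


class TestFieldAndSoil:
    def test_field_indicator_convention(self):
        assert field_indicator("irrigated") == 0
        assert field_indicator("rainfed") == 1
        with pytest.raises(ValueError):
            field_indicator("upland")

    def test_design_has_half_rainfed(self, ed):
        vals = [field_indicator(f) for f in ed.design_meta["field"]]
        assert sum(vals) == len(vals) // 2

    def test_irrigated_soil_constant(self, soil):
        sm = soil["irrigated"]
        t = sm.frames["dry"].index[1000]
        assert soil_moisture_params(sm, t) == (1.0, 1.0)

    def test_uncovered_time_raises(self, soil):
        with pytest.raises(ValueError, match="not covered"):
            soil_moisture_params(soil["rainfed"], pd.Timestamp("2012-01-01"))


class TestAssembly:
    def test_table_grid_complete(self, weather, soil, anchors, design):
        raw, meta = build_raw_parameters(weather, soil, anchors, design)
        for factor in CLIMATE_FACTORS:
            for label in L_WINDOWS:
                assert f"{factor}_{label}" in raw.index
        for label in NL_WINDOWS:
            assert f"so_{label}_NL+" in raw.index
            assert f"so_{label}_NL-" in raw.index
        for factor in DELTA_FACTORS:
            for label in DELTA_LAGS:
                assert f"{factor}_delta{label}" in raw.index
        for label in EPS_WINDOWS:
            assert f"tp_eps{label}" in raw.index
        for pid in ("sm15", "sm30", "field", "dev"):
            assert pid in raw.index
        assert len(raw) == 6 * 8 + 6 + 12 + 3 + 4

    def test_duplicate_rows_merge_to_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        v = pd.DataFrame([base, base, rng.normal(size=20)],
                         index=["a", "b", "c"])
        merged, mm = merge_similar(v, merge_r=0.98)
        assert mm["a"] == mm["b"] == "a+b"
        assert len(merged) == 2

    def test_sign_aligned_merge_of_anticorrelated(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        v = pd.DataFrame([base, -base + rng.normal(0, 1e-3, 30)],
                         index=["a", "b"])
        merged, mm = merge_similar(v, merge_r=0.98)
        assert len(merged) == 1
        # merged profile keeps the first member's orientation
        assert np.corrcoef(merged.iloc[0], base)[0, 1] > 0.99

    def test_merged_matrix_respects_threshold(self, ed):
        corr = np.corrcoef(ed.values.to_numpy())
        off = np.abs(corr - np.eye(len(corr)))
        assert off.max() <= 0.98 + 1e-9

    def test_constant_row_raises_by_default(self):
        v = pd.DataFrame([[1.0] * 10, list(range(10))], index=["flat", "x"])
        with pytest.raises(ValueError, match="flat"):
            merge_similar(v)

    def test_finalize_block_means_and_unit_sd(self, ed):
        for _, sub in ed.design_meta.groupby(["genotype", "season"]):
            block = ed.values[sub.index]
            assert np.abs(block.mean(axis=1)).max() < 1e-9
        assert np.allclose(ed.values.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_finalize_idempotent(self, ed):
        again = finalize(ed.values, ed.design_meta)
        assert np.allclose(again.to_numpy(), ed.values.to_numpy(),
                           atol=1e-10)

    def test_every_window_param_matches_brute_force(self, weather, soil,
                                                    anchors, design, ed):
        """Windowed statistics recomputed directly from the raw grid agree
        to 1e-10 (merged parameters are checked via the merge map)."""
        raw, _ = build_raw_parameters(weather, soil, anchors, design)
        times = pd.to_datetime(design["timestamp"])
        for label, window in L_WINDOWS.items():
            pid = f"tp_{label}"
            frame_vals = []
            for t in times:
                season = weather.season_of(t)
                f = weather.frames[season]
                mask = (f.index >= t - window) & (f.index <= t)
                frame_vals.append(f.loc[mask, "tp"].mean())
            assert np.allclose(raw.loc[pid].to_numpy(), frame_vals,
                               atol=1e-10)
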