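"""Ozone exposure metrics: hand-checked values, unit bookkeeping and
self-consistency of the peak/nonpeak hourly reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agriair import exposure as E


class TestMDA8:
    @pytest.mark.parametrize(
        "hours, expected",
        [
            (np.full(24, 50.0), 50.0),  # constant series
            (np.arange(24.0), 19.5),  # max window is hours 16-23
            (np.r_[80.0, np.zeros(23)], 10.0),  # single spike spread over 8h
        ],
    )
    def test_hand_values(self, hours, expected):
        assert E.mda8(E.HourlySeries(hours)) == pytest.approx(expected)

    def test_brute_force_windows(self, rng):
        vals = rng.uniform(0, 90, 24)
        expected = max(vals[s : s + 8].mean() for s in range(17))
        assert E.mda8(vals) == pytest.approx(expected)

    def test_missing_day_flagged_not_raised(self):
        vals = np.full(24, 50.0)
        vals[:7] = np.nan  # 17 valid hours < 18
        assert np.isnan(E.mda8(vals))

    def test_sparse_windows_skipped(self):
        vals = np.full(24, np.nan)
        vals[::2] = 40.0  # 12 valid hours total, max 4 per window
        assert np.isnan(E.mda8(vals))

    def test_wrong_unit_rejected(self):
        with pytest.raises(E.UnitError):
            E.mda8(E.HourlySeries(np.full(24, 50.0), unit="ug/m3"))


class TestUnitConversion:
    def test_who_guideline_value(self):
        # 60 μg/m³ ozone at 298 K / 1013 hPa is 31 ppb after rounding
        ppb = E.ugm3_to_ppb(60.0, 298.0, 1013.0)
        assert round(ppb) == 31
        assert ppb == pytest.approx(30.6, abs=0.05)

    def test_zero_maps_to_zero(self):
        assert E.ugm3_to_ppb(0.0) == 0.0

    def test_round_trip_identity(self):
        x = 123.456
        back = E.ugm3_to_ppb(E.ppb_to_ugm3(x, 285.0, 990.0), 285.0, 990.0)
        assert back == pytest.approx(x, abs=1e-10)

    @pytest.mark.parametrize("bad", [{"temperature_k": -1.0}, {"pressure_hpa": 0.0}])
    def test_nonpositive_conditions_rejected(self, bad):
        with pytest.raises(ValueError):
            E.ugm3_to_ppb(10.0, **bad)


class TestCumulativeIndices:
    def test_aot40_hand_values(self):
        assert E.aot40(E.HourlySeries([50.0, 30.0, 45.0])) == 15.0
        assert E.aot40(E.HourlySeries(np.full(10, 40.0))) == 0.0  # strict >
        assert E.aot40(E.HourlySeries(np.zeros(5))) == 0.0

    def test_sum06_hand_values(self):
        assert E.sum06(E.HourlySeries([70.0, 50.0, 61.0])) == 131.0
        assert E.sum06(E.HourlySeries([60.0, 59.0])) == 0.0  # strict >
        # an hour at exactly 60 never contributes
        assert E.sum06(E.HourlySeries([70.0, 50.0, 61.0, 60.0])) == 131.0

    def test_w126_scalar_hand_value(self):
        # single hour at 0.060 ppm, direct formula
        expected = 0.060 / (1 + 4403 * np.exp(-126 * 0.060))
        assert E.w126(E.HourlySeries([0.060], unit="ppm")) == pytest.approx(expected)
        # ppb input converts internally
        assert E.w126(E.HourlySeries([60.0], unit="ppb")) == pytest.approx(expected)

    def test_w126_weight_limits(self):
        assert E.w126_weight(0.0) == pytest.approx(1 / 4404)
        assert E.w126_weight(10.0) == pytest.approx(1.0, abs=1e-12)
        grid = np.linspace(0, 0.3, 100)
        w = E.w126_weight(grid)
        assert np.all(np.diff(w) > 0) and np.all((w > 0) & (w < 1))

    def test_mass_unit_rejected(self):
        with pytest.raises(E.UnitError):
            E.w126(E.HourlySeries([50.0], unit="ug/m3"))

    @given(st.lists(st.floats(0, 150), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_monotone_under_pointwise_increase(self, values):
        base = E.HourlySeries(np.asarray(values))
        bumped = E.HourlySeries(np.asarray(values) + 5.0)
        assert E.aot40(bumped) >= E.aot40(base)
        assert E.sum06(bumped) >= E.sum06(base)
        assert E.w126(bumped) >= E.w126(base)

    @given(st.lists(st.floats(0, 150), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_sum06_hours_subset_of_aot40_hours(self, values):
        v = np.asarray(values)
        assert set(np.where(v > 60)[0]) <= set(np.where(v > 40)[0])


class TestReconstruction:
    def _monthly(self, mda8=45.0):
        return pd.DataFrame(
            {"region": ["r"], "year": [2015], "month": [7], "mda8": [mda8]}
        )

    def test_flat_profile_when_ratio_one(self):
        ratios = pd.DataFrame({"region": ["r"], "month": [7], "ratio": [1.0]})
        series = E.reconstruct_hourly(self._monthly(), ratios)[("r", 2015, 7)]
        assert np.allclose(series.values, 45.0)
        assert len(series) == 31 * 24

    def test_peak_and_nonpeak_levels(self):
        ratios = pd.DataFrame({"region": ["r"], "month": [7], "ratio": [1.5]})
        series = E.reconstruct_hourly(self._monthly(), ratios)[("r", 2015, 7)]
        day = series.values[:24]
        assert day[list(E.PEAK_HOURS)] == pytest.approx(45.0)
        off = np.setdiff1d(np.arange(24), E.PEAK_HOURS)
        assert day[off] == pytest.approx(30.0)

    @pytest.mark.parametrize("ratio", [1.0, 1.3, 2.0])
    def test_mda8_of_reconstruction_is_identity(self, ratio):
        ratios = pd.DataFrame({"region": ["r"], "month": [7], "ratio": [ratio]})
        series = E.reconstruct_hourly(self._monthly(45.0), ratios)[("r", 2015, 7)]
        assert E.mda8(series.values[:24]) == pytest.approx(45.0)

    def test_missing_ratio_raises_with_keys(self):
        ratios = pd.DataFrame({"region": ["q"], "month": [1], "ratio": [1.0]})
        with pytest.raises(KeyError, match="r"):
            E.reconstruct_hourly(self._monthly(), ratios)

    def test_closed_form_indices_match_hourly_expansion(self):
        monthly = np.array([25, 28, 35, 42, 50, 58, 62, 60, 52, 43, 33, 26.0])
        ratio = 1.4
        closed = E.annual_indices_from_monthly(monthly, ratio)
        totals = {"aot40": 0.0, "sum06": 0.0, "w126": 0.0}
        for m, v in enumerate(monthly, start=1):
            mdf = pd.DataFrame({"region": ["r"], "year": [2015], "month": [m], "mda8": [v]})
            rdf = pd.DataFrame({"region": ["r"], "month": [m], "ratio": [ratio]})
            series = E.reconstruct_hourly(mdf, rdf)[("r", 2015, m)]
            totals["aot40"] += E.aot40(series)
            totals["sum06"] += E.sum06(series)
            totals["w126"] += E.w126(series)
        for k in totals:
            assert closed[k] == pytest.approx(totals[k], rel=1e-12)


class TestRatiosAndSeasons:
    def _hourly_frame(self, day_fn, n_days=3, month=6):
        rows = []
        for d in range(1, n_days + 1):
            ts = pd.date_range(f"2015-{month:02d}-{d:02d}", periods=24, freq="h")
            for h, t in enumerate(ts):
                rows.append({"region": "r", "timestamp": t, "concentration": day_fn(h)})
        return pd.DataFrame(rows)

    def test_constant_series_gives_ratio_one(self):
        df = self._hourly_frame(lambda h: 40.0)
        ratios = E.estimate_ratios(df)
        assert ratios["ratio"].iloc[0] == pytest.approx(1.0)

    def test_two_level_profile_gives_exact_ratio(self):
        df = self._hourly_frame(lambda h: 60.0 if 8 <= h < 16 else 30.0)
        ratios = E.estimate_ratios(df)
        assert ratios["ratio"].iloc[0] == pytest.approx(2.0)

    def test_diurnal_sinusoid_matches_hand_integral(self):
        # C(h) = 50 + 20·cos(2π(h-13)/24): peak window centred on hour 13
        conc = lambda h: 50.0 + 20.0 * np.cos(2 * np.pi * (h - 13) / 24.0)
        df = self._hourly_frame(conc)
        hours = np.arange(24)
        vals = conc(hours)
        best = max(range(17), key=lambda s: vals[s : s + 8].mean())
        peak = vals[best : best + 8].mean()
        nonpeak = np.delete(vals, np.s_[best : best + 8]).mean()
        ratios = E.estimate_ratios(df)
        assert ratios["ratio"].iloc[0] == pytest.approx(peak / nonpeak, rel=1e-12)

    def test_seasonal_means_split(self):
        monthly = pd.DataFrame(
            {
                "region": "r",
                "year": 2010,
                "month": list(range(1, 13)),
                "mda8": [20.0 if m in (12, 1, 2) else 50.0 for m in range(1, 13)],
            }
        )
        out = E.seasonal_means(monthly)
        assert out["winter"].iloc[0] == pytest.approx(20.0)
        assert out["nonwinter"].iloc[0] == pytest.approx(50.0)

    def test_equal_months_equal_seasons(self):
        monthly = pd.DataFrame(
            {"region": "r", "year": 2010, "month": range(1, 13), "mda8": 40.0}
        )
        out = E.seasonal_means(monthly)
        assert out["winter"].iloc[0] == out["nonwinter"].iloc[0] == pytest.approx(40.0)
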