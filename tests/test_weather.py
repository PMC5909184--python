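"""Weather reading, validation, classification, analog selection, splicing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eonrcast import (
    classify_year,
    read_weather,
    select_scenario_years,
    splice,
    write_weather,
)
from eonrcast.weather import (
    DAYS_PER_YEAR,
    WeatherFormatError,
    WeatherLibrary,
    WeatherValidationError,
)
from .conftest import make_constant_series


def _csv_frame(year: int, n_days: int) -> pd.DataFrame:
    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    rng = np.random.default_rng(0)
    tmin = rng.uniform(-5, 15, n_days).round(2)
    return pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "tmax": (tmin + rng.uniform(1, 12, n_days)).round(2),
            "tmin": tmin,
            "precip": rng.choice([0, 0, 4.5, 12.0], n_days),
            "radiation": rng.uniform(2, 25, n_days).round(2),
        }
    )


class TestReading:
    def test_csv_round_trip_single_year(self, tmp_path):
        df = _csv_frame(1985, 365)
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        lib = read_weather(path, "csv")
        assert lib.years == [1985]
        s = lib[1985]
        np.testing.assert_allclose(s.tmax, df["tmax"].to_numpy())
        np.testing.assert_allclose(s.precip, df["precip"].to_numpy())

    def test_leap_year_drops_feb29(self, tmp_path):
        df = _csv_frame(1984, 366)  # 1984 is a leap year
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        lib = read_weather(path, "csv")
        s = lib[1984]
        assert s.tmax.shape == (365,)
        # day-of-year 60 in the result is Mar 1 (row 60 of the file, 0-based)
        assert s.tmax[59] == df["tmax"].iloc[60]
        assert s.tmax[58] == df["tmax"].iloc[58]  # Feb 28 untouched

    def test_negative_precip_names_the_year(self, tmp_path):
        df = _csv_frame(1990, 365)
        df.loc[41, "precip"] = -1.0
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        with pytest.raises(WeatherValidationError, match="1990.*precip.*42"):
            read_weather(path, "csv")

    def test_tmax_below_tmin_rejected(self, tmp_path):
        df = _csv_frame(1991, 365)
        df.loc[10, "tmax"] = df.loc[10, "tmin"] - 5
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        with pytest.raises(WeatherValidationError, match="tmax < tmin"):
            read_weather(path, "csv")

    def test_missing_column_is_format_error(self, tmp_path):
        df = _csv_frame(1992, 365).drop(columns=["radiation"])
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        with pytest.raises(WeatherFormatError, match="radiation"):
            read_weather(path, "csv")

    def test_incomplete_year_rejected(self, tmp_path):
        df = _csv_frame(1993, 200)
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        with pytest.raises(WeatherValidationError, match="incomplete"):
            read_weather(path, "csv")

    @pytest.mark.parametrize("dialect", ["csv", "met"])
    def test_write_read_round_trip(self, tmp_path, small_lib, dialect):
        path = tmp_path / f"lib.{dialect}"
        write_weather(small_lib, path, dialect)
        back = read_weather(path, dialect)
        assert back.years == small_lib.years
        y = small_lib.years[0]
        np.testing.assert_allclose(back[y].tmax, small_lib[y].tmax, atol=0.006)
        np.testing.assert_allclose(back[y].precip, small_lib[y].precip, atol=0.006)


class TestClassification:
    def test_annual_anomaly_signs(self, quadrant_lib):
        cls = classify_year(quadrant_lib, 2006, "annual")
        assert cls.quadrant == ("warm", "wet")
        assert classify_year(quadrant_lib, 2004, "annual").quadrant == ("cold", "dry")

    def test_exact_tie_resolves_warm_wet(self):
        lib = WeatherLibrary()
        # two identical years: each sits exactly at the long-term mean
        for y in (2000, 2001):
            lib.add(make_constant_series(y, tmean=9.0, annual_precip=900.0))
        cls = classify_year(lib, 2000, "annual")
        assert cls.quadrant == ("warm", "wet")

    def test_summer_period_uses_summer_block(self):
        lib = WeatherLibrary()
        # same annual mean everywhere; 2002's summer is cooler and drier
        lib.add(make_constant_series(2001, summer_tmean=22.0, summer_precip_total=300.0))
        lib.add(make_constant_series(2002, summer_tmean=18.0, summer_precip_total=200.0))
        assert classify_year(lib, 2002, "summer").quadrant == ("cold", "dry")
        assert classify_year(lib, 2001, "summer").quadrant == ("warm", "wet")

    def test_quadrants_partition_library(self, small_lib):
        quads = [classify_year(small_lib, y, "annual").quadrant for y in small_lib.years]
        assert len(quads) == len(small_lib)
        for q in quads:
            assert q[0] in ("warm", "cold") and q[1] in ("wet", "dry")

    def test_unknown_year_raises(self, small_lib):
        with pytest.raises(KeyError):
            classify_year(small_lib, 1492, "annual")


class TestScenarioSelection:
    def test_prior_year_windows(self, lib35):
        # library 1980-2014: the 20/5 calendar years before 2010
        assert select_scenario_years(lib35, 2010, "V") == list(range(1990, 2010))
        assert select_scenario_years(lib35, 2010, "III") == list(range(2005, 2010))
        assert select_scenario_years(lib35, 2010, "IV") == list(range(2000, 2010))

    def test_full_library_selection(self, lib35):
        sel = select_scenario_years(lib35, 2010, "full35")
        assert sel == lib35.years and len(sel) == 35

    def test_insufficient_prior_years(self, lib35):
        with pytest.raises(ValueError, match="needs 20"):
            select_scenario_years(lib35, 1985, "V")

    def test_annual_analog_quadrant_matching(self, quadrant_lib):
        assert select_scenario_years(quadrant_lib, 2006, "I") == [2001, 2002, 2003]

    def test_target_year_excluded_from_own_analogs(self, small_lib):
        for scenario in ("I", "II"):
            for y in small_lib.years:
                assert y not in select_scenario_years(small_lib, y, scenario)

    def test_scenario_nesting(self, lib35):
        iii = set(select_scenario_years(lib35, 2010, "III"))
        iv = set(select_scenario_years(lib35, 2010, "IV"))
        v = set(select_scenario_years(lib35, 2010, "V"))
        full = set(select_scenario_years(lib35, 2010, "full35"))
        assert iii < iv < v < full


class TestSplice:
    def test_degenerate_splice_at_year_end(self, small_lib):
        ys = small_lib.years
        obs, donor = small_lib[ys[0]], small_lib[ys[1]]
        out = splice(obs, donor, 365)
        np.testing.assert_array_equal(out.tmax, obs.tmax)
        np.testing.assert_array_equal(out.precip, obs.precip)
        assert out.provenance == "spliced" and out.donor_label == donor.year_label

    def test_boundary_contract(self, small_lib):
        ys = small_lib.years
        obs, donor = small_lib[ys[0]], small_lib[ys[1]]
        with pytest.raises(ValueError):
            splice(obs, donor, 0)
        out = splice(obs, donor, 1)
        assert out.tmax[0] == obs.tmax[0]
        np.testing.assert_array_equal(out.tmax[1:], donor.tmax[1:])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(doy=st.integers(min_value=1, max_value=365))
    def test_partition_property(self, small_lib, doy):
        """Every spliced day equals exactly one of its two sources."""
        ys = small_lib.years
        obs, donor = small_lib[ys[2]], small_lib[ys[3]]
        out = splice(obs, donor, doy)
        for arr, o, d in (
            (out.tmax, obs.tmax, donor.tmax),
            (out.precip, obs.precip, donor.precip),
            (out.radiation, obs.radiation, donor.radiation),
        ):
            np.testing.assert_array_equal(arr[:doy], o[:doy])
            np.testing.assert_array_equal(arr[doy:], d[doy:])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(doy=st.integers(min_value=1, max_value=365))
    def test_self_splice_is_identity(self, small_lib, doy):
        obs = small_lib[small_lib.years[0]]
        out = splice(obs, obs, doy)
        np.testing.assert_array_equal(out.tmax, obs.tmax)
        np.testing.assert_array_equal(out.tmin, obs.tmin)
        np.testing.assert_array_equal(out.precip, obs.precip)
        np.testing.assert_array_equal(out.radiation, obs.radiation)
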