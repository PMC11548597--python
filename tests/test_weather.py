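"""Weather generation, hydrological-year classification, ET0, and file I/O."""

import dataclasses
import datetime as dt
import math

import numpy as np
import pytest

from mulchsim import reference, weather
from mulchsim.weather import (
    ClimateSpec,
    WeatherDay,
    WeatherError,
    classify_hydro_year,
    generate_weather,
    penman_monteith_et0,
    read_weather,
    write_weather,
)


class TestWeatherDay:
    def test_tavg_derived_from_extremes(self):
        d = WeatherDay(dt.date(2020, 6, 1), tmax=30.0, tmin=16.0, srad=22.0,
                       precip=0.0)
        assert d.tavg == pytest.approx(23.0)

    def test_inconsistent_extremes_rejected(self):
        with pytest.raises(WeatherError):
            WeatherDay(dt.date(2020, 6, 1), tmax=10.0, tmin=16.0, srad=22.0,
                       precip=0.0)

    def test_negative_forcing_rejected(self):
        with pytest.raises(WeatherError):
            WeatherDay(dt.date(2020, 6, 1), 20.0, 10.0, srad=-1.0, precip=0.0)
        with pytest.raises(WeatherError):
            WeatherDay(dt.date(2020, 6, 1), 20.0, 10.0, srad=1.0, precip=-2.0)


class TestGenerator:
    def test_seeded_generation_is_reproducible(self, climate_spec):
        a = generate_weather(climate_spec, 2, seed=7)
        b = generate_weather(climate_spec, 2, seed=7)
        assert a.to_frame().equals(b.to_frame())
        c = generate_weather(climate_spec, 2, seed=8)
        assert not a.to_frame().equals(c.to_frame())

    def test_long_run_mean_annual_precip_near_study_value(self, climate_spec):
        series = generate_weather(climate_spec, 50, seed=1)
        mean_annual = np.mean(list(series.annual_totals().values()))
        # 324 mm long-run mean, +/-15%
        assert 275.0 <= mean_annual <= 373.0

    def test_growing_season_totals_span_observed_range(self, climate_spec):
        series = generate_weather(climate_spec, 50, seed=1)
        totals = [series.growing_season_total(y) for y in series.years()]
        assert min(totals) < 240.0 and max(totals) > 330.0

    def test_zero_precip_spec_yields_dry_series(self, climate_spec):
        dry = dataclasses.replace(climate_spec,
                                  monthly_precip_mm=(0.0,) * 12)
        series = generate_weather(dry, 1, seed=3)
        assert all(d.precip == 0.0 for d in series)

    def test_tmin_never_exceeds_tmax(self, weather_3y):
        assert all(d.tmin <= d.tmax for d in weather_3y)

    def test_july_september_concentration(self, climate_spec):
        assert climate_spec.july_september_share() >= 0.6

    def test_invalid_years_rejected(self, climate_spec):
        with pytest.raises(WeatherError):
            generate_weather(climate_spec, 0, seed=1)

    def test_negative_event_rate_rejected(self):
        with pytest.raises(WeatherError):
            ClimateSpec(monthly_event_rate=(-1.0,) + (1.0,) * 11)


class TestHydroYear:
    def test_observed_wet_year_classifies_wet(self, climatology):
        cls = classify_hydro_year(414.89, climatology)
        assert cls.label == "wet"

    def test_observed_dry_year_classifies_dry(self, climatology):
        cls = classify_hydro_year(212.56, climatology)
        assert cls.label == "dry"

    def test_median_season_is_normal(self, climatology):
        cls = classify_hydro_year(float(np.median(climatology)), climatology)
        assert cls.label == "normal"

    def test_classification_is_monotone_in_rainfall(self, climatology):
        order = {"dry": 0, "normal": 1, "wet": 2}
        labels = [classify_hydro_year(t, climatology).label
                  for t in np.linspace(100, 500, 60)]
        ranks = [order[l] for l in labels]
        assert ranks == sorted(ranks)

    def test_thresholds_partition_one_label_each(self, climatology):
        for total in np.linspace(50, 600, 40):
            cls = classify_hydro_year(float(total), climatology)
            assert cls.label in {"wet", "normal", "dry"}

    def test_empty_climatology_rejected(self):
        with pytest.raises(WeatherError):
            classify_hydro_year(300.0, [])


def _fao56_et0_oracle(day, elevation, latitude):
    """Independent step-by-step FAO-56 daily ET0 (Rs/Rso clipped to [0.3, 1])."""
    T = (day.tmax + day.tmin) / 2
    e0 = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    slope = 4098 * e0(T) / (T + 237.3) ** 2
    P = 101.3 * ((293 - 0.0065 * elevation) / 293) ** 5.26
    gamma = 0.000665 * P
    es = (e0(day.tmax) + e0(day.tmin)) / 2
    ea = es * day.rhum / 100
    J = day.date.timetuple().tm_yday
    dr = 1 + 0.033 * math.cos(2 * math.pi * J / 365)
    dec = 0.409 * math.sin(2 * math.pi * J / 365 - 1.39)
    phi = math.radians(latitude)
    ws = math.acos(max(-1, min(1, -math.tan(phi) * math.tan(dec))))
    Ra = 24 * 60 / math.pi * 0.082 * dr * (
        ws * math.sin(phi) * math.sin(dec)
        + math.cos(phi) * math.cos(dec) * math.sin(ws))
    Rso = (0.75 + 2e-5 * elevation) * Ra
    Rns = 0.77 * day.srad
    ratio = max(0.3, min(1.0, day.srad / Rso))
    Rnl = 4.903e-9 * (((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4) / 2) \
        * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * ratio - 0.35)
    Rn = Rns - Rnl
    num = 0.408 * slope * Rn + gamma * 900 / (T + 273) * day.wind * (es - ea)
    return max(0.0, num / (slope + gamma * (1 + 0.34 * day.wind)))


class TestReferenceET:
    def test_no_energy_limit(self):
        d = WeatherDay(dt.date(2020, 6, 1), tmax=15.0, tmin=15.0, srad=0.0,
                       precip=0.0, rhum=60.0, wind=0.0)
        assert penman_monteith_et0(d) == pytest.approx(0.0, abs=0.1)

    def test_midsummer_day_matches_independent_oracle(self):
        d = WeatherDay(dt.date(2020, 6, 22), tmax=30.0, tmin=15.0, srad=25.0,
                       precip=0.0, rhum=50.0, wind=2.0)
        expected = _fao56_et0_oracle(d, reference.SITE_ELEVATION_M,
                                     reference.SITE_LATITUDE_DEG)
        assert penman_monteith_et0(d) == pytest.approx(expected, abs=0.05)
        assert 4.0 < expected < 9.0  # plausible midsummer magnitude

    def test_ten_random_days_agree_with_oracle(self, rng):
        for _ in range(10):
            tmin = rng.uniform(-5, 20)
            d = WeatherDay(
                dt.date(2020, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365))),
                tmax=tmin + rng.uniform(2, 15), tmin=tmin,
                srad=rng.uniform(2, 30), precip=0.0,
                rhum=rng.uniform(25, 95), wind=rng.uniform(0.3, 6.0),
            )
            expected = _fao56_et0_oracle(d, reference.SITE_ELEVATION_M,
                                         reference.SITE_LATITUDE_DEG)
            assert penman_monteith_et0(d) == pytest.approx(expected, abs=0.05)

    def test_monotone_in_radiation(self):
        vals = []
        for srad in (5.0, 12.0, 20.0, 28.0):
            d = WeatherDay(dt.date(2020, 7, 1), tmax=28.0, tmin=16.0,
                           srad=srad, precip=0.0, rhum=55.0, wind=2.0)
            vals.append(penman_monteith_et0(d))
        assert vals == sorted(vals)

    def test_missing_humidity_and_wind_fall_back_with_warning(self, caplog):
        d = WeatherDay(dt.date(2020, 7, 1), 28.0, 16.0, srad=20.0, precip=0.0)
        with caplog.at_level("WARNING"):
            et0 = penman_monteith_et0(d)
        assert et0 > 0
        assert "humidity" in caplog.text and "wind" in caplog.text


class TestIO:
    def test_csv_three_day_fixture(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "date,tmax,tmin,srad,precip\n"
            "2020-05-01,20,8,18,0\n"
            "2020-05-02,22,9,20,5.5\n"
            "2020-05-03,19,7,15,0\n"
        )
        series = read_weather(path)
        assert len(series) == 3
        assert series[1].precip == pytest.approx(5.5)

    def test_csv_round_trip_is_identity(self, tmp_path, weather_3y):
        path = tmp_path / "rt.csv"
        write_weather(weather_3y, path)
        back = read_weather(path)
        for a, b in zip(weather_3y, back):
            assert a.date == b.date
            for f in ("tmax", "tmin", "srad", "precip", "rhum", "wind"):
                assert getattr(a, f) == pytest.approx(getattr(b, f))

    def test_missing_day_reported_with_date(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "date,tmax,tmin,srad,precip\n"
            "2020-05-01,20,8,18,0\n"
            "2020-05-03,19,7,15,0\n"
        )
        with pytest.raises(WeatherError, match="2020-05-02"):
            read_weather(path)

    def test_dssat_round_trip_preserves_values_to_precision(self, tmp_path,
                                                            weather_3y):
        path = tmp_path / "w.wth"
        write_weather(weather_3y, path, dialect="dssat")
        back = read_weather(path, dialect="dssat")
        assert len(back) == len(weather_3y)
        for a, b in zip(weather_3y, back):
            assert a.date == b.date
            assert b.tmax == pytest.approx(a.tmax, abs=0.051)
            assert b.precip == pytest.approx(a.precip, abs=0.051)

    def test_daylength_midsummer_exceeds_fifteen_hours(self):
        assert weather.daylength_hours(44.1, 172) > 15.0
        assert weather.daylength_hours(44.1, 355) < 9.5
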