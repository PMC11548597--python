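"""Daily weather: data model, I/O, reference ET, and a synthetic generator.

The generator emulates the semi-arid continental climate of the Xiliaohe
Plain (eastern Inner Mongolia): ~324 mm mean annual precipitation with more
than 60% falling from July to September, ~80% during the May-September maize
growing season, hot summers (July means near 24 degC) and cold winters.
Temperatures follow a seasonal sinusoid with AR(1) day-to-day anomalies;
precipitation is a per-month Poisson event count with gamma-distributed
amounts; solar radiation is extraterrestrial radiation times a transmissivity
that drops on rain days.

Hydrological-year classification labels a growing season wet / normal / dry
by its precipitation total against an empirical climatology (>= 75th
percentile -> wet, <= 25th -> dry), the convention used in Chinese
agrohydrology.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import reference

log = logging.getLogger(__name__)

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1 (FAO-56)
STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 d-1


class WeatherError(ValueError):
    """Malformed or physically inconsistent weather input."""


@dataclass(frozen=True)
class WeatherDay:
    """One day of atmospheric forcing.

    srad is daily total solar radiation in MJ m-2 d-1; precip in mm.
    rhum (%) and wind (m/s) are optional and only needed for FAO-56 ET0.
    """

    date: dt.date
    tmax: float
    tmin: float
    srad: float
    precip: float
    tavg: float | None = None
    rhum: float | None = None
    wind: float | None = None

    def __post_init__(self):
        if self.tmin > self.tmax + 1e-9:
            raise WeatherError(f"{self.date}: tmin {self.tmin} > tmax {self.tmax}")
        if self.srad < 0:
            raise WeatherError(f"{self.date}: negative solar radiation")
        if self.precip < 0:
            raise WeatherError(f"{self.date}: negative precipitation")
        if self.tavg is None:
            object.__setattr__(self, "tavg", (self.tmax + self.tmin) / 2.0)

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday


class WeatherSeries:
    """Ordered, gap-free sequence of :class:`WeatherDay`."""

    def __init__(self, days: Iterable[WeatherDay]):
        days = list(days)
        if not days:
            raise WeatherError("empty weather series")
        for prev, cur in zip(days, days[1:]):
            delta = (cur.date - prev.date).days
            if delta != 1:
                missing = prev.date + dt.timedelta(days=1)
                raise WeatherError(
                    f"gap in weather series: expected {missing}, got {cur.date}"
                )
        self._days = days
        self._by_date = {d.date: d for d in days}

    def __len__(self) -> int:
        return len(self._days)

    def __iter__(self) -> Iterator[WeatherDay]:
        return iter(self._days)

    def __getitem__(self, i) -> WeatherDay:
        return self._days[i]

    @property
    def start(self) -> dt.date:
        return self._days[0].date

    @property
    def end(self) -> dt.date:
        return self._days[-1].date

    def on(self, date: dt.date) -> WeatherDay:
        try:
            return self._by_date[date]
        except KeyError:
            raise WeatherError(f"date {date} outside weather series") from None

    def window(self, start: dt.date, end: dt.date) -> "WeatherSeries":
        """Inclusive sub-series; raises if not fully covered."""
        if start < self.start or end > self.end:
            raise WeatherError(
                f"window {start}..{end} not covered by series "
                f"{self.start}..{self.end}"
            )
        return WeatherSeries(d for d in self._days if start <= d.date <= end)

    def years(self) -> list[int]:
        return sorted({d.date.year for d in self._days})

    def growing_season_total(self, year: int, months: tuple[int, int] = (5, 9)) -> float:
        lo, hi = months
        return sum(
            d.precip for d in self._days
            if d.date.year == year and lo <= d.date.month <= hi
        )

    def annual_totals(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for d in self._days:
            out[d.date.year] = out.get(d.date.year, 0.0) + d.precip
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.date.isoformat() for d in self._days],
                "tmax": [d.tmax for d in self._days],
                "tmin": [d.tmin for d in self._days],
                "srad": [d.srad for d in self._days],
                "precip": [d.precip for d in self._days],
                "rhum": [d.rhum for d in self._days],
                "wind": [d.wind for d in self._days],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WeatherSeries":
        days = []
        for row in frame.itertuples(index=False):
            rhum = getattr(row, "rhum", None)
            wind = getattr(row, "wind", None)
            days.append(
                WeatherDay(
                    date=dt.date.fromisoformat(str(row.date)[:10]),
                    tmax=float(row.tmax),
                    tmin=float(row.tmin),
                    srad=float(row.srad),
                    precip=float(row.precip),
                    rhum=None if rhum is None or pd.isna(rhum) else float(rhum),
                    wind=None if wind is None or pd.isna(wind) else float(wind),
                )
            )
        return cls(days)


@dataclass(frozen=True)
class HydroYearClass:
    """Wet / normal / dry label for one growing season."""

    label: str
    season_total_mm: float
    wet_threshold_mm: float
    dry_threshold_mm: float


@dataclass(frozen=True)
class ClimateSpec:
    """Parameters of the synthetic climate.

    Defaults reproduce the study region: seasonal mean-temperature sinusoid
    peaking around DOY 202 (annual mean 6.5 degC, amplitude 18.5 degC),
    monthly precipitation means summing to ~315 mm/yr with a July maximum,
    and radiation driven by clear-sky transmissivity ~0.70.
    """

    latitude_deg: float = reference.SITE_LATITUDE_DEG
    tmean_annual: float = 6.5
    tamp: float = 18.5
    tpeak_doy: float = 202.0
    tnoise_sd: float = 2.3
    tnoise_ar1: float = 0.65
    diurnal_range_mean: float = 11.5
    diurnal_range_sd: float = 2.0
    #: Jan..Dec mean monthly precipitation, mm.
    monthly_precip_mm: tuple[float, ...] = (
        2.0, 3.0, 7.0, 15.0, 26.0, 36.0, 112.0, 60.0, 30.0, 15.0, 6.0, 3.0)
    #: Jan..Dec mean number of precipitation events.
    monthly_event_rate: tuple[float, ...] = (
        1.0, 1.0, 2.0, 4.0, 5.0, 6.0, 10.0, 8.0, 5.0, 4.0, 2.0, 1.0)
    # heavy-tailed event sizes: summer rain arrives as a few large storms
    rain_gamma_shape: float = 0.7
    # Angstrom-derived: ~3254 sunshine h/yr gives n/N ~ 0.74 on dry days
    clear_transmissivity: float = 0.62
    wet_transmissivity: float = 0.35
    transmissivity_sd: float = 0.06

    def __post_init__(self):
        if len(self.monthly_precip_mm) != 12 or len(self.monthly_event_rate) != 12:
            raise WeatherError("monthly parameters must have 12 entries")
        if any(r < 0 for r in self.monthly_event_rate):
            raise WeatherError("negative event rate")
        if any(m < 0 for m in self.monthly_precip_mm):
            raise WeatherError("negative monthly precipitation")

    def annual_precip_mm(self) -> float:
        return float(sum(self.monthly_precip_mm))

    def july_september_share(self) -> float:
        """Expected July-September share of annual precipitation."""
        return sum(self.monthly_precip_mm[6:9]) / self.annual_precip_mm()

    def scaled_precip(self, factor: float) -> "ClimateSpec":
        return replace(
            self, monthly_precip_mm=tuple(m * factor for m in self.monthly_precip_mm)
        )


# --- astronomy ---------------------------------------------------------------

def solar_declination(doy: int) -> float:
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def sunset_hour_angle(latitude_deg: float, doy: int) -> float:
    phi = math.radians(latitude_deg)
    delta = solar_declination(doy)
    x = -math.tan(phi) * math.tan(delta)
    return math.acos(min(1.0, max(-1.0, x)))


def daylength_hours(latitude_deg: float, doy: int) -> float:
    """Astronomical daylength, hours."""
    return 24.0 / math.pi * sunset_hour_angle(latitude_deg, doy)


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra, MJ m-2 d-1 (FAO-56)."""
    phi = math.radians(latitude_deg)
    delta = solar_declination(doy)
    ws = sunset_hour_angle(latitude_deg, doy)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    return (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )


# --- synthetic generation ----------------------------------------------------

def generate_weather(
    spec: ClimateSpec,
    years: int,
    seed: int,
    start_year: int = 2000,
) -> WeatherSeries:
    """Generate ``years`` calendar years of daily weather, bit-reproducible
    for a fixed seed."""
    if years < 1:
        raise WeatherError("years must be >= 1")
    rng = np.random.default_rng(seed)
    days: list[WeatherDay] = []
    anomaly = 0.0
    innov_sd = spec.tnoise_sd * math.sqrt(max(1e-12, 1.0 - spec.tnoise_ar1 ** 2))
    for year in range(start_year, start_year + years):
        # plan precipitation events month by month
        precip_by_date: dict[dt.date, float] = {}
        for month in range(1, 13):
            rate = spec.monthly_event_rate[month - 1]
            mean_mm = spec.monthly_precip_mm[month - 1]
            if rate <= 0 or mean_mm <= 0:
                continue
            n_events = rng.poisson(rate)
            if n_events == 0:
                continue
            ndays = (dt.date(year + (month == 12), month % 12 + 1, 1)
                     - dt.date(year, month, 1)).days
            scale = mean_mm / (rate * spec.rain_gamma_shape)
            amounts = rng.gamma(spec.rain_gamma_shape, scale, size=n_events)
            event_days = rng.integers(1, ndays + 1, size=n_events)
            for d, amt in zip(event_days, amounts):
                date = dt.date(year, month, int(d))
                precip_by_date[date] = precip_by_date.get(date, 0.0) + float(amt)
        date = dt.date(year, 1, 1)
        while date.year == year:
            doy = date.timetuple().tm_yday
            seasonal = spec.tmean_annual + spec.tamp * math.cos(
                2.0 * math.pi * (doy - spec.tpeak_doy) / 365.0
            )
            anomaly = spec.tnoise_ar1 * anomaly + rng.normal(0.0, innov_sd)
            tavg = seasonal + anomaly
            drange = max(2.0, rng.normal(spec.diurnal_range_mean, spec.diurnal_range_sd))
            precip = precip_by_date.get(date, 0.0)
            wet = precip > 0.1
            if wet:
                drange *= 0.7
            tau = spec.wet_transmissivity if wet else spec.clear_transmissivity
            tau = min(0.80, max(0.10, tau + rng.normal(0.0, spec.transmissivity_sd)))
            srad = max(0.1, extraterrestrial_radiation(spec.latitude_deg, doy) * tau)
            rhum = min(98.0, max(20.0, rng.normal(82.0 if wet else 55.0, 7.0)))
            wind = float(min(10.0, max(0.3, rng.lognormal(math.log(2.0), 0.4))))
            days.append(
                WeatherDay(
                    date=date,
                    tmax=tavg + drange / 2.0,
                    tmin=tavg - drange / 2.0,
                    srad=srad,
                    precip=precip,
                    rhum=rhum,
                    wind=wind,
                )
            )
            date += dt.timedelta(days=1)
    return WeatherSeries(days)


def classify_hydro_year(
    season_total_mm: float,
    climatology: Sequence[float],
    wet_percentile: float = 75.0,
    dry_percentile: float = 25.0,
) -> HydroYearClass:
    """Classify a growing-season precipitation total against climatology.

    Empirical-frequency rule: totals at or above the ``wet_percentile`` of the
    climatology are wet, at or below the ``dry_percentile`` dry, else normal.
    Monotone: more rain never moves the label toward dry.
    """
    clim = np.asarray(list(climatology), dtype=float)
    if clim.size == 0:
        raise WeatherError("empty climatology")
    wet_thr = float(np.percentile(clim, wet_percentile))
    dry_thr = float(np.percentile(clim, dry_percentile))
    if season_total_mm >= wet_thr:
        label = "wet"
    elif season_total_mm <= dry_thr:
        label = "dry"
    else:
        label = "normal"
    return HydroYearClass(label, float(season_total_mm), wet_thr, dry_thr)


# --- FAO-56 reference evapotranspiration -------------------------------------

def _sat_vapor_pressure(t: float) -> float:
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def penman_monteith_et0(
    day: WeatherDay,
    elevation_m: float = reference.SITE_ELEVATION_M,
    latitude_deg: float = reference.SITE_LATITUDE_DEG,
) -> float:
    """FAO-56 daily reference evapotranspiration, mm/d.

    Missing humidity defaults to 60% and missing wind to 2 m/s (logged).
    The clear-sky ratio Rs/Rso is clipped to [0.3, 1.0].
    """
    if day.srad is None:
        raise WeatherError("radiation required for ET0")
    rhum = day.rhum
    wind = day.wind
    if rhum is None:
        log.warning("%s: humidity missing, assuming 60%%", day.date)
        rhum = 60.0
    if wind is None:
        log.warning("%s: wind missing, assuming 2 m/s", day.date)
        wind = 2.0
    t = (day.tmax + day.tmin) / 2.0
    delta = 4098.0 * _sat_vapor_pressure(t) / (t + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    es = (_sat_vapor_pressure(day.tmax) + _sat_vapor_pressure(day.tmin)) / 2.0
    ea = es * rhum / 100.0
    ra = extraterrestrial_radiation(latitude_deg, day.doy)
    rso = (0.75 + 2e-5 * elevation_m) * ra
    ratio = 0.3 if rso <= 0 else min(1.0, max(0.3, day.srad / rso))
    rns = (1.0 - 0.23) * day.srad
    rnl = (
        STEFAN_BOLTZMANN
        * (((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4) / 2.0)
        * (0.34 - 0.14 * math.sqrt(max(0.0, ea)))
        * (1.35 * ratio - 0.35)
    )
    rn = rns - rnl
    num = 0.408 * delta * rn + gamma * (900.0 / (t + 273.0)) * wind * (es - ea)
    et0 = num / (delta + gamma * (1.0 + 0.34 * wind))
    return max(0.0, et0)


# --- file I/O ----------------------------------------------------------------

def read_weather(path: str | Path, dialect: str = "csv") -> WeatherSeries:
    """Read a weather file.  ``dialect`` is 'csv' or 'dssat'.

    CSV columns: date,tmax,tmin,srad,precip[,rhum,wind].  DSSAT-style text has
    an @DATE SRAD TMAX TMIN RAIN header with YYDDD dates.  Date gaps raise
    :class:`WeatherError` naming the first missing date.
    """
    path = Path(path)
    if dialect == "csv":
        frame = pd.read_csv(path)
        required = {"date", "tmax", "tmin", "srad", "precip"}
        missing = required - set(frame.columns)
        if missing:
            raise WeatherError(f"{path}: missing columns {sorted(missing)}")
        return WeatherSeries.from_frame(frame)
    if dialect == "dssat":
        days = []
        header_cols: list[str] | None = None
        base_century = 2000
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("*", "!")):
                    continue
                if line.startswith("@"):
                    header_cols = line[1:].split()
                    continue
                if header_cols is None:
                    continue
                parts = line.split()
                if len(parts) < len(header_cols):
                    raise WeatherError(f"{path}:{lineno}: malformed row {line!r}")
                rec = dict(zip(header_cols, parts))
                yyddd = rec["DATE"]
                yy, ddd = int(yyddd[:2]), int(yyddd[2:])
                year = base_century + yy if yy < 70 else 1900 + yy
                date = dt.date(year, 1, 1) + dt.timedelta(days=ddd - 1)
                days.append(
                    WeatherDay(
                        date=date,
                        tmax=float(rec["TMAX"]),
                        tmin=float(rec["TMIN"]),
                        srad=float(rec["SRAD"]),
                        precip=float(rec["RAIN"]),
                    )
                )
        return WeatherSeries(days)
    raise WeatherError(f"unknown dialect {dialect!r}")


def write_weather(series: WeatherSeries, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        series.to_frame().to_csv(path, index=False)
        return
    if dialect == "dssat":
        with open(path, "w") as fh:
            fh.write("*WEATHER DATA : mulchsim synthetic station\n")
            fh.write("@DATE  SRAD  TMAX  TMIN  RAIN\n")
            for d in series:
                yyddd = f"{d.date.year % 100:02d}{d.doy:03d}"
                fh.write(
                    f"{yyddd}  {d.srad:5.1f} {d.tmax:5.1f} {d.tmin:5.1f} "
                    f"{d.precip:5.1f}\n"
                )
        return
    raise WeatherError(f"unknown dialect {dialect!r}")
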