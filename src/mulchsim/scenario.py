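"""Seasonal orchestration: weather -> film -> thermal -> soil water -> crop.

``run_season`` wires the component models into one daily loop for a single
treatment (BM60 / BM80 / BM100 = biodegradable film with a 60 / 80 / 100 day
induction period, or CK = bare soil) and returns the daily trace plus the
seasonal summary: effective precipitation, crop evapotranspiration, yield and
water-use efficiency.  ``run_matrix`` repeats this across years and
treatments and produces a prediction-table-shaped summary with
hydrological-year labels.

Irrigation follows the regional drip-irrigation recommendation (seasonal
total 183 mm in normal/dry years, 105 mm in wet years) split over eight
events patterned on the field records; metered depths are divided by the
wetted-width fraction (film width / tape spacing = 70/120) to express them on
the near-tape soil column the one-dimensional model represents.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import crop, film, reference, soilwater, thermal, weather

log = logging.getLogger(__name__)

TREATMENT_INDUCTION = {"BM60": 60, "BM80": 80, "BM100": 100, "CK": None}

#: Default irrigation event pattern: (day after sowing, weight) from the
#: 2016 field schedule (weights proportional to the metered depths).
DEFAULT_IRRIGATION_PATTERN = (
    (10, 30), (34, 30), (71, 30), (84, 15),
    (95, 10), (101, 20), (107, 20), (118, 20),
)

WETTED_FRACTION = reference.FILM_WIDTH_CM / reference.DRIP_TAPE_SPACING_CM


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One treatment-year simulation setup."""

    treatment: str = "BM60"
    sowing_doy: int = 119                 # late April
    max_season_days: int = 170
    irrigation_total_mm: float | None = None   # metered scale; None = by class
    irrigation_schedule: tuple[tuple[int, float], ...] | None = None
    genetics: crop.GeneticCoefficients = crop.GeneticCoefficients()
    crop_params: crop.CropParams = crop.CropParams()
    damage_params: film.DamageCurveParams = film.DamageCurveParams()
    density_per_ha: float = reference.PLANT_DENSITY_PER_HA
    initial_soil_fraction: float = 0.75
    wetted_fraction: float = WETTED_FRACTION
    wetting_depth_cm: float = 60.0
    drain_coeff: float = 0.35
    evap_alpha: float = 3.5
    evap_stage1_limit: float = 6.0
    rewet_threshold_mm: float = 10.0
    uptake_fraction: float = 0.10         # share of extractable water per day
    waterlog_threshold_frac: float = 0.2  # above fc, fraction of (sat - fc)
    waterlog_trigger_days: int = 3
    waterlog_penalty_per_day: float = 0.008
    pollination_rain_mm: float = 25.0     # storm size disrupting pollination
    pollination_penalty_per_day: float = 0.025
    excess_water_max_penalty: float = 0.5
    dta_max: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.treatment not in TREATMENT_INDUCTION:
            raise ScenarioError(f"unknown treatment {self.treatment!r}")

    @property
    def induction_period(self) -> int | None:
        return TREATMENT_INDUCTION[self.treatment]

    @property
    def mulched(self) -> bool:
        return self.induction_period is not None

    def schedule(self, total_mm: float) -> list[tuple[int, float]]:
        """Irrigation events as (day after sowing, metered depth mm)."""
        if self.irrigation_schedule is not None:
            return [(d, a) for d, a in self.irrigation_schedule]
        weight_sum = sum(w for _, w in DEFAULT_IRRIGATION_PATTERN)
        return [(d, total_mm * w / weight_sum) for d, w in DEFAULT_IRRIGATION_PATTERN]


@dataclass(frozen=True)
class SimulationResult:
    """Daily trace plus seasonal summary for one treatment-year."""

    config: ScenarioConfig
    trace: pd.DataFrame
    calendar: crop.PhenologyCalendar
    water_balance: soilwater.WaterBalance
    effective_precip_mm: float
    irrigation_input_mm: float
    gauge_precip_mm: float
    etc_total_mm: float
    yield_kg_ha: float
    wue: float
    waterlog_excess_days: int
    storm_tassel_days: int = 0
    hydro_class: weather.HydroYearClass | None = None


_STAGE_TO_COMP = {
    crop.Stage.SOWN: "sowing_to_emergence",
    crop.Stage.EMERGED: "emergence_to_elongation",
    crop.Stage.JUVENILE_END: "elongation_to_tasseling",
}


def run_season(
    config: ScenarioConfig,
    series: weather.WeatherSeries,
    year: int | None = None,
    hydro_class: weather.HydroYearClass | None = None,
) -> SimulationResult:
    """Simulate one sowing-to-maturity season.

    ``series`` must cover the whole season window.  CK (bare soil) runs with
    damage ratio 1, no temperature compensation, and gauge rainfall as
    effective rainfall.  Deterministic for identical inputs.
    """
    if year is None:
        year = series.start.year
    sowing = dt.date(year, 1, 1) + dt.timedelta(days=config.sowing_doy - 1)
    end = sowing + dt.timedelta(days=config.max_season_days - 1)
    season = series.window(sowing, min(end, series.end))
    if len(season) < config.max_season_days and season.end < end:
        log.debug("season window truncated at %s", season.end)

    if config.irrigation_total_mm is not None:
        irr_total = config.irrigation_total_mm
    elif hydro_class is not None:
        irr_total = reference.SEASONAL_IRRIGATION_MM[hydro_class.label]
    else:
        irr_total = reference.SEASONAL_IRRIGATION_MM["normal"]
    irrigation = dict(config.schedule(irr_total))

    film_spec = (
        film.FilmSpec(induction_period=config.induction_period)
        if config.mulched else None
    )
    comp = thermal.CompensationCoefficients.for_treatment(config.treatment)
    ck_early, ck_late = thermal.default_soil_temp_models("CK")
    trt_early, trt_late = thermal.default_soil_temp_models(
        config.treatment if config.mulched else "CK"
    )

    profile = soilwater.SoilProfile.xiliaohe_default(config.initial_soil_fraction)
    storage_start = profile.water_storage_mm()
    evap_state = soilwater.EvapState(
        alpha=config.evap_alpha, stage1_limit=config.evap_stage1_limit
    )
    state = crop.CropState()
    params = config.crop_params
    calendar: dict[str, int | None] = {k: None for k in
                                       crop.PhenologyCalendar().as_dict()}

    rows = []
    totals = {"pe": 0.0, "irr": 0.0, "precip": 0.0, "es": 0.0, "ep": 0.0,
              "drain": 0.0}
    waterlog_streak = 0
    waterlog_excess_days = 0
    storm_tassel_days = 0

    for das, wd in enumerate(season):
        # --- film damage
        if film_spec is not None:
            fd = film.damage_curve(das, film_spec, config.damage_params).fd
        else:
            fd = 1.0

        # --- temperature compensation
        if config.mulched and state.stage in _STAGE_TO_COMP:
            c = comp.for_stage(_STAGE_TO_COMP[state.stage])
            ck_model = ck_early if das <= 70 else ck_late
            trt_model = trt_early if das <= 70 else trt_late
            ts_bare = thermal.soil_temp_from_air(wd.tavg, ck_model)
            ts_film = thermal.soil_temp_from_air(wd.tavg, trt_model)
            tmax_f, tmin_f = thermal.compensate_air_temps(
                wd.tmax, wd.tmin, c, ts_film - ts_bare, wd.tavg, ts_bare,
                dta_max=config.dta_max,
            )
        else:
            tmax_f, tmin_f = wd.tmax, wd.tmin

        # --- water inputs
        if film_spec is not None:
            pe = film.effective_precip(wd.precip, fd,
                                       baseline_fd=config.damage_params.baseline_fd)
        else:
            pe = wd.precip
        irr_in = 0.0
        if das in irrigation:
            irr_in = irrigation[das] / config.wetted_fraction
            irr_fluxes = soilwater.water_balance_step(
                profile, irr_in, 0.0, 0.0,
                drain_coeff=config.drain_coeff,
                wetting_depth_cm=config.wetting_depth_cm,
            )
            totals["drain"] += irr_fluxes.drainage

        # --- evaporative demand and partition
        td = soilwater.approximate_mean_temp(tmax_f, tmin_f)
        eeq = soilwater.equilibrium_evap(wd.srad, albedo=0.23, td=td,
                                         langley_units=True)
        etp = soilwater.potential_et(eeq)
        fint = 1.0 - np.exp(-params.k_extinction * state.lai)
        es_pot = etp * (1.0 - fint)
        ep_pot = etp * fint

        evap_state, es_bare = soilwater.soil_evaporation_step(
            evap_state, es_pot, rewet_mm=pe + irr_in,
            rewet_threshold=config.rewet_threshold_mm,
        )
        es_demand = soilwater.mulch_scaled_evap(es_bare, fd)

        root_depth = 30.0 + 70.0 * min(1.0, state.cum_tt / 800.0)
        supply = config.uptake_fraction * soilwater.extractable_water_mm(
            profile, root_depth)
        stress = crop.water_stress(supply, ep_pot)
        ep_demand = min(ep_pot, supply)

        fluxes = soilwater.water_balance_step(
            profile, pe, es_demand, ep_demand,
            root_depth_cm=root_depth, drain_coeff=config.drain_coeff,
        )

        # --- waterlogging bookkeeping
        top = profile.layers[0]
        threshold = top.fc + config.waterlog_threshold_frac * (top.sat - top.fc)
        if top.swc > threshold:
            waterlog_streak += 1
            if waterlog_streak >= config.waterlog_trigger_days:
                waterlog_excess_days += 1
        else:
            waterlog_streak = 0
        if (state.stage in (crop.Stage.TASSELING, crop.Stage.SILKING)
                and wd.precip >= config.pollination_rain_mm):
            storm_tassel_days += 1

        # --- crop
        dtt = crop.daily_thermal_time(tmax_f, tmin_f, params.tb)
        prev_stage = state.stage
        dl = weather.daylength_hours(reference.SITE_LATITUDE_DEG, wd.doy)
        state = crop.advance_phenology(state, dtt, config.genetics, dl, params)
        if state.stage != prev_stage:
            name = {
                crop.Stage.EMERGED: "emergence",
                crop.Stage.JUVENILE_END: "juvenile_end",
                crop.Stage.TASSELING: "tasseling",
                crop.Stage.SILKING: "silking",
                crop.Stage.FILLING: "filling",
                crop.Stage.MATURE: "maturity",
            }[state.stage]
            calendar[name] = das + 1
        state = crop.update_lai(state, dtt, stress, config.genetics, params)
        state = crop.accrue_biomass(state, wd.srad, stress,
                                    tmax_f, tmin_f, params)
        state = crop.record_stress_bookkeeping(state, stress, config.genetics,
                                               params)

        totals["pe"] += pe
        totals["irr"] += irr_in
        totals["precip"] += wd.precip
        totals["es"] += fluxes.evaporation + (irr_fluxes.evaporation if irr_in else 0)
        totals["ep"] += fluxes.transpiration
        totals["drain"] += fluxes.drainage
        rows.append({
            "date": wd.date, "das": das, "stage": state.stage.name.lower(),
            "tmax_f": tmax_f, "tmin_f": tmin_f, "dtt": dtt, "fd": fd,
            "precip": wd.precip, "pe": pe, "irrigation": irr_in,
            "es": fluxes.evaporation, "ep": fluxes.transpiration,
            "drainage": fluxes.drainage + (irr_fluxes.drainage if irr_in else 0),
            "stress": stress, "lai": state.lai, "biomass": state.biomass,
            "topsoil_swc": top.swc,
            "storage_mm": profile.water_storage_mm(),
        })
        if state.stage == crop.Stage.MATURE:
            break

    storage_end = profile.water_storage_mm()
    delta_w = storage_end - storage_start
    etc_total = totals["es"] + totals["ep"]
    balance = soilwater.WaterBalance(
        irrigation=totals["irr"],
        effective_precip=totals["pe"],
        delta_storage=delta_w,
        drainage=totals["drain"],
        etc_total=etc_total,
    )

    if state.stage >= crop.Stage.FILLING and state.fill_days > 0:
        raw_yield = crop.yield_formation(
            state, config.genetics, config.density_per_ha, params=params)
    else:
        raw_yield = 0.0
    # excess-water yield emulation: prolonged topsoil saturation plus
    # storm interference with pollination around tasseling
    penalty = min(
        config.excess_water_max_penalty,
        config.waterlog_penalty_per_day * waterlog_excess_days
        + config.pollination_penalty_per_day * storm_tassel_days,
    )
    yield_kg = raw_yield * (1.0 - penalty)
    wue_val = soilwater.wue(yield_kg, etc_total) if etc_total > 0 else 0.0

    return SimulationResult(
        config=config,
        trace=pd.DataFrame(rows),
        calendar=crop.PhenologyCalendar(**calendar),
        water_balance=balance,
        effective_precip_mm=totals["pe"],
        irrigation_input_mm=totals["irr"],
        gauge_precip_mm=totals["precip"],
        etc_total_mm=etc_total,
        yield_kg_ha=yield_kg,
        wue=wue_val,
        waterlog_excess_days=waterlog_excess_days,
        storm_tassel_days=storm_tassel_days,
        hydro_class=hydro_class,
    )


def run_matrix(
    series: weather.WeatherSeries,
    treatments: tuple[str, ...] = ("BM60", "BM80", "BM100", "CK"),
    years: list[int] | None = None,
    climatology: list[float] | None = None,
    base_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Run every (year, treatment) pair and summarize.

    Years are classified wet/normal/dry against ``climatology`` (defaults to
    the growing-season totals of the series itself) and receive the
    corresponding seasonal irrigation total.
    """
    if years is None:
        years = [y for y in series.years()
                 if dt.date(y, 1, 1) >= series.start
                 and dt.date(y, 12, 31) <= series.end]
    if not years:
        raise ScenarioError("no complete years in weather series")
    if climatology is None:
        climatology = [series.growing_season_total(y) for y in years]
    rows = []
    for year in years:
        total = series.growing_season_total(year)
        hydro = weather.classify_hydro_year(total, climatology)
        for trt in treatments:
            cfg = (replace(base_config, treatment=trt) if base_config
                   else ScenarioConfig(treatment=trt))
            res = run_season(cfg, series, year=year, hydro_class=hydro)
            rows.append({
                "year": year,
                "treatment": trt,
                "hydro_class": hydro.label,
                "season_precip_mm": total,
                "effective_precip_mm": res.effective_precip_mm,
                "irrigation_input_mm": res.irrigation_input_mm,
                "etc_mm": res.etc_total_mm,
                "yield_kg_ha": res.yield_kg_ha,
                "wue": res.wue,
                "waterlog_days": res.waterlog_excess_days,
                "storm_tassel_days": res.storm_tassel_days,
            })
    return pd.DataFrame(rows)


def wet_normal_experiment(
    seed: int,
    n_years: int = 3,
    normal_total_mm: float = 250.0,
    wet_total_mm: float = 415.0,
    climatology_years: int = 30,
    treatments: tuple[str, ...] = ("BM60", "BM80", "BM100"),
    base_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Matched-pair hydrological-year experiment.

    For each of ``n_years`` synthetic years, the same daily weather is run
    twice: once with the growing-season precipitation rescaled to a typical
    normal-year total (~250 mm) and once rescaled to a wet-year total
    (~415 mm, the observed wet-season benchmark).  Temperatures, radiation
    and event days are identical within a pair, so differences isolate the
    hydrological-year effect.  Each member is classified against a
    separately generated climatology and irrigated accordingly (183 mm
    normal / 105 mm wet, metered scale).

    Returns one row per (year, scenario, treatment).
    """
    spec = weather.ClimateSpec()
    clim_series = weather.generate_weather(
        spec, climatology_years, seed=seed + 10_000, start_year=1980)
    climatology = [clim_series.growing_season_total(y)
                   for y in range(1980, 1980 + climatology_years)]
    rows = []
    for k in range(n_years):
        year_seed = seed + k
        base = weather.generate_weather(spec, 1, seed=year_seed, start_year=2019)
        total0 = base.growing_season_total(2019)
        if total0 <= 0:
            raise ScenarioError("degenerate precipitation draw")
        for label, target in (("normal", normal_total_mm), ("wet", wet_total_mm)):
            scaled = weather.generate_weather(
                spec.scaled_precip(target / total0), 1,
                seed=year_seed, start_year=2019)
            hydro = weather.classify_hydro_year(
                scaled.growing_season_total(2019), climatology)
            for trt in treatments:
                cfg = (replace(base_config, treatment=trt) if base_config
                       else ScenarioConfig(treatment=trt))
                res = run_season(cfg, scaled, year=2019, hydro_class=hydro)
                rows.append({
                    "year_index": k,
                    "scenario": label,
                    "hydro_class": hydro.label,
                    "treatment": trt,
                    "season_precip_mm": scaled.growing_season_total(2019),
                    "effective_precip_mm": res.effective_precip_mm,
                    "etc_mm": res.etc_total_mm,
                    "yield_kg_ha": res.yield_kg_ha,
                    "wue": res.wue,
                    "waterlog_days": res.waterlog_excess_days,
                    "storm_tassel_days": res.storm_tassel_days,
                })
    return pd.DataFrame(rows)


def glue_recovery_runner(
    series_list: list[weather.WeatherSeries],
    base_config: ScenarioConfig | None = None,
    lai_days: tuple[int, ...] = tuple(range(20, 141, 10)),
):
    """Build a deterministic GLUE runner over (p1, p5).

    The runner simulates each weather year with the candidate juvenile-phase
    (P1) and grain-fill (P5) thermal-time coefficients and returns the
    observable summaries a field campaign would record: the LAI trajectory
    sampled every ten days and the tasseling / fill-start / maturity dates
    (days after sowing).  Grain yield is deliberately not scored: its
    inter-annual range is comparable to realistic measurement noise, so in a
    range-normalized likelihood it contributes noise rather than constraint.
    """
    cfg = base_config or ScenarioConfig(treatment="BM60")

    def runner(params: dict[str, float]):
        genetics = crop.GeneticCoefficients(
            p1=params["p1"], p5=params["p5"],
            p2=cfg.genetics.p2, phint=cfg.genetics.phint,
            g2=cfg.genetics.g2, g3=cfg.genetics.g3,
        )
        c = replace(cfg, genetics=genetics)
        lai, phen = [], []
        for s in series_list:
            res = run_season(c, s)
            t = res.trace
            for d in lai_days:
                idx = min(d, len(t) - 1)
                lai.append(float(t.lai.iloc[idx]))
            cal = res.calendar
            phen.extend([float(cal.tasseling or 0), float(cal.filling or 0),
                         float(cal.maturity or len(t))])
        return {
            "lai": np.asarray(lai),
            "phenology_das": np.asarray(phen),
        }

    return runner


def parameter_recovery_experiment(
    seed: int = 0,
    n_samples: int = 500,
    n_years: int = 4,
    noise: float = 0.05,
    true_p1: float | None = None,
    true_p5: float | None = None,
) -> dict[str, float]:
    """Synthetic-truth GLUE recovery of the P1 and P5 thermal-time coefficients.

    Observations (LAI trajectory, phenology dates, yield over ``n_years``
    synthetic seasons) are generated from the known cultivar coefficients,
    perturbed with ``noise`` (5% default) multiplicative Gaussian noise, and
    the calibration must find P1 and P5 again from wide uniform priors.
    Returns truth, best estimates, and relative errors in percent.
    """
    from . import evaluate

    true_p1 = crop.GeneticCoefficients().p1 if true_p1 is None else true_p1
    true_p5 = crop.GeneticCoefficients().p5 if true_p5 is None else true_p5
    series_list = [
        weather.generate_weather(weather.ClimateSpec(), 1,
                                 seed=seed + 200 + i, start_year=2019)
        for i in range(n_years)
    ]
    runner = glue_recovery_runner(series_list)
    truth = runner({"p1": true_p1, "p5": true_p5})
    rng = np.random.default_rng(seed)
    observations = {
        k: v * (1.0 + noise * rng.standard_normal(v.shape))
        for k, v in truth.items()
    }
    config = evaluate.GlueConfig(
        priors={"p1": (120.0, 280.0), "p5": (600.0, 1100.0)},
        n_samples=n_samples,
        seed=seed,
    )
    result = evaluate.glue_calibrate(runner, config, observations)
    p1_hat = result.best_params["p1"]
    p5_hat = result.best_params["p5"]
    return {
        "true_p1": true_p1,
        "true_p5": true_p5,
        "p1_estimate": p1_hat,
        "p5_estimate": p5_hat,
        "p1_error_pct": abs(p1_hat - true_p1) / true_p1 * 100.0,
        "p5_error_pct": abs(p5_hat - true_p5) / true_p5 * 100.0,
        "best_score": result.best_score,
    }


def scenario_config_from_yaml(path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from a YAML file.

    Top-level keys map to ScenarioConfig fields; the nested blocks
    ``genetics``, ``crop`` and ``damage`` map to the genetic coefficients,
    crop parameters and film damage-curve parameters.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ScenarioError("scenario config must be a mapping")
    genetics = crop.GeneticCoefficients(**(data.pop("genetics", None) or {}))
    crop_params = crop.CropParams(**(data.pop("crop", None) or {}))
    damage = film.DamageCurveParams(**(data.pop("damage", None) or {}))
    if "irrigation_schedule" in data and data["irrigation_schedule"] is not None:
        data["irrigation_schedule"] = tuple(
            (int(d), float(a)) for d, a in data["irrigation_schedule"])
    try:
        return ScenarioConfig(genetics=genetics, crop_params=crop_params,
                              damage_params=damage, **data)
    except TypeError as exc:
        raise ScenarioError(f"bad scenario config: {exc}") from None
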