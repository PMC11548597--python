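"""Simplified CERES-like spring-maize engine.

Phenology is driven by thermal time above the 8 degC base temperature using
the six CERES genetic coefficients: P1 (juvenile-phase thermal time), P2
(photoperiod sensitivity above 12.5 h), P5 (silking-to-maturity thermal
time), PHINT (phyllochron), G2 (potential kernels per plant) and G3 (kernel
fill rate).  Leaf area expands one increment per phyllochron scaled by water
stress, peaks at silking and senesces thereafter.  Biomass accrues by
radiation-use efficiency on intercepted PAR.  Grain is kernel-limited
(G2 x G3 x effective fill days x density) and capped by a maximum harvest
index on accumulated biomass.

This is deliberately a compact engine, not a CERES port: no nitrogen cycling
(the field experiments fertilized to non-limiting levels), no detailed
photosynthesis, and a single linear photoperiod hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum

from . import reference

BASE_TEMPERATURE_C = 8.0


class CropError(ValueError):
    """Invalid crop state or parameter."""


class Stage(IntEnum):
    SOWN = 0
    EMERGED = 1
    JUVENILE_END = 2   # ~ elongation / jointing
    TASSELING = 3
    SILKING = 4
    FILLING = 5
    MATURE = 6


@dataclass(frozen=True)
class GeneticCoefficients:
    p1: float = reference.GENETIC_NONGHUA106["p1"]        # degC d
    p2: float = reference.GENETIC_NONGHUA106["p2"]        # d per h
    p5: float = reference.GENETIC_NONGHUA106["p5"]        # degC d
    phint: float = reference.GENETIC_NONGHUA106["phint"]  # degC d
    g2: float = reference.GENETIC_NONGHUA106["g2"]        # kernels/plant
    g3: float = reference.GENETIC_NONGHUA106["g3"]        # mg/kernel/d

    def __post_init__(self):
        if min(self.p1, self.p2, self.p5, self.phint, self.g2, self.g3) <= 0:
            raise CropError("genetic coefficients must be positive")


@dataclass(frozen=True)
class CropParams:
    """Engine defaults calibrated to the study cultivar and climate.

    tt_emergence reproduces the observed ~16-day sowing-to-emergence interval
    under compensated early-May temperatures; tassel_tt sets the
    elongation-to-tasseling span; rue is radiation-use efficiency on
    intercepted PAR (g/MJ); hi_max caps grain at a maximum harvest index.
    """

    tb: float = BASE_TEMPERATURE_C
    tt_emergence: float = 110.0      # degC d, sowing -> emergence
    tassel_tt: float = 620.0         # degC d, juvenile end -> tasseling
    silking_tt: float = 60.0         # degC d, tasseling -> silking
    fill_lag_tt: float = 280.0       # degC d, silking -> grain fill start
    photoperiod_threshold_h: float = 12.5
    lai_per_leaf: float = 0.22      # LAI increment per phyllochron
    senescence_per_leaf: float = 0.25
    rue: float = 3.0                 # g dry matter per MJ intercepted PAR
    par_fraction: float = 0.5        # PAR share of global radiation
    k_extinction: float = 0.65
    hi_max: float = 0.55
    silking_stress_window_tt: float = 170.0  # degC d around silking


@dataclass(frozen=True)
class CropState:
    stage: Stage = Stage.SOWN
    day_after_sowing: int = 0
    cum_tt: float = 0.0          # thermal time since sowing
    phase_tt: float = 0.0        # thermal time within the current phase
    leaf_number: float = 0.0
    lai: float = 0.0
    biomass: float = 0.0         # kg/ha
    grain: float = 0.0           # kg/ha
    stress: float = 1.0          # today's water-stress index [0, 1]
    photoperiod_delay_tt: float = 0.0
    silking_stress_sum: float = 0.0
    silking_stress_n: int = 0
    fill_stress_sum: float = 0.0
    fill_days: int = 0

    def __post_init__(self):
        if self.lai < 0:
            raise CropError("LAI cannot be negative")
        if self.grain > self.biomass + 1e-6:
            raise CropError("grain exceeds biomass")


@dataclass(frozen=True)
class PhenologyCalendar:
    """Day-after-sowing of each stage transition (None if not reached)."""

    emergence: int | None = None
    juvenile_end: int | None = None
    tasseling: int | None = None
    silking: int | None = None
    filling: int | None = None
    maturity: int | None = None

    def as_dict(self) -> dict[str, int | None]:
        return {
            "emergence": self.emergence,
            "juvenile_end": self.juvenile_end,
            "tasseling": self.tasseling,
            "silking": self.silking,
            "filling": self.filling,
            "maturity": self.maturity,
        }


def daily_thermal_time(tmax_f: float, tmin_f: float,
                       tb: float = BASE_TEMPERATURE_C) -> float:
    """Growing degree days: max(0, mean temperature - base temperature)."""
    if tmax_f < tmin_f:
        raise CropError("tmax < tmin")
    return max(0.0, (tmax_f + tmin_f) / 2.0 - tb)


def water_stress(supply: float, demand: float) -> float:
    """Soil-water supply/demand stress index in [0, 1] (1 = unstressed)."""
    if demand < 0:
        raise CropError("negative transpiration demand")
    if demand == 0:
        return 1.0
    return min(1.0, max(0.0, supply / demand))


def _phase_threshold(state: CropState, coeffs: GeneticCoefficients,
                     params: CropParams) -> float:
    if state.stage == Stage.SOWN:
        return params.tt_emergence
    if state.stage == Stage.EMERGED:
        return coeffs.p1
    if state.stage == Stage.JUVENILE_END:
        return params.tassel_tt + state.photoperiod_delay_tt
    if state.stage == Stage.TASSELING:
        return params.silking_tt
    if state.stage == Stage.SILKING:
        return params.fill_lag_tt
    if state.stage == Stage.FILLING:
        # silking -> maturity spans P5 in total
        return coeffs.p5 - params.fill_lag_tt
    return math.inf


def advance_phenology(
    state: CropState,
    dtt: float,
    coeffs: GeneticCoefficients,
    daylength_h: float = 12.0,
    params: CropParams = CropParams(),
) -> CropState:
    """Accumulate one day of thermal time and apply stage transitions.

    The photoperiod delay P2 * max(daylength - 12.5, 0) days is converted to
    thermal time at the current daily rate when the juvenile phase ends, and
    lengthens the pre-tasseling phase.  Silking-to-maturity spans P5.
    """
    if dtt < 0:
        raise CropError("negative thermal time")
    phase_tt = state.phase_tt + dtt
    new = replace(
        state,
        day_after_sowing=state.day_after_sowing + 1,
        cum_tt=state.cum_tt + dtt,
        phase_tt=phase_tt,
    )
    threshold = _phase_threshold(state, coeffs, params)
    if phase_tt >= threshold and state.stage < Stage.MATURE:
        next_stage = Stage(state.stage + 1)
        carry = phase_tt - threshold
        delay_tt = state.photoperiod_delay_tt
        if next_stage == Stage.JUVENILE_END:
            delay_days = coeffs.p2 * max(0.0, daylength_h
                                         - params.photoperiod_threshold_h)
            delay_tt = delay_days * max(dtt, 1e-9)
        new = replace(new, stage=next_stage, phase_tt=carry,
                      photoperiod_delay_tt=delay_tt)
    return new


def update_lai(
    state: CropState,
    dtt: float,
    stress: float,
    coeffs: GeneticCoefficients,
    params: CropParams = CropParams(),
) -> CropState:
    """Leaf-area dynamics: phyllochron-paced expansion scaled by stress
    before silking, linear senescence afterwards.  Unimodal in time."""
    if not 0.0 <= stress <= 1.0:
        raise CropError("stress index outside [0, 1]")
    lai = state.lai
    leaves = state.leaf_number
    if Stage.EMERGED <= state.stage < Stage.SILKING:
        increment = dtt / coeffs.phint
        leaves += increment
        lai += increment * params.lai_per_leaf * stress
    elif state.stage >= Stage.SILKING and state.stage < Stage.MATURE:
        lai -= (dtt / coeffs.phint) * params.senescence_per_leaf
    lai = max(0.0, lai)
    return replace(state, lai=lai, leaf_number=leaves, stress=stress)


def photosynthesis_temp_factor(tmax: float, tmin: float) -> float:
    """CERES-style photosynthesis temperature factor PRFT in [0, 1].

    1 - 0.0025 * (Tday - 26)^2 with the daytime temperature weighted
    0.25*Tmin + 0.75*Tmax; optimal near 26 degC, zero at +/-20 degC away.
    """
    tday = 0.25 * tmin + 0.75 * tmax
    return max(0.0, 1.0 - 0.0025 * (tday - 26.0) ** 2)


def accrue_biomass(
    state: CropState,
    srad: float,
    stress: float,
    tmax: float = 26.0,
    tmin: float = 26.0,
    params: CropParams = CropParams(),
) -> CropState:
    """Radiation-use-efficiency biomass accrual on intercepted PAR, kg/ha."""
    if state.stage < Stage.EMERGED or state.stage >= Stage.MATURE:
        return state
    fint = 1.0 - math.exp(-params.k_extinction * state.lai)
    prft = photosynthesis_temp_factor(tmax, tmin)
    growth_g_m2 = params.rue * params.par_fraction * srad * fint * stress * prft
    return replace(state, biomass=state.biomass + growth_g_m2 * 10.0)


def record_stress_bookkeeping(
    state: CropState,
    stress: float,
    coeffs: GeneticCoefficients,
    params: CropParams = CropParams(),
) -> CropState:
    """Track stress around silking (kernel set) and during grain fill."""
    new = state
    if state.stage in (Stage.TASSELING, Stage.SILKING):
        new = replace(new,
                      silking_stress_sum=new.silking_stress_sum + stress,
                      silking_stress_n=new.silking_stress_n + 1)
    if state.stage == Stage.FILLING:
        new = replace(new,
                      fill_stress_sum=new.fill_stress_sum + stress,
                      fill_days=new.fill_days + 1)
    return new


def yield_formation(
    state: CropState,
    coeffs: GeneticCoefficients,
    density_per_ha: float = reference.PLANT_DENSITY_PER_HA,
    mean_fill_stress: float | None = None,
    params: CropParams = CropParams(),
) -> float:
    """Grain yield, kg/ha.

    Kernels per plant are G2 scaled by mean stress around silking; grain is
    kernels x G3 (mg/kernel/d) x effective fill days x density, where
    effective fill days are stress-weighted calendar days of grain fill; the
    total is capped at hi_max x accumulated biomass.
    """
    if state.stage < Stage.FILLING:
        raise CropError("yield requested before grain fill")
    silking_factor = (state.silking_stress_sum / state.silking_stress_n
                      if state.silking_stress_n else 1.0)
    kernels = coeffs.g2 * silking_factor
    if mean_fill_stress is None:
        eff_fill_days = state.fill_stress_sum
    else:
        eff_fill_days = mean_fill_stress * state.fill_days
    grain = kernels * coeffs.g3 * eff_fill_days * density_per_ha * 1e-6
    return min(grain, params.hi_max * state.biomass)
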