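"""Layered soil-water balance, drip-irrigation correction, and evaporation.

The soil is a tipping-bucket cascade of layers bounded by wilting point and
saturation.  Water between field capacity and saturation drains downward with
a daily drainage coefficient; excess above saturation cascades immediately.
Bottom-layer outflow is deep drainage D.  Groundwater rise and surface runoff
are neglected (deep water table, leveled drip-irrigated field), so seasonal
crop evapotranspiration closes as ETc = I + Pe - dW - D.

Potential evaporative demand uses the Priestley-Taylor equilibrium rate
(ETp = 1.1 x EEQ).  Soil evaporation follows the Ritchie two-stage scheme:
stage I at the potential rate until the cumulative stage-I limit U, then
stage II where cumulative evaporation grows as alpha * sqrt(t); mulch reduces
soil evaporation by the film damage ratio (an intact film nearly shuts it
off).  Drip irrigation is localized, so metered depths are corrected to the
wetted strip via before/after moisture readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from . import reference

#: MJ m-2 to langley (cal cm-2): 1 langley = 0.04184 MJ m-2.
MJ_TO_LANGLEY = 1.0 / 0.04184


class SoilWaterError(ValueError):
    """Invalid soil or water-balance input."""


# --- soil profile ------------------------------------------------------------

@dataclass
class SoilLayer:
    top_cm: float
    bottom_cm: float
    clay: float
    silt: float
    sand: float
    fc: float   # field capacity, cm3/cm3
    sat: float  # saturated water content, cm3/cm3
    wp: float   # wilting point, cm3/cm3
    bd: float   # bulk density, g/cm3
    swc: float = 0.0  # state: volumetric water content, cm3/cm3

    def __post_init__(self):
        if not (self.wp < self.fc < self.sat):
            raise SoilWaterError("layer requires wp < fc < sat")
        texture = self.clay + self.silt + self.sand
        if abs(texture - 100.0) > 0.5:
            raise SoilWaterError(f"texture fractions sum to {texture}, not 100")
        if self.swc == 0.0:
            self.swc = self.fc  # default initial state
        if not (self.wp - 1e-9 <= self.swc <= self.sat + 1e-9):
            raise SoilWaterError("swc outside [wp, sat]")

    @property
    def thickness_mm(self) -> float:
        return (self.bottom_cm - self.top_cm) * 10.0

    @property
    def water_mm(self) -> float:
        return self.swc * self.thickness_mm


class SoilProfile:
    """Ordered stack of :class:`SoilLayer` (surface first)."""

    def __init__(self, layers: list[SoilLayer]):
        if not layers:
            raise SoilWaterError("profile needs at least one layer")
        for upper, lower in zip(layers, layers[1:]):
            if abs(upper.bottom_cm - lower.top_cm) > 1e-9:
                raise SoilWaterError("layers must be contiguous")
        self.layers = layers

    @classmethod
    def xiliaohe_default(cls, initial_fraction: float = 0.75) -> "SoilProfile":
        """Study-site 0-1 m profile; initial water a fraction of fc-wp above wp."""
        layers = []
        for top, bot, clay, silt, sand, fc, sat, wp, bd in reference.SOIL_PROFILE_ROWS:
            swc = wp + initial_fraction * (fc - wp)
            layers.append(SoilLayer(top, bot, clay, silt, sand, fc, sat, wp, bd, swc))
        return cls(layers)

    def copy(self) -> "SoilProfile":
        return SoilProfile([replace(l) for l in self.layers])

    @property
    def depth_cm(self) -> float:
        return self.layers[-1].bottom_cm

    def water_storage_mm(self, to_depth_cm: float | None = None) -> float:
        total = 0.0
        for l in self.layers:
            if to_depth_cm is not None and l.top_cm >= to_depth_cm:
                break
            total += l.water_mm
        return total

    def topsoil_swc(self) -> float:
        return self.layers[0].swc


# --- irrigation correction ---------------------------------------------------

def correct_irrigation(theta_before: float, theta_after: float, h_m: float) -> float:
    """Actual irrigation depth near the drip tape, mm: 1000 * dTheta * H.

    theta readings are volumetric (cm3/cm3); H is the wetted soil depth in m.
    """
    if h_m <= 0:
        raise SoilWaterError("wetted depth must be positive")
    if theta_after < theta_before:
        raise SoilWaterError("moisture reading decreased across irrigation")
    return 1000.0 * (theta_after - theta_before) * h_m


# --- Priestley-Taylor demand -------------------------------------------------

def equilibrium_evap(
    srad: float,
    albedo: float = 0.23,
    td: float = 20.0,
    langley_units: bool = False,
) -> float:
    """Equilibrium evaporation rate EEQ = SLANG*(2.04e-4 - 1.83e-4*ALBEDO)*(TD+29).

    The coefficients descend from the langley-based Priestley-Taylor form;
    with ``langley_units=True`` the MJ m-2 d-1 radiation input is converted to
    langleys first, which yields physically realistic mm/d magnitudes.
    """
    if srad < 0:
        raise SoilWaterError("negative radiation")
    slang = srad * MJ_TO_LANGLEY if langley_units else srad
    return slang * (2.04e-4 - 1.83e-4 * albedo) * (td + 29.0)


def approximate_mean_temp(tmax_f: float, tmin_f: float) -> float:
    """Daytime-weighted mean temperature TD = 0.6*Tmax + 0.4*Tmin, degC."""
    if tmax_f < tmin_f:
        raise SoilWaterError("tmax < tmin")
    return 0.6 * tmax_f + 0.4 * tmin_f


def potential_et(eeq: float) -> float:
    """Potential evapotranspiration: 1.1 x the equilibrium rate."""
    if eeq < 0:
        raise SoilWaterError("negative equilibrium evaporation")
    return 1.1 * eeq


# --- Ritchie two-stage soil evaporation --------------------------------------

@dataclass(frozen=True)
class EvapState:
    """Two-stage soil-evaporation state within a drying cycle."""

    stage: str = "I"              # "I" constant-rate, "II" falling-rate
    cum_stage1: float = 0.0       # mm evaporated in stage I since last rewet
    time_in_stage2: int = 0       # days since entering stage II
    alpha: float = 3.5            # soil hydraulic parameter, mm d^-0.5
    stage1_limit: float = 6.0     # U, mm

    def __post_init__(self):
        if self.cum_stage1 < 0 or self.time_in_stage2 < 0:
            raise SoilWaterError("negative evaporation state")


def soil_evaporation_step(
    state: EvapState,
    potential_es: float,
    rewet_mm: float = 0.0,
    rewet_threshold: float = 10.0,
) -> tuple[EvapState, float]:
    """Advance one day of bare-soil evaporation.

    Stage I evaporates at the potential rate until the cumulative stage-I
    limit U is reached, then stage II follows the square-root law
    (cumulative = alpha*sqrt(t), daily = alpha*(sqrt(t)-sqrt(t-1))), still
    capped by the potential rate.  A water input of at least
    ``rewet_threshold`` mm resets the cycle to stage I.
    """
    if potential_es < 0:
        raise SoilWaterError("negative potential evaporation")
    if rewet_mm >= rewet_threshold:
        state = replace(state, stage="I", cum_stage1=0.0, time_in_stage2=0)
    if state.stage == "I":
        es = potential_es
        cum = state.cum_stage1 + es
        if cum >= state.stage1_limit:
            return replace(state, stage="II", cum_stage1=cum, time_in_stage2=0), es
        return replace(state, cum_stage1=cum), es
    t = state.time_in_stage2 + 1
    es = state.alpha * (math.sqrt(t) - math.sqrt(t - 1))
    es = min(es, potential_es)
    return replace(state, time_in_stage2=t), es


def mulch_scaled_evap(es: float, fd: float) -> float:
    """Soil evaporation under film: bare-soil rate scaled by the damage ratio."""
    if not 0.0 <= fd <= 1.0:
        raise SoilWaterError("fd must lie in [0, 1]")
    return es * fd


# --- daily water balance -----------------------------------------------------

@dataclass(frozen=True)
class WaterFluxes:
    """One day's realized water fluxes, mm."""

    inflow: float
    evaporation: float
    transpiration: float
    drainage: float
    delta_storage: float

    def closure_error(self) -> float:
        return (self.inflow - self.evaporation - self.transpiration
                - self.drainage - self.delta_storage)


def water_balance_step(
    profile: SoilProfile,
    inflow_mm: float,
    evap_demand_mm: float,
    transp_demand_mm: float,
    root_depth_cm: float = 100.0,
    drain_coeff: float = 0.5,
    wetting_depth_cm: float | None = None,
) -> WaterFluxes:
    """Advance the profile one day (in place) and return realized fluxes.

    Infiltration fills layers toward saturation from the top (restricted to
    ``wetting_depth_cm`` for localized irrigation when given); water above
    field capacity drains downward at ``drain_coeff`` per day; bottom outflow
    is deep drainage.  Evaporation draws on the surface layer and
    transpiration on layers within the root depth, both limited by water
    above wilting point.  The daily budget closes exactly.
    """
    if inflow_mm < 0 or evap_demand_mm < 0 or transp_demand_mm < 0:
        raise SoilWaterError("negative water-balance input")
    layers = profile.layers
    storage_before = profile.water_storage_mm()

    # 1. infiltrate: fill to saturation top-down, cascade the excess
    water = inflow_mm
    drainage = 0.0
    for l in layers:
        if wetting_depth_cm is not None and l.top_cm >= wetting_depth_cm:
            break
        if water <= 0:
            break
        room = (l.sat - l.swc) * l.thickness_mm
        taken = min(water, max(0.0, room))
        l.swc += taken / l.thickness_mm
        water -= taken
    drainage += water  # anything the (wetted) profile cannot hold

    # 2. gravity drainage of water held between fc and sat
    carry = 0.0
    for l in layers:
        if carry > 0:
            room = (l.sat - l.swc) * l.thickness_mm
            taken = min(carry, max(0.0, room))
            l.swc += taken / l.thickness_mm
            carry -= taken
        excess = max(0.0, (l.swc - l.fc) * l.thickness_mm)
        drained = excess * drain_coeff
        l.swc -= drained / l.thickness_mm
        carry += drained
    drainage += carry

    # 3. soil evaporation from the surface layer
    top = layers[0]
    avail = max(0.0, (top.swc - top.wp) * top.thickness_mm)
    es = min(evap_demand_mm, avail)
    top.swc -= es / top.thickness_mm

    # 4. transpiration extraction across the root zone, weighted by
    #    plant-available water
    avail_by_layer = []
    for l in layers:
        if l.top_cm >= root_depth_cm:
            avail_by_layer.append(0.0)
            continue
        depth_frac = min(1.0, (root_depth_cm - l.top_cm) / (l.bottom_cm - l.top_cm))
        avail_by_layer.append(max(0.0, (l.swc - l.wp) * l.thickness_mm) * depth_frac)
    total_avail = sum(avail_by_layer)
    ep = min(transp_demand_mm, total_avail)
    if ep > 0 and total_avail > 0:
        for l, a in zip(layers, avail_by_layer):
            take = ep * a / total_avail
            l.swc -= take / l.thickness_mm

    for l in layers:  # numerical guard
        l.swc = min(l.sat, max(l.wp, l.swc))

    storage_after = profile.water_storage_mm()
    delta = storage_after - storage_before
    # enforce exact closure by charging rounding residue to drainage
    residue = inflow_mm - es - ep - drainage - delta
    drainage += residue
    return WaterFluxes(
        inflow=inflow_mm,
        evaporation=es,
        transpiration=ep,
        drainage=drainage,
        delta_storage=delta,
    )


def extractable_water_mm(profile: SoilProfile, root_depth_cm: float) -> float:
    """Plant-available water (above wilting point) within the root zone, mm."""
    total = 0.0
    for l in profile.layers:
        if l.top_cm >= root_depth_cm:
            continue
        depth_frac = min(1.0, (root_depth_cm - l.top_cm) / (l.bottom_cm - l.top_cm))
        total += max(0.0, (l.swc - l.wp) * l.thickness_mm) * depth_frac
    return total


# --- seasonal closure and WUE ------------------------------------------------

@dataclass(frozen=True)
class WaterBalance:
    """Seasonal water balance, mm (ETc = I + Pe - dW - D by construction)."""

    irrigation: float
    effective_precip: float
    delta_storage: float
    drainage: float
    etc_total: float

    def closure_error(self) -> float:
        return self.etc_total - (
            self.irrigation + self.effective_precip
            - self.delta_storage - self.drainage
        )


def wue(yield_kg_ha: float, etc_total_mm: float) -> float:
    """Water use efficiency, kg per mm per ha: grain yield over seasonal ETc."""
    if etc_total_mm <= 0:
        raise SoilWaterError("ETc must be positive")
    if yield_kg_ha == 0:
        return 0.0
    return yield_kg_ha / etc_total_mm
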