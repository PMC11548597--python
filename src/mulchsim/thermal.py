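"""Air-to-soil temperature relations and mulch temperature compensation.

Plastic and biodegradable films warm the plough layer; the crop engine sees
this as an equivalent air-temperature increment ("temperature-increase
compensation").  The chain is:

1. Daily mean 5 cm soil temperature is a linear function of daily mean air
   temperature, with treatment-specific slopes (film regressions are steeper
   than bare soil).
2. Effective accumulated temperature Tcum sums daily positive exceedances of
   the maize base temperature Tb = 8 degC.
3. The stage-wise compensation coefficient C is the ratio of the film/bare
   difference in air thermal accumulation to the film/bare difference in soil
   thermal accumulation.
4. The daily increment dTa = C * dTs * (Ta - Tb) / (Ts - Tb) shifts both Tmax
   and Tmin, preserving the diurnal range.

C is largest from sowing to emergence (~1.5), decays through elongation and
tasseling, and is zero once the canopy closes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import reference

log = logging.getLogger(__name__)

BASE_TEMPERATURE_C = 8.0


class ThermalError(ValueError):
    """Degenerate thermal input (e.g. zero accumulation difference)."""


@dataclass(frozen=True)
class SoilTempModel:
    """Linear model ts = slope * ta + intercept for 5 cm soil temperature."""

    slope: float
    intercept: float
    period: str = "early"  # "early" = 0-70 d post-sowing, "late" = 71-140 d
    treatment: str = "CK"
    stderr: float | None = None

    def __post_init__(self):
        if self.slope <= 0:
            raise ThermalError("regression slope must be positive")


def default_soil_temp_models(
    treatment: str,
    early_intercept: float | None = None,
    late_intercept: float | None = None,
) -> tuple[SoilTempModel, SoilTempModel]:
    """(early, late) soil-temperature models with study-derived slopes.

    Regression intercepts were not published; defaults are chosen so that the
    mean 0-70 d film-vs-bare warming is ~2.65 degC at typical spring air
    temperatures (bare-soil intercept 2.0, film 3.2 early; 3.0 / 3.6 late).
    """
    early_slope, late_slope = reference.SOIL_TEMP_SLOPES[treatment]
    if treatment == "CK":
        b_early = 2.0 if early_intercept is None else early_intercept
        b_late = 3.0 if late_intercept is None else late_intercept
    else:
        b_early = 3.2 if early_intercept is None else early_intercept
        b_late = 3.6 if late_intercept is None else late_intercept
    return (
        SoilTempModel(early_slope, b_early, "early", treatment),
        SoilTempModel(late_slope, b_late, "late", treatment),
    )


def soil_temp_from_air(ta: float, model: SoilTempModel) -> float:
    """Predicted daily mean 5 cm soil temperature, degC."""
    return model.slope * ta + model.intercept


def fit_soil_temp_model(
    ta: np.ndarray,
    ts: np.ndarray,
    period: str = "early",
    treatment: str = "CK",
) -> SoilTempModel:
    """Least-squares fit of the soil-on-air temperature regression."""
    ta = np.asarray(ta, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if ta.size < 3 or ta.size != ts.size:
        raise ThermalError("need >= 3 paired temperature observations")
    res = stats.linregress(ta, ts)
    return SoilTempModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        period=period,
        treatment=treatment,
        stderr=float(res.stderr),
    )


@dataclass(frozen=True)
class ThermalAccumulation:
    """Effective accumulated temperature, degC d."""

    tcum: float
    n_days: int
    tb: float = BASE_TEMPERATURE_C

    def __post_init__(self):
        if self.tcum < -1e-9:
            raise ThermalError("effective accumulation cannot be negative")


def accumulate_effective_temp(
    temps: np.ndarray | list[float],
    tb: float = BASE_TEMPERATURE_C,
) -> ThermalAccumulation:
    """Sum of daily positive exceedances over the base temperature.

    Daily terms are floored at zero (effective-accumulation convention), so
    cold days never reduce the total.
    """
    arr = np.asarray(list(temps), dtype=float)
    if arr.size == 0:
        raise ThermalError("empty temperature series")
    tcum = float(np.maximum(arr - tb, 0.0).sum())
    return ThermalAccumulation(tcum=tcum, n_days=int(arr.size), tb=tb)


def compensation_coefficient(
    acc_air_nofilm: ThermalAccumulation,
    acc_air_film: ThermalAccumulation,
    acc_soil_film: ThermalAccumulation,
    acc_soil_nofilm: ThermalAccumulation,
) -> float:
    """Stage compensation coefficient C.

    C = (air accumulation under film - air accumulation bare)
        / (soil accumulation under film - soil accumulation bare).

    The soil difference is the warming signal; C converts it into the air
    scale.  A zero soil difference is a degenerate input.
    """
    soil_diff = acc_soil_film.tcum - acc_soil_nofilm.tcum
    air_diff = acc_air_film.tcum - acc_air_nofilm.tcum
    if abs(soil_diff) < 1e-12:
        raise ThermalError("zero soil accumulation difference")
    return air_diff / soil_diff


def compensate_air_temps(
    tmax: float,
    tmin: float,
    c: float,
    delta_ts: float,
    ta: float,
    ts: float,
    tb: float = BASE_TEMPERATURE_C,
    dta_max: float = 6.0,
) -> tuple[float, float]:
    """Shift (tmax, tmin) by the compensation increment dTa.

    dTa = C * dTs * (Ta - Tb) / (Ts - Tb), floored at 0 and capped at
    ``dta_max`` (the quotient blows up when bare-soil temperature nears the
    base temperature).  When Ts <= Tb the increment is defined as 0.
    """
    if ts <= tb:
        log.debug("Ts %.2f <= Tb %.2f: compensation set to 0", ts, tb)
        dta = 0.0
    else:
        dta = c * delta_ts * (ta - tb) / (ts - tb)
        dta = min(dta_max, max(0.0, dta))
    return tmax + dta, tmin + dta


#: Ordered growth stages over which C is defined.
COMPENSATION_STAGES = (
    "sowing_to_emergence",
    "emergence_to_elongation",
    "elongation_to_tasseling",
)


@dataclass(frozen=True)
class CompensationCoefficients:
    """Per-growth-stage compensation coefficients with base temperature."""

    by_stage: dict[str, float]
    tb: float = BASE_TEMPERATURE_C

    def __post_init__(self):
        for stage in COMPENSATION_STAGES:
            if stage not in self.by_stage:
                raise ThermalError(f"missing stage {stage!r}")
            if self.by_stage[stage] < 0:
                raise ThermalError("C must be >= 0 in warming stages")

    def for_stage(self, stage: str) -> float:
        """C for a stage; stages after tasseling default to 0."""
        return self.by_stage.get(stage, 0.0)

    @classmethod
    def for_treatment(cls, treatment: str) -> "CompensationCoefficients":
        """Study-mean coefficients for BM60/BM80/BM100; zeros for CK."""
        if treatment == "CK":
            return cls({s: 0.0 for s in COMPENSATION_STAGES})
        means = {
            stage: float(np.mean(vals))
            for stage, vals in reference.COMPENSATION_TABLE[treatment].items()
        }
        return cls(means)
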