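# Methods

This note documents the models in `mulchsim`, their assumptions, the
parameter defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## System and scope

The package simulates one growing season of spring maize (cultivar-level
CERES genetic coefficients, default Nonghua 106) on a four-layer, 1 m soil
profile under subsurface drip irrigation, either bare (CK) or covered by a
70 cm fully biodegradable film strip with an induction period of 60, 80 or
100 days (BM60/BM80/BM100). The site template is the Xiliaohe Plain
(44.1° N, 173.5 m a.s.l.): cold semi-arid, ~324 mm annual precipitation, over
60% of it July–September, maize sown in late April and harvested in late
September. Groundwater is ~8.5 m deep and the field is leveled, so capillary
rise and runoff are neglected; nitrogen is treated as non-limiting (the
reference experiments fertilized to sufficiency).

## Film damage

Damage ratio `Fd` is dimensionless in [0, 1] internally and only expressed
in percent at formula boundaries. Components:

- Planting-hole baseline: hemispherical hole area `2πr²` (r = 4 cm) times
  8.1 plants per 70 × 100 cm film strip gives `Fd ≈ 0.116`.
- Degradation: `Fd(t) = max(baseline, logistic(t − induction))` with midpoint
  33 d after induction and rate 0.0669 d⁻¹, solved from the field observation
  that damage exceeds 40–45% thirty days after the induction period. A
  standard logistic cannot have its midpoint at +25 d *and* pass 0.45 at
  +30 d (it is above 0.5 past the midpoint), hence the +33 d midpoint.
  `Fd(+120 d) ≈ 1`. Both parameters are config-exposed
  (`DamageCurveParams`).

## Effective rainfall

`Pe = P·λ/100` with the empirical quadratic
`λ = 54.7167 − 2.258P + 1.4297Fd + 0.0310P² − 0.0238Fd² + 0.045P·Fd`
(P in mm, Fd in percent), clamped to [0, 100] %. Two numerical decisions:

- **Neglect rule.** While `Fd` is within 0.02 of the intact baseline, rain is
  shed off the strip entirely (`Pe = 0`); the quadratic itself does not
  approach zero for intact film, so the rule is applied explicitly.
- **Monotone domain.** The fitted quadratic turns *down* in Fd beyond the
  ridge `Fd* = (1.4297 + 0.045P)/(2·0.0238) ≈ 30 + 0.95P`, which would make a
  fully degraded film absorb less rain than a half-degraded one — an artifact
  of extrapolating a regression outside its support. λ is held at its ridge
  value for `Fd > Fd*`. This makes seasonal effective rainfall monotone in
  film damage, and therefore the treatment ordering
  `Pe(BM60) ≥ Pe(BM80) ≥ Pe(BM100)` structural rather than statistical.

## Temperature compensation

Daily mean 5 cm soil temperature is linear in daily mean air temperature with
published slopes (bare 0.66/0.58 early/late; film 0.71–0.74 / 0.61–0.64).
The regression intercepts were not published; defaults (bare 2.0/3.0 °C,
film 3.2/3.6 °C) are set so the mean 0–70 d film–bare soil warming is
≈ 2.65 °C at spring air temperatures, the reported magnitude. The early/late
boundary is day 70 after sowing (config).

The compensation coefficient uses the consistent subscript reading
`C = (Tcum,air,film − Tcum,air,bare)/(Tcum,soil,film − Tcum,soil,bare)` with
effective accumulations `Σ max(Tᵢ − Tb, 0)`, `Tb = 8 °C` (daily terms floored
at zero). Stage defaults are the published five-year means: ~1.5 sowing →
emergence; 0.36/0.40/0.42 emergence → elongation and 0.11/0.14/0.18
elongation → tasseling for BM60/BM80/BM100; 0 afterwards.

The daily increment `ΔTa = C·ΔTs·(Ta − Tb)/(Ts − Tb)` shifts `Tmax` and
`Tmin` equally (diurnal range preserved). The quotient is singular as the
bare-soil temperature approaches `Tb`; `ΔTa` is floored at 0 and capped at
6 °C (config `dta_max`) as a numerical safeguard — without the cap a single
cool spring day can receive a >10 °C increment.

## Evaporative demand and soil evaporation

Equilibrium evaporation uses the radiation form
`EEQ = SLANG·(2.04·10⁻⁴ − 1.83·10⁻⁴·ALBEDO)·(TD + 29)`, with
`TD = 0.6·Tmax + 0.4·Tmin` and albedo 0.23. The coefficients descend from
the langley-era Priestley–Taylor implementation; evaluated directly with
radiation in MJ m⁻² d⁻¹ the formula yields ~0.17 mm/d on a midsummer day,
three orders of magnitude too small. The function therefore carries a
`langley_units` flag (1 MJ m⁻² = 23.9 langley); the scenario engine enables
it, giving ~4–5 mm/d midsummer equilibrium rates. `ETp = 1.1·EEQ`.

Potential demand is partitioned by canopy light interception
(`1 − exp(−k·LAI)`, k = 0.65) into soil evaporation and transpiration.
Soil evaporation follows Ritchie's two stages: stage I at the potential rate
until cumulative stage-I evaporation reaches `U` (default 6 mm, config);
stage II with cumulative evaporation `α√t` (α default 3.5 mm d⁻⁰·⁵), daily
`α(√t − √(t−1))`, capped by the potential rate; a daily water input of
≥ 10 mm resets the cycle to stage I. Under film the bare-soil rate is scaled
by `Fd` — an intact film nearly shuts evaporation off, a fully damaged one
leaves it unchanged.

Reference ET (reporting only, not used by the engine) is standard FAO-56
Penman–Monteith with the clear-sky ratio clipped to [0.3, 1.0].

## Soil water balance

Tipping-bucket cascade over the published layer table (field capacity,
saturation, wilting point per layer). Infiltration fills layers toward
saturation top-down; water held between field capacity and saturation drains
to the next layer at `drain_coeff` (default 0.35 d⁻¹ — the 20–70 cm layers
are silty-clay; 1.0 recovers an instant cascade); bottom outflow is deep
drainage. Evaporation draws the surface layer and transpiration the root
zone (roots grow 30 → 100 cm with thermal time), both bounded by water above
wilting point. Every daily step closes `inflow − Es − Ep − D − ΔW = 0`
exactly (float residue charged to drainage), so the seasonal closure
`ETc = I + Pe − ΔW − D` is exact by construction.

Drip irrigation is localized: metered depths are divided by the wetted-width
fraction (film width / tape spacing = 70/120 ≈ 0.583) to express them on the
near-tape 1-D column, reproducing the ~1.7–1.9 input/metered ratios of the
field records, and are infiltrated only within the 60 cm wetted depth.
The moisture-based correction `Q = 1000·(θafter − θbefore)·H` is provided
for working from probe readings.

## Crop engine

A compact CERES-like engine, not a port. Thermal time is
`max((Tmax,f + Tmin,f)/2 − 8, 0)` on compensated temperatures. Phase
thresholds: sowing → emergence 110 °C·d (calibrated so emergence falls
~14–16 d after late-April sowing under film warming; the textbook 45 °C·d
emerges in under a week here); emergence → end of juvenile phase P1;
juvenile end → tasseling 620 °C·d plus the photoperiod delay
`P2·max(daylength − 12.5 h, 0)` days (daylength computed astronomically at
44.1° N); tasseling → silking 60 °C·d; silking → maturity P5 (fill starts
280 °C·d after silking). With the default climate this lands tasseling in
late July and maturity ~135–145 d after sowing, matching the observed
calendar within a few days.

LAI expands by `lai_per_leaf` (0.22) per phyllochron scaled by water stress,
peaks near silking (~4.3 unstressed) and senesces at 0.25 per phyllochron.
Biomass accrues as RUE (3.0 g/MJ) × intercepted PAR (half of global
radiation) × a CERES-style temperature factor
`1 − 0.0025·(0.75Tmax + 0.25Tmin − 26)²` × stress. Grain is kernel-limited —
`G2·(mean stress around silking) × G3 × stress-weighted fill days × density`
— and capped at `hi_max = 0.55` of biomass; in unstressed runs the cap binds,
so yields track biomass at a modern harvest index.

Two **excess-water emulations** translate the wet-year yield narrative into
the model (neither is a published formula; both are config-exposed):
saturation days (topsoil above `fc + 0.2(sat − fc)` for ≥ 3 consecutive
days) each cost 0.8% of yield, and heavy-storm days (≥ 25 mm) during
tasseling/silking each cost 2.5% (pollination interference), jointly capped
at 50%.

## Synthetic weather

Temperature: annual sinusoid (mean 6.5 °C, amplitude 18.5 °C, peak DOY 202)
plus AR(1) anomalies (sd 2.3 °C, ρ 0.65); diurnal range ~11.5 °C, compressed
on rain days. Radiation: FAO-56 extraterrestrial radiation times a
transmissivity of 0.62 (dry) / 0.35 (wet) — the dry value follows the
Ångström relation from the region's ~3254 sunshine hours per year.
Precipitation: per-month Poisson event counts × gamma amounts with shape 0.7
(heavy-tailed: summer rain arrives as a few large storms, as in the region's
wet-year records where one July carried 70% of the season); monthly means
peak at 112 mm in July, totalling ~315 mm/yr with a 64% July–September
share. All draws flow from one `numpy` generator seeded by the caller;
generation is bit-reproducible.

What the generator does **not** emulate: multi-day synoptic rain spells
(event days are independent within a month), humidity/wind co-variation with
storms beyond a wet/dry switch, and the tight inter-annual variance of the
real station record (synthetic growing-season totals span ~100–430 mm).
Consequently, passing scenario tests show the model's *contrasts* (treatment
orderings, hydrological-year effects) under plausible forcing — they are not
evidence of predictive skill for any particular station year.

## Hydrological years and scenario experiments

A growing season is wet / normal / dry by empirical frequency against a
climatology: ≥ 75th percentile wet, ≤ 25th dry. Irrigation totals follow the
regional drip recommendation: 183 mm in normal and dry years, 105 mm in wet
years, split over eight events patterned on the field schedule.

The wet/normal contrast is evaluated on **matched pairs**: the same synthetic
year is rescaled to a 250 mm (typical normal) and a 415 mm (observed wet
benchmark) growing-season total, so temperatures, radiation and event days
are identical within a pair and scaling the amounts can only increase
storm counts and effective rainfall. This isolates the hydrological-year
effect; freely sampled years confound it with radiation differences.

## GLUE calibration

Uniform priors, Latin-hypercube sampling (`scipy.stats.qmc`), likelihood
`exp(−nRMSE²/2σ²)` with the score the mean range-normalized RMSE across
observation variables, behavioural set the top 5%. The parameter-recovery
experiment perturbs synthetic truth (LAI every 10 days plus tasseling /
fill / maturity dates over four seasons) with 5% multiplicative noise and
recovers P1 and P5 from priors [120, 280] and [600, 1100] °C·d at 500
samples. Grain yield is deliberately excluded from the likelihood: its
inter-annual range is at the noise scale, so a range-normalized score of it
rewards noise-fitting rather than constraining parameters.

## Evaluation statistics

`MRE = 100/n·Σ|Sᵢ−Oᵢ|/Sᵢ` — note the *simulated* value in the denominator,
the convention of the reference tables (flag to switch);
`nRMSE = 100·RMSE/(Omax−Omin)`; `R²` the squared Pearson correlation. Table
comparisons round half-up to two decimals with ±0.01 absolute tolerance to
absorb mixed rounding/truncation in the published cells.

## Numerical conventions and degenerate inputs

Zero soil-accumulation difference raises a degenerate-input error in the
compensation coefficient; `Ts ≤ Tb` defines `ΔTa = 0`; constant observations
are rejected by nRMSE/R²; empty climatologies, inverted prior bounds,
negative forcings and date gaps raise typed errors naming the offending
value. Layer water contents are clamped to [wilting point, saturation] after
every step; closure residues (≤ 1e-12 mm) are charged to drainage.

## Problem sizes

Default experiment sizes: 50-year climate summaries, 100 × 120-day
conservation audits, 500-sample GLUE calibration over four seasons, and a
3-year × 2-scenario × 3-treatment matched matrix; together they run in
about a minute on one core, and the full test suite in under half a minute.

## Known limitations

- Yields are harvest-index-capped in unstressed runs, so kernel-number
  responses (G2) only surface under stress around silking.
- The excess-water mechanisms are emulations of a narrative, tuned to
  magnitude, not calibrated to data.
- Phenology uses daily mean temperature only (no Tmax/Tmin cardinal-
  temperature response, no vernalization/photoperiod genotypes beyond the
  linear P2 hook).
- The effective-rainfall quadratic is empirical and inherited; outside
  roughly P ∈ [0, 60] mm its clamps, not its fit, determine behaviour.
- One-dimensional column: no 2-D wetting front under emitters, no lateral
  film-edge effects.
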