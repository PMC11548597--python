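# mulchsim

Daily-timestep simulation of drip-irrigated spring maize grown under **fully
biodegradable plastic mulch film** in the semi-arid Xiliaohe Plain of
Northeast China, for agrohydrologists and crop modellers who want to ask: *how
long should the film's induction period be* (the interval before it starts to
degrade) *to balance early-season warming and moisture retention against
late-season rainwater harvesting?*

Standard DSSAT/CERES-style crop models assume bare, uniformly irrigated soil.
`mulchsim` adds the four mulch-specific processes around a compact CERES-like
maize engine:

1. **Film damage dynamics.** The damage ratio
   `Fd = Σ 2πr²ᵢ / A_d` counts hemispherical hole areas over the film area
   between the narrow maize rows; planting holes give an intact-film baseline
   (~11.6% at 67,500 plants/ha), and after the induction period a logistic
   trajectory (anchored so `Fd` exceeds 40–45% thirty days later) drives
   `Fd → 1`.
2. **Temperature compensation.** Film warms the 5 cm soil layer
   (`Ts = a·Ta + b`, film slopes 0.71–0.74 vs 0.66 bare). A stage-wise
   coefficient `C` converts the soil warming into an equivalent air-temperature
   increment `ΔTa = C·ΔTs·(Ta − Tb)/(Ts − Tb)` (base temperature `Tb = 8 °C`),
   which accelerates thermal-time phenology: `C ≈ 1.5` from sowing to
   emergence, decaying to 0 after tasseling.
3. **Effective rainfall.** Intact film sheds rain away from the planted strip
   (`Pe = 0`); once damaged, `Pe = P·λ(P, Fd)` with an empirical quadratic
   infiltration rate λ that grows with both storm size and damage.
4. **Evaporation under mulch.** Priestley–Taylor equilibrium demand
   (`ETp = 1.1·EEQ`), Ritchie two-stage soil evaporation (stage I at the
   potential rate up to a limit `U`, stage II following `α√t`), and the mulch
   scaling `Es,film = Es·Fd`.

Around these sit a layered tipping-bucket soil-water balance with localized
drip-irrigation correction (`Q = 1000·Δθ·H`), closing exactly as
`ETc = I + Pe − ΔW − D`; evaluation statistics (MRE, nRMSE, R²); GLUE
calibration of the CERES genetic coefficients (P1, P2, P5, PHINT, G2, G3);
and a seeded synthetic weather generator emulating the study climate
(~324 mm/yr, >60% of it July–September).

## Worked example

```python
from mulchsim import ClimateSpec, ScenarioConfig, generate_weather, run_season

series = generate_weather(ClimateSpec(), years=1, seed=42, start_year=2019)
result = run_season(ScenarioConfig(treatment="BM80"), series, year=2019)

print(result.calendar.as_dict())
print(f"effective rain {result.effective_precip_mm:6.1f} mm")
print(f"seasonal ETc   {result.etc_total_mm:6.1f} mm")
print(f"yield          {result.yield_kg_ha:6.0f} kg/ha")
print(f"WUE            {result.wue:6.2f} kg/mm/ha")
```

prints

```
{'emergence': 13, 'juvenile_end': 33, 'tasseling': 76, 'silking': 79, 'filling': 97, 'maturity': 146}
effective rain   48.6 mm
seasonal ETc    398.7 mm
yield           12661 kg/ha
WUE             31.76 kg/mm/ha
```

Reading: under an 80-day induction film the crop emerges 13 days after the
late-April sowing, tassels in late July and matures in mid-September; of the
158 mm of gauge rainfall only 48.6 mm infiltrates the mulched strip (the film
is intact through July), irrigation dominates the water supply, and the
season closes at 399 mm of crop evapotranspiration — a yield of 12.7 t/ha and
a water-use efficiency of 31.8 kg per mm per hectare. The daily trace
(`result.trace`) carries state and fluxes for every day; the water balance
closes to machine precision.

A thin CLI wraps the same calls:

```sh
mulchsim weather --years 5 --seed 1 --out w.csv
mulchsim run --treatment BM60 --weather w.csv --out results/
mulchsim matrix --years 5 --treatments BM60,BM80,BM100,CK
```

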