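"""Reference data from the Xiliaohe Plain (Tongliao, Inner Mongolia) field study.

A 2016-2018 drip-irrigated spring-maize experiment under fully biodegradable
mulch film with three induction periods (BM60 / BM80 / BM100 = film intact for
~60 / 80 / 100 days after sowing) plus a bare-soil control (CK) provides the
calibration and evaluation context for this package.  The constants below are
the published summaries of that study: site soil hydraulic properties, the
CERES genetic coefficients of the cultivar Nonghua 106, stage-wise
temperature-compensation coefficients, irrigation metering records, the
calibration/validation result pairs, and the 2019-2023 prediction summaries.

They serve as fixtures for the evaluation statistics and as defaults for the
scenario engine; nothing in the simulation pipeline is fitted to them at run
time.
"""

from __future__ import annotations

# --- Site ------------------------------------------------------------------

SITE_LATITUDE_DEG = 44.1
SITE_LONGITUDE_DEG = 122.35
SITE_ELEVATION_M = 173.5

#: Long-run (1951-2018) mean annual precipitation at the site, mm.
MEAN_ANNUAL_PRECIP_MM = 324.0

#: May-September (growing-season) precipitation totals, 2016-2023, mm.
GROWING_SEASON_PRECIP_MM = {
    2016: 272.03,
    2017: 290.42,
    2018: 212.56,
    2019: 244.37,
    2020: 262.99,
    2021: 257.46,
    2022: 252.56,
    2023: 414.89,
}

#: Published hydrological-year labels for the observation record.
HYDRO_YEAR_LABELS = {2018: "dry", 2023: "wet"}

#: Plant density used throughout the experiment, plants per hectare.
PLANT_DENSITY_PER_HA = 67_500

#: Film geometry: 70 cm wide strips over drip tapes spaced 1.2 m apart.
FILM_WIDTH_CM = 70.0
DRIP_TAPE_SPACING_CM = 120.0
FILM_THICKNESS_MM = 0.008
PLANTING_HOLE_RADIUS_CM = 4.0

# --- Soil profile (0-1 m, four layers) --------------------------------------

#: Columns: top_cm, bottom_cm, clay %, silt %, sand %, field capacity,
#: saturated water content, wilting point (all cm3/cm3), bulk density g/cm3.
SOIL_PROFILE_ROWS = [
    (0, 20, 10.54, 52.70, 36.76, 0.26, 0.40, 0.08, 1.39),
    (20, 40, 29.54, 48.81, 21.65, 0.34, 0.45, 0.08, 1.38),
    (40, 70, 40.67, 39.15, 20.18, 0.45, 0.53, 0.10, 1.41),
    (70, 100, 1.41, 25.58, 73.01, 0.17, 0.38, 0.05, 1.52),
]

# --- Genetic coefficients (Nonghua 106) --------------------------------------

#: P1 (juvenile thermal time, deg C d), P2 (photoperiod sensitivity, d/h),
#: P5 (silking-to-maturity thermal time, deg C d), PHINT (phyllochron, deg C d),
#: G2 (potential kernels per plant), G3 (kernel fill rate, mg/kernel/d).
GENETIC_NONGHUA106 = {
    "p1": 196.0,
    "p2": 0.55,
    "p5": 858.0,
    "phint": 45.0,
    "g2": 980.0,
    "g3": 6.2,
}

# --- Temperature-increase compensation coefficients --------------------------

#: Stage-wise compensation coefficients C derived from 2019-2023 temperature
#: series, per treatment.  Keys: stage -> list of five yearly values
#: (2019..2023).  Stages after tasseling take C = 0.
COMPENSATION_TABLE = {
    "BM60": {
        "sowing_to_emergence": [1.47, 1.38, 1.59, 1.61, 1.42],
        "emergence_to_elongation": [0.35, 0.32, 0.43, 0.37, 0.33],
        "elongation_to_tasseling": [0.10, 0.12, 0.13, 0.09, 0.13],
    },
    "BM80": {
        "sowing_to_emergence": [1.48, 1.38, 1.59, 1.61, 1.42],
        "emergence_to_elongation": [0.41, 0.38, 0.45, 0.39, 0.36],
        "elongation_to_tasseling": [0.15, 0.13, 0.16, 0.11, 0.15],
    },
    "BM100": {
        "sowing_to_emergence": [1.49, 1.39, 1.59, 1.62, 1.42],
        "emergence_to_elongation": [0.44, 0.40, 0.47, 0.42, 0.39],
        "elongation_to_tasseling": [0.21, 0.16, 0.20, 0.16, 0.18],
    },
}

#: Published stage means of the table above (rounded to 2 decimals).
COMPENSATION_MEANS = {
    "BM60": {"sowing_to_emergence": 1.49, "emergence_to_elongation": 0.36,
             "elongation_to_tasseling": 0.11},
    "BM80": {"sowing_to_emergence": 1.50, "emergence_to_elongation": 0.40,
             "elongation_to_tasseling": 0.14},
    "BM100": {"sowing_to_emergence": 1.50, "emergence_to_elongation": 0.42,
              "elongation_to_tasseling": 0.18},
}

# --- Air <-> 5 cm soil temperature regression slopes (by treatment) ----------

#: (early 0-70 d post-sowing, late 71-140 d) regression slopes of daily mean
#: 5 cm soil temperature on daily mean air temperature.
SOIL_TEMP_SLOPES = {
    "CK": (0.66, 0.58),
    "BM60": (0.71, 0.61),
    "BM80": (0.72, 0.63),
    "BM100": (0.74, 0.64),
}

#: Mean 0-70 d soil warming of film treatments over bare soil, deg C.
EARLY_SOIL_WARMING_C = 2.65

# --- Calibration / validation results ----------------------------------------

#: Simulated vs observed pairs with published mean-relative-error cells.
#: Phenology entries are day-of-year; yield kg/ha; ETc mm.
#: Rows: (year, treatment, variable, simulated, observed, published MRE %).
CALIBRATION_TABLE = [
    (2016, "BM60", "emergence", 135, 136, 0.74),
    (2016, "BM60", "tasseling", 203, 205, 0.99),
    (2016, "BM60", "filling", 228, 229, 0.44),
    (2016, "BM60", "harvest", 262, 264, 0.76),
    (2016, "BM60", "yield", 13301, 13484, 1.37),
    (2016, "BM60", "etc", 443.25, 450.69, 1.68),
    (2016, "BM80", "emergence", 135, 136, 0.74),
    (2016, "BM80", "tasseling", 202, 205, 1.49),
    (2016, "BM80", "filling", 227, 229, 0.88),
    (2016, "BM80", "harvest", 261, 264, 1.15),
    (2016, "BM80", "yield", 13015, 12995, 0.15),
    (2016, "BM80", "etc", 438.22, 445.52, 1.67),
    (2016, "BM100", "emergence", 135, 136, 0.74),
    (2016, "BM100", "tasseling", 201, 205, 1.99),
    (2016, "BM100", "filling", 226, 228, 0.88),
    (2016, "BM100", "harvest", 260, 264, 1.54),
    (2016, "BM100", "yield", 12409, 12471, 0.50),
    (2016, "BM100", "etc", 427.07, 435.39, 1.95),
    (2017, "BM60", "emergence", 136, 138, 1.47),
    (2017, "BM60", "tasseling", 206, 206, 0.00),
    (2017, "BM60", "filling", 231, 233, 0.87),
    (2017, "BM60", "harvest", 265, 265, 0.00),
    (2017, "BM60", "yield", 12890, 13379, 3.79),
    (2017, "BM60", "etc", 491.74, 471.35, 4.15),
    (2017, "BM80", "emergence", 136, 138, 1.47),
    (2017, "BM80", "tasseling", 205, 206, 0.49),
    (2017, "BM80", "filling", 230, 233, 1.30),
    (2017, "BM80", "harvest", 264, 265, 0.38),
    (2017, "BM80", "yield", 12361, 12848, 3.94),
    (2017, "BM80", "etc", 490.99, 470.43, 4.19),
    (2017, "BM100", "emergence", 136, 138, 1.47),
    (2017, "BM100", "tasseling", 204, 206, 0.98),
    (2017, "BM100", "filling", 229, 233, 1.75),
    (2017, "BM100", "harvest", 263, 265, 0.76),
    (2017, "BM100", "yield", 12351, 12727, 3.05),
    (2017, "BM100", "etc", 484.87, 464.97, 4.10),
    (2018, "BM60", "emergence", 135, 134, 0.74),
    (2018, "BM60", "tasseling", 206, 204, 0.97),
    (2018, "BM60", "filling", 231, 230, 0.43),
    (2018, "BM60", "harvest", 265, 263, 0.75),
    (2018, "BM60", "yield", 11305, 11193, 0.99),
    (2018, "BM60", "etc", 415.44, 435.95, 4.94),
    (2018, "BM80", "emergence", 135, 134, 0.74),
    (2018, "BM80", "tasseling", 206, 204, 0.97),
    (2018, "BM80", "filling", 231, 230, 0.43),
    (2018, "BM80", "harvest", 265, 263, 0.75),
    (2018, "BM80", "yield", 12125, 12461, 2.77),
    (2018, "BM80", "etc", 411.36, 431.62, 4.93),
    (2018, "BM100", "emergence", 135, 134, 0.74),
    (2018, "BM100", "tasseling", 205, 204, 0.49),
    (2018, "BM100", "filling", 230, 228, 0.87),
    (2018, "BM100", "harvest", 264, 263, 0.38),
    (2018, "BM100", "yield", 12330, 12732, 3.26),
    (2018, "BM100", "etc", 402.26, 423.19, 5.20),
]

# --- 2019-2023 prediction summaries ------------------------------------------

#: Rows: (year, treatment, effective precipitation mm, ETc mm, yield kg/ha,
#: WUE kg/mm/ha).
PREDICTION_TABLE = [
    (2019, "BM60", 192.53, 449.74, 12659.15, 28.15),
    (2019, "BM80", 177.81, 434.68, 12471.10, 28.69),
    (2019, "BM100", 168.97, 423.74, 12223.73, 28.85),
    (2020, "BM60", 203.98, 459.85, 13692.62, 29.78),
    (2020, "BM80", 203.98, 455.12, 13531.60, 29.73),
    (2020, "BM100", 184.86, 439.28, 13114.28, 29.85),
    (2021, "BM60", 242.34, 449.90, 12903.12, 28.68),
    (2021, "BM80", 226.56, 435.48, 12715.48, 29.20),
    (2021, "BM100", 204.58, 412.70, 12140.05, 29.42),
    (2022, "BM60", 209.05, 457.10, 12316.49, 26.94),
    (2022, "BM80", 192.87, 442.48, 12284.17, 27.76),
    (2022, "BM100", 183.42, 434.80, 12179.04, 28.01),
    (2023, "BM60", 382.13, 498.03, 11819.63, 23.73),
    (2023, "BM80", 364.80, 480.30, 11442.29, 23.82),
    (2023, "BM100", 352.64, 467.84, 11163.77, 23.86),
]

# --- Irrigation metering records ----------------------------------------------

#: Per-event (month, day, metered depth mm, model input depth mm).  The input
#: depth rescales the metered volume to the wetted strip near the drip tape.
IRRIGATION_RECORDS = {
    2016: [(5, 9, 30, 51), (6, 2, 30, 53), (7, 9, 30, 44), (7, 22, 15, 27),
           (8, 2, 10, 31), (8, 8, 20, 42), (8, 14, 20, 46), (8, 25, 20, 39)],
    2017: [(5, 8, 30, 52), (6, 11, 30, 56), (6, 27, 30, 50), (7, 2, 30, 46),
           (7, 17, 20, 39), (7, 22, 10, 18), (8, 2, 10, 24)],
    2018: [(5, 9, 15, 33), (5, 18, 30, 59), (6, 10, 30, 58), (6, 22, 30, 52),
           (7, 17, 30, 42), (8, 1, 30, 37), (8, 9, 30, 40)],
}

#: Recommended seasonal drip-irrigation totals (metered scale), mm.
SEASONAL_IRRIGATION_MM = {"normal": 183.0, "wet": 105.0, "dry": 183.0}
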