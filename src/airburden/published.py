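"""Benchmark values from the published global assessment this pipeline
implements the methodology of.

These printed summary numbers — world-row population-weighted exposure
statistics, global burden totals in thousands, and the sensitivity-
scenario totals — serve as worked-example inputs: the reporting
conventions (percent change, rounding, YLL-per-death consistency) are
checked by recomputing derived quantities from them.  They are inputs,
not outputs, of this package; the gridded fields behind them are not
distributed and the absolute totals are not reproducible from synthetic
data.
"""

# World-row population-weighted averages of the exposure metrics
# (seasonal-average daily 1-hr max O3 in ppb; annual-average PM2.5 in
# ug/m3) for the preindustrial and present-day simulations, and the
# min/max over individual grid cells.
WORLD_EXPOSURE = {
    "o3_pre_avg": 19.61,
    "o3_present_avg": 56.70,
    "o3_pre_range": (3.74, 35.9),
    "o3_present_range": (6.41, 90.3),
    "pm_pre_avg": 1.13,
    "pm_present_avg": 16.11,
    "pm_pre_range": (0.11, 3.89),
    "pm_present_range": (0.25, 55.9),
}

# Global annual mortality burdens, thousands, mean and 1 SD, for the
# no-threshold ("background") and LCT scenarios (33.3 ppb O3 / 5.8 ug/m3
# PM2.5).
WORLD_MORT_THOUSANDS = {
    ("o3", "respiratory", "background"): (700.0, 335.0),
    ("o3", "respiratory", "threshold"): (470.0, 288.0),
    ("pm25", "cardiopulmonary", "background"): (3499.0, 864.0),
    ("pm25", "cardiopulmonary", "threshold"): (2506.0, 816.0),
    ("pm25", "lung_cancer", "background"): (222.0, 80.0),
    ("pm25", "lung_cancer", "threshold"): (164.0, 68.0),
}

# Matching global annual years of life lost, thousands.
WORLD_YLL_THOUSANDS = {
    ("o3", "respiratory", "background"): (6251.0, 2992.0),
    ("o3", "respiratory", "threshold"): (4197.0, 2572.0),
    ("pm25", "cardiopulmonary", "background"): (27607.0, 6817.0),
    ("pm25", "cardiopulmonary", "threshold"): (19772.0, 6438.0),
    ("pm25", "lung_cancer", "background"): (2169.0, 782.0),
    ("pm25", "lung_cancer", "threshold"): (1602.0, 664.0),
}

# O3 sensitivity scenarios (respiratory mortality, thousands) against the
# two-pollutant-model no-LCT baseline of 700, with the printed percent
# change each pair should reproduce.
O3_SENSITIVITY = {
    # scenario: (total_thousands, baseline_thousands, printed_percent)
    "lct25": (605.0, 700.0, -13.6),
    "lct33.3": (470.0, 700.0, -32.9),
    "single_pollutant": (524.0, 700.0, -25.1),
    "single_lct25": (452.0, 700.0, -35.4),
    "single_lct33.3": (350.0, 700.0, -50.0),
    "threshold_model_lct56": (178.0, 700.0, -74.6),
}

# PM2.5 sensitivity scenarios per cause (thousands) against the central-RR
# no-threshold baselines (all causes 3381, cardiopulmonary 3499, lung
# cancer 222).
PM_BASELINE_THOUSANDS = {"all_cause": 3381.0, "cardiopulmonary": 3499.0, "lung_cancer": 222.0}
PM_SENSITIVITY = {
    # scenario: {cause: (total_thousands, printed_percent)}
    "lct5.8": {"all_cause": (2378.0, -29.7), "cardiopulmonary": (2506.0, -28.4),
               "lung_cancer": (164.0, -26.1)},
    "lct7.5": {"all_cause": (2077.0, -38.6), "cardiopulmonary": (2201.0, -37.1),
               "lung_cancer": (146.0, -34.2)},
    "hct30": {"all_cause": (3059.0, -9.5), "cardiopulmonary": (3205.0, -8.4),
              "lung_cancer": (201.0, -9.5)},
    "hct50": {"all_cause": (3338.0, -1.3), "cardiopulmonary": (3464.0, -1.0),
              "lung_cancer": (219.0, -1.4)},
    "pope2002": {"all_cause": (2333.0, -31.0), "cardiopulmonary": (1800.0, -48.6),
                 "lung_cancer": (139.0, -37.4)},
    "laden2006": {"all_cause": (7714.0, 128.2), "cardiopulmonary": (4549.0, 30.0),
                  "lung_cancer": (336.0, 51.4)},
}

# Global-average baseline YLL per death (years) by cause.
YLL0_GLOBAL_AVERAGE = {
    "cardiopulmonary": 7.89,
    "respiratory": 9.77,
    "lung_cancer": 8.93,
}
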