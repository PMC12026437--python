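"""Published reference statistics from the ready-to-eat crayfish storage
study used as frozen oracles: per-temperature goodness-of-fit grids,
Arrhenius regression parameters, a 10 °C validation table and a
single-factor sensory test.
"""

TEMPERATURES_C = (4.0, 25.0, 37.0)

# Per-indicator R^2 and RMSE for each (temperature, order) fit, plus the
# published per-order R^2 sums.  Layout: {indicator: {order: ([r2...], [rmse...])}}.
FIT_GRID = {
    "TVB-N": {
        0: ((0.956, 0.972, 0.978), (0.967, 2.961, 3.848)),
        1: ((0.910, 0.972, 0.974), (1.382, 2.955, 4.208)),
        2: ((0.873, 0.886, 0.797), (1.492, 4.019, 4.025)),
    },
    "TVC": {
        0: ((0.952, 0.963, 0.963), (0.108, 0.551, 0.629)),
        1: ((0.970, 0.952, 0.966), (0.084, 0.534, 0.600)),
        2: ((0.960, 0.855, 0.810), (0.105, 1.278, 2.301)),
    },
    "AV": {
        0: ((0.980, 0.979, 0.986), (0.107, 0.170, 0.248)),
        1: ((0.998, 0.993, 0.949), (0.032, 0.100, 0.467)),
        2: ((0.977, 0.856, 0.872), (0.031, 1.160, 1.802)),
    },
    "springiness": {
        0: ((0.934, 0.876, 0.884), (0.070, 0.151, 0.178)),
        1: ((0.924, 0.856, 0.859), (0.077, 0.161, 0.195)),
        2: ((0.913, 0.821, 0.820), (0.505, 0.813, 1.017)),
    },
    "hardness": {
        0: ((0.988, 0.982, 0.943), (3.630, 10.052, 28.032)),
        1: ((0.991, 0.983, 0.984), (3.578, 9.829, 14.868)),
        2: ((0.989, 0.952, 0.978), (5.463, 20.864, 32.768)),
    },
}

#: Published per-order R^2 sums (three of which are exactly the column sums;
#: the hardness order-0 entry is printed as 2.916 although its addends sum
#: to 2.913 — a typo in the source table that never affects selection).
PUBLISHED_SUM_R2 = {
    "TVB-N": {0: 2.906, 1: 2.856, 2: 2.556},
    "TVC": {0: 2.878, 1: 2.888, 2: 2.625},
    "AV": {0: 2.945, 1: 2.940, 2: 2.705},
    "springiness": {0: 2.694, 1: 2.639, 2: 2.554},
    "hardness": {0: 2.913, 1: 2.958, 2: 2.919},
}

SELECTED_ORDERS = {"TVB-N": 0, "TVC": 1, "AV": 0, "springiness": 0, "hardness": 1}

# Arrhenius regression rows: intercept ln K0, slope magnitude (K), published
# Ea (kJ/mol) and K0.  The springiness K0 is inconsistent with its intercept
# in the source (exp(17.259) ~ 3.13e7, printed 4.10e7) and is excluded from
# consistency checks.
ARRHENIUS_ROWS = {
    "TVB-N": {
        "order": 0, "intercept": 30.935, "slope_magnitude": 8507.390,
        "ea_kj_per_mol": 70.736, "k0": 2.72e13, "k0_consistent": True,
    },
    "TVC": {
        "order": 1, "intercept": 17.924, "slope_magnitude": 5527.722,
        "ea_kj_per_mol": 45.961, "k0": 6.09e7, "k0_consistent": True,
    },
    "AV": {
        "order": 0, "intercept": 19.695, "slope_magnitude": 5911.062,
        "ea_kj_per_mol": 49.149, "k0": 3.58e8, "k0_consistent": True,
    },
    "springiness": {
        "order": 0, "intercept": 17.259, "slope_magnitude": 5521.926,
        "ea_kj_per_mol": 45.913, "k0": 4.10e7, "k0_consistent": False,
    },
    "hardness": {
        "order": 1, "intercept": 24.527, "slope_magnitude": 7776.532,
        "ea_kj_per_mol": 64.660, "k0": 4.49e10, "k0_consistent": True,
    },
}

# 10 °C validation table: (storage day, measured, predicted, published %).
VALIDATION_TABLE = {
    "TVB-N": [
        (2, 12.71, 11.79, 7.80),
        (4, 17.18, 16.57, 3.66),
        (6, 21.09, 21.36, 1.27),
        (8, 27.00, 26.15, 3.25),
        (10, 29.31, 30.94, 5.24),
    ],
    "TVC": [
        (2, 0.81, 0.84, 4.33),
        (4, 1.21, 1.26, 4.22),
        (6, 2.04, 1.88, 8.80),
        (8, 2.76, 2.81, 1.79),
        (10, 3.83, 4.19, 8.45),
    ],
    "AV": [
        (2, 1.95, 1.81, 7.62),
        (4, 2.51, 2.42, 3.89),
        (6, 3.05, 3.02, 0.87),
        (8, 3.42, 3.63, 5.78),
        (10, 4.48, 4.24, 5.61),
    ],
    "springiness": [
        (2, 3.76, 3.96, 4.99),
        (4, 3.73, 3.68, 1.43),
        (6, 3.16, 3.40, 7.14),
        (8, 3.21, 3.13, 2.58),
        (10, 2.94, 2.85, 3.11),
    ],
    "hardness": [
        (2, 324.27, 341.38, 5.01),
        (4, 335.13, 307.49, 8.99),
        (6, 251.84, 276.96, 9.07),
        (8, 268.20, 249.47, 7.51),
        (10, 238.05, 224.70, 5.94),
    ],
}

#: Headline bound on the validation deviations.
MAX_DEVIATION_BOUND_PCT = 9.5

# Single-factor sensory test: level -> mean score.
SENSORY_FACTORS = {
    "spice_pct": ((0.6, 0.8, 1.0, 1.2, 1.4), (7.62, 7.83, 8.36, 8.92, 8.46)),
    "salt_pct": ((0.35, 0.50, 0.65, 0.80, 0.95), (7.91, 8.13, 8.37, 8.96, 8.06)),
    "simmer_min": ((50, 60, 70, 80, 90), (7.52, 8.29, 9.25, 8.28, 7.80)),
}

#: Initial values of the spoilage indicators reported at t = 0.
INITIAL_VALUES = {"TVC": 0.57, "springiness": 4.23, "hardness": 379.0}
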