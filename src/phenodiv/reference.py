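"""Published summary statistics for the 1,558-accession foxtail millet panel.

These are the per-trait descriptive statistics, qualitative class counts,
and PCA summaries reported for a two-year (2023-2024) field evaluation of
1,558 *Setaria italica* accessions in Chifeng, Inner Mongolia. The raw
accession-level data are not public; the values below serve two purposes:

* default simulation targets for :mod:`phenodiv.cohort`, so the synthetic
  panels match the real panel's marginal distributions; and
* inputs for consistency checks on quantities that are pure functions of
  other published numbers (composite weights, loading/coefficient
  relations, class-frequency percentages).

Trait order everywhere follows :func:`phenodiv.traits.default_registry`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PANEL_SIZE = 1558

#: Composition of the panel by material class (sums to PANEL_SIZE).
MATERIAL_CLASS_COUNTS = {
    "landrace": 847,
    "breeding_line": 432,
    "selected_cultivar": 256,
    "genetic_stock": 4,
    "other": 19,
}

#: Quantitative traits: mean, sample SD, observed min and max.
QUANTITATIVE_SUMMARY: dict[str, dict[str, float]] = {
    "STC": {"mean": 73.56, "sd": 6.63, "min": 58.00, "max": 99.00},
    "GP": {"mean": 111.99, "sd": 4.63, "min": 102.00, "max": 126.00},
    "MPL": {"mean": 29.06, "sd": 5.32, "min": 12.60, "max": 51.63},
    "MTL": {"mean": 129.51, "sd": 20.04, "min": 67.50, "max": 184.13},
    "ST": {"mean": 6.26, "sd": 1.25, "min": 2.24, "max": 10.69},
    "SSW": {"mean": 98.90, "sd": 27.21, "min": 10.36, "max": 187.12},
    "SGW": {"mean": 80.88, "sd": 22.96, "min": 7.43, "max": 161.76},
    "TGW": {"mean": 3.11, "sd": 0.39, "min": 2.05, "max": 5.43},
    "L": {"mean": 62.53, "sd": 2.44, "min": 46.96, "max": 71.30},
    "a": {"mean": 6.77, "sd": 1.13, "min": 0.97, "max": 10.18},
    "b": {"mean": 28.03, "sd": 3.38, "min": 8.13, "max": 35.77},
}

#: Published CV (%) per quantitative trait, used as recovery checkpoints.
QUANTITATIVE_CV = {
    "STC": 9.02, "GP": 4.14, "MPL": 18.29, "MTL": 15.47, "ST": 19.97,
    "SSW": 27.52, "SGW": 28.38, "TGW": 12.50, "L": 3.90, "a": 16.73,
    "b": 12.07,
}

#: Qualitative traits: accession counts per category code (code 1 first),
#: padded with zeros up to the registry's category count.
QUALITATIVE_COUNTS: dict[str, tuple[int, ...]] = {
    "LSC": (1035, 232, 291),
    "SLC": (1306, 252),
    "SZ": (989, 1, 568),
    "SS": (1066, 235, 22, 235),
    "SE": (513, 308, 737),
    "SNC": (1547, 10, 0, 0),
    "SL": (1105, 135, 314, 4),
    "BC": (94, 1051, 413),
    "AC": (569, 382, 607),
    "HC": (7, 29, 20, 9, 77, 1398, 18),
    "SLS": (99, 1217, 227, 15),
    "FLS": (30, 352, 1176),
    "TL": (272, 191, 1095),
    "LR": (199, 216, 146, 758, 239),
}

#: Published Shannon-Wiener H' per qualitative trait (two rows of the
#: source table are mutually swapped and one is internally inconsistent;
#: see docs/methods.md - recomputed values are asserted in tests instead).
QUALITATIVE_SHANNON = {
    "LSC": 0.44, "SLC": 0.87, "SZ": 0.66, "SS": 0.89, "SE": 1.04,
    "SNC": 0.04, "SL": 0.79, "BC": 0.79, "AC": 1.08, "HC": 0.44,
    "SLS": 0.69, "FLS": 0.62, "TL": 0.81, "LR": 1.40,
}

#: Qualitative rows whose published H' recomputes exactly from the counts.
QUALITATIVE_CONSISTENT = (
    "SZ", "SS", "SE", "SNC", "SL", "BC", "AC", "SLS", "FLS", "TL", "LR",
)

#: Rows whose published CV recomputes from the counts (SNC's printed 7.44
#: does not follow from its own counts, which give 7.94).
QUALITATIVE_CV_CONSISTENT = (
    "SZ", "SS", "SE", "SL", "BC", "AC", "SLS", "FLS", "TL", "LR",
)

QUALITATIVE_CV_PUBLISHED = {
    "LSC": 31.71, "SLC": 51.86, "SZ": 55.66, "SS": 66.20, "SE": 41.25,
    "SNC": 7.44, "SL": 54.62, "BC": 24.16, "AC": 42.91, "HC": 13.05,
    "SLS": 23.20, "FLS": 17.65, "TL": 30.61, "LR": 37.11,
}

#: Eigenvalues of the 25-trait correlation matrix for the retained PCs.
PCA_EIGENVALUES = np.array(
    [3.31, 2.27, 2.00, 1.79, 1.41, 1.16, 1.11, 1.07, 1.01, 0.95]
)

#: Contribution rate (%) of each retained PC: 100 * eigenvalue / 25.
PCA_CONTRIBUTION_RATES = np.array(
    [13.25, 9.08, 7.99, 7.17, 5.66, 4.62, 4.42, 4.27, 4.03, 3.82]
)

#: Running cumulative contribution (%).
PCA_CUMULATIVE_RATES = np.array(
    [13.25, 22.33, 30.32, 37.49, 43.14, 47.77, 52.19, 56.46, 60.48, 64.30]
)

#: Published 3-dp composite weights (rates normalized by the cumulative
#: 64.30 then rounded; they sum to 0.999 because of the rounding).
COMPOSITE_WEIGHTS_3DP = np.array(
    [0.206, 0.141, 0.124, 0.111, 0.088, 0.072, 0.069, 0.066, 0.063, 0.059]
)

_TRAIT_ORDER = (
    "STC", "GP", "MPL", "MTL", "ST", "SSW", "SGW", "TGW", "L", "a", "b",
    "LSC", "SLC", "SZ", "SS", "SE", "SNC", "SL", "BC", "AC", "HC", "SLS",
    "FLS", "TL", "LR",
)

_LOADINGS = [
    [0.54, 0.10, -0.20, -0.44, 0.39, -0.09, 0.04, -0.09, 0.02, 0.10],
    [0.10, -0.24, -0.17, -0.41, 0.42, 0.25, 0.07, 0.24, -0.14, 0.01],
    [0.37, -0.08, 0.52, 0.19, 0.41, 0.14, 0.17, 0.02, -0.11, 0.05],
    [-0.07, -0.13, 0.29, -0.03, 0.26, 0.06, -0.37, 0.43, 0.20, 0.21],
    [0.62, -0.19, -0.24, -0.10, 0.21, -0.14, 0.19, -0.03, 0.05, 0.11],
    [0.84, -0.25, 0.07, 0.12, -0.07, 0.06, -0.14, -0.14, 0.25, 0.07],
    [0.81, -0.25, 0.08, 0.15, -0.11, 0.06, -0.15, -0.16, 0.27, 0.06],
    [0.21, -0.23, 0.39, 0.49, -0.22, 0.08, 0.02, 0.19, -0.34, -0.08],
    [0.16, 0.49, -0.24, 0.25, 0.18, 0.16, 0.12, 0.25, 0.14, -0.12],
    [0.32, 0.71, -0.23, 0.27, -0.01, 0.07, -0.09, 0.02, -0.06, 0.00],
    [0.36, 0.77, -0.26, 0.32, 0.07, 0.11, -0.01, 0.12, -0.02, -0.04],
    [-0.34, -0.25, -0.15, 0.29, 0.22, 0.26, 0.07, -0.09, 0.45, -0.08],
    [0.21, 0.43, 0.36, -0.26, -0.17, -0.15, -0.07, -0.05, 0.12, 0.12],
    [-0.41, -0.05, -0.22, 0.39, 0.13, -0.17, 0.06, -0.15, 0.11, 0.16],
    [0.14, -0.13, -0.42, -0.15, -0.32, 0.01, 0.13, 0.24, 0.22, 0.10],
    [-0.07, 0.21, 0.44, 0.02, 0.36, -0.14, 0.26, 0.04, -0.11, -0.16],
    [0.08, 0.02, 0.04, 0.02, -0.31, -0.03, 0.65, 0.22, 0.23, 0.06],
    [-0.05, 0.06, 0.36, -0.10, -0.03, -0.19, 0.45, 0.11, 0.21, 0.04],
    [-0.31, -0.26, -0.23, 0.46, 0.36, -0.01, 0.05, -0.04, 0.18, -0.12],
    [-0.07, -0.06, 0.08, -0.08, -0.12, 0.74, 0.08, 0.23, -0.08, 0.24],
    [0.18, -0.03, 0.11, -0.30, -0.10, 0.29, 0.01, -0.13, 0.15, -0.78],
    [-0.07, 0.09, -0.11, -0.05, 0.00, 0.38, 0.29, -0.62, -0.20, 0.26],
    [0.24, 0.04, 0.43, 0.26, 0.17, -0.02, 0.04, -0.18, 0.07, 0.03],
    [0.39, -0.40, -0.16, 0.40, -0.24, -0.06, 0.06, 0.09, -0.25, -0.05],
    [0.32, -0.29, -0.43, -0.01, 0.19, -0.18, 0.16, 0.12, -0.33, -0.14],
]

_SCORE_COEFFICIENTS = [
    [0.298, 0.064, -0.144, -0.331, 0.330, -0.086, 0.042, -0.084, 0.023, 0.105],
    [0.054, -0.158, -0.120, -0.303, 0.354, 0.231, 0.064, 0.233, -0.142, 0.008],
    [0.201, -0.053, 0.364, 0.140, 0.348, 0.132, 0.157, 0.018, -0.107, 0.054],
    [-0.037, -0.085, 0.206, -0.022, 0.220, 0.051, -0.349, 0.412, 0.200, 0.217],
    [0.343, -0.125, -0.168, -0.071, 0.179, -0.132, 0.178, -0.024, 0.049, 0.110],
    [0.463, -0.163, 0.051, 0.090, -0.057, 0.055, -0.129, -0.134, 0.249, 0.070],
    [0.447, -0.165, 0.054, 0.112, -0.095, 0.055, -0.140, -0.150, 0.267, 0.058],
    [0.116, -0.151, 0.275, 0.364, -0.185, 0.071, 0.022, 0.181, -0.340, -0.082],
    [0.088, 0.324, -0.169, 0.188, 0.150, 0.151, 0.112, 0.241, 0.138, -0.125],
    [0.174, 0.469, -0.164, 0.198, -0.006, 0.062, -0.087, 0.023, -0.056, -0.003],
    [0.197, 0.510, -0.182, 0.242, 0.055, 0.103, -0.012, 0.114, -0.022, -0.043],
    [-0.186, -0.167, -0.103, 0.216, 0.186, 0.242, 0.062, -0.088, 0.448, -0.085],
    [0.116, 0.283, 0.254, -0.196, -0.146, -0.143, -0.064, -0.049, 0.115, 0.125],
    [-0.226, -0.030, -0.158, 0.289, 0.112, -0.162, 0.056, -0.142, 0.110, 0.168],
    [0.077, -0.086, -0.298, -0.113, -0.268, 0.007, 0.121, 0.234, 0.214, 0.106],
    [-0.040, 0.142, 0.312, 0.014, 0.301, -0.129, 0.244, 0.038, -0.105, -0.160],
    [0.042, 0.011, 0.030, 0.016, -0.261, -0.029, 0.619, 0.208, 0.226, 0.057],
    [-0.030, 0.037, 0.252, -0.075, -0.024, -0.173, 0.424, 0.109, 0.209, 0.045],
    [-0.169, -0.172, -0.165, 0.343, 0.302, -0.012, 0.047, -0.038, 0.182, -0.120],
    [-0.037, -0.039, 0.057, -0.056, -0.098, 0.687, 0.071, 0.223, -0.076, 0.247],
    [0.097, -0.021, 0.079, -0.224, -0.085, 0.265, 0.010, -0.124, 0.145, -0.795],
    [-0.039, 0.061, -0.078, -0.034, -0.002, 0.356, 0.273, -0.602, -0.202, 0.261],
    [0.130, 0.028, 0.306, 0.195, 0.140, -0.015, 0.039, -0.173, 0.067, 0.032],
    [0.217, -0.268, -0.111, 0.298, -0.200, -0.051, 0.057, 0.090, -0.250, -0.054],
    [0.177, -0.192, -0.303, -0.005, 0.158, -0.167, 0.154, 0.120, -0.329, -0.145],
]

_PC_COLS = [f"PC{i}" for i in range(1, 11)]

#: Published component loadings (trait x retained PC).
PCA_LOADINGS = pd.DataFrame(_LOADINGS, index=list(_TRAIT_ORDER), columns=_PC_COLS)

#: Published component score coefficients (unit eigenvector elements).
PCA_SCORE_COEFFICIENTS = pd.DataFrame(
    _SCORE_COEFFICIENTS, index=list(_TRAIT_ORDER), columns=_PC_COLS
)

#: Top composite F scores published for the real panel (ranks 1-3).
TOP_COMPOSITE_SCORES = (0.933, 0.850, 0.814)
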