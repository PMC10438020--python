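"""Published reference cross-tabulations for the 2019 Colombian
psychoactive-substance survey (ENCSPA) cluster analysis.

These are the published counts of six demographic/social variables
across the three consumption-pattern clusters, together with the
reported chi-square statistics, adjusted residuals and per-cluster
substance-use prevalences.  They serve as a recomputation benchmark:
the profiling statistics must reproduce the published values exactly
from the counts alone.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CLUSTER_SIZES",
    "CROSSTABS",
    "REPORTED_CHI2",
    "REPORTED_RESIDUALS",
    "PREVALENCE_POSITIVES",
    "TOTAL_POSITIVE",
    "TOTAL_N",
]

#: records per consumption-pattern cluster (columns of every table)
CLUSTER_SIZES = (14935, 11528, 23005)

#: observed counts, category x cluster
CROSSTABS: dict[str, dict[str, tuple[int, int, int]]] = {
    "region": {
        "Caribbean": (3004, 2991, 4075),
        "Central-Eastern": (2526, 2299, 6175),
        "Central-Southern": (1843, 1299, 1702),
        "Eje Cafetero-Antioquia": (3902, 2354, 6371),
        "Llanos Orientales": (1687, 1305, 1496),
        "Pacific": (1973, 1280, 3186),
    },
    "gender": {
        "Male": (6606, 3927, 10233),
        "Female": (8329, 7601, 12772),
    },
    "housing": {
        "House": (8250, 6538, 11834),
        "Apartment": (6275, 4724, 10595),
        "Room": (395, 256, 543),
        "Indigenous dwelling": (15, 10, 33),
    },
    "ses": {
        "1": (3889, 3626, 6945),
        "2": (4627, 3902, 8851),
        "3": (4284, 2867, 5683),
        "4": (1341, 718, 979),
        "5": (510, 256, 362),
        "6": (284, 159, 185),
    },
    "age_band": {
        "(0,20]": (2105, 1576, 2998),
        "(20,40]": (6814, 4329, 10889),
        "(40,68]": (6016, 5623, 9118),
    },
    "contributes": {
        "Yes": (10128, 7473, 16041),
        "No": (4807, 4055, 6964),
    },
}

#: published (chi-square, df) per variable
REPORTED_CHI2: dict[str, tuple[float, int]] = {
    "region": (1472.9, 10),
    "gender": (386.72, 2),
    "housing": (114.18, 6),
    "ses": (843.92, 10),
    "age_band": (345.87, 4),
    "contributes": (85.24, 2),
}

#: published adjusted standardized residuals (same row order as CROSSTABS)
REPORTED_RESIDUALS: dict[str, dict[str, tuple[float, float, float]]] = {
    "region": {
        "Caribbean": (-0.88, 17.02, -13.61),
        "Central-Eastern": (-18.72, -6.76, 22.97),
        "Central-Southern": (12.54, 6.09, -16.7),
        "Eje Cafetero-Antioquia": (2.02, -14.36, 10.31),
        "Llanos Orientales": (11.32, 9.59, -18.55),
        "Pacific": (0.84, -6.97, 5.13),
    },
    "gender": {
        "Male": (6.68, -19.66, 10.52),
        "Female": (-6.68, 19.66, -10.52),
    },
    "housing": {
        "House": (4.17, 7.13, -9.88),
        "Apartment": (-4.83, -6.61, 10.05),
        "Room": (2.2, -1.54, -0.72),
        "Indigenous dwelling": (-0.72, -1.09, 1.59),
    },
    "ses": {
        "1": (-10.26, 5.99, 4.37),
        "2": (-12.72, -3.3, 14.51),
        "3": (9.14, -3.0, -5.87),
        "4": (17.29, 0.44, -16.29),
        "5": (11.12, -0.49, -9.82),
        "6": (8.26, 1.2, -8.62),
    },
    "age_band": {
        "(0,20]": (2.54, 0.61, -2.85),
        "(20,40]": (3.2, -17.23, 11.66),
        "(40,68]": (-4.98, 16.93, -9.77),
    },
    "contributes": {
        "Yes": (-0.61, -8.37, 7.65),
        "No": (0.61, 8.37, -7.65),
    },
}

#: published substance-use positives per cluster and in total
PREVALENCE_POSITIVES = (1726, 392, 3396)
TOTAL_POSITIVE = 5514
TOTAL_N = 49468


def contingency(variable: str):
    """Reference counts for one variable as a ContingencyTable."""
    from .profiling import ContingencyTable

    rows = CROSSTABS[variable]
    return ContingencyTable(
        np.array(list(rows.values())),
        tuple(rows.keys()),
        ("0", "1", "2"),
    )
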