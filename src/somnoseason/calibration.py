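"""Published reference values used to calibrate the synthetic cohort.

These constants are the printed summary tables of a large Japanese Holter
cohort (~68,600 ambulatory recordings, 2010–2016): the month x age-decade
sample counts, the monthly sleep-parameter means, and the meteorological
effect sizes selected by the bootstrap-averaged adaptive LASSO. They are the
targets the synthetic-data generator is calibrated against; nothing in the
pipeline estimates *from* them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_GROUPS = ["10s", "20s", "30s", "40s", "50s", "60s", "70s", "80s"]
MONTHS = list(range(1, 13))

# Rows = month 1..12, columns = age decade. Counts of subject-recordings.
COHORT_MONTH_AGE_COUNTS = pd.DataFrame(
    np.array(
        [
            # 10s 20s  30s  40s  50s   60s   70s   80s
            [70, 111, 269, 507, 694, 1305, 1856, 1157],
            [64, 109, 208, 435, 674, 1250, 1783, 1081],
            [101, 139, 234, 508, 688, 1457, 2160, 1283],
            [103, 114, 206, 411, 559, 1264, 1824, 1197],
            [169, 133, 216, 447, 596, 1179, 1780, 1156],
            [180, 134, 245, 452, 580, 1219, 1846, 1227],
            [160, 144, 268, 454, 640, 1085, 1698, 1084],
            [135, 95, 186, 350, 458, 858, 1242, 856],
            [92, 112, 204, 376, 506, 1067, 1667, 1100],
            [84, 121, 263, 478, 682, 1434, 2172, 1371],
            [63, 89, 245, 491, 668, 1363, 1939, 1233],
            [93, 120, 272, 539, 616, 1246, 1743, 1061],
        ]
    ),
    index=pd.Index(MONTHS, name="month"),
    columns=AGE_GROUPS,
)

# Monthly mean sleep parameters (clock times as elapsed minutes from the
# recording-start-day midnight; get-up falls on day 2, hence the +1440).
MONTHLY_PARAMETER_MEANS = pd.DataFrame(
    {
        "n": [5969, 5604, 6570, 5678, 5676, 5883, 5533, 4180, 5124, 6605, 6091, 5690],
        "tst": [437.8, 430.6, 426.2, 421.0, 409.1, 402.6, 398.6, 404.4, 404.7, 417.2, 425.4, 429.7],
        "in_bed": [1339, 1346, 1340, 1337, 1342, 1337, 1343, 1333, 1333, 1335, 1339, 1345],
        "get_up": [1440 + 387, 1440 + 387, 1440 + 378, 1440 + 359, 1440 + 368, 1440 + 359,
                   1440 + 366, 1440 + 362, 1440 + 361, 1440 + 370, 1440 + 377, 1440 + 383],
        "sl": [14.1, 13.4, 13.8, 14.7, 15.0, 16.0, 16.0, 15.8, 16.4, 14.8, 14.1, 13.4],
        "se": [92.4, 92.3, 92.0, 91.7, 90.7, 90.4, 89.3, 89.4, 89.6, 90.7, 91.9, 92.6],
        "waso": [36.7, 36.7, 37.8, 39.2, 42.5, 43.5, 48.0, 49.0, 47.5, 43.3, 39.0, 35.3],
        "wep": [3.78, 3.81, 3.94, 4.19, 4.81, 5.24, 5.90, 6.07, 5.67, 4.73, 4.05, 3.69],
    },
    index=pd.Index(MONTHS, name="month"),
)

# Selected meteorological regressors and their ensemble-averaged coefficients:
# response parameter -> {covariate: coefficient}. Units: response units per
# degree C (ta) or per minute of sunrise elapsed time (sunrise). The get-up /
# sunrise coefficient uses the three-decimal value reported in the text.
METEO_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "get_up": {"sunrise": 0.182},
    "tst": {"ta": -1.58},
    "sl": {"ta": 0.11},
    "se": {"ta": -0.111, "sunrise": 0.005},
    "waso": {"ta": 0.48},
    "wep": {"ta": 0.082, "sunrise": -0.0022},
}

# Empirical collinearity between daily mean ambient temperature and sunrise
# elapsed time in the reference dataset.
TA_SUNRISE_CORRELATION = 0.70

# Gender split of the reference cohort (30,485 male / 37,951 female).
FEMALE_FRACTION = 37951 / (30485 + 37951)

# Reported agreement of the SVM sleep-wake classifier with a wrist actigraph.
CLASSIFIER_REFERENCE_ACCURACY = 94.4
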