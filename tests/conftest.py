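import numpy as np
import pandas as pd
import pytest

from pestwarn.series import ALL_COLUMNS

# the eight example field records used by the hand-checked correlation and
# level-assignment tests (levels shown 0-3, displayed I-IV)
FIELD_ROWS = [
    ("2017-11-02", 0.0, 24.45, 21.71, 143.88, 6.52, 58, 1),
    ("2017-11-03", 0.0, 24.32, 20.58, 279.29, 9.67, 66, 3),
    ("2017-11-04", 0.0, 24.36, 21.90, 42.00, 10.10, 78, 2),
    ("2017-11-05", 0.0, 24.64, 23.33, 143.52, 8.04, 81, 2),
    ("2017-11-06", 0.0, 24.80, 24.04, 193.21, 11.21, 79, 0),
    ("2017-11-07", 0.0, 24.97, 22.95, 250.52, 9.29, 81, 1),
    ("2017-11-08", 0.0, 23.98, 18.00, 20.62, 3.60, 76, 2),
    ("2017-11-09", 0.5, 25.08, 25.41, 41.54, 11.58, 89, 2),
]

# published six-factor score pairs (Pearson r, grey degree) and the impact
# factors the study reports for them
PUBLISHED_SCORES = {
    "precipitation": (0.283327, 0.7125),
    "air_humidity": (0.161855, 0.621),
    "air_temperature": (0.404526, 0.7011),
    "soil_temperature": (0.465947, 0.6903),
    "soil_moisture": (0.392791, 0.6218),
    "leaf_wetness": (0.473599, 0.75399),
}
PUBLISHED_IMPACT = {
    "precipitation": 1.11,
    "air_humidity": 0.08,
    "soil_temperature": 1.54,
    "air_temperature": 1.37,
    "soil_moisture": 0.72,
    "leaf_wetness": 1.94,
}

# published per-level one-vs-rest counts (TP, FN, FP, TN) of the reference
# 761-record verification set
PUBLISHED_COUNTS = {
    "I": (367, 11, 14, 369),
    "II": (206, 8, 11, 536),
    "III": (143, 6, 0, 612),
    "IV": (20, 0, 0, 741),
}


@pytest.fixture
def field_table() -> pd.DataFrame:
    df = pd.DataFrame(FIELD_ROWS, columns=ALL_COLUMNS[:-1] + ["pest_level"])
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
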