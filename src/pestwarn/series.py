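"""Sensor-series container conventions.

A sensor series is a :class:`pandas.DataFrame` with one row per day:

    date, precipitation, soil_temperature, air_temperature,
    soil_moisture, leaf_wetness, air_humidity, pest_count

``date`` holds ISO-8601 calendar dates, strictly increasing.  The six factor
columns are floats; ``pest_count`` is a nonnegative integer (float dtype when
missing values are present).  Missing cells are ``NaN`` in memory and empty
fields in CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError

#: environmental factor columns, in canonical order
FACTOR_COLUMNS = [
    "precipitation",
    "soil_temperature",
    "air_temperature",
    "soil_moisture",
    "leaf_wetness",
    "air_humidity",
]

COUNT_COLUMN = "pest_count"
DATE_COLUMN = "date"

ALL_COLUMNS = [DATE_COLUMN, *FACTOR_COLUMNS, COUNT_COLUMN]

#: factors bounded to [0, 100] by their physical definition (percentages)
PERCENT_FACTORS = ("leaf_wetness", "air_humidity")


def validate_series(series: pd.DataFrame) -> None:
    """Check the structural invariants of a sensor series.

    Raises
    ------
    InputError
        on missing columns, non-increasing dates, out-of-range percentage
        factors, or negative pest counts.
    """
    missing_cols = [c for c in ALL_COLUMNS if c not in series.columns]
    if missing_cols:
        raise InputError(f"sensor series lacks columns: {missing_cols}")
    dates = pd.to_datetime(series[DATE_COLUMN])
    if len(dates) > 1 and not dates.is_monotonic_increasing:
        raise InputError("dates must be strictly increasing")
    if len(dates) > 1 and dates.duplicated().any():
        raise InputError("dates must be strictly increasing (duplicates found)")
    for col in PERCENT_FACTORS:
        vals = series[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise InputError(f"column {col!r} outside [0, 100]")
    counts = series[COUNT_COLUMN].dropna()
    if (counts < 0).any():
        raise InputError("pest_count must be nonnegative")


def read_csv(path) -> pd.DataFrame:
    """Read a sensor series CSV (empty fields are missing values)."""
    df = pd.read_csv(path, dtype={DATE_COLUMN: str})
    validate_series(df)
    return df


def write_csv(series: pd.DataFrame, path) -> None:
    """Write a sensor series CSV; NaN cells become empty fields."""
    out = series.copy()
    # integer counts print without a trailing ".0" unless missing cells force floats
    if out[COUNT_COLUMN].notna().all():
        out[COUNT_COLUMN] = out[COUNT_COLUMN].astype(np.int64)
    out.to_csv(path, index=False, na_rep="")
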