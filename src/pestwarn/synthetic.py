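"""Synthetic field-data generator.

Emulates a ~250-day multi-sensor vegetable-field campaign: six daily
environmental factors (rain gauge, soil/air temperature, soil moisture, leaf
wetness, air humidity) paired with a daily trap count of pests.  The count
model is log-linear and monotone in a weighted sum of the (range-scaled)
factors, with a four-regime mixture producing the well-separated abundance
bands that warning-level clustering assumes, plus multiplicative log-normal
noise.  One factor (air humidity by default) carries zero weight, giving a
planted null that downstream feature screening should reject.

Missing factor cells are injected completely at random at a configurable
per-cell rate; dates and pest counts are never blanked (the count is the
level ground truth, not a sensor reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigError, InputError
from .series import COUNT_COLUMN, DATE_COLUMN, FACTOR_COLUMNS

DEFAULT_WEIGHTS = {
    "precipitation": 1.0,
    "soil_temperature": 1.0,
    "air_temperature": 1.0,
    "soil_moisture": 1.0,
    "leaf_wetness": 1.2,
    "air_humidity": 0.0,
}

#: plausible sensor ranges (units of :mod:`pestwarn.series`)
DEFAULT_RANGES = {
    "precipitation": (0.0, 40.0),
    "soil_temperature": (10.0, 30.0),
    "air_temperature": (5.0, 35.0),
    "soil_moisture": (10.0, 300.0),
    "leaf_wetness": (0.0, 100.0),
    "air_humidity": (40.0, 100.0),
}

#: (count center, log-scale half-width, proportion) per abundance regime;
#: centers chosen so cluster cut points land near 56 / 131 / 299
DEFAULT_MIXTURE = [
    (20.0, 0.85, 0.45),
    (88.0, 0.30, 0.28),
    (200.0, 0.30, 0.17),
    (430.0, 0.30, 0.10),
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic campaign.

    ``factor_weights`` act on the log expected count through the weighted sum
    of range-scaled factors; any factor listed in ``null_factors`` has its
    weight forced to zero.  ``level_mixture`` holds one
    (count center, log spread, proportion) triple per abundance regime;
    ``missing_rate`` is the per-cell blanking probability for factor cells.
    """

    n_records: int = 2536
    seed: int = 0
    factor_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    null_factors: tuple = ("air_humidity",)
    base_count: float = 10.0
    noise_sd: float = 0.08
    missing_rate: float = 0.009
    level_mixture: list = field(default_factory=lambda: list(DEFAULT_MIXTURE))
    factor_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    start_date: str = "2017-06-01"

    def validate(self) -> None:
        if self.n_records < 10:
            raise ConfigError(f"n_records must be >= 10, got {self.n_records}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.base_count <= 0:
            raise ConfigError(f"base_count must be positive, got {self.base_count}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        props = sum(p for _, _, p in self.level_mixture)
        if abs(props - 1.0) > 1e-9:
            raise ConfigError(f"mixture proportions sum to {props}, not 1")
        for f in FACTOR_COLUMNS:
            if f not in self.factor_weights:
                raise ConfigError(f"factor_weights missing {f!r}")
            lo, hi = self.factor_ranges[f]
            if not lo < hi:
                raise ConfigError(f"empty range for {f!r}: ({lo}, {hi})")
        for f in self.null_factors:
            if f not in FACTOR_COLUMNS:
                raise ConfigError(f"unknown null factor {f!r}")

    def effective_weights(self) -> dict:
        """Weights with null factors forced to exactly zero."""
        w = dict(self.factor_weights)
        for f in self.null_factors:
            w[f] = 0.0
        return w


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent substreams for factors / count noise / missingness."""
    return tuple(np.random.default_rng(s)
                 for s in np.random.SeedSequence(seed).spawn(3))


def _scaled_factors(series: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    cols = []
    for f in FACTOR_COLUMNS:
        lo, hi = config.factor_ranges[f]
        cols.append((series[f].to_numpy(dtype=float) - lo) / (hi - lo))
    return np.column_stack(cols)


def generate_pest_counts(series: pd.DataFrame,
                         config: GeneratorConfig) -> pd.DataFrame:
    """Attach pest counts driven by the configured factor weights.

    Each row's count is ``round(exp(log base + regime offset + noise))``,
    clamped at zero, where the regime and its interior offset follow the
    row's weighted factor sum: the sum's theoretical distribution (normal
    approximation of the sum of range-scaled uniforms) is cut at the mixture
    proportions, so regime membership — and hence the eventual warning
    level — is a monotone function of the factors and the regime shares land
    near the configured proportions.  With all weights zero and zero noise
    every count equals ``round(base_count)``.

    Raises
    ------
    InputError
        missing values in any factor column.
    """
    config.validate()
    if series[FACTOR_COLUMNS].isna().any().any():
        raise InputError("factor columns must be complete before count generation")
    _, rng_noise, _ = _streams(config.seed)
    n = len(series)
    w = np.array([config.effective_weights()[f] for f in FACTOR_COLUMNS])
    noise = rng_noise.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 \
        else np.zeros(n)

    if np.all(w == 0):
        log_count = np.log(config.base_count) + noise
    else:
        s = _scaled_factors(series, config) @ w
        s_min = np.minimum(w, 0.0).sum()
        s_max = np.maximum(w, 0.0).sum()
        u = np.clip((s - s_min) / (s_max - s_min), 0.0, 1.0)
        # theoretical moments of u for unit-uniform scaled factors
        mean_u = (w.sum() / 2.0 - s_min) / (s_max - s_min)
        sd_u = np.sqrt((w ** 2).sum() / 12.0) / (s_max - s_min)
        props = np.array([p for _, _, p in config.level_mixture])
        cuts = mean_u + sd_u * norm.ppf(np.cumsum(props)[:-1])
        edges = np.concatenate([[mean_u - 3 * sd_u], cuts, [mean_u + 3 * sd_u]])
        regime = np.searchsorted(cuts, u, side="right")
        lo = edges[regime]
        hi = edges[regime + 1]
        t = np.clip(2.0 * (u - lo) / (hi - lo) - 1.0, -1.0, 1.0)
        centers = np.array([c for c, _, _ in config.level_mixture])
        spreads = np.array([s_ for _, s_, _ in config.level_mixture])
        log_count = np.log(centers[regime]) + spreads[regime] * t + noise

    counts = np.maximum(np.round(np.exp(log_count)), 0.0).astype(np.int64)
    out = series.copy()
    out[COUNT_COLUMN] = counts
    return out


def generate_sensor_series(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete campaign table, then blank factor cells MCAR.

    Returns a sensor series of ``n_records`` daily rows.  Factor values are
    drawn uniformly within their configured ranges; pest counts come from
    :func:`generate_pest_counts` on the complete factors; afterwards each
    factor cell is independently blanked with probability ``missing_rate``.
    The injected cell positions are recorded in ``df.attrs["missing_cells"]``
    as (row, column) pairs for cross-checks.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng_factors, _, rng_miss = _streams(config.seed)
    n = config.n_records
    data = {DATE_COLUMN: pd.date_range(config.start_date, periods=n,
                                       freq="D").strftime("%Y-%m-%d")}
    for f in FACTOR_COLUMNS:
        lo, hi = config.factor_ranges[f]
        data[f] = rng_factors.uniform(lo, hi, size=n)
    series = pd.DataFrame(data)
    series = generate_pest_counts(series, config)

    injected: list[tuple[int, str]] = []
    if config.missing_rate > 0:
        mask = rng_miss.random((n, len(FACTOR_COLUMNS))) < config.missing_rate
        for j, f in enumerate(FACTOR_COLUMNS):
            col = series[f].to_numpy(dtype=float)
            col[mask[:, j]] = np.nan
            series[f] = col
            injected.extend((int(r), f) for r in np.nonzero(mask[:, j])[0])
    injected.sort()
    series.attrs["missing_cells"] = injected
    return series


def planted_predictor(series: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """The noiseless weighted factor sum each row's count was driven by
    (oracle for screening cross-checks; requires complete factors)."""
    if series[FACTOR_COLUMNS].isna().any().any():
        raise InputError("factor columns must be complete")
    w = np.array([config.effective_weights()[f] for f in FACTOR_COLUMNS])
    return _scaled_factors(series, config) @ w
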