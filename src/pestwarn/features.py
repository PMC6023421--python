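"""Feature scoring and selection.

Each environmental factor is scored against the warning-level sequence two
ways: the Pearson product-moment correlation (linear association) and the
grey relational degree (trend similarity of the min-max-scaled curves).  The
two rankings are fused into a single impact factor

    E_k = minmax(|r_k|) + minmax(rho_k)   in [0, 2],

where ``minmax`` rescales each score family to [0, 1] over the factors under
consideration; factors at or above a threshold (default 0.5) enter the
classifier's feature set.  Correlation magnitude, not sign, measures
relevance, hence |r| in the first term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError
from .preprocessing import LevelScheme, assign_levels
from .series import COUNT_COLUMN, FACTOR_COLUMNS

DEFAULT_RESOLUTION = 0.5
DEFAULT_THRESHOLD = 0.5


@dataclass
class FeatureScores:
    """Per-factor relevance scores and the selection decision."""

    factor_name: str
    pearson_r: float
    grey_degree: float
    impact_factor: float = float("nan")
    selected: bool = False


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length sequences.

    Raises
    ------
    InputError
        length mismatch or fewer than 3 points.
    DegenerateInputError
        either sequence constant.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise InputError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 3:
        raise InputError(f"need >= 3 points, got {len(xa)}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise DegenerateInputError("constant sequence has no defined correlation")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def minmax_scale(x: Sequence[float]) -> np.ndarray:
    """Scale a sequence to [0, 1]; a constant sequence maps to all zeros."""
    a = np.asarray(list(x), dtype=float)
    span = a.max() - a.min()
    if span == 0:
        return np.zeros_like(a)
    return (a - a.min()) / span


def grey_relational_degrees(reference: Sequence[float],
                            comparisons: Sequence[Sequence[float]],
                            resolution: float = DEFAULT_RESOLUTION,
                            global_extrema: bool = True) -> np.ndarray:
    """Grey relational degree of each comparison sequence to the reference.

    Per-point coefficients are

        r(k) = (dmin + resolution * dmax) / (d_i(k) + resolution * dmax)

    with ``d_i(k) = |x0(k) - xi(k)|`` and ``dmin``/``dmax`` the extrema of
    the deviations — over the whole batch of comparison sequences when
    ``global_extrema`` (standard practice), else per sequence.  The degree is
    the mean coefficient, in (0, 1]; an identical sequence scores exactly 1.

    Sequences are assumed pre-scaled to a common range (see
    :func:`score_factors`, which min-max scales each to [0, 1]).

    Raises
    ------
    InputError
        length mismatch or fewer than 2 points.
    PestwarnError
        resolution outside (0, 1).
    """
    if not 0.0 < resolution < 1.0:
        raise InputError(f"resolution must lie in (0, 1), got {resolution}")
    ref = np.asarray(list(reference), dtype=float)
    if len(ref) < 2:
        raise InputError(f"need >= 2 points, got {len(ref)}")
    comp = np.asarray([list(c) for c in comparisons], dtype=float)
    if comp.ndim != 2 or comp.shape[1] != len(ref):
        raise InputError("comparison sequences must match reference length")
    delta = np.abs(comp - ref[None, :])
    if global_extrema:
        dmin = delta.min()
        dmax = delta.max()
        if dmax == 0:  # every comparison identical to the reference
            return np.ones(len(comp))
        coeff = (dmin + resolution * dmax) / (delta + resolution * dmax)
    else:
        dmin = delta.min(axis=1, keepdims=True)
        dmax = delta.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            coeff = (dmin + resolution * dmax) / (delta + resolution * dmax)
        coeff = np.where(np.isnan(coeff), 1.0, coeff)  # identical sequence: all d=0
    return coeff.mean(axis=1)


def grey_relational_degree(reference: Sequence[float],
                           comparison: Sequence[float],
                           resolution: float = DEFAULT_RESOLUTION) -> float:
    """Single-sequence convenience wrapper (batch of one)."""
    return float(grey_relational_degrees(reference, [comparison], resolution)[0])


def impact_factor_scores(pearson: Sequence[float], grey: Sequence[float],
                         factor_names: Sequence[str] | None = None
                         ) -> list[FeatureScores]:
    """Fuse the two score families into impact factors E_k in [0, 2].

    Each family is min-max normalized across factors (|r| for the Pearson
    family), and the two normalized terms are summed, so the factor maximal
    in both families scores exactly 2 and the minimal one exactly 0.

    Raises
    ------
    InputError
        fewer than 2 factors or mismatched lengths.
    DegenerateInputError
        all scores equal within a family (normalization undefined).
    """
    p = np.asarray(list(pearson), dtype=float)
    g = np.asarray(list(grey), dtype=float)
    if len(p) != len(g):
        raise InputError(f"score families differ in length: {len(p)} vs {len(g)}")
    if len(p) < 2:
        raise InputError("need >= 2 factors to normalize scores")
    if factor_names is None:
        factor_names = [f"factor_{i}" for i in range(len(p))]
    pa = np.abs(p)
    for name, fam in (("pearson", pa), ("grey", g)):
        if fam.max() == fam.min():
            raise DegenerateInputError(
                f"all {name} scores equal ({fam[0]:g}); min-max normalization undefined")
    ek = (pa - pa.min()) / (pa.max() - pa.min()) + (g - g.min()) / (g.max() - g.min())
    return [FeatureScores(factor_name=n, pearson_r=float(r), grey_degree=float(d),
                          impact_factor=float(e))
            for n, r, d, e in zip(factor_names, p, g, ek)]


def select_features(scores: list[FeatureScores],
                    threshold: float = DEFAULT_THRESHOLD) -> list[FeatureScores]:
    """Mark ``selected = (impact_factor >= threshold)`` on each score."""
    for s in scores:
        s.selected = bool(s.impact_factor >= threshold)
    return scores


def score_factors(series: pd.DataFrame, scheme: LevelScheme,
                  resolution: float = DEFAULT_RESOLUTION,
                  threshold: float = DEFAULT_THRESHOLD) -> list[FeatureScores]:
    """Score every factor column against the warning-level sequence.

    Pearson correlates each raw factor with the integer level sequence; grey
    relational degrees compare the min-max-scaled factor curves with the
    min-max-scaled level curve, with deviation extrema taken over the whole
    six-factor batch.  The series must be complete (impute first).
    """
    if series[FACTOR_COLUMNS].isna().any().any():
        raise InputError("factor columns must be complete; impute first")
    levels = assign_levels(series[COUNT_COLUMN].to_numpy(dtype=float), scheme)
    pearson = [pearson_r(series[f], levels) for f in FACTOR_COLUMNS]
    ref = minmax_scale(levels)
    comps = [minmax_scale(series[f]) for f in FACTOR_COLUMNS]
    grey = grey_relational_degrees(ref, comps, resolution)
    scores = impact_factor_scores(pearson, grey, FACTOR_COLUMNS)
    return select_features(scores, threshold)


def scores_to_frame(scores: list[FeatureScores]) -> pd.DataFrame:
    """Tabulate scores (columns: factor, pearson_r, grey_degree,
    impact_factor, selected)."""
    return pd.DataFrame(
        {"factor": [s.factor_name for s in scores],
         "pearson_r": [s.pearson_r for s in scores],
         "grey_degree": [s.grey_degree for s in scores],
         "impact_factor": [s.impact_factor for s in scores],
         "selected": [s.selected for s in scores]})
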