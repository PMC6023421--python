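"""Data preprocessing: missing-value imputation, warning-level discretization,
and z-score normalization.

The stage mirrors how gappy daily field-sensor data are prepared for pest
early warning: gaps left by sensor damage or dropped transmissions are filled
by local Lagrange polynomial interpolation along the time axis, daily trap
counts are discretized into ordered warning levels (I < II < ...) by
one-dimensional k-means on the counts, and feature columns are standardized
to zero mean and unit (population) standard deviation before model fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError, InsufficientDataError
from .series import COUNT_COLUMN, FACTOR_COLUMNS, PERCENT_FACTORS

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


# ---------------------------------------------------------------------------
# missing values
# ---------------------------------------------------------------------------

def scan_missing(series: pd.DataFrame,
                 columns: Sequence[str] | None = None) -> list[tuple[int, str]]:
    """Locate missing cells.

    Parameters
    ----------
    series
        Sensor series (see :mod:`pestwarn.series`).
    columns
        Columns to scan; defaults to the six factor columns plus the count.

    Returns
    -------
    list of (row position, column name), in row-major order.
    """
    if columns is None:
        columns = [*FACTOR_COLUMNS, COUNT_COLUMN]
    mask = series[list(columns)].isna().to_numpy()
    rows, cols = np.nonzero(mask)
    return [(int(r), columns[c]) for r, c in zip(rows, cols)]


def lagrange_interpolate(points: Sequence[tuple[float, float]],
                         x_query: float) -> float:
    """Evaluate the Lagrange interpolation polynomial through ``points``.

    L(x) = sum_i y_i * prod_{j != i} (x - x_j) / (x_i - x_j)

    Exactly reproduces any polynomial of degree <= n-1 sampled at the nodes.

    Raises
    ------
    InsufficientDataError
        fewer than two points.
    DegenerateInputError
        duplicate x coordinates.
    """
    pts = list(points)
    if len(pts) < 2:
        raise InsufficientDataError(
            f"Lagrange interpolation needs >= 2 points, got {len(pts)}")
    xs = np.asarray([p[0] for p in pts], dtype=float)
    ys = np.asarray([p[1] for p in pts], dtype=float)
    if len(np.unique(xs)) != len(xs):
        raise DegenerateInputError("duplicate x coordinates in interpolation nodes")
    total = 0.0
    for i in range(len(xs)):
        num = 1.0
        den = 1.0
        for j in range(len(xs)):
            if j == i:
                continue
            num *= x_query - xs[j]
            den *= xs[i] - xs[j]
        total += ys[i] * num / den
    return float(total)


def impute_series(series: pd.DataFrame, window: int = 4) -> pd.DataFrame:
    """Fill missing factor cells by local Lagrange interpolation.

    For each missing cell the ``window`` nearest non-missing rows of the same
    column (by row-index distance, lower index on ties) serve as nodes, with
    the row index as the x coordinate — daily records are evenly sampled, so
    index distance is time distance.  Observed cells are never altered, and
    the pest-count column is never imputed (warning levels are ground truth,
    not a sensor reading).  Imputed percentage factors are clamped to
    [0, 100].

    Raises
    ------
    InsufficientDataError
        a factor column with fewer than two observed values (an entirely
        missing column included), naming the column.
    """
    out = series.copy()
    n = len(out)
    for col in FACTOR_COLUMNS:
        values = out[col].to_numpy(dtype=float)
        missing = np.isnan(values)
        if not missing.any():
            continue
        known_idx = np.nonzero(~missing)[0]
        if len(known_idx) < 2:
            raise InsufficientDataError(
                f"column {col!r} has {len(known_idx)} observed values; "
                "need at least 2 to interpolate")
        w = min(window, len(known_idx))
        filled = values.copy()
        for row in np.nonzero(missing)[0]:
            # nearest known rows; stable sort keeps the lower index on ties
            order = np.argsort(np.abs(known_idx - row), kind="stable")
            nodes = known_idx[order[:w]]
            est = lagrange_interpolate(
                [(float(i), float(values[i])) for i in nodes], float(row))
            if col in PERCENT_FACTORS:
                est = min(max(est, 0.0), 100.0)
            filled[row] = est
        out[col] = filled
    _ = n  # row count unchanged by construction
    return out


def drop_missing_counts(series: pd.DataFrame) -> pd.DataFrame:
    """Drop rows whose pest count is missing (counts are never imputed)."""
    out = series[series[COUNT_COLUMN].notna()].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# warning-level discretization
# ---------------------------------------------------------------------------

@dataclass
class LevelScheme:
    """Ordered mapping from pest-count ranges to warning levels.

    Levels partition the nonnegative integers into ``k`` contiguous closed
    ranges: level i covers ``boundaries[i-1]+1 .. boundaries[i]`` (level 1
    starts at 0; the top level is unbounded above).  A count equal to a cut
    point belongs to the lower level.
    """

    k: int
    centroids: list[float]
    boundaries: list[int]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = ROMAN[: self.k]
        if len(self.centroids) != self.k or len(self.boundaries) != self.k - 1:
            raise InputError("scheme needs k centroids and k-1 boundaries")
        if any(b >= a for a, b in zip(self.centroids[1:], self.centroids[:-1])):
            raise InputError("centroids must be strictly ascending")
        if any(b >= a for a, b in zip(self.boundaries[1:], self.boundaries[:-1])):
            raise InputError("boundaries must be strictly ascending")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k,
                       "centroids": list(map(float, self.centroids)),
                       "boundaries": list(map(int, self.boundaries)),
                       "labels": list(self.labels)}, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LevelScheme":
        with open(path) as fh:
            d = json.load(fh)
        return cls(k=d["k"], centroids=d["centroids"],
                   boundaries=d["boundaries"], labels=d["labels"])


def _kmeanspp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on the 1-D sample."""
    centroids = [values[rng.integers(len(values))]]
    for _ in range(k - 1):
        d2 = np.min((values[:, None] - np.asarray(centroids)[None, :]) ** 2, axis=1)
        if d2.sum() == 0:
            # all remaining mass on chosen points; fall back to uniform
            centroids.append(values[rng.integers(len(values))])
            continue
        probs = d2 / d2.sum()
        centroids.append(values[rng.choice(len(values), p=probs)])
    return np.asarray(centroids, dtype=float)


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int,
           tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd iterations from the given seeds; returns (centroids, assignment,
    per-iteration E history, which is non-increasing)."""
    k = len(centroids)
    centroids = np.sort(centroids)
    history: list[float] = []
    assign = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        # centroids kept ascending, so argmin's first-minimum rule implements
        # the assign-to-lower-centroid tie-break
        dist = np.abs(x[:, None] - centroids[None, :])
        assign = np.argmin(dist, axis=1)
        new_centroids = centroids.copy()
        for j in range(k):
            members = x[assign == j]
            if len(members):
                new_centroids[j] = members.mean()
            else:  # re-seed an empty cluster at the worst-fit point
                worst = np.argmax(np.min(dist, axis=1))
                new_centroids[j] = x[worst]
        centroids = np.sort(new_centroids)
        dist = np.abs(x[:, None] - centroids[None, :])
        assign = np.argmin(dist, axis=1)
        e = float(np.sum((x - centroids[assign]) ** 2))
        if history and abs(history[-1] - e) <= tol:
            history.append(e)
            break
        history.append(e)
    return centroids, assign, history


def _exact_1d_kmeans(x: np.ndarray, k: int) -> np.ndarray:
    """Globally optimal 1-D k-means by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the problem
    reduces to an optimal contiguous partition of the sorted sample,
    solvable exactly in O(k n^2) with prefix sums.  Returns the cluster
    index (0..k-1, ascending) of each point of the *unsorted* input.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    s = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def sse(i: np.ndarray, j: int) -> np.ndarray:
        # within-group sum of squares of xs[i..j] inclusive, vectorized in i
        cnt = j - i + 1
        tot = s[j + 1] - s[i]
        return (s2[j + 1] - s2[i]) - tot ** 2 / cnt

    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    idx = np.arange(n)
    cost[0] = s2[1:] - s[1:] ** 2 / np.arange(1, n + 1)
    for m in range(1, k):
        for j in range(m, n):
            i = idx[m:j + 1]  # first index of the m-th group
            cand = cost[m - 1][i - 1] + sse(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            split[m, j] = i[best]
    # backtrack group boundaries
    assign_sorted = np.empty(n, dtype=int)
    j = n - 1
    for m in range(k - 1, -1, -1):
        i = split[m, j] if m else 0
        assign_sorted[i:j + 1] = m
        j = i - 1
    assign = np.empty(n, dtype=int)
    assign[order] = assign_sorted
    return assign


def kmeans_1d(values: Sequence[float], k: int = 4, seed: int = 0,
              max_iter: int = 300, tol: float = 1e-9,
              method: str = "exact", n_init: int = 10) -> LevelScheme:
    """Cluster nonnegative counts into ``k`` ordered levels by k-means.

    Minimizes the within-cluster sum of squared Euclidean distances
    ``E = sum_k sum_{x in c_k} (x - m_k)^2``.  The default ``method="exact"``
    solves the 1-D problem to global optimality by dynamic programming over
    the sorted sample (optimal 1-D clusters are contiguous), so the result
    does not depend on ``seed``; ``method="lloyd"`` runs classical seeded
    k-means++ / Lloyd iterations (best of ``n_init`` restarts), under which
    a point equidistant to two centroids joins the lower-centroid cluster.

    Clusters are relabelled I, II, ... in ascending centroid order, and each
    integer cut point is the floored midpoint between the maximum of the
    lower cluster and the minimum of the upper cluster, so the resulting
    ranges are contiguous.

    Raises
    ------
    DegenerateInputError
        fewer distinct values than ``k``.
    """
    x = np.asarray(list(values), dtype=float)
    if len(np.unique(x)) < k:
        raise DegenerateInputError(
            f"need >= {k} distinct values for k={k}, got {len(np.unique(x))}")
    if method == "exact":
        assign = _exact_1d_kmeans(x, k)
        centroids = np.array([x[assign == j].mean() for j in range(k)])
    elif method == "lloyd":
        rng = np.random.default_rng(seed)
        best: tuple[float, np.ndarray, np.ndarray] | None = None
        for _ in range(max(1, n_init)):
            centroids, assign, history = _lloyd(
                x, _kmeanspp_init(x, k, rng), max_iter, tol)
            if best is None or history[-1] < best[0]:
                best = (history[-1], centroids, assign)
        _, centroids, assign = best
    else:
        raise InputError(f"unknown method {method!r}")
    boundaries = []
    for j in range(k - 1):
        lo = x[assign == j].max()
        hi = x[assign == j + 1].min()
        boundaries.append(int(np.floor((lo + hi) / 2.0)))
    return LevelScheme(k=k, centroids=[float(c) for c in centroids],
                       boundaries=boundaries)


def cluster_energy(values: Sequence[float], scheme: LevelScheme) -> float:
    """Within-cluster sum of squares E of ``values`` under ``scheme``'s
    centroids (each value assigned to its nearest centroid)."""
    x = np.asarray(list(values), dtype=float)
    c = np.asarray(scheme.centroids)
    d = np.min((x[:, None] - c[None, :]) ** 2, axis=1)
    return float(d.sum())


def assign_level(count: float, scheme: LevelScheme) -> str:
    """Map a pest count to its warning-level label.

    A count equal to a cut point maps to the lower level; counts above the
    top cut map to the highest level.
    """
    if count < 0:
        raise InputError(f"pest count must be nonnegative, got {count}")
    idx = int(np.searchsorted(np.asarray(scheme.boundaries), count, side="left"))
    return scheme.labels[idx]


def assign_levels(counts: Sequence[float], scheme: LevelScheme) -> np.ndarray:
    """Vectorized :func:`assign_level`: returns integer level indices 0..k-1."""
    c = np.asarray(list(counts), dtype=float)
    if (c < 0).any():
        raise InputError("pest counts must be nonnegative")
    return np.searchsorted(np.asarray(scheme.boundaries), c, side="left")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def zscore_normalize(matrix: np.ndarray,
                     column_names: Sequence[str] | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns to mean 0 and population standard deviation 1.

    Returns ``(normalized, means, sds)`` so held-out data can be transformed
    with the training statistics via :func:`zscore_apply`.

    Raises
    ------
    DegenerateInputError
        a constant column (zero standard deviation), naming it.
    """
    m = np.asarray(matrix, dtype=float)
    means = m.mean(axis=0)
    sds = m.std(axis=0)  # population (divide-by-n) convention
    zero = np.nonzero(sds == 0)[0]
    if len(zero):
        name = column_names[zero[0]] if column_names is not None else f"#{zero[0]}"
        raise DegenerateInputError(f"constant column {name} cannot be z-scored")
    return (m - means) / sds, means, sds


def zscore_apply(matrix: np.ndarray, means: np.ndarray,
                 sds: np.ndarray) -> np.ndarray:
    """Apply previously fitted z-score statistics (for test data)."""
    return (np.asarray(matrix, dtype=float) - means) / sds


def zscore_invert(matrix: np.ndarray, means: np.ndarray,
                  sds: np.ndarray) -> np.ndarray:
    """Invert :func:`zscore_apply` (algebraic round-trip)."""
    return np.asarray(matrix, dtype=float) * sds + means
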