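"""Imputation, level discretization and normalization contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestwarn import (DegenerateInputError, GeneratorConfig, InputError,
                      InsufficientDataError, LevelScheme, assign_level,
                      assign_levels, generate_sensor_series, impute_series,
                      kmeans_1d, lagrange_interpolate, scan_missing,
                      zscore_apply, zscore_invert, zscore_normalize)
from pestwarn.preprocessing import _kmeanspp_init, _lloyd, cluster_energy
from pestwarn.series import FACTOR_COLUMNS


# ---------------------------------------------------------------------------
# missing-value scan
# ---------------------------------------------------------------------------

class TestScanMissing:
    def test_complete_series_yields_empty_list(self):
        df = generate_sensor_series(GeneratorConfig(n_records=20, seed=0,
                                                    missing_rate=0.0))
        assert scan_missing(df) == []

    def test_single_gap_located(self):
        df = generate_sensor_series(GeneratorConfig(n_records=20, seed=0,
                                                    missing_rate=0.0))
        df.loc[5, "soil_temperature"] = np.nan
        assert scan_missing(df) == [(5, "soil_temperature")]

    def test_scan_matches_generator_injection_log(self):
        df = generate_sensor_series(GeneratorConfig(n_records=1000, seed=7,
                                                    missing_rate=0.05))
        found = scan_missing(df, columns=FACTOR_COLUMNS)
        assert sorted(found) == sorted(df.attrs["missing_cells"])


# ---------------------------------------------------------------------------
# Lagrange interpolation
# ---------------------------------------------------------------------------

def newton_divided_difference(points, xq):
    """Independent oracle: Newton's divided-difference form."""
    xs = [p[0] for p in points]
    coef = [p[1] for p in points]
    n = len(xs)
    for j in range(1, n):
        for i in range(n - 1, j - 1, -1):
            coef[i] = (coef[i] - coef[i - 1]) / (xs[i] - xs[i - j])
    acc = coef[-1]
    for i in range(n - 2, -1, -1):
        acc = acc * (xq - xs[i]) + coef[i]
    return acc


class TestLagrange:
    @pytest.mark.parametrize("points,xq,expected", [
        ([(0, 0), (1, 2)], 0.5, 1.0),               # line through two points
        ([(0, 0), (1, 1), (2, 4)], 3.0, 9.0),        # y = x^2 extrapolated
        ([(0, 5), (1, 5), (2, 5)], 7.3, 5.0),        # constant polynomial
    ])
    def test_known_polynomials(self, points, xq, expected):
        assert lagrange_interpolate(points, xq) == pytest.approx(expected)

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(DegenerateInputError):
            lagrange_interpolate([(1, 2), (1, 3)], 0.0)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            lagrange_interpolate([(1, 2)], 0.0)

    def test_matches_newton_oracle_on_random_nodes(self, rng):
        for _ in range(25):
            xs = rng.permutation(rng.uniform(-5, 5, 6))
            while len(np.unique(xs)) < 6:
                xs = rng.uniform(-5, 5, 6)
            ys = rng.uniform(-10, 10, 6)
            xq = rng.uniform(-6, 6)
            pts = list(zip(xs, ys))
            expected = newton_divided_difference(pts, xq)
            got = lagrange_interpolate(pts, xq)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(coeffs=st.lists(st.floats(-3, 3), min_size=1, max_size=5),
           xq=st.floats(-2, 2))
    def test_reproduces_sampled_polynomial(self, coeffs, xq):
        """Degree <= n-1 polynomials are reproduced exactly at any query."""
        poly = np.polynomial.Polynomial(coeffs)
        xs = np.linspace(-1.5, 1.5, len(coeffs) + 1)
        pts = [(x, poly(x)) for x in xs]
        assert lagrange_interpolate(pts, xq) == pytest.approx(
            poly(xq), rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImpute:
    def test_complete_series_is_noop(self):
        df = generate_sensor_series(GeneratorConfig(n_records=40, seed=1,
                                                    missing_rate=0.0))
        pd.testing.assert_frame_equal(impute_series(df), df)

    def test_linear_column_gap_filled_exactly(self):
        df = generate_sensor_series(GeneratorConfig(n_records=30, seed=1,
                                                    missing_rate=0.0))
        df["soil_temperature"] = np.arange(30) * 0.5 + 12.0
        df.loc[14, "soil_temperature"] = np.nan
        out = impute_series(df, window=4)
        assert out.loc[14, "soil_temperature"] == pytest.approx(14 * 0.5 + 12.0)

    def test_observed_cells_never_altered(self):
        cfg = GeneratorConfig(n_records=300, seed=8, missing_rate=0.05)
        df = generate_sensor_series(cfg)
        out = impute_series(df, window=4)
        observed = df[FACTOR_COLUMNS].notna()
        for col in FACTOR_COLUMNS:
            m = observed[col]
            np.testing.assert_array_equal(out.loc[m, col], df.loc[m, col])

    def test_percent_factors_clamped(self):
        df = generate_sensor_series(GeneratorConfig(n_records=12, seed=1,
                                                    missing_rate=0.0))
        # steep local trend whose cubic extrapolation would exceed 100
        df["air_humidity"] = [10, 30, 55, 85, np.nan, 99, 98, 97, 96, 95, 94, 93]
        out = impute_series(df, window=4)
        assert 0 <= out.loc[4, "air_humidity"] <= 100

    def test_imputation_error_bounded_by_local_variation(self):
        cfg = GeneratorConfig(n_records=500, seed=21, missing_rate=0.05)
        complete = generate_sensor_series(
            GeneratorConfig(n_records=500, seed=21, missing_rate=0.0))
        gappy = generate_sensor_series(cfg)
        out = impute_series(gappy, window=4)
        for col in FACTOR_COLUMNS:
            holes = gappy[col].isna()
            if not holes.any():
                continue
            err = np.abs(out.loc[holes, col] - complete.loc[holes, col]).mean()
            scale = np.abs(np.diff(complete[col])).mean()
            assert err < 2 * scale, col

    def test_empty_column_error_names_column(self):
        df = generate_sensor_series(GeneratorConfig(n_records=20, seed=1,
                                                    missing_rate=0.0))
        df["leaf_wetness"] = np.nan
        with pytest.raises(InsufficientDataError, match="leaf_wetness"):
            impute_series(df)


# ---------------------------------------------------------------------------
# 1-D k-means and level schemes
# ---------------------------------------------------------------------------

def exhaustive_partition_energy(values, k):
    """Global optimum of E by brute force over contiguous sorted partitions."""
    xs = np.sort(np.asarray(values, float))
    n = len(xs)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        e, lo = 0.0, 0
        for c in (*cuts, n):
            g = xs[lo:c]
            e += ((g - g.mean()) ** 2).sum()
            lo = c
        best = min(best, e)
    return best


class TestKmeans1D:
    def test_separated_pairs_split_cleanly(self):
        scheme = kmeans_1d([1, 2, 100, 101], k=2)
        assert scheme.centroids == [1.5, 100.5]
        assert 2 < scheme.boundaries[0] < 100

    def test_identical_values_single_cluster(self):
        scheme = kmeans_1d([7, 7, 7, 7], k=1)
        assert scheme.centroids == [7.0]
        assert cluster_energy([7, 7, 7, 7], scheme) == 0.0

    def test_fewer_distinct_values_than_k_rejected(self):
        with pytest.raises(DegenerateInputError):
            kmeans_1d([1, 1, 2, 2], k=3)

    @pytest.mark.parametrize("method", ["exact", "lloyd"])
    def test_determinism(self, method):
        vals = np.random.default_rng(5).uniform(0, 400, 200)
        a = kmeans_1d(vals, 4, seed=3, method=method)
        b = kmeans_1d(vals, 4, seed=3, method=method)
        assert a.centroids == b.centroids and a.boundaries == b.boundaries

    def test_exact_solver_matches_exhaustive_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(8, 25))
            k = int(rng.integers(2, 5))
            vals = np.round(rng.uniform(0, 100, n), 2)
            if len(np.unique(vals)) < k:
                continue
            scheme = kmeans_1d(vals, k)
            assert cluster_energy(vals, scheme) == pytest.approx(
                exhaustive_partition_energy(vals, k), rel=1e-12, abs=1e-9)

    def test_lloyd_energy_non_increasing(self, rng):
        vals = rng.uniform(0, 300, 150)
        init = _kmeanspp_init(vals, 4, np.random.default_rng(0))
        _, _, history = _lloyd(vals, init, max_iter=100, tol=0.0)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_boundaries_between_centroids(self, rng):
        vals = rng.uniform(0, 500, 400)
        s = kmeans_1d(vals, 4)
        for i, b in enumerate(s.boundaries):
            assert s.centroids[i] <= b <= s.centroids[i + 1]


class TestLevelScheme:
    @pytest.fixture
    def study_scheme(self):
        # the four-level scheme with cut points at 56 / 131 / 299
        return LevelScheme(k=4, centroids=[25.0, 90.0, 200.0, 420.0],
                           boundaries=[56, 131, 299])

    def test_low_count_maps_to_level_one(self, study_scheme):
        assert assign_level(0, study_scheme) == "I"

    def test_count_300_maps_to_top_level(self, study_scheme):
        assert assign_level(300, study_scheme) == "IV"

    def test_cut_point_counts_map_to_lower_level(self, study_scheme):
        for b, expected in zip(study_scheme.boundaries, ["I", "II", "III"]):
            assert assign_level(b, study_scheme) == expected
            assert assign_level(b + 1, study_scheme) != expected

    def test_negative_count_rejected(self, study_scheme):
        with pytest.raises(InputError):
            assign_level(-1, study_scheme)

    def test_levels_partition_nonnegative_integers(self, study_scheme):
        counts = np.arange(0, 500)
        levels = assign_levels(counts, study_scheme)
        # contiguous, ordered, no gaps
        assert (np.diff(levels) >= 0).all()
        assert set(levels) == {0, 1, 2, 3}

    def test_json_round_trip(self, study_scheme, tmp_path):
        p = tmp_path / "scheme.json"
        study_scheme.to_json(p)
        back = LevelScheme.from_json(p)
        assert back == study_scheme

    def test_invalid_scheme_rejected(self):
        with pytest.raises(InputError):
            LevelScheme(k=3, centroids=[5.0, 4.0, 10.0], boundaries=[4, 7])


# ---------------------------------------------------------------------------
# z-score normalization
# ---------------------------------------------------------------------------

class TestZScore:
    def test_symmetric_three_point_column(self):
        norm, means, sds = zscore_normalize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(norm[:, 0], [-1.224744871, 0.0, 1.224744871],
                                   atol=1e-9)
        assert means[0] == 2.0 and sds[0] == pytest.approx(np.sqrt(2 / 3))

    def test_output_moments(self, rng):
        m = rng.normal(5, 3, size=(1000, 5))
        norm, _, _ = zscore_normalize(m)
        np.testing.assert_allclose(norm.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(norm.std(axis=0), 1, atol=1e-9)

    def test_idempotence_on_normalized_input(self, rng):
        m = rng.normal(size=(200, 3))
        once, _, _ = zscore_normalize(m)
        twice, _, _ = zscore_normalize(once)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_round_trip_identity(self, rng):
        m = rng.uniform(-50, 50, size=(1000, 5))
        norm, means, sds = zscore_normalize(m)
        np.testing.assert_allclose(zscore_invert(norm, means, sds), m, atol=1e-9)
        np.testing.assert_allclose(zscore_apply(m, means, sds), norm, atol=1e-12)

    def test_constant_column_error_names_column(self):
        m = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(DegenerateInputError, match="humidity"):
            zscore_normalize(m, column_names=["temp", "humidity"])
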