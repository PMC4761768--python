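"""Geodesic distances, environmental PCA, and scalar difference matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from distdecay.containers import SiteTable
from distdecay.geodesic import geodesic_km, haversine_km
from distdecay.spatial import (
    env_distance_matrix,
    env_pca,
    geo_distance_matrix,
    scalar_diff_matrix,
)

# reference values from an independent WGS84 geodesic implementation
# (Karney's algorithm as exposed by R geosphere::distGeo)
GEODESIC_ORACLE = [
    # lat1, lon1, lat2, lon2, km
    (0.0, 0.0, 0.0, 1.0, 111.319491),
    (25.0, 98.0, 30.0, 102.0, 680.448230),
    (21.7, 92.3, 34.9, 105.8, 1969.067219),
    (28.0, 100.0, 28.001, 100.001, 0.148175),
]

coord_st = st.tuples(
    st.floats(min_value=-60, max_value=60),
    st.floats(min_value=-179, max_value=179),
)

# a mountainous mid-latitude survey window (half-open haversine bound holds here)
region_st = st.tuples(
    st.floats(min_value=15, max_value=45),
    st.floats(min_value=90, max_value=110),
)


class TestGeodesic:
    @pytest.mark.parametrize("lat1,lon1,lat2,lon2,km", GEODESIC_ORACLE)
    def test_against_independent_oracle(self, lat1, lon1, lat2, lon2, km):
        assert geodesic_km(lat1, lon1, lat2, lon2) == pytest.approx(km, abs=1e-4)

    def test_identical_coordinates(self):
        assert geodesic_km(28.0, 100.0, 28.0, 100.0) == 0.0

    @given(region_st, region_st)
    def test_haversine_agrees_within_half_percent_in_study_window(self, p, q):
        (lat1, lon1), (lat2, lon2) = p, q
        d_ell = float(geodesic_km(lat1, lon1, lat2, lon2))
        d_sph = float(haversine_km(lat1, lon1, lat2, lon2))
        if d_ell > 1.0:
            assert abs(d_sph - d_ell) / d_ell < 0.005

    @given(coord_st, coord_st)
    def test_haversine_global_deviation_bounded(self, p, q):
        # the mean-radius sphere deviates up to ~0.56% on meridional arcs
        (lat1, lon1), (lat2, lon2) = p, q
        d_ell = float(geodesic_km(lat1, lon1, lat2, lon2))
        d_sph = float(haversine_km(lat1, lon1, lat2, lon2))
        if d_ell > 1.0:
            assert abs(d_sph - d_ell) / d_ell < 0.006

    @given(coord_st, coord_st, coord_st)
    def test_triangle_inequality(self, p, q, r):
        d = lambda u, v: float(geodesic_km(u[0], u[1], v[0], v[1]))
        assert d(p, q) + d(q, r) >= d(p, r) - 1e-6

    def test_symmetry(self):
        assert geodesic_km(21.0, 92.0, 35.0, 106.0) == pytest.approx(
            float(geodesic_km(35.0, 106.0, 21.0, 92.0)), abs=1e-9
        )


class TestGeoDistanceMatrix:
    def test_shape_and_invariants(self, sites3):
        m = geo_distance_matrix(sites3)
        assert m.kind == "distance"
        np.testing.assert_array_equal(np.diag(m.values), 0.0)
        assert (m.values >= 0).all()
        np.testing.assert_allclose(m.values, m.values.T)

    def test_coincident_sites_flagged_not_fatal(self, sites3, caplog):
        df = sites3.data.copy()
        df.loc[1, ["lon", "lat"]] = df.loc[0, ["lon", "lat"]]
        with caplog.at_level("WARNING"):
            m = geo_distance_matrix(SiteTable(df))
        assert m.values[0, 1] == 0.0
        assert "coincident" in caplog.text


def make_env_sites(X: np.ndarray) -> SiteTable:
    n = X.shape[0]
    df = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "lon": np.linspace(92, 106, n),
            "lat": np.linspace(21, 35, n),
            "mean_elev": 1000.0,
            "elev_range": 100.0,
            "area": 1000.0,
        }
    )
    for j in range(X.shape[1]):
        df[f"v{j}"] = X[:, j]
    return SiteTable(df)


class TestEnvPCA:
    def test_perfectly_correlated_pair_collapses_to_one_axis(self, rng):
        x = rng.normal(size=30)
        sites = make_env_sites(np.column_stack([x, 2 * x + 3]))
        pca = env_pca(sites)
        assert pca.n_retained == 1
        assert pca.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_variables_share_variance(self, rng):
        X = rng.normal(size=(4000, 3))
        pca = env_pca(make_env_sites(X), variance_target=0.999)
        # at large n the three standardized axes carry ~equal fractions
        np.testing.assert_allclose(pca.explained_fraction, 1 / 3, atol=0.04)

    def test_fixed_component_count_override(self, rng):
        X = rng.normal(size=(50, 9))
        pca = env_pca(make_env_sites(X), n_components=4)
        assert pca.n_retained == 4
        assert pca.scores.shape == (50, 4)

    def test_correlation_matrix_scaling(self, rng):
        # variables on wildly different scales must not dominate
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        raw = np.column_stack([x, 1e6 * y])
        pca = env_pca(make_env_sites(raw), variance_target=0.999)
        assert pca.explained_fraction[0] < 0.75

    def test_scores_centred_and_fractions_monotone(self, rng):
        X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5))
        pca = env_pca(make_env_sites(X), variance_target=0.99)
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0.0, atol=1e-10)
        assert (np.diff(pca.explained_fraction) <= 1e-12).all()

    def test_constant_variable_dropped(self, rng, caplog):
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with caplog.at_level("WARNING"):
            pca = env_pca(make_env_sites(X), variance_target=0.5)
        assert pca.variables == ["v0"]

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            env_pca(make_env_sites(np.zeros((1, 2))))


class TestEnvDistance:
    def test_one_axis_difference(self, rng):
        X = rng.normal(size=(10, 3))
        pca = env_pca(make_env_sites(X), n_components=1)
        pca.scores = np.array([[1.0], [4.0], [0.0]] + [[0.0]] * 7)
        m = env_distance_matrix(pca)
        assert m.values[0, 1] == pytest.approx(3.0)

    def test_matches_brute_force_euclidean(self, rng):
        X = rng.normal(size=(12, 6))
        pca = env_pca(make_env_sites(X), n_components=4)
        m = env_distance_matrix(pca)
        brute = np.sqrt(
            ((pca.scores[:, None, :] - pca.scores[None, :, :]) ** 2).sum(axis=2)
        )
        np.testing.assert_allclose(m.values, brute, atol=1e-10)

    def test_invariant_to_axis_sign_flip(self, rng):
        X = rng.normal(size=(15, 5))
        pca = env_pca(make_env_sites(X), n_components=3)
        m1 = env_distance_matrix(pca).values
        pca.scores = pca.scores * np.array([1.0, -1.0, -1.0])
        m2 = env_distance_matrix(pca).values
        np.testing.assert_allclose(m1, m2, atol=1e-10)

    def test_identical_environments_distance_zero(self, rng):
        X = np.tile(rng.normal(size=(1, 4)), (3, 1)) + np.array([[0], [0], [1.0]])
        pca = env_pca(make_env_sites(X), variance_target=0.5)
        m = env_distance_matrix(pca)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-10)


class TestScalarDiff:
    def test_elevation_difference(self, sites3):
        m = scalar_diff_matrix(sites3, "mean_elev")
        assert m.values[0, 1] == pytest.approx(2700.0)
        np.testing.assert_allclose(m.values, m.values.T)

    def test_equal_values_give_zero(self, sites3):
        df = sites3.data.copy()
        df["area"] = 1234.0
        m = scalar_diff_matrix(SiteTable(df), "area")
        np.testing.assert_array_equal(m.values, 0.0)

    def test_unknown_field_rejected(self, sites3):
        with pytest.raises(Exception, match="nope"):
            scalar_diff_matrix(sites3, "nope")
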