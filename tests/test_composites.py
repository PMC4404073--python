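"""Environmental composites: PCA, perception index, KDE, grids, buffers."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from gwcommute.composites import (
    bartlett_sphericity,
    buffer_mean,
    densify_polyline,
    disaggregate_to_grid,
    kde_raster,
    kmo_statistic,
    nearest_distance,
    pca_composites,
    perception_index,
)
from gwcommute.raster import RasterGrid


class TestPcaComposites:
    def test_uncorrelated_variables_identity_loadings(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5000, 2))
        out = pca_composites(X, kaiser=False, rotation="varimax")
        assert np.allclose(out.eigenvalues, 1.0, atol=0.06)
        # after varimax each variable aligns with one component (up to
        # sign/permutation the loading matrix is the identity)
        L = np.abs(out.rotated_loadings.to_numpy())
        assert np.allclose(np.sort(L.max(axis=0)), [1, 1], atol=0.1)
        assert np.allclose(np.sort(L.min(axis=0)), [0, 0], atol=0.1)

    def test_two_factor_block_retains_two(self, cohort200):
        out = pca_composites(cohort200.env_variables)
        assert out.retained_count == 2
        assert 0.55 <= out.variance_fractions[:2].sum() <= 0.75

    def test_varimax_agrees_with_statsmodels_on_generic_matrix(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        from gwcommute.composites import varimax_rotation

        L = np.array([[0.8, 0.3], [0.2, 0.75], [0.7, 0.4], [0.1, 0.9],
                      [0.6, 0.2]])
        ours, _ = varimax_rotation(L, normalize=False)
        ref, _ = rotate_factors(L, "varimax")
        # same optimum up to column sign
        for j in range(2):
            assert (np.allclose(ours[:, j], ref[:, j], atol=1e-4)
                    or np.allclose(ours[:, j], -ref[:, j], atol=1e-4))

    def test_varimax_escapes_symmetric_saddle(self):
        from gwcommute.composites import varimax_rotation

        L = np.array([[0.717, 0.697], [0.717, -0.697]])
        out, _ = varimax_rotation(L)
        A = np.abs(out)
        assert np.allclose(np.sort(A.max(axis=0)), [1, 1], atol=0.03)

    def test_varimax_preserves_communalities(self, cohort200):
        out = pca_composites(cohort200.env_variables, rotation="varimax")
        rotated_comm = (out.rotated_loadings**2).sum(axis=1)
        np.testing.assert_allclose(rotated_comm, out.communalities, atol=1e-8)

    def test_unrotated_scores_orthogonal(self, cohort200):
        out = pca_composites(cohort200.env_variables)
        C = np.corrcoef(out.scores_unrotated.to_numpy(), rowvar=False)
        assert np.max(np.abs(C - np.eye(out.retained_count))) < 1e-10

    def test_diagnostics_in_range(self, cohort200):
        out = pca_composites(cohort200.env_variables)
        assert 0.0 <= out.kmo <= 1.0
        assert 0.0 <= out.bartlett_p <= 1.0
        # a strongly collinear block is highly factorable
        assert out.kmo > 0.7 and out.bartlett_p < 0.001

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.raises(ValueError, match="b"):
            pca_composites(X)

    def test_more_variables_than_rows_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            pca_composites(np.random.default_rng(0).normal(size=(3, 5)))

    def test_kmo_bartlett_on_identity_like_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 4))
        R = np.corrcoef(X, rowvar=False)
        assert 0.0 <= kmo_statistic(R) <= 1.0
        chi2, p = bartlett_sphericity(R, 500)
        assert p > 0.01  # independent columns: sphericity not rejected


class TestPerceptionIndex:
    def test_one_factor_structure_recovered(self, cohort200):
        out = perception_index(cohort200.likert)
        assert 0.4 <= out["variance_fraction"] <= 0.9
        load = out["loadings"]
        assert load["bike_safety"] > 0 and load["pollution"] > 0
        assert load["aesthetics"] < 0

    def test_identical_respondents_rejected(self):
        items = pd.DataFrame({"a": [3] * 10, "b": [2] * 10, "c": [4] * 10})
        with pytest.raises(ValueError):
            perception_index(items)

    def test_reverse_coding_flips_loading_not_scores(self, cohort200):
        items = cohort200.likert.copy()
        out1 = perception_index(items)
        items["pollution"] = 6 - items["pollution"]  # reverse the 1-5 coding
        out2 = perception_index(items)
        assert np.sign(out1["loadings"]["pollution"]) == -np.sign(
            out2["loadings"]["pollution"]
        )
        np.testing.assert_allclose(out1["index"], out2["index"], atol=1e-10)


class TestKdeRaster:
    def test_compact_support(self):
        g = RasterGrid.from_extent(0, 0, 4000, 4000, 100.0)
        k = kde_raster(np.array([[2000.0, 2000.0]]), g, bandwidth=500)
        assert k.value_at(200, 200) == 0.0
        assert k.value_at(2000, 2000) > 0.0
        assert np.all(k.values >= 0)

    def test_mass_conservation(self):
        g = RasterGrid.from_extent(0, 0, 4000, 4000, 50.0)
        k = kde_raster(np.array([[2000.0, 2000.0]]), g, bandwidth=500)
        mass = k.values.sum() * (g.cell_size / 1000.0) ** 2  # per-km2 x km2
        assert mass == pytest.approx(1.0, rel=0.02)

    def test_coincident_points_double_density(self):
        g = RasterGrid.from_extent(0, 0, 2000, 2000, 100.0)
        one = kde_raster(np.array([[1000.0, 1000.0]]), g, bandwidth=400)
        two = kde_raster(np.array([[1000.0, 1000.0]] * 2), g, bandwidth=400)
        np.testing.assert_allclose(two.values, 2 * one.values)

    def test_empty_features_all_zero(self):
        g = RasterGrid.from_extent(0, 0, 1000, 1000, 100.0)
        k = kde_raster(np.empty((0, 2)), g, bandwidth=500)
        assert np.all(k.values == 0)

    def test_polyline_weights_sum_to_length(self):
        pts, w = densify_polyline([(0, 0), (100, 0), (100, 50)], spacing=10)
        assert w.sum() == pytest.approx(150.0)
        assert len(pts) == 15


class TestDisaggregateToGrid:
    def test_single_zone_constant(self):
        zones = [(box(-100, -100, 3000, 3000), 7.0)]
        out = disaggregate_to_grid(zones, RasterGrid.empty(0, 0, 200, 5, 5))
        assert np.all(out.values == 7.0)

    def test_half_plane_split_no_mixing(self):
        zones = [(box(0, 0, 1000, 2000), 1.0), (box(1000, 0, 2000, 2000), 2.0)]
        out = disaggregate_to_grid(zones, RasterGrid.empty(0, 0, 200, 10, 10))
        assert np.all(out.values[:, :5] == 1.0)
        assert np.all(out.values[:, 5:] == 2.0)

    def test_uncovered_cells_nodata(self):
        zones = [(box(0, 0, 600, 600), 4.0)]
        out = disaggregate_to_grid(zones, RasterGrid.empty(0, 0, 200, 5, 5))
        assert int((~out.mask()).sum()) == 25 - 9

    def test_overlap_at_center_rejected(self):
        zones = [(box(0, 0, 1000, 1000), 1.0), (box(0, 0, 1000, 1000), 2.0)]
        with pytest.raises(ValueError, match="overlapping"):
            disaggregate_to_grid(zones, RasterGrid.empty(0, 0, 200, 5, 5))


class TestBufferMean:
    def test_constant_raster(self):
        r = RasterGrid.empty(0, 0, 200, 5, 5, fill=3.3)
        assert buffer_mean(r, (512, 488), 500).value == pytest.approx(3.3)

    def test_small_radius_single_cell(self):
        r = RasterGrid(0, 0, 200, np.arange(25, dtype=float).reshape(5, 5))
        out = buffer_mean(r, (500, 500), 100)
        assert out.n_cells == 1 and out.value == r.value_at(500, 500)

    def test_symmetric_two_cells(self):
        r = RasterGrid(0, 0, 200, np.array([[0.0, 10.0]]))
        out = buffer_mean(r, (200, 100), 150)
        assert out.value == pytest.approx(5.0) and out.n_cells == 2

    def test_nodata_outside_buffer_irrelevant(self):
        vals = np.full((5, 5), 2.0)
        vals[0, :] = -9999.0
        r = RasterGrid(0, 0, 200, vals)
        out = buffer_mean(r, (500, 300), 250)
        assert out.value == pytest.approx(2.0)

    def test_empty_buffer_flagged_missing(self):
        r = RasterGrid.empty(0, 0, 200, 5, 5)
        out = buffer_mean(r, (50000, 50000), 100)
        assert out.missing and out.n_cells == 0


class TestNearestDistance:
    def test_examples(self):
        assert nearest_distance((0, 0), [(3, 4)]) == 5.0
        assert nearest_distance((3, 4), [(3, 4), (10, 10)]) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        feats = rng.uniform(0, 1000, size=(100, 2))
        loc = (400.0, 600.0)
        brute = min(np.hypot(f[0] - loc[0], f[1] - loc[1]) for f in feats)
        assert nearest_distance(loc, feats) == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nearest_distance((0, 0), np.empty((0, 2)))
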