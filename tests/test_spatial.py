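"""Raster/vector operations: TIS, distances, neighbourhoods, clustering,
ranking, and container I/O."""

import numpy as np
import pytest

from popimpact.raster import PointSet, RasterGrid
from popimpact.spatial import (
    cluster_candidates,
    compute_tis,
    distance_covariates,
    neighborhood_percent_cover,
    rank_sites,
    supercover_line,
)


def brute_force_tis(dem: RasterGrid, source_cell, start_cell, n_steps=512):
    """Independent oracle: sample the start->source segment densely at
    sub-cell resolution, look up the DEM cell under each sample point, and
    take the maximum (baseline - elevation)."""
    r0, c0 = start_cell
    sr, sc = source_cell
    z = dem.values
    t = np.linspace(0.0, 1.0, n_steps)
    rows = r0 + 0.5 + t * (sr - r0)
    cols = c0 + 0.5 + t * (sc - c0)
    ri = np.clip(rows.astype(int), 0, z.shape[0] - 1)
    ci = np.clip(cols.astype(int), 0, z.shape[1] - 1)
    baseline = z[r0, c0] + t * (z[sr, sc] - z[r0, c0])
    return float((baseline - z[ri, ci]).max())


class TestSupercoverLine:
    @pytest.mark.parametrize("a,b", [((0, 0), (0, 5)), ((0, 0), (5, 0)),
                                     ((2, 3), (7, 11)), ((5, 5), (0, 0)),
                                     ((0, 0), (4, 4))])
    def test_endpoints_and_connectivity(self, a, b):
        line = supercover_line(*a, *b)
        assert tuple(line[0]) == a and tuple(line[-1]) == b
        steps = np.abs(np.diff(line, axis=0))
        assert np.all(steps.max(axis=1) <= 1)

    def test_single_cell(self):
        line = supercover_line(3, 3, 3, 3)
        assert line.shape == (1, 2)


class TestComputeTis:
    def test_flat_dem_all_zero(self):
        dem = RasterGrid(np.full((12, 12), 800.0))
        tis = compute_tis(dem, (6, 6))
        assert np.allclose(tis.values, 0.0)

    def test_dip_of_fifty_metres(self):
        """Line elevations (0, -50, 0): constant-slope baseline is 0, so the
        maximum difference along the line is 50."""
        dem = RasterGrid(np.array([[0.0, -50.0, 0.0]]))
        tis = compute_tis(dem, (0, 2))
        assert tis.values[0, 0] == pytest.approx(50.0)

    def test_adjacent_start_zero(self):
        rng = np.random.default_rng(0)
        dem = RasterGrid(rng.uniform(100, 200, size=(5, 5)))
        tis = compute_tis(dem, (2, 2))
        # start adjacent to the source: no intervening cell, baseline hits
        # both endpoints exactly
        assert tis.values[2, 3] == pytest.approx(0.0, abs=1e-9)
        assert tis.values[2, 2] == pytest.approx(0.0, abs=1e-9)

    def test_sign_flag_flips_convention(self):
        dem = RasterGrid(np.array([[0.0, 80.0, 0.0]]))
        below = compute_tis(dem, (0, 2), sign="below_line")
        above = compute_tis(dem, (0, 2), sign="above_line")
        assert above.values[0, 0] == pytest.approx(80.0)
        assert below.values[0, 0] <= 0.0

    def test_matches_brute_force_on_smooth_dem(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        z = gaussian_filter(rng.normal(0, 60, size=(20, 20)), 2.0)
        dem = RasterGrid(z)
        tis = compute_tis(dem, (10, 10))
        tol = np.abs(np.diff(z, axis=0)).max() + np.abs(np.diff(z, axis=1)).max()
        for r in range(0, 20, 3):
            for c in range(0, 20, 3):
                bf = brute_force_tis(dem, (10, 10), (r, c))
                assert abs(tis.values[r, c] - bf) <= tol

    def test_nodata_propagates(self):
        z = np.full((5, 5), 10.0)
        z[2, 1] = -9999.0
        dem = RasterGrid(z)
        with pytest.warns(UserWarning, match="nodata"):
            tis = compute_tis(dem, (2, 4))
        assert tis.values[2, 0] == dem.nodata

    def test_source_outside_rejected(self):
        with pytest.raises(ValueError):
            compute_tis(RasterGrid(np.zeros((3, 3))), (5, 5))


class TestDistanceCovariates:
    def _infra(self):
        return PointSet(["a", "b"], np.array([[0.0, 0.0], [1000.0, 0.0]]))

    def test_point_on_feature(self):
        d = distance_covariates(np.array([[0.0, 0.0]]), self._infra())
        assert d[0] == 0.0
        dec = distance_covariates(np.array([[0.0, 0.0]]), self._infra(),
                                  form="expdecay", decay_scale=500.0)
        assert dec[0] == 1.0

    def test_decay_at_scale_distance(self):
        dec = distance_covariates(np.array([[0.0, 500.0]]), self._infra(),
                                  form="expdecay", decay_scale=500.0)
        assert dec[0] == pytest.approx(np.exp(-1.0))

    def test_nearest_feature_chosen(self):
        d = distance_covariates(np.array([[900.0, 0.0]]), self._infra())
        assert d[0] == pytest.approx(100.0)

    def test_moving_toward_feature_never_increases_distance(self):
        pts = np.column_stack([np.linspace(900.0, 1000.0, 11), np.zeros(11)])
        d = distance_covariates(pts, self._infra())
        assert np.all(np.diff(d) <= 1e-9)

    def test_line_feature_edge_distance(self):
        from shapely.geometry import LineString

        d = distance_covariates(np.array([[5.0, 3.0]]),
                                [LineString([(0, 0), (10, 0)])])
        assert d[0] == pytest.approx(3.0)

    def test_empty_infrastructure_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_covariates(np.array([[0.0, 0.0]]), [])


class TestNeighborhoodCover:
    def test_all_ones_is_full_cover(self):
        r = RasterGrid(np.ones((20, 20)), cell_size=30.0)
        x, y = r.center_of(10, 10)
        out = neighborhood_percent_cover(r, np.array([[x, y]]), 167.9)
        assert out[0] == pytest.approx(1.0)

    def test_checkerboard_large_radius_half(self):
        z = np.indices((60, 60)).sum(axis=0) % 2
        r = RasterGrid(z.astype(float), cell_size=30.0)
        x, y = r.center_of(30, 30)
        out = neighborhood_percent_cover(r, np.array([[x, y]]), 439.5)
        assert out[0] == pytest.approx(0.5, abs=0.02)

    def test_counting_oracle_small_radius(self):
        z = np.zeros((10, 10))
        z[5, 5] = 1.0
        r = RasterGrid(z, cell_size=30.0)
        x, y = r.center_of(5, 5)
        # radius 40 m captures the centre cell + 4 rook neighbours
        out = neighborhood_percent_cover(r, np.array([[x, y]]), 40.0)
        assert out[0] == pytest.approx(1.0 / 5.0)

    def test_off_raster_point_rejected(self):
        r = RasterGrid(np.ones((5, 5)), cell_size=30.0)
        with pytest.raises(ValueError, match="off the raster"):
            neighborhood_percent_cover(r, np.array([[1e6, 1e6]]), 100.0)

    def test_radius_below_half_cell_rejected(self):
        r = RasterGrid(np.ones((5, 5)), cell_size=30.0)
        with pytest.raises(ValueError, match="radius"):
            neighborhood_percent_cover(r, np.array([[45.0, -45.0]]), 10.0)


class TestClusterCandidates:
    def test_two_points_within_radius_merge(self):
        p = PointSet(["a", "b"], np.array([[0.0, 0.0], [3000.0, 0.0]]),
                     {"mwh": np.array([10.0, 20.0])})
        out = cluster_candidates(p, radius_km=4.0)
        assert len(out) == 1
        assert np.allclose(out.xy[0], [1500.0, 0.0])
        assert out.attributes["mwh"][0] == pytest.approx(30.0)

    def test_two_points_beyond_radius_unchanged(self):
        p = PointSet(["a", "b"], np.array([[0.0, 0.0], [5000.0, 0.0]]))
        out = cluster_candidates(p, radius_km=4.0)
        assert len(out) == 2

    def test_chain_merges_by_single_linkage(self):
        p = PointSet(["a", "b", "c"],
                     np.array([[0.0, 0.0], [3000.0, 0.0], [6000.0, 0.0]]))
        out = cluster_candidates(p, radius_km=4.0)
        assert len(out) == 1  # a-b and b-c within 4 km even though a-c is 6 km

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_candidates(PointSet([], np.zeros((0, 2))))


class TestRankSites:
    def _aligned(self, values):
        return RasterGrid(values, origin=(0.0, 0.0), cell_size=30.0)

    def test_zero_surface_all_tied(self):
        z = np.zeros((40, 40))
        dl, aui = self._aligned(z), self._aligned(np.ones_like(z))
        sites = PointSet(["s1", "s2"], np.array([[300.0, -300.0], [900.0, -900.0]]))
        tab = rank_sites(dl, aui, sites, buffers_km=(2.0,))
        assert (tab["score_2km"] == 0).all()
        assert (tab["rank_2km"] == 1).all()

    def test_hotspot_site_ranks_first(self):
        z = np.zeros((40, 40))
        z[10, 10] = 5.0
        dl, aui = self._aligned(z), self._aligned(np.ones_like(z))
        hot = dl.center_of(10, 10)
        cold = dl.center_of(35, 35)
        sites = PointSet(["hot", "cold"], np.array([hot, cold]))
        tab = rank_sites(dl, aui, sites, buffers_km=(0.2,))
        assert tab.loc[tab.site_id == "hot", "rank_0.2km"].iloc[0] == 1

    def test_zero_aui_masks_everything(self):
        z = np.full((20, 20), 3.0)
        dl, aui = self._aligned(z), self._aligned(np.zeros_like(z))
        sites = PointSet(["s"], np.array([[300.0, -300.0]]))
        tab = rank_sites(dl, aui, sites, buffers_km=(2.0,))
        assert tab["score_2km"].iloc[0] == 0.0

    def test_score_additive_over_partitions(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(30, 30))
        a = rng.uniform(0, 1, size=(30, 30))
        left, right = z.copy(), z.copy()
        left[:, 15:] = 0.0
        right[:, :15] = 0.0
        sites = PointSet(["s"], np.array([[450.0, -450.0]]))
        full = rank_sites(self._aligned(z), self._aligned(a), sites, (5.0,))
        p1 = rank_sites(self._aligned(left), self._aligned(a), sites, (5.0,))
        p2 = rank_sites(self._aligned(right), self._aligned(a), sites, (5.0,))
        assert full["score_5km"].iloc[0] == pytest.approx(
            p1["score_5km"].iloc[0] + p2["score_5km"].iloc[0]
        )

    def test_misaligned_rasters_rejected(self):
        dl = self._aligned(np.zeros((10, 10)))
        aui = RasterGrid(np.zeros((10, 10)), origin=(5.0, 5.0), cell_size=30.0)
        with pytest.raises(ValueError, match="aligned"):
            rank_sites(dl, aui, PointSet(["s"], np.array([[0.0, 0.0]])))


class TestContainerIO:
    def test_raster_tiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        r = RasterGrid(rng.normal(size=(8, 9)).astype(np.float32),
                       origin=(123.0, 456.0), cell_size=30.0, crs="EPSG:26911")
        p = tmp_path / "r.tif"
        r.to_tiff(p)
        back = RasterGrid.from_tiff(p)
        np.testing.assert_allclose(back.values, r.values, rtol=1e-6)
        assert back.origin == (123.0, 456.0)
        assert back.crs == "EPSG:26911"

    def test_pointset_geojson_roundtrip(self, tmp_path):
        p = PointSet(["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]),
                     {"mwh": np.array([5.0, 6.0])})
        f = tmp_path / "p.geojson"
        p.to_geojson(f)
        back = PointSet.from_geojson(f)
        assert back.ids == ["a", "b"]
        np.testing.assert_allclose(back.xy, p.xy)
        np.testing.assert_allclose(back.attributes["mwh"], [5.0, 6.0])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PointSet(["a"], np.array([[np.nan, 0.0]]))
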