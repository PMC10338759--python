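"""Terrain modelling: ground classification, DTM, normalization, pit-free CHM."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from canopycce import (PitFreeConfig, PointCloud, build_dtm, classify_ground,
                       naive_chm, normalize_heights, pitfree_chm)
from canopycce.terrain import TerrainError, default_resolution


def _grid_cloud(nx=21, ny=21, spacing=1.0, zfunc=lambda x, y: 0.0 * x):
    xx, yy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    x, y = xx.ravel(), yy.ravel()
    return PointCloud(x, y, zfunc(x, y), ground=np.ones(x.size, dtype=bool))


class TestClassifyGround:
    def test_preclassified_pass_through(self):
        cloud = PointCloud([0, 1], [0, 1], [0, 10], ground=[True, False])
        out = classify_ground(cloud)
        np.testing.assert_array_equal(out.ground, [True, False])

    def test_flat_plane_with_trees(self, rng):
        # ground on a 0.5 m grid so every minimum-grid cell is occupied
        xx, yy = np.meshgrid(np.arange(0, 20.5, 0.5), np.arange(0, 20.5, 0.5))
        gx, gy = xx.ravel(), yy.ravel()
        n = gx.size
        tx, ty = rng.uniform(0, 20, 50), rng.uniform(0, 20, 50)
        tz = rng.uniform(3, 15, 50)
        cloud = PointCloud(np.r_[gx, tx], np.r_[gy, ty], np.r_[np.zeros(n), tz])
        out = classify_ground(cloud, grid_size=1.0, tol=0.2)
        expected = np.r_[np.ones(n, bool), np.zeros(50, bool)]
        np.testing.assert_array_equal(out.ground, expected)

    def test_single_point_is_ground(self):
        out = classify_ground(PointCloud([1.0], [2.0], [3.0]))
        assert out.ground[0]


class TestBuildDtm:
    def test_plane_reproduced_at_in_hull_cells(self, rng):
        plane = lambda x, y: 0.1 * x + 0.05 * y
        cloud = _grid_cloud(zfunc=plane)
        dtm = build_dtm(cloud, resolution=0.5)
        tri = Delaunay(np.c_[cloud.x, cloud.y])
        xq, yq = np.meshgrid(dtm.x_centers, dtm.y_centers)
        in_hull = tri.find_simplex(np.c_[xq.ravel(), yq.ravel()]) >= 0
        expected = plane(xq.ravel(), yq.ravel())
        np.testing.assert_allclose(dtm.values.ravel()[in_hull], expected[in_hull],
                                   atol=1e-9)

    def test_horizontal_plane_constant(self):
        cloud = _grid_cloud(zfunc=lambda x, y: np.full_like(x, 7.5))
        dtm = build_dtm(cloud, resolution=1.0)
        np.testing.assert_allclose(dtm.values, 7.5, atol=1e-9)

    def test_resolution_refinement_consistent(self):
        plane = lambda x, y: 0.1 * x + 0.05 * y
        cloud = _grid_cloud(spacing=0.97, zfunc=plane)
        coarse = build_dtm(cloud, resolution=1.0)
        fine = build_dtm(cloud, resolution=0.5)
        assert fine.values.size == 4 * coarse.values.size
        # both reproduce the same (planar) surface wherever in-hull
        tri = Delaunay(np.c_[cloud.x, cloud.y])
        for dtm in (coarse, fine):
            xq, yq = np.meshgrid(dtm.x_centers, dtm.y_centers)
            inh = tri.find_simplex(np.c_[xq.ravel(), yq.ravel()]) >= 0
            np.testing.assert_allclose(
                dtm.values.ravel()[inh], plane(xq.ravel(), yq.ravel())[inh], atol=1e-9)

    def test_too_few_ground_points(self):
        cloud = PointCloud([0, 1], [0, 0], [0, 0], ground=[True, True])
        with pytest.raises(TerrainError):
            build_dtm(cloud, resolution=1.0)


class TestNormalize:
    def test_ground_surface_normalizes_to_zero(self):
        cloud = _grid_cloud(zfunc=lambda x, y: 0.2 * x + 1.0)
        dtm = build_dtm(cloud, resolution=1.0)
        out = normalize_heights(cloud, dtm)
        np.testing.assert_allclose(out.z, 0.0, atol=1e-6)

    def test_apex_height_subtraction(self):
        ground = _grid_cloud(nx=5, ny=5, zfunc=lambda x, y: np.full_like(x, 5.0))
        cloud = PointCloud(np.r_[ground.x, 2.0], np.r_[ground.y, 2.0],
                           np.r_[ground.z, 20.0],
                           ground=np.r_[np.ones(ground.n, bool), False])
        dtm = build_dtm(cloud, resolution=1.0)
        out = normalize_heights(cloud, dtm)
        assert out.z[-1] == pytest.approx(15.0, abs=1e-6)

    def test_idempotent(self):
        cloud = _grid_cloud(zfunc=lambda x, y: 0.15 * x - 0.05 * y + 3)
        dtm = build_dtm(cloud, resolution=1.0)
        once = normalize_heights(cloud, dtm)
        dtm0 = build_dtm(once, resolution=1.0)
        twice = normalize_heights(once, dtm0)
        np.testing.assert_allclose(twice.z, once.z, atol=1e-9)

    def test_sloped_synthetic_plot_tallest_tree(self, small_plot):
        spec, cloud, truth = small_plot
        flagged = classify_ground(cloud)
        dtm = build_dtm(flagged, resolution=0.2)
        norm = normalize_heights(flagged, dtm)
        assert norm.z.max() == pytest.approx(truth.height.max(), abs=0.3)


class TestPitFreeChm:
    def test_single_cone_apex_height(self):
        # cone apex 18 m at the center of a flat normalized cloud
        rng = np.random.default_rng(5)
        n = 3000
        depth = 9.0 * np.cbrt(rng.uniform(size=n))
        r = (2.0 * depth / 9.0) * np.sqrt(rng.uniform(size=n))
        az = rng.uniform(0, 2 * np.pi, n)
        cloud = PointCloud(np.r_[5 + r * np.cos(az), 5.0],
                           np.r_[5 + r * np.sin(az), 5.0],
                           np.r_[18.0 - depth, 18.0])
        chm = pitfree_chm(cloud, PitFreeConfig(resolution=0.25))
        assert chm.values.max() == pytest.approx(18.0, abs=0.3)

    def test_low_points_single_layer_equals_naive(self, rng):
        # points exactly at cell centers, all below 2 m: only layer 0
        # contributes and TIN through the cell centers equals the naive CHM
        xx, yy = np.meshgrid(np.arange(10) + 0.5, np.arange(10) + 0.5)
        z = rng.uniform(0.0, 1.9, size=xx.size)
        cloud = PointCloud(xx.ravel(), yy.ravel(), z)
        cfg = PitFreeConfig(resolution=1.0)
        pf = pitfree_chm(cloud, cfg, origin=(0.0, 0.0), shape=(10, 10))
        nv = naive_chm(cloud, 1.0, origin=(0.0, 0.0), shape=(10, 10))
        np.testing.assert_allclose(pf.values, nv.values, atol=1e-9)

    def test_pitfree_at_least_naive_with_dropout(self, small_plot):
        spec, cloud, _ = small_plot
        flagged = classify_ground(cloud)
        dtm = build_dtm(flagged, resolution=0.2)
        norm = normalize_heights(flagged, dtm).subset(~flagged.ground)
        # inject pits: drop 40% of crown points
        rng = np.random.default_rng(9)
        keep = rng.uniform(size=norm.n) > 0.4
        thin = norm.subset(keep)
        origin = (float(norm.x.min()), float(norm.y.min()))
        shape = None
        cfg = PitFreeConfig(resolution=0.25)
        pf = pitfree_chm(thin, cfg, origin=origin)
        nv = naive_chm(thin, 0.25, origin=origin, shape=(pf.n_rows, pf.n_cols))
        assert (pf.values >= nv.values - 1e-9).all()


def test_default_resolution_density_switch():
    assert default_resolution(300.0) == 0.1
    assert default_resolution(20.0) == 0.2


def test_pitfree_config_validation():
    with pytest.raises(ValueError):
        PitFreeConfig(layer_thresholds=(2.0, 5.0))
    with pytest.raises(ValueError):
        PitFreeConfig(layer_thresholds=(0.0, 5.0, 5.0))
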