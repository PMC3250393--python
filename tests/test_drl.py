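"""Discrete-return lidar products: gridding, CHM, tree detection, plot metrics."""

import numpy as np
import pandas as pd
import pytest

from canopyfuse import drl, sensors
from canopyfuse.raster import Raster

from conftest import flat_scene, make_trees


def cloud_from_points(points):
    """(x, y, elevation, return_index, n_returns) tuples -> point cloud."""
    df = pd.DataFrame(
        points, columns=["x", "y", "elevation", "return_index", "n_returns"]
    )
    df["pulse_id"] = np.arange(len(df))
    return df


class TestInterpolateSurface:
    def test_one_return_per_cell_reproduces_elevations(self):
        pts = cloud_from_points(
            [(0.25, 0.75, 10.0, 1, 1), (0.75, 0.75, 11.0, 1, 1),
             (0.25, 0.25, 12.0, 1, 1), (0.75, 0.25, 13.0, 1, 1)]
        )
        dsm = drl.interpolate_surface(pts, "first", 0.5, extent=(1.0, 1.0))
        np.testing.assert_allclose(dsm.values, [[10.0, 11.0], [12.0, 13.0]])

    def test_max_rule_for_first_min_rule_for_last(self):
        pts = cloud_from_points(
            [(0.25, 0.25, 10.0, 1, 2), (0.3, 0.3, 12.0, 1, 2),
             (0.25, 0.25, 4.0, 2, 2), (0.3, 0.3, 3.0, 2, 2)]
        )
        dsm = drl.interpolate_surface(pts, "first", 0.5, extent=(0.5, 0.5))
        dem = drl.interpolate_surface(pts, "last", 0.5, extent=(0.5, 0.5))
        assert dsm.values[0, 0] == 12.0
        assert dem.values[0, 0] == 3.0

    def test_empty_cells_filled_from_nearest_neighbor(self):
        pts = cloud_from_points([(0.25, 3.75, 5.0, 1, 1), (3.75, 0.25, 9.0, 1, 1)])
        dsm = drl.interpolate_surface(pts, "first", 0.5, extent=(4.0, 4.0))
        assert np.isfinite(dsm.values).all()
        assert dsm.values[0, 0] == 5.0  # next to the 5 m point
        assert dsm.values[-1, -1] == 9.0

    def test_matches_bruteforce_cell_scan(self):
        rng = np.random.default_rng(42)
        n = 500
        pts = cloud_from_points(
            [
                (x, y, z, 1, 1)
                for x, y, z in zip(
                    rng.uniform(0, 10, n), rng.uniform(0, 10, n), rng.uniform(0, 30, n)
                )
            ]
        )
        res = 1.0
        dsm = drl.interpolate_surface(pts, "first", res, extent=(10.0, 10.0))
        for r in range(10):
            for c in range(10):
                x_lo, x_hi = c * res, (c + 1) * res
                y_hi, y_lo = 10.0 - r * res, 10.0 - (r + 1) * res
                sel = pts[
                    (pts.x >= x_lo) & (pts.x < x_hi) & (pts.y > y_lo) & (pts.y <= y_hi)
                ]
                if len(sel):
                    assert dsm.values[r, c] == pytest.approx(sel.elevation.max())

    def test_no_returns_of_class_errors(self):
        pts = cloud_from_points([(0.2, 0.2, 5.0, 1, 1)])
        pts = pts[pts.return_index == 99]
        with pytest.raises(ValueError):
            drl.interpolate_surface(pts, "first", 0.5, extent=(1.0, 1.0))


class TestCHM:
    def _raster(self, values):
        return Raster(np.asarray(values, dtype=float), 0.5, origin=(0.0, 1.0))

    def test_equal_surfaces_give_zero_chm(self):
        dem = self._raster([[300.0, 301.0], [302.0, 303.0]])
        chm = drl.compute_chm(dem, dem)
        assert (chm.values == 0.0).all()

    def test_constant_offset(self):
        dem = self._raster([[300.0, 301.0], [302.0, 303.0]])
        dsm = dem.with_values(dem.values + 20.0)
        assert (drl.compute_chm(dsm, dem).values == 20.0).all()

    def test_negative_differences_clipped(self):
        dem = self._raster([[300.0, 300.0], [300.0, 300.0]])
        dsm = dem.with_values(np.array([[299.5, 300.0], [305.0, 300.0]]))
        chm = drl.compute_chm(dsm, dem)
        assert chm.values[0, 0] == 0.0
        assert chm.values[1, 0] == 5.0

    def test_grid_mismatch_errors(self):
        a = self._raster([[1.0]])
        b = Raster(np.zeros((1, 1)), 1.0)
        with pytest.raises(ValueError):
            drl.compute_chm(a, b)


class TestWindowModel:
    def test_exact_line_recovered(self):
        h = np.array([5.0, 10.0, 20.0, 30.0])
        r = 1.0 + 0.1 * h
        wm = drl.calibrate_window_model(h, r)
        assert wm.intercept == pytest.approx(1.0)
        assert wm.slope == pytest.approx(0.1)

    def test_two_point_closed_form(self):
        wm = drl.calibrate_window_model([10.0, 30.0], [2.0, 4.0])
        assert wm.slope == pytest.approx(0.1)
        assert wm.intercept == pytest.approx(1.0)
        assert wm.bounds == (2.0, 4.0)

    def test_constant_radius_gives_zero_slope(self):
        wm = drl.calibrate_window_model([10.0, 20.0, 30.0], [2.0, 2.0, 2.0])
        assert wm.slope == pytest.approx(0.0)

    def test_degenerate_heights_rejected(self):
        with pytest.raises(ValueError):
            drl.calibrate_window_model([10.0, 10.0], [2.0, 3.0])

    def test_prediction_clipped_to_bounds(self):
        wm = drl.WindowModel(intercept=1.0, slope=0.1, bounds=(2.0, 4.0))
        assert wm.predict(0.0) == 2.0
        assert wm.predict(100.0) == 4.0


def paraboloid_chm(apexes, shape=(60, 60), res=0.5):
    """CHM of ideal paraboloid crowns: apex (row, col, height, radius_m)."""
    values = np.zeros(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r0, c0, h, rad in apexes:
        d2 = ((rr - r0) ** 2 + (cc - c0) ** 2) * res**2
        crown = np.maximum(h * (1.0 - d2 / rad**2), 0.0)
        values = np.maximum(values, crown)
    return Raster(values, res, origin=(0.0, shape[0] * res))


def bruteforce_detect(chm, wm, min_height):
    """Independent exhaustive scan implementing the documented rule."""
    v = chm.values
    nrows, ncols = v.shape
    res = chm.resolution
    tops = []
    for r in range(nrows):
        for c in range(ncols):
            if v[r, c] < min_height:
                continue
            radius = max(float(wm.predict(v[r, c])), res)
            rad_px = int(np.floor(radius / res))
            is_top = True
            for dr in range(-rad_px, rad_px + 1):
                for dc in range(-rad_px, rad_px + 1):
                    if dr == 0 and dc == 0:
                        continue
                    if (dr**2 + dc**2) * res**2 > radius**2:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols):
                        continue
                    if v[rr, cc] > v[r, c]:
                        is_top = False
                    elif v[rr, cc] == v[r, c] and (rr * ncols + cc) < (r * ncols + c):
                        is_top = False
            if is_top:
                tops.append((r, c))
    return set(tops)


class TestDetectTrees:
    wm = drl.WindowModel(intercept=0.5, slope=0.1, bounds=(1.0, 4.0))

    def test_single_crown_single_detection_at_apex(self):
        chm = paraboloid_chm([(30, 30, 20.0, 5.0)])
        trees = drl.detect_trees(chm, self.wm, min_height=2.0)
        assert len(trees) == 1
        assert trees.iloc[0]["height"] == pytest.approx(20.0)
        assert trees.iloc[0]["x"] == pytest.approx(30 * 0.5 + 0.25)

    def test_two_separated_crowns_two_detections(self):
        chm = paraboloid_chm([(20, 15, 18.0, 4.0), (20, 75, 22.0, 4.0)], shape=(40, 90))
        trees = drl.detect_trees(chm, self.wm, min_height=2.0)
        assert len(trees) == 2

    def test_matches_exhaustive_scan_on_random_chm(self):
        rng = np.random.default_rng(17)
        chm = Raster(rng.uniform(0.0, 12.0, (25, 25)), 0.5, origin=(0.0, 12.5))
        trees = drl.detect_trees(chm, self.wm, min_height=2.0)
        got = {
            (int(round((12.5 - y) / 0.5 - 0.5)), int(round(x / 0.5 - 0.5)))
            for x, y in zip(trees.x, trees.y)
        }
        assert got == bruteforce_detect(chm, self.wm, 2.0)

    def test_plateau_counted_once(self):
        values = np.zeros((10, 10))
        values[4:6, 4:6] = 8.0  # 2x2 flat plateau
        chm = Raster(values, 0.5, origin=(0.0, 5.0))
        trees = drl.detect_trees(chm, self.wm, min_height=2.0)
        assert len(trees) == 1
        got = bruteforce_detect(chm, self.wm, 2.0)
        assert len(got) == 1

    def test_crown_attributes_follow_window_model(self):
        chm = paraboloid_chm([(30, 30, 20.0, 5.0)])
        tree = drl.detect_trees(chm, self.wm, min_height=2.0).iloc[0]
        r = self.wm.predict(tree["height"])
        assert tree["crown_radius"] == pytest.approx(r)
        assert tree["crown_area"] == pytest.approx(np.pi * r**2)
        assert tree["h_times_diam"] == pytest.approx(tree["height"] * 2 * r)


class TestPlotScalars:
    def test_stem_density_examples(self):
        trees = pd.DataFrame({"x": np.zeros(50), "y": np.zeros(50)})
        assert drl.stem_density(trees, 10_000.0) == 50.0
        assert drl.stem_density(trees.iloc[:0], 10_000.0) == 0.0
        trees39 = pd.DataFrame({"x": np.zeros(39)})
        assert drl.stem_density(trees39, 7_900.0) == pytest.approx(49.37, abs=0.01)

    def test_stem_density_rejects_bad_area(self):
        with pytest.raises(ValueError):
            drl.stem_density(pd.DataFrame({"x": []}), 0.0)

    def test_weighted_height_examples(self):
        one = pd.DataFrame({"height": [20.0], "crown_area": [10.0]})
        assert drl.crown_area_weighted_height(one) == 20.0
        equal = pd.DataFrame({"height": [10.0, 20.0], "crown_area": [5.0, 5.0]})
        assert drl.crown_area_weighted_height(equal) == 15.0
        skew = pd.DataFrame({"height": [10.0, 20.0], "crown_area": [1.0, 3.0]})
        assert drl.crown_area_weighted_height(skew) == pytest.approx(17.5)

    def test_weighted_height_scale_invariant_and_bounded(self):
        rng = np.random.default_rng(3)
        trees = pd.DataFrame(
            {"height": rng.uniform(5, 30, 40), "crown_area": rng.uniform(1, 50, 40)}
        )
        v = drl.crown_area_weighted_height(trees)
        scaled = trees.assign(crown_area=trees.crown_area * 7.3)
        assert drl.crown_area_weighted_height(scaled) == pytest.approx(v, rel=1e-12)
        assert trees.height.min() <= v <= trees.height.max()

    def test_empty_plot_is_missing(self):
        empty = pd.DataFrame({"height": [], "crown_area": []})
        assert np.isnan(drl.crown_area_weighted_height(empty))


class TestEndToEndRecovery:
    def test_well_separated_stand_recovered(self):
        """Zero-noise simulation of a 16-tree lattice: the full chain
        (points -> DSM/DEM -> CHM -> detection) finds >= 95 % of stems and
        the density estimate lands within 5 % of truth."""
        rows = [
            (x, y, 18.0 + 0.5 * ((x + y) % 3), 3.0, "deciduous")
            for x in (20.0, 60.0, 100.0, 140.0)
            for y in (20.0, 60.0, 100.0, 140.0)
        ]
        scene = flat_scene(make_trees(rows), extent=(160.0, 160.0), elevation=400.0)
        cloud = sensors.simulate_drl(
            scene, density_per_m2=4.0, vertical_error_sd=0.0, seed=5
        )
        dsm = drl.interpolate_surface(cloud, "first", 0.5, extent=(160.0, 160.0))
        dem = drl.interpolate_surface(cloud, "last", 0.5, extent=(160.0, 160.0))
        chm = drl.compute_chm(dsm, dem)
        assert (chm.values >= 0.0).all()
        wm = drl.calibrate_window_model([10.0, 25.0], [2.0, 3.5])
        trees = drl.detect_trees(chm, wm, min_height=2.0)
        assert len(trees) >= 0.95 * 16
        density = drl.stem_density(trees, 160.0 * 160.0)
        true_density = 16 / (160.0 * 160.0 / 1e4)
        assert abs(density - true_density) <= 0.05 * true_density
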