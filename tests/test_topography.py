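"""Density estimators, landmarks, group statistics and profiles against
direct-summation oracles."""

import math

import numpy as np
import pytest
from scipy.spatial import Voronoi, cKDTree

from conftest import hex_lattice
from foveamap.core import ConeSet, ScalarMap
from foveamap.synthetic_mosaic import MosaicSpec, render
from foveamap.topography import (DensityMap, GroupStats, Landmarks,
                                 build_group_stats, convert_to_mm2,
                                 find_landmarks, icd_density, radial_profile,
                                 voronoi_density, yellott_density, zscore_map)

SQRT3 = math.sqrt(3.0)


def cell_areas_and_bounded(pts):
    vor = Voronoi(pts)
    areas = np.zeros(len(pts))
    bounded = np.zeros(len(pts), bool)
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if len(region) >= 3 and -1 not in region:
            v = vor.vertices[region]
            areas[i] = 0.5 * abs(np.dot(v[:, 0], np.roll(v[:, 1], 1))
                                 - np.dot(v[:, 1], np.roll(v[:, 0], 1)))
            bounded[i] = True
    return areas, bounded


class TestVoronoiDensity:
    def test_flat_mosaic_interior_recovers_density(self, flat_positions, flat_spec):
        rho = flat_spec.peak_density_deg2
        dm = voronoi_density(flat_positions, grid_step_px=20.0, k=150,
                             shape=flat_spec.field_size_px)
        h, w = dm.data.shape
        interior = dm.data[h // 2 - 2:h // 2 + 3, w // 2 - 2:w // 2 + 3]
        assert dm.units == "deg2"
        assert abs(interior.mean() / rho - 1) < 0.02
        np.testing.assert_allclose(interior, rho, rtol=0.05)

    def test_k1_on_lattice_is_reciprocal_cell_area(self):
        pts = hex_lattice(10.0, 7, 7, origin=5.0)
        dm = voronoi_density(ConeSet(pts), grid_step_px=35.0, k=1, shape=(70, 70))
        areas, bounded = cell_areas_and_bounded(pts)
        probe_xy = np.array([35.0, 35.0])
        nearest = int(cKDTree(pts).query(probe_xy)[1])
        assert bounded[nearest]
        i, j = 1, 1  # probe grid point at (35, 35)
        assert dm.data[i, j] == pytest.approx(1.0 / areas[nearest])

    def test_matches_brute_force_retessellation(self):
        """Full Voronoi + k-NN + area-sum oracle at 10 probe points."""
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 200, size=(500, 2))
        k = 40
        dm = voronoi_density(ConeSet(pts), grid_step_px=50.0, k=k, shape=(201, 201))
        areas, bounded = cell_areas_and_bounded(pts)
        tree = cKDTree(pts)
        h, w = dm.data.shape
        for i in range(h):
            for j in range(w):
                probe = np.array([j * 50.0, i * 50.0])
                _, idx = tree.query(probe, k=k)
                nb = bounded[idx]
                expect = nb.sum() / areas[idx][nb].sum()
                assert dm.data[i, j] == pytest.approx(expect)
                assert dm.valid[i, j] == ((k - nb.sum()) <= 0.2 * k)

    def test_too_few_cones_rejected(self):
        with pytest.raises(ValueError, match="k"):
            voronoi_density(ConeSet(np.random.default_rng(0).uniform(
                0, 50, size=(30, 2))), k=150)


class TestIcdDensity:
    def test_hex_lattice_formula(self):
        pts = hex_lattice(10.0, 9, 9, origin=5.0)
        dm = icd_density(ConeSet(pts), grid_step_px=45.0, shape=(90, 90))
        # central probe lands on the interior of the lattice
        assert dm.data[1, 1] == pytest.approx(2.0 / (SQRT3 * 100.0), rel=1e-6)

    def test_square_lattice_hex_assumption_bias(self):
        """Square packing of unit spacing: 4 edge-sharing neighbors at distance
        1 give ICD = 1 and density 2/sqrt(3) — overestimating the true 1.0."""
        n = 11
        pts = np.array([(x, y) for y in range(n) for x in range(n)], float)
        dm = icd_density(ConeSet(pts), grid_step_px=5.0, shape=(n, n))
        assert dm.data[1, 1] == pytest.approx(2.0 / SQRT3, rel=1e-9)

    def test_nearest_neighbor_interpolation_contract(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 60, size=(80, 2))
        dm = icd_density(ConeSet(pts), grid_step_px=7.0, shape=(61, 61))
        # recompute per-cone densities for bounded cells
        vor = Voronoi(pts)
        _, bounded = cell_areas_and_bounded(pts)
        nbrs = {i: set() for i in range(len(pts))}
        for a, b in vor.ridge_points:
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
        dens = {}
        for i in range(len(pts)):
            if bounded[i] and nbrs[i]:
                icd = np.mean([np.hypot(*(pts[n] - pts[i])) for n in nbrs[i]])
                dens[i] = 2.0 / (SQRT3 * icd ** 2)
        src = sorted(dens)
        tree = cKDTree(pts[src])
        probe = np.array([21.0, 14.0])
        i, j = 2, 3  # probe (x=21, y=14) on the 7-px grid
        nearest = src[int(tree.query(probe)[1])]
        assert dm.data[i, j] == pytest.approx(dens[nearest])

    def test_flat_mosaic_interior_within_2pct(self, flat_positions, flat_spec):
        rho = flat_spec.peak_density_deg2
        dm = icd_density(flat_positions, grid_step_px=20.0,
                         shape=flat_spec.field_size_px)
        h, w = dm.data.shape
        interior = dm.data[h // 2 - 2:h // 2 + 3, w // 2 - 2:w // 2 + 3]
        assert abs(interior.mean() / rho - 1) < 0.02


class TestYellottDensity:
    def test_pure_grating_peak_within_one_bin(self):
        n = 128
        f = 10.0 / n  # 10 cycles across the window
        x = np.arange(n)
        img = np.tile(0.5 + 0.4 * np.cos(2 * np.pi * f * x), (n, 1))
        dm = yellott_density(img, window_px=n, grid_step_px=n,
                             scale_px_per_deg=600.0)
        assert dm.valid[0, 0]
        f_detected = math.sqrt(dm.data[0, 0] / (SQRT3 / 2.0)) / 600.0
        assert abs(f_detected - f) <= 1.0 / n

    def test_rendered_hex_mosaic_density_within_10pct(self):
        spacing = 7.0
        pts = hex_lattice(spacing, 40, 46, origin=3.0)
        keep = (pts[:, 0] < 255) & (pts[:, 1] < 255)
        spec = MosaicSpec(field_size_px=(256, 256), reflectivity_cv=0.0,
                          dropout_fraction=0.0, noise_sd=0.0, psf_fwhm_px=3.0,
                          seed=0)
        img = render(ConeSet(pts[keep]), spec).image
        dm = yellott_density(img, window_px=128, grid_step_px=128,
                             scale_px_per_deg=600.0)
        true_rho = 2.0 / (SQRT3 * spacing ** 2) * 600.0 ** 2
        assert dm.valid[0, 0]
        assert dm.data[0, 0] == pytest.approx(true_rho, rel=0.10)

    def test_white_noise_window_marked_invalid(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(128, 128))
        dm = yellott_density(img, window_px=128, grid_step_px=128,
                             scale_px_per_deg=600.0)
        assert not dm.valid[0, 0]

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            yellott_density(np.zeros((64, 64)), window_px=128)


def _map_from(data, valid=None, step=2.0, scale=600.0):
    return DensityMap(data=np.asarray(data, float),
                      valid=np.ones_like(np.asarray(data), bool) if valid is None
                      else valid, method="voronoi", scale_px_per_deg=scale,
                      grid_step_px=step)


class TestLandmarks:
    def test_gaussian_bump_cdc_at_center(self):
        ii, jj = np.mgrid[0:41, 0:41]
        data = 1000 * np.exp(-((ii - 23.0) ** 2 + (jj - 17.0) ** 2) / 60.0)
        lm = find_landmarks(_map_from(data, step=1.0))
        assert lm.pcd_xy == (17.0, 23.0)
        assert np.hypot(lm.cdc_xy[0] - 17.0, lm.cdc_xy[1] - 23.0) <= 0.5
        assert lm.pcd_value >= lm.cdc_value

    def test_two_equal_peaks_uses_pcd_component(self):
        data = np.zeros((20, 20))
        data[4, 4] = data[15, 15] = 100.0
        data[4, 5] = 90.0
        lm = find_landmarks(_map_from(data, step=1.0))
        # CDC stays inside the component containing the PCD
        assert np.hypot(lm.cdc_xy[0] - lm.pcd_xy[0],
                        lm.cdc_xy[1] - lm.pcd_xy[1]) < 5.0

    def test_cdc_equals_weighted_centroid_oracle(self):
        rng = np.random.default_rng(6)
        from scipy.ndimage import gaussian_filter
        data = gaussian_filter(rng.uniform(size=(30, 30)), 4.0)
        step = 3.0
        lm = find_landmarks(_map_from(data, step=step), top_fraction=0.2)
        thr = 0.8 * data.max()
        from scipy.ndimage import label as nd_label
        labels, _ = nd_label(data >= thr)
        pi, pj = np.unravel_index(np.argmax(data), data.shape)
        region = labels == labels[pi, pj]
        ii, jj = np.nonzero(region)
        w = data[ii, jj]
        assert lm.cdc_xy[0] == pytest.approx(step * np.sum(jj * w) / w.sum())
        assert lm.cdc_xy[1] == pytest.approx(step * np.sum(ii * w) / w.sum())

    def test_flat_map_warns_and_uses_whole_region(self):
        with pytest.warns(UserWarning, match="flat"):
            lm = find_landmarks(_map_from(np.ones((11, 11)), step=1.0))
        assert lm.cdc_xy == (5.0, 5.0)


class TestGroupStatsAndZscore:
    def _bump(self, cx, cy, shape=(25, 25)):
        ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
        return 1000 + 500 * np.exp(-((ii - cy) ** 2 + (jj - cx) ** 2) / 30.0)

    def test_identical_maps_mean_is_map_sigma_zero(self):
        dm = _map_from(self._bump(12, 12))
        lm = find_landmarks(dm)
        gs = build_group_stats([dm, dm, dm], [lm, lm, lm],
                               out_shape=dm.data.shape)
        ok = gs.mu.valid
        np.testing.assert_allclose(gs.mu.data[ok], dm.data[ok], rtol=1e-9)
        np.testing.assert_allclose(gs.sigma.data[ok], 0.0, atol=1e-9)

    def test_two_maps_mean_is_pointwise_average(self):
        a = _map_from(self._bump(12, 12))
        b = _map_from(self._bump(12, 12) * 1.5)
        lma, lmb = find_landmarks(a), find_landmarks(b)
        gs = build_group_stats([a, b], [lma, lmb], out_shape=a.data.shape)
        ok = gs.mu.valid
        # CDCs coincide, so no resampling shift: mu = (a+b)/2 where defined
        np.testing.assert_allclose(gs.mu.data[ok],
                                   ((a.data + b.data) / 2)[ok], rtol=1e-6)

    def test_disjoint_valid_regions_give_no_overlap(self):
        # both maps already CDC-centered: disjoint validity stays disjoint
        va = np.zeros((25, 25), bool)
        va[:, :10] = True
        vb = np.zeros((25, 25), bool)
        vb[:, 15:] = True
        a = _map_from(self._bump(12, 12), valid=va)
        b = _map_from(self._bump(12, 12), valid=vb)
        center = Landmarks(cdc_xy=(24.0, 24.0), cdc_value=1.0,
                           pcd_xy=(24.0, 24.0), pcd_value=1.0)
        gs = build_group_stats([a, b], [center, center], out_shape=(25, 25))
        assert not gs.mu.valid.any()

    def test_zscore_of_group_mean_is_zero(self):
        maps = [_map_from(self._bump(12, 12) * s) for s in (0.9, 1.0, 1.1)]
        lms = [find_landmarks(m) for m in maps]
        gs = build_group_stats(maps, lms, out_shape=(25, 25))
        mean_map = _map_from(gs.mu.data, valid=gs.mu.valid)
        z = zscore_map(mean_map, gs)
        assert z.valid.any()
        np.testing.assert_allclose(z.data[z.valid], 0.0, atol=1e-9)

    def test_zscore_formula_and_sigma_zero_handling(self):
        mu = _map_from(np.full((5, 5), 10.0))
        gs = GroupStats(mu=ScalarMap(np.full((5, 5), 10.0)),
                        sigma=ScalarMap(np.zeros((5, 5))), n_eyes=2,
                        laterality="right", grid_step_px=2.0, units="deg2")
        gs.sigma.data[0, 0] = 2.0
        dm = _map_from(np.full((5, 5), 10.0))
        dm.data[0, 0] = 12.0   # (x - mu)/sigma = 1
        dm.data[1, 1] = 11.0   # sigma = 0, x != mu -> invalid
        z = zscore_map(dm, gs)
        assert z.data[0, 0] == pytest.approx(1.0)
        assert not z.valid[1, 1]
        assert z.valid[2, 2] and z.data[2, 2] == 0.0

    def test_misaligned_grids_rejected(self):
        gs = GroupStats(mu=ScalarMap(np.zeros((5, 5))),
                        sigma=ScalarMap(np.zeros((5, 5))), n_eyes=2,
                        laterality="right", grid_step_px=2.0, units="deg2")
        with pytest.raises(ValueError, match="aligned"):
            zscore_map(_map_from(np.zeros((6, 6))), gs)

    def test_random_maps_match_pointwise_recomputation(self):
        rng = np.random.default_rng(9)
        base = self._bump(12, 12)
        maps = [_map_from(base + rng.normal(scale=20, size=base.shape))
                for _ in range(5)]
        lm = find_landmarks(_map_from(base))  # common alignment: same CDC
        gs = build_group_stats(maps, [lm] * 5, out_shape=base.shape)
        stack = np.stack([m.data for m in maps])
        ok = gs.mu.valid
        np.testing.assert_allclose(gs.mu.data[ok], stack.mean(0)[ok], rtol=1e-9)
        np.testing.assert_allclose(gs.sigma.data[ok],
                                   stack.std(0, ddof=1)[ok], rtol=1e-9)
        z = zscore_map(maps[0], gs)
        expect = (maps[0].data - stack.mean(0)) / stack.std(0, ddof=1)
        np.testing.assert_allclose(z.data[z.valid], expect[z.valid], rtol=1e-9)


class TestRadialProfile:
    def test_constant_map_all_bins_constant(self):
        dm = _map_from(np.full((21, 21), 7.0), step=6.0)
        prof = radial_profile(dm, (60.0, 60.0), bin_deg=0.02)
        got = prof[prof["n"] > 0]
        assert (got["mean"] == 7.0).all()
        assert (got["sd"] == 0.0).all()

    def test_exponential_map_monotone_decreasing(self):
        ii, jj = np.mgrid[0:31, 0:31]
        r = np.hypot(ii - 15, jj - 15) * 4.0 / 600.0
        dm = _map_from(np.exp(-r / 0.2), step=4.0)
        prof = radial_profile(dm, (60.0, 60.0), bin_deg=0.02)
        m = prof[prof["n"] > 3]["mean"].to_numpy()
        assert (np.diff(m) < 0).all()

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(12)
        dm = _map_from(rng.uniform(size=(15, 15)), step=5.0)
        center = (30.0, 40.0)
        bin_deg = 0.01
        prof = radial_profile(dm, center, bin_deg=bin_deg)
        ii, jj = np.mgrid[0:15, 0:15]
        ecc = np.hypot(jj * 5.0 - center[0], ii * 5.0 - center[1]) / 600.0
        for _, row in prof.iterrows():
            b = row["eccentricity_deg"] - bin_deg / 2
            sel = (ecc >= b - 1e-12) & (ecc < b + bin_deg - 1e-12)
            assert row["n"] == sel.sum()
            if sel.sum():
                assert row["mean"] == pytest.approx(dm.data[sel].mean())

    def test_meridional_profile_is_signed(self):
        dm = _map_from(np.arange(21 * 21, dtype=float).reshape(21, 21), step=3.0)
        prof = radial_profile(dm, (30.0, 30.0), mode="horizontal", bin_deg=0.01)
        assert (prof["eccentricity_deg"] < 0).any()
        assert (prof["eccentricity_deg"] > 0).any()


class TestUnitConversion:
    def test_mm2_factor_exact_and_landmarks_commute(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter
        dm = _map_from(gaussian_filter(rng.uniform(size=(20, 20)), 3.0) * 1e4)
        rmf = 291.0  # microns per degree
        out = convert_to_mm2(dm, rmf)
        f = (1000.0 / rmf) ** 2
        np.testing.assert_allclose(out.data, dm.data * f, rtol=1e-12)
        lm_deg, lm_mm = find_landmarks(dm), find_landmarks(out)
        assert lm_mm.cdc_xy == pytest.approx(lm_deg.cdc_xy)
        assert lm_mm.pcd_value == pytest.approx(lm_deg.pcd_value * f)
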