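"""Correlation scoring: CC convention, Laplacian, FFT scan, exhaustive search."""

import numpy as np
import pytest

from minisitus.convert import Kernel
from minisitus.fixtures import make_hexamer_map
from minisitus.scoring import (Pose, ScoreConfig, cc, colores_search, euler_grid,
                               fft_translation_scan, laplacian)
from minisitus.voldata import AtomicModel, VolumeMap

from conftest import nearest_protomer_error


def brute_force_cc(a, b):
    num = sa = sb = 0.0
    for idx in np.ndindex(a.shape):
        num += a[idx] * b[idx]
        sa += a[idx] ** 2
        sb += b[idx] ** 2
    return num / np.sqrt(sa * sb)


class TestCC:
    def test_self_correlation_is_one(self, rng):
        m = VolumeMap(1.0, (0, 0, 0), rng.uniform(0.1, 1, (4, 4, 4)))
        assert cc(m, m) == pytest.approx(1.0, abs=1e-14)

    def test_scale_invariance(self, rng):
        m = VolumeMap(1.0, (0, 0, 0), rng.normal(size=(4, 4, 4)))
        assert cc(m, m.with_data(3.7 * m.data)) == pytest.approx(1.0, abs=1e-14)

    def test_nonnegative_maps_score_in_unit_interval(self, rng):
        for _ in range(20):
            a = VolumeMap(1.0, (0, 0, 0), rng.uniform(0, 1, (5, 5, 5)))
            b = a.with_data(rng.uniform(0, 1, (5, 5, 5)))
            assert 0.0 <= cc(a, b) <= 1.0

    def test_matches_brute_force_triple_loop(self, rng):
        for _ in range(10):
            a = VolumeMap(1.0, (0, 0, 0), rng.normal(size=(5, 5, 5)))
            b = a.with_data(rng.normal(size=(5, 5, 5)))
            assert cc(a, b) == pytest.approx(brute_force_cc(a.data, b.data),
                                             abs=1e-12)

    def test_lattice_mismatch_rejected(self, rng):
        a = VolumeMap(1.0, (0, 0, 0), rng.normal(size=(4, 4, 4)))
        b = VolumeMap(2.0, (0, 0, 0), rng.normal(size=(4, 4, 4)))
        with pytest.raises(ValueError):
            cc(a, b)

    def test_zero_map_warns_and_scores_zero(self, rng):
        a = VolumeMap(1.0, (0, 0, 0), np.zeros((3, 3, 3)))
        b = VolumeMap(1.0, (0, 0, 0), rng.normal(size=(3, 3, 3)))
        with pytest.warns(UserWarning):
            assert cc(a, b) == 0.0


class TestLaplacian:
    def test_constant_map_vanishes_in_interior(self):
        m = VolumeMap(1.0, (0, 0, 0), np.full((5, 5, 5), 3.0))
        lap = laplacian(m)
        assert np.allclose(lap.data[1:-1, 1:-1, 1:-1], 0.0)

    def test_quadratic_ramp_closed_form(self):
        width = 2.0
        data = np.broadcast_to(np.arange(7.0)[:, None, None] ** 2,
                               (7, 7, 7)).copy()
        lap = laplacian(VolumeMap(width, (0, 0, 0), data))
        assert np.allclose(lap.data[1:-1, 1:-1, 1:-1], 2.0 / width ** 2)

    def test_edge_mask_zeroes_shell_around_blob(self):
        data = np.zeros((7, 7, 7))
        data[2:5, 2:5, 2:5] = 1.0
        masked = laplacian(VolumeMap(1.0, (0, 0, 0), data), mask_edges=True)
        # voxels adjacent to the thresholded-to-zero region are suppressed
        assert np.allclose(masked.data[1, 2:5, 2:5], 0.0)
        assert np.allclose(masked.data[2, 3, 3], 0.0)  # blob surface voxel

    def test_small_map_rejected(self):
        with pytest.raises(ValueError):
            laplacian(VolumeMap(1.0, (0, 0, 0), np.ones((2, 5, 5))))

    def test_contour_filter_distinguishes_cube_from_sphere(self):
        # equal-volume cube and sphere: contours differ more than volumes
        n = 24
        idx = np.indices((n, n, n)) - (n - 1) / 2
        r = np.sqrt((idx ** 2).sum(axis=0))
        sphere = VolumeMap(1.0, (0, 0, 0), (r <= 8.0).astype(float))
        side = (4 / 3 * np.pi) ** (1 / 3) * 8.0  # same volume as the ball
        cube_mask = np.all(np.abs(idx) <= side / 2, axis=0)
        cube = VolumeMap(1.0, (0, 0, 0), cube_mask.astype(float))
        plain = cc(cube, sphere)
        contoured = cc(laplacian(cube), laplacian(sphere))
        assert contoured < plain


class TestTranslationScan:
    def test_planted_subblock_recovered(self, rng):
        target = VolumeMap(1.0, (0, 0, 0), np.zeros((10, 10, 10)))
        block = rng.uniform(0.5, 1.0, (3, 3, 3))
        target.data[4:7, 2:5, 5:8] = block
        probe = VolumeMap(1.0, (0, 0, 0), block.copy())
        offset, score = fft_translation_scan(target, probe).best()
        assert tuple(offset) == (4, 2, 5)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_equals_brute_force_overlap_loop(self, rng):
        target = VolumeMap(1.0, (0, 0, 0), rng.uniform(0, 1, (8, 8, 8)))
        probe = VolumeMap(1.0, (0, 0, 0), rng.uniform(0, 1, (3, 3, 3)))
        scan = fft_translation_scan(target, probe)
        norm = np.linalg.norm(target.data) * np.linalg.norm(probe.data)
        for d in [(0, 0, 0), (2, 3, 1), (-1, 4, 5), (7, 7, 7), (-2, -2, -2)]:
            num = 0.0
            for u in np.ndindex(3, 3, 3):
                v = tuple(np.add(u, d))
                if all(0 <= x < 8 for x in v):
                    num += probe.data[u] * target.data[v]
            idx = tuple(np.add(d, (2, 2, 2)))
            assert scan.cc_field[idx] == pytest.approx(num / norm, abs=1e-8)

    def test_situs_cc_and_pearson_agree_on_argmax(self, rng):
        # with a fixed probe fully inside the target, both conventions
        # rank the same translation first
        target = VolumeMap(1.0, (0, 0, 0), rng.uniform(0, 1, (8, 8, 8)))
        target.data[3:6, 3:6, 3:6] += 2.0
        probe_block = target.data[3:6, 3:6, 3:6].copy()
        situs_best, pearson_best = None, None
        for d in np.ndindex(6, 6, 6):
            window = target.data[d[0]:d[0] + 3, d[1]:d[1] + 3, d[2]:d[2] + 3]
            s = float((window * probe_block).sum())
            p = float(np.corrcoef(window.ravel(), probe_block.ravel())[0, 1])
            if situs_best is None or s > situs_best[0]:
                situs_best = (s, d)
            if pearson_best is None or p > pearson_best[0]:
                pearson_best = (p, d)
        assert situs_best[1] == pearson_best[1] == (3, 3, 3)

    def test_width_mismatch_rejected(self, rng):
        a = VolumeMap(1.0, (0, 0, 0), rng.uniform(0, 1, (4, 4, 4)))
        b = VolumeMap(2.0, (0, 0, 0), rng.uniform(0, 1, (3, 3, 3)))
        with pytest.raises(ValueError):
            fft_translation_scan(a, b)

    def test_zero_probe_warns_with_zero_field(self, rng):
        target = VolumeMap(1.0, (0, 0, 0), rng.uniform(0, 1, (4, 4, 4)))
        probe = VolumeMap(1.0, (0, 0, 0), np.zeros((2, 2, 2)))
        with pytest.warns(UserWarning):
            scan = fft_translation_scan(target, probe)
        assert np.all(scan.cc_field == 0.0)


class TestEulerGrid:
    def test_poles_deduplicated_and_identity_present(self):
        grid = euler_grid(30.0)
        assert (0.0, 0.0, 0.0) in grid
        polar = [g for g in grid if g[1] in (0.0, 180.0)]
        assert all(g[2] == 0.0 for g in polar)

    def test_equal_area_theta_sampling(self):
        thetas = sorted({g[1] for g in euler_grid(30.0)})
        cos_vals = np.cos(np.deg2rad(thetas))
        assert np.allclose(np.diff(cos_vals), np.diff(cos_vals)[0])


class TestColores:
    def test_whole_structure_probe_ranks_identity_first(self, hexamer):
        coords = np.concatenate([rt.apply(hexamer.monomer.coords)
                                 for rt in hexamer.transforms])
        whole = AtomicModel(coords)
        config = ScoreConfig(kernel=Kernel("gaussian", resolution=15.0),
                             angular_step=90.0, n_best=3)
        top = colores_search(hexamer.map, whole, config)[0]
        assert top.cc == pytest.approx(1.0, abs=1e-3)
        assert np.linalg.norm(top.transform.apply(whole.centroid)
                              - whole.centroid) < 1e-6
        # identity up to the assembly's own C6 symmetry
        residual = min(top.transform.rotation_angle_deg(rt)
                       for rt in hexamer.transforms)
        assert residual < 1e-6

    def test_laplacian_rescues_low_resolution_misranking(self):
        # at 25 A the plain CC misranks the protomer pose on this fixture;
        # contour scoring ranks it first
        fx = make_hexamer_map(seed=0, resolution=25.0)
        kernel = Kernel("gaussian", resolution=25.0)
        plain_cfg = ScoreConfig(kernel=kernel, angular_step=30.0, n_best=1)
        lap_cfg = ScoreConfig(kernel=kernel, angular_step=30.0, n_best=1,
                              use_laplacian=True)
        plain_top = colores_search(fx.map, fx.monomer, plain_cfg)[0]
        lap_top = colores_search(fx.map, fx.monomer, lap_cfg)[0]
        p_dt, p_dr = nearest_protomer_error(plain_top.transform, fx)
        l_dt, l_dr = nearest_protomer_error(lap_top.transform, fx)
        assert l_dt <= fx.map.width and l_dr <= 15.0
        assert p_dt > fx.map.width or p_dr > 15.0

    def test_empty_probe_rejected(self, hexamer):
        with pytest.raises(ValueError):
            colores_search(hexamer.map, AtomicModel(np.zeros((0, 3))),
                           ScoreConfig())

    def test_angular_step_bounds(self):
        with pytest.raises(ValueError):
            ScoreConfig(angular_step=2.0)
        with pytest.raises(ValueError):
            ScoreConfig(angular_step=120.0)
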