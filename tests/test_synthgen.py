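import numpy as np
import pytest

import sstmorph.synthgen as sg
from sstmorph.tracegeom import Polyline3D, arclength, resample_equidistant

from conftest import cylinder_scene


class TestMakeCenterline:
    def test_zero_tortuosity_straight(self):
        poly = sg.make_centerline(seed=1, total_length=100.0, tortuosity=0.0)
        total, _ = arclength(poly)
        assert total == pytest.approx(100.0, rel=1e-9)
        # collinear with +x
        assert np.allclose(poly.points[:, 1:], 0.0)

    def test_length_normalized(self):
        poly = sg.make_centerline(seed=1, total_length=100.0, tortuosity=0.3)
        total, _ = arclength(poly)
        assert total == pytest.approx(100.0, rel=0.005)

    def test_deterministic(self):
        p1 = sg.make_centerline(seed=7, total_length=80.0, tortuosity=0.4)
        p2 = sg.make_centerline(seed=7, total_length=80.0, tortuosity=0.4)
        assert np.array_equal(p1.points, p2.points)

    def test_different_seed_differs(self):
        p1 = sg.make_centerline(seed=7, total_length=80.0, tortuosity=0.4)
        p2 = sg.make_centerline(seed=8, total_length=80.0, tortuosity=0.4)
        assert not np.allclose(p1.points, p2.points)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="total_length"):
            sg.make_centerline(seed=1, total_length=0.0, tortuosity=0.1)


class TestGeometryTypes:
    def test_negative_profile_rejected(self):
        ctrl = np.array([[0, 0, 0], [100, 0, 0]], float)
        with pytest.raises(ValueError, match="positive"):
            sg.SSTGeometry(ctrl, 100.0, (1.0, -5.0, 0.0))

    def test_ellipticity_below_one_rejected(self):
        ctrl = np.array([[0, 0, 0], [100, 0, 0]], float)
        with pytest.raises(ValueError, match="ellipticity"):
            sg.SSTGeometry(ctrl, 100.0, (10.0, 0.0, 0.0), ellipticity=0.9)

    def test_axes_recover_mean_and_ratio(self):
        ctrl = np.array([[0, 0, 0], [100, 0, 0]], float)
        g = sg.SSTGeometry(ctrl, 100.0, (10.0, 4.0, -2.0), ellipticity=1.6)
        s = np.array([0.0, 50.0, 100.0])
        d1, d2 = g.axes(s)
        assert np.allclose((d1 + d2) / 2, g.diameter(s))
        assert np.allclose(d1 / d2, 1.6)

    def test_render_config_validation(self):
        with pytest.raises(ValueError):
            sg.RenderConfig(voxel_spacing=(0.0, 0.5, 0.5))


class TestRenderSST:
    def test_lumen_dark_wall_bright(self, cylinder10):
        volume, gt, _, _ = cylinder10
        pts = gt.centerline.points
        sz, sy, sx = volume.spacing
        lumen_vals, wall_vals = [], []
        for p in pts[50:-50:40]:
            iz, iy, ix = int(p[2] / sz), int(p[1] / sy), int(p[0] / sx)
            lumen_vals.append(volume.data[iz, iy, ix])
            iy_wall = int((p[1] + 4.0) / sy)  # 4 um off-axis: inside the wall
            wall_vals.append(volume.data[iz, iy_wall, ix])
        assert max(lumen_vals) < 0.1 * np.median(wall_vals)

    def test_zero_density_only_background(self):
        ctrl = np.array([[10, 20, 20], [90, 20, 20]], float)
        geom = sg.SSTGeometry(ctrl, 80.0, (10.0, 0.0, 0.0))
        cfg = sg.RenderConfig(
            volume_shape=(40, 40, 100), voxel_spacing=(1.0, 1.0, 1.0),
            granule_density=0.0, seed=4,
        )
        vol, gt = sg.render_sst(geom, cfg)
        assert np.all(vol.data == 0.0)
        assert gt.n_granules == 0

    def test_deterministic_volume(self):
        ctrl = np.array([[10, 20, 20], [90, 20, 20]], float)
        geom = sg.SSTGeometry(ctrl, 80.0, (10.0, 0.0, 0.0))
        cfg = sg.RenderConfig(
            volume_shape=(40, 40, 100), voxel_spacing=(1.0, 1.0, 1.0),
            granule_density=10.0, poisson_scale=5.0, read_noise_sd=1.0, seed=11,
        )
        v1, _ = sg.render_sst(geom, cfg)
        v2, _ = sg.render_sst(geom, cfg)
        assert np.array_equal(v1.data, v2.data)

    def test_granule_count_conservation(self):
        ctrl = np.array([[10, 20, 20], [90, 20, 20]], float)
        geom = sg.SSTGeometry(ctrl, 80.0, (10.0, 0.0, 0.0))
        cfg = sg.RenderConfig(
            volume_shape=(40, 40, 100), voxel_spacing=(1.0, 1.0, 1.0),
            granule_density=7.3, seed=2,
        )
        _, gt = sg.render_sst(geom, cfg)
        assert gt.n_granules == int(np.floor(7.3 * 80.0))

    def test_out_of_bounds_names_position(self):
        ctrl = np.array([[10, 20, 20], [300, 20, 20]], float)  # exits +x face
        geom = sg.SSTGeometry(ctrl, 290.0, (10.0, 0.0, 0.0))
        cfg = sg.RenderConfig(
            volume_shape=(40, 40, 100), voxel_spacing=(1.0, 1.0, 1.0), seed=0
        )
        with pytest.raises(ValueError, match=r"s = \d+\.\d+ um"):
            sg.render_sst(geom, cfg)

    def test_anisotropic_z_supported(self):
        ctrl = np.array([[15, 20, 20], [85, 20, 20]], float)
        geom = sg.SSTGeometry(ctrl, 70.0, (8.0, 0.0, 0.0))
        cfg = sg.RenderConfig(
            volume_shape=(20, 80, 200), voxel_spacing=(2.0, 0.5, 0.5),
            granule_density=50.0, seed=6,
        )
        vol, _ = sg.render_sst(geom, cfg)
        assert vol.data.shape == (20, 80, 200)
        assert vol.data.max() > 0


class TestSideTraces:
    def test_straight_cylinder_parallel_lines(self):
        ctrl = np.array([[10, 30, 30], [110, 30, 30]], float)
        geom = sg.SSTGeometry(ctrl, 100.0, (10.0, 0.0, 0.0))
        gt = sg._dense_geometry(geom, 0.5)
        a, b = sg.simulate_side_traces(gt, jitter_sd=0.0, seed=0)
        gaps = np.linalg.norm(a.points - b.points, axis=1)
        assert np.allclose(gaps, 10.0, atol=1e-9)

    def test_midpoints_on_centerline_jitter_free(self):
        poly = sg.make_centerline(seed=3, total_length=120.0, tortuosity=0.3, start=(30, 40, 40))
        geom = sg.SSTGeometry(poly.points, 120.0, (10.0, 2.0, -1.0), ellipticity=1.4)
        gt = sg._dense_geometry(geom, 0.5)
        a, b = sg.simulate_side_traces(gt, jitter_sd=0.0, seed=0)
        mids = 0.5 * (a.points + b.points)
        # point-to-polyline (segment) distance, not vertex distance
        pts = gt.centerline.points
        seg = np.diff(pts, axis=0)
        seglen2 = np.einsum("ij,ij->i", seg, seg)
        for m in mids:
            rel = m - pts[:-1]
            t = np.clip(np.einsum("ij,ij->i", rel, seg) / seglen2, 0.0, 1.0)
            d = np.linalg.norm(pts[:-1] + t[:, None] * seg - m, axis=1)
            assert d.min() < 0.1

    def test_jittered_midpoints_unbiased(self):
        # Monte-Carlo: perpendicular distance of pair midpoints to the true
        # axis has mean sigma/sqrt(2)*sqrt(pi/2) ~ 0.44 um for sigma = 0.5
        ctrl = np.array([[0, 50, 50], [500, 50, 50]], float)
        geom = sg.SSTGeometry(ctrl, 500.0, (10.0, 0.0, 0.0))
        gt = sg._dense_geometry(geom, 0.5)
        a, b = sg.simulate_side_traces(gt, jitter_sd=0.5, seed=12, n_points=200)
        mids = 0.5 * (a.points + b.points)
        perp = np.linalg.norm(mids[:, 1:] - np.array([50.0, 50.0]), axis=1)
        assert perp.mean() < 0.5

    def test_orifice_first(self):
        poly = sg.make_centerline(seed=3, total_length=100.0, tortuosity=0.2, start=(30, 40, 40))
        geom = sg.SSTGeometry(poly.points, 100.0, (10.0, 0.0, 0.0))
        gt = sg._dense_geometry(geom, 0.5)
        a, b = sg.simulate_side_traces(gt, jitter_sd=0.0, seed=0)
        start = gt.centerline.points[0]
        assert np.linalg.norm(a.points[0] - start) < np.linalg.norm(a.points[-1] - start)

    def test_negative_jitter_rejected(self):
        ctrl = np.array([[0, 0, 0], [10, 0, 0]], float)
        geom = sg.SSTGeometry(ctrl, 10.0, (5.0, 0.0, 0.0))
        gt = sg._dense_geometry(geom, 0.5)
        with pytest.raises(ValueError):
            sg.simulate_side_traces(gt, jitter_sd=-1.0, seed=0)


class TestMeasurementTable:
    def test_row_count(self):
        tab = sg.make_measurement_table(10, 10, (10.0, 0.1, -3e-4), 1.0, seed=0)
        assert len(tab) == 100
        assert tab["bird_id"].nunique() == 10

    def test_zero_noise_exact_quadratic(self):
        tab = sg.make_measurement_table(
            4, 8, (10.0, 0.1, -3e-4), 0.0, seed=1, intercept_sd=0.0
        )
        s = tab["s_um"].to_numpy()
        expected = 10.0 + 0.1 * s - 3e-4 * s**2
        assert np.allclose(tab["mean_diameter_um"], expected, atol=1e-12)

    def test_deterministic(self):
        t1 = sg.make_measurement_table(5, 6, (10.0, 0.1, -3e-4), 1.0, seed=9)
        t2 = sg.make_measurement_table(5, 6, (10.0, 0.1, -3e-4), 1.0, seed=9)
        assert t1.equals(t2)

    def test_schema(self):
        tab = sg.make_measurement_table(3, 5, (10.0, 0.1, -3e-4), 1.0, seed=0)
        for col in ("bird_id", "s_um", "d1_um", "d2_um", "total_length_um"):
            assert col in tab.columns
        assert (tab["d1_um"] >= tab["d2_um"]).all()
        assert (tab.groupby("bird_id")["s_um"].min() == 0.0).all()

    def test_min_birds_enforced(self):
        with pytest.raises(ValueError):
            sg.make_measurement_table(1, 10, (10.0, 0.1, -3e-4), 1.0, seed=0)


class TestFrames:
    def test_transport_frames_orthonormal(self):
        poly = sg.make_centerline(seed=5, total_length=150.0, tortuosity=0.5)
        dense = resample_equidistant(poly, 300)
        _, s = arclength(dense)
        tang = np.gradient(dense.points, s, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        u, v = sg.transport_frames(tang)
        for i in range(0, 300, 37):
            assert abs(u[i] @ tang[i]) < 1e-9
            assert abs(u[i] @ v[i]) < 1e-12
            assert np.linalg.norm(u[i]) == pytest.approx(1.0, abs=1e-9)
        # continuity: no frame flips
        assert np.all(np.einsum("ij,ij->i", u[1:], u[:-1]) > 0.9)
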