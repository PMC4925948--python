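import numpy as np
import pytest
from scipy.spatial import cKDTree

from angio3d.centerline import CenterlineCurve
from angio3d.recon.reconstruct import (VesselModel3D, correspond_and_reconstruct,
                                       estimate_radii)
from angio3d.walls import WallCurve


def curve_from_points(pts, bifurcations=()):
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return CenterlineCurve(np.asarray(pts, dtype=float), arc,
                           list(bifurcations))


def project_curve(geom, X):
    return geom.project_points(np.asarray(X))


def densify(X, factor=20):
    """Dense resampling of a polyline so point-set distances approximate
    point-to-curve distances."""
    X = np.asarray(X, dtype=float)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(X, axis=0), axis=1))])
    t = np.linspace(0.0, arc[-1], factor * len(X))
    return np.column_stack([np.interp(t, arc, X[:, k]) for k in range(X.shape[1])])


@pytest.fixture()
def helix_curves(geom_pair_30):
    geomA, geomB = geom_pair_30
    t = np.linspace(0, 2.4, 150)
    X = np.column_stack([6 * np.cos(2 * np.pi * t / 2.4) - 6,
                         6 * np.sin(2 * np.pi * t / 2.4),
                         10 * (t - 1.2)])
    return X, curve_from_points(project_curve(geomA, X)), \
        curve_from_points(project_curve(geomB, X))


class TestCorrespond:
    def test_helix_reconstruction_noise_free(self, geom_pair_30, helix_curves):
        geomA, geomB = geom_pair_30
        X, cA, cB = helix_curves
        model = correspond_and_reconstruct(cA, cB, geomA, geomB)
        d = cKDTree(densify(X)).query(model.centerline3d)[0]
        assert np.sqrt((d**2).mean()) < 0.1  # mm

    def test_straight_vessel_converges(self, geom_pair):
        geomA, geomB = geom_pair
        t = np.linspace(0, 1, 80)
        X = np.column_stack([30 * (t - 0.5), np.zeros_like(t), 25 * (t - 0.5)])
        cA = curve_from_points(project_curve(geomA, X))
        cB = curve_from_points(project_curve(geomB, X))
        model = correspond_and_reconstruct(cA, cB, geomA, geomB, max_iter=20)
        assert model.n_iterations <= 20
        u = model.update_norms
        assert all(b <= a + 1e-9 for a, b in zip(u, u[1:]))  # monotone decreasing

    def test_reversed_curve_auto_reoriented(self, geom_pair_30, helix_curves):
        geomA, geomB = geom_pair_30
        X, cA, cB = helix_curves
        cB_rev = curve_from_points(cB.points[::-1].copy())
        m1 = correspond_and_reconstruct(cA, cB, geomA, geomB)
        m2 = correspond_and_reconstruct(cA, cB_rev, geomA, geomB)
        d = cKDTree(m1.centerline3d).query(m2.centerline3d)[0]
        assert d.max() < 0.05

    def test_uniform_arclength_output(self, geom_pair_30, helix_curves):
        geomA, geomB = geom_pair_30
        _, cA, cB = helix_curves
        model = correspond_and_reconstruct(cA, cB, geomA, geomB)
        seg = np.linalg.norm(np.diff(model.centerline3d, axis=0), axis=1)
        assert seg.std() / seg.mean() < 0.05

    def test_bifurcation_anchor_used(self, geom_pair_30):
        geomA, geomB = geom_pair_30
        t = np.linspace(0, 1, 100)
        X = np.column_stack([30 * (t - 0.5), 8 * np.sin(np.pi * t), 20 * (t - 0.5)])
        pA = project_curve(geomA, X)
        pB = project_curve(geomB, X)
        bifA = tuple(np.round(pA[50]).astype(int))
        bifB = tuple(np.round(pB[50]).astype(int))
        cA = curve_from_points(pA, [bifA])
        cB = curve_from_points(pB, [bifB])
        model = correspond_and_reconstruct(cA, cB, geomA, geomB)
        d = cKDTree(densify(X)).query(model.centerline3d)[0]
        assert np.sqrt((d**2).mean()) < 0.1


class TestEstimateRadii:
    def test_closed_form_symmetric_walls(self):
        from angio3d.recon.geometry import ProjectionGeometry

        geom = ProjectionGeometry(1000.0, 0.5, 0.0, 0.0, sod_mm=500.0,
                                  image_shape=(128, 128))
        geomB = ProjectionGeometry(1000.0, 0.5, 90.0, 0.0, sod_mm=500.0,
                                   image_shape=(128, 128))
        # straight centreline through the isocenter along z (in both views'
        # detector planes); magnification at the isocenter = SID/SOD = 2
        t = np.linspace(-20, 20, 60)
        X = np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
        pA = geom.project_points(X)
        pB = geomB.project_points(X)
        d_px = 4.0
        model = VesselModel3D(X, frac_a=np.arange(60.0), frac_b=np.arange(60.0))
        wallsA = (WallCurve(pA + [0.0, d_px], "left", 0.0),
                  WallCurve(pA - [0.0, d_px], "right", 0.0))
        wallsB = (WallCurve(pB + [0.0, d_px], "left", 0.0),
                  WallCurve(pB - [0.0, d_px], "right", 0.0))
        radii = estimate_radii(model, wallsA, wallsB, geom, geomB)
        expected = d_px * 0.5 / 2.0  # d * pixel_size / magnification
        assert np.allclose(radii, expected, atol=1e-6)

    def test_constant_radius_phantom(self, geom_pair, helix_scene):
        from angio3d.phantom import make_phantom, render_views
        from angio3d.walls import extract_vessel_walls
        from tests.conftest import extract_view_centerline

        geomA, geomB = geom_pair
        ves = make_phantom("helix", a=6.0, b=10.0, turns=0.6, r0=1.5)
        imgA, imgB, gt = render_views(ves, geomA, geomB, seed=5, noise_sigma=0.01)
        cA = extract_view_centerline(imgA, gt, 0)
        cB = extract_view_centerline(imgB, gt, 1)
        wallsA = extract_vessel_walls(imgA, cA)
        wallsB = extract_vessel_walls(imgB, cB)
        model = correspond_and_reconstruct(cA, cB, geomA, geomB)
        radii = estimate_radii(model, wallsA, wallsB, geomA, geomB, smooth_window=7)
        assert np.abs(radii - 1.5).mean() / 1.5 < 0.05

    def test_all_invalid_at_point_interpolated(self):
        from angio3d.recon.geometry import ProjectionGeometry

        geom = ProjectionGeometry(1000.0, 0.5, 0.0, 0.0, image_shape=(128, 128))
        geomB = ProjectionGeometry(1000.0, 0.5, 90.0, 0.0, image_shape=(128, 128))
        t = np.linspace(-20, 20, 30)
        X = np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
        pA = geom.project_points(X)
        pB = geomB.project_points(X)
        wallsA = (WallCurve(pA + [0.0, 3.0], "left", 0.0),
                  WallCurve(pA - [0.0, 3.0], "right", 0.0))
        # one wall point coincides with the centreline in both views -> zero
        # distances there are excluded, neighbours fill in
        badA = (WallCurve(np.vstack([pA[:10] + [0, 3.0], pA[10:11], pA[11:] + [0, 3.0]]),
                          "left", 0.0), wallsA[1])
        badB = (WallCurve(np.vstack([pB[:10] + [0, 3.0], pB[10:11], pB[11:] + [0, 3.0]]),
                          "left", 0.0),
                WallCurve(np.vstack([pB[:10] - [0, 3.0], pB[10:11], pB[11:] - [0, 3.0]]),
                          "right", 0.0))
        model = VesselModel3D(X, frac_a=np.arange(30.0), frac_b=np.arange(30.0))
        radii = estimate_radii(model, badA, badB, geom, geomB)
        assert np.all(np.isfinite(radii)) and np.all(radii > 0)
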