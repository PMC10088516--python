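"""Cross-section contours and the nine per-point morphological features."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy import integrate

from cvmorph.features import (ContourError, contour_metrics, cross_section_contour,
                              point_features)
from cvmorph.segmentation import SurfaceMesh


def _analytic_cylinder_mesh(radius=2.0, height=40.0, sections=128):
    tm = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


class TestCrossSectionContour:
    def test_perpendicular_cut_recovers_circle_area(self):
        mesh = _analytic_cylinder_mesh()
        poly = cross_section_contour(mesh, np.zeros(3), np.array([0, 0, 1.0]))
        m = contour_metrics(poly)
        assert abs(m["area_mm2"] / (np.pi * 4.0) - 1) < 0.02
        assert m["circularity"] > 0.98

    def test_oblique_cut_gives_cos_angle_axis_ratio(self):
        """Cutting a cylinder at 60 deg to the axis: ellipse ratio cos(60) = 0.5."""
        mesh = _analytic_cylinder_mesh()
        ang = np.deg2rad(60.0)
        tangent = np.array([np.sin(ang), 0.0, np.cos(ang)])
        poly = cross_section_contour(mesh, np.zeros(3), tangent)
        m = contour_metrics(poly)
        assert abs(m["min_max_ratio"] / np.cos(ang) - 1) < 0.03

    def test_plane_outside_mesh_raises(self):
        mesh = _analytic_cylinder_mesh(height=10.0)
        with pytest.raises(ContourError):
            cross_section_contour(mesh, np.array([0, 0, 50.0]), np.array([0, 0, 1.0]))

    def test_point_outside_lumen_raises(self):
        mesh = _analytic_cylinder_mesh(radius=2.0, height=10.0)
        # plane hits the mesh but the (far-off) point is in no loop
        with pytest.raises(ContourError, match="encloses"):
            cross_section_contour(mesh, np.array([10.0, 0, 0.0]), np.array([0, 0, 1.0]))

    def test_zero_tangent_rejected(self):
        mesh = _analytic_cylinder_mesh()
        with pytest.raises(ValueError, match="nonzero"):
            cross_section_contour(mesh, np.zeros(3), np.zeros(3))

    def test_contour_is_counterclockwise(self):
        mesh = _analytic_cylinder_mesh()
        poly = cross_section_contour(mesh, np.zeros(3), np.array([0, 0, 1.0]))
        x, y = poly[:, 0], poly[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0


class TestContourMetrics:
    def test_regular_360gon_approximates_unit_circle(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        poly = np.column_stack([np.cos(th), np.sin(th)])
        m = contour_metrics(poly)
        assert abs(m["area_mm2"] - np.pi) < 2e-3
        assert abs(m["perimeter_mm"] - 2 * np.pi) < 2e-3
        assert abs(m["circularity"] - 1.0) < 1e-3
        assert abs(m["min_diameter_mm"] - 2.0) < 1e-3
        assert abs(m["max_diameter_mm"] - 2.0) < 1e-3

    def test_unit_square_closed_forms(self):
        poly = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        m = contour_metrics(poly)
        assert m["area_mm2"] == pytest.approx(1.0)
        assert m["perimeter_mm"] == pytest.approx(4.0)
        assert m["circularity"] == pytest.approx(np.pi / 4)
        assert m["min_diameter_mm"] == pytest.approx(1.0)
        assert m["max_diameter_mm"] == pytest.approx(np.sqrt(2))

    def test_two_one_ellipse_against_quadrature_perimeter(self):
        """2:1 ellipse: area 2*pi, ratio 0.5; perimeter vs elliptic integral."""
        a, b = 2.0, 1.0
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        poly = np.column_stack([a * np.cos(th), b * np.sin(th)])
        m = contour_metrics(poly)
        assert abs(m["area_mm2"] / (2 * np.pi) - 1) < 0.005
        assert abs(m["min_max_ratio"] / 0.5 - 1) < 0.01
        per, _ = integrate.quad(
            lambda t: np.hypot(a * np.sin(t), b * np.cos(t)), 0, 2 * np.pi)
        assert abs(m["perimeter_mm"] / per - 1) < 0.005

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]])
        with pytest.raises(ValueError):
            contour_metrics(bowtie)

    def test_degenerate_area_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0.0]])
        with pytest.raises(ValueError):
            contour_metrics(line)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(5, 40), st.integers(0, 10 ** 6))
    def test_circularity_bounded_by_isoperimetric_inequality(self, n, seed):
        """4*pi*A/P^2 <= 1 for every simple polygon (convex-hull construction)."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2)) * rng.uniform(0.5, 5)
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        m = contour_metrics(pts[hull.vertices])
        assert m["circularity"] <= 1.0 + 1e-12
        assert 0 < m["min_max_ratio"] <= 1.0 + 1e-12
        # isodiametric bound: A <= pi d_max^2 / 4
        assert m["area_mm2"] <= np.pi * m["max_diameter_mm"] ** 2 / 4 + 1e-9


class TestPointFeatures:
    def test_cylinder_mean_area_and_circularity(self, cylinder_case):
        """r=2 tube: mean area ~ pi r^2 within 3%, circularity >= 0.98."""
        v = cylinder_case["feats"].valid()
        assert abs(v.area_mm2.mean() / (np.pi * 4.0) - 1) < 0.03
        assert v.circularity.mean() >= 0.98

    def test_cylinder_caliber_estimates_agree(self, cylinder_case):
        """2*misr, min and max Feret diameter within 5% of each other."""
        v = cylinder_case["feats"].valid()
        vals = [2 * v.misr_mm.mean(), v.min_diameter_mm.mean(), v.max_diameter_mm.mean()]
        assert max(vals) / min(vals) < 1.05

    def test_torus_curvature_and_area_simultaneously(self, torus_case):
        v = torus_case["feats"].valid()
        mid = v.iloc[len(v) // 4: 3 * len(v) // 4]
        assert abs(mid.curvature_per_mm.mean() / 0.1 - 1) < 0.05
        assert abs(v.area_mm2.mean() / (np.pi * 4.0) - 1) < 0.03

    def test_radius_recovery_across_noise_seeds(self):
        """min_diameter/2 within 5% of truth for r >= 3 voxels, 5 noise seeds."""
        from cvmorph.cohort import measure_cylinder

        r_true = 1.2  # ~4.2 voxels at 0.284 mm
        for seed in range(5):
            s = measure_cylinder(r_true, length_mm=15.0, noise_sigma=5.0, seed=seed,
                                 origin_jitter_mm=(0.05 * seed,) * 3)
            assert abs(s.min_diameter_mm[0] / 2 / r_true - 1) < 0.05

    def test_bifurcation_missing_points_flagged_not_dropped(self, bifurcation_case):
        table = bifurcation_case["feats"].table
        assert table.missing.any()
        # every centerline point has a row, missing or not
        cl = bifurcation_case["cl"]
        assert len(table) == cl.total_points()

    def test_features_invariant_under_rotation(self, cylinder_case):
        """Feature means move < 2% when the phantom is rigidly rotated."""
        from scipy.spatial.transform import Rotation

        from conftest import run_phantom_case
        from cvmorph.phantom import TubeSpec

        base = cylinder_case["feats"].valid()
        rng = np.random.default_rng(4)
        for _ in range(3):
            R = Rotation.random(random_state=rng).as_matrix()
            spec = TubeSpec(kind="cylinder", radius_mm=2.0, length_mm=40.0, pose=R)
            v = run_phantom_case(spec)["feats"].valid()
            for col in ("area_mm2", "min_diameter_mm", "max_diameter_mm",
                        "perimeter_mm", "circularity"):
                assert abs(v[col].mean() / base[col].mean() - 1) < 0.02, col
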