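import math

import numpy as np
import pytest

from rootplan.root_measure import (
    DegenerateGeometryError,
    MeasurementWarning,
    Plane,
    commissural_heights,
    commissure_circle,
    cusp_angles,
    cusp_coaptation_height,
    disproportionate_ratio,
    ellipse_axes,
    estimated_vbr_diameter,
    fit_vbr_plane,
    intercommissural_distances,
    measure_root,
    polygon_area_perimeter,
    predicted_commissural_height,
    project_to_plane,
    radial_offset_e,
)
from rootplan.synthetic_roots import RigidTransform, SyntheticRootParams, make_root


def _circle2d(r, n=360):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestPlaneFitting:
    def test_axis_aligned_nadirs_give_z_plane(self, simple_geometry):
        g = simple_geometry
        g.nadirs = {
            "L": np.array([1.0, 0, 0]),
            "R": np.array([0, 1.0, 0]),
            "N": np.array([0.0, 0, 0]),
        }
        plane = fit_vbr_plane(g)
        np.testing.assert_allclose(plane.unit_normal, [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(0.0, abs=1e-12)

    def test_normal_points_toward_commissures(self, simple_geometry):
        plane = fit_vbr_plane(simple_geometry)
        com = np.mean([simple_geometry.commissures[k] for k in ("NL", "LR", "RN")], axis=0)
        assert plane.signed_distance(com)[0] > 0

    def test_collinear_nadirs_rejected(self, simple_geometry):
        g = simple_geometry
        g.nadirs = {
            "L": np.array([0.0, 0, 0]),
            "R": np.array([1.0, 1, 1]),
            "N": np.array([2.0, 2, 2]),
        }
        with pytest.raises(DegenerateGeometryError):
            fit_vbr_plane(g)

    def test_tilted_synthetic_root_normal_recovered(self):
        tr = RigidTransform.from_euler([10.0, 0.0, 0.0])
        g, _ = make_root(SyntheticRootParams(rigid_transform=tr))
        plane = fit_vbr_plane(g)
        expected = tr.rotation @ np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose(plane.unit_normal, expected, atol=1e-9)


class TestProjection:
    def test_coplanar_square_preserved(self):
        plane = Plane(unit_normal=np.array([0.0, 0.0, 1.0]), offset=0.0)
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        p2 = project_to_plane(square, plane)
        area, per = polygon_area_perimeter(p2)
        assert area == pytest.approx(1.0, abs=1e-12)
        assert per == pytest.approx(4.0, abs=1e-12)

    def test_offset_point_projects_to_foot(self):
        plane = Plane(unit_normal=np.array([0.0, 0.0, 1.0]), offset=0.0)
        above = project_to_plane([[2.0, 3.0, 5.0]], plane)
        foot = project_to_plane([[2.0, 3.0, 0.0]], plane)
        np.testing.assert_allclose(above, foot, atol=1e-12)

    def test_tilted_circle_radius_preserved(self):
        # circle r=14 tilted 30 degrees, projected onto its own plane
        tr = RigidTransform.from_euler([30.0, 0.0, 0.0], translation=[5, -3, 7])
        t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        circle = np.column_stack([14 * np.cos(t), 14 * np.sin(t), np.zeros_like(t)])
        pts = tr.apply(circle)
        normal = tr.rotation @ np.array([0.0, 0.0, 1.0])
        plane = Plane(unit_normal=normal, offset=float(normal @ tr.translation))
        p2 = project_to_plane(pts, plane)
        radii = np.linalg.norm(p2 - p2.mean(axis=0), axis=1)
        np.testing.assert_allclose(radii, 14.0, atol=1e-9)


class TestPolygonMetrics:
    def test_unit_square(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        assert polygon_area_perimeter(pts) == (1.0, 4.0)

    def test_regular_ngon_matches_closed_form(self):
        n, r = 360, 14.0
        area, per = polygon_area_perimeter(_circle2d(r, n))
        assert area == pytest.approx(0.5 * n * r**2 * math.sin(2 * math.pi / n), rel=1e-12)
        assert per == pytest.approx(2 * n * r * math.sin(math.pi / n), rel=1e-12)
        # and both converge to the circle within 0.01%
        assert area == pytest.approx(math.pi * r**2, rel=1e-4)
        assert per == pytest.approx(2 * math.pi * r, rel=1e-4)

    def test_orientation_invariance(self):
        pts = _circle2d(10, 17)
        assert polygon_area_perimeter(pts) == polygon_area_perimeter(pts[::-1])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            polygon_area_perimeter([[0, 0], [1, 1]])


class TestEstimatedDiameter:
    @pytest.mark.parametrize(
        "area,perimeter,expected,tol",
        [
            (621.3, 88.9, 28.2, 0.05),       # expert-measured group means
            (615.752, 87.965, 28.000, 1e-3),  # perfect circle d=28
            (616.5, 89.7, 28.28, 0.005),      # hand arithmetic
        ],
    )
    def test_values(self, area, perimeter, expected, tol):
        assert estimated_vbr_diameter(area, perimeter) == pytest.approx(expected, abs=tol)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            estimated_vbr_diameter(0.0, 88.0)


class TestEllipseAxes:
    def test_circle(self):
        major, minor = ellipse_axes(_circle2d(14))
        assert major == pytest.approx(28.0, rel=1e-9)
        assert minor == pytest.approx(28.0, rel=1e-4)
        assert major >= minor

    def test_ellipse_16_12(self):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.column_stack([16 * np.cos(t), 12 * np.sin(t)])
        major, minor = ellipse_axes(pts)
        assert major == pytest.approx(32.0, abs=1e-6)
        assert minor == pytest.approx(24.0, abs=1e-6)
        assert major / minor == pytest.approx(4.0 / 3.0, abs=1e-6)


class TestCommissureCircle:
    def test_equilateral(self):
        com = {"NL": [0, 0, 0], "LR": [2, 0, 0], "RN": [1, math.sqrt(3), 0]}
        _, radius, cca = commissure_circle(com)
        assert radius == pytest.approx(2 / math.sqrt(3), rel=1e-12)
        assert cca == pytest.approx(math.pi * radius**2, rel=1e-12)

    def test_right_triangle_thales(self):
        com = {"NL": [0, 0, 1], "LR": [3, 0, 1], "RN": [0, 4, 1]}
        center, radius, _ = commissure_circle(com)
        assert radius == pytest.approx(2.5, rel=1e-12)
        np.testing.assert_allclose(center, [1.5, 2.0, 1.0], atol=1e-12)

    def test_generator_circle_radius_recovered(self):
        p = SyntheticRootParams(
            commissure_heights={"NL": 23.0, "LR": 23.0, "RN": 23.0}
        )
        g, _ = make_root(p)
        _, radius, _ = commissure_circle(g.commissures)
        assert radius == pytest.approx(20.58, abs=1e-6)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            commissure_circle({"NL": [0, 0, 0], "LR": [1, 0, 0], "RN": [2, 0, 0]})


class TestDistancesHeightsAngles:
    def test_equilateral_icds(self):
        ang = {"NL": 90.0, "LR": 210.0, "RN": 330.0}
        com = {
            k: [20 * math.cos(math.radians(v)), 20 * math.sin(math.radians(v)), 0]
            for k, v in ang.items()
        }
        a, b, c = intercommissural_distances(com)
        for d in (a, b, c):
            assert d == pytest.approx(20 * math.sqrt(3), rel=1e-12)

    def test_height_above_plane(self):
        plane = Plane(unit_normal=np.array([0.0, 0.0, 1.0]), offset=0.0)
        com = {"NL": [0, 0, 25.0], "LR": [1, 0, 10.0], "RN": [0, 1, 5.0]}
        h = commissural_heights(com, plane)
        assert h == {"NL": 25.0, "LR": 10.0, "RN": 5.0}

    def test_negative_height_warns(self):
        plane = Plane(unit_normal=np.array([0.0, 0.0, 1.0]), offset=0.0)
        com = {"NL": [0, 0, -2.0], "LR": [1, 0, 10.0], "RN": [0, 1, 5.0]}
        with pytest.warns(MeasurementWarning):
            h = commissural_heights(com, plane)
        assert h["NL"] == pytest.approx(-2.0)

    @pytest.mark.parametrize(
        "icds,expected",
        [
            ((32.0, 36.5, 34.8), (111.5, 127.2, 121.3)),  # cohort means, 1 dp
            ((1.0, 1.0, 1.0), (120.0, 120.0, 120.0)),
        ],
    )
    def test_cusp_angles(self, icds, expected):
        angles = cusp_angles(*icds)
        for got, want in zip(angles, expected):
            assert round(got, 1) == want
        assert sum(angles) == 360.0

    def test_cusp_angles_reject_nonpositive(self):
        with pytest.raises(ValueError):
            cusp_angles(0.0, 1.0, 1.0)


class TestPredictedHeight:
    def test_rn_worked_example(self):
        # d=24.9, CCA=1330.7, VBR=28.0 -> 25.8 at one decimal
        f = predicted_commissural_height(24.9, 1330.7, 28.0)
        assert round(f, 1) == 25.8
        assert f == pytest.approx(25.755, abs=1e-3)

    def test_zero_offset(self):
        assert predicted_commissural_height(10.0, math.pi * 14**2, 28.0) == pytest.approx(10.0)

    def test_nl_value(self):
        assert predicted_commissural_height(22.6, 1330.7, 28.0) == pytest.approx(23.54, abs=0.005)

    def test_small_cca_clamps_offset_with_warning(self):
        with pytest.warns(MeasurementWarning):
            f = predicted_commissural_height(10.0, 100.0, 28.0)
        assert f == pytest.approx(10.0)

    def test_radial_offset_value(self):
        e = radial_offset_e(1330.7, 28.0)
        assert e == pytest.approx(math.sqrt(1330.7 / math.pi) - 14.0, rel=1e-12)


class TestScalars:
    @pytest.mark.parametrize(
        "gh,vbr,expected",
        [(18.6, 28.0, 4.6), (14.0, 28.0, 0.0), (20.7, 26.0, 7.7)],
    )
    def test_cch(self, gh, vbr, expected):
        assert cusp_coaptation_height(gh, vbr) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "values,expected",
        [
            ((32.0, 36.5, 34.8), 14.06),
            ((5.0, 5.0, 5.0), 0.0),
            ((10.0, 20.0, 15.0), 100.0),
        ],
    )
    def test_disproportionate_ratio(self, values, expected):
        assert disproportionate_ratio(values) == pytest.approx(expected, abs=0.005)

    def test_disproportionate_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            disproportionate_ratio((0.0, 1.0, 2.0))


class TestMeasureRoot:
    def test_noise_free_circle_recovers_closed_forms(self, circle_root):
        g, truth = circle_root
        m = measure_root(g)
        assert m.estimated_vbr_diameter == pytest.approx(28.0, abs=1e-3)
        assert m.cca == pytest.approx(truth.cca, rel=1e-9)
        assert m.predicted_ch["RN"] == pytest.approx(truth.predicted_ch["RN"], abs=1e-3)
        assert m.ellipticity_index == pytest.approx(1.0, abs=1e-4)
        assert not m.oval_vbr

    def test_elliptical_root_flagged_oval(self):
        g, truth = make_root(SyntheticRootParams(vbr_semi_axes=(16.0, 12.0)))
        m = measure_root(g)
        assert m.ellipticity_index == pytest.approx(4.0 / 3.0, abs=1e-4)
        assert m.oval_vbr and truth.oval_vbr

    def test_rigid_transform_leaves_measurements_unchanged(self, circle_root):
        g, _ = circle_root
        m0 = measure_root(g)
        tr = RigidTransform.from_euler([17.0, -33.0, 59.0], translation=[12.0, -7.0, 40.0])
        g2, _ = make_root(SyntheticRootParams(rigid_transform=tr))
        m1 = measure_root(g2)
        assert m1.vbr_area == pytest.approx(m0.vbr_area, rel=1e-9)
        assert m1.vbr_perimeter == pytest.approx(m0.vbr_perimeter, rel=1e-9)
        assert m1.cca == pytest.approx(m0.cca, rel=1e-9)
        for k in ("NL", "LR", "RN"):
            assert m1.ch[k] == pytest.approx(m0.ch[k], rel=1e-9)
            assert m1.predicted_ch[k] == pytest.approx(m0.predicted_ch[k], rel=1e-9)
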