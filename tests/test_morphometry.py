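"""Unit tests of the individual measurement stages against analytic oracles."""
import numpy as np
import pytest
import trimesh

from femaw import PhantomSpec, build_phantom
from femaw.geometry import GeometryError, Line3D, Plane3D, unit
from femaw.morphometry import (Contour, CutError, SphereFitError, WallFitError,
                               anterior_wall_line, build_isb_frame,
                               build_tabletop_frame, fit_sphere,
                               narrowest_neck_section, neck_axis,
                               select_head_points, shaft_axis, simulate_gt_cut)
from femaw.phantom import _neck_direction

from conftest import random_rigid_transform


def _sphere_points(rng, center, radius, n=500, cap_cos=-1.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v = v[v[:, 2] >= cap_cos] if cap_cos > -1.0 else v
    return np.asarray(center) + radius * v


# ---------------------------------------------------------------------------
# sphere fit

class TestFitSphere:
    def test_exact_points_recovered_to_machine_precision(self):
        pts = _sphere_points(np.random.default_rng(0), (10, 20, 30), 25.0)
        c, r, rms = fit_sphere(pts)
        assert np.allclose(c, (10, 20, 30), atol=1e-8)
        assert r == pytest.approx(25.0, abs=1e-8)
        assert rms < 1e-8

    def test_noisy_points_mean_center_error_below_005mm(self):
        """sd 0.2 mm isotropic noise, 500 points, averaged over 100 seeds."""
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = _sphere_points(rng, (10, 20, 30), 25.0) + rng.normal(scale=0.2, size=(500, 3))
            c, _, _ = fit_sphere(pts)
            errs.append(np.linalg.norm(c - (10, 20, 30)))
        assert np.mean(errs) < 0.05

    def test_hemisphere_coverage_center_within_01mm(self):
        """Partial (cap >= 90 deg) coverage, as for a femoral head in situ."""
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            pts = _sphere_points(rng, (10, 20, 30), 25.0, n=1000, cap_cos=0.0)
            pts += rng.normal(scale=0.05, size=pts.shape)
            c, _, _ = fit_sphere(pts)
            errs.append(np.linalg.norm(c - (10, 20, 30)))
        assert np.mean(errs) < 0.1

    def test_coplanar_points_raise(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(SphereFitError):
            fit_sphere(pts)

    def test_matches_bruteforce_nonlinear_oracle(self):
        """Independent BFGS minimisation of the geometric objective, 20 sets."""
        from scipy.optimize import minimize

        for seed in range(20):
            rng = np.random.default_rng(seed)
            center = rng.uniform(-50, 50, size=3)
            radius = rng.uniform(10, 40)
            pts = _sphere_points(rng, center, radius, n=200, cap_cos=-0.2)
            pts += rng.normal(scale=0.1, size=pts.shape)
            c, r, _ = fit_sphere(pts)

            def objective(p):
                return np.sum((np.linalg.norm(pts - p[:3], axis=1) - p[3]) ** 2)

            x0 = [*pts.mean(axis=0), np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()]
            ora = minimize(objective, x0, method="BFGS", tol=1e-14)
            assert np.allclose(c, ora.x[:3], atol=1e-6)
            assert r == pytest.approx(ora.x[3], abs=1e-6)


def test_select_head_points_all_lie_on_the_sphere(default_phantom, default_spec):
    mesh, lm = default_phantom
    pts = select_head_points(mesh, lm.hip_center_hint)
    c, r, rms = fit_sphere(pts)
    assert r == pytest.approx(default_spec.head_radius, abs=1e-6)
    assert rms < 1e-9


# ---------------------------------------------------------------------------
# neck section and axis

class TestNarrowestNeck:
    def _run(self, mesh, lm, head_center, direction):
        return narrowest_neck_section(mesh, head_center, direction,
                                      scan_start_mm=1.05 * 24.0)

    def test_recovers_constructed_waist(self, default_spec):
        mesh, lm = build_phantom(PhantomSpec(hint_jitter_mm=0.0))
        head = np.asarray(lm.hip_center_hint)
        d = -_neck_direction(default_spec)  # head -> base
        waist_true = head + (default_spec.head_radius + 6.0) * d
        sec = self._run(mesh, lm, head, d)
        assert sec.area == pytest.approx(np.pi * 14.0**2, rel=0.02)
        assert np.linalg.norm(sec.midpoint - waist_true) < 0.5
        assert sec.unique_minimum

    def test_converges_from_perturbed_initial_direction(self, default_spec):
        mesh, lm = build_phantom(PhantomSpec(hint_jitter_mm=0.0))
        head = np.asarray(lm.hip_center_hint)
        d = -_neck_direction(default_spec)
        base = self._run(mesh, lm, head, d)
        for angle in (-10.0, 10.0):
            axis = unit(np.cross(d, [0.0, 1.0, 0.0]))
            from femaw.geometry import rotation_matrix
            sec = self._run(mesh, lm, head, rotation_matrix(axis, angle) @ d)
            assert np.linalg.norm(sec.midpoint - base.midpoint) < 0.5

    def test_constant_radius_cylinder_flags_nonunique_minimum(self):
        cyl = trimesh.creation.cylinder(radius=14.0, height=120.0, sections=64)
        sec = narrowest_neck_section(cyl, [0, 0, -60.0], [0, 0, 1.0],
                                     scan_start_mm=25.0)
        assert not sec.unique_minimum
        assert np.allclose(sec.midpoint[:2], 0.0, atol=0.1)


class TestNeckAxis:
    def test_direction_head_to_neck(self):
        line = neck_axis([0, 0, 0], [10, 0, 0])
        assert np.allclose(line.direction, [1, 0, 0])

    def test_swapped_arguments_reverse_orientation(self):
        a = neck_axis([0, 0, 0], [10, 5, 2])
        b = neck_axis([10, 5, 2], [0, 0, 0])
        assert np.allclose(a.direction, -b.direction)
        assert a.distance_to(b.point) < 1e-12  # same carrier line

    def test_coincident_points_raise(self):
        with pytest.raises(GeometryError):
            neck_axis([0, 0, 0], [0.5, 0, 0])


# ---------------------------------------------------------------------------
# shaft axis

class TestShaftAxis:
    def test_parallel_to_phantom_shaft_within_01deg(self, default_phantom):
        mesh, lm = default_phantom
        line = shaft_axis(mesh, lm.lesser_trochanter_base_level,
                          distal_point=lm.epicondyle_midpoint)
        ang = np.degrees(np.arccos(abs(np.dot(line.direction, [0, 1, 0]))))
        assert ang < 0.1
        assert line.direction[1] < 0  # oriented proximal -> distal

    def test_translation_equivariance(self, default_phantom):
        mesh, lm = default_phantom
        a = shaft_axis(mesh, lm.lesser_trochanter_base_level,
                       distal_point=lm.epicondyle_midpoint)
        moved = mesh.copy()
        moved.apply_translation([5, 5, 5])
        b = shaft_axis(moved, lm.lesser_trochanter_base_level,
                       distal_point=lm.epicondyle_midpoint + 5.0)
        assert np.allclose(b.direction, a.direction, atol=1e-9)
        assert np.allclose(b.point, a.point + 5.0, atol=1e-6)

    def test_station_beyond_mesh_raises(self, default_phantom):
        mesh, lm = default_phantom
        from femaw.morphometry import SectionError
        with pytest.raises(SectionError):
            shaft_axis(mesh, -500.0, distal_point=lm.epicondyle_midpoint)


# ---------------------------------------------------------------------------
# GT cut and anterior wall

@pytest.fixture(scope="module")
def cut(default_phantom):
    mesh, lm = default_phantom
    shaft = shaft_axis(mesh, lm.lesser_trochanter_base_level,
                       distal_point=lm.epicondyle_midpoint)
    frame = build_tabletop_frame(lm, shaft=shaft)
    plane, contour = simulate_gt_cut(mesh, lm.lateral_ridge_GT, shaft, frame)
    return lm, shaft, plane, contour


class TestGtCut:
    def test_resected_cap_thickness_is_10mm(self, cut):
        _, _, _, contour = cut
        assert contour.cap_thickness_mm == pytest.approx(10.0, abs=0.1)

    def test_entry_point_lies_on_cut_plane(self, cut):
        lm, shaft, plane, _ = cut
        entry = lm.lateral_ridge_GT + 5.0 * shaft.direction
        assert abs(plane.signed_distance(entry)) < 1e-6

    def test_contour_is_simple_closed_polygon(self, cut):
        from shapely.geometry import Polygon
        _, _, _, contour = cut
        poly = Polygon(contour.to_2d())
        assert poly.is_valid and poly.is_simple and poly.area > 100.0

    def test_unreachable_thickness_raises_with_diagnostic(self, default_phantom):
        mesh, lm = default_phantom
        shaft = shaft_axis(mesh, lm.lesser_trochanter_base_level,
                           distal_point=lm.epicondyle_midpoint)
        frame = build_tabletop_frame(lm, shaft=shaft)
        with pytest.raises(CutError, match="thickness"):
            simulate_gt_cut(mesh, lm.lateral_ridge_GT, shaft, frame,
                            thickness_mm=80.0)


class TestAnteriorWallLine:
    def _frame(self):
        return build_tabletop_frame(
            _FakeLandmarks(), scanner_axes=np.eye(3))

    def test_rectangle_contour_line_is_anterior_edge(self):
        # rectangle in the z=0 plane: x anterior in the identity frame
        pts = np.array([[5, -10, 0], [5, 10, 0], [-5, 10, 0], [-5, -10, 0], [5, -10, 0]],
                       dtype=float)
        contour = Contour(plane=Plane3D([0, 0, 0], [0, 0, 1]), points=pts)
        res = anterior_wall_line(contour, self._frame())
        assert abs(np.dot(res.line.direction, [0, 1, 0])) == pytest.approx(1.0, abs=1e-9)
        assert res.line.point[0] == pytest.approx(5.0, abs=1e-9)
        assert res.is_flat

    def test_semicircular_wall_returns_apex_tangent_with_flatness_warning(self):
        t = np.linspace(-np.pi / 2, np.pi / 2, 181)
        arc = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        back = np.array([[0.0, 10.0, 0.0], [0.0, -10.0, 0.0]])
        pts = np.vstack([arc, back, arc[:1]])
        contour = Contour(plane=Plane3D([0, 0, 0], [0, 0, 1]), points=pts)
        res = anterior_wall_line(contour, self._frame())
        assert not res.is_flat and res.rms_mm > 0.2
        # analytic tangent of the circle at its anterior apex: x = 10, dir +-y
        assert abs(np.dot(res.line.direction, [0, 1, 0])) > 0.99
        assert res.line.point[0] == pytest.approx(10.0, abs=0.05)

    def test_no_anterior_arc_raises(self):
        # sliver polygon whose anterior-facing boundary is shorter than 5 mm
        pts = np.array([[1, -10, 0], [1, 10, 0], [-1, 10, 0], [-1, -10, 0], [1, -10, 0]],
                       dtype=float)
        contour = Contour(plane=Plane3D([0, 0, 0], [0, 0, 1]), points=pts)
        with pytest.raises(WallFitError):
            anterior_wall_line(contour, self._frame(), min_arc_mm=25.0)

    def test_phantom_wall_line_lies_in_the_constructed_face(self, default_phantom,
                                                            default_spec):
        from femaw.phantom import _anterior_wall_plane, _GT_ANTERIOR_REF
        mesh, lm = default_phantom
        shaft = shaft_axis(mesh, lm.lesser_trochanter_base_level,
                           distal_point=lm.epicondyle_midpoint)
        table = build_tabletop_frame(lm, shaft=shaft)
        pts = select_head_points(mesh, lm.hip_center_hint)
        head_center, _, _ = fit_sphere(pts)
        isb = build_isb_frame(lm, head_center)
        _, contour = simulate_gt_cut(mesh, lm.lateral_ridge_GT, shaft, table)
        res = anterior_wall_line(contour, isb)
        n_face = _anterior_wall_plane(default_spec, head_center, lm.epicondyle_midpoint,
                                      lm.medial_posterior_condyle,
                                      lm.lateral_posterior_condyle)
        off_plane = np.degrees(np.arcsin(abs(np.dot(res.line.direction, n_face))))
        assert off_plane < 0.1
        assert res.is_flat and res.rms_mm < 0.01


class _FakeLandmarks:
    """Minimal landmark stand-in for frame construction in contour tests."""

    def __init__(self):
        self.epicondyle_midpoint = np.array([0.0, -150.0, 0.0])
        self.medial_posterior_condyle = np.array([-26.0, -150.0, -20.0])
        self.lateral_posterior_condyle = np.array([-26.0, -150.0, 20.0])


# ---------------------------------------------------------------------------
# frames

class TestFrames:
    def test_tabletop_identity_scanner(self):
        f = build_tabletop_frame(_FakeLandmarks(), scanner_axes=np.eye(3))
        assert np.allclose(f.axes, np.eye(3))

    def test_tabletop_rotated_scanner(self):
        from femaw.geometry import rotation_matrix
        R = rotation_matrix([0, 0, 1], 30.0)
        f = build_tabletop_frame(_FakeLandmarks(), scanner_axes=R @ np.eye(3))
        assert np.allclose(f.axes, R @ np.eye(3))

    def test_isb_frame_matches_closed_form_for_canonical_phantom(self, default_phantom):
        """The ISB frame equals its closed-form construction: proximal from the
        epicondyle midpoint to the head centre, lateral = condylar direction
        orthogonalised against it (tilted from the scanner axes by the medial
        head offset -- about 14 deg for this proximal-femur geometry)."""
        mesh, lm = default_phantom
        head_center, _, _ = fit_sphere(select_head_points(mesh, lm.hip_center_hint))
        isb = build_isb_frame(lm, head_center)
        p_expect = unit(head_center - lm.epicondyle_midpoint)
        lat_raw = lm.lateral_posterior_condyle - lm.medial_posterior_condyle
        lat_expect = unit(lat_raw - np.dot(lat_raw, p_expect) * p_expect)
        assert np.allclose(isb.proximal, p_expect, atol=1e-9)
        assert np.allclose(isb.lateral, lat_expect, atol=1e-9)
        assert np.allclose(isb.anterior, np.cross(p_expect, lat_expect), atol=1e-9)
        assert isb.side == "right"
        # still broadly aligned with the scanner axes in canonical pose
        assert np.dot(isb.proximal, [0, 1, 0]) > 0.9
        assert np.dot(isb.lateral, [0, 0, 1]) > 0.9

    def test_isb_frame_rigid_equivariance(self, default_phantom):
        mesh, lm = default_phantom
        head_center, _, _ = fit_sphere(select_head_points(mesh, lm.hip_center_hint))
        isb = build_isb_frame(lm, head_center)
        T = random_rigid_transform(np.random.default_rng(3))
        lm2 = lm.transformed(T)
        isb2 = build_isb_frame(lm2, T[:3, :3] @ head_center + T[:3, 3])
        assert np.allclose(isb2.axes, isb.axes @ T[:3, :3].T, atol=1e-9)

    def test_collinear_landmarks_raise(self):
        lm = _FakeLandmarks()
        head = lm.epicondyle_midpoint + np.array([0.0, 100.0, 0.0])
        lm.medial_posterior_condyle = lm.epicondyle_midpoint + np.array([0, -5.0, 0])
        lm.lateral_posterior_condyle = lm.epicondyle_midpoint + np.array([0, 5.0, 0])
        with pytest.raises(GeometryError):
            build_isb_frame(lm, head)
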