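import numpy as np
import pytest
from scipy.optimize import brentq

from osteosim.frame import build_frame, true_lateral_project
from osteosim.osteotomy import (InfeasiblePlanError, PlacementConfig,
                                apply_osteotomy, close_wedge, place_points,
                                projected_inclination, solve_opening,
                                split_mesh, _plateau_line_2d)


# ---------------------------------------------------------------------- #
# independent closed-form oracle (pure vector algebra, no meshes)
# ---------------------------------------------------------------------- #
def rodrigues(u, phi):
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(phi) * K + (1 - np.cos(phi)) * (K @ K)


def closed_form_opening(plan, frame):
    """Oracle for the hinge axis, opening angle, gaps and slope change.

    Axis: the gap constraint beta1 = r*beta3 with beta(q) = (n x u).q is
    solved by u parallel to q1 - r*q3 (write u = a q1 + b q3; the
    triple-product identity kills the diagonal terms). phi follows from
    the coronal projection; the slope change from rotating the plateau
    landmarks analytically.
    """
    n = np.cross(plan.p3 - plan.p1, plan.p2 - plan.p1)
    n = n / np.linalg.norm(n)
    if n @ frame.proximal_dir < 0:
        n = -n
    q1, q3 = plan.p1 - plan.p2, plan.p3 - plan.p2
    u = q1 - plan.gap_ratio_target * q3
    u = u / np.linalg.norm(u)
    if np.cross(n, u) @ q1 < 0:
        u = -u
    b1 = float(np.cross(n, u) @ q1)
    b3 = float(np.cross(n, u) @ q3)

    y, s = frame.y_axis, frame.proximal_dir

    def coronal(phi):
        sp = rodrigues(u, phi).T @ s
        a = s - y * (s @ y)
        b = sp - y * (sp @ y)
        a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
        return np.degrees(np.arccos(np.clip(a @ b, -1, 1)))

    phi = brentq(lambda f: coronal(f) - plan.correction_angle,
                 1e-12, np.radians(45.0), xtol=1e-14)
    return u, np.degrees(phi), b1 * np.sin(phi), b3 * np.sin(phi)


def closed_form_pts_change(model, frame, plan, u, phi_deg):
    """Slope change from pure rigid-body algebra on the landmarks: the
    plateau line and viewing axis rotate with the proximal segment; the
    shaft axis (distal) is the exact prism axis."""
    R = rodrigues(u, np.radians(phi_deg))

    def pts_of(rot):
        ant = rot @ np.asarray(model.landmarks["medial_plateau_anterior_edge"])
        post = rot @ np.asarray(model.landmarks["medial_plateau_posterior_edge"])
        yv = rot @ frame.y_axis
        pv = rot @ frame.proximal_dir
        plat = ant - post
        plat2 = np.array([plat @ yv, plat @ pv])
        if plat2[0] < 0:
            plat2 = -plat2
        shaft = np.array([0.0, 0.0, 1.0])  # canonical prism axis
        sh2 = np.array([shaft @ yv, shaft @ pv])
        if sh2[1] < 0:
            sh2 = -sh2
        perp = np.array([sh2[1], -sh2[0]])
        if perp[0] < 0:
            perp = -perp
        a = np.degrees(np.arctan2(plat2[1], plat2[0])
                       - np.arctan2(perp[1], perp[0]))
        return (a + 180) % 360 - 180

    return pts_of(R) - pts_of(np.eye(3))


@pytest.fixture(scope="module")
def prism_setup(asym_prism):
    frame, _ = build_frame(asym_prism)
    return asym_prism, frame


class TestPlacePoints:
    def test_parallel_line_at_zero(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 0.0)
        plat = _plateau_line_2d(model, frame)
        assert projected_inclination(plan.p1, plan.p3, plat, frame) == \
            pytest.approx(0.0, abs=0.2)

    @pytest.mark.parametrize("angle", [-30, -10, 0, 10, 30])
    def test_achieved_inclination_exact(self, prism_setup, angle):
        model, frame = prism_setup
        plan = place_points(model, frame, float(angle))
        plat = _plateau_line_2d(model, frame)
        assert projected_inclination(plan.p1, plan.p3, plat, frame) == \
            pytest.approx(angle, abs=1e-6)

    def test_sign_convention_p3_position(self, prism_setup):
        # anteriorly inclined (+) moves P3 proximally, posteriorly (-)
        # distally, relative to the parallel position
        model, frame = prism_setup
        prox = frame.proximal_dir
        z0 = place_points(model, frame, 0.0).p3 @ prox
        z_plus = place_points(model, frame, 10.0).p3 @ prox
        z_minus = place_points(model, frame, -10.0).p3 @ prox
        assert z_plus > z0 > z_minus

    def test_p1_depth(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 0.0)
        depth = (np.asarray(model.landmarks["medial_plateau_end"]) - plan.p1) \
            @ frame.proximal_dir
        assert depth == pytest.approx(35.0, abs=1e-6)

    def test_p2_position(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 0.0)
        depth = (frame.plane_point - plan.p2) @ frame.proximal_dir
        assert depth == pytest.approx(15.0, abs=1e-6)

    def test_excessive_inclination_rejected(self, prism_setup):
        model, frame = prism_setup
        with pytest.raises(InfeasiblePlanError):
            place_points(model, frame, 50.0)


class TestSplitMesh:
    def test_volume_conservation(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 10.0)
        split = split_mesh(model, plan)
        total = split.above.volume() + split.below.volume()
        assert total == pytest.approx(model.mesh.volume(), rel=1e-3)

    def test_pieces_watertight(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, -20.0)
        split = split_mesh(model, plan)
        assert split.above.is_watertight()
        assert split.below.is_watertight()

    def test_cap_vertices_on_cut_plane(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 0.0)
        split = split_mesh(model, plan)
        point, n = plan.plane(frame.proximal_dir)
        for piece, n_body in ((split.above, split.above_n_body),
                              (split.below, split.below_n_body)):
            cap_idx = np.unique(piece.faces[n_body:])
            d = np.abs((piece.vertices[cap_idx] - point) @ n)
            assert d.max() < 1e-6

    def test_proximal_piece_contains_plateau(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 0.0)
        split = split_mesh(model, plan)
        top = np.asarray(model.landmarks["medial_extreme"])
        d = np.linalg.norm(split.above.vertices - top, axis=1).min()
        assert d < 1e-9


class TestSolveOpening:
    def test_axis_in_cut_plane(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 15.0)
        u, phi = solve_opening(model, frame, plan)
        _, n = plan.plane(frame.proximal_dir)
        assert abs(u @ n) < 1e-6
        assert phi > 0

    def test_zero_correction_identity(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 5.0)
        plan.correction_angle = 0.0
        u, phi = solve_opening(model, frame, plan)
        assert phi == 0.0

    def test_matches_closed_form_axis(self, prism_setup):
        model, frame = prism_setup
        for angle in (-20.0, 0.0, 20.0):
            plan = place_points(model, frame, angle)
            u, phi = solve_opening(model, frame, plan)
            u_o, phi_o, g1_o, g3_o = closed_form_opening(plan, frame)
            assert abs(abs(u @ u_o) - 1.0) < 1e-9
            assert phi == pytest.approx(phi_o, abs=1e-6)

    def test_symmetric_ratio_one_gives_ap_axis(self, rect_prism):
        # mirror-symmetric P1/P3 (same medial offset, +/- y) with equal
        # gaps (target 1.0) force an anteroposterior hinge axis and equal
        # closed-form gaps 2*d*sin(phi)*... evaluated at both corners
        from osteosim.osteotomy import OsteotomyPlan
        frame, _ = build_frame(rect_prism)
        plan = OsteotomyPlan(
            p1=np.array([-30.0, 20.0, -30.0]),
            p3=np.array([-30.0, -20.0, -30.0]),
            p2=np.array([20.0, 0.0, -15.0]),
            inclination_angle=0.0, correction_angle=10.0,
            gap_ratio_target=1.0)
        u, phi = solve_opening(rect_prism, frame, plan)
        # hinge is anteroposterior: no mediolateral component
        assert abs(u @ np.array([1.0, 0.0, 0.0])) < 1e-9
        u_o, phi_o, g1, g3 = closed_form_opening(plan, frame)
        assert g1 == pytest.approx(g3, rel=1e-9)
        # gap = (in-plane distance from axis) * sin(phi), closed form
        _, n = plan.plane(frame.proximal_dir)
        q1 = plan.p1 - plan.p2
        d_perp = np.cross(n, u_o) @ q1
        assert g1 == pytest.approx(d_perp * np.sin(np.radians(phi_o)), rel=1e-9)


class TestApplyOsteotomy:
    def test_constraints_hit(self, prism_setup):
        model, frame = prism_setup
        for angle in (-25.0, 0.0, 25.0):
            plan = place_points(model, frame, angle)
            o = apply_osteotomy(model, frame, plan)
            assert o.achieved_gap_ratio == pytest.approx(0.67, abs=0.01)
            assert o.achieved_coronal_correction == \
                pytest.approx(plan.correction_angle, abs=0.1)

    def test_rotation_orthonormal(self, prism_setup):
        model, frame = prism_setup
        o = apply_osteotomy(model, frame, place_points(model, frame, 10.0))
        R = o.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_hinge_point_is_p2(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 10.0)
        o = apply_osteotomy(model, frame, plan)
        assert np.allclose(o.hinge_point, plan.p2)
        # p2 is a fixed point of the applied transform
        assert np.allclose(o.rotation @ plan.p2 + o.translation, plan.p2,
                           atol=1e-9)

    def test_oracle_equivalence_all_13_angles(self, prism_setup):
        model, frame = prism_setup
        for angle in range(-30, 31, 5):
            plan = place_points(model, frame, float(angle))
            o = apply_osteotomy(model, frame, plan)
            u_o, phi_o, g1_o, g3_o = closed_form_opening(plan, frame)
            d_o = closed_form_pts_change(model, frame, plan, u_o, phi_o)
            assert o.anterior_gap == pytest.approx(g1_o, abs=1e-6)
            assert o.posterior_gap == pytest.approx(g3_o, abs=1e-6)
            assert o.pts_change == pytest.approx(d_o, abs=0.1), f"angle {angle}"

    def test_monotonic_in_inclination(self, default_model, default_frame):
        changes = []
        for angle in range(-30, 31, 5):
            plan = place_points(default_model, default_frame, float(angle))
            o = apply_osteotomy(default_model, default_frame, plan)
            changes.append(o.pts_change)
        assert np.all(np.diff(changes) > 0)

    def test_doubling_phi_keeps_gap_ratio(self, prism_setup):
        model, frame = prism_setup
        plan = place_points(model, frame, 10.0)
        u, phi = solve_opening(model, frame, plan)
        _, n = plan.plane(frame.proximal_dir)
        b1 = np.cross(n, u) @ (plan.p1 - plan.p2)
        b3 = np.cross(n, u) @ (plan.p3 - plan.p2)
        r1 = (b1 * np.sin(np.radians(phi))) / (b3 * np.sin(np.radians(phi)))
        r2 = (b1 * np.sin(np.radians(2 * phi))) / (b3 * np.sin(np.radians(2 * phi)))
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestCloseWedge:
    def test_round_trip_vertices(self, prism_setup):
        from scipy.spatial import cKDTree
        model, frame = prism_setup
        plan = place_points(model, frame, 10.0)
        o = apply_osteotomy(model, frame, plan)
        restored = close_wedge(o)
        assert restored.mesh.is_watertight()
        d, _ = cKDTree(restored.mesh.vertices).query(model.mesh.vertices)
        assert d.max() <= 1e-6

    def test_round_trip_volume(self, prism_setup):
        model, frame = prism_setup
        o = apply_osteotomy(model, frame, place_points(model, frame, -15.0))
        restored = close_wedge(o)
        assert restored.mesh.volume() == \
            pytest.approx(model.mesh.volume(), rel=1e-9)

    def test_round_trip_pts(self, default_model, default_frame):
        from osteosim.measure import measure_pts
        pre = measure_pts(default_model, default_frame).pts
        plan = place_points(default_model, default_frame, 20.0)
        o = apply_osteotomy(default_model, default_frame, plan)
        restored = close_wedge(o)
        f2, _ = build_frame(restored)
        assert measure_pts(restored, f2).pts == pytest.approx(pre, abs=1e-6)

    def test_restoration_rotation_equals_opening(self, prism_setup):
        # the restoring rotation has exactly the opening magnitude
        model, frame = prism_setup
        o = apply_osteotomy(model, frame, place_points(model, frame, 10.0))
        tr = np.trace(o.rotation)
        angle = np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1)))
        assert angle == pytest.approx(o.opening_angle, abs=1e-9)
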