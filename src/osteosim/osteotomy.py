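"""Virtual medial open-wedge osteotomy.

Pipeline per model: place the three cut-defining points (P1 anteromedial
start, P2 lateral hinge, P3 posteromedial, chosen so the P1-P3 line makes
a prescribed signed inclination angle with the medial plateau line in
true-lateral view), split the mesh along the P1/P2/P3 plane, then open
the wedge by rotating the proximal segment about an in-plane hinge axis
through P2. The axis direction is solved so the anterior/posterior gap
ratio hits its target; the rotation magnitude is solved so the
coronal-projection correction equals the prescribed correction angle.

Rigid-body identity used throughout: for a point q on the cut plane and
a unit axis u in the plane through P2, the opening gap measured
perpendicular to the distal cut plane is  gap(q) = beta(q) * sin(phi)
with  beta(q) = (n x u) . (q - P2),  so the gap ratio depends on the
axis direction only, decoupling the two constraints into nested 1D
root-finds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .frame import CoordinateFrame, true_lateral_project
from .measure import (DEFAULT_SHAFT_DEPTHS, measure_coronal_correction,
                      measure_pts, measure_pts_parts)
from .mesh import (MeshCutError, PlaneSplit, TriMesh, cross_section,
                   rotation_about_axis, split_by_plane)
from .synthetic import TibiaModel

__all__ = [
    "PlacementConfig",
    "OsteotomyPlan",
    "OsteotomyOutcome",
    "InfeasiblePlanError",
    "InfeasibleOpeningError",
    "place_points",
    "split_mesh",
    "solve_opening",
    "apply_osteotomy",
    "close_wedge",
]


class InfeasiblePlanError(RuntimeError):
    pass


class InfeasibleOpeningError(RuntimeError):
    pass


@dataclass
class PlacementConfig:
    p1_depth_below_plateau_end: float = 35.0  # mm, along proximal axis
    p1_azimuth_deg: float = 75.0              # anterior of medial direction
    p2_depth: float = 15.0                    # mm below articular surface
    p2_medial_offset: float = 10.0            # mm medial to lateral cortex
    p3_azimuth_deg: float = 20.0              # posterior of medial direction
    inclination_tol: float = 0.2              # deg, plan verification
    gap_ratio_tol: float = 0.01
    correction_tol: float = 0.1               # deg
    shaft_depths: tuple[float, float] = DEFAULT_SHAFT_DEPTHS


@dataclass
class OsteotomyPlan:
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    inclination_angle: float   # degrees, signed (+ = anteriorly inclined)
    correction_angle: float    # degrees (coronal, Miniaci-style input)
    gap_ratio_target: float = 0.67

    def plane(self, proximal_hint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cut plane (point, unit normal oriented proximally)."""
        n = np.cross(self.p3 - self.p1, self.p2 - self.p1)
        norm = np.linalg.norm(n)
        if norm < 1e-9:
            raise InfeasiblePlanError("P1/P2/P3 are collinear")
        n = n / norm
        if n @ proximal_hint < 0:
            n = -n
        return self.p1, n

    def validate(self) -> None:
        if not (0.0 < self.gap_ratio_target < 2.0):
            raise InfeasiblePlanError(
                f"gap ratio target {self.gap_ratio_target} outside (0, 2)")


@dataclass
class OsteotomyOutcome:
    proximal_mesh: TriMesh          # in post-opening position
    distal_mesh: TriMesh
    hinge_point: np.ndarray         # = plan.p2
    hinge_dir: np.ndarray           # unit, in the cut plane
    opening_angle: float            # phi, degrees
    anterior_gap: float             # mm
    posterior_gap: float            # mm
    achieved_gap_ratio: float
    achieved_coronal_correction: float  # degrees
    pts_pre: float
    pts_post: float
    pts_change: float
    plan: OsteotomyPlan
    rotation: np.ndarray            # 3x3 applied to the proximal segment
    translation: np.ndarray         # so that x -> R x + t rotates about p2
    split: PlaneSplit = field(repr=False, default=None)
    source_model: TibiaModel = field(repr=False, default=None)
    frame: CoordinateFrame = field(repr=False, default=None)
    post_frame: CoordinateFrame = field(repr=False, default=None)
    post_landmarks: dict = field(repr=False, default=None)


# ---------------------------------------------------------------------- #
# point placement
# ---------------------------------------------------------------------- #
def _largest_section(mesh: TriMesh, point: np.ndarray, normal: np.ndarray
                     ) -> np.ndarray:
    loops = cross_section(mesh, point, normal)
    if not loops:
        raise InfeasiblePlanError("no cross-section at requested level")
    return max(loops, key=len)


def _cortex_point(mesh: TriMesh, frame: CoordinateFrame, level_point: np.ndarray,
                  direction_2d: np.ndarray, ray_origin: np.ndarray | None = None
                  ) -> np.ndarray:
    """Intersection of an in-plane ray with the cortical outline of the
    cross-section at ``level_point`` (plane normal to the proximal axis).

    ``direction_2d`` is (medial, anterior) components; the ray starts at
    the section centroid unless ``ray_origin`` is given.
    """
    loop = _largest_section(mesh, level_point, frame.proximal_dir)
    medial = -frame.x_axis
    d3 = direction_2d[0] * medial + direction_2d[1] * frame.y_axis
    d3 = d3 - frame.proximal_dir * (d3 @ frame.proximal_dir)
    d3 /= np.linalg.norm(d3)
    origin = loop.mean(axis=0) if ray_origin is None else np.asarray(ray_origin)
    # in-plane 2D coordinates
    e1 = medial - frame.proximal_dir * (medial @ frame.proximal_dir)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(frame.proximal_dir, e1)
    P = np.column_stack([(loop - origin) @ e1, (loop - origin) @ e2])
    d2 = np.array([d3 @ e1, d3 @ e2])
    best_t = None
    n = len(P)
    for i in range(n):
        a, b = P[i], P[(i + 1) % n]
        seg = b - a
        denom = d2[0] * (-seg[1]) - d2[1] * (-seg[0])
        if abs(denom) < 1e-14:
            continue
        rhs = a
        t = (rhs[0] * (-seg[1]) - rhs[1] * (-seg[0])) / denom
        s = (d2[0] * rhs[1] - d2[1] * rhs[0]) / denom
        if t > 0 and -1e-9 <= s <= 1 + 1e-9:
            if best_t is None or t > best_t:
                best_t = t
    if best_t is None:
        raise InfeasiblePlanError("cortical ray cast found no intersection")
    return origin + best_t * d3


def _plateau_line_2d(model: TibiaModel, frame: CoordinateFrame) -> np.ndarray:
    ant = true_lateral_project(
        np.asarray(model.landmarks["medial_plateau_anterior_edge"], dtype=float), frame)
    post = true_lateral_project(
        np.asarray(model.landmarks["medial_plateau_posterior_edge"], dtype=float), frame)
    d = ant - post
    if d[0] < 0:
        d = -d
    return d / np.linalg.norm(d)


def projected_inclination(p1: np.ndarray, p3: np.ndarray,
                          plateau_dir_2d: np.ndarray,
                          frame: CoordinateFrame) -> float:
    """Signed angle (deg) between the P1-P3 line and the medial plateau
    line in true-lateral view; positive when the anterior end of the cut
    is inclined distally."""
    u1 = true_lateral_project(p1, frame)
    u3 = true_lateral_project(p3, frame)
    d = u1 - u3  # anterior-going
    if d[0] < 0:
        d = -d
    ang = np.degrees(np.arctan2(plateau_dir_2d[1], plateau_dir_2d[0])
                     - np.arctan2(d[1], d[0]))
    return (ang + 180.0) % 360.0 - 180.0


def place_points(model: TibiaModel, frame: CoordinateFrame,
                 inclination: float, correction_angle: float = 10.3,
                 gap_ratio_target: float = 0.67,
                 config: PlacementConfig | None = None) -> OsteotomyPlan:
    """Place P1/P2/P3 for a prescribed signed sagittal inclination."""
    if abs(inclination) > 45.0:
        raise InfeasiblePlanError(f"|inclination| {inclination} > 45 deg")
    cfg = config or PlacementConfig()
    lm = model.landmarks
    prox = frame.proximal_dir

    # P1: anteromedial cortex, 35 mm below the medial end of the plateau
    a1 = np.radians(cfg.p1_azimuth_deg)
    lvl1 = np.asarray(lm["medial_plateau_end"], dtype=float) - \
        cfg.p1_depth_below_plateau_end * prox
    p1 = _cortex_point(model.mesh, frame, lvl1,
                       np.array([np.cos(a1), np.sin(a1)]))

    # P2: 10 mm medial to the lateral cortex on the x-axis, 15 mm below
    # the articular surface, at the AP midpoint of the articular surface
    lvl2 = frame.plane_point - cfg.p2_depth * prox
    origin_in_plane = frame.origin - prox * ((frame.origin - lvl2) @ prox)
    lat_pt = _cortex_point(model.mesh, frame, lvl2, np.array([-1.0, 0.0]),
                           ray_origin=origin_in_plane)
    p2 = lat_pt + cfg.p2_medial_offset * (-frame.x_axis)
    band = np.abs((model.mesh.vertices - frame.plane_point) @ prox) <= 8.0
    ap = (model.mesh.vertices[band] - frame.origin) @ frame.y_axis
    y_mid = 0.5 * (ap.min() + ap.max())
    p2 = p2 + (y_mid - (p2 - frame.origin) @ frame.y_axis) * frame.y_axis

    # P3: posteromedial cortex at the depth where the projected P1-P3
    # line makes the requested angle with the medial plateau line
    plat = _plateau_line_2d(model, frame)
    a3 = np.radians(cfg.p3_azimuth_deg)
    dir3 = np.array([np.cos(a3), -np.sin(a3)])

    def p3_at(depth: float) -> np.ndarray:
        lvl = frame.plane_point - depth * prox
        return _cortex_point(model.mesh, frame, lvl, dir3)

    def resid(depth: float) -> float:
        return projected_inclination(p1, p3_at(depth), plat, frame) - inclination

    d_lo, d_hi = 4.0, 120.0
    r_lo, r_hi = resid(d_lo), resid(d_hi)
    if r_lo * r_hi > 0:
        raise InfeasiblePlanError(
            f"inclination {inclination} deg infeasible: residuals "
            f"{r_lo:.2f}/{r_hi:.2f} at depth bracket [{d_lo}, {d_hi}] mm")
    depth = brentq(resid, d_lo, d_hi, xtol=1e-10)
    p3 = p3_at(depth)

    plan = OsteotomyPlan(p1=p1, p2=p2, p3=p3,
                         inclination_angle=float(inclination),
                         correction_angle=float(correction_angle),
                         gap_ratio_target=float(gap_ratio_target))
    plan.validate()
    achieved = projected_inclination(p1, p3, plat, frame)
    if abs(achieved - inclination) > cfg.inclination_tol:
        raise InfeasiblePlanError(
            f"achieved inclination {achieved:.3f} != target {inclination}")
    return plan


# ---------------------------------------------------------------------- #
# mesh split
# ---------------------------------------------------------------------- #
def split_mesh(model: TibiaModel, plan: OsteotomyPlan) -> PlaneSplit:
    """Cut the model along the P1/P2/P3 plane.

    Returns a PlaneSplit whose ``above`` piece is proximal (plateau side)
    and ``below`` distal, both watertight and capped.
    """
    plateau = np.asarray(model.landmarks["medial_extreme"], dtype=float)
    centroid = model.mesh.vertices.mean(axis=0)
    hint = plateau - centroid
    point, n = plan.plane(hint)
    split = split_by_plane(model.mesh, point, n)
    vol = model.mesh.volume()
    if abs(split.above.volume() + split.below.volume() - vol) > 1e-3 * abs(vol):
        raise MeshCutError("volume not conserved by plane split")
    return split


# ---------------------------------------------------------------------- #
# wedge opening
# ---------------------------------------------------------------------- #
def solve_opening(model: TibiaModel, frame: CoordinateFrame,
                  plan: OsteotomyPlan) -> tuple[np.ndarray, float]:
    """Hinge-axis direction and opening angle satisfying the gap-ratio
    and coronal-correction constraints.

    Returns (unit axis direction in the cut plane, phi in degrees).
    """
    plateau = np.asarray(model.landmarks["medial_extreme"], dtype=float)
    point, n = plan.plane(plateau - model.mesh.vertices.mean(axis=0))
    e1 = frame.y_axis - n * (frame.y_axis @ n)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    q1 = plan.p1 - plan.p2
    q3 = plan.p3 - plan.p2

    def beta(psi: float, q: np.ndarray) -> float:
        u = np.cos(psi) * e1 + np.sin(psi) * e2
        return float(np.cross(n, u) @ q)

    def h(psi: float) -> float:
        return beta(psi, q1) - plan.gap_ratio_target * beta(psi, q3)

    # h is sinusoidal in psi (beta is linear in cos/sin psi): exactly one
    # root per half-turn. Prefer the +/-45 deg bracket around the
    # anteroposterior direction; fall back to a full-circle scan.
    grid = np.linspace(np.radians(-45.0), np.radians(45.0), 19)
    vals = np.array([h(g) for g in grid])
    if vals[0] * vals[-1] > 0:
        grid = np.linspace(-np.pi, np.pi, 73)
        vals = np.array([h(g) for g in grid])
    sign_change = np.nonzero(vals[:-1] * vals[1:] <= 0)[0]
    if len(sign_change) == 0:
        raise InfeasibleOpeningError(
            "no axis direction satisfies the gap-ratio constraint")
    i = sign_change[0]
    sub = np.array([h(g) for g in np.linspace(grid[i], grid[i + 1], 8)])
    d = np.diff(sub)
    if not (np.all(d <= 1e-12) or np.all(d >= -1e-12)):
        raise InfeasibleOpeningError("gap-ratio residual not monotone in bracket")
    psi = brentq(h, grid[i], grid[i + 1], xtol=1e-12)
    u = np.cos(psi) * e1 + np.sin(psi) * e2
    if beta(psi, q1) < 0:
        u = -u
    b1 = float(np.cross(n, u) @ q1)
    b3 = float(np.cross(n, u) @ q3)
    if b1 <= 0 or b3 <= 0:
        raise InfeasibleOpeningError("solved axis does not open both gaps")

    if plan.correction_angle == 0:
        return u, 0.0

    def g(phi_rad: float) -> float:
        R = rotation_about_axis(u, phi_rad)
        return measure_coronal_correction(R, frame) - plan.correction_angle

    phi_hi = np.radians(45.0)
    if g(phi_hi) < 0:
        raise InfeasibleOpeningError(
            f"correction {plan.correction_angle} deg unreachable within 45 deg "
            "of opening")
    phi = brentq(g, 1e-12, phi_hi, xtol=1e-12)
    return u, float(np.degrees(phi))


def apply_osteotomy(model: TibiaModel, frame: CoordinateFrame,
                    plan: OsteotomyPlan,
                    config: PlacementConfig | None = None) -> OsteotomyOutcome:
    """Cut, open and measure one virtual osteotomy."""
    cfg = config or PlacementConfig()
    split = split_mesh(model, plan)
    u, phi_deg = solve_opening(model, frame, plan)
    phi = np.radians(phi_deg)

    R = rotation_about_axis(u, phi)
    t = plan.p2 - R @ plan.p2
    proximal_post = split.above.transformed(R, t)
    post_landmarks = {k: R @ np.asarray(v, dtype=float) + t
                      for k, v in model.landmarks.items()}
    post_frame = frame.transformed(R, t)

    point, n = plan.plane(np.asarray(model.landmarks["medial_extreme"], dtype=float)
                          - model.mesh.vertices.mean(axis=0))
    b1 = float(np.cross(n, u) @ (plan.p1 - plan.p2))
    b3 = float(np.cross(n, u) @ (plan.p3 - plan.p2))
    ant_gap = b1 * np.sin(phi)
    post_gap = b3 * np.sin(phi)
    ratio = ant_gap / post_gap if post_gap > 0 else float("nan")
    coronal = measure_coronal_correction(R, frame)

    pts_pre = measure_pts(model, frame, cfg.shaft_depths).pts
    pts_post = measure_pts_parts(post_landmarks, split.below, post_frame,
                                 cfg.shaft_depths).pts

    return OsteotomyOutcome(
        proximal_mesh=proximal_post,
        distal_mesh=split.below,
        hinge_point=plan.p2.copy(),
        hinge_dir=u,
        opening_angle=phi_deg,
        anterior_gap=float(ant_gap),
        posterior_gap=float(post_gap),
        achieved_gap_ratio=float(ratio),
        achieved_coronal_correction=float(coronal),
        pts_pre=float(pts_pre),
        pts_post=float(pts_post),
        pts_change=float(pts_post - pts_pre),
        plan=plan,
        rotation=R,
        translation=t,
        split=split,
        source_model=model,
        frame=frame,
        post_frame=post_frame,
        post_landmarks=post_landmarks,
    )


def close_wedge(outcome: OsteotomyOutcome) -> TibiaModel:
    """Invert the opening rotation and weld the two segments back into a
    single watertight model (the restoration round trip)."""
    R = outcome.rotation
    t = outcome.translation
    Rinv = R.T
    tinv = -Rinv @ t
    proximal_back = outcome.proximal_mesh.transformed(Rinv, tinv)

    split = outcome.split
    v_above = proximal_back.vertices
    f_above = proximal_back.faces[:split.above_n_body]
    v_below = outcome.distal_mesh.vertices
    f_below = outcome.distal_mesh.faces[:split.below_n_body]

    verts = np.concatenate([v_above, v_below], axis=0)
    faces = np.concatenate([f_above, f_below + len(v_above)], axis=0)
    key = np.round(verts / 1e-7).astype(np.int64)
    uniq, index, inverse = np.unique(key, axis=0, return_index=True,
                                     return_inverse=True)
    welded = TriMesh(verts[index], inverse[faces])
    if not welded.is_watertight():
        raise MeshCutError("restored mesh is not watertight after welding")

    src = outcome.source_model
    landmarks = {k: Rinv @ np.asarray(v, dtype=float) + tinv
                 for k, v in outcome.post_landmarks.items()}
    return TibiaModel(welded, landmarks, side=src.side, provenance="restored")
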