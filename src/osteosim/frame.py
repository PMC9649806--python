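"""Tibial coordinate-frame construction.

The joint plane is spanned by three plateau landmarks; the mediolateral
x-axis joins the centres of circles fitted to the medial and lateral
plateau margins; y is the in-plane perpendicular oriented anteriorly;
z = x cross y. ``proximal_dir`` (the joint-plane normal oriented away
from the shaft) is carried alongside so that measurements stay
side-independent (z itself points distally on left-side models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull

from .mesh import TriMesh
from .synthetic import TibiaModel

__all__ = [
    "CoordinateFrame",
    "CondyleCircles",
    "DegenerateGeometryError",
    "joint_plane_from_landmarks",
    "fit_circle_2d",
    "plateau_margin",
    "build_frame",
    "true_lateral_project",
]


class DegenerateGeometryError(RuntimeError):
    pass


@dataclass
class CoordinateFrame:
    origin: np.ndarray        # midpoint of the condylar circle centres
    x_axis: np.ndarray        # medial -> lateral, unit, in joint plane
    y_axis: np.ndarray        # anterior, unit, in joint plane
    z_axis: np.ndarray        # x cross y (proximal on right, distal on left)
    proximal_dir: np.ndarray  # joint-plane normal, away from shaft
    plane_point: np.ndarray
    plane_normal: np.ndarray

    def validate(self) -> None:
        for v in (self.x_axis, self.y_axis, self.z_axis):
            assert abs(np.linalg.norm(v) - 1.0) < 1e-12
        assert abs(self.x_axis @ self.y_axis) < 1e-9
        assert np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) < 1e-9
        assert abs(self.x_axis @ self.plane_normal) < 1e-9
        assert abs(self.y_axis @ self.plane_normal) < 1e-9

    def transformed(self, rotation=None, translation=None) -> "CoordinateFrame":
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return CoordinateFrame(
            origin=R @ self.origin + t,
            x_axis=R @ self.x_axis,
            y_axis=R @ self.y_axis,
            z_axis=R @ self.z_axis,
            proximal_dir=R @ self.proximal_dir,
            plane_point=R @ self.plane_point + t,
            plane_normal=R @ self.plane_normal,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {k: list(map(float, getattr(self, k)))
                   for k in ("origin", "x_axis", "y_axis", "z_axis",
                             "proximal_dir", "plane_point", "plane_normal")}
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "CoordinateFrame":
        payload = json.loads(Path(path).read_text())
        return CoordinateFrame(**{k: np.asarray(v, dtype=float)
                                  for k, v in payload.items()})


@dataclass
class CondyleCircles:
    medial_center: np.ndarray
    lateral_center: np.ndarray
    medial_radius: float
    lateral_radius: float
    fit_residual: float  # RMS radial misfit, mm


def joint_plane_from_landmarks(model: TibiaModel) -> tuple[np.ndarray, np.ndarray]:
    """Plane through the three plateau landmarks, normal oriented
    proximally (away from the shaft/centroid)."""
    lm = model.landmarks
    p1 = np.asarray(lm["medial_extreme"], dtype=float)
    p2 = np.asarray(lm["medial_posterior_extreme"], dtype=float)
    p3 = np.asarray(lm["lateral_extreme"], dtype=float)
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1))
    if norm < 1e-9 * scale ** 2:
        raise DegenerateGeometryError("joint-plane landmarks are collinear")
    n = n / norm
    centroid = model.mesh.vertices.mean(axis=0)
    if (centroid - p1) @ n > 0:  # shaft mass lies distally
        n = -n
    return p1, n


def fit_circle_2d(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through 2D points.

    Algebraic (Kasa) initialisation refined by geometric least squares.
    Returns (center, radius, RMS radial residual).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 2D points")
    # collinearity check via second singular value
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are collinear")

    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r0 = float(np.sqrt(sol[2] + cx ** 2 + cy ** 2))

    def resid(q):
        return np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1]) - q[2]

    out = least_squares(resid, x0=[cx, cy, r0], method="lm")
    center = out.x[:2]
    radius = float(abs(out.x[2]))
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return center, radius, rms


def plateau_margin(model: TibiaModel, plane_point: np.ndarray,
                   plane_normal: np.ndarray, band: float = 8.0,
                   n_samples: int = 72) -> np.ndarray:
    """Peripheral margin of the articular surface: the convex outline of
    mesh vertices lying within ``band`` mm of the joint plane, projected
    onto the plane and resampled evenly by arc length.

    Returns (n_samples, 2) in-plane coordinates in the basis of
    :func:`_plane_basis` seeded with the model's mediolateral landmark
    direction, so the construction is exactly equivariant under rigid
    motions of the model.
    """
    e1, e2 = _plane_basis(plane_normal, _ml_ref(model))
    d = (model.mesh.vertices - plane_point) @ plane_normal
    # the articular surface lies on/above the joint plane; a tight lower
    # bound keeps sub-margin cortex out of the outline
    near = model.mesh.vertices[(d >= -0.5) & (d <= band)]
    if len(near) < 8:
        raise DegenerateGeometryError("too few vertices near the joint plane")
    uv = np.column_stack([(near - plane_point) @ e1,
                          (near - plane_point) @ e2])
    hull = ConvexHull(uv)
    loop = uv[hull.vertices]
    closed = np.vstack([loop, loop[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    # canonical start: where the +e1 ray from the hull centroid crosses
    # the outline. Model-intrinsic, hence rotation-equivariant, and it
    # keeps the sampling mirror-symmetric for symmetric shapes.
    centroid = loop.mean(axis=0)
    s0 = 0.0
    for j in range(len(loop)):
        a, b = closed[j] - centroid, closed[j + 1] - centroid
        # crossing of segment a->b with the ray {y = 0, x > 0}
        if (a[1] > 0) != (b[1] > 0):
            t = a[1] / (a[1] - b[1])
            x = a[0] + t * (b[0] - a[0])
            if x > 0:
                s0 = cum[j] + t * seg[j]
                break
    samples = (s0 + np.linspace(0.0, total, n_samples, endpoint=False)) % total
    out = np.empty((n_samples, 2))
    for i, s in enumerate(samples):
        j = int(np.searchsorted(cum, s, side="right") - 1)
        j = min(j, len(seg) - 1)
        t = (s - cum[j]) / max(seg[j], 1e-12)
        out[i] = closed[j] + t * (closed[j + 1] - closed[j])
    return out


def _ml_ref(model: TibiaModel) -> np.ndarray:
    med = np.asarray(model.landmarks["medial_extreme"], dtype=float)
    lat = np.asarray(model.landmarks["lateral_extreme"], dtype=float)
    return lat - med


def _plane_basis(normal: np.ndarray, ref: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis with e1 along the projection of the
    (model-intrinsic) reference direction."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    e1 = ref - n * (ref @ n)
    nrm = np.linalg.norm(e1)
    if nrm < 1e-9:
        raise DegenerateGeometryError("reference direction parallel to normal")
    e1 = e1 / nrm
    e2 = np.cross(n, e1)
    return e1, e2


def build_frame(model: TibiaModel, band: float = 8.0,
                n_margin_samples: int = 72
                ) -> tuple[CoordinateFrame, CondyleCircles]:
    """Construct the tibial coordinate frame from the joint plane and the
    best-fit condylar circles."""
    plane_point, n = joint_plane_from_landmarks(model)
    e1, e2 = _plane_basis(n, _ml_ref(model))
    margin = plateau_margin(model, plane_point, n, band=band,
                            n_samples=n_margin_samples)

    lm = model.landmarks
    med = np.asarray(lm["medial_extreme"], dtype=float)
    lat = np.asarray(lm["lateral_extreme"], dtype=float)
    ml = np.column_stack([(np.vstack([med, lat]) - plane_point) @ e1,
                          (np.vstack([med, lat]) - plane_point) @ e2])
    axis_dir = ml[1] - ml[0]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    coord = margin @ axis_dir
    mid = 0.5 * (ml[0] @ axis_dir + ml[1] @ axis_dir)
    medial_pts = margin[coord <= mid]
    lateral_pts = margin[coord > mid]
    mc, mr, mres = fit_circle_2d(medial_pts)
    lc, lr, lres = fit_circle_2d(lateral_pts)

    def to3d(uv):
        return plane_point + uv[0] * e1 + uv[1] * e2

    med_c3, lat_c3 = to3d(mc), to3d(lc)
    circles = CondyleCircles(med_c3, lat_c3, mr, lr,
                             float(np.sqrt(0.5 * (mres ** 2 + lres ** 2))))

    x = lat_c3 - med_c3
    x = x - n * (x @ n)   # numerically exact in-plane
    x = x / np.linalg.norm(x)
    w = np.cross(n, x)
    post = np.asarray(lm["medial_posterior_extreme"], dtype=float)
    origin = 0.5 * (med_c3 + lat_c3)
    if w @ (post - origin) > 0:
        w = -w
    y = w / np.linalg.norm(w)
    z = np.cross(x, y)

    frame = CoordinateFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z,
                            proximal_dir=n, plane_point=plane_point,
                            plane_normal=n)
    frame.validate()
    return frame, circles


def true_lateral_project(model_or_points, frame: CoordinateFrame) -> np.ndarray:
    """Orthographic projection along the x-axis onto the (y, proximal)
    plane: horizontal coordinate = anterior, vertical = proximal.

    Accepts a TibiaModel (projects mesh vertices), a TriMesh, or an
    (n, 3) point array.
    """
    if isinstance(model_or_points, TibiaModel):
        pts = model_or_points.mesh.vertices
    elif isinstance(model_or_points, TriMesh):
        pts = model_or_points.vertices
    else:
        pts = np.asarray(model_or_points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    rel = pts - frame.origin
    uv = np.column_stack([rel @ frame.y_axis, rel @ frame.proximal_dir])
    return uv[0] if single else uv
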