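"""Parametric synthetic proximal-tibia generator.

Models are built in a canonical coordinate system (+x lateral for right
side, +y anterior, +z proximal, plateau margin at z ~ 0) from stacked
convex cross-sections: an asymmetric bicondylar plateau outline
(anteriorly narrower than posteriorly, medially deeper than laterally),
a metaphyseal flare blending into a tubular shaft. The medial articular
facet is tilted posteriorly-distally by the subject's target slope via a
depth-decaying shear, so the constructed slope is recoverable by the
measurement chain.

Generated models are given a random rigid pose (and mirrored for left
sides) so downstream coordinate-frame construction is genuinely
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .mesh import TriMesh, rotation_about_axis

__all__ = [
    "SubjectParams",
    "CohortSpec",
    "TibiaModel",
    "sample_cohort",
    "build_tibia",
    "build_prism_fixture",
    "DEFAULT_SIZE_DISTRIBUTIONS",
]

#: population means/SDs (mm unless noted) for subject dimensions, scaled
#: by height_scale. General adult proximal-tibia anatomy; configurable.
DEFAULT_SIZE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "plateau_ml_width": (74.0, 2.0),
    "plateau_ap_depth_medial": (47.0, 1.6),
    "plateau_ap_depth_lateral": (41.0, 1.5),
    "shaft_length": (300.0, 6.0),
    "shaft_radius": (10.0, 0.5),
    "flare_length": (60.0, 3.0),
}


class ValidationError(ValueError):
    pass


class ConstructionError(RuntimeError):
    pass


@dataclass
class SubjectParams:
    subject_id: str
    target_pts: float            # degrees
    correction_angle: float      # degrees
    height_scale: float
    plateau_ml_width: float      # mm
    plateau_ap_depth_medial: float
    plateau_ap_depth_lateral: float
    shaft_length: float
    side: str = "right"
    # shape details beyond the headline dimensions
    shaft_radius: float = 10.0
    flare_length: float = 60.0
    anterior_share: float = 0.44     # anterior fraction of AP depth
    posterior_bilobe: float = 0.06   # bicondylar indentation of posterior rim
    shape_seed: int = 0              # drives cortical irregularity + pose

    def validate(self) -> None:
        if not (6.4 <= self.correction_angle <= 16.0):
            raise ValidationError(
                f"correction_angle {self.correction_angle} outside [6.4, 16.0]")
        if not np.isfinite(self.target_pts):
            raise ValidationError("target_pts must be finite")
        for name in ("height_scale", "plateau_ml_width", "plateau_ap_depth_medial",
                     "plateau_ap_depth_lateral", "shaft_length", "shaft_radius",
                     "flare_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.plateau_ml_width <= self.plateau_ap_depth_medial:
            raise ValidationError("plateau_ml_width must exceed AP depth")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side!r}")


@dataclass
class CohortSpec:
    n_subjects: int = 30
    pts_mean: float = 8.9
    pts_sd: float = 3.2
    correction_mean: float = 10.3
    correction_sd: float = 2.2
    correction_range: tuple[float, float] = (6.4, 16.0)
    height_mean_cm: float = 159.2
    height_sd_cm: float = 7.4
    size_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTIONS))
    size_jitter: float = 0.5   # multiplier on dimension SDs
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for name in ("pts_sd", "correction_sd", "height_sd_cm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.correction_range
        if not lo < hi:
            raise ValidationError("correction_range must be a nonempty interval")


@dataclass
class TibiaModel:
    mesh: TriMesh
    landmarks: dict[str, np.ndarray]
    side: str = "right"
    provenance: object = None  # SubjectParams or "restored"

    REQUIRED_LANDMARKS = (
        "medial_extreme",
        "medial_posterior_extreme",
        "lateral_extreme",
        "medial_plateau_anterior_edge",
        "medial_plateau_posterior_edge",
        "medial_plateau_end",
    )

    def transformed(self, rotation=None, translation=None) -> "TibiaModel":
        lm = dict(self.landmarks)
        for k, v in lm.items():
            p = np.asarray(v, dtype=float)
            if rotation is not None:
                p = np.asarray(rotation) @ p
            if translation is not None:
                p = p + np.asarray(translation)
            lm[k] = p
        return TibiaModel(self.mesh.transformed(rotation, translation),
                          lm, self.side, self.provenance)


# ---------------------------------------------------------------------- #
# cohort sampling
# ---------------------------------------------------------------------- #
def sample_cohort(spec: CohortSpec) -> list[SubjectParams]:
    """Draw a reproducible cohort of subject parameters.

    Slopes are Normal(pts_mean, pts_sd); correction angles are
    Normal(correction_mean, correction_sd) truncated to
    ``correction_range``; dimensions scale with a Normal body height.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    lo, hi = spec.correction_range
    for i in range(spec.n_subjects):
        pts = rng.normal(spec.pts_mean, spec.pts_sd)
        corr = rng.normal(spec.correction_mean, spec.correction_sd)
        while not (lo <= corr <= hi):
            corr = rng.normal(spec.correction_mean, spec.correction_sd)
        hs = rng.normal(spec.height_mean_cm, spec.height_sd_cm) / spec.height_mean_cm
        dims = {}
        for name, (mu, sd) in spec.size_distributions.items():
            dims[name] = hs * (mu + spec.size_jitter * rng.normal(0.0, sd))
        side = "right" if rng.random() < 0.5 else "left"
        subjects.append(SubjectParams(
            subject_id=f"S{i + 1:02d}",
            target_pts=float(pts),
            correction_angle=float(corr),
            height_scale=float(hs),
            plateau_ml_width=float(dims["plateau_ml_width"]),
            plateau_ap_depth_medial=float(dims["plateau_ap_depth_medial"]),
            plateau_ap_depth_lateral=float(dims["plateau_ap_depth_lateral"]),
            shaft_length=float(dims["shaft_length"]),
            shaft_radius=float(dims["shaft_radius"]),
            flare_length=float(dims["flare_length"]),
            side=side,
            shape_seed=int(rng.integers(0, 2**31 - 1)),
        ))
        for s in subjects[-1:]:
            s.validate()
    return subjects


# ---------------------------------------------------------------------- #
# cross-section model
# ---------------------------------------------------------------------- #
def _plateau_radius(az: np.ndarray, p: SubjectParams,
                    perturb: np.ndarray | None = None) -> np.ndarray:
    """Polar radius of the plateau outline at azimuth ``az``.

    Azimuth 0 = lateral (+x), pi/2 = anterior (+y). Quadrant-ellipse
    construction with a mediolaterally varying AP depth, an
    anteriorly-narrow split and a mild posterior bicondylar indentation.
    """
    c, s = np.cos(az), np.sin(az)
    a = p.plateau_ml_width / 2.0
    medial_frac = (1.0 - c) / 2.0
    depth = (medial_frac * p.plateau_ap_depth_medial
             + (1.0 - medial_frac) * p.plateau_ap_depth_lateral)
    b_ant = depth * p.anterior_share
    b_post = depth * (1.0 - p.anterior_share)
    bilobe = np.where(s < 0, 1.0 + p.posterior_bilobe * np.cos(2 * az), 1.0)
    b = np.where(s >= 0, b_ant, b_post * bilobe)
    r = 1.0 / np.sqrt((c / a) ** 2 + (s / np.maximum(b, 1e-9)) ** 2)
    if perturb is not None:
        r = r * perturb
    return r


def _taper(z: np.ndarray, flare_length: float) -> np.ndarray:
    """Cosine blend from plateau outline (1 at z=0) to shaft (0 below
    ``flare_length``); steepest mid-metaphysis, like a real tibia."""
    t = np.clip(-z / flare_length, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _shear_weight(z: np.ndarray, scale: float = 20.0) -> np.ndarray:
    return np.exp(np.minimum(z, 0.0) / scale)


def _section_points(z: float, az: np.ndarray, p: SubjectParams,
                    perturb: np.ndarray, tilt_tan: float) -> np.ndarray:
    r_plat = _plateau_radius(az, p, perturb)
    g = _taper(np.asarray(z, dtype=float), p.flare_length)
    r = p.shaft_radius + (r_plat - p.shaft_radius) * g
    x = r * np.cos(az)
    y = r * np.sin(az)
    zz = np.full_like(x, float(z)) + y * tilt_tan * _shear_weight(np.asarray(z))
    return np.column_stack([x, y, zz])


def build_tibia(params: SubjectParams) -> TibiaModel:
    """Construct a watertight proximal tibia + shaft for one subject."""
    params.validate()
    rng = np.random.default_rng(params.shape_seed)

    # smooth low-order cortical irregularity (per-subject)
    n_az = 64
    az = np.arange(n_az) / n_az * 2.0 * np.pi
    perturb = np.ones(n_az)
    for k in (2, 3, 4):
        amp = rng.normal(0.0, 0.006)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        perturb += amp * np.cos(k * az + phase)

    tilt_tan = np.tan(np.radians(params.target_pts))

    z_flare = np.arange(0.0, -params.flare_length - 1.0, -2.5)
    z_shaft = np.arange(z_flare[-1] - 8.0, -params.shaft_length + 4.0, -8.0)
    levels = np.concatenate([z_flare, z_shaft, [-params.shaft_length]])

    rings = [_section_points(z, az, params, perturb, tilt_tan) for z in levels]

    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    for ring in rings:
        verts.append(ring)
    n_levels = len(rings)

    def ring_idx(level: int, i: int) -> int:
        return level * n_az + i % n_az

    for k in range(n_levels - 1):
        for i in range(n_az):
            a0, a1 = ring_idx(k, i), ring_idx(k, i + 1)
            b0, b1 = ring_idx(k + 1, i), ring_idx(k + 1, i + 1)
            faces.append((a0, b0, b1))
            faces.append((a0, b1, a1))

    base = n_levels * n_az
    # top cap: two shrunken rings + centre, all on the tilted facet plane
    top = rings[0]
    cap_rings = []
    for frac in (0.62, 0.3):
        ring = top.copy()
        ring[:, 0] *= frac
        ring[:, 1] *= frac
        ring[:, 2] = ring[:, 1] * tilt_tan
        cap_rings.append(ring)
    centre_top = np.array([0.0, 0.0, 0.0])
    for ring in cap_rings:
        verts.append(ring)
    verts.append(centre_top[None, :])
    c_top = base + 2 * n_az

    def cap_idx(j: int, i: int) -> int:
        return base + j * n_az + i % n_az

    for i in range(n_az):  # outer margin ring -> first cap ring
        a0, a1 = ring_idx(0, i), ring_idx(0, i + 1)
        b0, b1 = cap_idx(0, i), cap_idx(0, i + 1)
        faces.append((a0, b1, b0))
        faces.append((a0, a1, b1))
    for i in range(n_az):  # first -> second cap ring
        a0, a1 = cap_idx(0, i), cap_idx(0, i + 1)
        b0, b1 = cap_idx(1, i), cap_idx(1, i + 1)
        faces.append((a0, b1, b0))
        faces.append((a0, a1, b1))
    for i in range(n_az):  # second cap ring -> centre
        faces.append((cap_idx(1, i), cap_idx(1, i + 1), c_top))

    # bottom cap
    c_bot = c_top + 1
    verts.append(np.array([[0.0, 0.0, -params.shaft_length]]))
    for i in range(n_az):
        a0, a1 = ring_idx(n_levels - 1, i), ring_idx(n_levels - 1, i + 1)
        faces.append((a1, a0, c_bot))

    mesh = TriMesh(np.concatenate(verts, axis=0), np.array(faces))
    if mesh.volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    if not mesh.is_watertight():
        raise ConstructionError("generated tibia mesh is not watertight")

    landmarks = _plateau_landmarks(top, params)

    model = TibiaModel(mesh, landmarks, side=params.side, provenance=params)
    if params.side == "left":
        model = TibiaModel(model.mesh.mirrored_x(),
                           {k: v * np.array([-1.0, 1.0, 1.0])
                            for k, v in model.landmarks.items()},
                           side="left", provenance=params)

    # randomized rigid pose so the frame module is genuinely exercised
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, 12.0))
    R = rotation_about_axis(axis, angle)
    t = rng.uniform(-25.0, 25.0, size=3)
    return model.transformed(R, t)


def _plateau_landmarks(margin: np.ndarray, params: SubjectParams
                       ) -> dict[str, np.ndarray]:
    """Pick the named anatomical points off the (canonical, right-side)
    plateau margin ring."""
    x, y = margin[:, 0], margin[:, 1]
    medial = margin[np.argmin(x)]
    lateral = margin[np.argmax(x)]
    med_mask = x < -0.2 * params.plateau_ml_width / 2.0
    med_pts = margin[med_mask]
    posterior = med_pts[np.argmin(med_pts[:, 1])]

    # medial condyle AP articular edges: margin points nearest the
    # mid-medial meridian, one anterior and one posterior
    target_x = -0.55 * params.plateau_ml_width / 2.0
    ant_mask = y > 0
    ant = margin[ant_mask]
    post = margin[~ant_mask]
    ant_edge = ant[np.argmin(np.abs(ant[:, 0] - target_x))]
    post_edge = post[np.argmin(np.abs(post[:, 0] - target_x))]

    return {
        "medial_extreme": medial.copy(),
        "medial_posterior_extreme": posterior.copy(),
        "lateral_extreme": lateral.copy(),
        "medial_plateau_anterior_edge": ant_edge.copy(),
        "medial_plateau_posterior_edge": post_edge.copy(),
        "medial_plateau_end": medial.copy(),
    }


# ---------------------------------------------------------------------- #
# analytic prism fixture
# ---------------------------------------------------------------------- #
def _polygon_is_simple(poly: np.ndarray) -> bool:
    n = len(poly)

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def seg_intersect(p, q, r, s):
        d1 = cross2(q - p, r - p)
        d2 = cross2(q - p, s - p)
        d3 = cross2(s - r, p - r)
        d4 = cross2(s - r, q - r)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1, n - 1):
                continue
            if seg_intersect(poly[i], poly[(i + 1) % n],
                             poly[j], poly[(j + 1) % n]):
                return False
    return True


def build_prism_fixture(cross_section: Iterable[Iterable[float]],
                        length: float, pts: float,
                        ring_spacing: float = 5.0,
                        boundary_spacing: float = 2.0) -> TibiaModel:
    """Extrude a 2D polygon into a prism 'tibia' whose top facet is
    tilted by ``pts`` degrees about the mediolateral axis.

    Every geometric quantity on this fixture has a closed form, which is
    what makes it useful as an oracle against the full mesh pipeline.
    """
    poly = np.asarray(list(cross_section), dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValidationError("cross_section must be a (k>=3, 2) polygon")
    if length <= 0:
        raise ValidationError("length must be > 0")
    if not _polygon_is_simple(poly):
        raise ValidationError("cross_section polygon is self-intersecting")
    # enforce CCW orientation
    area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                   - np.roll(poly[:, 0], -1) * poly[:, 1])
    if area2 < 0:
        poly = poly[::-1]

    # resample boundary so landmark extremes and cut curves are well
    # sampled even for coarse polygons
    pts2d = []
    for i in range(len(poly)):
        a, b = poly[i], poly[(i + 1) % len(poly)]
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / boundary_spacing)))
        if n > 1 and n % 2:
            n += 1  # keep edge midpoints in the sample (landmark ties)
        for t in np.arange(n) / n:
            pts2d.append(a + t * (b - a))
    ring2d = np.array(pts2d)
    n_az = len(ring2d)
    tilt_tan = np.tan(np.radians(pts))

    levels = np.arange(0.0, -length - ring_spacing / 2.0, -ring_spacing)
    if levels[-1] > -length:
        levels = np.concatenate([levels, [-length]])
    verts = []
    for z in levels:
        ring = np.column_stack([
            ring2d[:, 0], ring2d[:, 1],
            np.full(n_az, z) + (ring2d[:, 1] * tilt_tan if z == 0.0 else 0.0)])
        verts.append(ring)
    n_levels = len(levels)
    faces: list[tuple[int, int, int]] = []

    def ridx(level, i):
        return level * n_az + i % n_az

    for k in range(n_levels - 1):
        for i in range(n_az):
            a0, a1 = ridx(k, i), ridx(k, i + 1)
            b0, b1 = ridx(k + 1, i), ridx(k + 1, i + 1)
            faces.append((a0, b0, b1))
            faces.append((a0, b1, a1))
    centroid2d = ring2d.mean(axis=0)
    c_top = n_levels * n_az
    verts.append(np.array([[centroid2d[0], centroid2d[1],
                            centroid2d[1] * tilt_tan]]))
    c_bot = c_top + 1
    verts.append(np.array([[centroid2d[0], centroid2d[1], -length]]))
    for i in range(n_az):
        faces.append((ridx(0, i), ridx(0, i + 1), c_top))
        faces.append((ridx(n_levels - 1, i + 1), ridx(n_levels - 1, i), c_bot))

    mesh = TriMesh(np.concatenate(verts, axis=0), np.array(faces))
    if mesh.volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    if not mesh.is_watertight():
        raise ConstructionError("prism fixture is not watertight")

    margin = mesh.vertices[:n_az]
    x, y = margin[:, 0], margin[:, 1]
    cx = 0.5 * (x.min() + x.max())

    def pick(mask, key):
        cand = margin[mask]
        return cand[key(cand)]

    med_candidates = margin[np.abs(x - x.min()) < 1e-9]
    medial = med_candidates[np.argmin(np.abs(med_candidates[:, 1]))]
    lat_candidates = margin[np.abs(x - x.max()) < 1e-9]
    lateral = lat_candidates[np.argmin(np.abs(lat_candidates[:, 1]))]
    med_half = margin[x <= cx]
    posterior = med_half[np.lexsort((med_half[:, 0], med_half[:, 1]))][0]
    ant_edge = pick(x <= cx, lambda c: int(np.lexsort((c[:, 0], -c[:, 1]))[0]))
    post_edge = pick(x <= cx, lambda c: int(np.lexsort((c[:, 0], c[:, 1]))[0]))
    landmarks = {
        "medial_extreme": medial.copy(),
        "medial_posterior_extreme": posterior.copy(),
        "lateral_extreme": lateral.copy(),
        "medial_plateau_anterior_edge": ant_edge.copy(),
        "medial_plateau_posterior_edge": post_edge.copy(),
        "medial_plateau_end": medial.copy(),
    }
    return TibiaModel(mesh, landmarks, side="right", provenance="fixture")
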