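"""Slope morphometry on 3D tibia models.

The posterior slope is measured in the true-lateral projection as the
angle between the medial plateau line (through the projected anterior
and posterior articular edge landmarks) and the perpendicular to the
shaft axis (through the midpoints of the projected shaft outline at two
sampling depths). Positive slope = plateau tilted posteriorly-distally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frame import CoordinateFrame, true_lateral_project
from .mesh import TriMesh, cross_section
from .synthetic import TibiaModel

__all__ = [
    "PtsMeasurement",
    "MeasurementError",
    "measure_pts",
    "measure_pts_parts",
    "measure_coronal_correction",
    "measure_gap_ratio",
    "DEFAULT_SHAFT_DEPTHS",
]

#: depths below the joint plane (mm) at which the shaft outline is
#: sampled to construct the bisecting shaft axis
DEFAULT_SHAFT_DEPTHS = (80.0, 160.0)


class MeasurementError(RuntimeError):
    pass


@dataclass
class PtsMeasurement:
    pts: float                    # degrees, signed
    plateau_point: np.ndarray     # 2D, true-lateral frame
    plateau_dir: np.ndarray       # 2D unit, anterior-pointing
    shaft_point: np.ndarray       # 2D
    shaft_dir: np.ndarray         # 2D unit, proximal-pointing
    shaft_sample_depths: tuple[float, float] = DEFAULT_SHAFT_DEPTHS


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _shaft_axis_2d(shaft_mesh: TriMesh, frame: CoordinateFrame,
                   depths: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Midpoints of the projected shaft outline at the two sampling
    depths; returns (point2d, unit direction with proximal-positive v)."""
    mids = []
    for d in depths:
        point = frame.plane_point - d * frame.proximal_dir
        loops = cross_section(shaft_mesh, point, frame.proximal_dir)
        if not loops:
            raise MeasurementError(
                f"shaft too short: no cross-section {d} mm below joint plane")
        pts = np.concatenate(loops, axis=0)
        uv = true_lateral_project(pts, frame)
        u_mid = 0.5 * (uv[:, 0].min() + uv[:, 0].max())
        v_mid = float(np.mean(uv[:, 1]))
        mids.append(np.array([u_mid, v_mid]))
    p0, p1 = mids
    dvec = p0 - p1  # deep -> shallow = distal -> proximal
    if dvec[1] < 0:
        dvec = -dvec
    dvec = dvec / np.linalg.norm(dvec)
    return p1, dvec


def measure_pts_parts(landmarks: dict[str, np.ndarray],
                      shaft_mesh: TriMesh, frame: CoordinateFrame,
                      depths: tuple[float, float] = DEFAULT_SHAFT_DEPTHS
                      ) -> PtsMeasurement:
    """Measure the posterior slope from plateau landmarks plus a shaft
    mesh (which may be a different rigid body after an osteotomy)."""
    if depths[0] >= depths[1]:
        raise MeasurementError("sampling depths must be increasing")
    ant = true_lateral_project(np.asarray(landmarks["medial_plateau_anterior_edge"],
                                          dtype=float), frame)
    post = true_lateral_project(np.asarray(landmarks["medial_plateau_posterior_edge"],
                                           dtype=float), frame)
    plat = ant - post
    if plat[0] < 0:
        plat = -plat
    plat = plat / np.linalg.norm(plat)

    shaft_pt, shaft_dir = _shaft_axis_2d(shaft_mesh, frame, depths)
    # perpendicular to the shaft axis, anterior-pointing
    perp = np.array([shaft_dir[1], -shaft_dir[0]])
    if perp[0] < 0:
        perp = -perp
    ang = np.degrees(np.arctan2(plat[1], plat[0])
                     - np.arctan2(perp[1], perp[0]))
    pts = _wrap_deg(ang)
    if abs(pts) >= 45.0:
        raise MeasurementError(f"implausible slope {pts:.1f} deg")
    return PtsMeasurement(pts=float(pts), plateau_point=post, plateau_dir=plat,
                          shaft_point=shaft_pt, shaft_dir=shaft_dir,
                          shaft_sample_depths=tuple(depths))


def measure_pts(model: TibiaModel, frame: CoordinateFrame,
                depths: tuple[float, float] = DEFAULT_SHAFT_DEPTHS
                ) -> PtsMeasurement:
    """Posterior slope of an intact (or restored) tibia model.

    Deliberately consumes only the mesh + landmarks, never generator
    parameters.
    """
    return measure_pts_parts(model.landmarks, model.mesh, frame, depths)


def measure_coronal_correction(applied_rotation: np.ndarray,
                               frame: CoordinateFrame) -> float:
    """Coronal-projection angle (degrees) between the pre and post
    distal-shaft axes, expressed relative to the proximal segment.

    The proximal segment was rotated by ``applied_rotation``; relative to
    it the distal shaft rotated by its inverse.
    """
    R = np.asarray(applied_rotation, dtype=float)
    s_pre = frame.proximal_dir
    s_post = R.T @ s_pre
    y = frame.y_axis

    def coronal(v):
        w = v - y * (v @ y)
        return w / np.linalg.norm(w)

    a, b = coronal(s_pre), coronal(s_post)
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def measure_gap_ratio(anterior_gap: float, posterior_gap: float) -> float:
    """Anterior/posterior opening gap ratio; NaN when the wedge is
    closed (zero opening) rather than raising."""
    if posterior_gap <= 0 or anterior_gap <= 0:
        return float("nan")
    return float(anterior_gap / posterior_gap)
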