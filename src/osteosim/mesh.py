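"""Minimal triangle-mesh container and the geometric primitives the
simulator needs: signed volume, watertightness checks, rigid transforms,
plane cross-sections and watertight plane splitting with cap generation.

Vertices are in millimetres. Faces are counter-clockwise when seen from
outside (outward normals).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriMesh",
    "MeshCutError",
    "PlaneSplit",
    "cross_section",
    "split_by_plane",
    "rotation_about_axis",
]


class MeshCutError(RuntimeError):
    """Raised when a plane split does not produce two watertight pieces."""


@dataclass
class TriMesh:
    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    # ------------------------------------------------------------------ #
    # basic properties
    # ------------------------------------------------------------------ #
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def volume(self) -> float:
        """Signed volume by summing tetrahedra against the origin.

        Positive for consistently outward-oriented watertight surfaces.
        """
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def is_watertight(self) -> bool:
        """Every directed edge must be matched by exactly one reverse edge."""
        e = self.edges()
        fwd = {}
        for i, (a, b) in enumerate(map(tuple, e)):
            if a == b:
                return False
            key = (a, b)
            if key in fwd:
                return False  # duplicated directed edge -> bad orientation
            fwd[key] = i
        for a, b in fwd:
            if (b, a) not in fwd:
                return False
        return True

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces.copy())

    def mirrored_x(self) -> "TriMesh":
        """Mirror about the x = 0 plane, flipping faces to preserve
        outward orientation."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        return TriMesh(v, self.faces[:, ::-1].copy())

    # ------------------------------------------------------------------ #
    # IO: ASCII STL / PLY (text formats keep artifacts diffable)
    # ------------------------------------------------------------------ #
    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".stl":
            self._save_stl_ascii(path)
        elif path.suffix.lower() == ".ply":
            self._save_ply_ascii(path)
        else:
            raise ValueError(f"unsupported mesh format: {path.suffix}")

    def _save_stl_ascii(self, path: Path) -> None:
        nrm = self.face_normals()
        v = self.vertices
        with open(path, "w") as fh:
            fh.write("solid osteosim\n")
            for f, n in zip(self.faces, nrm):
                fh.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
                fh.write(" outer loop\n")
                for idx in f:
                    p = v[idx]
                    fh.write(f"  vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid osteosim\n")

    def _save_ply_ascii(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {self.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {self.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in self.vertices:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    @staticmethod
    def load(path: str | Path) -> "TriMesh":
        path = Path(path)
        if path.suffix.lower() == ".ply":
            return _load_ply(path)
        if path.suffix.lower() == ".stl":
            return _load_stl(path)
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def _load_ply(path: Path) -> TriMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    nv = nf = 0
    i = 0
    while lines[i].strip() != "end_header":
        tok = lines[i].split()
        if tok[:2] == ["element", "vertex"]:
            nv = int(tok[2])
        elif tok[:2] == ["element", "face"]:
            nf = int(tok[2])
        i += 1
    body = lines[i + 1:]
    verts = np.array([[float(x) for x in body[j].split()[:3]] for j in range(nv)])
    faces = np.array([[int(x) for x in body[nv + j].split()[1:4]] for j in range(nf)])
    return TriMesh(verts, faces)


def _load_stl(path: Path) -> TriMesh:
    raw = path.read_bytes()
    if raw[:5] == b"solid" and b"facet" in raw[:500]:
        tris = []
        for line in raw.decode().splitlines():
            line = line.strip()
            if line.startswith("vertex"):
                tris.append([float(x) for x in line.split()[1:4]])
        tri = np.array(tris).reshape(-1, 3, 3)
    else:  # binary STL
        (n,) = struct.unpack("<I", raw[80:84])
        data = np.frombuffer(raw[84:84 + n * 50], dtype=np.uint8).reshape(n, 50)
        tri = data[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(float)
    flat = tri.reshape(-1, 3)
    uniq, inverse = np.unique(np.round(flat, 6), axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriMesh(uniq, faces)


def save_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(map(float, v)) for k, v in landmarks.items()}, fh, indent=1)


def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        return {k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()}


# ---------------------------------------------------------------------- #
# rotations
# ---------------------------------------------------------------------- #
def rotation_about_axis(direction: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``direction``."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0.0, -u[2], u[1]],
                  [u[2], 0.0, -u[0]],
                  [-u[1], u[0], 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


# ---------------------------------------------------------------------- #
# plane cross-section
# ---------------------------------------------------------------------- #
def _plane_signed_distance(vertices: np.ndarray, point: np.ndarray,
                           normal: np.ndarray) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return (vertices - np.asarray(point, dtype=float)) @ n


def cross_section(mesh: TriMesh, point: np.ndarray, normal: np.ndarray
                  ) -> list[np.ndarray]:
    """Intersect the mesh with a plane.

    Returns a list of closed polylines, each an (k, 3) array of ordered
    points (last point != first; closure implied).
    """
    d = _plane_signed_distance(mesh.vertices, point, normal)
    side_all = d[mesh.faces] > 0
    crossing = mesh.faces[side_all.any(axis=1) & ~side_all.all(axis=1)]
    segs = []
    for f in crossing:
        pts = []
        for i in range(3):
            a, b = f[i], f[(i + 1) % 3]
            da, db = d[a], d[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                pts.append(mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))
        if len(pts) == 2:
            segs.append((pts[0], pts[1]))
    if not segs:
        return []
    # chain segments into closed loops
    pts = np.array([p for s in segs for p in s])
    key = np.round(pts / 1e-7).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    adj: dict[int, list[int]] = {}
    for i in range(len(segs)):
        a, b = inv[2 * i], inv[2 * i + 1]
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    coords = {}
    for i in range(len(pts)):
        coords[inv[i]] = pts[i]
    loops = []
    visited = set()
    for start in adj:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur, prev = start, None
        while True:
            nxt = None
            for cand in adj[cur]:
                if cand != prev and (cand not in visited or cand == start):
                    nxt = cand
                    break
            if nxt is None or nxt == start:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(np.array([coords[i] for i in loop]))
    return loops


# ---------------------------------------------------------------------- #
# plane splitting with caps
# ---------------------------------------------------------------------- #
@dataclass
class PlaneSplit:
    """Result of splitting a watertight mesh by a plane.

    ``above``/``below`` refer to the side of the plane normal. Cap faces
    are appended after the body faces; ``above_n_body``/``below_n_body``
    record where the caps start so that a closure operation can weld the
    halves back together.
    """
    above: TriMesh
    below: TriMesh
    above_n_body: int
    below_n_body: int
    plane_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


def split_by_plane(mesh: TriMesh, point: np.ndarray, normal: np.ndarray,
                   tol: float = 1e-9) -> PlaneSplit:
    """Split a watertight mesh into two watertight capped pieces.

    The cut curve must be a single closed loop (enforced); the cap is a
    fan triangulation from the loop centroid, valid for the star-shaped
    cut polygons produced by convex-sectioned bone models.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = _plane_signed_distance(mesh.vertices, point, normal)
    # nudge vertices lying exactly on the plane to keep topology simple
    on = np.abs(d) < tol
    if on.any():
        d = d.copy()
        d[on] = tol

    verts = [mesh.vertices.copy()]
    extra: dict[tuple[int, int], int] = {}
    n0 = len(mesh.vertices)

    def edge_point(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key in extra:
            return extra[key]
        da, db = d[a], d[b]
        t = da / (da - db)
        p = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
        idx = n0 + len(extra)
        extra[key] = idx
        verts.append(p[None, :])
        return idx

    faces_above: list[tuple[int, int, int]] = []
    faces_below: list[tuple[int, int, int]] = []
    cut_edges: list[tuple[int, int]] = []  # directed, boundary of *above* piece

    for f in mesh.faces:
        sides = d[f] > 0
        ns = sides.sum()
        if ns == 3:
            faces_above.append(tuple(f))
            continue
        if ns == 0:
            faces_below.append(tuple(f))
            continue
        # rotate so the lone vertex comes first (cyclic order preserved)
        lone_above = ns == 1
        lone = next(i for i in range(3) if (d[f[i]] > 0) == lone_above)
        a, b, c = f[lone], f[(lone + 1) % 3], f[(lone + 2) % 3]
        pab = edge_point(a, b)
        pca = edge_point(c, a)
        tri_lone = [(a, pab, pca)]
        quad = [(pab, b, c), (pab, c, pca)]
        if lone_above:
            faces_above.extend(tri_lone)
            faces_below.extend(quad)
            cut_edges.append((pca, pab))
        else:
            faces_below.extend(tri_lone)
            faces_above.extend(quad)
            cut_edges.append((pab, pca))

    all_verts = np.concatenate(verts, axis=0)

    loop = _chain_single_loop(cut_edges)
    if loop is None:
        raise MeshCutError("cut curve is not a single closed loop")

    def build(faces: list[tuple[int, int, int]], loop_idx: list[int],
              flip_cap: bool) -> tuple[TriMesh, int]:
        n_body = len(faces)
        centroid = all_verts[loop_idx].mean(axis=0)
        cap_faces = []
        c_idx = len(all_verts)  # placeholder; remap below handles it
        ring = loop_idx if not flip_cap else loop_idx[::-1]
        for i in range(len(ring)):
            cap_faces.append((c_idx, ring[i], ring[(i + 1) % len(ring)]))
        used = sorted(set(i for tri in faces + cap_faces for i in tri))
        remap = {old: new for new, old in enumerate(used)}
        vtx = np.array([all_verts[i] if i != c_idx else centroid for i in used])
        tris = np.array([[remap[i] for i in tri] for tri in faces + cap_faces])
        return TriMesh(vtx, tris), n_body

    above, na = build(faces_above, loop, flip_cap=False)
    below, nb = build(faces_below, loop, flip_cap=True)

    for m, label in ((above, "above"), (below, "below")):
        if not m.is_watertight():
            raise MeshCutError(f"{label} piece is not watertight after split")
    return PlaneSplit(above, below, na, nb,
                      np.asarray(point, dtype=float), normal)


def _chain_single_loop(edges: list[tuple[int, int]]) -> list[int] | None:
    if not edges:
        return None
    nxt = {}
    for a, b in edges:
        if a in nxt:
            return None
        nxt[a] = b
    start = edges[0][0]
    loop = [start]
    cur = nxt.get(start)
    while cur is not None and cur != start:
        loop.append(cur)
        cur = nxt.get(cur)
        if len(loop) > len(edges) + 1:
            return None
    if cur != start or len(loop) != len(edges):
        return None
    return loop
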