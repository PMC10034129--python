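"""Triangulated-surface geometry: meshing from label volumes, volume/area/thickness
measurements, and percent atrophy rates.

All meshes live in world millimetre coordinates.  Voxel-to-world mapping is
axis-aligned: ``world = origin + index * spacing`` with 0-based indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import trimesh
from skimage import measure as _skmeasure


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh inputs."""


@dataclass
class TriSurface:
    """A triangulated surface: vertices (mm) and consistently oriented cells.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array
        Vertex-index triples; outward orientation gives positive signed volume
        for closed surfaces.
    vertex_labels : optional (V,) int array
        Per-vertex region labels (e.g. entorhinal vs transentorhinal, or
        inner vs outer laminar sheet).
    cell_labels : optional (F,) int array
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: Optional[np.ndarray] = None
    cell_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "TriSurface":
        """Same connectivity/labels with new vertex positions."""
        return replace(self, vertices=np.asarray(vertices, dtype=float))

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_labels is None else self.vertex_labels.copy(),
            None if self.cell_labels is None else self.cell_labels.copy(),
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces (opposite senses)."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        und = np.sort(edges, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals."""
        fn = face_area_normals(self.vertices, self.faces)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms


@dataclass
class ThicknessField:
    """Per-vertex laminar thickness (mm) on the inner surface."""

    thickness: np.ndarray
    vertex_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.thickness = np.asarray(self.thickness, dtype=float)
        if np.any(self.thickness < -1e-9):
            raise ValueError("thickness must be nonnegative")

    def mean(self, label: Optional[int] = None) -> float:
        if label is None or self.vertex_labels is None:
            return float(np.mean(self.thickness))
        sel = self.vertex_labels == label
        if not np.any(sel):
            raise ValueError(f"no vertices labeled {label}")
        return float(np.mean(self.thickness[sel]))

    def composite_mean(self, labels: Sequence[int]) -> float:
        """Average of per-label mean thicknesses (composite regional measure)."""
        return float(np.mean([self.mean(l) for l in labels]))


# ---------------------------------------------------------------------------
# geometry primitives


def face_area_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted face normals N_c = 0.5 (x2-x1) x (x3-x1); |N_c| = area."""
    v = np.asarray(vertices, float)
    e1 = v[faces[:, 1]] - v[faces[:, 0]]
    e2 = v[faces[:, 2]] - v[faces[:, 0]]
    return 0.5 * np.cross(e1, e2)


def cell_geometry(surface: TriSurface, warn_degenerate: bool = True):
    """Per-cell areas |γ_c| and centers m_c.

    Returns
    -------
    areas : (F,) array, centers : (F, 3) array
    """
    N = face_area_normals(surface.vertices, surface.faces)
    areas = np.linalg.norm(N, axis=1)
    centers = surface.vertices[surface.faces].mean(axis=1)
    if warn_degenerate and np.any(areas == 0):
        warnings.warn(f"{int(np.sum(areas == 0))} degenerate zero-area cells")
    return areas, centers


def surface_area(surface: TriSurface) -> float:
    areas, _ = cell_geometry(surface, warn_degenerate=False)
    return float(areas.sum())


def surface_volume(surface: TriSurface) -> float:
    """Signed enclosed volume: V = sum_c (1/6) x_c1 . (x_c2 x x_c3).

    Positive for outward-oriented closed surfaces; translation invariant.
    """
    if not surface.is_closed():
        raise MeshError("surface_volume requires a closed (watertight) surface")
    v = surface.vertices
    f = surface.faces
    return float(np.einsum("ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])) / 6.0)


def percent_atrophy_rate(m_initial: float, m_final: float,
                         t_initial: float, t_final: float) -> float:
    """Percent loss per year: -100 (m_f - m_i) / (m_i (t_f - t_i)).

    Positive values mean shrinkage (loss); negative mean growth.
    """
    if m_initial <= 0:
        raise ValueError("baseline measure must be positive")
    if t_final <= t_initial:
        raise ValueError("time interval must be positive")
    return float(-100.0 * (m_final - m_initial) / (m_initial * (t_final - t_initial)))


# ---------------------------------------------------------------------------
# meshing from label volumes


def mesh_from_mask(volume: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                   label: int = 1, smooth_iterations: int = 10,
                   target_vertices: Optional[int] = 1500) -> TriSurface:
    """Closed oriented mesh of the boundary of ``volume == label``.

    Marching cubes on the binarized label, light Taubin-style smoothing, and
    optional decimation toward a vertex budget.  Multiple connected components:
    the largest is kept with a warning.
    """
    mask = np.asarray(volume) == label
    if not mask.any():
        raise MeshError(f"label {label} is empty in the volume")
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    pad = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = _skmeasure.marching_cubes(pad, level=0.5)
    verts = (verts - 1.0) * spacing + origin
    mesh = trimesh.Trimesh(verts, faces, process=True)
    comps = mesh.split(only_watertight=False)
    if len(comps) > 1:
        warnings.warn(f"{len(comps)} connected components; keeping largest")
        mesh = max(comps, key=lambda m: len(m.vertices))
    if smooth_iterations:
        trimesh.smoothing.filter_taubin(mesh, iterations=smooth_iterations)
    if target_vertices is not None and len(mesh.vertices) > target_vertices:
        mesh = _decimate(mesh, target_vertices)
    if mesh.volume < 0:
        mesh.invert()
    return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def _decimate(mesh: trimesh.Trimesh, target_vertices: int) -> trimesh.Trimesh:
    """Decimation toward a vertex budget; falls back to the input mesh if no
    backend is available or the result is not watertight."""
    try:
        face_target = max(4, int(len(mesh.faces) * target_vertices / len(mesh.vertices)))
        dec = mesh.simplify_quadric_decimation(face_count=face_target)
        dec = trimesh.Trimesh(np.asarray(dec.vertices), np.asarray(dec.faces), process=True)
        if dec.is_watertight and len(dec.vertices) >= 4:
            if dec.volume < 0:
                dec.invert()
            return dec
    except BaseException:
        pass
    return mesh


# ---------------------------------------------------------------------------
# laminar thickness


def thickness(inner: TriSurface, outer: TriSurface, method: str = "normal_flow",
              step_mm: float = 0.05, max_mm: float = 20.0) -> ThicknessField:
    """Per-vertex thickness of the laminar region between two sheets.

    ``normal_flow``: the inner sheet is advanced along its own (recomputed)
    normals in small steps; each vertex accumulates path length until it has
    crossed the outer sheet.  This discretizes a flow constrained to move
    normal to the deforming surface.

    ``closest_point``: closed-form fallback — distance from each inner vertex
    to the outer sheet along the inner vertex normal (ray cast, with nearest
    point as backstop).
    """
    if inner.n_vertices == 0 or outer.n_vertices == 0:
        raise MeshError("empty surface")
    if inner.vertices.shape == outer.vertices.shape and np.allclose(
            inner.vertices, outer.vertices):
        return ThicknessField(np.zeros(inner.n_vertices), inner.vertex_labels)
    tri = outer.vertices[outer.faces]    # (T, 3, 3)

    def surf_dist(points):
        return _closest_on_triangles(points, tri)

    closest0, d_guess = surf_dist(inner.vertices)
    if np.min(d_guess) > max_mm:
        raise MeshError("sheets do not overlap within max_mm")
    # orient flow direction toward the outer sheet
    normals = inner.vertex_normals()
    to_outer = closest0 - inner.vertices
    sign = np.sign(np.einsum("ij,ij->i", normals, to_outer))
    sign[sign == 0] = 1.0

    if method == "closest_point":
        t = _ray_thickness(inner, outer, normals * sign[:, None], d_guess, max_mm)
        return ThicknessField(t, inner.vertex_labels)

    # normal-constrained flow
    cur = inner.copy()
    n_v = inner.n_vertices
    path = np.zeros(n_v)
    done = np.zeros(n_v, dtype=bool)
    prev_d = d_guess.copy()
    n_steps = int(np.ceil(max_mm / step_mm))
    for _ in range(n_steps):
        normals = cur.vertex_normals() * sign[:, None]
        move = np.where(done[:, None], 0.0, normals * step_mm)
        cur = cur.with_vertices(cur.vertices + move)
        path += np.where(done, 0.0, step_mm)
        _, d = surf_dist(cur.vertices)
        # a vertex has arrived when its distance to the outer sheet stops
        # decreasing at the flow resolution (it has crossed / grazed the sheet)
        approaching = (~done) & (d < step_mm)
        crossed = (~done) & ~approaching & (d > prev_d - 0.25 * step_mm)
        # close the gap / remove the overshoot with the terminal distance
        path[approaching] += d[approaching]
        path[crossed] -= np.minimum(d[crossed], step_mm)
        done |= approaching | crossed
        prev_d = d
        if done.all():
            break
    return ThicknessField(np.maximum(path, 0.0), inner.vertex_labels)


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray):
    """Closest point on a triangle soup for each query point (vectorized).

    Barycentric projection onto each triangle's plane with clamping to the
    nearest edge/vertex (Ericson's region test), all P x T pairs at once.
    Suitable for the small laminar meshes thickness operates on.
    """
    p = points[:, None, :]               # (P, 1, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = (b - a)[None]
    ac = (c - a)[None]
    ap = p - a[None]
    d1 = np.einsum("ptd,ptd->pt", ab, ap)
    d2 = np.einsum("ptd,ptd->pt", ac, ap)
    bp = p - b[None]
    d3 = np.einsum("ptd,ptd->pt", ab, bp)
    d4 = np.einsum("ptd,ptd->pt", ac, bp)
    cp = p - c[None]
    d5 = np.einsum("ptd,ptd->pt", ab, cp)
    d6 = np.einsum("ptd,ptd->pt", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom_face = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(np.abs(denom_face) > 1e-30, vb / denom_face, 0.0)
        w_face = np.where(np.abs(denom_face) > 1e-30, vc / denom_face, 0.0)
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.clip(np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0), 0, 1)

    # region selection per Ericson
    v = v_face
    w = w_face
    v = np.where(vc <= 0, np.where((d1 >= 0) & (d3 <= 0), t_ab, v), v)
    w = np.where(vc <= 0, np.where((d1 >= 0) & (d3 <= 0), 0.0, w), w)
    in_vertex_a = (d1 <= 0) & (d2 <= 0)
    in_vertex_b = (d3 >= 0) & (d4 <= d3)
    in_vertex_c = (d6 >= 0) & (d5 <= d6)
    edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    edge_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    v = np.where(edge_ac, 0.0, v)
    w = np.where(edge_ac, t_ac, w)
    v = np.where(edge_bc, 1.0 - t_bc, v)
    w = np.where(edge_bc, t_bc, w)
    v = np.where(edge_ab, t_ab, v)
    w = np.where(edge_ab, 0.0, w)
    v = np.where(in_vertex_c, 0.0, v)
    w = np.where(in_vertex_c, 1.0, w)
    v = np.where(in_vertex_b, 1.0, v)
    w = np.where(in_vertex_b, 0.0, w)
    v = np.where(in_vertex_a, 0.0, v)
    w = np.where(in_vertex_a, 0.0, w)
    v = np.clip(v, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)
    over = v + w > 1.0
    scale = np.where(over, 1.0 / np.maximum(v + w, 1e-30), 1.0)
    v *= scale
    w *= scale

    closest = a[None] + v[..., None] * ab + w[..., None] * ac    # (P, T, 3)
    d2_all = np.einsum("ptd,ptd->pt", p - closest, p - closest)
    idx = np.argmin(d2_all, axis=1)
    rows = np.arange(len(points))
    return closest[rows, idx], np.sqrt(d2_all[rows, idx])


def _ray_thickness(inner: TriSurface, outer: TriSurface, directions: np.ndarray,
                   d_guess: np.ndarray, max_mm: float) -> np.ndarray:
    om = outer.to_trimesh()
    t = d_guess.copy()
    try:
        locs, idx_ray, _ = om.ray.intersects_location(
            ray_origins=inner.vertices, ray_directions=directions)
        if len(idx_ray):
            dist = np.linalg.norm(locs - inner.vertices[idx_ray], axis=1)
            best = np.full(inner.n_vertices, np.inf)
            np.minimum.at(best, idx_ray, dist)
            hit = np.isfinite(best) & (best <= max_mm)
            t[hit] = best[hit]
    except BaseException:
        pass
    return t
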