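"""Triangulated face surfaces: container, I/O, area, closest points.

A :class:`FaceMesh` is a plain vertices/triangles pair in mm.  Degenerate
triangles (area below ``DEGENERATE_AREA``) are dropped when a mesh is
constructed, with a logged warning, so downstream geodesic graphs are
well posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: Triangles with area below this (mm^2) are dropped at construction.
DEGENERATE_AREA = 1e-10


class MeshError(ValueError):
    """Raised for malformed meshes or off-surface query points."""


def _triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class FaceMesh:
    """Triangle mesh of a face surface (vertices in mm)."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise MeshError("triangle indices out of vertex range")
        if len(self.triangles):
            areas = _triangle_areas(self.vertices, self.triangles)
            bad = areas < DEGENERATE_AREA
            if bad.any():
                log.warning("dropping %d degenerate triangle(s)", int(bad.sum()))
                self.triangles = self.triangles[~bad]

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def area(self) -> float:
        """Total surface area in mm^2 (sum of triangle areas)."""
        if len(self.triangles) == 0:
            raise MeshError("mesh has no triangles")
        return float(_triangle_areas(self.vertices, self.triangles).sum())

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) sorted-index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
             self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "FaceMesh":
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return FaceMesh(scale * self.vertices @ R.T + t, self.triangles.copy())

    # -- closest-point queries --------------------------------------------

    def closest_point(self, points: np.ndarray, ties: bool = False):
        """Closest surface point for each query point.

        Returns ``(proj, dist, tri_index)``: the projected points, their
        distances to the surface, and the triangle each projects onto.
        With ``ties=True`` a fourth element lists, per point, *all*
        triangle indices whose closest point ties the minimum distance
        (within 1e-9 mm) — a point on a shared edge or vertex belongs to
        every adjacent triangle.  Brute-force vectorised point-triangle
        projection; fine for the mesh sizes this package works with.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        proj = np.empty_like(points)
        dist = np.empty(len(points))
        tri_idx = np.empty(len(points), dtype=np.int64)
        tied: list[np.ndarray] = []
        A = self.vertices[self.triangles[:, 0]]
        B = self.vertices[self.triangles[:, 1]]
        C = self.vertices[self.triangles[:, 2]]
        for i, p in enumerate(points):
            q = _closest_on_triangles(p, A, B, C)
            d2 = np.einsum("ij,ij->i", q - p, q - p)
            j = int(np.argmin(d2))
            proj[i] = q[j]
            dist[i] = np.sqrt(d2[j])
            tri_idx[i] = j
            if ties:
                tied.append(np.flatnonzero(
                    np.sqrt(d2) <= dist[i] + 1e-9))
        if ties:
            return proj, dist, tri_idx, tied
        return proj, dist, tri_idx


def _closest_on_triangles(p, A, B, C):
    """Closest point to ``p`` on each triangle (Ericson's method, vectorised
    over triangles)."""
    ab = B - A
    ac = C - A
    ap = p - A
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - B
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - C
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    q = A + v[:, None] * ab + w[:, None] * ac  # interior candidate

    # edge/vertex regions
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        t_bc = np.clip(
            np.where((d4 - d3) + (d5 - d6) != 0,
                     (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0), 0, 1)

    q = np.where((vc <= 0)[:, None], A + t_ab[:, None] * ab, q)
    q = np.where((vb <= 0)[:, None], A + t_ac[:, None] * ac, q)
    on_bc = (va <= 0)
    q = np.where(on_bc[:, None], B + t_bc[:, None] * (C - B), q)
    q = np.where(((d1 <= 0) & (d2 <= 0))[:, None], A, q)
    q = np.where(((d3 >= 0) & (d4 <= d3))[:, None], B, q)
    q = np.where(((d6 >= 0) & (d5 <= d6))[:, None], C, q)
    return q


def euclidean_distance(p, q) -> float:
    """Straight-line distance between two 3D points (mm)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def facial_area(mesh: FaceMesh) -> float:
    """Facial surface area (mm^2) from the point cloud + triangulation."""
    return mesh.area()


# -- I/O -------------------------------------------------------------------

def write_mesh(mesh: FaceMesh, path: str | Path) -> None:
    """Write a mesh as ASCII OBJ or PLY (by file extension)."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(tm))
    elif path.suffix.lower() == ".ply":
        path.write_bytes(
            trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        )
    else:
        raise MeshError(f"unsupported mesh format: {path.suffix!r}")


def read_mesh(path: str | Path) -> FaceMesh:
    """Read an OBJ/PLY mesh file (triangles only)."""
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise MeshError(f"could not parse mesh file {path}: {exc}") from exc
    faces = np.asarray(tm.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshError(f"{path}: mesh is not pure-triangle")
    return FaceMesh(np.asarray(tm.vertices, dtype=float), faces)
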