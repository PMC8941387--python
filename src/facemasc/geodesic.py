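"""Surface (geodesic) distances on triangle meshes.

Two-stage approximation:

1. *Graph stage.*  Every mesh edge carries ``steiner_per_edge`` evenly
   spaced extra nodes and, within each triangle, all boundary nodes
   (3 vertices + the Steiner points of its 3 edges) are completely
   connected by straight segments.  Dijkstra on this graph yields an
   on-surface polyline between any two query points
   (``steiner_per_edge=1`` is the classic midpoint-subdivision graph).
2. *Refinement stage.*  The polyline is iteratively shortened: each
   interior point slides along the mesh edge it lies on to minimise the
   length of its two adjacent segments (red-black coordinate descent).
   Every update keeps consecutive points on a common triangle, so the
   path remains on the surface and its length can only decrease, never
   dropping below the true geodesic of its corridor.

Query points are snapped to the surface (within ``snap_tolerance`` mm)
and joined to the boundary nodes of their triangle by straight segments
from the *original* 3D point, so every returned length is the length of a
3D polyline from p to q and therefore never falls below the Euclidean
distance.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import FaceMesh, MeshError

#: Default snap tolerance for off-surface query points, mm.
SNAP_TOLERANCE = 2.0


def _opt_t(P: np.ndarray, Q: np.ndarray, A: np.ndarray, B: np.ndarray
           ) -> float:
    """Minimise |x-P| + |x-Q| for x = A + t (B - A), t in [0, 1].

    Closed form in the unfolded axial/radial coordinates of the line
    through A and B (reflection principle)."""
    U = B - A
    L2 = float(U @ U)
    if L2 <= 1e-24:
        return 0.0
    L = np.sqrt(L2)
    uhat = U / L
    Pr = P - A
    Qr = Q - A
    pa = float(Pr @ uhat)
    qa = float(Qr @ uhat)
    pr = np.sqrt(max(float(Pr @ Pr) - pa * pa, 0.0))
    qr = np.sqrt(max(float(Qr @ Qr) - qa * qa, 0.0))
    if pr + qr < 1e-12:
        t = 0.5 * (pa + qa)
    else:
        t = (pa * qr + qa * pr) / (pr + qr)
    return min(max(t / L, 0.0), 1.0)


class GeodesicSolver:
    """Precomputed shortest-path machinery for one mesh.

    Parameters
    ----------
    mesh:
        Surface to measure on.
    steiner_per_edge:
        Extra graph nodes per mesh edge (>= 0); 1 reproduces midpoint
        subdivision and is enough once refinement is on.
    snap_tolerance:
        Maximum allowed distance (mm) from a query point to the surface.
    refine:
        Run the path-shortening stage (recommended; disable only to get
        raw graph distances).
    refine_tol:
        Relative length decrease below which refinement stops.
    max_sweeps:
        Hard cap on refinement sweeps per path.
    """

    def __init__(self, mesh: FaceMesh, steiner_per_edge: int = 1,
                 snap_tolerance: float = SNAP_TOLERANCE,
                 refine: bool = True, refine_tol: float = 1e-9,
                 max_sweeps: int = 300):
        if steiner_per_edge < 0:
            raise ValueError("steiner_per_edge must be >= 0")
        self.mesh = mesh
        self.steiner_per_edge = int(steiner_per_edge)
        self.snap_tolerance = float(snap_tolerance)
        self.refine = bool(refine)
        self.refine_tol = float(refine_tol)
        self.max_sweeps = int(max_sweeps)
        self._build()

    def _build(self) -> None:
        mesh = self.mesh
        k = self.steiner_per_edge
        V = mesh.vertices
        F = mesh.triangles
        edges = mesh.edges_unique()
        self._edges = edges
        n_vert = len(V)

        coords = [V]
        if k:
            fracs = (np.arange(1, k + 1) / (k + 1))[None, :, None]
            a = V[edges[:, 0]][:, None, :]
            b = V[edges[:, 1]][:, None, :]
            coords.append((a + fracs * (b - a)).reshape(-1, 3))
        self.node_coords = np.vstack(coords)
        self._n_vert = n_vert

        key = edges[:, 0] * n_vert + edges[:, 1]
        order = np.argsort(key)
        key_sorted = key[order]

        def edge_index(u, v):
            lo = np.minimum(u, v)
            hi = np.maximum(u, v)
            return order[np.searchsorted(key_sorted, lo * n_vert + hi)]

        face_nodes = [F]
        if k:
            for (u, v) in ((0, 1), (1, 2), (2, 0)):
                ei = edge_index(F[:, u], F[:, v])
                face_nodes.append(
                    n_vert + ei[:, None] * k + np.arange(k)[None, :]
                )
        face_nodes = np.hstack(face_nodes)
        self._face_nodes = face_nodes

        # adjacency used by endpoint connection and path refinement
        vert_faces: list[list[int]] = [[] for _ in range(n_vert)]
        for fi, tri in enumerate(F):
            for v in tri:
                vert_faces[v].append(fi)
        self._vert_faces = [np.array(fs, dtype=np.int64) for fs in vert_faces]

        edge_faces: list[list[int]] = [[] for _ in range(len(edges))]
        vert_edges: list[list[int]] = [[] for _ in range(n_vert)]
        face_edges = np.empty((len(F), 3), dtype=np.int64)
        for col, (u, v) in enumerate(((0, 1), (1, 2), (2, 0))):
            eis = edge_index(F[:, u], F[:, v])
            face_edges[:, col] = eis
            for fi, ei in enumerate(eis):
                edge_faces[int(ei)].append(fi)
        self._face_edges = face_edges
        for ei, (u, v) in enumerate(edges):
            vert_edges[u].append(ei)
            vert_edges[v].append(ei)
        self._edge_faces = [frozenset(fs) for fs in edge_faces]
        self._vert_edges = vert_edges

        fv = V[F]
        nrm = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0])
        self._face_normals = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)

        m = face_nodes.shape[1]
        iu, ju = np.triu_indices(m, 1)
        rows = face_nodes[:, iu].ravel()
        cols = face_nodes[:, ju].ravel()
        n = len(self.node_coords)
        lo = np.minimum(rows, cols).astype(np.int64)
        hi = np.maximum(rows, cols).astype(np.int64)
        # deduplicate shared-edge pairs so CSR construction cannot sum them
        _, keep = np.unique(lo * n + hi, return_index=True)
        rows, cols = lo[keep], hi[keep]
        w = np.linalg.norm(
            self.node_coords[rows] - self.node_coords[cols], axis=1
        )
        self._graph = csr_matrix((w, (rows, cols)), shape=(n, n))

    # -- constraint segment for each graph node ---------------------------

    def _node_segments(self, node_ids: np.ndarray):
        """(A, B) endpoints of the mesh edge each node may slide on.

        Mesh-vertex nodes are fixed (A == B == the vertex).
        """
        k = self.steiner_per_edge
        coords = self.node_coords[node_ids]
        A = coords.copy()
        B = coords.copy()
        if k:
            steiner = node_ids >= self._n_vert
            if steiner.any():
                ei = (node_ids[steiner] - self._n_vert) // k
                A[steiner] = self.mesh.vertices[self._edges[ei, 0]]
                B[steiner] = self.mesh.vertices[self._edges[ei, 1]]
        return A, B

    @staticmethod
    def _path_length(pts: np.ndarray) -> float:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    # element kinds used during refinement
    _FIXED, _EDGE, _VERTEX, _QUERY = 0, 1, 2, 3

    def _elem_faces(self, elem: tuple[int, int],
                    ring_faces: list) -> frozenset:
        kind, eid = elem
        if kind == self._EDGE:
            return self._edge_faces[eid]
        if kind == self._VERTEX:
            return frozenset(self._vert_faces[eid].tolist())
        if kind == self._QUERY:
            return frozenset(ring_faces[eid].tolist())
        return frozenset()

    def _common_normal(self, e1, e2, ring_faces):
        """Unit normal of a face shared by two path elements, or None."""
        fs = self._elem_faces(e1, ring_faces) & self._elem_faces(e2, ring_faces)
        if not fs:
            return None
        return self._face_normals[min(fs)]

    _FLAT_TOL = 1e-12

    def _shorten(self, pts: np.ndarray, segA: np.ndarray, segB: np.ndarray,
                 elems: list, ring_faces: list) -> float:
        """Rubber-band shortening of the path over its edge corridor.

        Sequential forward/backward sweeps; each interior point moves to
        the exact 1-D optimum on its constraint edge (closed form in the
        unfolded axial/radial coordinates), so information travels the
        whole chain in one sweep.  Between sweeps, points stuck on a mesh
        vertex may escape onto another edge of the vertex fan, and points
        whose neighbourhood is perfectly flat are deleted (the straight
        segment across a flat patch lies on the surface).  Returns the
        final path length.
        """
        m = len(pts)
        if m < 3:
            return self._path_length(pts)
        u = segB - segA
        slack = np.einsum("ij,ij->i", u, u) > 1e-24
        # doubly linked chain over path points
        nxt = list(range(1, m)) + [-1]
        prv = [-1] + list(range(m - 1))
        # unit normal of a face shared by consecutive elements ("gap"),
        # keyed by the right-hand point index
        gap_n: list = [None] * m
        for i in range(1, m):
            gap_n[i] = self._common_normal(elems[i - 1], elems[i], ring_faces)

        def chain_length() -> float:
            total, i = 0.0, 0
            while nxt[i] != -1:
                total += float(np.linalg.norm(pts[nxt[i]] - pts[i]))
                i = nxt[i]
            return total

        def update(i: int) -> None:
            A = segA[i]
            U = u[i]
            L2 = U @ U
            Lseg = np.sqrt(L2)
            uhat = U / Lseg
            P = pts[prv[i]] - A
            Q = pts[nxt[i]] - A
            pa = P @ uhat
            qa = Q @ uhat
            pr = np.sqrt(max(P @ P - pa * pa, 0.0))
            qr = np.sqrt(max(Q @ Q - qa * qa, 0.0))
            if pr + qr < 1e-12:
                t = 0.5 * (pa + qa)
            else:
                t = (pa * qr + qa * pr) / (pr + qr)
            t = min(max(t, 0.0), Lseg)
            pts[i] = A + t * uhat

        def flat_faces(elem, n) -> bool:
            for f in self._elem_faces(elem, ring_faces):
                if abs(float(self._face_normals[f] @ n)) < 1.0 - self._FLAT_TOL:
                    return False
            return True

        def escapes() -> bool:
            """Move any interior point onto a different mesh edge that
            keeps face-sharing with both neighbours when that shortens
            the path.  This lets the corridor migrate away from the
            Dijkstra tie that happened to seed it."""
            improved = False
            i = nxt[0]
            while nxt[i] != -1:
                f_prev = self._elem_faces(elems[prv[i]], ring_faces)
                f_next = self._elem_faces(elems[nxt[i]], ring_faces)
                P, Q = pts[prv[i]], pts[nxt[i]]
                cost0 = (np.linalg.norm(pts[i] - P)
                         + np.linalg.norm(pts[i] - Q))
                candidates: set[int] = set()
                for f in f_prev | f_next:
                    candidates.update(self._face_edges[f])
                kind, eid = elems[i]
                if kind == self._EDGE:
                    candidates.discard(eid)
                best = None
                for ei in candidates:
                    fe = self._edge_faces[ei]
                    if not (fe & f_prev and fe & f_next):
                        continue
                    A = self.mesh.vertices[self._edges[ei, 0]]
                    B = self.mesh.vertices[self._edges[ei, 1]]
                    t = _opt_t(P, Q, A, B)
                    x = A + t * (B - A)
                    cost = (np.linalg.norm(x - P) + np.linalg.norm(x - Q))
                    if cost < cost0 - 1e-12 and (best is None or cost < best[0]):
                        best = (cost, ei, x, A, B)
                if best is not None:
                    _, ei, x, A, B = best
                    pts[i] = x
                    segA[i], segB[i] = A, B
                    u[i] = B - A
                    slack[i] = True
                    elems[i] = (self._EDGE, ei)
                    gap_n[i] = self._common_normal(
                        elems[prv[i]], elems[i], ring_faces)
                    gap_n[nxt[i]] = self._common_normal(
                        elems[i], elems[nxt[i]], ring_faces)
                    improved = True
                i = nxt[i]
            return improved

        def deletions() -> None:
            """Drop path points that are redundant: across perfectly flat
            patches, or whenever the two neighbours lie on a common face
            (the direct segment is then on-surface) and skipping the
            point strictly shortens the path."""
            i = nxt[0]
            while i != -1 and nxt[i] != -1:
                p, q = prv[i], nxt[i]
                nl, nr = gap_n[i], gap_n[nxt[i]]
                flat_ok = (nl is not None and nr is not None
                           and abs(float(nl @ nr)) > 1.0 - self._FLAT_TOL
                           and flat_faces(elems[i], nl))
                drop = flat_ok
                new_n = nl
                if not drop:
                    fs = (self._elem_faces(elems[p], ring_faces)
                          & self._elem_faces(elems[q], ring_faces))
                    if fs:
                        direct = float(np.linalg.norm(pts[p] - pts[q]))
                        broken = (float(np.linalg.norm(pts[p] - pts[i]))
                                  + float(np.linalg.norm(pts[i] - pts[q])))
                        if direct < broken - 1e-12:
                            drop = True
                            new_n = self._face_normals[min(fs)]
                if drop:
                    nxt[p], prv[q] = q, p
                    gap_n[q] = new_n
                    i = q
                else:
                    i = nxt[i]

        def sweep_to_convergence(budget: int, length: float) -> float:
            for _ in range(budget):
                i = nxt[0]
                while nxt[i] != -1:
                    if slack[i]:
                        update(i)
                    i = nxt[i]
                while prv[i] != -1:
                    if slack[i] and nxt[i] != -1:
                        update(i)
                    i = prv[i]
                new_length = chain_length()
                if length - new_length <= self.refine_tol * max(length, 1e-12):
                    return new_length
                length = new_length
            return length

        length = chain_length()
        for _ in range(12):  # corridor-migration rounds
            deletions()
            length = sweep_to_convergence(self.max_sweeps, length)
            if not escapes():
                deletions()
                length = min(length, chain_length())
                break
        return length

    # -- queries -----------------------------------------------------------

    def _snap(self, points: np.ndarray):
        proj, dist, tri, tied = self.mesh.closest_point(points, ties=True)
        off = dist > self.snap_tolerance
        if off.any():
            i = int(np.flatnonzero(off)[0])
            raise MeshError(
                f"point {points[i]} is {dist[i]:.2f} mm from the surface "
                f"(snap tolerance {self.snap_tolerance} mm)"
            )
        return proj, tri, tied

    def pair_distances(self, points: np.ndarray,
                       pairs: np.ndarray) -> np.ndarray:
        """Geodesic distance for each (i, j) row of ``pairs``."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        n_pts = len(points)
        _, tri, tied = self._snap(points)

        # augmented graph: one virtual node per query point, connected by
        # straight segments to every graph node in the one-ring
        # neighbourhood of its containing triangle(s) — all triangles
        # tied at minimal distance count, so a point on a shared edge or
        # seam connects symmetrically
        n = self._graph.shape[0]
        rows_l, cols_l, w_l = [], [], []
        ring_faces: list[np.ndarray] = []
        for i in range(n_pts):
            verts = np.unique(self.mesh.triangles[tied[i]].ravel())
            fs = np.unique(np.concatenate(
                [self._vert_faces[v] for v in verts]
            ))
            ring_faces.append(fs)
            nodes = np.unique(self._face_nodes[fs].ravel())
            rows_l.append(np.full(len(nodes), n + i))
            cols_l.append(nodes)
            w_l.append(
                np.linalg.norm(points[i] - self.node_coords[nodes], axis=1)
            )
        rows = np.concatenate(rows_l)
        cols = np.concatenate(cols_l)
        w = np.concatenate(w_l)
        base = coo_matrix(self._graph)
        full = csr_matrix(
            (np.concatenate([base.data, w]),
             (np.concatenate([base.row, rows]),
              np.concatenate([base.col, cols]))),
            shape=(n + n_pts, n + n_pts),
        )
        sources = np.unique(pairs[:, 0])
        D, preds = dijkstra(full, directed=False, indices=n + sources,
                            return_predecessors=True)
        src_row = {s: r for r, s in enumerate(sources)}

        out = np.empty(len(pairs))
        chord = np.linalg.norm(
            points[pairs[:, 0]] - points[pairs[:, 1]], axis=1
        )
        for r, (i, j) in enumerate(pairs):
            if chord[r] == 0.0:
                out[r] = 0.0
                continue
            row = src_row[int(i)]
            d = D[row, n + j]
            if not np.isfinite(d):
                raise MeshError(
                    "no surface path between query points "
                    f"{i} and {j} (disconnected mesh components)"
                )
            if self.refine:
                node_path = self._walk(preds[row], n + int(i), n + int(j))
                interior = np.array(node_path[1:-1], dtype=np.int64)
                # a path may pass through another query point's virtual
                # node; treat it as a near-surface point at that position
                virt = interior >= n
                coords = np.empty((len(interior), 3))
                coords[~virt] = self.node_coords[interior[~virt]]
                coords[virt] = points[interior[virt] - n]
                A = coords.copy()
                B = coords.copy()
                if (~virt).any():
                    a_m, b_m = self._node_segments(interior[~virt])
                    A[~virt] = a_m
                    B[~virt] = b_m
                k = self.steiner_per_edge
                elems: list[tuple[int, int]] = [(self._QUERY, int(i))]
                for nid, is_virt in zip(interior, virt):
                    if is_virt:
                        elems.append((self._QUERY, int(nid - n)))
                    elif nid < self._n_vert:
                        elems.append((self._VERTEX, int(nid)))
                    else:
                        elems.append((self._EDGE, int((nid - self._n_vert) // k)))
                elems.append((self._QUERY, int(j)))
                pts_path = np.vstack([points[i], coords, points[j]])
                segA = np.vstack([points[i][None], A, points[j][None]])
                segB = np.vstack([points[i][None], B, points[j][None]])
                d = min(d, self._shorten(pts_path, segA, segB,
                                         elems, ring_faces))
            if tri[j] in ring_faces[i]:
                # neighbouring triangles: the straight segment tracks the
                # surface to within the local mesh resolution
                d = min(d, chord[r])
            out[r] = max(d, chord[r])  # numerical guard: polyline >= chord
        return out

    @staticmethod
    def _walk(pred_row: np.ndarray, src: int, dst: int) -> list[int]:
        path = [dst]
        while path[-1] != src:
            p = pred_row[path[-1]]
            if p < 0:
                raise MeshError("broken predecessor chain")
            path.append(int(p))
        path.reverse()
        return path

    def pairwise(self, points: np.ndarray) -> np.ndarray:
        """Full symmetric geodesic distance matrix between query points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n_pts = len(points)
        iu, ju = np.triu_indices(n_pts, 1)
        pairs = np.column_stack([iu, ju])
        D = np.zeros((n_pts, n_pts))
        if len(pairs):
            d = self.pair_distances(points, pairs)
            D[iu, ju] = d
            D[ju, iu] = d
        return D

    def distance(self, p, q) -> float:
        """Geodesic distance between two points (mm)."""
        return float(
            self.pair_distances(np.vstack([p, q]), np.array([[0, 1]]))[0]
        )


def geodesic_distance(mesh: FaceMesh, p, q, steiner_per_edge: int = 1,
                      snap_tolerance: float = SNAP_TOLERANCE) -> float:
    """One-shot geodesic distance; builds a solver per call.

    Prefer :class:`GeodesicSolver` when measuring many pairs on one mesh.
    """
    return GeodesicSolver(
        mesh, steiner_per_edge=steiner_per_edge, snap_tolerance=snap_tolerance
    ).distance(p, q)
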