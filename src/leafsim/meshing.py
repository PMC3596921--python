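"""Triangular leaf meshes: constrained Delaunay construction and optimization.

The leaf polygon is triangulated by incremental insertion (Bowyer–Watson with
a super-triangle), the polygon edges are recovered by edge flips, and
triangles outside the polygon are culled — a constrained Delaunay
triangulation of the leaf interior.  Because the boundary samples alone
usually produce long, narrow triangles, :func:`optimize` repeats two steps —
(1) relocate interior vertices, (2) modify triangle connectivity by Delaunay
edge flips — optionally interleaved with interior point insertion down to a
target edge length, until the mesh has even-sized, well-shaped triangles.

Boundary vertices are never moved: the optimized mesh still conforms exactly
to the input polygon.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import shapely

from .errors import InvalidInputError

__all__ = ["TriMesh", "MeshQuality", "triangulate", "optimize", "quality"]

# relative tolerance for in-circumcircle tests; ties count as "on the circle"
_INCIRCLE_RTOL = 1e-12


@dataclass
class TriMesh:
    """A triangulated leaf.

    Attributes
    ----------
    vertices
        (n, 2) planar coordinates, or (n, 3) once the mesh has been
        deformed.  Meshing itself is purely two-dimensional.
    triangles
        (m, 3) integer vertex indices, counter-clockwise in the plane.
    boundary
        (n,) bool, True for vertices lying on the input polygon.
    uv
        (n, 2) texture coordinates in [0, 1]^2 used for mask lookup.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: np.ndarray
    uv: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.boundary = np.asarray(self.boundary, dtype=bool)
        self.uv = np.asarray(self.uv, dtype=float)

    @property
    def vertices2(self) -> np.ndarray:
        return self.vertices[:, :2]

    @property
    def vertices3(self) -> np.ndarray:
        if self.vertices.shape[1] == 3:
            return self.vertices
        z = np.zeros((len(self.vertices), 1))
        return np.hstack([self.vertices, z])

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.boundary.copy(),
            self.uv.copy(),
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        return replace(self, vertices=np.asarray(vertices, dtype=float))


@dataclass(frozen=True)
class MeshQuality:
    min_angle: float  # degrees
    edge_length_cv: float  # stdev / mean of unique edge lengths
    triangle_count: int


# ---------------------------------------------------------------------------
# geometric predicates
# ---------------------------------------------------------------------------

def _signed_area(pa, pb, pc):
    return 0.5 * (
        (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])
    )


def _in_circumcircle(pa, pb, pc, pd, scale4) -> bool:
    """True iff pd lies strictly inside the circumcircle of CCW (pa,pb,pc)."""
    ax, ay = pa[0] - pd[0], pa[1] - pd[1]
    bx, by = pb[0] - pd[0], pb[1] - pd[1]
    cx, cy = pc[0] - pd[0], pc[1] - pd[1]
    det = (
        (ax * ax + ay * ay) * (bx * cy - by * cx)
        - (bx * bx + by * by) * (ax * cy - ay * cx)
        + (cx * cx + cy * cy) * (ax * by - ay * bx)
    )
    return det > _INCIRCLE_RTOL * scale4


def _orient(pa, pb, pc) -> float:
    return (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])


def _proper_intersect(p1, p2, p3, p4) -> bool:
    """Strict interior crossing of open segments p1p2 and p3p4."""
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def _ccw(tri, P):
    a, b, c = tri
    if _signed_area(P[a], P[b], P[c]) < 0:
        return (a, c, b)
    return (a, b, c)


# ---------------------------------------------------------------------------
# Bowyer–Watson incremental insertion
# ---------------------------------------------------------------------------

def _bowyer_watson(points: np.ndarray) -> list[tuple[int, int, int]]:
    """Delaunay triangulation of the convex hull by incremental insertion."""
    n = len(points)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    c = 0.5 * (lo + hi)
    r = max(np.max(hi - lo), 1e-12) * 10.0
    sup = np.array([[c[0] - 3 * r, c[1] - r],
                    [c[0] + 3 * r, c[1] - r],
                    [c[0], c[1] + 3 * r]])
    P = np.vstack([points, sup])
    # tolerance scale from the data extent, not the far-away super vertices
    scale4 = max(np.max(hi - lo), 1e-12) ** 4
    tris = [(n, n + 1, n + 2)]
    for i in range(n):
        p = P[i]
        # strict containment with a tiny relative slack so near-cocircular
        # configurations are resolved deterministically by insertion order
        bad = [t for t in tris
               if _in_circumcircle(P[t[0]], P[t[1]], P[t[2]], p, scale4)]
        if not bad:
            # point on/outside every circumcircle: numerically degenerate;
            # fall back to locating the containing triangle and splitting it
            for t in tris:
                a, b, cc = t
                if (
                    _orient(P[a], P[b], p) >= 0
                    and _orient(P[b], P[cc], p) >= 0
                    and _orient(P[cc], P[a], p) >= 0
                ):
                    bad = [t]
                    break
            if not bad:
                raise InvalidInputError("triangulation failed to locate point")
        edge_count: dict[tuple[int, int], int] = defaultdict(int)
        for t in bad:
            for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_count[tuple(sorted(e))] += 1
        cavity = [e for e, k in edge_count.items() if k == 1]
        badset = set(bad)
        tris = [t for t in tris if t not in badset]
        for a, b in cavity:
            tris.append(_ccw((a, b, i), P))
    return [t for t in tris if max(t) < n]


def _edge_map(tris) -> dict[tuple[int, int], list[int]]:
    em: dict[tuple[int, int], list[int]] = defaultdict(list)
    for ti, (a, b, c) in enumerate(tris):
        for e in ((a, b), (b, c), (c, a)):
            em[tuple(sorted(e))].append(ti)
    return em


def _flip(tris, em, edge, P) -> bool:
    """Flip the interior edge if its quad is strictly convex."""
    t1, t2 = em[edge]
    a, b = edge
    p = next(v for v in tris[t1] if v not in edge)
    q = next(v for v in tris[t2] if v not in edge)
    if not _proper_intersect(P[p], P[q], P[a], P[b]):
        return False
    tris[t1] = _ccw((p, q, a), P)
    tris[t2] = _ccw((p, q, b), P)
    return True


def _recover_segment(tris, seg, P, max_iter=10000):
    a, b = seg
    for _ in range(max_iter):
        em = _edge_map(tris)
        if tuple(sorted(seg)) in em:
            return
        progressed = False
        for e, owners in list(em.items()):
            if len(owners) != 2 or a in e or b in e:
                continue
            if _proper_intersect(P[a], P[b], P[e[0]], P[e[1]]):
                if _flip(tris, em, e, P):
                    progressed = True
                    break
        if not progressed:
            raise InvalidInputError(
                f"could not recover boundary edge {seg}; polygon may be degenerate"
            )
    raise InvalidInputError(f"edge recovery did not terminate for {seg}")


def triangulate(boundary: np.ndarray) -> TriMesh:
    """Constrained Delaunay triangulation of a simple closed polygon.

    The polygon vertices become mesh vertices 0..n-1 in input order; the
    triangle set covers exactly the polygon interior.  uv coordinates are
    assigned by normalizing (x, y) into the polygon's bounding box.
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise InvalidInputError("boundary must be an (n>=4, 2) array")
    poly = shapely.Polygon(pts)
    if (not poly.is_valid) or poly.area <= 0:
        raise InvalidInputError("boundary polygon is self-intersecting or degenerate")

    tris = _bowyer_watson(pts)
    n = len(pts)
    for k in range(n):
        _recover_segment(tris, (k, (k + 1) % n), pts)

    # cull triangles whose centroid falls outside the (possibly concave) polygon
    kept = []
    for t in tris:
        cx, cy = pts[list(t)].mean(axis=0)
        if shapely.contains_xy(poly, cx, cy):
            kept.append(_ccw(t, pts))
    if not kept:
        raise InvalidInputError("triangulation produced no interior triangles")

    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    uv = (pts - lo) / span
    return TriMesh(
        vertices=pts.copy(),
        triangles=np.array(kept, dtype=np.int64),
        boundary=np.ones(n, dtype=bool),
        uv=uv,
    )


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def _triangle_angles(P, tris) -> np.ndarray:
    """Interior angles in degrees, shape (m, 3)."""
    a = P[tris[:, 0]]
    b = P[tris[:, 1]]
    c = P[tris[:, 2]]
    out = []
    for v0, v1, v2 in ((a, b, c), (b, c, a), (c, a, b)):
        u = v1 - v0
        w = v2 - v0
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        out.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.stack(out, axis=1)


def quality(mesh: TriMesh) -> MeshQuality:
    """Minimum interior angle and edge-length coefficient of variation."""
    if len(mesh.triangles) == 0:
        raise InvalidInputError("mesh has no triangles")
    angles = _triangle_angles(mesh.vertices2, mesh.triangles)
    lengths = mesh.edge_lengths()
    mean = lengths.mean()
    cv = float(lengths.std() / mean) if mean > 0 else 0.0
    return MeshQuality(
        min_angle=float(angles.min()),
        edge_length_cv=cv,
        triangle_count=len(mesh.triangles),
    )


# ---------------------------------------------------------------------------
# the two-step optimization loop
# ---------------------------------------------------------------------------

def _min_incident_angle(P, tris, tri_ids):
    sub = np.array([tris[t] for t in tri_ids], dtype=np.int64)
    return _triangle_angles(P, sub).min()


def _smooth_pass(P, tris, boundary, vert_tris, scale) -> float:
    """Guarded area-weighted Laplacian relocation of interior vertices.

    A move is rejected if it would invert an incident triangle or reduce the
    minimum incident interior angle, so mesh minimum angle is non-decreasing
    across passes.  Returns the largest accepted displacement.
    """
    max_move = 0.0
    for v in range(len(P)):
        if boundary[v] or not vert_tris[v]:
            continue
        ids = vert_tris[v]
        areas = []
        cents = []
        for t in ids:
            a, b, c = tris[t]
            ar = _signed_area(P[a], P[b], P[c])
            areas.append(ar)
            cents.append((P[a] + P[b] + P[c]) / 3.0)
        areas = np.array(areas)
        total = areas.sum()
        if total <= 0:
            continue
        target = (areas[:, None] * np.array(cents)).sum(axis=0) / total
        old = P[v].copy()
        before = _min_incident_angle(P, tris, ids)
        P[v] = target
        ok = all(
            _signed_area(P[tris[t][0]], P[tris[t][1]], P[tris[t][2]]) > 0
            for t in ids
        )
        if ok and _min_incident_angle(P, tris, ids) >= before - 1e-12:
            max_move = max(max_move, float(np.linalg.norm(target - old)))
        else:
            P[v] = old
    return max_move


def _flip_pass(P, tris, scale4) -> int:
    """Delaunay edge flips until no interior edge violates the criterion."""
    flips = 0
    for _ in range(10 * len(tris) + 10):
        em = _edge_map(tris)
        did = False
        for e in sorted(em):
            owners = em[e]
            if len(owners) != 2:
                continue
            t1, t2 = owners
            a, b = e
            p = next(v for v in tris[t1] if v not in e)
            q = next(v for v in tris[t2] if v not in e)
            tri = _ccw((a, b, p), P)
            if _in_circumcircle(P[tri[0]], P[tri[1]], P[tri[2]], P[q], scale4):
                if _flip(tris, em, e, P):
                    flips += 1
                    did = True
                    break
        if not did:
            return flips
    return flips


def _vertex_tri_map(tris, n):
    vt = [[] for _ in range(n)]
    for ti, t in enumerate(tris):
        for v in t:
            vt[v].append(ti)
    return vt


def _split_triangle(P_list, tris, boundary_list, ti):
    """Insert the centroid of triangle ti, splitting it into three."""
    a, b, c = tris[ti]
    P = np.asarray(P_list)
    cent = (P[a] + P[b] + P[c]) / 3.0
    new = len(P_list)
    P_list.append(cent)
    boundary_list.append(False)
    tris[ti] = (a, b, new)
    tris.append((b, c, new))
    tris.append((c, a, new))


def optimize(
    mesh: TriMesh,
    iterations: int = 160,
    target_edge: float | None = None,
) -> TriMesh:
    """Repeat (relocate vertices; modify connectivity) for ``iterations`` passes.

    When ``target_edge`` is given, centroids of triangles whose longest edge
    exceeds 1.5x the target are inserted between passes until the median
    edge length reaches the target.  Boundary vertices are never touched;
    passes stop early once the mesh no longer changes.
    """
    if iterations < 0:
        raise InvalidInputError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy()

    P_list = [p.copy() for p in mesh.vertices2]
    tris = [tuple(t) for t in mesh.triangles]
    boundary_list = list(mesh.boundary)
    scale = float(np.max(np.ptp(mesh.vertices2, axis=0)))
    scale4 = max(scale, 1e-12) ** 4

    for _ in range(iterations):
        inserted = False
        if target_edge is not None:
            P = np.asarray(P_list)
            longest = np.array([
                max(
                    np.linalg.norm(P[t[0]] - P[t[1]]),
                    np.linalg.norm(P[t[1]] - P[t[2]]),
                    np.linalg.norm(P[t[2]] - P[t[0]]),
                )
                for t in tris
            ])
            elens = _unique_edge_lengths(P, tris)
            if np.median(elens) > target_edge:
                oversized = np.nonzero(longest > 1.5 * target_edge)[0]
                if len(oversized) == 0:
                    oversized = [int(np.argmax(longest))]
                for ti in oversized:
                    _split_triangle(P_list, tris, boundary_list, int(ti))
                inserted = True

        P = np.asarray(P_list, dtype=float)
        flips = _flip_pass(P, tris, scale4)
        vt = _vertex_tri_map(tris, len(P))
        moved = _smooth_pass(P, tris, boundary_list, vt, scale)
        flips += _flip_pass(P, tris, scale4)
        P_list = [p for p in P]
        if not inserted and moved < 1e-10 * max(scale, 1.0) and flips == 0:
            break

    P = np.asarray(P_list, dtype=float)
    lo = mesh.vertices2[mesh.boundary].min(axis=0)
    span = mesh.vertices2[mesh.boundary].max(axis=0) - lo
    span[span == 0] = 1.0
    uv = np.clip((P - lo) / span, 0.0, 1.0)
    out = TriMesh(
        vertices=P,
        triangles=np.array([_ccw(t, P) for t in tris], dtype=np.int64),
        boundary=np.array(boundary_list, dtype=bool),
        uv=uv,
    )
    # boundary vertices are pinned: restore bit-identical coordinates
    out.vertices[: len(mesh.vertices2)][mesh.boundary] = mesh.vertices2[mesh.boundary]
    return out


def _unique_edge_lengths(P, tris):
    e = set()
    for a, b, c in tris:
        for u, v in ((a, b), (b, c), (c, a)):
            e.add((min(u, v), max(u, v)))
    e = np.array(sorted(e))
    return np.linalg.norm(P[e[:, 0]] - P[e[:, 1]], axis=1)
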