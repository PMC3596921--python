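"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: the Delaunay oracle
enumerates every vertex triple and tests the empty-circumcircle property
directly, and the segment-intersection oracle is a plain all-pairs check.
"""
from itertools import combinations

import numpy as np


def brute_force_delaunay(points, rtol=1e-10):
    """All Delaunay triangles of a planar point set by exhaustive search.

    A triple is a Delaunay triangle iff no other point lies strictly inside
    its circumcircle.  Returns a set of frozensets of vertex indices.
    Assumes no four points are exactly co-circular (generic position).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    tris = set()
    for i, j, k in combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area2) < 1e-14:
            continue
        # circumcenter via perpendicular bisectors in the frame anchored at a
        B = b - a
        C = c - a
        d = 2.0 * area2
        ux = (np.dot(B, B) * C[1] - np.dot(C, C) * B[1]) / d
        uy = (np.dot(C, C) * B[0] - np.dot(B, B) * C[0]) / d
        center = a + np.array([ux, uy])
        r2 = np.sum((a - center) ** 2)
        d2 = np.sum((pts - center) ** 2, axis=1)
        d2[[i, j, k]] = np.inf
        if np.min(d2) > r2 * (1.0 - rtol):
            tris.add(frozenset((i, j, k)))
    return tris


def segments_properly_intersect(p1, p2, p3, p4):
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return d1 * d2 < 0 and d3 * d4 < 0


def polygon_is_simple(points):
    """All-pairs test that no two non-adjacent closed-loop edges cross."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (1, n - 1):
                continue
            if segments_properly_intersect(*edges[i], *edges[j]):
                return False
    return True


def triangulation_area(vertices, triangles):
    P = np.asarray(vertices, dtype=float)[:, :2]
    total = 0.0
    for a, b, c in triangles:
        total += 0.5 * abs(
            (P[b][0] - P[a][0]) * (P[c][1] - P[a][1])
            - (P[b][1] - P[a][1]) * (P[c][0] - P[a][0])
        )
    return total


def _max_incircle_violation(pts, tri):
    """Largest in-circle determinant of any other vertex against ``tri``.

    Positive values mean some vertex sits inside the circumcircle; values
    near zero mean the worst offender is essentially co-circular.
    """
    i, j, k = tri
    a, b, c = pts[i], pts[j], pts[k]
    if (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]) < 0:
        b, c = c, b
    worst = -np.inf
    for m in range(len(pts)):
        if m in (i, j, k):
            continue
        d = pts[m]
        ax, ay = a[0] - d[0], a[1] - d[1]
        bx, by = b[0] - d[0], b[1] - d[1]
        cx, cy = c[0] - d[0], c[1] - d[1]
        det = (
            (ax * ax + ay * ay) * (bx * cy - by * cx)
            - (bx * bx + by * by) * (ax * cy - ay * cx)
            + (cx * cx + cy * cy) * (ax * by - ay * bx)
        )
        worst = max(worst, det)
    return worst


def delaunay_sets_equivalent(points, tris_a, tris_b, rtol=1e-10):
    """True if two triangle sets agree up to co-circular ties.

    Any triangle present in only one set must still satisfy the
    empty-circumcircle property to within ``rtol`` of the squared data
    extent — i.e. the disagreement is a tie, not a structural error.
    """
    if tris_a == tris_b:
        return True
    pts = np.asarray(points, dtype=float)
    scale4 = float(np.max(pts.max(axis=0) - pts.min(axis=0))) ** 4
    return all(
        _max_incircle_violation(pts, tuple(t)) <= rtol * scale4
        for t in tris_a ^ tris_b
    )
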