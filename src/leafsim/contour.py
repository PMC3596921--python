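"""Closed-curve reconstruction of a leaf boundary.

A scanned or hand-picked set of edge key points is turned into a smooth
periodic cubic spline that interpolates every point, and the spline is then
resampled uniformly in arc length to produce the polygon handed to
triangulation.  Chord-length parameterization keeps the parameter speed
roughly proportional to geometric distance, which makes the arc-length
inversion table accurate even for modest table sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import CubicSpline

from .errors import InvalidInputError

__all__ = ["KeyPointSet", "ClosedCurve", "fit_closed_bspline", "sample_curve"]


@dataclass(frozen=True)
class KeyPointSet:
    """An ordered, closed loop of 2D key points on the leaf edge.

    Parameters
    ----------
    points
        Array of shape (n, 2), n >= 4, in traversal order.  The implicit
        closing segment from the last point back to the first is part of
        the loop.
    closed
        Always True for leaf outlines; kept for interface clarity.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError("key points must be an (n, 2) array")
        if len(pts) < 4:
            raise InvalidInputError(
                f"need at least 4 key points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("key points must be finite")
        closing = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closing, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise InvalidInputError("consecutive key points coincide")
        if not shapely.Polygon(pts).is_valid:
            raise InvalidInputError("key-point polygon is self-intersecting")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ClosedCurve:
    """A periodic parametric curve on u in [0, 1).

    ``key_params`` holds the parameter value assigned to each input key
    point, so interpolation can be checked exactly.
    """

    spline: CubicSpline = field(repr=False)
    key_params: np.ndarray

    def __call__(self, u) -> np.ndarray:
        return self.spline(np.mod(u, 1.0))


def fit_closed_bspline(key_points: KeyPointSet) -> ClosedCurve:
    """Fit a periodic cubic spline interpolating every key point.

    Chord-length parameterization: the parameter assigned to key point k is
    the cumulative polygon length up to k, normalized by the full closed
    length.  The spline is C2-continuous across the seam u = 0 == 1.
    """
    if not isinstance(key_points, KeyPointSet):
        key_points = KeyPointSet(np.asarray(key_points, dtype=float))
    pts = key_points.points
    loop = np.vstack([pts, pts[:1]])
    chords = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chords)])
    t /= t[-1]
    spline = CubicSpline(t, loop, axis=0, bc_type="periodic")
    return ClosedCurve(spline=spline, key_params=t[:-1])


def sample_curve(
    curve: ClosedCurve, n: int, table_size: int = 1024
) -> np.ndarray:
    """Resample a closed curve into ``n`` points ~uniform in arc length.

    A cumulative chord-length table over ``table_size`` dense segments is
    inverted with linear interpolation.  The first sample is exactly
    curve(0), i.e. the first key point.
    """
    if n < 4:
        raise InvalidInputError(f"need at least 4 samples, got {n}")
    u_dense = np.linspace(0.0, 1.0, table_size + 1)
    p_dense = curve(u_dense)
    seg = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s_targets = np.linspace(0.0, cum[-1], n, endpoint=False)
    u_samples = np.interp(s_targets, cum, u_dense)
    return curve(u_samples)
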