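"""Procedural stand-ins for scanned leaf data.

Real inputs to this pipeline are a scanned leaf contour, a hand-painted
grayscale mask, and a user-written senescence specification.  This module
generates all three programmatically — an ellipse or lobed "maple"
silhouette, masks with dark edge bands or a bright vein corridor, and a
feed-forward senescence chain ending in an absorbing fallen state — so
every other module is exercisable and testable with no external data.

The maple silhouette is this package's own construction,
r(theta) = R * (1 - depth * |sin(k * theta / 2)|^p), which produces k lobes
of relative depth ``depth``; a small seeded radial jitter (at most 2% of R)
breaks exact symmetry the way a real scan would.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .contour import KeyPointSet
from .deformation import MaskMap
from .errors import InvalidInputError
from .seasons import LeafState, SenescenceSpec

__all__ = [
    "OutlineRecipe",
    "MaskRecipe",
    "make_outline",
    "make_mask",
    "make_default_spec",
]


@dataclass(frozen=True)
class OutlineRecipe:
    """Parameters for a synthetic leaf outline.

    ``shape`` is "ellipse" (semi-axes a, b) or "maple" (base radius a,
    ``lobes`` lobes of relative ``lobe_depth`` with exponent
    ``lobe_sharpness``).  ``jitter`` is the radial perturbation amplitude
    as a fraction of the base radius, capped at 0.02.
    """

    shape: str = "maple"
    a: float = 1.0
    b: float = 0.6
    lobes: int = 5
    lobe_depth: float = 0.5
    lobe_sharpness: float = 1.5
    n_keypoints: int = 32
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("ellipse", "maple"):
            raise InvalidInputError(f"unknown shape {self.shape!r}")
        if self.a <= 0 or self.b <= 0:
            raise InvalidInputError("semi-axes must be positive")
        if not (0.0 <= self.lobe_depth < 1.0):
            raise InvalidInputError("lobe depth must lie in [0, 1)")
        if self.shape == "maple" and self.n_keypoints < 8:
            raise InvalidInputError("maple outlines need >= 8 key points")
        if self.n_keypoints < 4:
            raise InvalidInputError("need >= 4 key points")
        if not (0.0 <= self.jitter <= 0.02):
            raise InvalidInputError("jitter must lie in [0, 0.02]")
        if self.lobes < 1:
            raise InvalidInputError("need >= 1 lobe")


@dataclass(frozen=True)
class MaskRecipe:
    """Parameters for a synthetic grayscale mask.

    Patterns: "uniform" paints the interior with ``uniform_value``;
    "dark-edge" paints ``dark`` inside a band within ``edge_band`` of the
    boundary (in outline units) and ``bright`` elsewhere — emulating a mask
    that curls leaf corners and edges; "bright-vein" paints ``bright``
    inside the vertical midrib corridor of half-width ``vein_half_width``
    and ``dark`` elsewhere — keeping the vein stiff while the flanks curl.
    """

    pattern: str = "dark-edge"
    width: int = 128
    height: int = 128
    edge_band: float = 0.15
    vein_half_width: float = 0.08
    dark: int = 16
    bright: int = 200
    uniform_value: int = 128

    def __post_init__(self):
        if self.pattern not in ("uniform", "dark-edge", "bright-vein"):
            raise InvalidInputError(f"unknown mask pattern {self.pattern!r}")
        if self.width < 1 or self.height < 1:
            raise InvalidInputError("mask must have at least one pixel")
        for name in ("dark", "bright", "uniform_value"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise InvalidInputError(f"{name} must lie in [0, 255]")
        if self.dark >= self.bright:
            raise InvalidInputError("dark value must be below bright value")
        if self.edge_band <= 0 or self.vein_half_width <= 0:
            raise InvalidInputError("band widths must be positive")


def make_outline(recipe: OutlineRecipe) -> KeyPointSet:
    """Generate a closed, non-self-intersecting, CCW key-point loop."""
    n = recipe.n_keypoints
    theta = 2.0 * np.pi * np.arange(n) / n
    if recipe.shape == "ellipse":
        x = recipe.a * np.cos(theta)
        y = recipe.b * np.sin(theta)
        r_base = np.hypot(x, y)
        ux, uy = x / r_base, y / r_base
        r = r_base
    else:
        r = recipe.a * (
            1.0
            - recipe.lobe_depth
            * np.abs(np.sin(recipe.lobes * theta / 2.0)) ** recipe.lobe_sharpness
        )
        ux, uy = np.cos(theta), np.sin(theta)
    if recipe.jitter > 0:
        rng = np.random.default_rng(recipe.seed)
        r = r + rng.uniform(-1.0, 1.0, n) * recipe.jitter * recipe.a
    pts = np.column_stack([r * ux, r * uy])
    return KeyPointSet(pts)


def make_mask(recipe: MaskRecipe, boundary: np.ndarray) -> MaskMap:
    """Rasterize a mask over the boundary polygon's bounding box.

    Pixels outside the polygon read 255.  Distances to the boundary are
    exact point-to-segment distances, so the dark edge band does not depend
    on raster resolution.
    """
    pts = np.asarray(boundary, dtype=float)
    poly = shapely.Polygon(pts)
    if (not poly.is_valid) or poly.area <= 0:
        raise InvalidInputError("boundary polygon is degenerate")
    W, H = recipe.width, recipe.height
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    # pixel centers; row 0 is the top image row, uv origin at lower-left
    u = (np.arange(W) + 0.5) / W
    v = (H - 1 - np.arange(H) + 0.5) / H
    X = lo[0] + u[None, :] * span[0]
    Y = lo[1] + v[:, None] * span[1]
    XX = np.broadcast_to(X, (H, W))
    YY = np.broadcast_to(Y, (H, W))
    inside = shapely.contains_xy(poly, XX.ravel(), YY.ravel()).reshape(H, W)

    out = np.full((H, W), 255, dtype=np.uint8)
    if recipe.pattern == "uniform":
        out[inside] = recipe.uniform_value
    elif recipe.pattern == "dark-edge":
        pix = shapely.points(
            np.column_stack([XX.ravel()[inside.ravel()], YY.ravel()[inside.ravel()]])
        )
        d = shapely.distance(pix, poly.exterior)
        vals = np.where(d < recipe.edge_band, recipe.dark, recipe.bright)
        out[inside] = vals.astype(np.uint8)
    else:  # bright-vein
        midrib = poly.centroid.x
        vals = np.where(
            np.abs(XX - midrib) < recipe.vein_half_width, recipe.bright, recipe.dark
        )
        out[inside] = vals[inside].astype(np.uint8)
    return MaskMap(out)


_STATE_NAMES = ["green", "light-green", "yellow", "orange", "red", "brown"]


def make_default_spec(n_states: int = 4, seed: int = 0) -> SenescenceSpec:
    """A feed-forward senescence chain ending in an absorbing fallen state.

    Half-life corners are drawn uniformly in [5, 60] time units; transition
    weights favor the forward move (i -> i+1) with a small chance of
    skipping one state.  Deterministic for a fixed seed.
    """
    if n_states < 2:
        raise InvalidInputError("need at least 2 states (one must be absorbing)")
    rng = np.random.default_rng(seed)
    names = [
        _STATE_NAMES[i % len(_STATE_NAMES)] if i < n_states - 1 else "fallen"
        for i in range(n_states)
    ]
    # disambiguate repeated palette names for long chains
    seen: dict[str, int] = {}
    uniq = []
    for nm in names:
        seen[nm] = seen.get(nm, 0) + 1
        uniq.append(nm if seen[nm] == 1 else f"{nm}-{seen[nm]}")
    states = [
        LeafState(index=i, name=uniq[i], texture_label=f"texture_{i}")
        for i in range(n_states)
    ]
    tau = rng.uniform(5.0, 60.0, size=(n_states, 4))
    X = np.zeros((n_states, n_states, 4))
    for i in range(n_states - 1):
        X[i, i + 1] = rng.uniform(0.6, 0.95, size=4)
        if i + 2 < n_states:
            X[i, i + 2] = rng.uniform(0.02, 0.2, size=4)
    return SenescenceSpec(
        states=states,
        tau_corners=tau,
        X_corners=X,
        absorbing=frozenset({n_states - 1}),
    )
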