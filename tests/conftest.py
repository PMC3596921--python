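import numpy as np
import pytest
import shapely
from hypothesis import settings
from scipy.spatial import Delaunay as ScipyDelaunay

import leafsim as ls

settings.register_profile("leafsim", deadline=None, derandomize=True)
settings.load_profile("leafsim")


@pytest.fixture(scope="session")
def circle_keypoints():
    theta = 2 * np.pi * np.arange(8) / 8
    return ls.KeyPointSet(np.column_stack([np.cos(theta), np.sin(theta)]))


@pytest.fixture(scope="session")
def circle_curve(circle_keypoints):
    return ls.fit_closed_bspline(circle_keypoints)


@pytest.fixture(scope="session")
def square_boundary():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def maple_boundary():
    outline = ls.make_outline(
        ls.OutlineRecipe(shape="maple", n_keypoints=32, seed=7, jitter=0.02)
    )
    curve = ls.fit_closed_bspline(outline)
    return ls.sample_curve(curve, 48)


@pytest.fixture(scope="session")
def maple_mesh(maple_boundary):
    mesh = ls.triangulate(maple_boundary)
    return ls.optimize(mesh, iterations=60, target_edge=0.12)


@pytest.fixture(scope="session")
def dark_edge_mask(maple_boundary):
    return ls.make_mask(ls.MaskRecipe(pattern="dark-edge"), maple_boundary)


@pytest.fixture(scope="session")
def bright_vein_mask(maple_boundary):
    return ls.make_mask(ls.MaskRecipe(pattern="bright-vein"), maple_boundary)


@pytest.fixture(scope="session")
def sim_config():
    return ls.SimConfig(external_force=ls.constant_force([0.0, 0.0, -2.0]))


@pytest.fixture(scope="session")
def dark_edge_run(maple_mesh, dark_edge_mask, sim_config):
    """500-step deformation under the dark-edge mask, every step recorded."""
    return ls.simulate(
        maple_mesh, dark_edge_mask, sim_config, n_steps=500, snapshot_every=1
    )


@pytest.fixture(scope="session")
def bright_vein_run(maple_mesh, bright_vein_mask, sim_config):
    return ls.simulate(
        maple_mesh, bright_vein_mask, sim_config, n_steps=500, snapshot_every=500
    )


@pytest.fixture(scope="session")
def sliver_mesh():
    """A unit square whose interior row of points forces ~20:1 slivers.

    Boundary points every 0.1 along the square; interior points sit 0.005
    above the bottom edge at 0.1 spacing, so the triangles between them and
    the bottom edge have a 20:1 base-to-height ratio.  Connectivity comes
    from scipy's Delaunay (an implementation independent of the package).
    """
    edge = np.arange(0.0, 1.0, 0.1)
    boundary = np.concatenate([
        np.column_stack([edge, np.zeros_like(edge)]),
        np.column_stack([np.ones_like(edge), edge]),
        np.column_stack([1.0 - edge, np.ones_like(edge)]),
        np.column_stack([np.zeros_like(edge), 1.0 - edge]),
    ])
    interior = np.column_stack([
        np.arange(0.05, 1.0, 0.1), np.full(10, 0.005)
    ])
    pts = np.vstack([boundary, interior])
    tri = ScipyDelaunay(pts)
    tris = []
    for t in tri.simplices:
        a, b, c = pts[t]
        if (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]) < 0:
            t = t[[0, 2, 1]]
        tris.append(t)
    boundary_flags = np.zeros(len(pts), dtype=bool)
    boundary_flags[: len(boundary)] = True
    return ls.TriMesh(
        vertices=pts,
        triangles=np.array(tris),
        boundary=boundary_flags,
        uv=np.clip(pts, 0.0, 1.0),
    )


@pytest.fixture(scope="session")
def symmetric_cross_mesh():
    """Four triangles fanning around the center of a square; mirror-symmetric."""
    verts = np.array([
        [-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0], [0.0, 0.0]
    ])
    tris = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    uv = (verts + 1.0) / 2.0
    boundary = np.array([True, True, True, True, False])
    return ls.TriMesh(vertices=verts, triangles=tris, boundary=boundary, uv=uv)


def ellipse_convex_points(n, seed, a=1.5, b=1.0):
    """n points in convex position (on an ellipse), generic for Delaunay."""
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    # reject nearly coincident angles to keep the polygon robustly simple
    while np.min(np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))) < 1e-3:
        theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    return np.column_stack([a * np.cos(theta), b * np.sin(theta)])


@pytest.fixture(scope="session")
def maple_edge_regions(maple_boundary, maple_mesh):
    """Vertex index masks for edge band, vein corridor, and center regions."""
    poly = shapely.Polygon(maple_boundary)
    d = shapely.distance(shapely.points(maple_mesh.vertices2), poly.exterior)
    corridor = np.abs(maple_mesh.vertices2[:, 0] - poly.centroid.x) < 0.08
    edge = d < 0.15
    center = ~corridor & ~edge
    return {"edge": edge, "corridor": corridor, "center": center}
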