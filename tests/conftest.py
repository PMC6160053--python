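import numpy as np
import pytest

from trabnet.graph import SpatialGraph
from trabnet.volume import BinaryVolume


def straight_segment_graph(length=10.0, radius=2.0, n_points=5):
    """A single straight segment along +z with constant radius."""
    g = SpatialGraph()
    a = g.add_node((0.0, 0.0, 0.0), radius)
    b = g.add_node((0.0, 0.0, length), radius)
    t = np.linspace(0.0, 1.0, n_points)
    pts = np.column_stack([np.zeros_like(t), np.zeros_like(t), t * length])
    g.add_segment(a, b, pts, np.full(n_points, radius))
    return g


def semicircle_segment(radius=1.0, n_points=1001):
    """Dense semicircular polyline of radius ``radius`` (chord = 2 radius)."""
    g = SpatialGraph()
    t = np.linspace(0.0, np.pi, n_points)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                           np.zeros_like(t)])
    a = g.add_node(pts[0], 1.0)
    b = g.add_node(pts[-1], 1.0)
    g.add_segment(a, b, pts, np.ones(n_points))
    return g.segments[0]


def star_graph(directions, length=10.0, radius=1.5, center=(0.0, 0.0, 0.0)):
    """One central node with straight arms along the given unit directions."""
    g = SpatialGraph()
    c = np.asarray(center, dtype=float)
    cid = g.add_node(c, radius)
    for d in directions:
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        tip = c + length * d
        nid = g.add_node(tip, radius)
        pts = np.array([c, c + 0.5 * length * d, tip])
        g.add_segment(cid, nid, pts, np.full(3, radius))
    return g, cid


def random_graph(rng, n_segments=20, box=100.0, with_radii=True):
    """Random polyline graph for property tests (nodes shared pairwise)."""
    g = SpatialGraph()
    n_nodes = max(3, n_segments // 2)
    coords = rng.uniform(0, box, size=(n_nodes, 3))
    for c in coords:
        g.add_node(c, float(rng.uniform(0.5, 3.0)))
    for _ in range(n_segments):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        npts = int(rng.integers(2, 8))
        t = np.linspace(0, 1, npts)[:, None]
        pts = coords[a] + (coords[b] - coords[a]) * t
        if npts > 2:
            bow = rng.normal(0, 0.5, size=3)
            pts[1:-1] += np.sin(np.pi * t[1:-1]) * bow
        radii = rng.uniform(0.5, 3.0, size=npts) if with_radii else None
        g.add_segment(int(a), int(b), pts, radii)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_mask():
    """Planar '+': two crossing arms, 1 µm voxels."""
    m = np.zeros((3, 9, 9), dtype=bool)
    m[1, 4, :] = True
    m[1, :, 4] = True
    return BinaryVolume(m, 1.0)


@pytest.fixture
def cylinder_mask():
    """Solid axis-aligned cylinder, radius 4 vox, length 20 vox, 3 µm voxels."""
    zz, yy, xx = np.mgrid[0:28, 0:13, 0:13]
    m = (np.hypot(yy - 6, xx - 6) <= 4) & (zz >= 4) & (zz < 24)
    return BinaryVolume(m, 3.0)


@pytest.fixture
def torus_mask():
    """Solid torus (major radius 10, minor 3.5 vox), 3 µm voxels."""
    zz, yy, xx = np.mgrid[0:32, 0:32, 0:32]
    d = np.sqrt((np.hypot(xx - 15.5, yy - 15.5) - 10.0) ** 2 + (zz - 15.5) ** 2)
    return BinaryVolume(d <= 3.5, 3.0)
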