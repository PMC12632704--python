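import numpy as np
import pytest
import scipy.spatial
import trimesh as _trimesh

from valvestrain import fixtures as fx
from valvestrain.mesh_core import TriMesh


@pytest.fixture(scope="session")
def dome300():
    return fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=300, seed=0))


@pytest.fixture(scope="session")
def dome600():
    return fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=600, seed=0))


@pytest.fixture(scope="session")
def dome1000():
    return fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=1000, seed=0))


@pytest.fixture(scope="session")
def sphere15():
    """Closed icosphere, radius 15 mm."""
    ico = _trimesh.creation.icosphere(subdivisions=4, radius=15.0)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def grid_patch(n=8, spacing=1.0, z=0.0):
    """Structured flat triangulated patch; interior vertices have a
    symmetric 6-neighbourhood (umbrella fixed point)."""
    xs = np.arange(n) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriMesh(pts, np.asarray(faces))


@pytest.fixture
def flat_patch():
    return grid_patch(n=9)


def random_surface_pair(seed=0, n=40):
    """Two small random smooth height-field meshes for metric oracles."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(2):
        pts2 = rng.uniform(-5, 5, (n, 2))
        z = 0.5 * np.sin(pts2[:, 0]) + 0.3 * pts2[:, 1] ** 2 / 10 + k * 0.4
        tri = scipy.spatial.Delaunay(pts2).simplices
        out.append(TriMesh(np.column_stack([pts2, z]), tri))
    return out
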