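import numpy as np
import pytest
import trimesh

from laminaseg.io_formats import Mesh, Volume3D
from laminaseg.synthetic import SyntheticCortexSpec, _default_layers


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def icosahedron():
    tm = trimesh.creation.icosahedron()
    return Mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def icosphere(subdivisions=3, radius=1.0):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture
def small_volume(rng):
    return Volume3D(rng.uniform(0, 1, (16, 16, 16)), voxel_size_um=20.0)


@pytest.fixture
def default_spec():
    return SyntheticCortexSpec()


@pytest.fixture
def clean_spec():
    """Low-noise profile spec: deterministic layout, mild texture."""
    return SyntheticCortexSpec(layer_specs=_default_layers(0.02))


def flat_sheet(nx=8, ny=8, spacing=1.0, z=0.0):
    """Open planar grid mesh in the z-plane."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(nx * ny, z)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01, v10 = v00 + 1, v00 + ny
            tris.extend([[v00, v10, v01], [v01, v10, v10 + 1]])
    return Mesh(verts, np.asarray(tris))
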