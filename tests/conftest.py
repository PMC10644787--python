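import numpy as np
import pytest

from footacs.mesh_io import TriangleMesh
from footacs.registry import TemplateRegistry
from footacs.synthetic import generate_template_set


@pytest.fixture(scope="session")
def template_dir(tmp_path_factory):
    """One synthetic template directory shared by the whole session."""
    d = tmp_path_factory.mktemp("templates")
    generate_template_set(str(d), seed=0)
    return str(d)


@pytest.fixture(scope="session")
def registry(template_dir):
    return TemplateRegistry(template_dir)


def uv_sphere_mesh(radius: float = 10.0, center=(0.0, 0.0, 0.0), n_lat: int = 17, n_lon: int = 24):
    """A latitude/longitude sphere mesh whose vertex set contains the exact
    axis-crossing points (±r,0,0), (0,±r,0), (0,0,±r), so axis-aligned ray
    casts hit analytic surface points exactly.

    n_lat must be odd (equator row included); n_lon a multiple of 4 (cardinal
    longitudes included).
    """
    assert n_lat % 2 == 1 and n_lon % 4 == 0
    center = np.asarray(center, dtype=np.float64)
    lats = np.linspace(-np.pi / 2, np.pi / 2, n_lat)
    lons = np.linspace(0.0, 2 * np.pi, n_lon, endpoint=False)
    verts = [np.array([0.0, 0.0, -radius])]
    for lat in lats[1:-1]:
        for lon in lons:
            verts.append(
                radius * np.array([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)])
            )
    verts.append(np.array([0.0, 0.0, radius]))
    verts = np.array(verts)

    faces = []
    n_rings = n_lat - 2
    south, north = 0, len(verts) - 1

    def ring_vertex(ring, j):
        return 1 + ring * n_lon + (j % n_lon)

    for j in range(n_lon):  # south cap
        faces.append([south, ring_vertex(0, j + 1), ring_vertex(0, j)])
    for ring in range(n_rings - 1):
        for j in range(n_lon):
            a, b = ring_vertex(ring, j), ring_vertex(ring, j + 1)
            c, d = ring_vertex(ring + 1, j), ring_vertex(ring + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(n_lon):  # north cap
        faces.append([north, ring_vertex(n_rings - 1, j), ring_vertex(n_rings - 1, j + 1)])
    return TriangleMesh(verts + center, np.array(faces), name="sphere")
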