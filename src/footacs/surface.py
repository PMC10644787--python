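"""Surface queries on triangle meshes: sampling, closest points, ray casts.

These are the geometric primitives the registration and axis-construction
steps are built on.  Closest-point queries use a KD-tree over triangle
centroids to shortlist candidate triangles, then an exact point-to-triangle
projection on the candidates; ray casts are a vectorized Moller-Trumbore
intersection over all triangles (bone meshes are small enough that brute
force over faces is cheap).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _closest_on_triangles

from .mesh_io import TriangleMesh

__all__ = ["SurfaceQuery", "sample_surface", "area_centroid", "ray_mesh_intersections"]


def area_centroid(mesh: TriangleMesh) -> np.ndarray:
    """Exact area-weighted centroid of the surface (mean of triangle
    centroids weighted by triangle area)."""
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return (centroids * areas[:, None]).sum(axis=0) / areas.sum()


def sample_surface(mesh: TriangleMesh, count: int, seed: int = 0) -> np.ndarray:
    """Area-weighted random points on the surface of *mesh*.

    Deterministic given *seed*.  Area weighting removes mesh-density bias, so
    two tessellations of the same shape yield statistically identical samples.
    """
    rng = np.random.default_rng(seed)
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    face_idx = rng.choice(len(areas), size=count, p=areas / total)
    tri = mesh.vertices[mesh.faces[face_idx]]  # (count, 3, 3)
    # uniform barycentric sampling via square-root trick
    r1 = np.sqrt(rng.random(count))[:, None]
    r2 = rng.random(count)[:, None]
    return (1 - r1) * tri[:, 0] + r1 * (1 - r2) * tri[:, 1] + r1 * r2 * tri[:, 2]


class SurfaceQuery:
    """Reusable closest-point structure for one mesh.

    ``k_candidates`` nearest triangle centroids are shortlisted per query
    point; exact closest points are then computed on those triangles.  For the
    near-uniform tessellations this package produces the shortlist virtually
    always contains the true nearest triangle.
    """

    def __init__(self, mesh: TriangleMesh, k_candidates: int = 10):
        self.mesh = mesh
        self.triangles = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self.k = min(k_candidates, len(mesh.faces))
        self._tree = cKDTree(self.triangles.mean(axis=1))

    def closest_points(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, distances) for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        tris = self.triangles[cand.ravel()]  # (n*k, 3, 3)
        reps = np.repeat(points, k, axis=0)
        nearest = _closest_on_triangles(tris, reps).reshape(n, k, 3)
        d2 = np.einsum("nkj,nkj->nk", nearest - points[:, None, :], nearest - points[:, None, :])
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        return nearest[rows, best], np.sqrt(d2[rows, best])

    def rms_distance(self, points: np.ndarray) -> float:
        _, d = self.closest_points(points)
        return float(np.sqrt(np.mean(d**2)))


def ray_mesh_intersections(
    mesh: TriangleMesh, origin: np.ndarray, direction: np.ndarray, eps: float = 1e-12
) -> np.ndarray:
    """All intersections of the ray ``origin + t * direction`` (t > eps) with
    *mesh*, sorted by distance.  Returns an (n, 3) array, possibly empty.
    """
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    tri = mesh.vertices[mesh.faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    # Moller-Trumbore, vectorized over triangles
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    bary_tol = 1e-9
    hit = ok & (u >= -bary_tol) & (v >= -bary_tol) & (u + v <= 1 + bary_tol) & (t > eps)
    t_hit = np.sort(t[hit])
    return origin + t_hit[:, None] * direction


def first_ray_hit(mesh: TriangleMesh, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Nearest ray-surface intersection; raises if the ray misses the mesh."""
    hits = ray_mesh_intersections(mesh, origin, direction)
    if len(hits) == 0:
        raise ValueError(
            "ray from origin misses the mesh surface (open or cropped mesh, "
            "or origin outside the bone)"
        )
    return hits[0]
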