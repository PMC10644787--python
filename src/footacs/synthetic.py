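"""Synthetic bone-like test shapes with known ground-truth anatomy.

Real foot/ankle surface models and the statistical-shape-model templates
derived from them cannot ship with the package, so every other module is
exercised against a generated shape family instead: superellipsoids elongated
along each bone's primary anatomical axis, decorated with a few off-axis
Gaussian bumps that break all mirror and 180-degree flip symmetries (without
them a smooth ellipsoid's ACS would be ambiguous up to axis sign).  The
canonical frame of every generated bone is its identity ACS at the
area-weighted surface centroid, so ground truth is known exactly under any
rigid pose, mirroring, added noise or remeshing.

The same machinery produces template directories, segmentation-noise twins
(a surrogate for re-segmenting the same bone with different software) and
small populations with group-level shape offsets plus correspondence
particles at fixed parametric surface locations.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .alignment import RigidTransform, mirror_mesh
from .acs_core import ACS
from .mesh_io import ParticleSet, TriangleMesh, write_mesh
from .registry import ALL_BONE_VARIANTS, PARTIAL_CAPABLE, get_bone_spec, valid_variants

__all__ = [
    "SyntheticBoneParams",
    "SyntheticBoneRecord",
    "PopulationSet",
    "default_params",
    "generate_bone",
    "generate_template_set",
    "perturb_segmentation",
    "generate_population",
    "random_rigid_transform",
    "VARIANT_ROTATION_DEG",
]

#: joint-variant templates are the default template rotated about the ML axis
VARIANT_ROTATION_DEG = {
    "default": 0.0,
    "talonavicular": 2.0,
    "tibiotalar": -2.0,
    "subtalar_talus": 2.0,
    "subtalar_calcaneus": -2.0,
    "calcaneocuboid": 2.0,
}

#: superellipsoid exponent: 2 is an ellipsoid, larger is boxier
_SUPERELLIPSOID_P = 2.5

#: semi-axes (ML, AP, SI) in mm per bone/variant; elongation follows each
#: bone's primary anatomical axis so extreme-region centroids are well spread
_SEMI_AXES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("tibia", "default"): (14.0, 17.0, 60.0),
    ("fibula", "default"): (9.0, 11.5, 55.0),
    ("talus", "talonavicular"): (20.0, 34.0, 15.0),
    ("talus", "tibiotalar"): (34.0, 20.0, 15.0),
    ("talus", "subtalar_talus"): (20.0, 34.0, 15.0),
    ("calcaneus", "subtalar_calcaneus"): (22.0, 50.0, 26.0),
    ("calcaneus", "calcaneocuboid"): (22.0, 50.0, 26.0),
    ("navicular", "default"): (30.0, 14.0, 18.0),
    ("cuboid", "default"): (16.0, 28.0, 19.5),
    ("medial_cuneiform", "default"): (12.0, 22.0, 16.0),
    ("intermediate_cuneiform", "default"): (10.0, 20.0, 14.0),
    ("lateral_cuneiform", "default"): (11.0, 21.0, 15.0),
    ("metatarsal1", "default"): (9.0, 40.0, 11.5),
    ("metatarsal2", "default"): (7.0, 44.0, 9.5),
    ("metatarsal3", "default"): (7.5, 41.0, 9.8),
    ("metatarsal4", "default"): (7.2, 39.0, 9.2),
    ("metatarsal5", "default"): (8.0, 38.0, 10.5),
}

#: bump directions expressed in a (t1, t2, primary) frame so the bump mass
#: stays near the primary-axis equator and leaves the extreme regions (which
#: anchor the primary axis) essentially untouched
_BUMPS_PRIMARY_FRAME = (
    # (t1, t2, along-primary), amplitude mm, angular width rad
    ((0.95, 0.28, 0.15), 1.8, 0.45),
    ((-0.55, -0.80, 0.24), 1.4, 0.45),
)

_AXIS_INDEX = {"ML": 0, "AP": 1, "SI": 2}


@dataclass
class SyntheticBoneParams:
    """Everything needed to rebuild one synthetic bone deterministically."""

    bone_id: str
    acs_variant: str = "default"
    semi_axes: tuple = (15.0, 30.0, 18.0)  # (ML, AP, SI) mm
    bumps: tuple = ()  # ((direction xyz), amplitude mm, width rad)
    taper: float = 0.0  # fractional radius gain toward +taper_axis (breaks
    # end-for-end flips without biasing the axis construction)
    taper_axis: tuple = (0.0, 1.0, 0.0)
    noise_sd: float = 0.0  # mm, i.i.d. vertex noise added after posing
    mesh_resolution: int = 3  # icosphere subdivision level
    seed: int = 0


@dataclass
class SyntheticBoneRecord:
    """A generated bone in 'scanner' space plus its exact ground truth."""

    mesh: TriangleMesh
    true_acs: ACS  # ground truth in the record's own (original) space
    pose: RigidTransform
    side: str
    params: SyntheticBoneParams
    particles: ParticleSet | None = None


@dataclass
class PopulationSet:
    """A synthetic population: per-group individuals, per-group mean shapes,
    one overall mean shape; every record carries correspondence particles."""

    groups: list  # list of list[SyntheticBoneRecord]
    group_means: list  # list[SyntheticBoneRecord]
    overall_mean: SyntheticBoneRecord

    @property
    def individuals(self) -> list:
        return [rec for group in self.groups for rec in group]


def _primary_frame_to_xyz(primary_axis: str) -> np.ndarray:
    """Columns (t1, t2, primary) expressed in xyz for the given primary axis."""
    e = np.eye(3)
    if primary_axis == "AP":
        t1, t2, w = e[0], e[2], e[1]
    elif primary_axis == "SI":
        t1, t2, w = e[0], e[1], e[2]
    else:  # ML
        t1, t2, w = e[1], e[2], e[0]
    return np.column_stack([t1, t2, w])


def default_params(bone_id: str, acs_variant: str = "default", seed: int = 0) -> SyntheticBoneParams:
    """The canonical shape parameters for one bone/variant."""
    spec = get_bone_spec(bone_id, acs_variant)
    semi = _SEMI_AXES[(bone_id, acs_variant)]
    M = _primary_frame_to_xyz(spec.primary_region_axis)
    bumps = []
    for dir_pf, amp, width in _BUMPS_PRIMARY_FRAME:
        d = M @ np.asarray(dir_pf, dtype=np.float64)
        d /= np.linalg.norm(d)
        bumps.append((tuple(d), amp, width))
    return SyntheticBoneParams(
        bone_id=bone_id,
        acs_variant=acs_variant,
        semi_axes=semi,
        bumps=tuple(bumps),
        taper=0.12,
        taper_axis=tuple(M[:, 2]),  # fatter toward +primary (e.g. anteriorly)
        seed=seed,
    )


def _surface_radius(directions: np.ndarray, params: SyntheticBoneParams) -> np.ndarray:
    """Radius of the analytic bone surface along unit *directions*."""
    d = np.atleast_2d(directions)
    s = np.asarray(params.semi_axes, dtype=np.float64)
    p = _SUPERELLIPSOID_P
    t = np.sum(np.abs(d / s) ** p, axis=1) ** (-1.0 / p)
    r = t.copy()
    if params.taper != 0.0:
        r = r * (1.0 + params.taper * (d @ np.asarray(params.taper_axis, dtype=np.float64)))
    for bump_dir, amp, width in params.bumps:
        cosang = np.clip(d @ np.asarray(bump_dir, dtype=np.float64), -1.0, 1.0)
        ang = np.arccos(cosang)
        r = r + amp * np.exp(-(ang**2) / (2.0 * width**2))
    return r


def _area_centroid(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    centroids = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return (centroids * areas[:, None]).sum(axis=0) / areas.sum()


def _canonical_offset(params: SyntheticBoneParams) -> np.ndarray:
    """Translation that puts the area-weighted surface centroid at the origin."""
    sphere = trimesh.creation.icosphere(subdivisions=params.mesh_resolution)
    dirs = np.asarray(sphere.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    verts = dirs * _surface_radius(dirs, params)[:, None]
    return _area_centroid(verts, np.asarray(sphere.faces))


def _canonical_mesh(params: SyntheticBoneParams) -> TriangleMesh:
    sphere = trimesh.creation.icosphere(subdivisions=params.mesh_resolution)
    dirs = np.asarray(sphere.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    verts = dirs * _surface_radius(dirs, params)[:, None]
    verts = verts - _area_centroid(verts, np.asarray(sphere.faces))
    return TriangleMesh(verts, np.asarray(sphere.faces), name=f"{params.bone_id}.{params.acs_variant}")


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 50.0) -> RigidTransform:
    """A uniformly random proper rotation plus a bounded random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)


def generate_bone(
    params: SyntheticBoneParams,
    pose: RigidTransform | str | None = None,
    side: str = "left",
) -> SyntheticBoneRecord:
    """Generate one synthetic bone in 'scanner' space.

    The canonical shape (identity ACS at its surface centroid) is mirrored for
    right-side bones, rigidly posed (``None`` = identity, ``"random"`` = a
    seeded random pose), and finally perturbed with i.i.d. normal vertex noise
    of ``params.noise_sd``.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    mesh = _canonical_mesh(params)
    if side == "right":
        mesh = mirror_mesh(mesh)
    elif side != "left":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    if pose is None:
        pose_t = RigidTransform.identity()
    elif pose == "random":
        pose_t = random_rigid_transform(rng)
    elif isinstance(pose, RigidTransform):
        pose_t = pose
    else:
        raise ValueError(f"pose must be None, 'random' or a RigidTransform, got {pose!r}")

    vertices = pose_t.apply(mesh.vertices)
    if params.noise_sd > 0:
        vertices = vertices + rng.normal(0.0, params.noise_sd, size=vertices.shape)
    posed = TriangleMesh(vertices, mesh.faces.copy(), name=mesh.name)

    axes = pose_t.rotation  # identity canonical ACS carried through the pose
    true_acs = ACS(
        origin=pose_t.translation.copy(),
        ML=axes[:, 0],
        AP=axes[:, 1],
        SI=axes[:, 2],
        space="original",
        bone_id=params.bone_id,
        acs_variant=params.acs_variant,
    ).validate()
    return SyntheticBoneRecord(mesh=posed, true_acs=true_acs, pose=pose_t, side=side, params=params)


def _rotation_about_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def generate_template_set(out_dir: str, bone_ids=None, seed: int = 0) -> str:
    """Write a complete synthetic template directory with manifest.

    One noise-free canonical-pose template per bone and ACS variant (joint
    variants rotated about the ML axis per ``VARIANT_ROTATION_DEG``), plus a
    cropped partial-length variant for tibia, fibula and metatarsals.  Layout:
    ``<out_dir>/<bone>/<variant>/<full|partial>.ply`` + ``manifest.json``.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {}
    for bone_id, variant in ALL_BONE_VARIANTS:
        if bone_ids is not None and bone_id not in bone_ids:
            continue
        spec = get_bone_spec(bone_id, variant)
        params = default_params(bone_id, variant, seed=seed)
        mesh = _canonical_mesh(params)
        R = _rotation_about_x(VARIANT_ROTATION_DEG[variant])
        mesh = TriangleMesh(mesh.vertices @ R.T, mesh.faces.copy(), name=f"{bone_id}.{variant}")
        axis_i = _AXIS_INDEX[spec.primary_region_axis]
        extent = float(mesh.vertices[:, axis_i].max() - mesh.vertices[:, axis_i].min())

        subdir = os.path.join(out_dir, bone_id, variant)
        os.makedirs(subdir, exist_ok=True)
        write_mesh(mesh, os.path.join(subdir, "full.ply"))
        entry = {
            "full": {
                "file": os.path.join(bone_id, variant, "full.ply"),
                "template_id": f"{bone_id}.{variant}.synthetic",
                "extent_along_primary": extent,
            }
        }
        if bone_id in PARTIAL_CAPABLE:
            coord = mesh.vertices[:, axis_i]
            cutoff = coord.min() + 0.5 * (coord.max() - coord.min())
            keep = (coord[mesh.faces] < cutoff).all(axis=1)
            partial = TriangleMesh(
                mesh.vertices.copy(), mesh.faces[keep], name=f"{bone_id}.{variant}.partial"
            )
            # drop unreferenced vertices
            used = np.unique(partial.faces)
            remap = -np.ones(len(partial.vertices), dtype=np.int64)
            remap[used] = np.arange(len(used))
            partial = TriangleMesh(
                partial.vertices[used], remap[partial.faces], name=partial.name
            )
            write_mesh(partial, os.path.join(subdir, "partial.ply"))
            entry["partial"] = {
                "file": os.path.join(bone_id, variant, "partial.ply"),
                "template_id": f"{bone_id}.{variant}.partial.synthetic",
                "extent_along_primary": extent,  # ratio is taken vs the full extent
            }
        manifest.setdefault(bone_id, {})[variant] = entry
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out_dir


def _star_resample(record: SyntheticBoneRecord, n_faces_target: int) -> TriangleMesh:
    """Remesh by casting rays from the bone center through fresh sphere
    vertices (the shape family is star-shaped about its centroid)."""
    # pick a sphere tessellation with roughly the requested face count
    best = None
    for sub in range(1, 6):
        n = 20 * 4**sub
        if best is None or abs(n - n_faces_target) < abs(best[1] - n_faces_target):
            best = (sub, n)
    sub, n = best
    if abs(n - n_faces_target) / max(n_faces_target, 1) > 0.25:
        # fall back to a uv sphere, whose tessellation is freely adjustable;
        # face counts follow no simple formula, so search the resolution
        sphere = None
        for m in range(4, 64):
            cand = trimesh.creation.uv_sphere(radius=1.0, count=(m, m))
            if sphere is None or abs(len(cand.faces) - n_faces_target) < abs(
                len(sphere.faces) - n_faces_target
            ):
                sphere = cand
            if len(cand.faces) > 1.5 * n_faces_target:
                break
    else:
        sphere = trimesh.creation.icosphere(subdivisions=sub)
    dirs = np.asarray(sphere.vertices, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    center = record.true_acs.origin

    tri = record.mesh.vertices[record.mesh.faces]
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    # batched Moller-Trumbore: rays (n, 1, 3) against faces (1, m, 3)
    tvec = center - v0  # (m, 3), shared by all rays
    qvec = np.cross(tvec, e1)  # (m, 3)
    tq = np.einsum("mj,mj->m", e2, qvec)  # (m,)
    new_verts = np.empty_like(dirs)
    chunk = 256
    for start in range(0, len(dirs), chunk):
        D = dirs[start : start + chunk]  # (n, 3)
        pvec = np.cross(D[:, None, :], e2[None, :, :])  # (n, m, 3)
        det = np.einsum("mj,nmj->nm", e1, pvec)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        u = np.einsum("mj,nmj->nm", tvec, pvec) * inv
        v = (D @ qvec.T) * inv
        t = tq[None, :] * inv
        tol = 1e-9
        hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t > 1e-9)
        t_first = np.where(hit, t, np.inf).min(axis=1)
        if np.any(~np.isfinite(t_first)):
            raise ValueError("star-shaped resampling ray missed the surface")
        new_verts[start : start + chunk] = center + D * t_first[:, None]
    return TriangleMesh(new_verts, np.asarray(sphere.faces), name=record.mesh.name)


def perturb_segmentation(
    record: SyntheticBoneRecord,
    noise_sd: float = 0.2,
    remesh_factor: float = 1.0,
    seed: int = 0,
) -> SyntheticBoneRecord:
    """A 'second segmentation' of the same bone: remesh to ``remesh_factor``
    times the original face count, then add surface-normal noise of
    ``noise_sd`` mm.  The ground-truth ACS is unchanged."""
    if remesh_factor == 1.0:
        mesh = TriangleMesh(
            record.mesh.vertices.copy(), record.mesh.faces.copy(), name=record.mesh.name
        )
    else:
        mesh = _star_resample(record, int(round(remesh_factor * record.mesh.n_faces)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        normals = np.asarray(mesh.as_trimesh().vertex_normals)
        mesh = TriangleMesh(
            mesh.vertices + normals * rng.normal(0.0, noise_sd, size=len(mesh.vertices))[:, None],
            mesh.faces.copy(),
            name=mesh.name,
        )
    return SyntheticBoneRecord(
        mesh=mesh,
        true_acs=record.true_acs,
        pose=record.pose,
        side=record.side,
        params=replace(record.params, noise_sd=noise_sd),
        particles=record.particles,
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n deterministic, well-spread unit directions (fixed parametric
    locations shared by every shape -> exact correspondence)."""
    i = np.arange(n, dtype=np.float64)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _particles_for(record: SyntheticBoneRecord, directions: np.ndarray) -> ParticleSet:
    params = record.params
    radii = _surface_radius(directions, params)
    pts = directions * radii[:, None] - _canonical_offset(params)
    if record.side == "right":
        pts = pts.copy()
        pts[:, 0] = -pts[:, 0]
    return ParticleSet(record.pose.apply(pts), source_path=f"synthetic:{params.bone_id}")


def generate_population(
    bone_id: str,
    n_groups: int = 3,
    n_per_group: int = 8,
    group_effect_scale: float = 0.5,
    seed: int = 0,
    acs_variant: str = "default",
    n_particles: int = 128,
    random_pose: bool = True,
) -> PopulationSet:
    """A synthetic population with group-level shape offsets.

    Group mean shapes differ from the overall mean by seeded bump-amplitude
    offsets of magnitude ``group_effect_scale`` (mm); individuals jitter
    around their group mean (3% semi-axis jitter, 0.15 mm bump jitter) and
    are randomly posed.  Correspondence particles sit at ``n_particles``
    fixed parametric surface locations, identical across all shapes.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if acs_variant == "default" and bone_id in ("talus", "calcaneus"):
        acs_variant = valid_variants(bone_id)[0]
    rng = np.random.default_rng(seed)
    directions = _fibonacci_directions(n_particles)
    base = default_params(bone_id, acs_variant, seed=seed)

    overall = generate_bone(base)
    overall.particles = _particles_for(overall, directions)

    groups: list[list[SyntheticBoneRecord]] = []
    group_means: list[SyntheticBoneRecord] = []
    for _ in range(n_groups):
        u = rng.normal(size=len(base.bumps))
        norm = np.linalg.norm(u)
        offsets = group_effect_scale * (u / norm if norm > 0 else u)
        g_bumps = tuple(
            (d, max(0.0, amp + off), w) for (d, amp, w), off in zip(base.bumps, offsets)
        )
        g_params = replace(base, bumps=g_bumps, seed=int(rng.integers(2**31 - 1)))
        g_mean = generate_bone(g_params)
        g_mean.particles = _particles_for(g_mean, directions)
        group_means.append(g_mean)

        members = []
        for _ in range(n_per_group):
            semi = tuple(
                s * (1.0 + 0.03 * rng.normal()) for s in g_params.semi_axes
            )
            i_bumps = tuple(
                (d, max(0.0, amp + 0.15 * rng.normal()), w) for d, amp, w in g_bumps
            )
            i_params = replace(
                g_params, semi_axes=semi, bumps=i_bumps, seed=int(rng.integers(2**31 - 1))
            )
            rec = generate_bone(i_params, pose="random" if random_pose else None)
            rec.particles = _particles_for(rec, directions)
            members.append(rec)
        groups.append(members)

    return PopulationSet(groups=groups, group_means=group_means, overall_mean=overall)
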