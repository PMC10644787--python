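"""Construction of the anatomical coordinate system in template-aligned space.

After a bone is temporarily aligned to its pre-oriented template, it is
divided into equal-width volumetric regions (slabs) along each anatomical
plane.  The centroids of two bone-specific extreme regions define the primary
axis; the centroid of a third region (superior for most bones, lateral for
tibia/fibula) is projected orthogonally onto the primary line to form the
secondary axis; the cross product supplies the tertiary axis.  The three axes
are then labelled medial-lateral (ML), anterior-posterior (AP) and
superior-inferior (SI), sign-corrected against the template convention
(medial +x, anterior +y, superior +z), and mapped back to the bone's
original space.

Region centroids are computed over area-weighted surface samples (20,000 by
default, seeded), which makes the construction insensitive to tessellation
density and tolerant of open meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    AlignmentResult,
    RigidTransform,
    icp_align,
    initial_alignment,
    map_acs_between_spaces,
    mirror_mesh,
)
from .mesh_io import TriangleMesh
from .registry import (
    PARTIAL_CAPABLE,
    BoneSpec,
    Template,
    TemplateRegistry,
    get_bone_spec,
)
from .surface import area_centroid, first_ray_hit, sample_surface

__all__ = [
    "ACS",
    "RegionPartition",
    "DegenerateGeometryError",
    "AlignmentFailureError",
    "partition_regions",
    "compute_primary_axis",
    "compute_third_point",
    "compute_secondary_axis",
    "assemble_acs",
    "place_origin",
    "assign_acs",
    "ACSAssignment",
]

_AXIS_INDEX = {"ML": 0, "AP": 1, "SI": 2}
_UNIT_TOL = 1e-9

#: default number of area-weighted surface samples used for region centroids
DEFAULT_REGION_SAMPLES = 20000


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate for axis construction (empty slab, coincident
    centroids, third point on the primary line)."""


class AlignmentFailureError(RuntimeError):
    """The constructed frame contradicts the template convention, indicating a
    catastrophically wrong alignment or laterality."""


@dataclass
class ACS:
    """An anatomical coordinate system: origin plus orthonormal right-handed
    ML / AP / SI axes, expressed in a named space."""

    origin: np.ndarray
    ML: np.ndarray
    AP: np.ndarray
    SI: np.ndarray
    space: str  # "original" or "aligned"
    bone_id: str = ""
    acs_variant: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.ML = np.asarray(self.ML, dtype=np.float64)
        self.AP = np.asarray(self.AP, dtype=np.float64)
        self.SI = np.asarray(self.SI, dtype=np.float64)

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix with ML, AP, SI as columns."""
        return np.column_stack([self.ML, self.AP, self.SI])

    def validate(self, tol: float = _UNIT_TOL) -> "ACS":
        A = self.axes
        if np.abs(np.linalg.norm(A, axis=0) - 1.0).max() > tol:
            raise ValueError("ACS axes must have unit norm")
        gram = A.T @ A - np.eye(3)
        if np.abs(gram).max() > tol:
            raise ValueError("ACS axes must be pairwise orthogonal")
        if np.abs(np.cross(self.ML, self.AP) - self.SI).max() > tol:
            raise ValueError("ACS must be right-handed (ML x AP = SI)")
        return self


@dataclass
class RegionPartition:
    """Equal-width slabs of the aligned bone's extent along one axis, with the
    surface-sample centroid of each slab."""

    axis: str  # ML (x), AP (y) or SI (z), in aligned space
    n_regions: int
    boundaries: np.ndarray  # (n_regions + 1,) ascending, mm
    region_centroids: np.ndarray  # (n_regions, 3)
    region_counts: np.ndarray  # (n_regions,)


def partition_regions(samples: np.ndarray, axis: str, n_regions: int) -> RegionPartition:
    """Divide surface samples into *n_regions* equal-width slabs along *axis*.

    Slabs are half-open ``[b_i, b_{i+1})`` except the last, which is closed.
    An empty slab signals pathological cropping and raises
    :class:`DegenerateGeometryError`.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be ML, AP or SI, got {axis!r}")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if len(samples) < n_regions:
        raise ValueError(f"need at least {n_regions} samples, got {len(samples)}")
    coords = samples[:, _AXIS_INDEX[axis]]
    lo, hi = coords.min(), coords.max()
    if np.unique(coords).size < n_regions:
        raise ValueError(f"need >= {n_regions} distinct coordinates along {axis}")
    boundaries = np.linspace(lo, hi, n_regions + 1)
    width = (hi - lo) / n_regions
    idx = np.clip(((coords - lo) / width).astype(int) if width > 0 else np.zeros(len(coords), int), 0, n_regions - 1)
    counts = np.bincount(idx, minlength=n_regions)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        kind = "extreme" if empty in (0, n_regions - 1) else "interior"
        raise DegenerateGeometryError(
            f"empty {kind} region {empty} along axis {axis}: geometry is pathologically cropped"
        )
    centroids = np.zeros((n_regions, 3))
    for axis_i in range(3):
        centroids[:, axis_i] = np.bincount(idx, weights=samples[:, axis_i], minlength=n_regions)
    centroids /= counts[:, None]
    return RegionPartition(axis, n_regions, boundaries, centroids, counts)


def compute_primary_axis(partition: RegionPartition):
    """Unit vector from the low-coordinate extreme-slab centroid to the
    high-coordinate one, plus the two anchor centroids.

    Points toward +x (medial), +y (anterior) or +z (superior) depending on the
    bone's primary partition axis.
    """
    c_low = partition.region_centroids[0]
    c_high = partition.region_centroids[-1]
    vec = c_high - c_low
    norm = np.linalg.norm(vec)
    if norm < 1e-6:
        raise DegenerateGeometryError(
            f"extreme-region centroids along {partition.axis} coincide (distance {norm:.2e} mm)"
        )
    return vec / norm, (c_low, c_high)


def compute_third_point(partition: RegionPartition, spec: BoneSpec) -> np.ndarray:
    """Centroid of the bone-specific third region: the most superior slab for
    most bones, the most lateral (lowest-x) slab for tibia and fibula."""
    if spec.third_point_region == "superior":
        if partition.axis != "SI":
            raise ValueError("superior third point requires the SI partition")
        return partition.region_centroids[-1]
    if spec.third_point_region == "lateral":
        if partition.axis != "ML":
            raise ValueError("lateral third point requires the ML partition")
        return partition.region_centroids[0]  # lateral = lowest x (medial is +x)
    raise ValueError(f"unknown third_point_region {spec.third_point_region!r}")


def compute_secondary_axis(
    primary: np.ndarray, anchor: np.ndarray, third_point: np.ndarray
) -> np.ndarray:
    """Unit vector from the orthogonal projection of the third point onto the
    primary line, toward the third point; exactly orthogonal to primary."""
    primary = np.asarray(primary, dtype=np.float64)
    third_point = np.asarray(third_point, dtype=np.float64)
    anchor = np.asarray(anchor, dtype=np.float64)
    rel = third_point - anchor
    foot = anchor + (rel @ primary) * primary
    vec = third_point - foot
    dist = np.linalg.norm(vec)
    if dist < 1e-6:
        raise DegenerateGeometryError(
            f"third point lies on the primary axis (perpendicular distance {dist:.2e} mm)"
        )
    vec = vec / dist
    vec = vec - (vec @ primary) * primary  # kill residual float component
    return vec / np.linalg.norm(vec)


def assemble_acs(
    primary: np.ndarray,
    secondary: np.ndarray,
    spec: BoneSpec,
    origin: np.ndarray,
) -> ACS:
    """Label primary/secondary/tertiary axes as ML/AP/SI, sign-correct against
    the template convention, and enforce right-handedness.

    ML must point toward +x (medial) and AP toward +y (anterior) in aligned
    space; SI is then recomputed as ML x AP and must point toward +z
    (superior) — if it does not, the alignment or laterality is wrong and an
    :class:`AlignmentFailureError` is raised.
    """
    primary = np.asarray(primary, dtype=np.float64)
    secondary = np.asarray(secondary, dtype=np.float64)
    if abs(primary @ secondary) > 1e-9:
        raise ValueError("primary and secondary axes must be orthogonal")
    tertiary = np.cross(primary, secondary)
    tertiary /= np.linalg.norm(tertiary)

    by_label = {
        spec.axis_role_map["primary"]: primary,
        spec.axis_role_map["secondary"]: secondary,
        spec.axis_role_map["tertiary"]: tertiary,
    }
    ML, AP = by_label["ML"].copy(), by_label["AP"].copy()
    if ML[0] < 0:
        ML = -ML
    if AP[1] < 0:
        AP = -AP
    SI = np.cross(ML, AP)
    SI /= np.linalg.norm(SI)
    if SI[2] <= 0:
        raise AlignmentFailureError(
            f"{spec.bone_id}/{spec.acs_variant}: constructed SI axis points inferiorly in "
            "template space — check template choice and bone laterality"
        )
    return ACS(
        origin=np.asarray(origin, dtype=np.float64),
        ML=ML,
        AP=AP,
        SI=SI,
        space="aligned",
        bone_id=spec.bone_id,
        acs_variant=spec.acs_variant,
    ).validate(tol=1e-9)


def place_origin(
    mesh: TriangleMesh,
    spec: BoneSpec,
    acs: ACS,
    mode: str = "bone_center",
) -> np.ndarray:
    """Place the ACS origin on the aligned bone.

    ``bone_center`` is the exact area-weighted surface centroid;
    ``joint_surface`` casts a ray from the bone center along the bone's
    joint direction (expressed in the ACS) and takes the first surface hit.
    """
    if mode not in spec.origin_modes:
        raise ValueError(f"origin mode {mode!r} not available for {spec.bone_id}; valid: {spec.origin_modes}")
    center = area_centroid(mesh)
    if mode == "bone_center":
        return center
    direction = acs.axes @ np.asarray(spec.joint_direction, dtype=np.float64)
    try:
        return first_ray_hit(mesh, center, direction)
    except ValueError as exc:
        raise DegenerateGeometryError(
            f"{spec.bone_id}: joint-surface ray misses the mesh ({exc}); mesh may be open or cropped"
        ) from exc


@dataclass
class ACSAssignment:
    """Everything produced for one bone: the ACS in both spaces, the alignment
    that links them, and any warnings raised along the way."""

    acs_aligned: ACS
    acs_original: ACS
    alignment: AlignmentResult
    spec: BoneSpec
    warnings: list = field(default_factory=list)


def assign_acs(
    mesh: TriangleMesh,
    bone_id: str,
    acs_variant: str,
    registry: TemplateRegistry,
    side: str = "left",
    origin_mode: str = "bone_center",
    seed: int = 0,
    region_samples: int = DEFAULT_REGION_SAMPLES,
    icp_sample_count: int = 2000,
    max_iterations: int = 200,
    icp_tolerance: float = 1e-5,
) -> ACSAssignment:
    """End-to-end ACS assignment for one bone surface model in arbitrary pose.

    Pipeline: mirror (right bones) -> principal-axes initialization ->
    point-to-surface ICP onto the bone/variant template -> area-weighted
    surface sampling -> equal-width region partitions -> primary / third-point
    / secondary / tertiary axis construction -> origin placement -> mapping of
    the ACS back to the bone's original space.  Deterministic given *seed*.
    """
    import warnings as _warnings

    spec = get_bone_spec(bone_id, acs_variant)
    caught: list = []

    working = mesh
    mirrored = side == "right"
    if mirrored:
        working = mirror_mesh(mesh)

    template = registry.get(bone_id, acs_variant)
    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")
        init = initial_alignment(working, template, seed=seed)
        if bone_id in PARTIAL_CAPABLE:
            # provisional aligned extent decides full vs partial template
            axis_i = _AXIS_INDEX[spec.primary_region_axis]
            moved = init.apply(working.vertices)
            extent = moved[:, axis_i].max() - moved[:, axis_i].min()
            ratio = extent / template.extent_along_primary
            chosen = registry.select_template(bone_id, acs_variant, ratio)
            if chosen.partial_variant != template.partial_variant:
                template = chosen
                init = initial_alignment(working, template, seed=seed)
        result = icp_align(
            working,
            template,
            max_iterations=max_iterations,
            tolerance=icp_tolerance,
            sample_count=icp_sample_count,
            seed=seed,
            initial=init,
        )
    caught.extend(wlist)

    transform = RigidTransform(
        result.transform.rotation, result.transform.translation, mirrored=mirrored
    )
    result.transform = transform

    aligned = TriangleMesh(
        transform.apply(working.vertices), working.faces.copy(), name=mesh.name
    )
    samples = sample_surface(aligned, region_samples, seed=seed + 13)

    partitions = {
        ax: partition_regions(samples, ax, spec.regions_per_plane) for ax in ("ML", "AP", "SI")
    }
    primary, anchors = compute_primary_axis(partitions[spec.primary_region_axis])
    third_axis = "SI" if spec.third_point_region == "superior" else "ML"
    third_point = compute_third_point(partitions[third_axis], spec)
    anchor = 0.5 * (anchors[0] + anchors[1])  # midpoint of the primary anchors
    secondary = compute_secondary_axis(primary, anchor, third_point)

    provisional = assemble_acs(primary, secondary, spec, origin=samples.mean(axis=0))
    origin = place_origin(aligned, spec, provisional, mode=origin_mode)
    acs_aligned = ACS(
        origin=origin,
        ML=provisional.ML,
        AP=provisional.AP,
        SI=provisional.SI,
        space="aligned",
        bone_id=bone_id,
        acs_variant=acs_variant,
    ).validate()

    # a mirrored transform maps the *mirrored* working mesh; to_original of the
    # ACS therefore lands in the right bone's own scanner space
    acs_original = map_acs_between_spaces(acs_aligned, transform, "to_original").validate()

    return ACSAssignment(
        acs_aligned=acs_aligned,
        acs_original=acs_original,
        alignment=result,
        spec=spec,
        warnings=[str(w.message) for w in caught],
    )
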