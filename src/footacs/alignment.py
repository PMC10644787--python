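"""Rigid registration of subject bones to pre-oriented templates.

Right-side bones are first mirrored across the sagittal (x = 0) plane so a
single left-side template per bone suffices.  Alignment then proceeds in two
stages: a principal-axes initialization (with exhaustive resolution of the
four proper-rotation sign ambiguities) followed by point-to-surface iterative
closest point refinement.  Rotation + translation only — no scaling, since
subject and template share physical units and scaling would distort the
volumetric-region extents used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh_io import TriangleMesh
from .registry import Template
from .surface import SurfaceQuery, sample_surface

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "mirror_mesh",
    "initial_alignment",
    "icp_align",
    "map_acs_between_spaces",
]

_ORTHO_TOL = 1e-9


class DegeneratePrincipalAxesWarning(UserWarning):
    """Principal spreads nearly equal; falling back to centroid alignment."""


@dataclass
class RigidTransform:
    """x -> R x + t, with a flag recording whether a sagittal mirror was
    applied to the subject before this rigid map."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), mm
    mirrored: bool = False

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        R = self.rotation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6 or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls, mirrored: bool = False) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), mirrored=mirrored)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            mirrored=self.mirrored or other.mirrored,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, mirrored=self.mirrored)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class AlignmentResult:
    transform: RigidTransform
    rms_residual: float  # mm, point-to-surface RMS at convergence
    iterations_used: int
    converged: bool
    residual_history: list = field(default_factory=list)


def mirror_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Reflect across the x = 0 plane, reversing face winding so outward
    normals are preserved.  The arbitrary choice of mirror plane is absorbed
    by the subsequent rigid alignment."""
    vertices = mesh.vertices.copy()
    vertices[:, 0] = -vertices[:, 0]
    faces = mesh.faces[:, [0, 2, 1]].copy()
    return TriangleMesh(vertices, faces, name=mesh.name)


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors (columns, descending spread) and singular values of the
    centered point cloud."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:  # proper basis so sign candidates stay rotations
        evecs[:, 2] = -evecs[:, 2]
    return evecs, np.sqrt(np.maximum(evals[order], 0.0))


def initial_alignment(
    subject: TriangleMesh,
    template: Template,
    sample_count: int = 2000,
    seed: int = 0,
) -> RigidTransform:
    """Coarse alignment: centroid translation + principal-axes rotation.

    Principal axes of area-weighted surface samples are matched; among the
    four sign assignments that give a proper rotation, the one minimizing the
    RMS nearest-surface distance of a 500-point subsample wins.  If the two
    largest spreads are nearly equal (ratio > 0.98) the axes are unreliable
    and a centroid-only translation is returned with a warning.
    """
    subj_pts = sample_surface(subject, sample_count, seed=seed)
    tmpl_pts = sample_surface(template.mesh, sample_count, seed=seed + 1)
    subj_centroid = subj_pts.mean(axis=0)
    tmpl_centroid = tmpl_pts.mean(axis=0)

    U_s, spread_s = _principal_axes(subj_pts)
    U_t, _ = _principal_axes(tmpl_pts)
    if spread_s[0] <= 0 or spread_s[1] / spread_s[0] > 0.98:
        warnings.warn(
            "nearly equal principal spreads; falling back to centroid-only alignment",
            DegeneratePrincipalAxesWarning,
            stacklevel=2,
        )
        return RigidTransform(np.eye(3), tmpl_centroid - subj_centroid)

    query = SurfaceQuery(template.mesh)
    subsample = subj_pts[:: max(1, len(subj_pts) // 500)][:500]
    best = None
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            signs = np.array([s1, s2, s1 * s2])  # det(R) stays +1
            R = U_t @ np.diag(signs) @ U_s.T
            t = tmpl_centroid - R @ subj_centroid
            # a few ICP iterations settle each candidate into its own basin,
            # so the flipped candidates can no longer win on PCA noise alone
            R, t, rms, _ = _icp_iterate(subsample, query, R, t, max_iterations=25, tolerance=1e-4)
            if best is None or rms < best[0]:
                best = (rms, R, t)
    _, R, t = best
    return RigidTransform(R, t)


def _icp_iterate(samples, query: SurfaceQuery, R, t, max_iterations: int, tolerance: float):
    """Core ICP loop: alternate closest-surface matching and a Kabsch refit of
    the absolute pose.  Returns (R, t, rms, history); the residual history is
    non-increasing by construction."""
    moved = samples @ R.T + t
    matched, dists = query.closest_points(moved)
    rms = float(np.sqrt(np.mean(dists**2)))
    if not np.isfinite(rms):
        raise FloatingPointError("non-finite ICP residual")
    history = [rms]
    for _ in range(max_iterations):
        R, t = _kabsch(samples, matched)
        moved = samples @ R.T + t
        matched, dists = query.closest_points(moved)
        new_rms = float(np.sqrt(np.mean(dists**2)))
        if not np.isfinite(new_rms):
            raise FloatingPointError("non-finite ICP residual")
        history.append(new_rms)
        improvement = rms - new_rms
        rms = new_rms
        if improvement < tolerance:
            break
    return R, t, rms, history


def _kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping source onto target."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, tc - R @ sc


def icp_align(
    subject: TriangleMesh,
    template: Template,
    max_iterations: int = 200,
    tolerance: float = 1e-5,
    sample_count: int = 2000,
    seed: int = 0,
    initial: RigidTransform | None = None,
) -> AlignmentResult:
    """Point-to-surface rigid ICP of *subject* onto *template*.

    Area-weighted surface samples of the subject are matched to their closest
    points on the template surface; a Kabsch solve updates the pose; iteration
    stops when the RMS residual improves by less than *tolerance* (mm) or the
    iteration budget runs out.  Deterministic given *seed*.
    """
    if sample_count < 100:
        raise ValueError("sample_count must be >= 100")
    if initial is None:
        initial = initial_alignment(subject, template, seed=seed)

    samples = sample_surface(subject, sample_count, seed=seed + 7)
    query = SurfaceQuery(template.mesh)

    R, t, rms, history = _icp_iterate(
        samples,
        query,
        initial.rotation.copy(),
        initial.translation.copy(),
        max_iterations=max_iterations,
        tolerance=tolerance,
    )
    iterations = len(history) - 1
    # converged iff the loop stopped on the improvement criterion
    converged = iterations < max_iterations or (
        len(history) >= 2 and history[-2] - history[-1] < tolerance
    )
    if max_iterations == 0:
        converged = False

    transform = RigidTransform(R, t, mirrored=initial.mirrored)
    return AlignmentResult(
        transform=transform,
        rms_residual=rms,
        iterations_used=iterations,
        converged=converged,
        residual_history=history,
    )


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def map_acs_between_spaces(acs, transform: RigidTransform, direction: str):
    """Carry an ACS between the bone's original space and template-aligned space.

    ``direction`` is ``"to_aligned"`` or ``"to_original"``.  For mirrored
    (right-side) bones the sagittal reflection is applied on the original-space
    side, with the ML axis negated afterwards so the frame stays right-handed
    (ML then points medially on the right bone as well).  Axes are
    re-orthonormalized after mapping; ``to_original`` of ``to_aligned`` is the
    identity.
    """
    from .acs_core import ACS  # local import to avoid a cycle

    if direction not in ("to_aligned", "to_original"):
        raise ValueError("direction must be 'to_aligned' or 'to_original'")

    origin = np.asarray(acs.origin, dtype=np.float64)
    axes = np.column_stack([acs.ML, acs.AP, acs.SI]).astype(np.float64)
    mirror = np.diag([-1.0, 1.0, 1.0])

    if direction == "to_aligned":
        if transform.mirrored:
            origin = mirror @ origin
            axes = mirror @ axes
            axes[:, 0] = -axes[:, 0]  # restore right-handedness, ML medial
        origin = transform.rotation @ origin + transform.translation
        axes = transform.rotation @ axes
        space = "aligned"
    else:
        inv = transform.inverse()
        origin = inv.rotation @ origin + inv.translation
        axes = inv.rotation @ axes
        if transform.mirrored:
            axes[:, 0] = -axes[:, 0]
            origin = mirror @ origin
            axes = mirror @ axes
        space = "original"

    axes = _nearest_rotation(axes)
    return ACS(
        origin=origin,
        ML=axes[:, 0],
        AP=axes[:, 1],
        SI=axes[:, 2],
        space=space,
        bone_id=acs.bone_id,
        acs_variant=acs.acs_variant,
    )
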