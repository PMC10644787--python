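"""Comparison metrics and group statistics for assigned coordinate systems.

Three analyses are supported, all carried out in the shared template-aligned
frame (the only frame common to bones that live in different scanner spaces):

* per-axis angle differences between two ACSs of the same bone (e.g. from two
  segmentations, or an individual vs its group mean);
* projection of each ACS axis to the bone surface, with the distance to the
  matching statistical-shape-model correspondence particle (group mean vs
  overall mean analysis);
* one-way ANOVA with Tukey's HSD post hoc across population groups.

Summary tables report sample mean ± sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acs_core import ACS
from .mesh_io import ParticleSet, TriangleMesh
from .surface import first_ray_hit

__all__ = [
    "AngleDifferenceResult",
    "ProjectionDistanceResult",
    "DegenerateDataError",
    "angle_difference",
    "project_axis_to_surface",
    "nearest_particle",
    "correspondence_distance",
    "one_way_anova",
    "tukey_hsd",
    "summarize",
]

AXES = ("ML", "AP", "SI")


class DegenerateDataError(ValueError):
    """Statistics requested on data with no usable variance."""


@dataclass
class AngleDifferenceResult:
    """Per-axis angles (degrees, in [0, 180]) between two ACSs of one bone."""

    theta_ML: float
    theta_AP: float
    theta_SI: float
    bone_id: str = ""
    pair_label: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_ML, self.theta_AP, self.theta_SI])


@dataclass
class ProjectionDistanceResult:
    """Distance between an axis-to-surface projection and the matching
    correspondence particle."""

    axis: str
    particle_index: int
    d: float  # mm
    projected_point: np.ndarray
    particle_point: np.ndarray


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    # direction-sensitive: a flipped axis reads ~180 deg, a genuine failure
    # signal.  atan2 form: exact 0 for identical vectors and well-conditioned
    # at small angles, unlike arccos of the clipped dot product.
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def angle_difference(acs_a: ACS, acs_b: ACS) -> AngleDifferenceResult:
    """Angles between corresponding labelled axes of two ACSs (degrees).

    Both ACSs must be expressed in the same space; the angle is the full
    direction-sensitive arccos of the dot product (no absolute value).
    """
    if acs_a.space != acs_b.space:
        raise ValueError(
            f"ACSs live in different spaces ({acs_a.space!r} vs {acs_b.space!r}); "
            "compare them in the shared template-aligned frame"
        )
    return AngleDifferenceResult(
        theta_ML=_angle_deg(acs_a.ML, acs_b.ML),
        theta_AP=_angle_deg(acs_a.AP, acs_b.AP),
        theta_SI=_angle_deg(acs_a.SI, acs_b.SI),
        bone_id=acs_a.bone_id or acs_b.bone_id,
        pair_label=f"{acs_a.bone_id}:{acs_a.acs_variant}",
    )


def project_axis_to_surface(acs: ACS, mesh: TriangleMesh) -> dict[str, np.ndarray]:
    """For each of ML/AP/SI, the nearest ray-surface intersection from the ACS
    origin along the positive axis direction."""
    out = {}
    for name in AXES:
        out[name] = first_ray_hit(mesh, acs.origin, getattr(acs, name))
    return out


def nearest_particle(point: np.ndarray, particles: ParticleSet) -> tuple[int, float]:
    """Index and exact Euclidean distance of the closest correspondence
    particle (ties break to the lowest index)."""
    pts = particles.points
    if len(pts) == 0:
        raise ValueError("empty particle set")
    point = np.asarray(point, dtype=np.float64)
    d = np.linalg.norm(pts - point, axis=1)
    idx = int(np.argmin(d))
    # recompute through the single-vector path so the result is bitwise equal
    # to a direct distance computation (self-comparison identities)
    return idx, float(np.linalg.norm(pts[idx] - point))


def correspondence_distance(
    reference: tuple[ACS, TriangleMesh, ParticleSet],
    target: tuple[ACS, TriangleMesh, ParticleSet],
) -> dict[str, ProjectionDistanceResult]:
    """Axis-projection distances of *target* against the particle indices
    identified on *reference*.

    On the reference (overall mean) each axis is projected to the surface and
    the nearest particle index recorded; on the target (a group mean) the same
    axis is projected and the distance to the particle with that SAME index is
    measured — correspondence particles share indices across shapes.
    """
    ref_acs, ref_mesh, ref_particles = reference
    tgt_acs, tgt_mesh, tgt_particles = target
    if len(ref_particles) != len(tgt_particles):
        raise ValueError(
            f"particle count mismatch: reference has {len(ref_particles)}, "
            f"target has {len(tgt_particles)} (no correspondence)"
        )
    ref_proj = project_axis_to_surface(ref_acs, ref_mesh)
    tgt_proj = project_axis_to_surface(tgt_acs, tgt_mesh)
    out = {}
    for name in AXES:
        idx, _ = nearest_particle(ref_proj[name], ref_particles)
        particle = tgt_particles.points[idx]
        d = float(np.linalg.norm(tgt_proj[name] - particle))
        out[name] = ProjectionDistanceResult(
            axis=name,
            particle_index=idx,
            d=d,
            projected_point=tgt_proj[name],
            particle_point=particle,
        )
    return out


# ---------------------------------------------------------------------------
# group statistics


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    return gs


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA.

    Returns ``(F, df_between, df_within, p)`` with
    ``F = (SSB / df_b) / (SSW / df_w)`` and p from the F distribution.
    """
    gs = _check_groups(groups)
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(all_vals) - len(gs)
    if ssw <= 0:
        raise DegenerateDataError(
            "zero within-group variance (all observations identical within groups); "
            "the F statistic is undefined"
        )
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def tukey_hsd(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey's honestly-significant-difference post hoc on all group pairs.

    Uses the studentized-range distribution with pooled within-group variance
    (Tukey-Kramer for unequal group sizes).  Returns one row per pair with the
    mean difference, q statistic, adjusted p and a significance flag at
    *alpha*.
    """
    gs = _check_groups(groups)
    k = len(gs)
    df_w = sum(len(g) for g in gs) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    if msw <= 0:
        raise DegenerateDataError("zero pooled within-group variance; Tukey q is undefined")
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            se = np.sqrt(msw / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "mean_diff": diff,
                    "q": q,
                    "q_critical": q_crit,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=np.float64)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def summarize(
    df: pd.DataFrame,
    value_col: str = "value",
    bone_col: str = "bone",
    group_col: str = "group",
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-bone-per-group mean ± SD table with a pooled ``Mean`` row.

    Mirrors the layout of a bones-by-groups results table: one row per bone
    entry, one column per group, cells formatted ``mean ± SD`` (sample SD,
    n-1 denominator; SD is 0 for a single observation).  The ``Mean`` row
    pools all observations of a group.
    """
    if len(df) == 0:
        raise ValueError("no results to summarize")
    bones = list(dict.fromkeys(df[bone_col]))
    groups = list(dict.fromkeys(df[group_col]))
    table = {}
    for g in groups:
        col = []
        sub_g = df[df[group_col] == g]
        for b in bones:
            vals = sub_g.loc[sub_g[bone_col] == b, value_col].to_numpy()
            if len(vals) == 0:
                col.append("")
                continue
            m, s = _mean_sd(vals)
            col.append(f"{m:.{decimals}f} ± {s:.{decimals}f}")
        m, s = _mean_sd(sub_g[value_col].to_numpy())
        col.append(f"{m:.{decimals}f} ± {s:.{decimals}f}")
        table[g] = col
    return pd.DataFrame(table, index=bones + ["Mean"])
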