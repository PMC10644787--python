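"""Per-bone rules for anatomical coordinate construction, plus template management.

Each of the 14 foot/ankle bones carries a rule set describing how its
anatomical coordinate system is built in template-aligned space: how many
equal-width volumetric regions the bone is divided into per plane, along
which axis the two extreme-region centroids define the primary axis, which
region's centroid supplies the third point for the secondary axis, and where
the origin may be placed.  The talus and calcaneus support joint-specific
variants (talonavicular, tibiotalar, subtalar, calcaneocuboid), each with its
own slightly re-oriented template.

Templates are pre-oriented left-side bones with medial along +x, anterior
along +y and superior along +z; right-side subjects are mirrored to left
before alignment.
"""

from __future__ import annotations

import json
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh_io import TriangleMesh, read_mesh

__all__ = [
    "BONE_IDS",
    "ALL_BONE_VARIANTS",
    "BoneSpec",
    "Template",
    "TemplateRegistry",
    "ConfigurationError",
    "CroppedBoneWarning",
    "detect_bone_and_side",
    "get_bone_spec",
    "valid_variants",
]

BONE_IDS = (
    "tibia",
    "fibula",
    "talus",
    "calcaneus",
    "navicular",
    "cuboid",
    "medial_cuneiform",
    "intermediate_cuneiform",
    "lateral_cuneiform",
    "metatarsal1",
    "metatarsal2",
    "metatarsal3",
    "metatarsal4",
    "metatarsal5",
)

#: valid ACS variants per bone; plain bones only carry the default ACS
_VARIANTS: dict[str, tuple[str, ...]] = {
    "talus": ("talonavicular", "tibiotalar", "subtalar_talus"),
    "calcaneus": ("subtalar_calcaneus", "calcaneocuboid"),
}
for _b in BONE_IDS:
    _VARIANTS.setdefault(_b, ("default",))

#: all 17 bone/variant combinations for which an ACS is defined
ALL_BONE_VARIANTS: tuple[tuple[str, str], ...] = tuple(
    (b, v) for b in BONE_IDS for v in _VARIANTS[b]
)

#: bones whose scans may be cropped (partial-length field of view)
PARTIAL_CAPABLE = frozenset(
    {"tibia", "fibula", "metatarsal1", "metatarsal2", "metatarsal3", "metatarsal4", "metatarsal5"}
)

#: extent ratio below which the partial-length template is selected
PARTIAL_TEMPLATE_RATIO = 0.6
#: extent ratio below which a "too cropped" warning is raised
CROPPED_WARNING_RATIO = 0.3


class ConfigurationError(ValueError):
    """Invalid bone/variant combination or missing template."""


class CroppedBoneWarning(UserWarning):
    """The subject bone is severely cropped; results may be unreliable."""


@dataclass(frozen=True)
class BoneSpec:
    """The rule set for constructing one bone's (or bone-variant's) ACS."""

    bone_id: str
    acs_variant: str
    regions_per_plane: int  # 3, 5 or 10 equal-width slabs per axis
    primary_region_axis: str  # ML / AP / SI: extreme slabs along this axis
    third_point_region: str  # "superior" or "lateral"
    axis_role_map: dict  # {"primary": .., "secondary": .., "tertiary": ..} -> axis labels
    origin_modes: tuple  # subset of {"bone_center", "joint_surface"}
    joint_direction: tuple  # template-space unit direction toward the joint
    template_id: str

    def __post_init__(self):
        roles = set(self.axis_role_map.values())
        if roles != {"ML", "AP", "SI"}:
            raise ConfigurationError(f"axis_role_map must be a bijection onto ML/AP/SI: {self.axis_role_map}")
        if self.axis_role_map["primary"] != self.primary_region_axis:
            raise ConfigurationError("primary role must map to primary_region_axis")
        if self.regions_per_plane not in (3, 5, 10):
            raise ConfigurationError(f"regions_per_plane must be 3, 5 or 10, got {self.regions_per_plane}")


def _regions_for(bone_id: str) -> int:
    if bone_id == "calcaneus":
        return 10
    if bone_id in ("navicular", "cuboid"):
        return 5
    return 3


def _primary_axis_for(bone_id: str, variant: str) -> str:
    # medial/lateral extreme regions for the navicular and the tibiotalar talus;
    # superior/inferior for tibia and fibula; anterior/posterior otherwise
    if bone_id == "navicular" or (bone_id == "talus" and variant == "tibiotalar"):
        return "ML"
    if bone_id in ("tibia", "fibula"):
        return "SI"
    return "AP"


def _role_map(primary: str, third_point_region: str) -> dict:
    if primary == "SI":  # tibia/fibula: lateral third point -> ML secondary
        return {"primary": "SI", "secondary": "ML", "tertiary": "AP"}
    if primary == "ML":
        return {"primary": "ML", "secondary": "SI", "tertiary": "AP"}
    return {"primary": "AP", "secondary": "SI", "tertiary": "ML"}


#: template-space direction from the bone center toward the articulating joint,
#: used when the user asks for an on-joint origin
_JOINT_DIRECTIONS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("talus", "talonavicular"): (0.0, 1.0, 0.0),
    ("talus", "tibiotalar"): (0.0, 0.0, 1.0),
    ("talus", "subtalar_talus"): (0.0, 0.0, -1.0),
    ("calcaneus", "subtalar_calcaneus"): (0.0, 0.0, 1.0),
    ("calcaneus", "calcaneocuboid"): (0.0, 1.0, 0.0),
    ("tibia", "default"): (0.0, 0.0, -1.0),
    ("fibula", "default"): (0.0, 0.0, -1.0),
}


def valid_variants(bone_id: str) -> tuple[str, ...]:
    if bone_id not in BONE_IDS:
        raise ConfigurationError(f"unknown bone '{bone_id}'; known: {', '.join(BONE_IDS)}")
    return _VARIANTS[bone_id]


def get_bone_spec(bone_id: str, acs_variant: str = "default") -> BoneSpec:
    """Return the fully populated rule set for one bone/variant combination."""
    variants = valid_variants(bone_id)
    if acs_variant not in variants:
        raise ConfigurationError(
            f"bone '{bone_id}' has no ACS variant '{acs_variant}'; valid: {', '.join(variants)}"
        )
    primary = _primary_axis_for(bone_id, acs_variant)
    third = "lateral" if bone_id in ("tibia", "fibula") else "superior"
    return BoneSpec(
        bone_id=bone_id,
        acs_variant=acs_variant,
        regions_per_plane=_regions_for(bone_id),
        primary_region_axis=primary,
        third_point_region=third,
        axis_role_map=_role_map(primary, third),
        origin_modes=("bone_center", "joint_surface"),
        joint_direction=_JOINT_DIRECTIONS.get((bone_id, acs_variant), (0.0, 1.0, 0.0)),
        template_id=f"{bone_id}.{acs_variant}",
    )


# ---------------------------------------------------------------------------
# filename detection

# keyword -> bone, tried in order (metatarsal patterns before "tal" so that
# "metatarsal" does not read as a talus)
_BONE_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"(?:met(?:atarsal)?|mt)[\s_\-]*1(?!\d)", "metatarsal1"),
    (r"(?:met(?:atarsal)?|mt)[\s_\-]*2(?!\d)", "metatarsal2"),
    (r"(?:met(?:atarsal)?|mt)[\s_\-]*3(?!\d)", "metatarsal3"),
    (r"(?:met(?:atarsal)?|mt)[\s_\-]*4(?!\d)", "metatarsal4"),
    (r"(?:met(?:atarsal)?|mt)[\s_\-]*5(?!\d)", "metatarsal5"),
    (r"calc", "calcaneus"),
    (r"nav", "navicular"),
    (r"cub", "cuboid"),
    (r"(?:med|1st)[\s_\-]*cun|cun[\s_\-]*(?:med|1)(?!\d)", "medial_cuneiform"),
    (r"(?:int|2nd|mid)[\s_\-]*cun|cun[\s_\-]*(?:int|2)(?!\d)", "intermediate_cuneiform"),
    (r"(?:lat|3rd)[\s_\-]*cun|cun[\s_\-]*(?:lat|3)(?!\d)", "lateral_cuneiform"),
    (r"tib", "tibia"),
    (r"fib", "fibula"),
    (r"tal", "talus"),
)

_RIGHT_TOKENS = {"r", "rt", "right"}
_LEFT_TOKENS = {"l", "lt", "left"}


def detect_bone_and_side(filename: str):
    """Guess (bone_id, side, confident) from a file name.

    Matching is case-insensitive against a documented keyword table; side is
    read from standalone tokens (``r``/``right``/``rt`` vs ``l``/``left``/
    ``lt``).  ``confident`` is False whenever either field is ambiguous or
    missing — the batch driver then asks for an override instead of guessing.
    Never raises.
    """
    stem = os.path.splitext(os.path.basename(str(filename)))[0].lower()
    bone = None
    for pattern, bone_id in _BONE_PATTERNS:
        if re.search(pattern, stem):
            bone = bone_id
            break
    # cuneiform without a med/int/lat qualifier stays ambiguous
    if bone is None and "cun" in stem:
        return (None, None, False)
    tokens = set(re.split(r"[^a-z0-9]+", stem))
    is_right = bool(tokens & _RIGHT_TOKENS)
    is_left = bool(tokens & _LEFT_TOKENS)
    if is_right == is_left:  # both or neither
        side = None
    else:
        side = "right" if is_right else "left"
    return (bone, side, bone is not None and side is not None)


# ---------------------------------------------------------------------------
# templates


@dataclass
class Template:
    """A pre-oriented left-side template bone in canonical orientation
    (medial +x, anterior +y, superior +z)."""

    mesh: TriangleMesh
    bone_id: str
    acs_variant: str
    extent_along_primary: float  # mm, full-template extent along the primary axis
    partial_variant: str = "n/a"  # full / partial / n/a
    template_id: str = ""


class TemplateRegistry:
    """Loads templates from ``<root>/<bone>/<variant>/<full|partial>.ply`` plus
    a ``manifest.json`` recording template ids and primary-axis extents."""

    def __init__(self, root: str):
        self.root = root
        manifest_path = os.path.join(root, "manifest.json")
        if not os.path.exists(manifest_path):
            raise ConfigurationError(f"no manifest.json found in template directory {root}")
        with open(manifest_path) as fh:
            self.manifest = json.load(fh)
        self._cache: dict[tuple[str, str, str], Template] = {}

    def _load(self, bone_id: str, acs_variant: str, which: str) -> Template:
        key = (bone_id, acs_variant, which)
        if key in self._cache:
            return self._cache[key]
        try:
            entry = self.manifest[bone_id][acs_variant][which]
        except KeyError:
            raise ConfigurationError(
                f"no '{which}' template registered for {bone_id}/{acs_variant} under {self.root}"
            ) from None
        path = os.path.join(self.root, entry["file"])
        if not os.path.exists(path):
            raise ConfigurationError(f"template file missing: {path}")
        mesh = read_mesh(path)
        spec = get_bone_spec(bone_id, acs_variant)
        tpl = Template(
            mesh=mesh,
            bone_id=bone_id,
            acs_variant=acs_variant,
            extent_along_primary=float(entry["extent_along_primary"]),
            partial_variant=which if bone_id in PARTIAL_CAPABLE else "n/a",
            template_id=entry.get("template_id", spec.template_id),
        )
        self._cache[key] = tpl
        return tpl

    def get(self, bone_id: str, acs_variant: str = "default") -> Template:
        """The full-length template for a bone/variant."""
        return self._load(bone_id, acs_variant, "full")

    def select_template(
        self, bone_id: str, acs_variant: str, aligned_extent_ratio: float
    ) -> Template:
        """Pick full vs partial template from the subject's extent ratio.

        The ratio is the subject's extent along the primary axis divided by
        the full template's, estimated after provisional alignment.  Only
        tibia, fibula and metatarsals have partial-length variants; a warning
        is raised when the bone looks too cropped to be reliable.
        """
        if bone_id not in PARTIAL_CAPABLE:
            return self._load(bone_id, acs_variant, "full")
        if aligned_extent_ratio < CROPPED_WARNING_RATIO:
            warnings.warn(
                f"{bone_id}: extent ratio {aligned_extent_ratio:.2f} — bone is severely "
                "cropped; coordinate axes may be unreliable",
                CroppedBoneWarning,
                stacklevel=2,
            )
        which = "partial" if aligned_extent_ratio < PARTIAL_TEMPLATE_RATIO else "full"
        return self._load(bone_id, acs_variant, which)
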