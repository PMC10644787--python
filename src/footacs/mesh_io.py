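"""Reading and writing of the surface-mesh and point-set formats the toolbox touches.

Bone surface models arrive as triangle meshes in STL, PLY, VTK (legacy or XML)
or LS-DYNA-style keyword (``.k``) shell files; statistical-shape-model
correspondence particles arrive as plain-text ``.particles`` files with one
``x y z`` triple per line.  Everything is validated on load: a file that does
not describe a sane closed-ish triangle surface raises rather than returning
partial geometry.

Coordinates are treated as millimetres throughout; no unit conversion is
attempted.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "ParticleSet",
    "MeshFormatError",
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "read_particles",
    "write_particles",
    "write_acs_table",
]

#: tolerance (mm) below which vertices are considered duplicates and merged
VERTEX_MERGE_TOL = 1e-9


class MeshFormatError(ValueError):
    """Raised for unsupported file formats."""


class MeshParseError(ValueError):
    """Raised when a file cannot be parsed into valid geometry."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh: vertices in millimetres plus face connectivity.

    Faces are triples of vertex indices with consistent outward winding.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int64
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshParseError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshParseError(f"faces must be (m, 3), got {self.faces.shape}")

    # -- derived geometry -------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def surface_area(self) -> float:
        return float(self.face_areas().sum())

    def validate(self) -> "TriangleMesh":
        """Check structural invariants; raise :class:`MeshParseError` on violation."""
        if self.n_vertices < 4:
            raise MeshParseError(f"mesh '{self.name}': only {self.n_vertices} vertices (need >= 4)")
        if self.n_faces < 4:
            raise MeshParseError(f"mesh '{self.name}': only {self.n_faces} faces (need >= 4)")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshParseError(f"mesh '{self.name}': face index out of range")
        a, b, c = self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]
        if np.any((a == b) | (b == c) | (a == c)):
            raise MeshParseError(f"mesh '{self.name}': degenerate face (repeated vertex index)")
        if not np.isfinite(self.vertices).all():
            raise MeshParseError(f"mesh '{self.name}': non-finite vertex coordinates")
        if self.surface_area() <= 0.0:
            raise MeshParseError(f"mesh '{self.name}': zero surface area")
        return self


@dataclass
class ParticleSet:
    """Ordered correspondence points; index k marks the same relative anatomical
    location on every shape of a population."""

    points: np.ndarray  # (n, 3) float64, mm
    source_path: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshParseError(f"particles must be (n, 3), got {self.points.shape}")
        if len(self.points) < 1:
            raise MeshParseError(f"particle file '{self.source_path}' contains no points")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# helpers


def merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = VERTEX_MERGE_TOL):
    """Merge vertices closer than *tol* and drop faces that collapse.

    STL stores each triangle's corners independently, so duplicate merging is
    what turns triangle soup back into connected geometry.
    """
    if len(vertices) == 0:
        return vertices, faces
    # quantize to a grid finer than tol; identical keys -> same vertex
    keys = np.round(vertices / max(tol, 1e-300)).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[np.sort(first)]
    # remap "first occurrence" order so output is stable w.r.t. input order
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    a, b, c = new_faces[:, 0], new_faces[:, 1], new_faces[:, 2]
    keep = (a != b) & (b != c) & (a != c)
    return new_vertices, new_faces[keep]


def _finalize(vertices, faces, name: str) -> TriangleMesh:
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    vertices, faces = merge_duplicate_vertices(vertices, faces)
    return TriangleMesh(vertices, faces, name=name).validate()


# ---------------------------------------------------------------------------
# .k (keyword-format shell mesh)
#
# Minimal dialect: *NODE and *ELEMENT_SHELL cards, fixed- or free-format,
# comma or whitespace separated.  Quads are split into two triangles along
# the 1-3 diagonal.  Anything else errors loudly.


def _read_k(path: str) -> TriangleMesh:
    nodes: dict[int, tuple[float, float, float]] = {}
    elems: list[tuple[int, ...]] = []
    section = None
    with open(path, "r", errors="replace") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("$"):
                continue
            if line.startswith("*"):
                kw = line.strip().upper()
                if kw.startswith("*NODE"):
                    section = "node"
                elif kw.startswith("*ELEMENT_SHELL"):
                    section = "shell"
                elif kw.startswith("*END"):
                    section = None
                else:
                    section = None  # ignore other cards
                continue
            if section is None:
                continue
            tokens = line.replace(",", " ").split()
            try:
                if section == "node":
                    nid = int(tokens[0])
                    x, y, z = (float(t) for t in tokens[1:4])
                    nodes[nid] = (x, y, z)
                else:  # shell: eid pid n1 n2 n3 [n4]
                    ids = [int(t) for t in tokens[2:6] if t]
                    if len(ids) < 3:
                        raise ValueError("fewer than 3 shell nodes")
                    elems.append(tuple(ids))
            except (ValueError, IndexError) as exc:
                raise MeshParseError(f"{path}:{lineno}: cannot parse {section} line: {exc}") from exc
    if not nodes or not elems:
        raise MeshParseError(f"{path}: no *NODE/*ELEMENT_SHELL data found")
    node_ids = sorted(nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    vertices = np.array([nodes[nid] for nid in node_ids])
    faces = []
    for el in elems:
        try:
            idx = [index[n] for n in el]
        except KeyError as exc:
            raise MeshParseError(f"{path}: shell references unknown node {exc}") from exc
        if len(idx) == 3 or idx[3] == idx[2]:  # triangles; dyna repeats n3 for tris
            faces.append(idx[:3])
        else:  # quad -> two triangles along the 1-3 diagonal
            faces.append([idx[0], idx[1], idx[2]])
            faces.append([idx[0], idx[2], idx[3]])
    return _finalize(vertices, faces, os.path.basename(path))


# ---------------------------------------------------------------------------
# VTK: legacy POLYDATA (ASCII) and XML PolyData / UnstructuredGrid (ASCII arrays)


def _read_vtk_legacy(path: str, text: str) -> TriangleMesh:
    tokens = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        tokens.extend(line.split())
    tokens_upper = [t.upper() for t in tokens]
    try:
        i = tokens_upper.index("POINTS")
        npts = int(tokens[i + 1])
        coords = np.array(tokens[i + 3 : i + 3 + 3 * npts], dtype=np.float64).reshape(npts, 3)
    except (ValueError, IndexError) as exc:
        raise MeshParseError(f"{path}: malformed POINTS block: {exc}") from exc
    faces: list[list[int]] = []

    def _cells_from(start: int, ncells: int) -> None:
        j = start
        for _ in range(ncells):
            cnt = int(tokens[j])
            cell = [int(t) for t in tokens[j + 1 : j + 1 + cnt]]
            j += cnt + 1
            if cnt == 3:
                faces.append(cell)
            elif cnt == 4:
                faces.append([cell[0], cell[1], cell[2]])
                faces.append([cell[0], cell[2], cell[3]])
            else:
                raise MeshParseError(f"{path}: only triangle/quad cells supported, got {cnt}-gon")

    if "POLYGONS" in tokens_upper:
        i = tokens_upper.index("POLYGONS")
        ncells = int(tokens[i + 1])
        _cells_from(i + 3, ncells)
    elif "CELLS" in tokens_upper:
        i = tokens_upper.index("CELLS")
        ncells = int(tokens[i + 1])
        _cells_from(i + 3, ncells)
    else:
        raise MeshParseError(f"{path}: no POLYGONS/CELLS block found")
    return _finalize(coords, faces, os.path.basename(path))


def _read_vtk_xml(path: str) -> TriangleMesh:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MeshParseError(f"{path}: invalid XML: {exc}") from exc
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshParseError(f"{path}: no <Piece> element")

    def _array(parent, name):
        for da in parent.iter("DataArray"):
            if da.get("Name") == name or (name == "Points" and parent.tag == "Points"):
                if da.get("format", "ascii") != "ascii":
                    raise MeshParseError(f"{path}: only ascii-format DataArrays supported")
                return np.fromstring(da.text or "", sep=" ")
        raise MeshParseError(f"{path}: missing DataArray '{name}'")

    pts_el = piece.find("Points")
    if pts_el is None:
        raise MeshParseError(f"{path}: no <Points> element")
    coords = _array(pts_el, "Points").reshape(-1, 3)
    cells_el = piece.find("Polys")
    if cells_el is None:
        cells_el = piece.find("Cells")
    if cells_el is None:
        raise MeshParseError(f"{path}: no <Polys>/<Cells> element")
    connectivity = _array(cells_el, "connectivity").astype(np.int64)
    offsets = _array(cells_el, "offsets").astype(np.int64)
    faces: list[list[int]] = []
    start = 0
    for off in offsets:
        cell = connectivity[start:off].tolist()
        start = off
        if len(cell) == 3:
            faces.append(cell)
        elif len(cell) == 4:
            faces.append([cell[0], cell[1], cell[2]])
            faces.append([cell[0], cell[2], cell[3]])
        else:
            raise MeshParseError(f"{path}: only triangle/quad cells supported, got {len(cell)}-gon")
    return _finalize(coords, faces, os.path.basename(path))


def _read_vtk(path: str) -> TriangleMesh:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if head.lstrip().startswith(b"<"):
        return _read_vtk_xml(path)
    try:
        text = open(path, "r", errors="strict").read()
    except UnicodeDecodeError as exc:
        raise MeshParseError(f"{path}: binary legacy VTK not supported: {exc}") from exc
    return _read_vtk_legacy(path, text)


def _write_vtk_legacy(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{mesh.name or 'footacs mesh'}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_stl_ascii(mesh: TriangleMesh, path: str) -> None:
    # own writer: full double precision (library binary STL is float32-lossy)
    v = mesh.vertices
    tri = v[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lengths = np.linalg.norm(normals, axis=1)
    normals = normals / np.where(lengths > 0, lengths, 1.0)[:, None]
    with open(path, "w") as fh:
        fh.write(f"solid {mesh.name or 'footacs'}\n")
        for n, t in zip(normals, tri):
            fh.write(f"  facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}\n")
            fh.write("    outer loop\n")
            for p in t:
                fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {mesh.name or 'footacs'}\n")


def _write_ply_ascii(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# public API

_EXT_ALIASES = {
    "stl": "stl",
    "ply": "ply",
    "vtk": "vtk",
    "vtp": "vtk",
    "vtu": "vtk",
    "k": "k",
    "key": "k",
}


def read_mesh(path: str, format_hint: str | None = None) -> TriangleMesh:
    """Read a triangle surface mesh from *path*.

    Supported formats: ``stl`` (ASCII + binary), ``ply`` (ASCII + binary),
    ``vtk`` (legacy POLYDATA and XML PolyData/UnstructuredGrid with ASCII
    arrays) and ``k`` keyword shell meshes.  Duplicate vertices within
    ``VERTEX_MERGE_TOL`` mm are merged.

    Parameters
    ----------
    path:
        File to read; must exist.
    format_hint:
        Override the format deduced from the extension.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = (format_hint or os.path.splitext(path)[1].lstrip(".")).lower()
    fmt = _EXT_ALIASES.get(ext)
    if fmt is None:
        raise MeshFormatError(
            f"unsupported mesh format '.{ext}' for {path}; supported: stl, ply, vtk, k"
        )
    if fmt == "k":
        return _read_k(path)
    if fmt == "vtk":
        return _read_vtk(path)
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted types for bad files
        raise MeshParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshParseError(f"{path}: no triangle geometry found")
    return _finalize(tm.vertices, tm.faces, os.path.basename(path))


def write_mesh(mesh: TriangleMesh, path: str, format: str | None = None) -> str:
    """Write *mesh* to *path* as ``stl``, ``ply`` or ``vtk`` (legacy ASCII).

    Round trip through :func:`read_mesh` reproduces vertices within 1e-6 mm
    and identical connectivity up to vertex reordering.
    """
    mesh.validate()
    ext = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    fmt = _EXT_ALIASES.get(ext)
    if fmt not in {"stl", "ply", "vtk"}:
        raise MeshFormatError(f"unsupported output format '{ext}'; supported: stl, ply, vtk")
    if fmt == "vtk":
        _write_vtk_legacy(mesh, path)
    elif fmt == "stl":
        _write_stl_ascii(mesh, path)
    else:
        _write_ply_ascii(mesh, path)
    return path


def read_particles(path: str) -> ParticleSet:
    """Read a plain-text correspondence-particle file (one ``x y z`` per line)."""
    points = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MeshParseError(f"{path}:{lineno}: expected 'x y z', got {line!r}")
            try:
                points.append([float(p) for p in parts])
            except ValueError as exc:
                raise MeshParseError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from exc
    if not points:
        raise MeshParseError(f"{path}: no particle points found")
    return ParticleSet(np.array(points), source_path=path)


def write_particles(particles: ParticleSet | np.ndarray, path: str) -> str:
    pts = particles.points if isinstance(particles, ParticleSet) else np.asarray(particles)
    with open(path, "w") as fh:
        for p in pts:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    return path


_ACS_COLUMNS = [
    "bone",
    "acs_variant",
    "space",
    "origin_x",
    "origin_y",
    "origin_z",
    "ML_x",
    "ML_y",
    "ML_z",
    "AP_x",
    "AP_y",
    "AP_z",
    "SI_x",
    "SI_y",
    "SI_z",
]


def write_acs_table(records, path: str) -> str:
    """Write the output spreadsheet: one row per bone per space.

    Each record is ``(bone_label, acs_original, acs_aligned)``; the table holds
    the origin and the three unit axis vectors in both the bone's original
    coordinate space and the template-aligned space, at full float precision.
    """
    lines = [",".join(_ACS_COLUMNS)]
    for bone_label, acs_orig, acs_aligned in records:
        for acs in (acs_orig, acs_aligned):
            vals = np.concatenate([acs.origin, acs.ML, acs.AP, acs.SI])
            row = [str(bone_label), acs.acs_variant or "", acs.space]
            row += [f"{v:.17g}" for v in vals]
            lines.append(",".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
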