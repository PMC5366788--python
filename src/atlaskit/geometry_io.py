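"""Readers for the polygonal formats atlas GeometrySegments reference.

Supported: Wavefront OBJ (with optional MTL diffuse color), STL (ASCII
and binary), and VTK legacy polydata in ASCII (POINTS + POLYGONS
sections).  Meshes are read for verification and statistics, not
rendering: polygons are fan-triangulated on ingestion and only vertex
positions, triangle connectivity and one optional material color are
kept.

OBJ and STL parsing goes through trimesh; the VTK legacy dialect is
parsed here directly.
"""

from __future__ import annotations

import os
import re
import struct
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import MeshFormatError

__all__ = ["Mesh", "MeshStats", "read_mesh", "mesh_stats",
           "weld_vertices", "triangle_set"]


@dataclass
class Mesh:
    """Triangle mesh: (n,3) float vertices, (m,3) int faces, optional RGB color."""

    vertices: np.ndarray
    faces: np.ndarray
    color: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError("face index out of vertex range")


@dataclass
class MeshStats:
    vertex_count: int
    face_count: int
    bbox_min: tuple[float, float, float] | None
    bbox_max: tuple[float, float, float] | None


def read_mesh(path: str | os.PathLike) -> Mesh:
    """Read an OBJ, STL or VTK legacy polydata file into a Mesh.

    Dispatch is by extension; OBJ 1-based indices arrive 0-based, and the
    diffuse color (``Kd``) of the material selected by ``usemtl`` is
    attached when an MTL file is present.  STL carries no color.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        return _read_obj(path)
    if ext == ".stl":
        return _read_stl(path)
    if ext == ".vtk":
        return _read_vtk_polydata(path)
    raise MeshFormatError(f"unknown geometry format: {path!r}")


def _read_obj(path: str) -> Mesh:
    try:
        m = trimesh.load(path, file_type="obj", process=False)
    except Exception as exc:
        raise MeshFormatError(f"cannot read OBJ {path!r}: {exc}") from exc
    if isinstance(m, trimesh.Scene):
        geoms = list(m.geometry.values())
        if not geoms:
            raise MeshFormatError(f"OBJ {path!r} contains no geometry")
        m = trimesh.util.concatenate(geoms)
    color = _obj_material_color(path)
    return Mesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces),
                color=color)


def _obj_material_color(path: str) -> tuple[float, float, float] | None:
    """Kd of the material selected by the first usemtl, if resolvable."""
    mtllib = usemtl = None
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "mtllib" and mtllib is None and len(tok) > 1:
                mtllib = tok[1]
            elif tok[0] == "usemtl" and usemtl is None and len(tok) > 1:
                usemtl = tok[1]
    if mtllib is None or usemtl is None:
        return None
    mtl_path = os.path.join(os.path.dirname(path), mtllib)
    if not os.path.exists(mtl_path):
        return None
    current = None
    with open(mtl_path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "newmtl" and len(tok) > 1:
                current = tok[1]
            elif tok[0] == "Kd" and current == usemtl and len(tok) >= 4:
                return tuple(float(x) for x in tok[1:4])
    return None


def _read_stl(path: str) -> Mesh:
    _check_stl_integrity(path)
    try:
        m = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:
        raise MeshFormatError(f"cannot read STL {path!r}: {exc}") from exc
    return Mesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces),
                color=None)


def _check_stl_integrity(path: str) -> None:
    """Reject truncated binary STL before handing the file to the reader."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(84)
    if len(head) < 15:
        raise MeshFormatError(f"STL {path!r} is too short")
    if head.lstrip()[:5] == b"solid" and b"facet" in open(path, "rb").read(4096):
        return  # ASCII STL; the reader validates record structure
    if len(head) < 84:
        raise MeshFormatError(f"binary STL {path!r} is truncated")
    (ntri,) = struct.unpack("<I", head[80:84])
    expected = 84 + 50 * ntri
    if size < expected:
        raise MeshFormatError(
            f"binary STL {path!r} truncated: {size} bytes, expected {expected}")


_VTK_HEADER = re.compile(r"^#\s*vtk\s+DataFile\s+Version\s+[\d.]+", re.I)


def _read_vtk_polydata(path: str) -> Mesh:
    """Parse VTK legacy ASCII polydata: POINTS and POLYGONS sections only."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines or not _VTK_HEADER.match(lines[0]):
        raise MeshFormatError(f"{path!r} is not a VTK legacy file")
    if len(lines) < 4 or lines[2].strip().upper() != "ASCII":
        raise MeshFormatError(f"VTK {path!r}: only the ASCII encoding is supported")
    if "POLYDATA" not in lines[3].upper():
        raise MeshFormatError(f"VTK {path!r}: DATASET must be POLYDATA")

    tokens = " ".join(lines[4:]).split()
    pos = 0

    def expect_int(what: str) -> int:
        nonlocal pos
        try:
            v = int(tokens[pos])
        except (IndexError, ValueError):
            raise MeshFormatError(f"VTK {path!r}: bad {what} count") from None
        pos += 1
        return v

    vertices = np.empty((0, 3))
    faces: list[tuple[int, int, int]] = []
    npoints = 0
    while pos < len(tokens):
        kw = tokens[pos].upper()
        if kw == "POINTS":
            pos += 1
            npoints = expect_int("POINTS")
            pos += 1  # dtype token
            need = 3 * npoints
            vals = tokens[pos:pos + need]
            if len(vals) < need:
                raise MeshFormatError(f"VTK {path!r}: POINTS section truncated")
            vertices = np.array(vals, dtype=np.float64).reshape(npoints, 3)
            pos += need
        elif kw == "POLYGONS":
            pos += 1
            npolys = expect_int("POLYGONS")
            expect_int("POLYGONS size")
            for _ in range(npolys):
                cnt = expect_int("polygon vertex")
                idx = [expect_int("polygon index") for _ in range(cnt)]
                if any(i >= npoints for i in idx):
                    raise MeshFormatError(
                        f"VTK {path!r}: face index out of range")
                for t in range(1, cnt - 1):  # fan triangulation
                    faces.append((idx[0], idx[t], idx[t + 1]))
        else:
            pos += 1  # skip unrecognized sections token-wise
    return Mesh(vertices=vertices, faces=np.array(faces, dtype=np.int64)
                if faces else np.empty((0, 3), dtype=np.int64))


def mesh_stats(mesh: Mesh) -> MeshStats:
    """Counts and componentwise bounding box; bbox is None for empty meshes."""
    if len(mesh.vertices) == 0:
        return MeshStats(0, 0, None, None)
    return MeshStats(
        vertex_count=len(mesh.vertices),
        face_count=len(mesh.faces),
        bbox_min=tuple(mesh.vertices.min(axis=0)),
        bbox_max=tuple(mesh.vertices.max(axis=0)),
    )


def weld_vertices(mesh: Mesh) -> Mesh:
    """Merge bit-identical vertices (exact equality, no epsilon).

    STL stores each triangle's vertices independently; welding makes a
    triangle soup comparable with its indexed OBJ/VTK twin.
    """
    if len(mesh.vertices) == 0:
        return Mesh(vertices=mesh.vertices.copy(), faces=mesh.faces.copy(),
                    color=mesh.color)
    unique, inverse = np.unique(mesh.vertices, axis=0, return_inverse=True)
    faces = inverse[mesh.faces]
    return Mesh(vertices=unique, faces=faces, color=mesh.color)


def triangle_set(mesh: Mesh) -> frozenset:
    """Order-independent set of triangles as coordinate tuples.

    Each triangle is cyclically rotated so its lexicographically smallest
    vertex comes first; the set is invariant to vertex indexing and face
    order, letting cross-format twins be compared exactly.
    """
    tris = set()
    for f in mesh.faces:
        pts = [tuple(mesh.vertices[i]) for i in f]
        k = min(range(3), key=lambda i: pts[i])
        tris.add((pts[k], pts[(k + 1) % 3], pts[(k + 2) % 3]))
    return frozenset(tris)
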