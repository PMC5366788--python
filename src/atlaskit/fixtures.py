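"""Deterministic synthetic-atlas generation and defect injection.

The generator writes a complete, self-consistent miniature atlas —
label-map and MRI-like NRRD volumes, per-structure cuboid meshes in OBJ
and ASCII STL, the atlas description in both canonical and nested JSON
forms, a TSV twin, and a manifest recording exactly what was written —
as a pure function of a seed and a size specification.  The synthetic
anatomy is a stack of disjoint axis-aligned boxes: trivially meshable as
cuboids, so the label map and the geometry agree exactly by
construction.  Everything the rest of the toolkit does can therefore be
tested against the manifest without downloading real atlas data.

:func:`mutate_atlas` copies a generated directory and injects exactly
one named defect, giving the validator a ground-truth harness: the
mutant must produce the injected finding and the pristine tree none.
"""

from __future__ import annotations

import json
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .converters import generated_color
from .errors import AtlasError
from .format_model import parse_atlas, serialize_atlas
from .volume_ops import Volume, load_volume, save_volume

__all__ = ["FixtureManifest", "generate_fixture_atlas", "mutate_atlas",
           "DEFECT_CODES"]

DEFECT_CODES = ("DUP_ID", "DANGLING_REF", "CYCLE", "MISSING_FILE",
                "LABEL_UNDECLARED", "LABEL_UNUSED", "LABEL_DUPLICATE",
                "MULTI_AUTHORITATIVE", "BAD_COLOR")

_SPACING = (0.9375, 0.9375, 1.5)  # mm per voxel along array axes


@dataclass
class FixtureManifest:
    """What the generator wrote, for use as a test oracle."""

    seed: int
    spec: dict
    node_counts: dict[str, int]
    label_map: dict[str, dict]          # label value (str) -> {structure, name}
    files: list[dict]                   # path, kind, per-kind details
    node_types: dict[str, list[str]]    # every node ID -> its type list
    geometry_segments: list[str]
    canonical_path: str = "atlas.json"
    nested_path: str = "atlas_nested.json"
    tsv_path: str = "structures.tsv"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "spec": self.spec,
            "nodeCounts": self.node_counts, "labelMap": self.label_map,
            "files": self.files, "nodeTypes": self.node_types,
            "geometrySegments": self.geometry_segments,
            "canonicalPath": self.canonical_path,
            "nestedPath": self.nested_path, "tsvPath": self.tsv_path,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FixtureManifest":
        return cls(seed=doc["seed"], spec=doc["spec"],
                   node_counts=doc["nodeCounts"], label_map=doc["labelMap"],
                   files=doc["files"], node_types=doc["nodeTypes"],
                   geometry_segments=doc["geometrySegments"],
                   canonical_path=doc["canonicalPath"],
                   nested_path=doc["nestedPath"], tsv_path=doc["tsvPath"])

    @classmethod
    def read(cls, directory: str | os.PathLike) -> "FixtureManifest":
        with open(Path(directory) / "manifest.json", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Geometry writers (fixed float formatting keeps output byte-deterministic)


_CUBOID_QUADS = (  # faces of a box, as corner-bit indices (x=1, y=2, z=4)
    (0, 2, 3, 1),  # k = lo
    (4, 5, 7, 6),  # k = hi
    (0, 1, 5, 4),  # j = lo
    (2, 6, 7, 3),  # j = hi
    (0, 4, 6, 2),  # i = lo
    (1, 3, 7, 5),  # i = hi
)


def _cuboid(lo: np.ndarray, hi: np.ndarray):
    """8 vertices and 12 triangles of the axis-aligned box [lo, hi]."""
    verts = [[hi[0] if b & 1 else lo[0],
              hi[1] if b & 2 else lo[1],
              hi[2] if b & 4 else lo[2]] for b in range(8)]
    tris = []
    for a, b, c, d in _CUBOID_QUADS:
        tris.append((a, b, c))
        tris.append((a, c, d))
    return np.array(verts, dtype=np.float64), tris


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _write_obj(path: Path, verts: np.ndarray, tris, mtl_name: str | None,
               material: str = "structure") -> None:
    lines = []
    if mtl_name is not None:
        lines.append(f"mtllib {mtl_name}")
        lines.append(f"usemtl {material}")
    for v in verts:
        lines.append("v " + " ".join(_fmt(c) for c in v))
    for a, b, c in tris:
        lines.append(f"f {a + 1} {b + 1} {c + 1}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_mtl(path: Path, color, material: str = "structure") -> None:
    path.write_text(
        f"newmtl {material}\nKd {' '.join(_fmt(c) for c in color)}\n",
        encoding="utf-8")


def _write_stl_ascii(path: Path, verts: np.ndarray, tris, name: str) -> None:
    lines = [f"solid {name}"]
    for a, b, c in tris:
        p0, p1, p2 = verts[a], verts[b], verts[c]
        n = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(n)
        n = n / norm if norm > 0 else n
        lines.append("  facet normal " + " ".join(_fmt(x) for x in n))
        lines.append("    outer loop")
        for p in (p0, p1, p2):
            lines.append("      vertex " + " ".join(_fmt(x) for x in p))
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Generation


def _pack_boxes(rng: np.random.Generator, grid_shape, n: int):
    """Disjoint axis-aligned boxes, one per structure, stacked along axis 0.

    Each structure gets its own slab of the grid with a one-voxel margin,
    and a random sub-box within it; disjointness is by construction.
    """
    slab = grid_shape[0] // n
    if slab < 3:
        raise AtlasError(
            f"{n} boxes do not pack into a grid of shape {tuple(grid_shape)}")
    boxes = []
    for i in range(n):
        lo = np.empty(3, dtype=np.int64)
        hi = np.empty(3, dtype=np.int64)
        lo[0] = i * slab + 1
        hi[0] = int(rng.integers(lo[0] + 1, (i + 1) * slab))
        for a in (1, 2):
            lo[a] = int(rng.integers(1, grid_shape[a] // 2))
            hi[a] = int(rng.integers(lo[a] + 1, grid_shape[a] - 1))
        boxes.append((lo, hi))
    return boxes


def _structure_names(n: int) -> list[str]:
    base = ["cortex", "thalamus", "putamen", "caudate", "hippocampus",
            "amygdala", "cerebellum", "brainstem", "ventricle", "pallidum"]
    return [base[i] if i < len(base) else f"region{i + 1}" for i in range(n)]


def generate_fixture_atlas(out_dir: str | os.PathLike, seed: int,
                           grid_shape: tuple[int, int, int] = (24, 24, 16),
                           n_structures: int = 5,
                           depth: int = 3) -> FixtureManifest:
    """Write a synthetic atlas directory; returns its manifest.

    All content is a pure function of ``(seed, grid_shape, n_structures,
    depth)``: the same call writes byte-identical trees.  ``depth`` is
    the number of Group levels in the hierarchy (root included);
    structures are attached round-robin along the chain of groups.
    """
    if n_structures < 1:
        raise AtlasError("need at least one structure")
    if any(s < 8 for s in grid_shape):
        raise AtlasError(f"grid shape {grid_shape} below the (8, 8, 8) minimum")
    if depth < 1:
        raise AtlasError("depth must be at least 1")

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "meshes").mkdir(exist_ok=True)

    rng = np.random.default_rng(seed)
    boxes = _pack_boxes(rng, grid_shape, n_structures)
    names = _structure_names(n_structures)
    colors = [generated_color(i, n_structures) for i in range(n_structures)]

    # -- volumes ---------------------------------------------------------
    labels = np.zeros(grid_shape, dtype=np.int16)
    for value, (lo, hi) in enumerate(boxes, start=1):
        labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = value
    save_volume(Volume(labels, spacing=_SPACING, kind="label"),
                out / "volumes" / "labels.nrrd")

    mri = ndimage.gaussian_filter(
        rng.normal(size=grid_shape), sigma=2.0)
    mri += 0.6 * (labels > 0)  # structures are brighter than background
    mri = ((mri - mri.min()) / (mri.max() - mri.min()) * 100.0).astype(
        np.float32)
    save_volume(Volume(mri, spacing=_SPACING, kind="scalar"),
                out / "volumes" / "mri.nrrd")

    # -- meshes ----------------------------------------------------------
    spacing = np.array(_SPACING)
    mesh_files = []
    for i, (lo, hi) in enumerate(boxes):
        verts, tris = _cuboid(lo * spacing, hi * spacing)
        slug = names[i]
        _write_mtl(out / "meshes" / f"{slug}.mtl", colors[i])
        _write_obj(out / "meshes" / f"{slug}.obj", verts, tris,
                   mtl_name=f"{slug}.mtl")
        _write_stl_ascii(out / "meshes" / f"{slug}.stl", verts, tris, slug)
        mesh_files.append({"path": f"meshes/{slug}.obj", "kind": "mesh",
                           "vertexCount": 8, "faceCount": 12})
        # STL stores vertices per triangle, so its soup reads back 36-wide
        mesh_files.append({"path": f"meshes/{slug}.stl", "kind": "mesh",
                           "vertexCount": 36, "faceCount": 12})

    # -- hierarchy -------------------------------------------------------
    n_groups = depth
    group_ids = ["#root"] + [f"#group{d}" for d in range(1, n_groups)]
    group_names = ["Synthetic anatomy"] + [f"level{d + 1}"
                                           for d in range(1, n_groups)]
    group_members: dict[str, list[str]] = {g: [] for g in group_ids}
    for d in range(n_groups - 1):
        group_members[group_ids[d]].append(group_ids[d + 1])
    attachment: dict[str, str] = {}
    for i in range(n_structures):
        g = group_ids[i % n_groups]
        sid = f"#{names[i]}"
        group_members[g].append(sid)
        attachment[sid] = g

    # -- nodes -----------------------------------------------------------
    canonical: list[dict] = [
        {"@id": "#header", "@type": ["Header"],
         "structureRoot": "#root", "images": ["#mri"],
         "title": "Synthetic atlas", "species": "synthetic",
         "version": "1.0"},
    ]
    for gid, gname in zip(group_ids, group_names):
        canonical.append({"@id": gid, "@type": ["Group"], "name": gname,
                          "members": group_members[gid]})

    structure_blocks: list[dict] = []  # used for the nested form too
    for i, name in enumerate(names):
        slug = name
        children = {
            "labelseg": {"@id": f"#{slug}_labelseg",
                         "@type": ["Segment", "LabelMapSegment"],
                         "authoritative": True, "labelValue": i + 1,
                         "dataSource": "#labelmap_source"},
            "geomsrc": {"@id": f"#{slug}_geometry_source",
                        "@type": ["DataSource", "FileDataSource"],
                        "location": f"meshes/{slug}.obj", "format": "OBJ"},
            "geomseg": {"@id": f"#{slug}_geomseg",
                        "@type": ["Segment", "GeometrySegment"],
                        "authoritative": False,
                        "dataSource": f"#{slug}_geometry_source"},
            "annotation": {"@id": f"#{slug}_annotation",
                           "@type": ["Annotation"], "title": name,
                           "description": f"Synthetic box standing in for "
                                          f"the {name}."},
            "style": {"@id": f"#{slug}_style", "@type": ["Style"],
                      "color": colors[i], "transparency": 0.0,
                      "visibility": True},
            "structure": {"@id": f"#{slug}", "@type": ["Structure"],
                          "name": name,
                          "segments": [f"#{slug}_labelseg", f"#{slug}_geomseg"],
                          "annotations": [f"#{slug}_annotation"],
                          "styles": [f"#{slug}_style"]},
        }
        structure_blocks.append(children)
        canonical += [children["structure"], children["labelseg"],
                      children["geomsrc"], children["geomseg"],
                      children["annotation"], children["style"]]

    canonical.append({"@id": "#labelmap_source",
                      "@type": ["DataSource", "FileDataSource"],
                      "location": "volumes/labels.nrrd", "format": "NRRD"})
    canonical.append({"@id": "#mri_source",
                      "@type": ["DataSource", "FileDataSource"],
                      "location": "volumes/mri.nrrd", "format": "NRRD"})
    canonical.append({"@id": "#mri", "@type": ["Image", "NRRDImage"],
                      "role": "MRI", "dataSource": "#mri_source"})

    graph = parse_atlas(json.dumps({"@graph": canonical}), strict=True)
    (out / "atlas.json").write_text(serialize_atlas(graph), encoding="utf-8")

    # Nested form: structures embed their segments, annotation and style
    # inline; groups and data sources stay top-level and reference by ID.
    nested_nodes: list[dict] = [canonical[0]]
    nested_nodes += [dict(n) for n in canonical[1:1 + n_groups]]
    for blk in structure_blocks:
        s = dict(blk["structure"])
        s["segments"] = [
            dict(blk["labelseg"]),
            dict(blk["geomseg"]),
        ]
        s["annotations"] = [dict(blk["annotation"])]
        s["styles"] = [dict(blk["style"])]
        nested_nodes.append(s)
        nested_nodes.append(dict(blk["geomsrc"]))
    nested_nodes += [dict(n) for n in canonical[-3:]]
    (out / "atlas_nested.json").write_text(
        json.dumps({"@graph": nested_nodes}, indent=2) + "\n", encoding="utf-8")

    # -- TSV twin --------------------------------------------------------
    tsv_lines = ["# synthetic structure table",
                 "name\tlabelValue\tgeometryFile\tparent\tcolor"]
    for i, name in enumerate(names):
        parent_group = attachment[f"#{name}"]
        parent = "" if parent_group == "#root" else \
            group_names[group_ids.index(parent_group)]
        hexcolor = "#" + "".join(
            f"{int(round(255 * c)):02x}" for c in colors[i])
        tsv_lines.append(
            f"{name}\t{i + 1}\tmeshes/{name}.obj\t{parent}\t{hexcolor}")
    (out / "structures.tsv").write_text("\n".join(tsv_lines) + "\n",
                                        encoding="utf-8")

    # -- manifest --------------------------------------------------------
    node_counts: dict[str, int] = {}
    for node in graph.nodes.values():
        node_counts[node.types[0]] = node_counts.get(node.types[0], 0) + 1
    manifest = FixtureManifest(
        seed=int(seed),
        spec={"gridShape": list(grid_shape), "nStructures": n_structures,
              "depth": depth},
        node_counts=node_counts,
        label_map={str(i + 1): {"structure": f"#{names[i]}", "name": names[i]}
                   for i in range(n_structures)},
        files=[{"path": "volumes/labels.nrrd", "kind": "labelVolume",
                "shape": list(grid_shape),
                "labels": list(range(1, n_structures + 1)),
                "spacing": list(_SPACING)},
               {"path": "volumes/mri.nrrd", "kind": "scalarVolume",
                "shape": list(grid_shape), "spacing": list(_SPACING)},
               *mesh_files],
        node_types={nid: list(n.types) for nid, n in graph.nodes.items()},
        geometry_segments=[f"#{n}_geomseg" for n in names],
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# Defect injection


def mutate_atlas(directory: str | os.PathLike, defect: str, seed: int = 0,
                 dest_dir: str | os.PathLike | None = None) -> Path:
    """Copy a fixture directory and inject exactly one defect.

    The copy differs from the original by one defect in the canonical
    atlas file or its data; the original tree is untouched.  Injections
    are designed to trigger only their own rule: validating the mutant
    yields finding(s) with code *defect* and nothing else.
    """
    if defect not in DEFECT_CODES:
        raise AtlasError(f"unknown defect code {defect!r}")
    src = Path(directory)
    dest = Path(dest_dir) if dest_dir is not None else \
        src.parent / f"{src.name}-{defect.lower()}"
    if dest.exists():
        shutil.rmtree(dest)
    shutil.copytree(src, dest)

    atlas_path = dest / "atlas.json"
    doc = json.loads(atlas_path.read_text(encoding="utf-8"))
    nodes: list[dict] = doc["@graph"]

    def first(pred) -> dict:
        for n in nodes:
            if pred(n):
                return n
        raise AtlasError(f"fixture lacks a node needed to inject {defect}")

    def types(n: dict) -> list[str]:
        t = n.get("@type", [])
        return [t] if isinstance(t, str) else t

    structures = [n for n in nodes if "Structure" in types(n)]
    rewrite = True

    if defect == "DUP_ID":
        nodes.append(dict(structures[0]))
    elif defect == "DANGLING_REF":
        structures[0].setdefault("annotations", []).append("#ghost")
    elif defect == "CYCLE":
        groups = [n for n in nodes if "Group" in types(n)]
        groups[-1].setdefault("members", []).append(groups[0]["@id"])
    elif defect == "MISSING_FILE":
        src_node = first(lambda n: "DataSource" in types(n)
                         and str(n.get("location", "")).endswith(".obj"))
        (dest / src_node["location"]).unlink()
        rewrite = False
    elif defect == "BAD_COLOR":
        style = first(lambda n: "Style" in types(n))
        style["color"] = [1.5, 0.0, 0.0]
    elif defect == "LABEL_DUPLICATE":
        if len(structures) < 2:
            raise AtlasError("LABEL_DUPLICATE needs at least two structures")
        seg = _label_segment_of(nodes, structures[0], types)
        nodes.append({"@id": "#mutant_duplicate_claim",
                      "@type": ["Segment", "LabelMapSegment"],
                      "authoritative": False,
                      "labelValue": seg["labelValue"],
                      "dataSource": seg["dataSource"]})
        structures[1].setdefault("segments", []).append(
            "#mutant_duplicate_claim")
    elif defect == "MULTI_AUTHORITATIVE":
        seg = _label_segment_of(nodes, structures[0], types)
        nodes.append({"@id": "#mutant_second_authoritative",
                      "@type": ["Segment", "LabelMapSegment"],
                      "authoritative": True,
                      "labelValue": seg["labelValue"],
                      "dataSource": seg["dataSource"]})
        structures[0].setdefault("segments", []).append(
            "#mutant_second_authoritative")
    elif defect in ("LABEL_UNDECLARED", "LABEL_UNUSED"):
        label_path = dest / "volumes" / "labels.nrrd"
        volume = load_volume(label_path, kind="label")
        voxels = volume.voxels
        if defect == "LABEL_UNDECLARED":
            # The one-voxel packing margin guarantees the corner is background.
            voxels[0:2, 0:2, 0:2] = int(voxels.max()) + 1
        else:
            voxels[voxels == 1] = 0
        save_volume(volume, label_path)
        rewrite = False

    if rewrite:
        atlas_path.write_text(json.dumps(doc, indent=2) + "\n",
                              encoding="utf-8")
    return dest


def _label_segment_of(nodes: list[dict], structure: dict, types) -> dict:
    for sid in structure.get("segments", []):
        for n in nodes:
            if n.get("@id") == sid and "LabelMapSegment" in types(n):
                return n
    raise AtlasError(f"structure {structure.get('@id')} has no LabelMapSegment")
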