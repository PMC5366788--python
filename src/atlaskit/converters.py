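"""TSV-to-atlas conversion.

The simplest way to author an atlas is a tab-separated table with one
row per anatomical structure.  Required columns are ``name`` and
``labelValue``; optional columns are ``geometryFile`` (adds a
GeometrySegment with a file DataSource), ``parent`` (nests the structure
under a named Group, created on demand), ``color`` ("#RRGGBB" or
"r,g,b" floats) and ``description`` (becomes an Annotation).

Dialect: UTF-8, tab-separated, first non-comment line is the header,
lines starting with ``#`` are ignored, no quoting.  The output graph
always passes a strict parse; when the referenced data files exist it
also validates clean.
"""

from __future__ import annotations

import colorsys
import os
import re

from .errors import ConversionError
from .format_model import AtlasGraph, parse_atlas, serialize_atlas
import json

__all__ = ["tsv_to_atlas", "generated_color"]

_GEOMETRY_FORMATS = {".obj": "OBJ", ".stl": "STL", ".vtk": "VTK"}

_SLUG_RE = re.compile(r"[^A-Za-z0-9_]+")


def _slug(name: str) -> str:
    s = _SLUG_RE.sub("_", name).strip("_")
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "n_" + s
    return s


def generated_color(index: int, total: int) -> list[float]:
    """Deterministic palette: evenly spaced hues at full saturation."""
    h = index / max(total, 1)
    return [round(c, 6) for c in colorsys.hsv_to_rgb(h, 1.0, 1.0)]


def _parse_color(text: str) -> list[float]:
    text = text.strip()
    if re.match(r"^#[0-9a-fA-F]{6}$", text):
        return [int(text[i:i + 2], 16) / 255.0 for i in (1, 3, 5)]
    parts = [p for p in re.split(r"[,\s]+", text) if p]
    if len(parts) == 3:
        try:
            rgb = [float(p) for p in parts]
        except ValueError:
            raise ConversionError(f"unparseable color {text!r}") from None
        if all(0 <= c <= 1 for c in rgb):
            return rgb
    raise ConversionError(f"unparseable color {text!r}")


def _read_rows(tsv_path: str) -> tuple[list[str], list[dict[str, str]]]:
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    with open(tsv_path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                continue
            row = {header[i]: cells[i].strip()
                   for i in range(min(len(header), len(cells)))}
            rows.append(row)
    if header is None:
        raise ConversionError(f"{tsv_path!r} has no header row")
    return header, rows


def tsv_to_atlas(tsv_path: str | os.PathLike,
                 atlas_title: str = "Converted atlas",
                 label_map_path: str = "labels.nrrd",
                 default_colors: bool = True) -> AtlasGraph:
    """Convert a structure table to an atlas graph.

    Every data row becomes a Structure with an authoritative
    LabelMapSegment (all rows share one label-map DataSource at
    *label_map_path*); rows with a ``geometryFile`` additionally get a
    GeometrySegment with its own file DataSource; a Style node carries
    the given or generated color.  Rows with a ``parent`` value nest
    under that named Group, otherwise directly under the root Group.
    """
    tsv_path = os.fspath(tsv_path)
    header, rows = _read_rows(tsv_path)
    for required in ("name", "labelValue"):
        if required not in header:
            raise ConversionError(f"TSV is missing required column {required!r}")
    if not rows:
        raise ConversionError("TSV has no data rows")

    names: set[str] = set()
    values: set[int] = set()
    nodes: list[dict] = []
    root_members: list[str] = []
    group_ids: dict[str, str] = {}
    group_members: dict[str, list[str]] = {}

    nodes.append({"@id": "#header", "@type": ["Header"],
                  "structureRoot": "#root", "title": atlas_title,
                  "version": "1.0"})
    nodes.append({"@id": "#labelmap_source",
                  "@type": ["DataSource", "FileDataSource"],
                  "location": label_map_path, "format": "NRRD"})

    body: list[dict] = []
    for i, row in enumerate(rows):
        name = row.get("name", "")
        if not name:
            raise ConversionError(f"row {i + 1}: empty structure name")
        if name in names:
            raise ConversionError(f"duplicate structure name {name!r}")
        names.add(name)
        try:
            label_value = int(row["labelValue"])
        except (KeyError, ValueError):
            raise ConversionError(
                f"row {i + 1}: labelValue {row.get('labelValue')!r} "
                "is not an integer") from None
        if label_value <= 0:
            raise ConversionError(
                f"row {i + 1}: labelValue must be positive, got {label_value}")
        if label_value in values:
            raise ConversionError(f"duplicate labelValue {label_value}")
        values.add(label_value)

        slug = _slug(name)
        sid = f"#{slug}"
        segment_ids = [f"#{slug}_labelmap"]
        body.append({"@id": segment_ids[0],
                     "@type": ["Segment", "LabelMapSegment"],
                     "authoritative": True, "labelValue": label_value,
                     "dataSource": "#labelmap_source"})

        geometry = row.get("geometryFile", "")
        if geometry:
            ext = os.path.splitext(geometry)[1].lower()
            fmt = _GEOMETRY_FORMATS.get(ext)
            if fmt is None:
                raise ConversionError(
                    f"row {i + 1}: unrecognized geometry format {geometry!r}")
            body.append({"@id": f"#{slug}_geometry_source",
                         "@type": ["DataSource", "FileDataSource"],
                         "location": geometry, "format": fmt})
            body.append({"@id": f"#{slug}_geometry",
                         "@type": ["Segment", "GeometrySegment"],
                         "authoritative": False,
                         "dataSource": f"#{slug}_geometry_source"})
            segment_ids.append(f"#{slug}_geometry")

        color_text = row.get("color", "")
        if color_text:
            color = _parse_color(color_text)
        elif default_colors:
            color = generated_color(i, len(rows))
        else:
            color = [0.5, 0.5, 0.5]
        body.append({"@id": f"#{slug}_style", "@type": ["Style"],
                     "color": color, "transparency": 0.0, "visibility": True})

        structure = {"@id": sid, "@type": ["Structure"], "name": name,
                     "segments": segment_ids, "styles": [f"#{slug}_style"]}
        description = row.get("description", "")
        if description:
            body.append({"@id": f"#{slug}_annotation", "@type": ["Annotation"],
                         "title": name, "description": description})
            structure["annotations"] = [f"#{slug}_annotation"]
        body.append(structure)

        parent = row.get("parent", "")
        if parent:
            if parent in names and parent != name or parent == name:
                raise ConversionError(
                    f"row {i + 1}: parent {parent!r} names a structure; "
                    "only groups may contain members")
            gid = group_ids.get(parent)
            if gid is None:
                gid = f"#group_{_slug(parent)}"
                group_ids[parent] = gid
                group_members[gid] = []
                root_members.append(gid)
            group_members[gid].append(sid)
        else:
            root_members.append(sid)

    for parent_name, gid in group_ids.items():
        nodes.append({"@id": gid, "@type": ["Group"], "name": parent_name,
                      "members": group_members[gid]})
    nodes.append({"@id": "#root", "@type": ["Group"], "name": atlas_title,
                  "members": root_members})
    nodes.extend(body)

    graph = parse_atlas(json.dumps({"@graph": nodes}), strict=True,
                        source_path=tsv_path)
    return graph
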