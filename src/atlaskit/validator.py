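"""Non-interactive consistency checking of an atlas and its data files.

A headless "testing client": it takes a leniently parsed graph and
reports structural defects (duplicate IDs, dangling references,
membership cycles, orphans, naming-convention violations) and — when
``check_data`` is on — data-level defects (missing or unreadable files,
label values present in the authoritative label map but declared by no
structure, declared values absent from the volume, clashing claims).

Severities are this module's own policy: label-coverage mismatches are
warnings because atlases legitimately omit background or unlabeled
tissue, while identity clashes (duplicate IDs, duplicate label claims,
out-of-range style channels) are errors.  Findings are deterministically
ordered by rule code and then file order, so repeated runs are
byte-comparable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import MeshFormatError, VolumeError
from .format_model import AtlasGraph, AtlasNode, iter_references

__all__ = ["Finding", "RULE_CODES", "validate",
           "findings_to_json_lines", "findings_to_text"]

RULE_CODES = (
    "DUP_ID", "DANGLING_REF", "NO_HEADER", "CYCLE",
    "BAD_TYPE_CASE", "BAD_ATTR_CASE",
    "MISSING_FILE", "BAD_FORMAT",
    "LABEL_UNDECLARED", "LABEL_UNUSED", "LABEL_DUPLICATE",
    "MULTI_AUTHORITATIVE", "BAD_COLOR", "ORPHAN_NODE",
)

_WARNINGS = {"BAD_TYPE_CASE", "BAD_ATTR_CASE", "LABEL_UNDECLARED",
             "LABEL_UNUSED", "MULTI_AUTHORITATIVE", "ORPHAN_NODE"}

KNOWN_FORMATS = ("NRRD", "VTK", "STL", "OBJ")


@dataclass(frozen=True)
class Finding:
    """One validator result."""

    severity: str  # "error" | "warning"
    code: str
    node_id: str | None
    message: str

    def to_json(self) -> str:
        return json.dumps({"severity": self.severity, "code": self.code,
                           "nodeId": self.node_id, "message": self.message},
                          sort_keys=True)


def _finding(code: str, node_id: str | None, message: str) -> Finding:
    severity = "warning" if code in _WARNINGS else "error"
    return Finding(severity=severity, code=code, node_id=node_id,
                   message=message)


def validate(graph: AtlasGraph, data_root: str | os.PathLike | None = None,
             check_data: bool = False) -> list[Finding]:
    """All findings for *graph*, deterministically ordered.

    *graph* should come from a lenient parse so that duplicate-ID,
    dangling-reference and missing-header defects are visible here
    rather than raised.  Data checks need *data_root* (usually the atlas
    file's directory) against which relative DataSource locations are
    resolved; remote (http/https) locations are skipped.
    """
    if check_data:
        if data_root is None:
            raise ValueError("check_data=True requires a data_root")
        if not os.path.isdir(data_root):
            raise OSError(f"data_root {os.fspath(data_root)!r} is not readable")

    findings: list[Finding] = []
    findings += _parse_issue_findings(graph)
    findings += _cycle_findings(graph)
    findings += _case_findings(graph)
    findings += _color_findings(graph)
    findings += _multi_authoritative_findings(graph)
    findings += _orphan_findings(graph)
    findings += _format_findings(graph)
    findings += _label_claim_findings(graph)
    if check_data:
        findings += _data_findings(graph, os.fspath(data_root))

    order = {nid: i for i, nid in enumerate(graph.nodes)}
    findings.sort(key=lambda f: (f.code, order.get(f.node_id, -1), f.message))
    return findings


# ---------------------------------------------------------------------------
# Structural rules


def _parse_issue_findings(graph: AtlasGraph) -> list[Finding]:
    return [_finding(issue.code, issue.node_id, issue.message)
            for issue in graph.issues
            if issue.code in ("DUP_ID", "DANGLING_REF", "NO_HEADER")]


def _cycle_findings(graph: AtlasGraph) -> list[Finding]:
    """Detect cycles in the Group membership graph (white/gray/black DFS)."""
    color: dict[str, int] = {}  # 0 visiting, 1 done
    findings: list[Finding] = []

    def visit(nid: str, path: list[str]) -> None:
        node = graph.nodes.get(nid)
        if node is None:
            return
        color[nid] = 0
        for child in node.members:
            if child not in graph.nodes:
                continue
            if color.get(child) == 0:
                findings.append(_finding(
                    "CYCLE", child,
                    f"membership cycle through {child!r} "
                    f"(declared again by {nid!r})"))
            elif child not in color:
                visit(child, path + [child])
        color[nid] = 1

    for node in graph.nodes.values():
        if node.has_type("Group") and node.id not in color:
            visit(node.id, [node.id])
    return findings


def _case_findings(graph: AtlasGraph) -> list[Finding]:
    findings = []
    for node in graph.nodes.values():
        for t in node.types:
            if not t or not t[0].isupper():
                findings.append(_finding(
                    "BAD_TYPE_CASE", node.id,
                    f"type {t!r} is not capitalized"))
        for attr in node.attributes:
            if not attr or not attr[0].islower():
                findings.append(_finding(
                    "BAD_ATTR_CASE", node.id,
                    f"attribute {attr!r} does not begin lower-case"))
    return findings


def _color_findings(graph: AtlasGraph) -> list[Finding]:
    findings = []
    for style in graph.nodes_of_type("Style"):
        color = style.get("color")
        if color is not None:
            bad = (not isinstance(color, list) or len(color) != 3
                   or any(not isinstance(c, (int, float)) or not 0 <= c <= 1
                          for c in color))
            if bad:
                findings.append(_finding(
                    "BAD_COLOR", style.id,
                    f"color {color!r} is not three channels in [0, 1]"))
        tr = style.get("transparency")
        if tr is not None and not (isinstance(tr, (int, float)) and 0 <= tr <= 1):
            findings.append(_finding(
                "BAD_COLOR", style.id,
                f"transparency {tr!r} outside [0, 1]"))
    return findings


def _segment_claims(graph: AtlasGraph):
    """Yield (structure, segment) for every LabelMapSegment declaration."""
    for structure in graph.nodes_of_type("Structure"):
        for sid in structure.segments:
            seg = graph.nodes.get(sid)
            if seg is not None and seg.has_type("LabelMapSegment"):
                yield structure, seg


def _multi_authoritative_findings(graph: AtlasGraph) -> list[Finding]:
    findings = []
    for structure in graph.nodes_of_type("Structure"):
        per_subtype: dict[str, int] = {}
        for sid in structure.segments:
            seg = graph.nodes.get(sid)
            if seg is None or not seg.authoritative:
                continue
            for subtype in ("LabelMapSegment", "GeometrySegment"):
                if seg.has_type(subtype):
                    per_subtype[subtype] = per_subtype.get(subtype, 0) + 1
        for subtype, n in per_subtype.items():
            if n > 1:
                findings.append(_finding(
                    "MULTI_AUTHORITATIVE", structure.id,
                    f"{n} authoritative {subtype}s on one structure"))
    return findings


def _orphan_findings(graph: AtlasGraph) -> list[Finding]:
    if graph.header is None:
        return []
    reached = {graph.header.id}
    stack = [graph.header.id]
    while stack:
        node = graph.nodes[stack.pop()]
        for _, ref in iter_references(node):
            if ref in graph.nodes and ref not in reached:
                reached.add(ref)
                stack.append(ref)
    return [_finding("ORPHAN_NODE", nid, "node unreachable from the header")
            for nid in graph.nodes if nid not in reached]


def _format_findings(graph: AtlasGraph) -> list[Finding]:
    findings = []
    for src in graph.nodes_of_type("DataSource"):
        fmt = src.get("format")
        if fmt not in KNOWN_FORMATS:
            findings.append(_finding(
                "BAD_FORMAT", src.id,
                f"format {fmt!r} not one of {'/'.join(KNOWN_FORMATS)}"))
        if not src.get("location"):
            findings.append(_finding(
                "MISSING_FILE", src.id, "DataSource has no location"))
    return findings


def _label_claim_findings(graph: AtlasGraph) -> list[Finding]:
    """LABEL_DUPLICATE: two structures claim one value in one label map."""
    findings = []
    claims: dict[tuple[str, int], list[str]] = {}
    for structure, seg in _segment_claims(graph):
        lv = seg.label_value
        src = seg.data_source
        if lv is None or src is None:
            continue
        owners = claims.setdefault((src, lv), [])
        if structure.id not in owners:
            owners.append(structure.id)
    for (src, lv), owners in claims.items():
        for other in owners[1:]:
            findings.append(_finding(
                "LABEL_DUPLICATE", other,
                f"label value {lv} in {src!r} already claimed by {owners[0]!r}"))
    return findings


# ---------------------------------------------------------------------------
# Data rules


def _is_remote(location: str) -> bool:
    return location.startswith(("http://", "https://"))


def _data_findings(graph: AtlasGraph, data_root: str) -> list[Finding]:
    findings: list[Finding] = []
    paths: dict[str, str] = {}
    for src in graph.nodes_of_type("DataSource"):
        location = src.get("location")
        if not location or _is_remote(location):
            continue
        path = location if os.path.isabs(location) else os.path.join(
            data_root, location)
        paths[src.id] = path
        if not os.path.exists(path):
            findings.append(_finding(
                "MISSING_FILE", src.id, f"referenced file {location!r} not found"))
            continue
        findings += _readable_findings(src, path)

    findings += _label_coverage_findings(graph, paths)
    return findings


def _readable_findings(src: AtlasNode, path: str) -> list[Finding]:
    fmt = src.get("format")
    try:
        if fmt == "NRRD":
            from .volume_ops import load_volume
            load_volume(path)
        elif fmt in ("VTK", "STL", "OBJ"):
            from .geometry_io import read_mesh
            read_mesh(path)
        else:
            return []  # already reported as BAD_FORMAT
    except (VolumeError, MeshFormatError, Exception) as exc:
        return [_finding("BAD_FORMAT", src.id,
                         f"file {os.path.basename(path)!r} unreadable as "
                         f"{fmt}: {exc}")]
    return []


def _label_coverage_findings(graph: AtlasGraph,
                             paths: dict[str, str]) -> list[Finding]:
    """Compare declared label values against the voxels actually present.

    Only label maps with at least one authoritative LabelMapSegment are
    scanned (non-authoritative maps are display conveniences); each
    volume is read once and its set of distinct nonzero values compared
    with every declaration pointing at it.
    """
    from .volume_ops import load_volume

    declared: dict[str, dict[int, str]] = {}   # src -> value -> structure
    authoritative_srcs: set[str] = set()
    for structure, seg in _segment_claims(graph):
        lv, src = seg.label_value, seg.data_source
        if lv is None or src is None:
            continue
        declared.setdefault(src, {}).setdefault(lv, structure.id)
        if seg.authoritative:
            authoritative_srcs.add(src)

    findings = []
    for src_id in declared:
        if src_id not in authoritative_srcs or src_id not in paths:
            continue
        path = paths[src_id]
        if not os.path.exists(path):
            continue
        try:
            volume = load_volume(path, kind="label")
        except (VolumeError, Exception):
            continue  # unreadable already reported
        present = set(int(v) for v in np.unique(volume.voxels)) - {0}
        decl = declared[src_id]
        undeclared = sorted(present - set(decl))
        if undeclared:
            findings.append(_finding(
                "LABEL_UNDECLARED", src_id,
                f"voxel values {undeclared} match no structure's labelValue"))
        for lv in sorted(set(decl) - present):
            findings.append(_finding(
                "LABEL_UNUSED", decl[lv],
                f"declared label value {lv} absent from the volume"))
    return findings


# ---------------------------------------------------------------------------
# Export


def findings_to_json_lines(findings: list[Finding]) -> str:
    return "\n".join(f.to_json() for f in findings) + ("\n" if findings else "")


def findings_to_text(findings: list[Finding]) -> str:
    if not findings:
        return "OK: no findings\n"
    lines = [f"{f.severity.upper():7s} {f.code:18s} "
             f"{f.node_id or '-':24s} {f.message}" for f in findings]
    return "\n".join(lines) + "\n"
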