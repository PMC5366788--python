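"""Node model, parser and serializer for JSON node-graph anatomy atlases.

An atlas file is a JSON document whose nodes are objects carrying an
``"@id"`` (a fragment-style token such as ``"#cortex"``), an ``"@type"``
list (most general type first, ``Header``, ``Group``, ``Structure``,
``Segment``, ``DataSource``, ``Image``, ``Annotation``, ``Style``, ...)
and arbitrary lower-case attributes.  Nodes link to each other by ID,
which keeps bulk data (label volumes, meshes, radiology images) out of
the metadata file: a ``Segment`` or ``Image`` points at a ``DataSource``
that knows where the bytes live.

Two serializations are accepted: the *canonical* form, a flat list of
nodes under a top-level ``"@graph"`` key (a bare top-level list is also
accepted), and a *nested* form in which child nodes may be embedded
inline as attribute values.  Parsing flattens nested input first;
serialization always emits the canonical form.  The parser is
deliberately an ad hoc JSON reader, not a general JSON-LD processor:
it implements exactly these two forms.  Unknown node types (for example
``Attribution`` or ``CoordinateFrame``) and unknown attributes survive a
parse/serialize round trip untouched.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterator

from .errors import (
    AtlasFormatError,
    DanglingReferenceError,
    DuplicateIDError,
    MissingHeaderError,
    UnknownIDError,
)

__all__ = [
    "NODE_ID_PATTERN",
    "AtlasNode",
    "AtlasGraph",
    "ParseIssue",
    "is_node_id",
    "parse_atlas",
    "flatten_nested",
    "resolve_reference",
    "serialize_atlas",
    "segments_for_structure",
    "iter_references",
]

#: IDs mirror URI fragment syntax: "#" followed by a nonempty identifier.
NODE_ID_PATTERN = re.compile(r"^#[A-Za-z_][A-Za-z0-9_.\-]*$")

_HEX_COLOR = re.compile(r"^#[0-9a-fA-F]{6}$")

# Types whose first entry callers most often dispatch on.
STRUCTURAL_TYPES = ("Header", "Group", "Structure", "Segment", "DataSource",
                    "Image", "Annotation", "Style")


def is_node_id(value: Any) -> bool:
    """True if *value* is a string shaped like a node ID ("#name")."""
    return isinstance(value, str) and bool(NODE_ID_PATTERN.match(value))


@dataclass
class ParseIssue:
    """A problem recorded during a lenient parse, consumed by the validator."""

    code: str          # DUP_ID | DANGLING_REF | NO_HEADER
    node_id: str | None
    message: str


@dataclass
class AtlasNode:
    """One typed node of the atlas graph.

    ``types`` is ordered most-general-first; ``attributes`` preserves the
    key order of the source document.  Attribute values are scalars,
    lists, or ID strings referencing other nodes.
    """

    id: str
    types: tuple[str, ...]
    attributes: dict[str, Any] = field(default_factory=dict)

    def has_type(self, name: str) -> bool:
        return name in self.types

    def get(self, name: str, default: Any = None) -> Any:
        return self.attributes.get(name, default)

    # -- convenience accessors for the core vocabulary ------------------

    @property
    def authoritative(self) -> bool:
        return bool(self.attributes.get("authoritative", False))

    @property
    def label_value(self) -> int | None:
        v = self.attributes.get("labelValue")
        return int(v) if v is not None else None

    @property
    def data_source(self) -> str | None:
        return self.attributes.get("dataSource")

    @property
    def members(self) -> list[str]:
        return _as_list(self.attributes.get("members"))

    @property
    def segments(self) -> list[str]:
        return _as_list(self.attributes.get("segments"))

    @property
    def styles(self) -> list[str]:
        return _as_list(self.attributes.get("styles"))

    @property
    def annotations(self) -> list[str]:
        return _as_list(self.attributes.get("annotations"))

    @property
    def structure_roots(self) -> list[str]:
        # The header attribute is "structureRoot"; a JSON list value
        # declares several independent hierarchy roots.  The plural
        # spelling is tolerated on input.
        v = self.attributes.get("structureRoot",
                                self.attributes.get("structureRoots"))
        return _as_list(v)

    def to_json_object(self) -> dict[str, Any]:
        obj: dict[str, Any] = {"@id": self.id, "@type": list(self.types)}
        obj.update(self.attributes)
        return obj


def _as_list(value: Any) -> list:
    if value is None:
        return []
    if isinstance(value, list):
        return list(value)
    return [value]


@dataclass
class AtlasGraph:
    """The resolved, in-memory form of one atlas file.

    ``nodes`` preserves file order (insertion order of the mapping).
    ``issues`` is nonempty only after a lenient parse of a defective
    document; a strict parse raises instead.
    """

    nodes: dict[str, AtlasNode]
    header: AtlasNode | None
    issues: list[ParseIssue] = field(default_factory=list)
    source_path: str | None = None

    @property
    def file_order(self) -> list[str]:
        return list(self.nodes)

    @property
    def structure_roots(self) -> list[str]:
        return self.header.structure_roots if self.header is not None else []

    def resolve(self, node_id: str) -> AtlasNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise UnknownIDError(f"no node with ID {node_id!r}") from None

    def nodes_of_type(self, type_name: str) -> list[AtlasNode]:
        return [n for n in self.nodes.values() if n.has_type(type_name)]

    def file_index(self, node_id: str) -> int:
        for i, nid in enumerate(self.nodes):
            if nid == node_id:
                return i
        return len(self.nodes)

    def isomorphic_to(self, other: "AtlasGraph") -> bool:
        """Equality of the node sets: same IDs, types and attributes.

        File order is not compared, so the canonical and nested
        serializations of the same atlas compare equal.
        """
        if set(self.nodes) != set(other.nodes):
            return False
        for nid, node in self.nodes.items():
            o = other.nodes[nid]
            if node.types != o.types or node.attributes != o.attributes:
                return False
        return True


# ---------------------------------------------------------------------------
# Parsing


def _extract_node_list(doc: Any) -> list[dict]:
    if isinstance(doc, dict) and "@graph" in doc:
        nodes = doc["@graph"]
        if not isinstance(nodes, list):
            raise AtlasFormatError('"@graph" must hold a JSON list of nodes')
        return nodes
    if isinstance(doc, list):
        return doc
    if isinstance(doc, dict) and "@type" in doc:
        # A single nested root node.
        return [doc]
    raise AtlasFormatError(
        "top level must be a node list, an object with '@graph', or a node")


def flatten_nested(doc: Any) -> list[dict]:
    """Convert a possibly nested node tree to the canonical flat list.

    Inline child nodes (objects with an ``"@type"`` key appearing as
    attribute values) are hoisted to the top level and replaced by their
    ID; nodes without an explicit ``"@id"`` get one assigned
    (``"#auto1"``, ``"#auto2"``, ... in file order).  Applying this to an
    already-canonical list is the identity on the node multiset.
    """
    nodes = _extract_node_list(doc)
    for n in nodes:
        if not isinstance(n, dict):
            raise AtlasFormatError("every node must be a JSON object")

    # Every ID anywhere in the document, so auto-assigned IDs never clash.
    all_ids: set[str] = set()

    def collect_ids(obj: Any) -> None:
        if isinstance(obj, dict):
            if "@id" in obj:
                all_ids.add(obj["@id"])
            for v in obj.values():
                collect_ids(v)
        elif isinstance(obj, list):
            for v in obj:
                collect_ids(v)

    for n in nodes:
        collect_ids(n)

    counter = 0

    def fresh_id() -> str:
        nonlocal counter
        while True:
            counter += 1
            cand = f"#auto{counter}"
            if cand not in all_ids:
                all_ids.add(cand)
                return cand

    # Duplicate IDs among the top-level nodes are passed through (the
    # lenient parser records them); an inline node colliding with any
    # other node's explicit ID is a flattening error.
    top_ids = {n["@id"] for n in nodes if "@id" in n}
    inline_ids: set[str] = set()
    out: list[dict] = []

    def is_inline_node(v: Any) -> bool:
        return isinstance(v, dict) and "@type" in v

    def hoist(node: dict, inline: bool) -> str:
        nid = node.get("@id")
        if nid is None:
            nid = fresh_id()
        elif inline:
            if nid in top_ids or nid in inline_ids:
                raise AtlasFormatError(
                    f"inline node collides with existing ID {nid!r}")
            inline_ids.add(nid)
        flat: dict[str, Any] = {"@id": nid}
        for key, value in node.items():
            if key == "@id":
                continue
            flat[key] = walk_value(value)
        out.append(flat)
        return nid

    def walk_value(value: Any) -> Any:
        if is_inline_node(value):
            return hoist(value, inline=True)
        if isinstance(value, list):
            return [walk_value(v) for v in value]
        return value

    for n in nodes:
        hoist(n, inline=False)
    return out


def _normalize_color(value: Any) -> Any:
    """Accept "#RRGGBB" or a 3-list of reals; normalize to floats."""
    if isinstance(value, str) and _HEX_COLOR.match(value):
        r, g, b = (int(value[i:i + 2], 16) for i in (1, 3, 5))
        return [r / 255.0, g / 255.0, b / 255.0]
    if isinstance(value, list) and len(value) == 3 and all(
            isinstance(c, (int, float)) and not isinstance(c, bool)
            for c in value):
        return [float(c) for c in value]
    return value


def iter_references(node: AtlasNode) -> Iterator[tuple[str, str]]:
    """Yield (attribute name, referenced ID) for each ID-shaped value."""
    for key, value in node.attributes.items():
        if key == "color":
            continue  # hex colors are normalized away, but never refs
        if is_node_id(value):
            yield key, value
        elif isinstance(value, list):
            for v in value:
                if is_node_id(v):
                    yield key, v


def parse_atlas(json_text: str, strict: bool = True,
                source_path: str | None = None) -> AtlasGraph:
    """Parse canonical or nested atlas JSON into a resolved graph.

    In strict mode a duplicate ID, a dangling reference or a missing
    Header raises; in lenient mode these are recorded as
    :class:`ParseIssue` entries for the validator and parsing proceeds
    (the first node wins a duplicated ID).
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise AtlasFormatError(f"malformed JSON: {exc}") from exc

    flat = flatten_nested(doc)

    issues: list[ParseIssue] = []
    nodes: dict[str, AtlasNode] = {}
    for obj in flat:
        nid = obj.get("@id")
        if not isinstance(nid, str) or not NODE_ID_PATTERN.match(nid):
            raise AtlasFormatError(f"node has a malformed or missing @id: {nid!r}")
        rawtypes = obj.get("@type")
        if rawtypes is None:
            raise AtlasFormatError(f"node {nid!r} has no @type")
        types = tuple([rawtypes] if isinstance(rawtypes, str) else rawtypes)
        if not types:
            raise AtlasFormatError(f"node {nid!r} has an empty type list")
        attrs = {k: v for k, v in obj.items() if k not in ("@id", "@type")}
        if "color" in attrs:
            attrs["color"] = _normalize_color(attrs["color"])
        if nid in nodes:
            if strict:
                raise DuplicateIDError(f"duplicate node ID {nid!r}")
            issues.append(ParseIssue("DUP_ID", nid,
                                     f"duplicate node ID {nid!r}; first wins"))
            continue
        nodes[nid] = AtlasNode(id=nid, types=types, attributes=attrs)

    headers = [n for n in nodes.values() if n.has_type("Header")]
    if not headers:
        if strict:
            raise MissingHeaderError("atlas has no Header node")
        issues.append(ParseIssue("NO_HEADER", None, "atlas has no Header node"))
        header = None
    else:
        header = headers[0]

    for node in nodes.values():
        for attr, ref in iter_references(node):
            if ref not in nodes:
                if strict:
                    raise DanglingReferenceError(
                        f"node {node.id!r} attribute {attr!r} references "
                        f"unknown ID {ref!r}")
                issues.append(ParseIssue(
                    "DANGLING_REF", node.id,
                    f"attribute {attr!r} references unknown ID {ref!r}"))

    return AtlasGraph(nodes=nodes, header=header, issues=issues,
                      source_path=source_path)


def resolve_reference(graph: AtlasGraph, node_id: str) -> AtlasNode:
    """Return the unique node with *node_id*; raise UnknownIDError otherwise."""
    return graph.resolve(node_id)


# ---------------------------------------------------------------------------
# Serialization


def serialize_atlas(graph: AtlasGraph) -> str:
    """Emit canonical-form JSON text for *graph*.

    Nodes follow file order; keys are sorted within each node, which
    makes ``serialize ∘ parse ∘ serialize`` a byte-stable fixpoint.
    Serializing a graph that still contains unresolved references is an
    error — lenient-parsed defective graphs are for the validator, not
    for re-emission.
    """
    for node in graph.nodes.values():
        for attr, ref in iter_references(node):
            if ref not in graph.nodes:
                raise DanglingReferenceError(
                    f"cannot serialize: {node.id!r}.{attr} references "
                    f"unknown ID {ref!r}")
    payload = {"@graph": [
        dict(sorted(node.to_json_object().items()))
        for node in graph.nodes.values()
    ]}
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# Structure queries


def segments_for_structure(graph: AtlasGraph, structure: str,
                           subtype: str | None = None,
                           authoritative_only: bool = False) -> list[AtlasNode]:
    """Segments of one Structure in declaration order, optionally filtered.

    *subtype* filters on a type-list entry (``"LabelMapSegment"`` or
    ``"GeometrySegment"``); *authoritative_only* keeps segments whose
    ``authoritative`` flag is true (the flag defaults to false).
    """
    node = graph.resolve(structure)
    if not node.has_type("Structure"):
        raise AtlasFormatError(f"{structure!r} is not a Structure node")
    out: list[AtlasNode] = []
    for sid in node.segments:
        seg = graph.resolve(sid)
        if subtype is not None and not seg.has_type(subtype):
            continue
        if authoritative_only and not seg.authoritative:
            continue
        out.append(seg)
    return out
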