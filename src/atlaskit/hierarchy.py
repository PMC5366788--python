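"""Hierarchy queries over the atlas structure tree.

Groups declare their children through the ``members`` attribute; a node
may legally appear under several groups (the membership graph is a DAG),
in which case its *primary parent* is the first group in file order that
declares it.  Breadcrumbs and subtree traversals use primary parents, so
every structure has one deterministic path to a root.
"""

from __future__ import annotations

from typing import Iterator

from .errors import UnreachableNodeError
from .format_model import AtlasGraph
from .state import ApplicationState

__all__ = ["primary_parent", "breadcrumb", "descendants",
           "set_subtree_visibility"]


def primary_parent(graph: AtlasGraph, node_id: str) -> str | None:
    """ID of the first Group in file order declaring *node_id* as a member."""
    graph.resolve(node_id)
    for candidate in graph.nodes.values():
        if candidate.has_type("Group") and node_id in candidate.members:
            return candidate.id
    return None


def breadcrumb(graph: AtlasGraph, node_id: str) -> list[str]:
    """Ancestor chain of *node_id*: root first, immediate parent last.

    The node itself is excluded; a root's breadcrumb is empty.  Raises
    UnreachableNodeError when the chain does not end at a declared
    hierarchy root (or a membership cycle prevents it from doing so).
    """
    roots = set(graph.structure_roots)
    if node_id in roots:
        return []
    chain: list[str] = []
    seen = {node_id}
    cur = node_id
    while True:
        parent = primary_parent(graph, cur)
        if parent is None or parent in seen:
            raise UnreachableNodeError(
                f"{node_id!r} is not reachable from any hierarchy root")
        chain.append(parent)
        if parent in roots:
            break
        seen.add(parent)
        cur = parent
    chain.reverse()
    return chain


def descendants(graph: AtlasGraph, node_id: str) -> Iterator[str]:
    """IDs reachable from *node_id* through Group membership (excluding it).

    Depth-first in declaration order; each node is yielded once even in a
    DAG, and unresolvable member references are skipped (the validator
    reports those).
    """
    seen = {node_id}
    stack = [node_id]
    while stack:
        nid = stack.pop()
        node = graph.nodes.get(nid)
        if node is None or not node.has_type("Group"):
            continue
        for child in reversed(node.members):
            if child not in seen and child in graph.nodes:
                seen.add(child)
                yield child
                stack.append(child)


def set_subtree_visibility(state: ApplicationState, graph: AtlasGraph,
                           node_id: str, visible: bool) -> ApplicationState:
    """New state with *node_id* and all its descendants toggled.

    Overrides are exceptions to the style-declared visibility: hiding
    writes a ``False`` override for the whole subtree, while showing
    *removes* the subtree's overrides, restoring whatever the styles
    say.  Hiding and then showing a subtree with no prior overrides is
    therefore the identity on the override map.  The input state is
    untouched.
    """
    graph.resolve(node_id)
    subtree = [node_id, *descendants(graph, node_id)]
    overrides = dict(state.visibility_map())
    if visible:
        for nid in subtree:
            overrides.pop(nid, None)
    else:
        for nid in subtree:
            overrides[nid] = False
    return state.with_visibility(overrides)
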