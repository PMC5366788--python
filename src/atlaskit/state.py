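"""Immutable application state, history, bookmarks and shared views.

The viewer's entire configuration — selected structure, slice indices,
contrast, overlay opacity, visibility overrides, pointer — lives in one
immutable :class:`ApplicationState` value.  Every interaction produces a
new state; stored states are wrapped in UUID-keyed
:class:`StateRecord` objects that never mutate.  On top of this sit an
undo/redo history stack, a bookmark store with owner-only deletion and a
small message inbox, and last-writer-wins merging for dynamic shared
views.

The store is an in-process table with optional JSON-lines file
persistence; ownership is a plain ``ownerId`` string and ordering between
collaborating clients comes from store-issued sequence numbers, not wall
clocks, so every behavior here is deterministic and testable.
"""

from __future__ import annotations

import json
import os
import time
import uuid as uuid_module
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping

from .errors import AtlasError, BookmarkPermissionError, UnknownBookmarkError
from .volume_ops import WindowLevel

__all__ = [
    "ApplicationState", "StateRecord", "HistoryStack",
    "push_state", "undo", "redo",
    "BookmarkStore", "save_bookmark", "load_bookmark", "delete_bookmark",
    "merge_remote_state", "Sequencer", "SharedViewClient",
    "state_to_dict", "state_from_dict", "bookmark_url",
]


def _freeze_overrides(value: Any) -> tuple[tuple[str, bool], ...]:
    if isinstance(value, Mapping):
        items = value.items()
    else:
        items = value
    return tuple(sorted((str(k), bool(v)) for k, v in items))


@dataclass(frozen=True)
class ApplicationState:
    """One immutable snapshot of the viewer configuration.

    ``atlas_ref`` is a (locator, version) pair identifying the atlas the
    state refers to; ``pointer`` is ((x, y, z), authorId) of the last
    user to move the shared pointer; ``camera`` is carried as an opaque
    value so bookmarks faithfully round-trip a 3D viewer's pose without
    this library interpreting it.
    """

    atlas_ref: tuple[str, str] = ("", "")
    selected_structure: str | None = None
    slice_indices: tuple[int, int, int] = (0, 0, 0)
    window_level: WindowLevel = WindowLevel(1.0, 0.5)
    overlay_opacity: float = 0.5
    transparency_ranges: tuple[tuple[float, float], ...] = ()
    visibility_overrides: tuple[tuple[str, bool], ...] = ()
    pointer: tuple[tuple[float, float, float], str] | None = None
    camera: Any = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atlas_ref", tuple(self.atlas_ref))
        object.__setattr__(self, "slice_indices",
                           tuple(int(i) for i in self.slice_indices))
        object.__setattr__(self, "transparency_ranges", tuple(
            (float(lo), float(hi)) for lo, hi in self.transparency_ranges))
        object.__setattr__(self, "visibility_overrides",
                           _freeze_overrides(self.visibility_overrides))
        if self.pointer is not None:
            coords, author = self.pointer
            object.__setattr__(self, "pointer",
                               (tuple(float(c) for c in coords), str(author)))
        if not 0.0 <= self.overlay_opacity <= 1.0:
            raise AtlasError(
                f"overlay opacity must be in [0, 1], got {self.overlay_opacity}")

    def visibility_map(self) -> dict[str, bool]:
        return dict(self.visibility_overrides)

    def with_visibility(self, overrides: Mapping[str, bool]) -> "ApplicationState":
        return replace(self, visibility_overrides=_freeze_overrides(overrides))

    def evolve(self, **changes: Any) -> "ApplicationState":
        """Functional update; the receiver is unchanged."""
        return replace(self, **changes)


@dataclass(frozen=True)
class StateRecord:
    """A stored, never-mutated state keyed by an RFC 4122 v4 UUID."""

    uuid: str
    state: ApplicationState
    owner_id: str
    created_at: float
    kind: str = "bookmark"  # history | bookmark | sharedSession


# ---------------------------------------------------------------------------
# Undo / redo


@dataclass(frozen=True)
class HistoryStack:
    """Undo/redo stack of states; entries after the cursor are the redo branch.

    The stack is itself a value: push/undo/redo return new stacks.  Undo
    at the bottom and redo at the top are signalled no-ops — the same
    stack object is returned, and ``can_undo``/``can_redo`` expose the
    boundary.
    """

    entries: tuple[ApplicationState, ...]
    cursor: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise AtlasError("a history stack is never empty")
        if not 0 <= self.cursor < len(self.entries):
            raise AtlasError(
                f"cursor {self.cursor} out of range for {len(self.entries)} entries")

    @classmethod
    def initial(cls, state: ApplicationState) -> "HistoryStack":
        return cls(entries=(state,), cursor=0)

    @property
    def current(self) -> ApplicationState:
        return self.entries[self.cursor]

    @property
    def can_undo(self) -> bool:
        return self.cursor > 0

    @property
    def can_redo(self) -> bool:
        return self.cursor < len(self.entries) - 1

    def push(self, state: ApplicationState) -> "HistoryStack":
        entries = self.entries[:self.cursor + 1] + (state,)
        return HistoryStack(entries=entries, cursor=self.cursor + 1)

    def undo(self) -> "HistoryStack":
        if not self.can_undo:
            return self
        return HistoryStack(entries=self.entries, cursor=self.cursor - 1)

    def redo(self) -> "HistoryStack":
        if not self.can_redo:
            return self
        return HistoryStack(entries=self.entries, cursor=self.cursor + 1)


def push_state(stack: HistoryStack, state: ApplicationState) -> HistoryStack:
    """Truncate the redo branch, append *state* and advance the cursor."""
    return stack.push(state)


def undo(stack: HistoryStack) -> HistoryStack:
    """Move the cursor back one entry; no-op (same object) at the bottom."""
    return stack.undo()


def redo(stack: HistoryStack) -> HistoryStack:
    """Move the cursor forward one entry; no-op (same object) at the top."""
    return stack.redo()


# ---------------------------------------------------------------------------
# State (de)serialization


def state_to_dict(state: ApplicationState) -> dict[str, Any]:
    return {
        "atlasRef": list(state.atlas_ref),
        "selectedStructure": state.selected_structure,
        "sliceIndices": list(state.slice_indices),
        "windowLevel": [state.window_level.window, state.window_level.level],
        "overlayOpacity": state.overlay_opacity,
        "transparencyRanges": [list(r) for r in state.transparency_ranges],
        "visibilityOverrides": {k: v for k, v in state.visibility_overrides},
        "pointer": None if state.pointer is None
        else {"coords": list(state.pointer[0]), "authorId": state.pointer[1]},
        "camera": state.camera,
    }


def state_from_dict(doc: Mapping[str, Any]) -> ApplicationState:
    pointer = doc.get("pointer")
    wl = doc.get("windowLevel", [1.0, 0.5])
    return ApplicationState(
        atlas_ref=tuple(doc.get("atlasRef", ("", ""))),
        selected_structure=doc.get("selectedStructure"),
        slice_indices=tuple(doc.get("sliceIndices", (0, 0, 0))),
        window_level=WindowLevel(float(wl[0]), float(wl[1])),
        overlay_opacity=float(doc.get("overlayOpacity", 0.5)),
        transparency_ranges=tuple(
            tuple(r) for r in doc.get("transparencyRanges", ())),
        visibility_overrides=doc.get("visibilityOverrides", {}),
        pointer=None if pointer is None
        else (tuple(pointer["coords"]), pointer["authorId"]),
        camera=doc.get("camera"),
    )


# ---------------------------------------------------------------------------
# Bookmark store


class BookmarkStore:
    """UUID-keyed immutable record store with optional JSONL persistence.

    Records are world-readable; only the owner may delete.  A small
    message system maps recipient IDs to bookmark UUIDs.  When *path* is
    given, every save/delete/send is appended as one JSON line and the
    table is rebuilt by replay on open.
    """

    def __init__(self, path: str | os.PathLike | None = None,
                 uuid_factory: Callable[[], uuid_module.UUID] | None = None,
                 clock: Callable[[], float] = time.time) -> None:
        self._records: dict[str, StateRecord] = {}
        self._inbox: dict[str, list[str]] = {}
        self._path = os.fspath(path) if path is not None else None
        self._uuid_factory = uuid_factory or uuid_module.uuid4
        self._clock = clock
        if self._path is not None and os.path.exists(self._path):
            self._replay()

    # -- persistence -----------------------------------------------------

    def _replay(self) -> None:
        with open(self._path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                doc = json.loads(line)
                op = doc.get("op", "save")
                if op == "save":
                    rec = StateRecord(
                        uuid=doc["uuid"], owner_id=doc["ownerId"],
                        created_at=doc["createdAt"], kind=doc.get("kind", "bookmark"),
                        state=state_from_dict(doc["state"]))
                    self._records[rec.uuid] = rec
                elif op == "delete":
                    self._records.pop(doc["uuid"], None)
                elif op == "send":
                    self._inbox.setdefault(doc["recipientId"], []).append(doc["uuid"])

    def _append(self, doc: dict[str, Any]) -> None:
        if self._path is None:
            return
        with open(self._path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(doc, sort_keys=True) + "\n")

    # -- operations ------------------------------------------------------

    def save(self, state: ApplicationState, owner_id: str,
             kind: str = "bookmark") -> str:
        """Persist *state* immutably under a fresh v4 UUID; return the UUID."""
        uid = str(self._uuid_factory())
        rec = StateRecord(uuid=uid, state=state, owner_id=owner_id,
                          created_at=self._clock(), kind=kind)
        self._records[uid] = rec
        self._append({"op": "save", "uuid": uid, "ownerId": owner_id,
                      "createdAt": rec.created_at, "kind": kind,
                      "state": state_to_dict(state)})
        return uid

    def load(self, uid: str,
             current_atlas_ref: tuple[str, str] | None = None
             ) -> tuple[ApplicationState, bool]:
        """Return the stored state and whether loading it requires an
        atlas switch (its atlas_ref differs from *current_atlas_ref*)."""
        rec = self.record(uid)
        switch = (current_atlas_ref is not None
                  and tuple(current_atlas_ref) != rec.state.atlas_ref)
        return rec.state, switch

    def record(self, uid: str) -> StateRecord:
        try:
            return self._records[uid]
        except KeyError:
            raise UnknownBookmarkError(f"no bookmark with UUID {uid!r}") from None

    def delete(self, uid: str, requester_id: str) -> None:
        """Remove a record; only its owner may do this."""
        rec = self.record(uid)
        if rec.owner_id != requester_id:
            raise BookmarkPermissionError(
                f"{requester_id!r} is not the owner of bookmark {uid}")
        del self._records[uid]
        self._append({"op": "delete", "uuid": uid})

    def list(self, owner_id: str | None = None) -> list[StateRecord]:
        recs = self._records.values()
        if owner_id is not None:
            recs = (r for r in recs if r.owner_id == owner_id)
        return sorted(recs, key=lambda r: (r.created_at, r.uuid))

    # -- messaging -------------------------------------------------------

    def send(self, uid: str, recipient_id: str) -> None:
        """Deliver a bookmark UUID to a recipient's inbox."""
        self.record(uid)  # must exist
        self._inbox.setdefault(recipient_id, []).append(uid)
        self._append({"op": "send", "uuid": uid, "recipientId": recipient_id})

    def inbox(self, recipient_id: str) -> list[str]:
        return list(self._inbox.get(recipient_id, ()))

    # -- interchange -----------------------------------------------------

    def export_record(self, uid: str) -> dict[str, Any]:
        rec = self.record(uid)
        return {"uuid": rec.uuid, "ownerId": rec.owner_id,
                "createdAt": rec.created_at,
                "atlasRef": list(rec.state.atlas_ref),
                "state": state_to_dict(rec.state)}


def bookmark_url(base: str, uid: str) -> str:
    """Render a bookmark as an exchangeable URL: <base>#<uuid>."""
    return f"{base}#{uid}"


def save_bookmark(store: BookmarkStore, state: ApplicationState,
                  owner_id: str) -> str:
    return store.save(state, owner_id)


def load_bookmark(store: BookmarkStore, uid: str,
                  current_atlas_ref: tuple[str, str] | None = None
                  ) -> tuple[ApplicationState, bool]:
    return store.load(uid, current_atlas_ref)


def delete_bookmark(store: BookmarkStore, uid: str, requester_id: str) -> None:
    store.delete(uid, requester_id)


# ---------------------------------------------------------------------------
# Dynamic shared views


def merge_remote_state(local: tuple[ApplicationState, int],
                       event: tuple[ApplicationState, int, str]
                       ) -> tuple[ApplicationState, int]:
    """Last-writer-wins merge of a remote state event into a client.

    The store issues a total-order sequence number with each event; an
    event newer than the client's own sequence number replaces state and
    pointer (the pointer is attributed to the event's author), while
    stale events are silently ignored.
    """
    local_state, local_seq = local
    event_state, event_seq, author_id = event
    if event_seq <= local_seq:
        return local
    if event_state.pointer is not None:
        coords, _ = event_state.pointer
        event_state = event_state.evolve(pointer=(coords, author_id))
    return event_state, event_seq


class Sequencer:
    """Issues strictly increasing sequence numbers (the session store's clock)."""

    def __init__(self) -> None:
        self._seq = 0

    def next(self) -> int:
        self._seq += 1
        return self._seq


@dataclass
class SharedViewClient:
    """A minimal simulated participant in a dynamic shared view."""

    client_id: str
    state: ApplicationState = field(default_factory=ApplicationState)
    seq: int = 0

    def publish(self, state: ApplicationState, sequencer: Sequencer
                ) -> tuple[ApplicationState, int, str]:
        """Locally apply *state* and emit the event for the other clients."""
        seq = sequencer.next()
        self.state, self.seq = merge_remote_state(
            (self.state, self.seq), (state, seq, self.client_id))
        return state, seq, self.client_id

    def receive(self, event: tuple[ApplicationState, int, str]) -> None:
        self.state, self.seq = merge_remote_state((self.state, self.seq), event)
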