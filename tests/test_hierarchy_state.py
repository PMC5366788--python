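"""Hierarchy queries, history, bookmarks and shared-view convergence."""

import dataclasses
import itertools
import json
import random
import uuid

import pytest

from atlaskit import (ApplicationState, BookmarkPermissionError, BookmarkStore,
                      HistoryStack, Sequencer, SharedViewClient,
                      UnknownBookmarkError, UnreachableNodeError, WindowLevel,
                      bookmark_url, breadcrumb, descendants,
                      merge_remote_state, parse_atlas, push_state, redo,
                      set_subtree_visibility, undo)
from atlaskit.state import state_from_dict, state_to_dict


class TestBreadcrumb:
    def test_root_has_empty_breadcrumb(self, graph):
        assert breadcrumb(graph, "#root") == []

    def test_two_level_chain(self):
        g = parse_atlas(json.dumps([
            {"@id": "#h", "@type": ["Header"], "structureRoot": "#r"},
            {"@id": "#r", "@type": ["Group"], "members": ["#g"]},
            {"@id": "#g", "@type": ["Group"], "members": ["#s1"]},
            {"@id": "#s1", "@type": ["Structure"]},
        ]))
        assert breadcrumb(g, "#s1") == ["#r", "#g"]

    def test_unreachable_node_raises(self, graph):
        assert breadcrumb  # sanity: imported
        with pytest.raises(UnreachableNodeError):
            breadcrumb(graph, "#mri")  # an Image, not in the hierarchy

    def test_every_structure_path_follows_declared_member_edges(self, graph):
        for structure in graph.nodes_of_type("Structure"):
            chain = breadcrumb(graph, structure.id) + [structure.id]
            assert chain[0] in graph.structure_roots
            for parent, child in zip(chain, chain[1:]):
                assert child in graph.resolve(parent).members

    def test_primary_parent_is_first_declaring_group(self):
        # s1 under both #a and #b: the first group in file order wins
        g = parse_atlas(json.dumps([
            {"@id": "#h", "@type": ["Header"], "structureRoot": "#r"},
            {"@id": "#r", "@type": ["Group"], "members": ["#a", "#b"]},
            {"@id": "#a", "@type": ["Group"], "members": ["#s1"]},
            {"@id": "#b", "@type": ["Group"], "members": ["#s1"]},
            {"@id": "#s1", "@type": ["Structure"]},
        ]))
        assert breadcrumb(g, "#s1") == ["#r", "#a"]


class TestSubtreeVisibility:
    def test_hide_root_overrides_every_hierarchy_node(self, graph):
        state = ApplicationState()
        hidden = set_subtree_visibility(state, graph, "#root", False)
        expected = {"#root"} | set(descendants(graph, "#root"))
        overrides = hidden.visibility_map()
        assert set(overrides) == expected
        assert all(v is False for v in overrides.values())
        assert state.visibility_map() == {}  # input untouched

    def test_hide_group_overrides_exactly_its_reachability_set(self, graph):
        gid = next(n.id for n in graph.nodes_of_type("Group")
                   if n.id != "#root")
        hidden = set_subtree_visibility(ApplicationState(), graph, gid, False)

        # graph-traversal oracle
        expected = {gid}
        frontier = [gid]
        while frontier:
            node = graph.resolve(frontier.pop())
            for child in node.members:
                if child not in expected:
                    expected.add(child)
                    frontier.append(child)
        assert set(hidden.visibility_map()) == expected

    def test_hide_then_show_restores_original_overrides(self, graph):
        state = ApplicationState()
        gid = next(n.id for n in graph.nodes_of_type("Group"))
        out = set_subtree_visibility(
            set_subtree_visibility(state, graph, gid, False),
            graph, gid, True)
        assert out.visibility_map() == state.visibility_map() == {}


def oracle_history(ops):
    """Two-list reference: an undo list and a redo list of plain states."""
    undo_list, redo_list = [0], []
    for op, arg in ops:
        if op == "push":
            undo_list.append(arg)
            redo_list.clear()
        elif op == "undo" and len(undo_list) > 1:
            redo_list.append(undo_list.pop())
        elif op == "redo" and redo_list:
            undo_list.append(redo_list.pop())
    return undo_list[-1], len(undo_list) - 1, len(redo_list)


def run_stack(ops):
    stack = HistoryStack.initial(ApplicationState(slice_indices=(0, 0, 0)))
    for op, arg in ops:
        if op == "push":
            stack = push_state(stack, ApplicationState(slice_indices=(arg, 0, 0)))
        elif op == "undo":
            stack = undo(stack)
        else:
            stack = redo(stack)
    return stack


class TestHistory:
    def test_push_push_undo_returns_first_state(self):
        s1 = ApplicationState(overlay_opacity=0.1)
        s2 = ApplicationState(overlay_opacity=0.2)
        stack = HistoryStack.initial(ApplicationState())
        stack = undo(push_state(push_state(stack, s1), s2))
        assert stack.current == s1

    def test_n_pushes_then_n_undos_is_initial(self):
        initial = ApplicationState()
        stack = HistoryStack.initial(initial)
        for i in range(7):
            stack = push_state(stack, ApplicationState(slice_indices=(i, 0, 0)))
        for _ in range(7):
            stack = undo(stack)
        assert stack.current == initial
        assert not stack.can_undo

    def test_push_truncates_redo_branch(self):
        stack = HistoryStack.initial(ApplicationState())
        stack = push_state(stack, ApplicationState(slice_indices=(1, 0, 0)))
        stack = undo(stack)
        assert stack.can_redo
        stack = push_state(stack, ApplicationState(slice_indices=(2, 0, 0)))
        assert not stack.can_redo
        assert stack.current.slice_indices == (2, 0, 0)

    def test_undo_at_bottom_and_redo_at_top_are_signalled_noops(self):
        stack = HistoryStack.initial(ApplicationState())
        assert undo(stack) is stack and not stack.can_undo
        assert redo(stack) is stack and not stack.can_redo

    def test_random_sequences_match_two_list_oracle(self):
        rng = random.Random(1234)
        for _ in range(300):
            ops = []
            counter = itertools.count(1)
            for _ in range(rng.randint(1, 30)):
                op = rng.choice(["push", "push", "undo", "redo"])
                ops.append((op, next(counter) if op == "push" else None))
            stack = run_stack(ops)
            current, undos, redos = oracle_history(ops)
            assert stack.current.slice_indices == (current, 0, 0)
            assert stack.cursor == undos
            assert len(stack.entries) - stack.cursor - 1 == redos
            # invariant: reachable undos + redo branch + 1 == entries
            assert stack.cursor + redos + 1 == len(stack.entries)


class TestImmutability:
    def test_states_are_frozen(self):
        state = ApplicationState()
        with pytest.raises(dataclasses.FrozenInstanceError):
            state.overlay_opacity = 0.9

    def test_evolve_returns_a_new_value(self):
        a = ApplicationState()
        b = a.evolve(overlay_opacity=0.9)
        assert a.overlay_opacity == 0.5 and b.overlay_opacity == 0.9

    def test_state_round_trips_through_dict_form(self):
        state = ApplicationState(
            atlas_ref=("https://example.org/atlas.json", "2.1"),
            selected_structure="#cortex", slice_indices=(3, 4, 5),
            window_level=WindowLevel(80.0, 40.0), overlay_opacity=0.25,
            transparency_ranges=((0.0, 10.0),),
            visibility_overrides={"#a": False},
            pointer=((1.0, 2.0, 3.0), "alice"), camera={"pose": [1, 2, 3]})
        assert state_from_dict(state_to_dict(state)) == state


class TestBookmarks:
    def test_save_then_load_round_trips_field_by_field(self):
        store = BookmarkStore()
        state = ApplicationState(atlas_ref=("a", "1"), slice_indices=(1, 2, 3))
        uid = store.save(state, "alice")
        loaded, switch = store.load(uid, current_atlas_ref=("a", "1"))
        assert loaded == state and switch is False

    def test_cross_atlas_load_requires_switch(self):
        store = BookmarkStore()
        uid = store.save(ApplicationState(atlas_ref=("a", "1")), "alice")
        _, switch = store.load(uid, current_atlas_ref=("a", "2"))
        assert switch is True

    def test_only_the_owner_can_delete(self):
        store = BookmarkStore()
        uid = store.save(ApplicationState(), "alice")
        with pytest.raises(BookmarkPermissionError):
            store.delete(uid, "mallory")
        store.delete(uid, "alice")
        with pytest.raises(UnknownBookmarkError):
            store.load(uid)

    def test_uuids_are_v4(self):
        store = BookmarkStore()
        uid = store.save(ApplicationState(), "alice")
        assert uuid.UUID(uid).version == 4

    def test_store_contents_survive_client_side_mutation_attempts(self):
        store = BookmarkStore()
        original = ApplicationState(overlay_opacity=0.3)
        uid = store.save(original, "alice")
        loaded, _ = store.load(uid)
        with pytest.raises(dataclasses.FrozenInstanceError):
            loaded.overlay_opacity = 0.99
        again, _ = store.load(uid)
        assert again == original

    def test_jsonl_persistence_replay(self, tmp_path):
        path = tmp_path / "store.jsonl"
        store = BookmarkStore(path=path)
        keep = store.save(ApplicationState(atlas_ref=("a", "1")), "alice")
        gone = store.save(ApplicationState(atlas_ref=("b", "2")), "bob")
        store.delete(gone, "bob")
        store.send(keep, "carol")

        reopened = BookmarkStore(path=path)
        state, _ = reopened.load(keep)
        assert state.atlas_ref == ("a", "1")
        with pytest.raises(UnknownBookmarkError):
            reopened.load(gone)
        assert reopened.inbox("carol") == [keep]

    def test_messaging_inbox(self):
        store = BookmarkStore()
        uid = store.save(ApplicationState(), "alice")
        store.send(uid, "bob")
        assert store.inbox("bob") == [uid]
        assert store.inbox("eve") == []

    def test_bookmark_url_rendering(self):
        assert bookmark_url("https://example.org/viewer", "abc") == \
            "https://example.org/viewer#abc"


class TestSharedViews:
    def test_newer_event_replaces_state_and_attributes_pointer(self):
        local = (ApplicationState(), 3)
        event_state = ApplicationState(pointer=((1.0, 2.0, 3.0), "stale"))
        state, seq = merge_remote_state(local, (event_state, 4, "bob"))
        assert seq == 4
        assert state.pointer == ((1.0, 2.0, 3.0), "bob")

    def test_stale_event_is_ignored(self):
        local_state = ApplicationState(overlay_opacity=0.9)
        state, seq = merge_remote_state(
            (local_state, 5), (ApplicationState(), 5, "bob"))
        assert state == local_state and seq == 5

    def test_clients_converge_under_any_arrival_interleaving(self):
        # one totally ordered event stream, replayed to 3 clients in
        # different per-client arrival orders
        sequencer = Sequencer()
        authors = ["a", "b", "c"]
        events = []
        for i, author in enumerate(authors * 3):
            state = ApplicationState(slice_indices=(i, 0, 0),
                                     pointer=((float(i), 0.0, 0.0), author))
            events.append((state, sequencer.next(), author))

        rng = random.Random(99)
        clients = [SharedViewClient(client_id=a) for a in authors]
        for client in clients:
            arrival = events[:]
            rng.shuffle(arrival)
            for ev in arrival:
                client.receive(ev)

        final = {(c.state, c.seq) for c in clients}
        assert len(final) == 1
        state, seq = final.pop()
        assert seq == 9
        assert state.pointer[1] == events[-1][2]  # last writer's pointer
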