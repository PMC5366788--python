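"""Undo/redo history, bookmarks and a synchronized shared view.

Walks the immutable application-state model: pushes states onto a
history stack and steps back, saves a bookmark that only its owner can
delete, and replays one ordered event stream to three clients in
different arrival orders to show they converge to the same view.
"""

import random

from atlaskit import (ApplicationState, BookmarkPermissionError, BookmarkStore,
                      HistoryStack, Sequencer, SharedViewClient, push_state,
                      undo)

# --- history -----------------------------------------------------------
stack = HistoryStack.initial(ApplicationState(atlas_ref=("brain.json", "1.0")))
for i in range(1, 4):
    stack = push_state(stack, stack.current.evolve(slice_indices=(i, 0, 0)))
print(f"after 3 pushes: slice {stack.current.slice_indices}, "
      f"can_undo={stack.can_undo}")
stack = undo(undo(stack))
print(f"after 2 undos:  slice {stack.current.slice_indices}, "
      f"can_redo={stack.can_redo}")

# --- bookmarks ---------------------------------------------------------
store = BookmarkStore()
uid = store.save(stack.current, owner_id="alice")
state, switch = store.load(uid, current_atlas_ref=("knee.json", "2.0"))
print(f"bookmark {uid[:8]}… restores slice {state.slice_indices}; "
      f"atlas switch required: {switch}")
try:
    store.delete(uid, "bob")
except BookmarkPermissionError as exc:
    print(f"bob cannot delete it: {exc}")

# --- dynamic shared view ----------------------------------------------
sequencer = Sequencer()
events = []
for i, author in enumerate(["alice", "bob", "carol"]):
    s = ApplicationState(slice_indices=(10 + i, 0, 0),
                         pointer=((float(i), 0.0, 0.0), author))
    events.append((s, sequencer.next(), author))

clients = [SharedViewClient(client_id=c) for c in ("alice", "bob", "carol")]
rng = random.Random(0)
for client in clients:
    arrival = events[:]
    rng.shuffle(arrival)          # each client sees a different order
    for event in arrival:
        client.receive(event)

views = {(c.state.slice_indices, c.state.pointer) for c in clients}
print(f"all three clients share one view: {len(views) == 1}; "
      f"pointer owned by {clients[0].state.pointer[1]}")

# Sequence numbers from the session store make 'last writer' well
# defined, so any arrival order converges to the same state and the
# displayed pointer belongs to the final writer.
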