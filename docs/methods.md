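# Methods

This note records the data model, the computations, the synthetic data
and the design choices behind `atlaskit`, in enough detail to judge what
its tests do and do not demonstrate.

## The atlas node graph

An atlas file is UTF-8 JSON. Nodes are JSON objects carrying `"@id"`
(a fragment-style token `#name`, unique within the file), `"@type"` (a
string or list, most general type first, capitalized by convention) and
arbitrary attributes whose names begin with a lower-case letter. Nodes
reference each other by ID string. The *canonical* form collects all
nodes in one flat list under a top-level `"@graph"` key (a bare
top-level list is also accepted). A *nested* form may embed child nodes
inline as attribute values; flattening hoists each inline node to the
top level (assigning `#auto1`, `#auto2`, … in file order when it has no
ID) and replaces it with its ID. These two forms are the whole grammar:
the parser is deliberately an ad hoc JSON reader, not a JSON-LD
processor — no context expansion, no remote contexts, no cross-file
references. Unknown node types (e.g. `Attribution`, `CoordinateFrame`,
`Transform`) and unknown attributes are carried verbatim through parse
and serialize, so files using future vocabulary survive round trips.

The core vocabulary: a `Header` names one or more hierarchy roots
through its `structureRoot` attribute (a list value declares several
independent, possibly overlapping hierarchies). `Group` nodes declare
ordered `members`; anatomical parts are `Structure` nodes. A structure's
spatial representation is a `Segment`, subtype `LabelMapSegment`
(an integer `labelValue` > 0 selecting voxels in a shared label volume)
or `GeometrySegment` (a polygonal model). A segment marked
`authoritative: true` (default false) is the spatial ground truth used
for overlays and picking; by convention the label map is authoritative
and geometry is display-only. Bulk data access is isolated in
`DataSource` nodes (`location` plus `format`: NRRD, VTK, STL or OBJ);
`Image` nodes reference source radiology volumes the same way.
`Annotation` (title/description) and `Style` (RGB color in [0,1]³,
transparency, visibility) are separate nodes so naming and appearance
can be edited independently of structure identity.

Decisions taken where the format leaves room:

- A structure may appear under several groups (a DAG); its *primary
  parent* — the first group in file order that declares it — makes
  breadcrumbs and subtree operations deterministic.
- The label-value attribute on `LabelMapSegment` is spelled
  `labelValue`.
- Colors are accepted as three floats or `"#RRGGBB"` hex and normalized
  to floats at parse time; serialization emits floats.
- Serialization orders nodes by file order and sorts keys within each
  node, making `serialize ∘ parse ∘ serialize` a byte-stable fixpoint —
  useful for diff-friendly storage of atlases under version control.
- Strict parsing raises on duplicate IDs, dangling references and a
  missing header; lenient parsing records them (first node wins a
  duplicated ID) so the validator can report them as findings.

## Validation

`validate(graph, data_root, check_data)` returns findings
`(severity, code, nodeId, message)` ordered by rule code then file
order, so repeated runs are identical. Rules: `DUP_ID`, `DANGLING_REF`,
`NO_HEADER`, `CYCLE` (group membership), `LABEL_DUPLICATE` (two
structures claim one value in one label map), `BAD_COLOR` (style channel
outside [0,1]), `MISSING_FILE`, `BAD_FORMAT` are errors;
`BAD_TYPE_CASE`, `BAD_ATTR_CASE`, `MULTI_AUTHORITATIVE` (two
authoritative segments of one subtype on one structure), `ORPHAN_NODE`
(unreachable from the header), `LABEL_UNDECLARED` and `LABEL_UNUSED` are
warnings. Label coverage is a warning, not an error, because atlases
legitimately omit background or unlabeled tissue. The voxel scan reads
each authoritative label volume once and compares its distinct nonzero
values against all declared `labelValue`s for that volume. Remote
(http/https) data sources are skipped by the file checks. An atlas with
no authoritative segment at all is not flagged. The CLI maps findings to
exit codes: 0 no errors, 1 errors, 2 unreadable input.

## Volume computations

Volumes are numpy arrays in array index order `(i, j, k)` with per-axis
spacing in mm. NRRD I/O goes through SimpleITK; because SimpleITK's
numpy view is `(z, y, x)`, spacing tuples are reversed on the way in and
out so `spacing[a]` always belongs to array axis `a`. Orientation
("space directions") is not applied: the interchange format defers
coordinate-frame semantics to the referenced files, so a "slice" here is
an array-axis plane and anatomical naming (axial/coronal/sagittal) is
left to callers.

- **Window/level**: `g = clamp((v − level)/window + ½, 0, 1)` — the
  standard radiology ramp, mid-gray at `level`, monotone in `v`,
  `window > 0` required.
- **Transparency ranges**: a pixel is transparent iff its *raw* value
  lies in any closed `[lo, hi]` interval.
- **Overlay compositing**: straight (non-premultiplied) alpha per
  channel, `out = α·color + (1−α)·gray` with
  `α = globalOpacity · (1 − styleTransparency)` — the per-structure
  transparency multiplies the global opacity. Label 0, hidden and
  unstyled labels pass grayscale through; output alpha is 1 except
  where masked (then 0).
- **Picking**: the structure whose authoritative `LabelMapSegment`
  declares the voxel's value; background and undeclared values pick
  nothing. When two structures claim one value (a validator error) the
  first in file order wins, keeping behavior deterministic.
- **PNG export** quantizes with `floor(255·x + 0.5)`.

Slices are nearest-voxel planes; there is no interpolation, oblique
reslicing or 3D rendering.

## Geometry

Meshes are read for verification, not display: vertices, triangles
(polygons fan-triangulated on ingestion), and at most one material
color. OBJ and STL parsing goes through trimesh (OBJ indices arrive
0-based; the `Kd` diffuse color of the first `usemtl` material is read
from the MTL directly); VTK legacy ASCII polydata (POINTS + POLYGONS
sections, versions 3–4.2) has its own small reader since no installed
library covers that dialect. Binary STL size is checked against its
declared triangle count before parsing so truncation is a clean error.
Vertex welding for cross-format comparison uses exact bit equality —
fixtures are authored to be exact — and the library never does epsilon
merging or mesh repair.

## Application state

`ApplicationState` is a frozen value: atlas reference
`(locator, version)`, selected structure, per-axis slice indices,
window/level, overlay opacity, transparency ranges, visibility
overrides, an optional `(coords, authorId)` pointer, and an opaque
camera payload (carried untouched so bookmarks faithfully contain a 3D
viewer's pose without this library interpreting it).

Visibility overrides are exceptions to style-declared visibility:
hiding a subtree writes `False` for the node and all its descendants;
showing *removes* the subtree's overrides. Hide-then-show on an
untouched subtree is therefore the identity.

History is a stack of states with a cursor; push truncates the redo
branch, undo/redo move the cursor, and both are signalled no-ops at the
boundaries (the same stack object is returned; `can_undo`/`can_redo`
expose the edge). The invariant `cursor + redo branch + 1 = entries`
holds for every operation sequence.

Bookmarks are `StateRecord`s — v4 UUID, state, owner ID, creation time,
kind — in an in-process store with optional JSON-lines persistence (one
operation per line, table rebuilt by replay). Records never mutate;
anyone can load, only the owner can delete; loading flags
`atlasSwitchRequired` when the bookmark's atlas reference differs from
the caller's current atlas. Messaging is an inbox table mapping a
recipient ID to bookmark UUIDs. A bookmark stores a single snapshot,
not the undo history. Authentication providers and network transport
are out of scope; an `ownerId` string stands in for a login.

Dynamic shared views use last-writer-wins: the session store issues
strictly increasing sequence numbers, an event newer than the client's
own replaces state and pointer (the pointer re-attributed to the event's
author), and stale events are ignored. Sequence numbers rather than
wall clocks define "last", which makes convergence exact and testable:
any set of clients that has received the same maximal sequence number
holds identical state, under any arrival interleaving.

## TSV conversion

One structure per row; required columns `name` and `labelValue`,
optional `geometryFile`, `parent`, `color`, `description`. Dialect:
tab-separated, UTF-8, `#` comment lines ignored, no quoting (the column
names are this package's own, since only the column *content* is
conventional). All rows share one label-map `DataSource`; a geometry
file adds a `GeometrySegment` with its own file source (format inferred
from the extension); `parent` nests the structure under a named group
created on demand beneath the single root. Missing columns, duplicate
names, duplicate or non-positive label values and unknown geometry
formats are rejected. Colors default to evenly spaced hues at full
saturation in row order. The output always passes a strict parse and is
structurally clean.

## Synthetic data

The generator emulates a tomography-derived atlas at miniature scale,
as a pure function of `(seed, gridShape, nStructures, depth)`:

- **Anatomy** is `n` disjoint axis-aligned boxes stacked along axis 0,
  each in its own slab with a one-voxel margin. Boxes are trivially
  meshable as cuboids, so the label map and the OBJ/STL meshes agree
  *exactly* by construction — intentional, because it lets
  label/geometry consistency be asserted bitwise rather than within a
  registration tolerance.
- **Volumes**: an int16 label map and a float32 "MRI-like" volume
  (seeded Gaussian noise, smoothed with σ = 2 voxels, structures
  brightened, rescaled to [0, 100]), both with spacing
  (0.9375, 0.9375, 1.5) mm — a typical MRI in-plane/slice anisotropy.
  Defaults (24 × 24 × 16 grid, 5 structures, depth 3) keep the full
  suite fast while exercising multi-level hierarchy and multi-label
  scans; sizes are configurable upward.
- **Outputs**: canonical and nested atlas JSON, per-structure OBJ (+MTL
  color) and ASCII STL twins with fixed 6-decimal formatting, a TSV
  twin, and a manifest recording node counts and types, the label→
  structure map, file shapes and mesh counts — the test oracle. Same
  seed, same bytes.

What the fixtures do *not* emulate: curved anatomy, partial-volume
voxels, orientation matrices, misregistration between slices and
models, and remote data sources. Tests passing on fixtures therefore
demonstrate the correctness of the graph, state and pixel *logic*, not
robustness to messy real-world imaging; the validator explicitly does
not attempt spatial agreement checks between label maps and meshes
beyond what construction guarantees.

`mutate_atlas` copies a fixture and injects exactly one of nine defects
(`DUP_ID`, `DANGLING_REF`, `CYCLE`, `MISSING_FILE`, `LABEL_UNDECLARED`,
`LABEL_UNUSED`, `LABEL_DUPLICATE`, `MULTI_AUTHORITATIVE`, `BAD_COLOR`).
Injections are designed to trigger *only* their own rule — e.g.
`LABEL_DUPLICATE` adds a new non-authoritative claiming segment instead
of re-pointing an existing one (which would also orphan a node), and
`LABEL_UNDECLARED` paints a guaranteed-background corner of the volume
rather than deleting a declaration. This makes "exactly the injected
finding" a meaningful completeness check in both directions.

## Problem sizes and determinism

The test and acceptance runs use 20 seeded fixture atlases
(16–20 × 16 × 8–11 grids, 2–5 structures, depth 1–3), five random
volumes of 16³–32³ for the slice oracle, exhaustive voxel sweeps for
picking, 1 000 random history sequences against a two-list reference,
and all 24 arrival permutations of a 4-event shared-view stream —
sizes chosen so the whole suite completes in seconds while every
comparison stays exact (oracle differences are asserted at zero, not
within a tolerance). All randomness flows from explicit seeds;
`scripts/acceptance.py` derives every generator seed from its `--seed`
argument.

## Known limitations

- No JSON-LD context processing; files relying on context-dependent
  term expansion will not resolve.
- Single-file atlases only; `#id` references never cross files.
- Array-axis slicing only; orientation metadata is preserved in the
  data files but not interpreted.
- The bookmark store trusts its `ownerId` strings; it models ownership
  semantics, not authentication.
- ASCII VTK polydata only (no XML `.vtp`, no binary legacy VTK); OBJ
  materials beyond `Kd` are ignored.
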