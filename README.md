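# atlaskit

Headless tools for JSON node-graph anatomy atlases.

Digital anatomy atlases bundle source radiology volumes, labeled
segmentation volumes ("label maps"), polygonal models of structures, and
a hierarchical organization of anatomical parts. Interoperable atlas
viewers describe all of this in a lightweight JSON metadata file: typed
nodes (`Header`, `Group`, `Structure`, `Segment`, `DataSource`, `Image`,
`Annotation`, `Style`) with fragment-style IDs (`"#cortex"`) that
reference each other, while the bulk image and geometry data stays in
standard external formats (NRRD volumes; VTK, STL and OBJ/MTL meshes).

`atlaskit` implements that interchange model as a library plus a thin
CLI, for atlas authors and tool builders who need everything a viewer
does *except* the screen:

- **Format** — parse canonical (flat node list) and nested atlas JSON,
  resolve references, serialize to a byte-stable canonical form, query a
  structure's segments (label-map vs. geometry, authoritative or not).
  Unknown node types round-trip untouched.
- **Validation** — a non-interactive consistency checker with 14 rule
  codes covering graph defects (duplicate IDs, dangling references,
  cycles, orphans), style defects, missing/unreadable data files, and
  agreement between declared label values and the voxels actually
  present in the authoritative label map.
- **Slice computations** — NRRD loading, axis-aligned slice extraction,
  window/level contrast (`g = clamp((v − level)/window + ½, 0, 1)`),
  voxel-value transparency ranges, straight-alpha label overlay
  compositing (`out = α·color + (1−α)·gray`, `α = opacity·(1−transparency)`),
  structure picking at a voxel, PNG export.
- **Hierarchy & state** — breadcrumbs to the root, subtree visibility
  toggles, and an immutable UUID-keyed application-state model: undo/redo
  history, an owner-aware bookmark store with messaging, and
  last-writer-wins merging for dynamic shared views ordered by
  store-issued sequence numbers.
- **Authoring & testing** — a TSV→atlas converter (one structure per
  row), a deterministic synthetic-atlas generator, and a defect injector
  that breaks a generated atlas in exactly one named way.

## Worked example

```python
from pathlib import Path
import tempfile
from atlaskit import (breadcrumb, generate_fixture_atlas, parse_atlas,
                      validate)

workdir = Path(tempfile.mkdtemp()) / "atlas"
generate_fixture_atlas(workdir, seed=7, grid_shape=(24, 24, 16),
                       n_structures=5, depth=3)
graph = parse_atlas((workdir / "atlas.json").read_text(), strict=True)
print(len(graph.nodes), graph.structure_roots)
print(breadcrumb(graph, "#putamen"))
print(validate(graph, data_root=workdir, check_data=True))
```

prints

```
37 ['#root']
['#root', '#group1', '#group2']
[]
```

— a 37-node atlas (1 Header, 3 Groups, 5 Structures, 10 Segments,
7 DataSources, 5 Annotations, 5 Styles, 1 Image), one hierarchy root,
the putamen nested two groups below the root, and zero validator
findings: the generated label map, meshes and metadata agree exactly.

The `examples/` directory holds one short script per capability
(inspection, validation with injected defects, slice rendering, TSV
conversion, collaborative state); each prints what it computes and says
what the numbers mean.

## Command line

```sh
atlaskit fixture demo --seed 3          # write a synthetic atlas
atlaskit validate demo/atlas.json       # exit 0 clean / 1 errors / 2 unreadable
atlaskit info demo/atlas.json --json
atlaskit slice demo/atlas.json --axis 2 --index 8 --opacity 0.5 --out s.png
atlaskit convert demo/structures.tsv -o converted.json
atlaskit mutate demo DANGLING_REF --out broken
atlaskit bookmark save --store bk.jsonl --owner alice --atlas brain.json@1.0
```

## Scope

No rendering, camera model or network transport: geometry is read and
verified, not drawn, and collaboration is modeled with an in-process
store and sequence numbers. Orientation metadata in volume headers is
read but not applied — slices are array-axis planes, not anatomical
planes. See `docs/methods.md` for the model, parameter and design
details.
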