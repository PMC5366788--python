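"""Compute a composited cross-section the way the slice panel would.

Loads the MRI-like volume and the authoritative label map of a synthetic
atlas, applies a window/level contrast ramp, blends the per-structure
colored overlay at half opacity, picks the structure under a voxel, and
writes the result as a PNG.
"""

import tempfile
from pathlib import Path

import numpy as np

from atlaskit import (WindowLevel, apply_window_level, composite_overlay,
                      extract_slice, generate_fixture_atlas, load_volume,
                      parse_atlas, pick_structure)
from atlaskit.volume_ops import label_styles, save_png

workdir = Path(tempfile.mkdtemp()) / "atlas"
generate_fixture_atlas(workdir, seed=11)
graph = parse_atlas((workdir / "atlas.json").read_text())

mri = load_volume(workdir / "volumes" / "mri.nrrd", kind="scalar")
labels = load_volume(workdir / "volumes" / "labels.nrrd", kind="label")

axis, index = 0, mri.shape[0] // 2
raw = extract_slice(mri, axis, index)
wl = WindowLevel(window=float(raw.max() - raw.min()), level=float(raw.mean()))
gray = apply_window_level(raw, wl)
image = composite_overlay(gray, extract_slice(labels, axis, index),
                          label_styles(graph), global_opacity=0.5,
                          axis=axis, index=index)
out = workdir / "slice.png"
save_png(image, out)

ijk = tuple(int(c[0]) for c in np.nonzero(labels.voxels > 0))
picked = pick_structure(graph, labels, ijk)
print(f"slice axis={axis} index={index} -> {out}")
print(f"window={wl.window:.1f} level={wl.level:.1f}; "
      f"pixels span [{image.pixels.min():.2f}, {image.pixels.max():.2f}]")
print(f"voxel {ijk} (value {int(labels.voxels[ijk])}) belongs to "
      f"{picked.get('name')} ({picked.id})")

# The PNG holds the windowed grayscale with each labeled region tinted in
# its structure's style color; picking maps a voxel value back to the
# structure whose authoritative label-map segment declares it.
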