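"""Volumetric computations behind the cross-sectional slice panel.

Volumes are 3D voxel arrays in plain array index order ``(i, j, k)``:
axis 0 is the slowest-varying array axis, and a "slice" is taken along
an array axis, not an anatomical plane.  Mapping array axes onto
axial/coronal/sagittal requires orientation metadata the interchange
format defers to the referenced image files, so anatomical naming is
left to callers.

NRRD input/output goes through SimpleITK.  SimpleITK indexes images
``(x, y, z)`` while its numpy view is ``(z, y, x)``; spacing tuples are
reversed on the way in and out so that ``spacing[a]`` is always
millimetres per voxel along array axis ``a``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import SimpleITK as sitk

from .errors import VolumeError
from .format_model import AtlasGraph, AtlasNode, segments_for_structure

__all__ = [
    "Volume", "WindowLevel", "SliceImage", "LabelStyle",
    "load_volume", "save_volume", "extract_slice", "apply_window_level",
    "transparency_mask", "composite_overlay", "pick_structure",
    "structure_label_map", "label_styles", "to_uint8", "save_png",
]


@dataclass
class Volume:
    """A 3D voxel array with per-axis spacing.

    ``kind`` distinguishes integer label maps (each value identifies one
    structure, 0 = background) from scalar intensity volumes (CT/MRI).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "scalar"  # "label" | "scalar"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeError(f"volume must be 3D, got {self.voxels.ndim}D")
        if self.kind not in ("label", "scalar"):
            raise VolumeError(f"unknown volume kind {self.kind!r}")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")
        if self.kind == "label":
            if not np.issubdtype(self.voxels.dtype, np.integer):
                raise VolumeError("label volumes must have integer voxels")
            if self.voxels.size and self.voxels.min() < 0:
                raise VolumeError("label volumes must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class WindowLevel:
    """Linear contrast mapping: intensity width *window* centred at *level*."""

    window: float
    level: float

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise VolumeError(f"window must be positive, got {self.window}")


@dataclass
class SliceImage:
    """A rendered 2D slice: grayscale (H, W) or RGBA (H, W, 4), values in [0,1]."""

    pixels: np.ndarray
    axis: int | None = None
    index: int | None = None


@dataclass(frozen=True)
class LabelStyle:
    """Display style of one label value in an overlay."""

    color: tuple[float, float, float]
    transparency: float = 0.0
    visible: bool = True


# ---------------------------------------------------------------------------
# NRRD I/O


def load_volume(path: str | os.PathLike, kind: str | None = None) -> Volume:
    """Read a 3D NRRD file.

    Integer-typed data defaults to ``kind="label"``, floating point to
    ``"scalar"``; pass *kind* to override (the atlas decides through its
    Segment/Image context, not the file).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # SimpleITK raises RuntimeError
        raise VolumeError(f"cannot read volume {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise VolumeError(f"{path!r} is {arr.ndim}D, expected a 3D volume")
    spacing = tuple(reversed(img.GetSpacing()))
    if kind is None:
        kind = "label" if np.issubdtype(arr.dtype, np.integer) else "scalar"
    return Volume(voxels=arr, spacing=spacing, kind=kind)


def save_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume as raw-encoded NRRD (byte-deterministic for equal input)."""
    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    sitk.WriteImage(img, os.fspath(path), useCompression=False)


# ---------------------------------------------------------------------------
# Slice computations


def extract_slice(volume: Volume, axis: int, index: int) -> np.ndarray:
    """The voxel plane at *index* along array *axis* (pure read, copied).

    Remaining axes keep ascending order, so the result of slicing axis 1
    of an (n0, n1, n2) volume has shape (n0, n2).
    """
    if axis not in (0, 1, 2):
        raise VolumeError(f"axis must be 0, 1 or 2, got {axis}")
    n = volume.shape[axis]
    if not 0 <= index < n:
        raise VolumeError(f"index {index} out of range [0, {n}) on axis {axis}")
    return np.take(volume.voxels, index, axis=axis).copy()


def apply_window_level(slice2d: np.ndarray, wl: WindowLevel) -> np.ndarray:
    """Map intensities to display gray: clamp((v − level)/window + 1/2, 0, 1).

    The standard radiology ramp: *level* maps to mid-gray 0.5 and the
    interval [level − window/2, level + window/2] spans black to white.
    """
    v = np.asarray(slice2d, dtype=np.float64)
    return np.clip((v - wl.level) / wl.window + 0.5, 0.0, 1.0)


def transparency_mask(slice2d: np.ndarray,
                      ranges: Sequence[Sequence[float]]) -> np.ndarray:
    """Boolean mask of pixels whose raw value lies in any closed [lo, hi] range."""
    v = np.asarray(slice2d)
    mask = np.zeros(v.shape, dtype=bool)
    for rng in ranges:
        lo, hi = rng
        if lo > hi:
            raise VolumeError(f"inverted transparency range [{lo}, {hi}]")
        mask |= (v >= lo) & (v <= hi)
    return mask


def composite_overlay(gray: np.ndarray, labels: np.ndarray,
                      style_map: Mapping[int, LabelStyle],
                      global_opacity: float = 1.0,
                      mask: np.ndarray | None = None,
                      axis: int | None = None,
                      index: int | None = None) -> SliceImage:
    """Blend a colored label overlay onto a windowed grayscale slice.

    For each labeled, visible pixel the straight-alpha blend
    ``out = a*color + (1-a)*gray`` is applied per channel with
    ``a = global_opacity * (1 - style.transparency)``.  Background
    (label 0), hidden and unstyled labels pass the grayscale through.
    Output alpha is 1 everywhere except masked pixels, which get 0.
    """
    gray = np.asarray(gray, dtype=np.float64)
    labels = np.asarray(labels)
    if gray.shape != labels.shape:
        raise VolumeError(
            f"grayscale {gray.shape} and labels {labels.shape} differ in shape")
    if not 0.0 <= global_opacity <= 1.0:
        raise VolumeError(f"opacity must be in [0, 1], got {global_opacity}")
    if mask is not None and mask.shape != gray.shape:
        raise VolumeError("mask shape does not match slice shape")

    rgba = np.empty(gray.shape + (4,), dtype=np.float64)
    rgba[..., 0] = rgba[..., 1] = rgba[..., 2] = gray
    rgba[..., 3] = 1.0

    for value, style in style_map.items():
        if value == 0 or not style.visible:
            continue
        sel = labels == value
        if not sel.any():
            continue
        a = global_opacity * (1.0 - style.transparency)
        for c in range(3):
            rgba[..., c][sel] = a * style.color[c] + (1.0 - a) * gray[sel]
    if mask is not None:
        rgba[..., 3][mask] = 0.0
    return SliceImage(pixels=np.clip(rgba, 0.0, 1.0), axis=axis, index=index)


# ---------------------------------------------------------------------------
# Picking and graph-derived maps


def structure_label_map(graph: AtlasGraph) -> dict[int, AtlasNode]:
    """Map label value → Structure, from authoritative LabelMapSegments.

    When two structures claim the same value (a validator error), the
    first in file order wins, keeping the mapping deterministic.
    """
    out: dict[int, AtlasNode] = {}
    for structure in graph.nodes_of_type("Structure"):
        for seg in segments_for_structure(graph, structure.id,
                                          subtype="LabelMapSegment",
                                          authoritative_only=True):
            lv = seg.label_value
            if lv is not None and lv not in out:
                out[lv] = structure
    return out


def label_styles(graph: AtlasGraph,
                 visibility_overrides: Mapping[str, bool] | None = None
                 ) -> dict[int, LabelStyle]:
    """Map label value → display style, from each Structure's first Style node.

    *visibility_overrides* (node ID → bool, e.g. from application state)
    takes precedence over the style's own visibility flag.  Structures
    without a style get no entry and therefore pass through as grayscale.
    """
    overrides = visibility_overrides or {}
    out: dict[int, LabelStyle] = {}
    for value, structure in structure_label_map(graph).items():
        if not structure.styles:
            continue
        style = graph.resolve(structure.styles[0])
        color = style.get("color", [0.5, 0.5, 0.5])
        visible = bool(style.get("visibility", True))
        if structure.id in overrides:
            visible = overrides[structure.id]
        out[value] = LabelStyle(color=tuple(float(c) for c in color),
                                transparency=float(style.get("transparency", 0.0)),
                                visible=visible)
    return out


def pick_structure(graph: AtlasGraph, volume: Volume,
                   ijk: tuple[int, int, int]) -> AtlasNode | None:
    """The Structure whose authoritative label value sits at voxel *ijk*.

    Returns None for background (0) or for a voxel value no structure
    declares.  *volume* must be the atlas's authoritative label map.
    """
    for a, (i, n) in enumerate(zip(ijk, volume.shape)):
        if not 0 <= i < n:
            raise VolumeError(f"index {i} out of range [0, {n}) on axis {a}")
    value = int(volume.voxels[tuple(ijk)])
    if value == 0:
        return None
    return structure_label_map(graph).get(value)


# ---------------------------------------------------------------------------
# PNG export


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize [0,1] floats to 8 bits: floor(255·x + 0.5)."""
    return np.floor(255.0 * np.clip(pixels, 0.0, 1.0) + 0.5).astype(np.uint8)


def save_png(image: SliceImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write a grayscale or RGBA slice image as an 8-bit PNG."""
    from PIL import Image

    pixels = image.pixels if isinstance(image, SliceImage) else image
    data = to_uint8(pixels)
    mode = "L" if data.ndim == 2 else "RGBA"
    Image.fromarray(data, mode=mode).save(os.fspath(path))
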