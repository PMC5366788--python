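"""Slice extraction, contrast, compositing and picking against naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlaskit import (FixtureManifest, LabelStyle, Volume, VolumeError,
                      WindowLevel, apply_window_level, composite_overlay,
                      extract_slice, load_volume, pick_structure, save_volume,
                      transparency_mask)
from atlaskit.volume_ops import save_png, to_uint8


def naive_slice(voxels, axis, index):
    """Triple-loop copy oracle."""
    shape = [s for a, s in enumerate(voxels.shape) if a != axis]
    out = np.empty(shape, dtype=voxels.dtype)
    for i in range(voxels.shape[0]):
        for j in range(voxels.shape[1]):
            for k in range(voxels.shape[2]):
                ijk = [i, j, k]
                if ijk[axis] != index:
                    continue
                rest = [x for a, x in enumerate(ijk) if a != axis]
                out[tuple(rest)] = voxels[i, j, k]
    return out


class TestIO:
    def test_label_nrrd_write_read_equality(self, tmp_path):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 7, size=(16, 16, 8)).astype(np.int16)
        vol = Volume(arr, spacing=(0.5, 0.5, 2.0), kind="label")
        save_volume(vol, tmp_path / "lab.nrrd")
        back = load_volume(tmp_path / "lab.nrrd")
        assert back.kind == "label"
        assert back.shape == (16, 16, 8)
        assert back.spacing == (0.5, 0.5, 2.0)
        assert np.array_equal(back.voxels, arr)

    def test_scalar_nrrd_round_trips_bitwise(self, tmp_path):
        arr = np.random.default_rng(6).normal(size=(8, 9, 10)).astype(
            np.float32)
        save_volume(Volume(arr, kind="scalar"), tmp_path / "s.nrrd")
        back = load_volume(tmp_path / "s.nrrd")
        assert back.kind == "scalar"
        assert np.array_equal(back.voxels, arr)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nrrd")

    def test_non_3d_volume_is_rejected(self):
        with pytest.raises(VolumeError):
            Volume(np.zeros((4, 4)))

    def test_float_label_volume_is_rejected(self):
        with pytest.raises(VolumeError):
            Volume(np.zeros((4, 4, 4)), kind="label")


class TestExtractSlice:
    def test_constant_volume_plane(self):
        vol = Volume(np.full((16, 16, 8), 7, dtype=np.int16), kind="label")
        plane = extract_slice(vol, axis=2, index=0)
        assert plane.shape == (16, 16)
        assert (plane == 7).all()

    def test_index_at_shape_is_out_of_range(self):
        vol = Volume(np.zeros((4, 5, 6)))
        with pytest.raises(VolumeError):
            extract_slice(vol, axis=1, index=5)
        with pytest.raises(VolumeError):
            extract_slice(vol, axis=3, index=0)

    def test_every_axis_and_index_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        vol = Volume(rng.normal(size=(6, 5, 4)))
        for axis in range(3):
            for index in range(vol.shape[axis]):
                got = extract_slice(vol, axis, index)
                assert np.array_equal(got, naive_slice(vol.voxels, axis, index))

    def test_slicing_is_a_pure_read(self):
        vol = Volume(np.zeros((4, 4, 4)))
        extract_slice(vol, 0, 0)[:] = 9
        assert (vol.voxels == 0).all()


class TestWindowLevel:
    def test_level_maps_to_mid_gray(self):
        out = apply_window_level(np.array([[40.0]]), WindowLevel(100.0, 40.0))
        assert out[0, 0] == 0.5

    def test_clamp_bounds(self):
        wl = WindowLevel(window=10.0, level=0.0)
        v = np.array([[-5.0, -100.0, 5.0, 100.0]])
        out = apply_window_level(v, wl)
        assert list(out[0]) == [0.0, 0.0, 1.0, 1.0]

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(scale=50, size=(12, 13))
        wl = WindowLevel(window=30.0, level=10.0)
        got = apply_window_level(v, wl)
        for i in range(v.shape[0]):
            for j in range(v.shape[1]):
                expected = min(max((v[i, j] - 10.0) / 30.0 + 0.5, 0.0), 1.0)
                assert got[i, j] == pytest.approx(expected)

    def test_nonpositive_window_is_rejected(self):
        with pytest.raises(VolumeError):
            WindowLevel(0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20),
           st.floats(1e-3, 1e4), st.floats(-1e4, 1e4))
    def test_output_in_unit_interval_and_monotone(self, values, window, level):
        v = np.array(sorted(values))
        out = apply_window_level(v, WindowLevel(window, level))
        assert ((out >= 0) & (out <= 1)).all()
        assert (np.diff(out) >= 0).all()


class TestTransparencyMask:
    def test_full_span_range_masks_everything(self):
        v = np.arange(12.0).reshape(3, 4)
        assert transparency_mask(v, [[0.0, 11.0]]).all()

    def test_empty_range_list_masks_nothing(self):
        assert not transparency_mask(np.ones((3, 3)), []).any()

    def test_inverted_range_is_rejected(self):
        with pytest.raises(VolumeError):
            transparency_mask(np.ones((2, 2)), [[3.0, 1.0]])

    def test_matches_interval_membership_oracle(self):
        rng = np.random.default_rng(9)
        v = rng.integers(0, 20, size=(10, 11)).astype(float)
        ranges = [[2.0, 5.0], [9.0, 9.0], [15.0, 18.0]]
        got = transparency_mask(v, ranges)
        for i in range(v.shape[0]):
            for j in range(v.shape[1]):
                expected = any(lo <= v[i, j] <= hi for lo, hi in ranges)
                assert got[i, j] == expected


class TestCompositeOverlay:
    STYLES = {1: LabelStyle(color=(1.0, 0.0, 0.0)),
              2: LabelStyle(color=(0.0, 0.0, 1.0), transparency=0.5),
              3: LabelStyle(color=(0.0, 1.0, 0.0), visible=False)}

    def _inputs(self):
        rng = np.random.default_rng(10)
        gray = rng.uniform(size=(9, 8))
        labels = rng.integers(0, 4, size=(9, 8))
        return gray, labels

    def test_zero_opacity_is_identity_on_grayscale(self):
        gray, labels = self._inputs()
        out = composite_overlay(gray, labels, self.STYLES, 0.0).pixels
        for c in range(3):
            assert np.array_equal(out[..., c], gray)
        assert (out[..., 3] == 1.0).all()

    def test_full_opacity_gives_pure_style_color(self):
        gray, labels = self._inputs()
        out = composite_overlay(gray, labels, self.STYLES, 1.0).pixels
        sel = labels == 1
        assert (out[sel][:, 0] == 1.0).all()
        assert (out[sel][:, 1] == 0.0).all()
        assert (out[sel][:, 2] == 0.0).all()

    def test_hidden_labels_pass_grayscale_through(self):
        gray, labels = self._inputs()
        out = composite_overlay(gray, labels, self.STYLES, 1.0).pixels
        sel = labels == 3
        for c in range(3):
            assert np.array_equal(out[..., c][sel], gray[sel])

    def test_half_opacity_matches_per_pixel_blend_oracle(self):
        gray, labels = self._inputs()
        mask = np.zeros(gray.shape, dtype=bool)
        mask[0, :] = True
        out = composite_overlay(gray, labels, self.STYLES, 0.5, mask).pixels
        for i in range(gray.shape[0]):
            for j in range(gray.shape[1]):
                style = self.STYLES.get(int(labels[i, j]))
                if style is None or not style.visible:
                    expected = (gray[i, j],) * 3
                else:
                    a = 0.5 * (1.0 - style.transparency)
                    expected = tuple(a * style.color[c]
                                     + (1 - a) * gray[i, j] for c in range(3))
                assert out[i, j, :3] == pytest.approx(expected)
                assert out[i, j, 3] == (0.0 if mask[i, j] else 1.0)

    def test_shape_mismatch_and_bad_opacity_are_rejected(self):
        with pytest.raises(VolumeError):
            composite_overlay(np.zeros((3, 3)), np.zeros((4, 4), int), {}, 1.0)
        with pytest.raises(VolumeError):
            composite_overlay(np.zeros((3, 3)), np.zeros((3, 3), int), {}, 1.5)

    def test_output_always_within_unit_interval(self):
        gray, labels = self._inputs()
        out = composite_overlay(gray, labels, self.STYLES, 0.7).pixels
        assert ((out >= 0) & (out <= 1)).all()


class TestPicking:
    def test_background_voxel_picks_nothing(self, graph, fixture_dir):
        vol = load_volume(fixture_dir / "volumes" / "labels.nrrd")
        assert vol.voxels[0, 0, 0] == 0
        assert pick_structure(graph, vol, (0, 0, 0)) is None

    def test_out_of_range_voxel_raises(self, graph, fixture_dir):
        vol = load_volume(fixture_dir / "volumes" / "labels.nrrd")
        with pytest.raises(VolumeError):
            pick_structure(graph, vol, (0, 0, vol.shape[2]))

    def test_every_voxel_picks_per_manifest_label_map(self, graph,
                                                      fixture_dir, manifest):
        vol = load_volume(fixture_dir / "volumes" / "labels.nrrd")
        for i in range(vol.shape[0]):
            for j in range(vol.shape[1]):
                for k in range(vol.shape[2]):
                    node = pick_structure(graph, vol, (i, j, k))
                    value = int(vol.voxels[i, j, k])
                    if value == 0:
                        assert node is None
                    else:
                        assert node.id == \
                            manifest.label_map[str(value)]["structure"]

    def test_picked_structure_declares_the_voxel_value(self, graph,
                                                       fixture_dir):
        from atlaskit import segments_for_structure
        vol = load_volume(fixture_dir / "volumes" / "labels.nrrd")
        i, j, k = np.argwhere(vol.voxels > 0)[0]
        node = pick_structure(graph, vol, (int(i), int(j), int(k)))
        seg = segments_for_structure(graph, node.id, "LabelMapSegment",
                                     authoritative_only=True)[0]
        assert seg.label_value == int(vol.voxels[i, j, k])


class TestPng:
    def test_quantization_is_round_half_up(self):
        x = np.array([[0.0, 1.0, 0.5, 0.002]])
        assert list(to_uint8(x)[0]) == [0, 255, 128, 1]

    def test_written_png_dimensions_match_slice(self, tmp_path):
        from PIL import Image
        save_png(np.zeros((5, 9)), tmp_path / "g.png")
        with Image.open(tmp_path / "g.png") as im:
            assert im.size == (9, 5) and im.mode == "L"
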