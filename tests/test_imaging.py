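"""Image I/O, thresholding, mask ingestion, and renderer contracts."""

import numpy as np
import pytest

from mitoscope import imaging as im
from conftest import brute_force_boundary, brute_force_dilate_3x3


class TestIO:
    def test_16bit_roundtrip(self, tmp_path, rng):
        pixels = rng.integers(0, 65535, size=(32, 40)).astype(np.uint16)
        path = im.write_image(im.ImageFrame(pixels), tmp_path / "x.tif")
        back = im.read_stack(path)
        assert len(back) == 1
        assert np.array_equal(back[0].pixels, pixels)

    def test_multipage_indices(self, tmp_path, rng):
        frames = [rng.integers(0, 255, size=(16, 16)).astype(np.uint8) for _ in range(3)]
        im.write_stack(frames, tmp_path / "stack.tif")
        back = im.read_stack(tmp_path / "stack.tif")
        assert [f.frame_index for f in back] == [0, 1, 2]

    def test_text_file_rejected(self, tmp_path):
        bad = tmp_path / "notes.tif"
        bad.write_text("this is not an image")
        with pytest.raises(ValueError):
            im.read_stack(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            im.read_stack(tmp_path / "absent.tif")


class TestTo8Bit:
    def test_full_range_8bit_unchanged(self):
        pixels = np.array([[0, 128], [200, 255]], dtype=np.uint8)
        out = im.to_8bit(im.ImageFrame(pixels))
        assert np.array_equal(out.pixels, pixels)

    def test_16bit_endpoints(self):
        pixels = np.array([[0, 65535]], dtype=np.uint16)
        out = im.to_8bit(im.ImageFrame(pixels))
        assert out.pixels[0, 0] == 0 and out.pixels[0, 1] == 255

    def test_constant_maps_to_zero(self):
        out = im.to_8bit(im.ImageFrame(np.full((4, 4), 500, dtype=np.uint16)))
        assert (out.pixels == 0).all()


class TestThresholdSegmentation:
    def test_strict_127_is_background(self):
        frame = im.ImageFrame(np.full((8, 8), 127, dtype=np.uint8))
        assert im.segment_by_threshold(frame).n_objects == 0

    def test_128_single_pixel_is_object(self):
        pixels = np.zeros((8, 8), dtype=np.uint8)
        pixels[3, 3] = 128
        mask = im.segment_by_threshold(im.ImageFrame(pixels))
        assert mask.n_objects == 1
        assert (mask.labels > 0).sum() == 1

    def test_two_blobs_two_labels(self):
        pixels = np.zeros((10, 10), dtype=np.uint8)
        pixels[1:3, 1:3] = 200
        pixels[7:9, 7:9] = 200
        mask = im.segment_by_threshold(im.ImageFrame(pixels))
        assert set(np.unique(mask.labels)) == {0, 1, 2}

    def test_all_below_threshold_empty(self, rng):
        pixels = rng.integers(0, 128, size=(16, 16)).astype(np.uint8)
        assert im.segment_by_threshold(im.ImageFrame(pixels)).n_objects == 0

    def test_connectivity_option(self):
        pixels = np.zeros((4, 4), dtype=np.uint8)
        pixels[0, 0] = pixels[1, 1] = 200  # diagonal touch
        assert im.segment_by_threshold(im.ImageFrame(pixels), connectivity=8).n_objects == 1
        assert im.segment_by_threshold(im.ImageFrame(pixels), connectivity=4).n_objects == 2


class TestIngestMask:
    def test_binary_input_labeled(self):
        binary = np.zeros((10, 10), dtype=np.uint8)
        binary[1:3, 1:3] = 1
        binary[5:7, 5:7] = 1
        binary[8:10, 0:2] = 1
        assert im.ingest_mask(binary).n_objects == 3

    def test_sparse_labels_compacted(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1:3, 1:3] = 2
        labels[5:7, 5:7] = 7
        mask = im.ingest_mask(labels)
        assert set(np.unique(mask.labels)) == {0, 1, 2}
        # geometry preserved under relabeling
        assert (mask.labels > 0).sum() == (labels > 0).sum()

    def test_disconnected_label_split(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[0:2, 0:2] = 5
        labels[7:9, 7:9] = 5
        mask = im.ingest_mask(labels)
        assert mask.n_objects == 2

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError):
            im.ingest_mask(np.array([[-1, 0], [0, 1]]))

    def test_max_label_equals_object_count(self, small_scene):
        mask = im.ingest_mask(small_scene.truth_mask.labels)
        assert mask.labels.max() == mask.n_objects


class TestPseudocolor:
    def test_anchor_mean_maps_to_anchor_color(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[1:3, 1:3] = 1
        pixels = np.zeros((6, 6), dtype=np.uint8)
        pixels[1:3, 1:3] = 85  # exactly the green anchor
        rgb = im.render_pseudocolor(im.LabeledMask(labels), im.ImageFrame(pixels))
        assert tuple(rgb[1, 1]) == (0, 255, 0)
        assert tuple(rgb[0, 0]) == (0, 0, 0)  # background untouched

    def test_midpoint_interpolation_rounds_half_up(self):
        cmap = im.ColorMapSpec([(0.0, (0, 0, 255)), (255.0, (255, 0, 0))])
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0:2, 0:2] = 1
        pixels = np.zeros((4, 4), dtype=np.uint8)
        pixels[0, 0] = pixels[0, 1] = 127
        pixels[1, 0] = pixels[1, 1] = 128  # mean = 127.5
        rgb = im.render_pseudocolor(im.LabeledMask(labels), im.ImageFrame(pixels), cmap)
        assert tuple(rgb[0, 0]) == (128, 0, 128)  # 127.5 rounds half up

    def test_render_deterministic(self, small_scene):
        frame = im.to_8bit(small_scene.image)
        a = im.render_pseudocolor(small_scene.truth_mask, frame)
        b = im.render_pseudocolor(small_scene.truth_mask, frame)
        assert np.array_equal(a, b)

    def test_mean_is_arithmetic_mean(self, small_scene):
        frame = im.to_8bit(small_scene.image)
        cmap = im.ColorMapSpec()
        rgb = im.render_pseudocolor(small_scene.truth_mask, frame, cmap)
        obj = small_scene.truth_mask.labels == 1
        mean = frame.pixels[obj].sum() / obj.sum()  # brute-force sum/count
        assert tuple(rgb[obj][0]) == cmap.color_for(mean)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            im.render_pseudocolor(
                im.LabeledMask(np.zeros((4, 4), dtype=int)),
                im.ImageFrame(np.zeros((5, 5), dtype=np.uint8)),
            )

    def test_bad_anchor_order_rejected(self):
        with pytest.raises(ValueError):
            im.ColorMapSpec([(0.0, (0, 0, 0)), (0.0, (1, 1, 1))])


class TestOverlays:
    def test_single_pixel_becomes_3x3_red_block(self):
        raw = im.ImageFrame(np.zeros((9, 9), dtype=np.uint8))
        skel = np.zeros((9, 9), dtype=bool)
        skel[4, 4] = True
        rgb = im.overlay_skeleton(raw, skel)
        red = (rgb == (255, 0, 0)).all(axis=-1)
        assert red.sum() == 9
        assert red[3:6, 3:6].all()

    def test_empty_skeleton_promotes_grayscale(self, rng):
        pixels = rng.integers(0, 255, (8, 8)).astype(np.uint8)
        rgb = im.overlay_skeleton(im.ImageFrame(pixels), np.zeros((8, 8), dtype=bool))
        for c in range(3):
            assert np.array_equal(rgb[..., c], pixels)

    def test_l_shape_dilation_matches_brute_force(self):
        skel = np.zeros((16, 16), dtype=bool)
        skel[3:10, 3] = True
        skel[9, 3:8] = True
        rgb = im.overlay_skeleton(im.ImageFrame(np.zeros((16, 16), dtype=np.uint8)), skel)
        red = (rgb == (255, 0, 0)).all(axis=-1)
        assert np.array_equal(red, brute_force_dilate_3x3(skel))

    def test_outline_colors_and_boundary(self, small_scene):
        mask = small_scene.truth_mask
        classes = {
            int(r.label): r.kind for r in small_scene.truth_table.itertuples()
        }
        rgb = im.outline_by_morphotype(mask, classes)
        colored = rgb.any(axis=-1)
        assert np.array_equal(colored, brute_force_boundary(mask.labels))
        # one known dot object gets a green contour
        dot_label = small_scene.truth_table.query("kind == 'dot'").label.iloc[0]
        edge = brute_force_boundary((mask.labels == dot_label).astype(int))
        assert (rgb[edge] == (0, 255, 0)).all()

    def test_outline_missing_class_raises(self, small_scene):
        with pytest.raises(KeyError):
            im.outline_by_morphotype(small_scene.truth_mask, {1: "dot"})

    def test_outline_empty_mask_unchanged(self):
        rgb = im.outline_by_morphotype(im.LabeledMask(np.zeros((5, 5), dtype=int)), {})
        assert (rgb == 0).all()
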