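"""Synthetic scene generator: determinism, label geometry, augmentations."""

import numpy as np
import pytest

from wheatear import (Box, SynthConfig, augment, easy_config, make_dataset,
                      mosaic, sample_scene)


@pytest.fixture(scope="module")
def scene():
    return sample_scene(SynthConfig(image_size=512), seed=11)


class TestSampling:
    def test_box_count_in_configured_range(self, scene):
        assert 20 <= len(scene.boxes) <= 70

    def test_deterministic_under_seed(self):
        cfg = SynthConfig(image_size=256, ear_count_range=(5, 12))
        a = sample_scene(cfg, seed=3)
        b = sample_scene(cfg, seed=3)
        np.testing.assert_array_equal(a.image, b.image)
        assert [x.as_xyxy() for x in a.boxes] == [x.as_xyxy() for x in b.boxes]

    def test_different_seeds_differ(self):
        cfg = SynthConfig(image_size=256, ear_count_range=(5, 12))
        a = sample_scene(cfg, seed=3)
        b = sample_scene(cfg, seed=4)
        assert not np.array_equal(a.image, b.image)

    def test_boxes_positive_area_inside_image(self, scene):
        s = 512
        for b in scene.boxes:
            assert b.area > 0
            assert 0 <= b.x1 < b.x2 <= s
            assert 0 <= b.y1 < b.y2 <= s

    def test_mean_count_matches_uniform_20_70(self):
        cfg = SynthConfig(image_size=512)
        counts = [len(sample_scene(cfg, seed=s).boxes) for s in range(200)]
        assert 42.0 <= np.mean(counts) <= 48.0

    def test_ear_pixels_covered_by_boxes(self):
        """The union of the labelled boxes must cover (almost all of) the
        pixels that differ from a background-only render."""
        cfg = SynthConfig(image_size=256, ear_count_range=(6, 10),
                          background_similarity=0.0)
        scene = sample_scene(cfg, seed=5)
        from wheatear.synth import _background
        bg = _background(np.random.default_rng(5), cfg).astype(np.uint8)
        changed = np.any(scene.image != bg, axis=2)
        covered = np.zeros_like(changed)
        for b in scene.boxes:
            covered[int(b.y1):int(np.ceil(b.y2)),
                    int(b.x1):int(np.ceil(b.x2))] = True
        frac = (changed & covered).sum() / max(changed.sum(), 1)
        assert frac >= 0.95

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(ear_count_range=(10, 5))


class TestAugment:
    def test_mirror_is_involution(self, tiny_scene):
        twice = augment(augment(tiny_scene, ["mirror"]), ["mirror"])
        np.testing.assert_array_equal(twice.image, tiny_scene.image)
        for a, b in zip(twice.boxes, tiny_scene.boxes):
            assert a.as_xyxy() == pytest.approx(b.as_xyxy())

    def test_rotate_zero_is_identity(self, tiny_scene):
        from wheatear.synth import rotate_scene
        img, boxes = rotate_scene(tiny_scene.image.astype(float),
                                  tiny_scene.boxes, 0.0)
        np.testing.assert_array_equal(img, tiny_scene.image)
        assert [b.as_xyxy() for b in boxes] \
            == [b.as_xyxy() for b in tiny_scene.boxes]

    def test_rotate_90_preserves_centered_square_box(self):
        from wheatear.synth import rotate_scene
        img = np.zeros((100, 100, 3))
        box = Box(30.0, 30.0, 70.0, 70.0)   # square, centred
        _, boxes = rotate_scene(img, [box], 90.0)
        assert len(boxes) == 1
        assert boxes[0].as_xyxy() == pytest.approx(box.as_xyxy(), abs=1e-9)

    def test_scale_multiplies_coordinates(self, tiny_scene):
        from wheatear.synth import scale_scene
        img, boxes = scale_scene(tiny_scene.image.astype(float),
                                 tiny_scene.boxes, 0.5)
        for a, b in zip(boxes, tiny_scene.boxes):
            assert a.as_xyxy() == pytest.approx(
                tuple(v * 0.5 for v in b.as_xyxy()))

    def test_saturation_changes_pixels_not_boxes(self, tiny_scene):
        out = augment(tiny_scene, ["saturation"], seed=1)
        assert [b.as_xyxy() for b in out.boxes] \
            == [b.as_xyxy() for b in tiny_scene.boxes]
        assert out.image.shape == tiny_scene.image.shape

    def test_unknown_op_rejected(self, tiny_scene):
        with pytest.raises(ValueError):
            augment(tiny_scene, ["sharpen"])


class TestMosaic:
    def _scenes(self):
        cfg = easy_config(128)
        return [sample_scene(cfg, seed=s) for s in range(4)]

    def test_output_size_equals_input_size(self):
        out = mosaic(self._scenes(), seed=0)
        assert out.image.shape == (128, 128, 3)

    def test_box_count_never_grows(self):
        scenes = self._scenes()
        out = mosaic(scenes, seed=0)
        assert len(out.boxes) <= sum(len(s.boxes) for s in scenes)

    def test_boxes_inside_their_quadrant(self):
        scenes = self._scenes()
        for seed in range(5):
            out = mosaic(scenes, seed=seed)
            for b in out.boxes:
                assert 0 <= b.x1 < b.x2 <= 128
                assert 0 <= b.y1 < b.y2 <= 128

    def test_quadrants_come_from_sources(self):
        scenes = self._scenes()
        out = mosaic(scenes, seed=3)
        # find the mosaic centre from the deterministic rng
        rng = np.random.default_rng(3)
        cx = int(rng.uniform(0.3, 0.7) * 128)
        cy = int(rng.uniform(0.3, 0.7) * 128)
        # top-left quadrant is a contiguous crop of scene 0
        patch = out.image[:cy, :cx]
        found = False
        big = scenes[0].image
        for oy in range(128 - patch.shape[0] + 1):
            for ox in range(128 - patch.shape[1] + 1):
                if np.array_equal(big[oy:oy + patch.shape[0],
                                      ox:ox + patch.shape[1]], patch):
                    found = True
                    break
            if found:
                break
        assert found

    def test_size_mismatch_rejected(self):
        cfg = easy_config(128)
        scenes = [sample_scene(cfg, seed=s) for s in range(3)]
        scenes.append(sample_scene(easy_config(256), seed=9))
        with pytest.raises(ValueError):
            mosaic(scenes, seed=0)


class TestMakeDataset:
    def test_files_and_manifest(self, tmp_path):
        cfg = easy_config(96)
        manifest = make_dataset(cfg, 10, seed=1, out_dir=tmp_path)
        assert len(manifest) == 10
        assert len(list((tmp_path / "images").glob("*.png"))) == 10
        assert len(list((tmp_path / "labels").glob("*.txt"))) == 10
        assert (tmp_path / "annotations.csv").exists()

    def test_csv_round_trip_reproduces_boxes(self, tmp_path):
        from wheatear.dataio import read_gwhd_csv
        cfg = easy_config(96)
        make_dataset(cfg, 3, seed=2, out_dir=tmp_path)
        scenes = [sample_scene(cfg, seed=2 * 100003 + i) for i in range(3)]
        parsed = read_gwhd_csv(tmp_path / "annotations.csv")
        for i, scene in enumerate(scenes):
            got = parsed[f"synth_2_{i:05d}"]["boxes"]
            assert [b.as_xyxy() for b in got] \
                == [b.as_xyxy() for b in scene.boxes]

    def test_split_partitions_without_overlap(self, tmp_path):
        manifest = make_dataset(easy_config(96), 10, seed=3,
                                out_dir=tmp_path, val_fraction=0.3)
        train = set(manifest[manifest.split == "train"].image_id)
        val = set(manifest[manifest.split == "val"].image_id)
        assert len(train) == 7 and len(val) == 3
        assert not train & val
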