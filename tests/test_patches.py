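"""Annotation I/O, splitting, patch extraction, augmentation, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from podquant import patches
from podquant.patches import (PointAnnotation, BorderAnnotationError,
                              read_annotations, write_annotations,
                              split_images, extract_training_patch, augment,
                              center_crop, fit_normalization,
                              apply_normalization, annotation_summary)


class TestAnnotationIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        anns = [PointAnnotation(f"img{i % 7}", int(rng.integers(0, 500)),
                                int(rng.integers(0, 500)), int(rng.integers(0, 4)))
                for i in range(100)]
        path = tmp_path / "ann.csv"
        write_annotations(path, anns)
        assert read_annotations(path) == anns

    def test_unknown_class_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("image_id,x,y,class_name\nimg0,10,10,tip\n"
                        "img0,20,20,flower\n")
        with pytest.raises(ValueError, match="line 3.*flower"):
            read_annotations(path)

    def test_malformed_coordinates_name_line(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("image_id,x,y,class_name\nimg0,ten,10,tip\n")
        with pytest.raises(ValueError, match="line 2"):
            read_annotations(path)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("image_id,x,y,class_name\n")
        assert read_annotations(path) == []

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PointAnnotation("img", 0, 0, 4)

    def test_summary_counts_per_class(self):
        anns = [PointAnnotation("a", 0, 0, 3)] * 2 + [PointAnnotation("a", 0, 0, 1)]
        counts = annotation_summary(anns)
        assert counts["tip"] == 2 and counts["body"] == 1
        assert counts.sum() == 3


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (144, (93, 29, 22)),   # largest remainder, ties to later partitions
        (100, (65, 20, 15)),   # exact fractions
        (18, (12, 3, 3)),
    ])
    def test_split_sizes(self, n, expected):
        ids = [f"img{i:03d}" for i in range(n)]
        s = split_images(ids, seed=5)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == expected

    def test_partition_properties(self):
        ids = [f"img{i}" for i in range(53)]
        s = split_images(ids, seed=2)
        union = set(s.train_ids) | set(s.val_ids) | set(s.test_ids)
        assert union == set(ids)
        assert len(s.train_ids) + len(s.val_ids) + len(s.test_ids) == 53

    def test_deterministic_and_order_invariant(self):
        ids = [f"img{i}" for i in range(40)]
        a = split_images(ids, seed=9)
        b = split_images(list(reversed(ids)), seed=9)
        assert a == b

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            split_images(["a", "b"], seed=0)


class TestPatchExtraction:
    def test_centred_window_arithmetic(self):
        img = np.arange(200 * 200 * 3, dtype=np.uint8).reshape(200, 200, 3)
        p = extract_training_patch(img, PointAnnotation("i", 100, 100, 0))
        assert p.shape == (50, 50, 3)
        np.testing.assert_array_equal(p, img[75:125, 75:125])

    def test_border_annotation_skipped(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.raises(BorderAnnotationError):
            extract_training_patch(img, PointAnnotation("i", 24, 24, 0))

    def test_uniform_image_gives_uniform_patch(self):
        img = np.full((80, 80, 3), 17, dtype=np.uint8)
        p = extract_training_patch(img, PointAnnotation("i", 40, 40, 2))
        assert np.all(p == 17)


class TestAugment:
    def test_seeded_repeatability_and_shape(self):
        patch = np.random.default_rng(0).integers(0, 255, (50, 50, 3)).astype(np.uint8)
        a = augment(patch, np.random.default_rng(4))
        b = augment(patch, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)
        assert a.shape == (32, 32, 3)

    def test_crop_containment(self):
        # every output pixel value exists in the source window
        patch = np.random.default_rng(1).integers(0, 255, (50, 50, 3)).astype(np.uint8)
        out = augment(patch, np.random.default_rng(2))
        src = set(map(tuple, patch.reshape(-1, 3)))
        assert set(map(tuple, out.reshape(-1, 3))) <= src

    def test_wrong_input_size_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((32, 32, 3), dtype=np.uint8), np.random.default_rng(0))

    def test_crop_offsets_uniform(self):
        # encode pixel coordinates in the channel values: the smallest value
        # surviving in the output identifies the crop offset regardless of
        # the mirror/rotation applied afterwards
        base = (np.arange(50)[:, None] * 50 + np.arange(50)[None, :])
        patch = np.stack([base // 256, base % 256, np.zeros_like(base)],
                         axis=-1).astype(np.uint8)
        rng = np.random.default_rng(99)
        counts = np.zeros((19, 19), dtype=int)
        for _ in range(10000):
            out = augment(patch, rng).astype(np.int32)
            v = int((out[..., 0] * 256 + out[..., 1]).min())
            counts[v // 50, v % 50] += 1
        p = sps.chisquare(counts.ravel()).pvalue
        assert p > 0.01

    def test_center_crop_is_centred(self):
        patch = np.random.default_rng(3).integers(0, 255, (50, 50, 3)).astype(np.uint8)
        np.testing.assert_array_equal(center_crop(patch), patch[9:41, 9:41])


class TestNormalization:
    def _train_patches(self):
        rng = np.random.default_rng(0)
        return rng.integers(0, 255, (64, 32, 32, 3)).astype(np.uint8)

    def test_mean_patch_of_zscored_set_is_zero_under_composed_mode(self):
        x = self._train_patches()
        stats = fit_normalization(x)
        z = apply_normalization(x, stats, mode="zscore_then_mean_patch")
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-4)

    def test_channel_zscore_standardizes_training_set(self):
        x = self._train_patches()
        stats = fit_normalization(x)
        z = apply_normalization(x, stats, mode="channel_zscore")
        np.testing.assert_allclose(z.mean(axis=(0, 1, 2)), 0.0, atol=1e-4)
        np.testing.assert_allclose(z.std(axis=(0, 1, 2)), 1.0, atol=1e-3)

    def test_mean_patch_mode_zeroes_the_mean_patch_itself(self):
        x = self._train_patches()
        stats = fit_normalization(x)
        out = apply_normalization(np.asarray(stats.mean_patch), stats,
                                  mode="mean_patch")
        np.testing.assert_allclose(out, 0.0, atol=1e-5)

    def test_constant_dataset_rejected(self):
        x = np.full((10, 32, 32, 3), 7, dtype=np.uint8)
        with pytest.raises(ValueError, match="zero channel"):
            fit_normalization(x)

    def test_shape_mismatch_rejected(self):
        stats = fit_normalization(self._train_patches())
        with pytest.raises(ValueError):
            apply_normalization(np.zeros((16, 16, 3)), stats, mode="mean_patch")

    def test_stats_json_round_trip(self, tmp_path):
        stats = fit_normalization(self._train_patches())
        stats.to_json(tmp_path / "s.json")
        loaded = patches.NormalizationStats.from_json(tmp_path / "s.json")
        np.testing.assert_allclose(loaded.mean_patch, stats.mean_patch)


def test_patchset_directory_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    sets = {name: (rng.integers(0, 255, (k, 32, 32, 3)).astype(np.uint8),
                   rng.integers(0, 4, k).astype(np.int64))
            for name, k in (("train", 6), ("val", 3), ("test", 2))}
    index = patches.save_patchset_dir(tmp_path, sets)
    assert len(index) == 11
    loaded = patches.load_patchset_dir(tmp_path)
    for name in ("train", "val", "test"):
        np.testing.assert_array_equal(loaded[name][0], sets[name][0])
        np.testing.assert_array_equal(loaded[name][1], sets[name][1])


@settings(max_examples=25, deadline=None)
@given(st.integers(3, 200), st.integers(0, 2 ** 20))
def test_split_always_partitions(n, seed):
    ids = [f"im{i}" for i in range(n)]
    s = split_images(ids, seed=seed)
    parts = [s.train_ids, s.val_ids, s.test_ids]
    assert sum(len(p) for p in parts) == n
    assert set().union(*map(set, parts)) == set(ids)
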