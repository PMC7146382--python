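"""Splitting and patch extraction: stratified image-level splits, stride
rules against a brute-force origin oracle, rotation augmentation, balance."""

import numpy as np
import pytest

from nestseg.patching import (ConfigurationError, DataError, PatchConfig,
                              augment_patch, augment_positives,
                              balance_report, extract_patches, grid_origins,
                              split_corpus)
from nestseg.synthdata import SlideImage, SynthParams, generate_corpus

from conftest import make_slide


def corpus_of(n, n_labeled):
    return ([make_slide(128, 128, labeled=True, image_id=f"lab{i}", seed=i)
             for i in range(n_labeled)]
            + [make_slide(128, 128, labeled=False, image_id=f"unl{i}", seed=i)
               for i in range(n - n_labeled)])


class TestSplitCorpus:
    def test_70_images_split_49_10_11(self):
        images = corpus_of(70, 39)
        split = split_corpus(images, (0.70, 0.143, 0.157), seed=5)
        sizes = {s: len(split.ids(s)) for s in ("train", "validation", "test")}
        assert sizes == {"train": 49, "validation": 10, "test": 11}

    def test_labeled_subset_splits_27_6_6(self):
        images = corpus_of(70, 39)
        split = split_corpus(images, (0.70, 0.143, 0.157), seed=5)
        labeled = {s.image_id for s in images if s.labeled}
        counts = {name: len([i for i in split.ids(name) if i in labeled])
                  for name in ("train", "validation", "test")}
        assert counts == {"train": 27, "validation": 6, "test": 6}

    def test_three_images_one_each(self):
        images = corpus_of(3, 3)
        split = split_corpus(images, (1 / 3, 1 / 3, 1 / 3), seed=0)
        assert sorted(len(split.ids(s)) for s in
                      ("train", "validation", "test")) == [1, 1, 1]

    def test_every_image_assigned_once(self):
        images = corpus_of(23, 11)
        split = split_corpus(images, (0.6, 0.2, 0.2), seed=1)
        assert sorted(split.assignment) == sorted(s.image_id for s in images)

    def test_stratification_within_one_image(self):
        images = corpus_of(40, 16)
        split = split_corpus(images, (0.7, 0.15, 0.15), seed=2)
        labeled = {s.image_id for s in images if s.labeled}
        for name in ("train", "validation", "test"):
            ids = split.ids(name)
            expected = len(ids) * 16 / 40
            got = len([i for i in ids if i in labeled])
            assert abs(got - expected) <= 1

    def test_deterministic_under_seed(self):
        images = corpus_of(12, 6)
        assert (split_corpus(images, (0.5, 0.25, 0.25), 9).assignment
                == split_corpus(images, (0.5, 0.25, 0.25), 9).assignment)

    def test_bad_fractions_raise(self):
        with pytest.raises(ConfigurationError):
            split_corpus(corpus_of(6, 3), (0.5, 0.4, 0.2), seed=0)

    def test_too_few_images_raise(self):
        with pytest.raises(ConfigurationError):
            split_corpus(corpus_of(2, 1), (0.4, 0.3, 0.3), seed=0)


def brute_force_origins(image, config):
    """Independent enumeration of all valid patch origins under the stride
    rules: coarse grid everywhere, plus fine-stride origins inside the 3x3
    grid neighbourhood of every positive coarse window."""
    p = config.patch_size
    rows = grid_origins(image.shape[0], p, config.negative_stride)
    cols = grid_origins(image.shape[1], p, config.negative_stride)
    origins = {(r, c) for r in rows for c in cols}
    if image.mask is None:
        return origins
    hp, wp = rows[-1] + p, cols[-1] + p
    mask = np.pad(image.mask, ((0, hp - image.shape[0]), (0, wp - image.shape[1])),
                  mode="reflect")

    def positive(r, c):
        return mask[r:r + p, c:c + p].sum() >= config.positive_rule

    for gi, r in enumerate(rows):
        for gj, c in enumerate(cols):
            if positive(r, c):
                r_lo, r_hi = rows[max(gi - 1, 0)], rows[min(gi + 1, len(rows) - 1)]
                c_lo, c_hi = cols[max(gj - 1, 0)], cols[min(gj + 1, len(cols) - 1)]
                for rr in range(r_lo, r_hi + 1, config.positive_stride):
                    for cc in range(c_lo, c_hi + 1, config.positive_stride):
                        origins.add((rr, cc))
    return origins


class TestExtractPatches:
    def test_unlabeled_256_grid_of_four(self):
        image = make_slide(256, 256, labeled=False)
        patches = extract_patches(image)
        assert sorted(p.origin for p in patches) == [(0, 0), (0, 128),
                                                     (128, 0), (128, 128)]
        assert all(p.mask is None and not p.positive for p in patches)

    def test_single_patch_for_128(self):
        patches = extract_patches(make_slide(128, 128, labeled=False))
        assert len(patches) == 1 and patches[0].origin == (0, 0)

    def test_overlap_scan_matches_brute_force_enumeration(self):
        image = make_slide(256, 256, mask_boxes=[(108, 148, 108, 148)])
        config = PatchConfig()
        patches = extract_patches(image, config)
        assert {p.origin for p in patches} == brute_force_origins(image, config)

    @pytest.mark.parametrize("h,w", [(200, 200), (300, 260), (512, 512),
                                     (130, 384)])
    def test_brute_force_equivalence_varied_sizes(self, h, w):
        image = make_slide(h, w, mask_boxes=[(h // 3, h // 3 + 30,
                                              w // 2, w // 2 + 25)], seed=h + w)
        config = PatchConfig()
        patches = extract_patches(image, config)
        assert {p.origin for p in patches} == brute_force_origins(image, config)

    def test_patch_geometry_and_uniqueness(self):
        image = make_slide(300, 260, mask_boxes=[(80, 140, 90, 160)])
        patches = extract_patches(image)
        origins = [p.origin for p in patches]
        assert len(origins) == len(set(origins))
        for p in patches:
            assert p.rgb.shape == (128, 128, 3)
            assert p.mask.shape == (128, 128)

    def test_positive_flag_follows_rule(self):
        image = make_slide(256, 256, mask_boxes=[(0, 10, 0, 10)])
        for p in extract_patches(image):
            assert p.positive == (p.mask.sum() >= 1)

    def test_decreasing_positive_stride_never_loses_positives(self):
        image = make_slide(256, 256, mask_boxes=[(100, 160, 100, 160)])
        counts = []
        for stride in (128, 64, 32):
            patches = extract_patches(image, PatchConfig(positive_stride=stride))
            counts.append(sum(p.positive for p in patches))
        assert counts[0] <= counts[1] <= counts[2]

    def test_mask_size_mismatch_raises(self):
        image = make_slide(256, 256, mask_boxes=[(0, 8, 0, 8)])
        image.mask = image.mask[:-2, :]
        with pytest.raises(DataError):
            extract_patches(image)

    def test_invalid_config_raises(self):
        with pytest.raises(ConfigurationError):
            extract_patches(make_slide(128, 128),
                            PatchConfig(positive_stride=256))


class TestAugmentPatch:
    @pytest.fixture
    def positive_patch(self):
        image = make_slide(128, 128, mask_boxes=[(30, 80, 20, 60)])
        (patch,) = extract_patches(image)
        assert patch.positive
        return patch

    def test_default_angles_emit_four_more_examples(self, positive_patch):
        extra = augment_patch(positive_patch)
        assert len(extra) == 4
        assert all(p.augmented for p in extra)

    def test_double_180_restores_pixels(self, positive_patch):
        once = augment_patch(positive_patch, [180])[0]
        twice = augment_patch(once, [180])[0]
        assert np.array_equal(twice.rgb, positive_patch.rgb)
        assert np.array_equal(twice.mask, positive_patch.mask)

    def test_right_angle_preserves_mask_count(self, positive_patch):
        rotated = augment_patch(positive_patch, [90])[0]
        assert rotated.mask.sum() == positive_patch.mask.sum()

    def test_45_degree_output_is_valid_patch(self, positive_patch):
        rotated = augment_patch(positive_patch, [45])[0]
        assert rotated.rgb.shape == (128, 128, 3)
        assert rotated.rgb.min() >= 0 and rotated.rgb.max() <= 1
        assert set(np.unique(rotated.mask)) <= {0, 1}

    def test_negative_patch_strict_raises(self):
        image = make_slide(128, 128, mask_boxes=[])
        (patch,) = extract_patches(image)
        with pytest.raises(DataError):
            augment_patch(patch)


class TestBalance:
    def test_empty(self):
        report = balance_report([])
        assert report.n_positive == report.n_negative == 0

    def test_one_to_one(self):
        image = make_slide(256, 256, mask_boxes=[(0, 140, 0, 140)])
        patches = extract_patches(image, PatchConfig(positive_stride=128))
        report = balance_report(patches)
        assert report.n_positive + report.n_negative == len(patches)

    def test_augmentation_moves_ratio_toward_one(self, small_params):
        corpus = generate_corpus(6, 1.0, small_params, seed=21, size_steps=1)
        patches = [p for s in corpus for p in extract_patches(s)]
        before = balance_report(patches)
        after = balance_report(augment_positives(patches))
        if 0 < before.ratio < 1:  # positives are the minority going in
            assert abs(np.log(after.ratio)) <= abs(np.log(before.ratio))


def test_split_before_patch_no_leakage(small_params):
    corpus = generate_corpus(10, 0.6, small_params, seed=31, size_steps=1)
    split = split_corpus(corpus, (0.6, 0.2, 0.2), seed=31)
    train_ids = set(split.ids("train"))
    train_patches = [p for s in corpus if s.image_id in train_ids
                     for p in extract_patches(s)]
    held_out = set(split.ids("validation")) | set(split.ids("test"))
    assert all(p.source_id not in held_out for p in train_patches)
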