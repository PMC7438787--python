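"""Patch extraction geometry, background rejection sampling, and the
split/fold partition arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from he2ihc.dataset import (
    Box,
    build_patch_dataset,
    cell_boxes,
    extract_cell_patches,
    kfold_partition,
    sample_background_boxes,
    split_dataset,
)
from he2ihc.synthetic import CellAnnotation, SyntheticConfig, generate_paired_roi, write_roi_bundle


class TestExtractCellPatches:
    def test_window_centering_arithmetic(self):
        img = np.arange(966 * 1889 * 3, dtype=np.float32).reshape(966, 1889, 3) % 255
        patches, skipped = extract_cell_patches(img, [CellAnnotation(100, 100, 0)], 64)
        assert skipped == 0
        assert np.array_equal(patches[0].pixels, img[68:132, 68:132])
        assert patches[0].label == 0 and patches[0].center == (100, 100)

    def test_border_annotation_is_skipped_not_padded(self):
        img = np.zeros((966, 1889, 3), np.float32)
        patches, skipped = extract_cell_patches(img, [CellAnnotation(10, 10, 1)], 64)
        assert patches == [] and skipped == 1

    def test_patch_larger_than_image_warns_and_skips_all(self):
        img = np.zeros((32, 32, 3), np.float32)
        with pytest.warns(UserWarning):
            patches, skipped = extract_cell_patches(img, [CellAnnotation(16, 16, 0)], 64)
        assert patches == [] and skipped == 1

    def test_odd_patch_size_rejected(self):
        with pytest.raises(ValueError):
            extract_cell_patches(np.zeros((128, 128, 3)), [], 63)

    def test_patch_centers_agree_with_ground_truth_mask(self):
        """Each extracted cell patch's central pixel lies on a nucleus of the
        matching class in the generator's mask."""
        cfg = SyntheticConfig(roi_height=1792, roi_width=1792, n_cells=200, seed=13)
        he, _, truth = generate_paired_roi(cfg)
        patches, skipped = extract_cell_patches(he, truth.annotations, 64)
        # a few small nuclei may sit closer than 32 px to the border
        assert len(patches) == 200 - skipped and skipped <= 10
        for p in patches:
            assert truth.nucleus_mask[p.center] == p.label + 1


class TestBackgroundSampling:
    def test_no_cell_boxes_accepts_first_candidates(self):
        boxes = sample_background_boxes((512, 512), [], 25, seed=3)
        assert len(boxes) == 25

    def test_full_occlusion_returns_nothing(self):
        wall = [Box(0, 0, 512, 512)]
        with pytest.warns(UserWarning, match="background boxes"):
            boxes = sample_background_boxes((512, 512), wall, 5, seed=3)
        assert boxes == []

    def test_accepted_boxes_never_overlap_cells_brute_force(self, roi_pair):
        he, _, truth = roi_pair
        cells = cell_boxes(truth.annotations, 64)
        boxes = sample_background_boxes(he.shape[:2], cells, 50, seed=5)
        assert len(boxes) == 50
        for b in boxes:
            assert 0 <= b.top and b.top + b.height <= he.shape[0]
            assert 0 <= b.left and b.left + b.width <= he.shape[1]
            for c in cells:
                # brute-force rectangle intersection
                dh = min(b.top + b.height, c.top + c.height) - max(b.top, c.top)
                dw = min(b.left + b.width, c.left + c.width) - max(b.left, c.left)
                assert max(dh, 0) * max(dw, 0) == 0

    def test_deterministic_under_seed(self):
        cells = [Box(100, 100, 64, 64)]
        assert sample_background_boxes((512, 512), cells, 10, seed=9) == sample_background_boxes(
            (512, 512), cells, 10, seed=9
        )


class TestSplitAndFolds:
    def test_full_cohort_split_arithmetic(self):
        """5,900 + 6,086 + 6,776 = 18,762 patches split 8:2 gives a
        15,009-image training set and 3,753-image validation set."""
        plan = split_dataset(5900 + 6086 + 6776, 0.8, seed=0)
        assert len(plan.train_ids) == 15009
        assert len(plan.val_ids) == 3753

    def test_small_split(self):
        plan = split_dataset(10, 0.8, seed=1)
        assert len(plan.train_ids) == 8 and len(plan.val_ids) == 2
        assert sorted(np.concatenate([plan.train_ids, plan.val_ids])) == list(range(10))

    def test_split_determinism_and_seed_sensitivity(self):
        a = split_dataset(1000, 0.8, seed=4)
        b = split_dataset(1000, 0.8, seed=4)
        c = split_dataset(1000, 0.8, seed=5)
        assert np.array_equal(a.train_ids, b.train_ids)
        assert not np.array_equal(a.train_ids, c.train_ids)

    def test_tenfold_of_training_set_sizes(self):
        """15,009 items in 10 folds: nine of 1,501 and one of 1,500."""
        folds = kfold_partition(15009, 10, seed=0)
        assert [len(f) for f in folds] == [1501] * 9 + [1500]

    def test_ten_items_ten_singletons(self):
        folds = kfold_partition(10, 10, seed=2)
        assert [len(f) for f in folds] == [1] * 10

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(5, 6)

    @settings(deadline=None)
    @given(st.integers(1, 50).flatmap(lambda n: st.tuples(st.just(n), st.integers(1, n))))
    def test_folds_are_balanced_exact_covers(self, nk):
        n, k = nk
        folds = kfold_partition(n, k, seed=0)
        sizes = [len(f) for f in folds]
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        assert sizes == sorted(sizes, reverse=True)
        assert sorted(np.concatenate(folds)) == list(range(n))


def test_build_patch_dataset_imagefolder_and_manifest(tmp_path):
    cfg = SyntheticConfig(n_cells=10, seed=31)
    for i in range(2):
        he, ihc, truth = generate_paired_roi(
            SyntheticConfig(n_cells=10, seed=31 + i)
        )
        write_roi_bundle(tmp_path / "rois" / f"roi_{i}", he, ihc, truth)
    out = tmp_path / "dataset"
    pset = build_patch_dataset(tmp_path / "rois", out, n_background_per_roi=5, seed=0)
    assert len(pset) == 2 * (10 + 5)
    manifest = (out / "manifest.csv").read_text().strip().splitlines()
    assert len(manifest) == 1 + len(pset)
    n_pngs = sum(1 for _ in out.rglob("*.png"))
    assert n_pngs == len(pset)
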