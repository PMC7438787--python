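"""Shared fixtures: synthetic ROI pairs and a small trained classifier.

Everything is generated programmatically and seeded; the trained model is
session-scoped because training the network, even at reduced scale, is the
expensive step several test modules want to share.
"""

from __future__ import annotations

import numpy as np
import pytest

from he2ihc.dataset import (
    PatchSet,
    Patch,
    build_patch_dataset,
    cell_boxes,
    extract_cell_patches,
    sample_background_boxes,
    split_dataset,
)
from he2ihc.synthetic import LABEL_BACKGROUND, SyntheticConfig, generate_paired_roi
from he2ihc.training import TrainingConfig, train_classifier


def make_patchset(
    n_rois: int,
    seed: int,
    class_signal: float = 3.0,
    n_cells: int = 24,
    n_background: int = 12,
) -> PatchSet:
    """Pooled three-class patch set from freshly generated ROI pairs."""
    patches: list[Patch] = []
    for i in range(n_rois):
        cfg = SyntheticConfig(n_cells=n_cells, class_signal=class_signal, seed=seed + i)
        he, _, truth = generate_paired_roi(cfg)
        cell, _ = extract_cell_patches(he, truth.annotations, roi_id=f"roi{i}")
        patches.extend(cell)
        for b in sample_background_boxes(
            he.shape[:2], cell_boxes(truth.annotations), n_background, seed=seed + i
        ):
            patches.append(
                Patch(
                    he[b.top : b.top + b.height, b.left : b.left + b.width].astype(np.float32),
                    LABEL_BACKGROUND,
                    (b.top + 32, b.left + 32),
                    f"roi{i}",
                )
            )
    return PatchSet.from_patches(patches)


@pytest.fixture(scope="session")
def roi_pair():
    """One default strong-signal ROI pair with its ground truth."""
    he, ihc, truth = generate_paired_roi(SyntheticConfig(class_signal=3.0, seed=42))
    return he, ihc, truth


@pytest.fixture(scope="session")
def trained_model():
    """Classifier trained on ~600 strong-signal patches for 5 epochs.

    Returns (net, history, train_set, val_set).  Several modules reuse it:
    training recovery, augmentation invariance, dense/patch agreement.
    """
    pset = make_patchset(n_rois=17, seed=300)
    plan = split_dataset(len(pset), 0.8, seed=7)
    train_set, val_set = pset.subset(plan.train_ids), pset.subset(plan.val_ids)
    config = TrainingConfig(epochs=5, lr_schedule=((4, 1e-3), (5, 1e-4)), seed=7)
    net, history = train_classifier(train_set, val_set, config)
    return net, history, train_set, val_set
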