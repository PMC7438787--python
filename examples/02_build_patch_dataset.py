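"""Build the three-class 64x64 patch dataset from annotated ROIs.

Cell patches are cut around each annotated center; background patches come
from rejection sampling of 64x64 boxes that do not overlap any cell box.
The pooled set is split 8:2 into training and validation.
"""

import numpy as np

from he2ihc import SyntheticConfig, generate_paired_roi, write_roi_bundle
from he2ihc.dataset import build_patch_dataset, split_dataset

for i in range(4):
    he, ihc, truth = generate_paired_roi(SyntheticConfig(seed=20 + i))
    write_roi_bundle(f"scratch/example_rois/roi_{i:03d}", he, ihc, truth)

pset = build_patch_dataset("scratch/example_rois", n_background_per_roi=12, seed=0)
labels, counts = np.unique(pset.labels, return_counts=True)
names = {0: "negative", 1: "positive", 2: "background"}
print(f"{len(pset)} patches:", {names[l]: int(c) for l, c in zip(labels, counts)})

plan = split_dataset(len(pset), ratio=0.8, seed=0)
print(f"8:2 split -> {len(plan.train_ids)} train / {len(plan.val_ids)} validation")
print("train size is floor(0.8 * N); the two index lists cover every patch once")
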