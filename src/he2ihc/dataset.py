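"""Three-class patch dataset construction.

From an annotated ROI we cut 64x64 patches centered on each labeled cell
(no resizing, no padding: a cell whose window would cross the image border
is skipped and tallied).  Background patches are drawn by rejection
sampling: candidate 64x64 boxes are kept only if they have zero-area
intersection with every cell box, where a cell box is the same 64x64 window
centered on the annotation point.  The pooled patches are split 8:2 into
training and validation (train size = floor(0.8 * N)), and the training set
can further be cut into k near-equal folds for cross-validation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .synthetic import CLASS_NAMES, LABEL_BACKGROUND, CellAnnotation

__all__ = [
    "Box",
    "Patch",
    "SplitPlan",
    "extract_cell_patches",
    "cell_boxes",
    "sample_background_boxes",
    "split_dataset",
    "kfold_partition",
    "read_labelme_points",
    "load_roi_bundle",
    "build_patch_dataset",
    "PatchSet",
]

PATCH_SIZE = 64


@dataclass(frozen=True)
class Box:
    """Half-open pixel rectangle [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("Box height and width must be positive")

    def intersection_area(self, other: "Box") -> int:
        dh = min(self.top + self.height, other.top + other.height) - max(self.top, other.top)
        dw = min(self.left + self.width, other.left + other.width) - max(self.left, other.left)
        return max(dh, 0) * max(dw, 0)

    def overlaps(self, other: "Box") -> bool:
        return self.intersection_area(other) > 0


@dataclass
class Patch:
    pixels: np.ndarray  # (patch, patch, 3) float32 in [0, 1]
    label: int  # 0 negative, 1 positive, 2 background
    center: tuple[int, int]  # (row, col) in the source ROI
    roi_id: str


@dataclass
class PatchSet:
    """Array-backed patch collection: images (N, p, p, 3) and labels (N,)."""

    images: np.ndarray
    labels: np.ndarray
    roi_ids: list[str] | None = None
    centers: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(
            self.images[idx],
            self.labels[idx],
            [self.roi_ids[i] for i in idx] if self.roi_ids is not None else None,
            self.centers[idx] if self.centers is not None else None,
        )

    @classmethod
    def from_patches(cls, patches: list[Patch]) -> "PatchSet":
        if not patches:
            return cls(np.zeros((0, PATCH_SIZE, PATCH_SIZE, 3), np.float32), np.zeros(0, np.int64))
        return cls(
            np.stack([p.pixels for p in patches]).astype(np.float32),
            np.array([p.label for p in patches], dtype=np.int64),
            [p.roi_id for p in patches],
            np.array([p.center for p in patches], dtype=np.int64),
        )


@dataclass(frozen=True)
class SplitPlan:
    train_ids: np.ndarray
    val_ids: np.ndarray
    seed: int


def extract_cell_patches(
    image: np.ndarray,
    annotations: list[CellAnnotation],
    patch_size: int = PATCH_SIZE,
    roi_id: str = "",
) -> tuple[list[Patch], int]:
    """Cut a `patch_size` window around each annotated cell center.

    The window top-left is (row - patch_size//2, col - patch_size//2).
    Annotations whose window crosses the image border are skipped; the
    second return value is the skip tally.
    """
    if patch_size <= 0 or patch_size % 2:
        raise ValueError("patch_size must be even and positive")
    h, w = image.shape[:2]
    half = patch_size // 2
    patches: list[Patch] = []
    skipped = 0
    if patch_size > min(h, w):
        warnings.warn(f"patch_size {patch_size} exceeds image {h}x{w}; all annotations skipped")
        return [], len(annotations)
    for ann in annotations:
        top, left = ann.row - half, ann.col - half
        if top < 0 or left < 0 or top + patch_size > h or left + patch_size > w:
            skipped += 1
            continue
        pixels = np.asarray(
            image[top : top + patch_size, left : left + patch_size], dtype=np.float32
        )
        patches.append(Patch(pixels, ann.label, (ann.row, ann.col), roi_id))
    return patches, skipped


def cell_boxes(annotations: list[CellAnnotation], patch_size: int = PATCH_SIZE) -> list[Box]:
    """The patch windows of the annotated cells, used for background rejection."""
    half = patch_size // 2
    return [Box(a.row - half, a.col - half, patch_size, patch_size) for a in annotations]


def sample_background_boxes(
    image_shape: tuple[int, int],
    cell_boxes_: list[Box],
    n: int,
    patch_size: int = PATCH_SIZE,
    seed: int = 0,
    attempts_per_box: int = 200,
) -> list[Box]:
    """Rejection-sample up to `n` background boxes of side `patch_size`.

    Candidates are uniform over all in-bounds positions; any candidate with a
    positive-area intersection with a cell box is rejected.  If the budget of
    ``attempts_per_box * n`` candidates runs out first, fewer boxes are
    returned with a warning.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    h, w = image_shape[:2]
    if patch_size > h or patch_size > w:
        warnings.warn("patch_size exceeds image; no background boxes")
        return []
    rng = np.random.default_rng(seed)
    out: list[Box] = []
    budget = attempts_per_box * max(n, 1)
    while len(out) < n and budget > 0:
        budget -= 1
        box = Box(
            int(rng.integers(0, h - patch_size + 1)),
            int(rng.integers(0, w - patch_size + 1)),
            patch_size,
            patch_size,
        )
        if any(box.overlaps(cb) for cb in cell_boxes_):
            continue
        out.append(box)
    if len(out) < n:
        warnings.warn(f"only {len(out)} of {n} background boxes accepted within attempt budget")
    return out


def split_dataset(n_items: int, ratio: float = 0.8, seed: int = 0) -> SplitPlan:
    """Uniform random split; train size = floor(ratio * n_items)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n_items)
    n_train = int(np.floor(ratio * n_items))
    return SplitPlan(perm[:n_train], perm[n_train:], seed)


def kfold_partition(n_items: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random partition into k folds with sizes differing by at most one,
    larger folds first."""
    if not 1 <= k <= n_items:
        raise ValueError(f"need 1 <= k <= n_items, got k={k}, n_items={n_items}")
    perm = np.random.default_rng(seed).permutation(n_items)
    base, rem = divmod(n_items, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        folds.append(perm[start : start + size])
        start += size
    return folds


def read_labelme_points(path: str | Path) -> tuple[list[CellAnnotation], tuple[int, int]]:
    """Read a Labelme-dialect point-annotation JSON.

    Labelme stores points as [x, y] = [column, row]; this reader converts to
    the package's (row, col) convention.  Returns (annotations, (H, W)).
    """
    doc = json.loads(Path(path).read_text())
    anns = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type") != "point":
            continue
        x, y = shape["points"][0]
        label = CLASS_NAMES.index(shape["label"])
        anns.append(CellAnnotation(int(round(y)), int(round(x)), label))
    return anns, (int(doc["imageHeight"]), int(doc["imageWidth"]))


def load_roi_bundle(prefix: str | Path):
    """Load `<prefix>_he.png`, `<prefix>_ihc.png`, `<prefix>.json` (and the
    ground-truth mask PNG if present).  Images come back float32 in [0, 1]."""
    prefix = Path(prefix)
    he = iio.imread(prefix.parent / f"{prefix.name}_he.png").astype(np.float32) / 255.0
    ihc_path = prefix.parent / f"{prefix.name}_ihc.png"
    ihc = iio.imread(ihc_path).astype(np.float32) / 255.0 if ihc_path.exists() else None
    anns, shape = read_labelme_points(prefix.parent / f"{prefix.name}.json")
    mask_path = prefix.parent / f"{prefix.name}_mask.png"
    mask = iio.imread(mask_path) if mask_path.exists() else None
    return he, ihc, anns, mask


def roi_prefixes(roi_dir: str | Path) -> list[Path]:
    """All bundle prefixes in a directory (one per `*_he.png`)."""
    return sorted(
        p.parent / p.name.removesuffix("_he.png")
        for p in Path(roi_dir).glob("*_he.png")
    )


def build_patch_dataset(
    roi_dir: str | Path,
    out_dir: str | Path | None = None,
    patch_size: int = PATCH_SIZE,
    n_background_per_roi: int = 16,
    seed: int = 0,
) -> PatchSet:
    """Build the pooled three-class patch set from every ROI bundle in a
    directory; optionally write it out as a class-named image-folder plus a
    manifest CSV (roi_id, row, col, label)."""
    patches: list[Patch] = []
    for i, prefix in enumerate(roi_prefixes(roi_dir)):
        he, _, anns, _ = load_roi_bundle(prefix)
        cp, _ = extract_cell_patches(he, anns, patch_size, roi_id=prefix.name)
        patches.extend(cp)
        boxes = sample_background_boxes(
            he.shape[:2], cell_boxes(anns, patch_size), n_background_per_roi, patch_size,
            seed=seed + i,
        )
        half = patch_size // 2
        for b in boxes:
            pixels = he[b.top : b.top + b.height, b.left : b.left + b.width]
            patches.append(
                Patch(
                    np.asarray(pixels, np.float32),
                    LABEL_BACKGROUND,
                    (b.top + half, b.left + half),
                    prefix.name,
                )
            )
    pset = PatchSet.from_patches(patches)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for name in CLASS_NAMES:
            (out_dir / name).mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "roi_id", "row", "col", "label"])
            for j, p in enumerate(patches):
                fname = f"{j:06d}.png"
                iio.imwrite(
                    out_dir / CLASS_NAMES[p.label] / fname,
                    (p.pixels * 255).round().astype(np.uint8),
                )
                writer.writerow([j, p.roi_id, p.center[0], p.center[1], p.label])
    return pset
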