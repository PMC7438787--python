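"""Synthetic paired-stain ROI generator.

Real training data for this problem is a pair of consecutive tissue
sections, one H&E-stained and one Ki-67 IHC-stained, with cell centers
annotated by hand.  This module fabricates such pairs with fully known
ground truth: elliptical nuclei are placed without overlap by rejection
sampling, and each cell's class (Ki-67 negative / positive) is rendered

* in the pseudo-IHC image as an unambiguous color code — DAB-brown nuclei
  for positive cells, hematoxylin-blue for negative, eosin-pink background —
  which is what the IHC color filter keys on, and
* in the pseudo-H&E image as a subtler morphological signal: both classes
  are hematoxylin-purple, but positive nuclei are darker and slightly
  larger in expectation, with the strength set by ``class_signal``
  (``class_signal=0`` makes the classes statistically identical in H&E).

The generator makes no attempt at stain physics, section-to-section
registration error, or tissue texture; it exists to give the pipeline a
measurable, known answer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "CellAnnotation",
    "GroundTruth",
    "PlacementError",
    "SyntheticConfig",
    "generate_paired_roi",
    "write_roi_bundle",
    "PALETTE",
    "LABEL_NEGATIVE",
    "LABEL_POSITIVE",
    "LABEL_BACKGROUND",
    "CLASS_NAMES",
]

LABEL_NEGATIVE = 0
LABEL_POSITIVE = 1
LABEL_BACKGROUND = 2
CLASS_NAMES = ("negative", "positive", "background")

#: RGB anchors in [0, 1].  The IHC filter's default thresholds are tuned to
#: these, so the filter can be validated against the generator's ground truth.
PALETTE = {
    "dab_brown": np.array([0.55, 0.33, 0.13], dtype=np.float32),
    "hematoxylin_blue": np.array([0.22, 0.28, 0.65], dtype=np.float32),
    "ihc_background": np.array([0.93, 0.82, 0.87], dtype=np.float32),
    "he_nucleus": np.array([0.42, 0.28, 0.58], dtype=np.float32),
    "he_background": np.array([0.91, 0.75, 0.83], dtype=np.float32),
}

# per unit of class_signal: how much darker and how much larger a Ki-67
# positive nucleus is rendered in pseudo-H&E
_INTENSITY_OFFSET_PER_SIGNAL = 0.05
_RADIUS_GAIN_PER_SIGNAL = 0.02
_COLOR_JITTER_SD = 0.015

#: rejection-sampling attempt cap per nucleus
MAX_PLACEMENT_ATTEMPTS = 100


class PlacementError(RuntimeError):
    """Raised when a nucleus cannot be placed without overlap."""


@dataclass(frozen=True)
class CellAnnotation:
    """A cell center at (row, col) with class label 0=negative / 1=positive."""

    row: int
    col: int
    label: int

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.label]


@dataclass
class GroundTruth:
    """Everything the generator knows: point annotations plus the per-pixel
    nucleus mask (0 background, 1 negative nucleus, 2 positive nucleus)."""

    annotations: list[CellAnnotation]
    nucleus_mask: np.ndarray

    def r_pos(self) -> float:
        """Area-based positive rate of the mask (nan if no nucleus pixels)."""
        pos = int((self.nucleus_mask == 2).sum())
        neg = int((self.nucleus_mask == 1).sum())
        if pos + neg == 0:
            return float("nan")
        return pos / (pos + neg)


@dataclass(frozen=True)
class SyntheticConfig:
    roi_height: int = 512
    roi_width: int = 512
    n_cells: int = 24
    positive_fraction: float = 0.5
    nucleus_radius_range: tuple[float, float] = (20.0, 35.0)
    class_signal: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.nucleus_radius_range
        if lo > hi or lo <= 0:
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        if self.class_signal < 0 or self.noise_sd < 0:
            raise ValueError("class_signal and noise_sd must be >= 0")


def _jitter(color: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.clip(color + rng.normal(0.0, _COLOR_JITTER_SD, 3).astype(np.float32), 0.0, 1.0)


def generate_paired_roi(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate one (pseudo-H&E, pseudo-IHC, ground truth) triple.

    Returns two float32 HxWx3 images in [0, 1] and the ground truth.  Output
    is bit-identical for identical configs (the seed is part of the config).

    Raises
    ------
    PlacementError
        if a nucleus cannot be placed without overlap within
        ``MAX_PLACEMENT_ATTEMPTS`` attempts (the ROI is too crowded).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.roi_height, config.roi_width
    mask = np.zeros((h, w), dtype=np.uint8)
    he = np.empty((h, w, 3), dtype=np.float32)
    ihc = np.empty((h, w, 3), dtype=np.float32)
    he[:] = PALETTE["he_background"]
    ihc[:] = PALETTE["ihc_background"]

    labels = (rng.random(config.n_cells) < config.positive_fraction).astype(np.int64)
    r_lo, r_hi = config.nucleus_radius_range
    radius_scale = 1.0 + _RADIUS_GAIN_PER_SIGNAL * config.class_signal
    darken = _INTENSITY_OFFSET_PER_SIGNAL * config.class_signal

    annotations: list[CellAnnotation] = []
    occupied = np.zeros((h, w), dtype=bool)
    for label in labels:
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            if label == LABEL_POSITIVE:
                a *= radius_scale
                b *= radius_scale
            theta = rng.uniform(0.0, np.pi)
            margin = int(np.ceil(max(a, b))) + 1
            if 2 * margin >= min(h, w):
                continue
            cr = int(rng.integers(margin, h - margin))
            cc = int(rng.integers(margin, w - margin))
            rr, cc_px = draw_ellipse(cr, cc, a, b, shape=(h, w), rotation=theta)
            if occupied[rr, cc_px].any():
                continue
            occupied[rr, cc_px] = True
            mask[rr, cc_px] = 2 if label == LABEL_POSITIVE else 1
            he_color = _jitter(PALETTE["he_nucleus"], rng)
            if label == LABEL_POSITIVE:
                he_color = np.clip(he_color - darken, 0.0, 1.0)
                ihc_color = _jitter(PALETTE["dab_brown"], rng)
            else:
                ihc_color = _jitter(PALETTE["hematoxylin_blue"], rng)
            he[rr, cc_px] = he_color
            ihc[rr, cc_px] = ihc_color
            annotations.append(CellAnnotation(cr, cc, int(label)))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus without overlap after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts (ROI too crowded: "
                f"{len(annotations)} of {config.n_cells} cells placed in {h}x{w})"
            )

    if config.noise_sd > 0:
        he = he + rng.normal(0.0, config.noise_sd, he.shape).astype(np.float32)
        ihc = ihc + rng.normal(0.0, config.noise_sd, ihc.shape).astype(np.float32)
    he = np.clip(he, 0.0, 1.0)
    ihc = np.clip(ihc, 0.0, 1.0)
    return he, ihc, GroundTruth(annotations, mask)


def write_roi_bundle(
    path: str | Path,
    he_image: np.ndarray,
    ihc_image: np.ndarray,
    truth: GroundTruth,
    write_mask: bool = True,
) -> dict[str, Path]:
    """Write one ROI bundle: `<stem>_he.png`, `<stem>_ihc.png`, `<stem>.json`.

    The JSON is a Labelme-dialect point-annotation file: each shape has a
    class ``label``, a single ``points`` entry ``[[x, y]]`` — note Labelme
    order is (x=column, y=row) — and ``shape_type: "point"``.  With
    ``write_mask`` the ground-truth nucleus mask is also stored as a
    single-channel PNG with values {0, 1, 2}.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    files = {
        "he": path.parent / f"{path.name}_he.png",
        "ihc": path.parent / f"{path.name}_ihc.png",
        "annotations": path.parent / f"{path.name}.json",
    }
    iio.imwrite(files["he"], (np.clip(he_image, 0, 1) * 255).round().astype(np.uint8))
    iio.imwrite(files["ihc"], (np.clip(ihc_image, 0, 1) * 255).round().astype(np.uint8))
    h, w = he_image.shape[:2]
    doc = {
        "shapes": [
            {
                "label": ann.class_name,
                "points": [[float(ann.col), float(ann.row)]],
                "shape_type": "point",
            }
            for ann in truth.annotations
        ],
        "imagePath": files["he"].name,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    files["annotations"].write_text(json.dumps(doc, indent=1))
    if write_mask:
        files["mask"] = path.parent / f"{path.name}_mask.png"
        iio.imwrite(files["mask"], truth.nucleus_mask)
    return files
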