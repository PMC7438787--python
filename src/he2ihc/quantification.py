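"""Ki-67 quantification by area.

An IHC image is reduced to a three-value label map by color channel
filtering: pixels are classified in HSV space — DAB-brown (positive) and
hematoxylin-blue (negative) occupy disjoint hue bands at sufficient
saturation, everything else is background — and connected components
smaller than a minimum object size are suppressed as noise.  From any
full-resolution label map the area indices follow:

    D_pos = S_pos / S_ROI      (fraction of ROI area covered by positive cells)
    D_neg = S_neg / S_ROI
    R_pos = S_pos / (S_pos + S_neg)   (area-based positive rate)

where S_pos and S_neg are the pixel counts of the two cell classes and
S_ROI the full ROI pixel count.  R_pos is undefined (NaN, flagged) when a
map contains no cell pixels at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_objects

from .inference import LabelMap

__all__ = ["ColorFilterConfig", "QuantResult", "ihc_color_filter", "quantify", "paired_quantification"]


@dataclass(frozen=True)
class ColorFilterConfig:
    """HSV box thresholds for the two chromogens.

    Defaults are tuned to the synthetic palette: DAB-brown sits near hue
    0.08 and hematoxylin-blue near hue 0.64, both far more saturated than
    the eosin-pink background (saturation ~0.12 at hue ~0.92).
    """

    positive_hue: tuple[float, float] = (0.0, 0.25)
    negative_hue: tuple[float, float] = (0.5, 0.8)
    min_saturation: float = 0.3
    max_value: float = 0.95  # nuclei are darker than the near-white background
    min_object_size: int = 20  # pixels; smaller components -> background

    def __post_init__(self) -> None:
        for name in ("positive_hue", "negative_hue"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range is degenerate")
        p, n = self.positive_hue, self.negative_hue
        if max(p[0], n[0]) < min(p[1], n[1]):
            raise ValueError("positive and negative hue ranges must be disjoint")


@dataclass(frozen=True)
class QuantResult:
    s_pos: int
    s_neg: int
    s_roi: int
    d_pos: float
    d_neg: float
    r_pos: float  # NaN when undefined
    r_pos_defined: bool


def ihc_color_filter(ihc: np.ndarray, config: ColorFilterConfig | None = None) -> LabelMap:
    """Classify every pixel of an RGB IHC image into {negative, positive,
    background} by HSV box thresholds, then suppress small components."""
    config = config or ColorFilterConfig()
    img = np.asarray(ihc, dtype=np.float32)
    if img.max() > 1.0:
        img = img / 255.0
    hsv = rgb2hsv(img)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    stained = (sat >= config.min_saturation) & (val <= config.max_value)
    pos = stained & (hue >= config.positive_hue[0]) & (hue < config.positive_hue[1])
    neg = stained & (hue >= config.negative_hue[0]) & (hue < config.negative_hue[1])
    if config.min_object_size > 1:
        # objects with fewer than min_object_size pixels become background
        pos = remove_small_objects(pos, max_size=config.min_object_size - 1)
        neg = remove_small_objects(neg, max_size=config.min_object_size - 1)
    labels = np.full(img.shape[:2], 2, dtype=np.uint8)
    labels[neg] = 0
    labels[pos] = 1
    return LabelMap(labels, resolution="full")


def quantify(label_map: LabelMap) -> QuantResult:
    """Area indices of one full-resolution label map."""
    if label_map.resolution != "full":
        raise ValueError("quantify expects a full-resolution label map")
    labels = label_map.labels
    s_pos = int((labels == 1).sum())
    s_neg = int((labels == 0).sum())
    s_roi = int(labels.size)
    cells = s_pos + s_neg
    return QuantResult(
        s_pos=s_pos,
        s_neg=s_neg,
        s_roi=s_roi,
        d_pos=s_pos / s_roi,
        d_neg=s_neg / s_roi,
        r_pos=s_pos / cells if cells else float("nan"),
        r_pos_defined=cells > 0,
    )


def paired_quantification(
    he_maps: list[LabelMap],
    ihc_maps: list[LabelMap],
    roi_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Quantify index-aligned H&E-derived and IHC-derived map lists.

    Returns one row per ROI per source with columns roi_id, source
    ("he"/"ihc"), S_pos, S_neg, S_ROI, D_pos, D_neg, R_pos.
    """
    if len(he_maps) != len(ihc_maps):
        raise ValueError(f"length mismatch: {len(he_maps)} H&E vs {len(ihc_maps)} IHC maps")
    roi_ids = roi_ids or [f"roi_{i:03d}" for i in range(len(he_maps))]
    rows = []
    for roi_id, he_map, ihc_map in zip(roi_ids, he_maps, ihc_maps):
        for source, m in (("he", he_map), ("ihc", ihc_map)):
            q = quantify(m)
            rows.append(
                {
                    "roi_id": roi_id,
                    "source": source,
                    "S_pos": q.s_pos,
                    "S_neg": q.s_neg,
                    "S_ROI": q.s_roi,
                    "D_pos": q.d_pos,
                    "D_neg": q.d_neg,
                    "R_pos": q.r_pos,
                }
            )
    return pd.DataFrame(rows)
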