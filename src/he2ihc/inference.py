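"""ROI-scale dense inference and class-map rendering.

``dense_predict`` runs the fully convolutional network over a whole ROI and
returns a 3-channel score map at output stride 32: score position (i, j) is
the classifier's verdict for the 64x64 receptive window anchored at pixel
(32 i, 32 j), i.e. the window centered at (32 i + 31.5, 32 j + 31.5),
capped at the borders.  Argmax over the three scores gives a grid label
map; nearest-neighbour upsampling paints each grid cell over its 32x32
footprint (the trailing margin takes the nearest cell) so that areas are
measured in ROI pixels, commensurable with the IHC color filter.

If an ROI exceeds the pixel budget it is processed in overlapping tiles.
Tiles are aligned to the output stride and carry enough context margin that
every retained score's full receptive field is either inside the tile crop
or outside the image, so the tiled pass is bit-identical to an untiled one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DenseResNet18, receptive_interval, score_map_size
from .training import TrainingConfig, normalize_images

__all__ = [
    "ScoreMap",
    "LabelMap",
    "dense_predict",
    "score_to_label_map",
    "upsample_label_map",
    "render_three_value_colormap",
    "colormap_to_labels",
    "CLASS_COLORS",
]

#: render convention: positive -> red, negative -> green, background -> white
CLASS_COLORS = {
    0: (0, 255, 0),  # negative cell
    1: (255, 0, 0),  # positive cell
    2: (255, 255, 255),  # background
}


@dataclass
class ScoreMap:
    scores: np.ndarray  # (3, h', w') float32
    stride: int = 32
    origin_offset: float = 31.5  # pixel center of the first receptive window

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score map contains non-finite values")


@dataclass
class LabelMap:
    labels: np.ndarray  # integer array over {0, 1, 2}
    resolution: str = "full"  # "grid" (stride-32) or "full" (ROI pixels)

    def __post_init__(self) -> None:
        bad = ~np.isin(self.labels, (0, 1, 2))
        if bad.any():
            raise ValueError("label map contains values outside {0, 1, 2}")


def dense_predict(
    dense_net: DenseResNet18,
    roi: np.ndarray,
    config: TrainingConfig | None = None,
    max_pixels: int = 4_000_000,
) -> ScoreMap:
    """Score a whole ROI ((H, W, 3) in [0, 1], H and W >= 64) densely.

    Applies the training normalisation, then a single forward pass — or an
    overlapping-tile pass, merged exactly, if H*W exceeds ``max_pixels``.
    """
    config = config or TrainingConfig()
    h, w = roi.shape[:2]
    spec = dense_net.spec
    if h < spec.patch_size or w < spec.patch_size:
        raise ValueError(f"ROI {h}x{w} smaller than minimum {spec.patch_size}")
    x = normalize_images(roi[None], config)
    hp, wp = score_map_size(spec, h), score_map_size(spec, w)
    if h * w <= max_pixels:
        scores = dense_net.forward(x, train=False)[0]
    else:
        scores = _tiled_forward(dense_net, x, (hp, wp), max_pixels)
    assert scores.shape[1:] == (hp, wp)
    return ScoreMap(scores.astype(np.float32))


def _axis_blocks(n_out: int, block: int) -> list[tuple[int, int]]:
    return [(s, min(s + block, n_out)) for s in range(0, n_out, block)]


def _tiled_forward(
    dense_net: DenseResNet18, x: np.ndarray, out_shape: tuple[int, int], max_pixels: int
) -> np.ndarray:
    spec = dense_net.spec
    stride, lo, hi = receptive_interval(spec)
    margin = -(-(-lo) // stride)  # ceil(-lo / stride): context rows of output, stride units
    h, w = x.shape[2:]
    hp, wp = out_shape
    scores = np.empty((spec.n_classes, hp, wp), dtype=np.float32)
    # choose an output block size whose input crop respects the budget
    ctx = max(-lo, hi + 1)
    block = max(1, int((np.sqrt(max_pixels) - 2 * ctx) // stride))
    for r0, r1 in _axis_blocks(hp, block):
        c_top = max(0, stride * (r0 - margin))
        c_bot = min(h, stride * (r1 - 1) + hi + 1)
        for q0, q1 in _axis_blocks(wp, block):
            c_left = max(0, stride * (q0 - margin))
            c_right = min(w, stride * (q1 - 1) + hi + 1)
            crop = x[:, :, c_top:c_bot, c_left:c_right]
            tile = dense_net.forward(crop, train=False)[0]
            i0 = r0 - c_top // stride
            j0 = q0 - c_left // stride
            scores[:, r0:r1, q0:q1] = tile[:, i0 : i0 + (r1 - r0), j0 : j0 + (q1 - q0)]
    return scores


def score_to_label_map(score_map: ScoreMap) -> LabelMap:
    """Per-position argmax; exact ties resolve to the lowest class index."""
    return LabelMap(score_map.scores.argmax(axis=0).astype(np.uint8), resolution="grid")


def upsample_label_map(
    grid_map: LabelMap, stride: int, roi_shape: tuple[int, int]
) -> LabelMap:
    """Nearest-neighbour expansion of a grid map to full ROI resolution.

    Grid cell (i, j) paints rows [stride*i, stride*(i+1)) and likewise for
    columns; pixels past the last full footprint take the nearest cell.
    """
    if grid_map.resolution != "grid":
        raise ValueError("expected a grid-resolution map")
    g = grid_map.labels
    h, w = roi_shape
    gh, gw = g.shape
    if stride * (gh - 1) >= h or stride * (gw - 1) >= w:
        raise ValueError(f"grid {gh}x{gw} at stride {stride} inconsistent with ROI {h}x{w}")
    rows = np.minimum(np.arange(h) // stride, gh - 1)
    cols = np.minimum(np.arange(w) // stride, gw - 1)
    return LabelMap(g[np.ix_(rows, cols)], resolution="full")


def render_three_value_colormap(label_map: LabelMap) -> np.ndarray:
    """Encode a label map as an RGB uint8 image (bijective with labels)."""
    lut = np.zeros((3, 3), dtype=np.uint8)
    for label, color in CLASS_COLORS.items():
        lut[label] = color
    return lut[label_map.labels]


def colormap_to_labels(image: np.ndarray, resolution: str = "full") -> LabelMap:
    """Invert :func:`render_three_value_colormap`."""
    labels = np.full(image.shape[:2], -1, dtype=np.int16)
    for label, color in CLASS_COLORS.items():
        labels[np.all(image == np.array(color, dtype=image.dtype), axis=-1)] = label
    if (labels < 0).any():
        raise ValueError("image contains colors outside the three-value palette")
    return LabelMap(labels.astype(np.uint8), resolution=resolution)
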