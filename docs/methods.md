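# Methods

## Problem and model

Ki-67 is a nuclear proliferation antigen; its positive-cell burden is a
prognostic marker, normally read from an IHC-stained section (DAB-brown
positive nuclei, hematoxylin-blue negative nuclei).  `he2ihc` implements a
cross-stain label-transfer pipeline: a CNN learns to recognise Ki-67
positive cells *in the H&E stain alone*, using labels carried over from a
consecutive IHC-stained section, and then quantifies positive-cell burden
over whole regions of interest.

The classifier is a modified ResNet18 over 64×64 RGB patches with three
output classes — negative cell, positive cell, background.  Two changes
relative to the canonical 18-layer design: the global average pool is
removed (the 512×2×2 feature map of a 64-px patch is flattened directly
into the final fully connected layer) and the head has 3 output nodes.
Block internals are the standard basic residual block: 3×3 conv–BN–ReLU–3×3
conv–BN with an additive shortcut and post-add ReLU, and a 1×1 stride-s
projection shortcut wherever shape changes.  Padding conventions (conv1
pad 3, pool1 pad 1, block convs pad 1) are the unique choice producing the
64→32→16→8→4→2 spatial chain.  Total parameter count: 11,182,659.

Removing the average pool is what makes dense inference possible: the FC
weight matrix over 512×2×2 features *is* a 2×2 convolution kernel over 512
channels.  `convert_to_fully_convolutional` performs that reshape (weights
are copied bit-for-bit), after which the network maps any H×W ≥ 64×64 input
to a 3×S(H)×S(W) score map at output stride 32, where S composes the
per-layer floor formulas (S(64)=1, S(96)=2).  Score position (i, j) is the
classifier's verdict for the 64×64 window anchored at pixel (32i, 32j).
Exact sliding-window equivalence on large inputs is impossible with
zero-padded convolutions — a cropped patch sees zeros where the dense pass
sees real neighbouring pixels, and the network's composed receptive field
spans 467 px, far beyond the nominal 64-px window.  The contract is
therefore: exact equivalence at 64×64 (≤1e-5); exact per-position
equivalence against full-receptive-field crops (the brute-force oracle the
tiling scheme relies on); and majority-level argmax agreement with the
isolated-patch route on interior windows.  Measured on a trained synthetic
model, dense and isolated-patch verdicts agree on ~60% of interior windows
and disagree mostly where wide-context tissue changes an off-center
window's call — a real property of the transformation, stated rather than
hidden.  Map quality in aggregate is what the quantification correlations
measure (r(R_pos) ≈ 0.9 at the scaled study conditions).

The network, its backward pass and the Adam optimiser are implemented
directly on numpy arrays (`he2ihc.nn`): im2col convolutions with a
slice-add input-gradient kernel, batch normalisation with running moments,
max-pooling with argmax routing.  Gradients are verified against central
differences in the test suite.

## Training recipe

Full recipe: batch 64, softmax cross-entropy, Adam with weight decay 1e-5
(L2 added to the gradient; β=0.9/0.999, ε=1e-8 — conventional values),
learning rate 1e-3 for epochs 1–10 and 1e-4 for 11–20, random
horizontal/vertical flips, per-channel normalisation with mean
(0.485, 0.456, 0.406) and sd (0.229, 0.224, 0.225).  The normalisation
constants are the usual natural-image ones; they are kept for synthetic
data because only train/inference consistency matters.  The final-epoch
model is returned — no early stopping.  Pretrained initialisation is an
opt-in flag taking a local weights file; the default is seeded He-normal
initialisation so builds need no network access.

**Batch-norm recalibration.**  After the final epoch the running moments of
every batch-norm layer are replaced by exact averages over the training set
(one forward pass with a cumulative-moving-average momentum).  Short scaled
runs take too few optimiser steps for momentum-based estimates (momentum
0.1) to converge, which otherwise depresses evaluation accuracy for reasons
unrelated to the weights; the recalibration is deterministic and standard
practice for models whose batch statistics lag their parameters.

**Scaled profile.**  Tests and the default pipeline run ~1,000 patches for
5 epochs with the learning-rate drop at epoch 4/5 (the same 
high-then-low shape as the full schedule); `RunConfig.full_scale()` restores
the 20-epoch recipe.  These sizes are the package's default study
conditions on one CPU; they finish in about three minutes.

## Synthetic data: what it emulates and what it does not

Real paired slides for this problem are not publicly deposited, so the
generator fabricates both stains with fully known ground truth.  Elliptical
nuclei (semi-axes uniform in 20–35 px, so cell extents span ~40–70 px) are
placed without overlap by rejection sampling, capped at 100 attempts per
nucleus (exceeding the cap raises an explicit error naming the limit).
Default ROIs are 512×512 with 24 cells ≈ 20% area coverage, a density at
which placement succeeds reliably given the large cell size.

In pseudo-IHC, class is a color code: DAB-brown positive nuclei,
hematoxylin-blue negative nuclei, eosin-pink background, with small
per-nucleus color jitter (sd 0.015) and additive Gaussian pixel noise
(sd 0.02).  In pseudo-H&E both classes are hematoxylin-purple; the
morphological class signal is controlled by a single knob, `class_signal`:
positive nuclei are rendered darker by 0.05·`class_signal` (in [0,1] color
units) and larger by a factor 1 + 0.02·`class_signal`.  No real
quantification of the H&E-visible correlate of Ki-67 status exists, so
`class_signal` is a free experimental knob, not a biological claim;
`class_signal=0` makes the two cell classes statistically identical in H&E
(verified by a two-sample test in the suite).  The recovery experiments use
`class_signal=3.0` ("strong": a 0.15 intensity offset against 0.02 noise),
chosen as clearly learnable but still requiring the network to read
nucleus-level appearance.

Not emulated: stain physics and stain variation, tissue texture,
touching/overlapping nuclei, section-to-section registration error,
gland-level structure, scanner artefacts.  Passing tests therefore show
that the pipeline's machinery is correct and can recover a known
morphology–class relationship; they do not show that real H&E morphology
predicts Ki-67 status — that is the underlying scientific claim of the
method, testable only on real paired slides.

## Dataset construction

Patch windows are `center − patch_size/2` top-left with integer division,
so ground-truth cross-checks are exact.  Border cells whose window crosses
the image edge are skipped and tallied, never padded or resized.
Background boxes are accepted only at zero-area intersection with every
cell box (any positive overlap rejects; an IoU threshold would admit
grazing overlaps), where a cell box is the same 64×64 window centered on
the annotation; under-supply within the attempt budget (200·n candidates)
returns fewer boxes with a warning.  The 8:2 split takes
floor(0.8·N) training items from a uniform permutation; k-fold partitions
differ in size by at most one, larger folds first.  The split is not
stratified by class.  Annotations round-trip through a Labelme-dialect JSON
whose points are [x, y] = [column, row]; the reader converts to (row, col).

## Quantification

IHC images are reduced to three-value label maps by HSV box thresholds:
stained pixels (saturation ≥ 0.3, value ≤ 0.95) are positive if hue ∈
[0.0, 0.25) (brown) and negative if hue ∈ [0.5, 0.8) (blue); connected
components under 20 px are relabelled background.  The thresholds are
config-exposed and tuned to the generator palette (brown ≈ hue 0.08, blue
≈ 0.64, pink background ≈ 0.92 at saturation ~0.12); on real slides they
would need re-tuning, which is a configuration concern, not an algorithmic
one.  Stain deconvolution is deliberately not used — the simplest reading
of color channel filtering.

Area indices on any full-resolution map: D_pos = S_pos/S_ROI,
D_neg = S_neg/S_ROI, R_pos = S_pos/(S_pos+S_neg), with R_pos flagged
undefined (NaN) when no cell pixels exist.  Network label maps are
upsampled nearest-neighbour (each grid cell paints its 32×32 footprint,
trailing margins take the nearest cell) so both sources are measured in ROI
pixels.  Argmax ties resolve to the lowest class index.  Agreement between
sources is the Pearson correlation of each index across ROIs, computed per
the covariance/variance formulas; ROIs with an undefined index are dropped
from that index's correlation.

## Dense inference tiling

ROIs above a pixel budget are processed in overlapping tiles aligned to the
output stride.  The receptive interval of the composed network is computed
analytically (stride 32; output i depends on input pixels [32i−217,
32i+249], receptive field 467 px) and each tile carries enough margin that
every retained score's receptive field lies inside the tile crop or outside
the image — so tiled and untiled passes agree exactly on argmax maps
(verified bit-wise in the suite), at the cost of generous overlap.

## Null control and its expected ceiling

With `class_signal=0` the positive/negative distinction is unlearnable, and
trained models score cell patches at chance (~0.5 binary).  Background,
however, remains visually distinct from nuclei — that distinctness is
inherent to H&E, not a signal artefact — so overall three-class validation
accuracy settles near 2/3 (background ~correct, cells ~chance), not near
1/3.  The informative null result is the cell-only discrimination
accuracy, which the acceptance script reports alongside the overall
number.

## Numerical and degenerate-case choices

float32 throughout the network; BN ε=1e-5; cross-entropy clips log inputs
at 1e-12.  Empty patch sets raise; a class missing from a fold or training
set warns but proceeds (the loss stays defined).  Zero-denominator
precision/recall report 0 with a per-class flag.  Pearson r on a
zero-variance input warns and returns NaN.  Identical config + seed
reproduces images bit-for-bit; training is deterministic given the seed
(init, shuffling and flips all derive from it) up to BLAS reduction order.

## Known limitations

* The synthetic H&E signal is intensity/size only; texture cues are absent,
  so the classifier's task is easier than on real tissue.
* Area-based R_pos is not the clinical Ki-67 index (a positive-cell *count*
  fraction); with size-skewed classes the two diverge by design.
* Dense maps label 32×32 blocks, so predicted areas are block-quantised;
  correlations across ROIs are the meaningful readout, not absolute areas.
* The numpy network trains at CPU speed (~25 ms/patch-step); the full
  18,000-patch, 20-epoch recipe is hours, which is why the scaled profile
  is the default.
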