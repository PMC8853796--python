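# Methods

`psobsa` measures the body-surface area (BSA) affected by plaque psoriasis
from whole-anatomical-region photographs.  The pipeline has four stages:
semantic segmentation of each image into background / healthy skin /
psoriasis, reduction of the predicted mask to a single psoriasis-to-body
ratio, pixel-level evaluation of the segmentation itself, and
method-agreement analysis between model-derived and reference ratios.
Because clinical psoriasis photographs cannot be redistributed, a seeded
synthetic scene generator is a first-class component: every stage of the
pipeline is exercised end to end on images whose ground truth is known by
construction.

## Segmentation model

The network is a classical U-shaped encoder-decoder.  The encoder applies,
per level, two 3x3 convolutions each followed by batch normalisation and
ReLU (convolution -> batch norm -> ReLU ordering), then 2x2 max pooling;
channel widths double per level from `base_filters`.  A double-convolution
bottleneck at `base_filters * 2^depth` channels joins the decoder, which
per level applies parameter-free 2x nearest-neighbour upsampling, a 3x3
convolution halving the channels, channel concatenation with the matching
encoder feature map (decoder channels first), and two further 3x3
convolutions.  The head is a 3x3 convolution to `final_reduce_filters`
channels and a 1x1 convolution to the 3 class logits with per-pixel
softmax.  At full scale (`base_filters=64`, `depth=4`,
`final_reduce_filters=32`) this is a 24-convolution network.

The network is implemented directly in NumPy (forward pass, hand-written
backpropagation, Adam).  Training-mode convolutions lower the input to an
im2col matrix and run one large BLAS matrix product, caching the columns
for the weight gradient; inference-mode convolutions instead accumulate
the nine shifted products, which keeps memory flat so multi-megapixel
images can be segmented in a single forward pass.  Correctness of the
backward pass is pinned by a finite-difference gradient check in float64.

**Trainable parameters.**  The full-scale architecture as specified counts
34,545,603 trainable parameters (kernels + biases + batch-norm affine
terms), a pure function of the configuration that the test suite audits
against an independent closed-form count.  Published descriptions of this
layout sometimes quote ~31.0M; that figure is consistent with a variant
using 2x2 transposed-convolution upsampling rather than the
nearest-neighbour-plus-3x3-convolution decoder implemented here, and
cannot be reconciled with the literal layer list.  We implement the layer
list verbatim and report the computed count.

**Variable-size inference.**  All operations are translation-equivariant;
the only spatial constraint is divisibility by `2^depth` (= 16), handled
by reflect padding that is cropped after the forward pass.  A model
trained on 512x512 patches therefore predicts arbitrary-size images
directly, and for a 512x512 input the whole-image path and the
single-patch path are bit-identical.  If a padded image exceeds an
optional pixel budget, inference falls back to nonoverlapping tiles that
are stitched back; tiles lack cross-boundary context, so the fallback is
flagged in the log rather than silently equated with the whole-image path.

**Training choices.**  Loss is unweighted per-pixel categorical
cross-entropy (an inverse-frequency class-weighting flag exists because
severe class imbalance is intrinsic to this data regime, but the default
pipeline addresses imbalance by background-patch filtering instead).
Optimiser is Adam at learning rate 1e-4 (3e-4 in the desk-scale
reproduction script, where the task is easier and budgets are tighter),
batch size 4.  Augmentation applies independent random horizontal and
vertical flips jointly to image and mask, and "normalisation" is
interpreted as scaling to [0, 1] followed by per-channel standardisation
with statistics of the training patches (stored with the checkpoint and
re-applied at inference).  When a validation set is given, the weights of
the best-validation-loss epoch are retained.  Checkpoints are `.npz`
weight archives with a JSON sidecar recording the configuration, seed and
parameter count.

## Tiling

Training and validation images are cut into nonoverlapping `patch_size`
(default 512) tiles, stride equal to the patch size; other strides are
rejected rather than half-supported.  Images whose sides are not multiples
of the patch size are reflect-padded on the bottom/right (zero padding
behind a flag); reflect padding is chosen because it preserves local
texture statistics and is exactly invertible — `stitch` removes the
padding, so stitch o extract is the identity pixelwise.  Tiles whose
skin+psoriasis fraction is not strictly greater than
`min_foreground_fraction` (default 0: pure-background tiles only) are
dropped by a deterministic rule; a manual-inspection step sometimes used
for this purpose is deliberately replaced by the reproducible rule.

## Evaluation indices

For positive class psoriasis (label 2), one-vs-rest over all pixels:
ACC = overall 3-class pixel accuracy (a psoriasis-vs-rest binary accuracy
is available behind a flag), JI = TP/(TP+FP+FN), DSC = 2TP/(2TP+FN+FP),
SE = TP/(TP+FN), SP = TN/(TN+FP).  A published formula for specificity
that reads TP/(TN+FP) is treated as a typographical slip: it is not a
specificity, and reported specificities near 0.99 alongside sensitivities
near 0.66 are only consistent with TN/(TN+FP).  JI, DSC and SE are
*undefined* (NaN) when their denominators vanish — e.g. an image with no
psoriasis in either truth or prediction — and summary tables exclude
undefined entries while reporting the reduced count, so such images lower
the count rather than contaminating the mean.

The BSA ratio of a mask is psoriasis / (skin + psoriasis) pixels — the
body is skin plus lesions, background excluded.  The residual of an image
is the absolute difference |predicted - reference| of the two ratios
(summary minima of exactly 0 and nonnegative quartiles force the
nonnegative definition); the signed difference (model minus reference) is
kept separately for Bland-Altman analysis, where the sign carries the
direction of bias.  Quartiles use linear interpolation between order
statistics; std is the sample (ddof=1) standard deviation.

## Agreement statistics

ICC for absolute agreement on single measurements — ICC(A,1) in the
McGraw-Wong taxonomy, the coefficient meant by "two-way model, absolute
agreement, single measurement" (naming in the applied literature sometimes
says "mixed"; the absolute-agreement single-measure coefficient is the
same computation) — is computed from the two-way ANOVA mean squares with
n subjects and k = 2 methods:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

Confidence intervals use the McGraw-Wong F-based construction with
Satterthwaite degrees of freedom and are always reported ascending.  The
implementation is from first principles so the CI construction is
testable; an independent ANOVA oracle and a third-party implementation
cross-check it in the tests.  A series with zero variance everywhere has
no defined ICC and raises a degenerate-case error instead of returning 1.

Bland-Altman: bias = mean(model - reference), limits of agreement
bias +/- 1.96 x sample SD of the differences.  An optional subset rule
keeps pairs whose *reference* ratio is strictly below a cut (0.50 isolates
agreement away from severe cases, where segmentation of indistinct plaque
borders typically degrades and models underestimate).

## Synthetic scene generator

Each scene is a star-convex "body" silhouette (an ellipse with low-order
angular harmonics) sized to cover `body_fraction` of the frame, shaded
smoothly; lesions are star-shaped blobs with per-lesion frozen angular
profiles, seeded strictly inside the eroded silhouette and rendered in an
erythematous red with speckle highlights; the backdrop is a cool studio
grey-blue.  Per-pixel Gaussian colour jitter (`texture_noise`) is added
and the raster is quantised to 8 bits so in-memory scenes equal their PNG
round trip.  The psoriasis fraction of body pixels is driven to the
requested target by bisecting a global lesion-radius multiplier (monotone
until lesions saturate the body); the multiplier is capped at 8x the
nominal lesion scale, and a target that cannot be reached within +/-0.05
raises an infeasibility error rather than silently falling short.  The
fraction definition used during generation is the same psoriasis-over-body
definition the evaluator reads, so generator targets and evaluator
readings agree by construction.

What the generator does *not* emulate: real lesion morphology (no
published morphology statistics exist for these scenes; the blob model is
a stand-in, not a claim about psoriasis appearance), camera optics, flash
and working-distance effects, occlusion, hair, clothing, or the indistinct
plaque borders that make clinical segmentation genuinely hard.  The
synthetic classes are separable mostly by colour, so a network reaching
Dice >= 0.8 here demonstrates that the training and inference machinery
works — not that clinical-grade accuracy is attainable; clinical
psoriasis indices reported on private data are not reproducible from this
package and are not claimed.

## Problem sizes

Default demo and test scales are chosen for a single CPU: scenes of a few
hundred pixels per side, 128x128 training patches, 8-16 base filters.
The reproduction script (`scripts/acceptance.py`) generates 40/6/12
train/val/test scenes of 224-288 px per side, trains a 16-filter model on
up to 200 foreground patches (at most 6 epochs, early-stopped once
validation pixel accuracy reaches 0.97), and evaluates the 12 test images
at native size.  The full-scale 64-filter network is instantiated only for
the parameter audit.

## Known limitations

* No GPU path; training beyond desk scale is impractical in pure NumPy.
* Stride < patch size (overlapping tiles, blended stitching) is out of
  scope by design.
* The tiled-inference fallback is not numerically identical to
  whole-image inference near tile boundaries.
* Only two-method agreement (one model vs one reference) is supported; no
  multi-rater or repeated-measures designs.
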