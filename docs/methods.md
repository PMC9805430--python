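# Methods

`octreveng` implements a reverse-engineering pipeline for dry age-related
macular degeneration (AMD): a segmentation network is trained to predict,
from a **baseline** OCT volume, the geographic atrophy (GA) that is only
visible on a **follow-up** FAF image, and the trained network is then
inverted to display which baseline OCT features drove each prediction.
Because clinical longitudinal image sets of this kind are private, the
package ships a seeded retinal-phantom generator that reproduces the
geometry of such a study with fully known ground truth, so every stage of
the pipeline is quantitatively testable.

## 1. Label transformation

The follow-up FAF annotation is brought into baseline OCT coordinates in
three steps.

**Registration.** A projective homography `H` (3x3, normalized so
`H[2,2] = 1`) is fitted to manually selected keypoint pairs by the
normalized direct linear transform (points centered and scaled to mean
distance `sqrt(2)`, algebraic least squares via SVD). At least 4 pairs are
required, with no 3 of them collinear; for noiseless consistent pairs the
fit is exact. Projective was chosen over affine because it subsumes it and
matches the camera geometry between a fundus camera and an OCT en-face
projection. Warping uses inverse-mapping resampling: bilinear for
grayscale, nearest-neighbor for binary masks (re-binarized at 0.5 whenever
an intensity path is used); out-of-frame samples are 0.

**En-face projection.** An OCT volume `(height, width, depth)` is
collapsed to a `(width, depth)` map by the arithmetic mean along the
height (axial) axis, which keeps values in [0, 1]. En-face arrays are
stored width-as-rows; keypoints are `(x, y) = (column, row)`, 0-based.

**Extrusion.** The registered 2D GA mask is nearest-resampled to the
volume's `(width, depth)` grid, then every positive en-face pixel `(w, d)`
marks rows `ilm(w,d) .. cs(w,d)` (closed interval — "within the bounds"
read inclusively) of column `w` in B-scan `d`. ILM (inner limiting
membrane) and C-S (choroid–sclera junction) boundaries are consumed as
input; for phantoms they are known exactly. Extrusion is exactly
invertible: collapsing the stack along height reproduces the input mask.

## 2. Segmentation network

A U-Net variant with square kernels operates per B-scan: `depth` levels of
[two 3x3 same-padded convolutions + ReLU], 2x2 max pooling with channel
doubling, a two-convolution bottleneck, learned 2x2 stride-2 transposed-
convolution upsampling, skip concatenation, and a final 1x1 convolution to
two channels with a softmax, giving a positive/negative probability pair
per pixel. Binarization takes positive probability strictly greater than
0.5 (a pixel exactly at threshold is negative).

The loss for prediction `y` and transferred ground truth `ŷ` is

    L = (1 − (2|y ∩ ŷ| + 1) / (|y| + |ŷ| + 1)) + H(y, ŷ)

with set cardinalities read as sums of probabilities (soft Dice — the only
differentiable reading) and `H` the mean binary cross entropy of the
positive channel, probabilities clamped to `[1e-7, 1 − 1e-7]`. The public
`dice_bce_loss` evaluates this per image pair. During optimization, the
Dice term of each mini-batch is computed over the batch pooled as one set:
with sparse truth (most B-scans carry an empty mask) the per-image
smoothed Dice scores an all-background network as perfect on every empty
mask, making collapse into the saturated "predict nothing" optimum an
attractor; pooling the batch removes that degenerate optimum without
changing the per-pair definition. For the same reason the final softmax
bias is initialized at the empirical positive-class prior
(`prior_bias_init`, default on): starting at `p = 0.5` gives the
background BCE a violent first pull toward the collapsed optimum before
features can form.

Training uses Adam (default learning rate 1e-4, the clinical-scale
protocol value; conventional betas/epsilon), seeded weight initialization
(He) and shuffling, mini-batches of 8, per-epoch mean loss recorded.
B-scans are min–max normalized to [0, 1] per scan.

The layers are implemented directly on numpy arrays with explicit
forward/backward passes; the convolution inner loops are numba-compiled
(direct NCHW loops vectorized along the contiguous width axis — an order
of magnitude faster than im2col+GEMM at these small channel counts on one
core). Gradients are exact: a finite-difference check at float64 on a
4x4 case agrees to better than 1e-4 relative error (at a generic point —
biases are randomized in the check because zero-initialized biases place
pre-activations exactly on ReLU kinks, where one-sided derivatives differ
legitimately).

## 3. Feature reconstruction (deconvnet inversion)

Each forward block is paired with a reverse block that shares its weights:
the reverse signal is rectified (plain positive part) and then passed
through the transposed convolution of each forward convolution in reverse
order; biases are not re-applied. Max pooling records, for every pooled
element, the position in its 2x2 window that carried the maximum
("switches"); unpooling places values back at those positions and zeroes
the rest. The adjoint of a same-padded correlation is implemented as the
same-padded correlation with spatially flipped kernels and in/out channels
swapped, so forward kernels are reused verbatim.

The reverse pass starts from the last decoder block's output features
(pre-softmax), reconstructing what feeds the segmentation logits. Skip
connections are inverted by splitting a decoder block's input
reconstruction back into its upsampled half and its encoder half; the
encoder half is routed into the encoder-side reverse path and summed where
paths merge. The pass performs no parameter updates (asserted by checksum)
and, with switches and ReLU gates frozen from one pass, is a linear map of
the starting features (asserted by superposition). `saliency_image`
rectifies the input-space reconstruction and max-normalizes it to [0, 1].

## 4. Evaluation

Per-B-scan probability maps are column-averaged along height, stacked over
depth into a `(width, depth)` map, and bilinearly resized to 512x512. The
map is binarized with the better of the 2-class Otsu threshold and the
upper threshold of the 3-class Otsu split (256-bin histograms), judged by
Dice against the registered truth — ties go to 2 classes. This
truth-dependent selection reproduces the protocol faithfully but is an
*optimistic-evaluation* step: the threshold choice peeks at the ground
truth, so reported metrics are upper bounds in that one respect. Dice for
the selection uses no smoothing and defines empty-vs-empty as 1, so
spurious positives on empty truths are never rewarded.

From the pixelwise confusion counts: accuracy `(TP+TN)/total`, sensitivity
`TP/(TP+FN)`, specificity `TN/(TN+FP)`, and overlap read as the Jaccard
index `TP/(TP+FP+FN)`; the literal fraction `TP/total` is also emitted
(`tp_fraction`) since the two readings of "overlap" differ. Ratios with
zero denominators are reported as missing (NaN), never coerced. Cross-
validation partitions *cases* (never B-scans) into k near-equal seeded
folds; each fold trains a fresh network on the other folds and evaluates
its held-out cases through the full pipeline. The combined row is the mean
over held-out cases (primary); the mean of fold means is also emitted.

## 5. The phantom generator

Each case emulates one patient's visit pair at default geometry
256x128x32 (height x width x depth; configurable up to clinical
1024x512x128 — all downstream geometry is parameterized). Smooth ILM/RPE/
C-S surfaces are drawn as Gaussian-filtered noise around anatomical
depth fractions (0.22/0.60/0.80 of height), with fixed tissue intensities
(vitreous 0.06, retina 0.32, RPE band 0.88, sub-RPE druse material 0.55,
choroid 0.25, sclera 0.10) and multiplicative speckle
`(1 + σ·N(0,1))`, σ = 0.08, clipped to [0, 1]. Three lesion classes are
placed by rejection sampling with a separation margin:

* **druse clusters** — 2–4 overlapping elliptical domes elevating the RPE
  by 5.5–10% of volume height, en-face radius 24–40 FAF px;
* **hyper-reflective foci (HRF)** — bright intraretinal ellipsoids of
  radius 2–3.5 voxels;
* **subretinal drusenoid deposits (SDD)** — thin bright sheets two rows
  above the RPE band, half the druse footprint radius.

The generative conversion rule is fixed: *druse clusters convert to GA;
isolated HRF and SDD never do*. This hard-codes the qualitative clinical
finding as ground truth so that the reconstruction property (saliency
concentrating on converting lesions) has a known answer. The follow-up GA
annotation is the union of converting footprints upscaled to the 512x512
FAF frame, dilated by `conversion_margin` (default 4 px), then warped into
the follow-up frame by the inverse of the ground-truth planar transform
(translation ≤10 px, rotation ≤3°, projective perturbation ≤4e-5, bounded
so corner displacement stays under 15% of the frame). Baseline and
follow-up FAF images share a rendered scene (smooth background, dark
vessel-like Bezier curves, subtle druse glow; GA dark on follow-up).
Keypoints are vessel-centerline points in general position whose source/
destination pairs are exact under the true transform by construction.
Lesion radii are free parameters chosen once at plausible macular scales;
they are not claims about anatomy. All intensities are quantized to their
on-disk precision at generation time, so case I/O round-trips exactly.

What the phantom does **not** emulate: realistic speckle statistics or
shadowing, vascular flow, curved-geometry distortions, disease dynamics
beyond the single binary conversion rule, annotation noise, or keypoint
selection error. Passing tests therefore demonstrate the *mechanics* of
the pipeline (registration, label transfer, learnability of a druse→GA
association, inversion localization), not clinical performance.

## 6. The desk-scale headline experiment

`octreveng.experiments.run_headline_experiment` is the scaled-down
analogue of a clinical study: 24 phantoms at 256x128x32, a depth-3 network
with 4 base channels, inputs anti-alias-downsampled to 128x64, Adam at
1e-3 for 30 epochs per fold, batch 8, 4-fold case-level cross-validation,
followed by the reconstruction-energy contrast on held-out converting
lesions (mean |input-space reconstruction| over a lesion's footprint
columns, compared with the non-converting footprints of the same case).
Sizing rationale: at this update count (~2,200 minibatches per fold) the
clinical-scale learning rate of 1e-4 moves the weights too little to learn
at all, so the experiment uses 1e-3; half-resolution inputs with proper
Gaussian prefiltering keep the druse morphology while quartering the
compute; 4 base channels are the smallest width that learns the druse→GA
association reliably. Everything runs single-threaded on one CPU core in
roughly a quarter of an hour.

## 7. Numerical and degenerate-input conventions

* All randomness flows through explicit `numpy.random.Generator`s derived
  from named seeds; two runs with one configuration are bitwise identical
  (the CLI's `--strict-determinism` additionally pins BLAS threading).
* Homography fits reject <4 pairs and rank-deficient configurations;
  singular matrices are rejected at construction.
* Otsu thresholding rejects constant maps by name; if the 3-class split is
  degenerate the 2-class threshold is used.
* A probability exactly at the 0.5 threshold is a negative classification.
* Metric ratios with empty denominators are NaN and are excluded from
  (NaN-aware) fold and combined means.
* float32 is the training dtype; float64 is used for loss reporting and
  supported end-to-end for gradient verification.

## Known limitations

* The Otsu-variant selection against ground truth (protocol-faithful) is
  optimistic, as documented above.
* Per-case evaluation happens at 512x512 after bilinear upsampling of a
  `(width, depth)` map; at very coarse depth sampling (few B-scans) the
  upsampling ramp itself limits attainable Dice.
* The numpy/numba network targets desk-scale problems on one core;
  clinical-scale volumes would want a GPU framework behind the same
  module surface.
* Phantom realism is deliberately minimal (see §5).
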