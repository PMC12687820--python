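# Methods

## Overview

`topobow` classifies 2-D histology-style images (the motivating case:
WGA-stained skeletal muscle sections, where green fluorescence outlines
fiber membranes and blue marks nuclei) as healthy vs. diseased by fusing
two complementary representations:

* a **global topological block**: Betti curves of the cubical sublevel-set
  filtration of each of four channel planes (gray, red, green, blue),
  100 bins per curve for homology dimensions 0 and 1 — 800 features;
* a **local texture block**: a bag-of-visual-words histogram over a
  K = 150 vocabulary of SURF-style 64-d descriptors — 150 features;

concatenated into a 950-dim vector, z-scored per fold, and classified by
a single-attention-layer MLP under stratified 20-fold cross-validation.

## Cubical persistence

Images are modelled with the **vertex construction**: each pixel is a
0-cell carrying its intensity; 4-adjacent pixels are joined by edges and
2×2 blocks by squares, both taking the maximum of their incident pixels.
An r×c image gives a (2r−1)×(2c−1) cell grid and a monotone filtration.
Consequences worth stating: sublevel components are the 4-connected
components of `{f ≤ t}`, and sublevel loops correspond to 8-connected
components of the superlevel complement `{f > t}` that do not reach the
image border.

Three routes to the same diagrams are implemented:

1. `persistence_reduction` — textbook Z/2 boundary-matrix reduction with
   a deterministic (value, dimension, row-major) cell order; used on
   small grids and as an internal oracle.
2. `h0_union_find` — elder-rule union-find over pixels in increasing
   intensity (fast H0).
3. `sublevel_diagrams` — the production path: union-find H0 plus H1 by
   Alexander duality, i.e. a superlevel union-find on the 8-connected
   complement with a border sentinel of infinite birth.  A complement
   component born at its maximum B that merges into an older component
   at pixel value W is the loop (W, B).

Tests assert multiset equality of all three routes on hundreds of random
grids, and agreement with an independent brute-force oracle that counts
components/holes by scipy.ndimage labeling at every distinct threshold.
Zero-persistence pairs are discarded throughout (they contribute nothing
to Betti curves); tie-breaking among equal values cannot change the
diagram as a multiset.

## Betti curves

Thresholds are the 100 **left bin edges** of the fixed global range
[0, 255]; a diagram point (b, d) counts at threshold t iff `b ≤ t < d`
(half-open, so features are not alive at their death).  The range is
fixed rather than per-image so that bin i means the same intensity in
every image — a requirement for the downstream classifier.  Essential
classes (death = ∞) count at every `t ≥ b`; numerically this equals
capping essential deaths one level past the maximum gray value.  The
800-dim block layout is `[gray β0, gray β1, red β0, red β1, green β0,
green β1, blue β0, blue β1]`, 100 values each.

## Bag of visual words

* **Detection**: maxima of the box-filter determinant-of-Hessian response
  on an integral image (`skimage.feature.blob_doh`), scales 2–16 px over
  8 levels (≈3 octaves), absolute response threshold 0.002 — chosen so a
  typical phantom yields on the order of 50–500 keypoints.  Keypoints
  closer than one scale unit to the border are discarded: clipped box
  responses there are unreliable (a constant image then yields exactly
  zero keypoints, as it should).
* **Description**: upright (non-rotation-invariant) 64-d SURF-style
  vectors: Haar responses dx, dy (filter size 2s) sampled on a 20×20 grid
  of spacing s, Gaussian-weighted (σ = 3.3s), accumulated as
  (Σdx, Σ|dx|, Σdy, Σ|dy|) over 4×4 subregions, L2-normalized.
  Orientation assignment is omitted deliberately: histology fields have
  no canonical orientation, and the upright variant is cheaper.
* **Vocabulary**: MiniBatch k-means, K = 150, k-means++ init, fixed seed,
  batch 1024, ≤100 iterations.  Random reassignment of sparse clusters is
  disabled so the objective never drifts above the initialization and the
  degenerate n = K case stays at its exact optimum.  The vocabulary
  records the training-image ids so the harness can prove fold isolation.
* **Encoding**: nearest centroid (Euclidean; ties to the lowest index),
  counts L1-normalized.  An image with no keypoints encodes as the
  all-zero histogram rather than an error — it remains classifiable via
  its topological block.

## Fusion and standardization

`x_hybrid = [x_TDA, x_BoVW] ∈ R^950`, TDA block first.  Block lengths are
asserted, never truncated: a wrong-sized block is a pipeline bug that
should surface loudly.  Standardization is per-feature z-scoring fitted
on training rows only, with a standard-deviation floor of 1e-8 —
features constant on the training fold (typically red-channel Betti bins
of red-empty images) map to exactly zero.  The standardizer knows which
fold is its validation fold and refuses to be fitted on rows from it
unless explicitly overridden.

## Classifier

The 950-dim standardized input is reshaped to **5 segments × 190
features** and processed by one **10-head** self-attention layer (head
width 19, scaled dot-product, learned query/key/value and output
projections of width 190, attention dropout 0.1), flattened back to 950,
and passed through a GELU MLP head — 1024/0.4, 512/0.4, 256/0.3,
1024/0.2 (units/dropout) — into a 2-unit linear output trained with
softmax cross-entropy.  During training, Gaussian noise of sd 0.05 is
added to the input as feature-level augmentation; noise and dropout are
off at inference, making eval-mode forwards deterministic.

Training uses AdamW (lr 1e-4, decoupled weight decay 0.01 on weight
matrices, batch 32) with cosine annealing of the learning rate to ~0
over the epoch budget (500 by default) and snapshotting of the
best-validation-accuracy epoch; optional early stopping (patience in
epochs without a new best) is available for compute-constrained runs.
One seed governs initialization, batching, noise and dropout masks, so
training histories are bit-reproducible.

The network is implemented directly in NumPy (float32): forward passes
cache intermediates, gradients are analytic and verified against finite
differences in float64.  No positional information is added to the 5
segments; attention summaries report the head-averaged,
query-averaged mass each segment receives (rows sum to 1).

## Evaluation protocol

Stratified k-fold (default k = 20) with per-fold refitting of everything
supervised or corpus-dependent: visual vocabulary (training-fold
descriptors only), standardizer, classifier.  The TDA block is computed
once per image — it is unsupervised and strictly per-image, so it cannot
leak.  Metrics (precision, recall, F1, accuracy, AUC) treat the disease
class (1) as positive; hard labels are the softmax argmax (score ≥ 0.5);
AUC is fold-averaged with pooled ROC points also emitted; single-class
validation folds report AUC as missing, never 0.  Summary statistics are
across-fold mean ± sd.

## Phantom generator

Real WGA data is not bundled, so the package ships a generator of
synthetic two-class images that emulates the morphological contrasts the
method targets: a Voronoi mosaic of polygonal fibers (membranes bright
green, red near-empty), one nucleus per fiber in blue, placed centrally
with probability `central_nucleus_prob` (0.05 healthy / 0.8 diseased)
and within ~2 px of the membrane otherwise, and fiber-size variability
driven by `fiber_size_cv` (0.2 healthy / 0.6 diseased) via seed
clustering.  Gaussian pixel noise (sd 8 gray levels) approximates sensor
noise.  Nucleus placement has a deliberate topological signature: a
central nucleus is an isolated bright island in the gray channel (one
extra sublevel loop), a peripheral one fuses with the membrane network
and adds none.

What the phantoms do **not** model: stain spectra and bleed-through,
illumination gradients, out-of-focus blur, fiber-interior texture,
necrosis/fibrosis, and any within-class biological heterogeneity beyond
the two knobs.  Passing the synthetic recovery tests therefore shows the
pipeline can read exactly the morphology it claims to read — not that it
reaches any particular accuracy on real tissue.

## Compute profile of tests and acceptance runs

Integration tests and the acceptance script use a scaled-down study:
100 phantoms (50 per class) at 112×112, 20-fold stratified CV, epoch
budget 60 with early-stopping patience 10, three CV seeds for the
recovery check and one seed for the ablation ordering (fused vs.
TDA-only vs. BoVW-only).  The dimensional contracts are verified on one
224×224 phantom.  These sizes are the package's own test profile; the
defaults of the public API remain 224×224 and 500 epochs.

## Known limitations

* Only 2-D grids and homology dimensions 0/1; no 3-D stacks.
* The boundary-matrix reduction is pure Python and intended for small
  grids; production diagrams always use the union-find/duality path.
* The descriptor is SURF-*style*, not bit-compatible with the patented
  original; absolute histogram values will differ from OpenCV SURF.
* Per-fold standardization and vocabulary refits make cross-validated
  scores honest but mean there is no single "the" vocabulary; the
  `features`/`train` CLI path that fits one vocabulary on all listed
  images is for exploration, not unbiased evaluation.
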