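# Methods

## Problem and pipeline

`osteotex` classifies 2-D grayscale bone radiographs as *cancerous* or
*healthy* from hand-crafted texture features. The pipeline is:

1. **Preprocessing.** A 3×3 median filter removes impulse noise (borders
   by edge replication), followed by unsharp masking
   `out = clip(img + amount·(img − G_σ(img)))` with `amount = 1.0`,
   `σ = 1.0`. The source material prescribes the median filter and "a
   sharpening step" without a method; unsharp masking was chosen because
   it is standard, parameterized and testable.
2. **Segmentation / ROI.** Canny edge detection (Gaussian `σ = 1.0`,
   hysteresis thresholds 0.1/0.2 expressed as fractions of the smoothed
   gradient-magnitude maximum; Sobel and Prewitt at 0.25 of gradient max
   are available for comparison). The region of interest is the tight
   bounding box of the largest 8-connected edge component. Coordinates
   are 0-based, half-open, row-major. Degenerate cases: with no edge
   pixels, or an ROI thinner than 8 px (a lone straight edge line whose
   bounding box is a sliver), features are computed on the full image and
   a warning is logged.
3. **Features.** Eight scalars in fixed order — entropy, energy,
   Hough-Gini, skewness, contrast, correlation, homogeneity, entropy
   product — optionally followed by a 384-entry HOG block (total 392).
4. **Classification.** Soft-margin linear SVM (C = 1, tolerance 1e−3) or
   a 100-tree random forest (√d features per split, unlimited depth,
   majority vote, ties → cancerous). Features are z-scored with
   statistics learned from training data only. Evaluation is stratified
   5-fold cross-validation with a pooled out-of-fold confusion matrix
   (cancerous = positive class).

## Feature definitions

**GLCM (Haralick) features.** Intensities are uniformly binned into 64
levels; co-occurrences at distance 1 are accumulated over the four
offsets 0°/45°/90°/135°, symmetrized, and normalized to a probability
matrix `A`. Then

- contrast `Σ (i−j)² A_ij`,
- correlation `Σ (i−μ_i)(j−μ_j) A_ij / (σ_i σ_j)` (defined as 0 with a
  warning when a marginal variance vanishes),
- energy `Σ A_ij²`,
- homogeneity `Σ A_ij / (1+|i−j|)`.

Whether to use one offset or average several is an open choice; the
four-offset accumulation is conventional and configurable
(`glcm.levels`, `glcm.distance`, `glcm.angles`, `glcm.symmetric`).

**First-order statistics.** Variance and standard deviation use the
population form (divide by n). Skewness is
`Σ_s (GL_s − μ)³ count_s / ((N−1)·σ³)` over the gray-level histogram;
the scale-free `(N−1)·σ³` denominator is the default, with the literal
alternative `(N−1)³·σ³` behind `skewness_denominator`. Constant images
return 0 with a warning.

**Entropy protocol.** Shannon entropy `E(X) = −Σ p(y) log₂ p(y)` is
computed after resizing the image to 70×70 (bilinear, rounded back to
integers) and rotating it by 35° (nearest-neighbor, zero fill). The
rotation-padding pixels are identified by rotating an all-ones mask and
are excluded from the histogram, so no artificial gray level is
injected. The weighted entropy is `D(X) = E(X)·σ` with σ taken over the
same pixel set as `E(X)` (an internal-consistency choice; the protocol
does not pin it down), and the trained feature is the product
`E(X)·D(X) = E(X)²·σ`. The resize/rotation protocol can be disabled
(`entropy.enabled_protocol`) — the unit tests use that mode for
closed-form answers. No rationale is known for the 35° rotation; it is
implemented as stated, not rationalized.

**Hough-Gini.** A standard line Hough transform (θ uniformly covering
[−90°, 90°) in 180 bins, 1-px ρ bins; every edge pixel votes once per θ)
produces a vote matrix whose dispersion is scored by the Gini index

`GI = 2 Σ_i i·X_(i) / (n Σ X) − (n+1)/n`, X sorted ascending.

Long straight structures concentrate votes (high GI); irregular edges
spread them. Zero-vote cells are included by default (they are
legitimate zero incomes; `gini.include_zeros` switches this), and a
per-θ-column mean variant is available. The sort order is ascending
because the formula is only non-negative under that convention —
verified against the pairwise mean-absolute-difference identity
`Σ_{i,j}|x_i−x_j| / (2n Σx)`.

**HOG.** The input is resized to 25×25; gradients are centered
differences (one-sided at borders); unsigned orientation (0–180°) is
quantized into 6 bins of 30° with magnitude-weighted linear
interpolation between adjacent bins; histograms are formed over
3×3-pixel cells. 25 is not divisible by 3, so the final partial pixel
row/column is dropped, leaving an 8×8 cell grid and a descriptor of
length 8·8·6 = 384. Each cell is L2-normalized independently with
ε = 1e−6 (no multi-cell blocks — no block geometry is specified by the
source protocol). For distribution summaries the descriptor is reduced
to its mean; classification always uses the full vector.

## Classifiers and evaluation

"Learning rate 0.001" is not meaningful for a batch linear SVM; it is
read as the solver tolerance 1e−3. A stochastic hinge-loss trainer with
constant step 0.001 is available (`train_svm(..., solver="sgd")`) for
comparison. Random-forest hyperparameters beyond the tree count are
classical defaults. All stochastic components take an explicit seed
(default 42). Metrics are percentages: accuracy, precision, recall and
the F1 harmonic mean; any metric with a zero denominator is reported as
*undefined*, never silently 0, so degenerate runs cannot look perfect.
Display rounding is two decimals; tests compare unrounded values.

## Synthetic phantoms

Real bone radiographs are not redistributable, so the pipeline is
validated on 256×256 phantoms that reproduce the *statistical* contrasts
between classes rather than anatomy:

- **Healthy**: a finite long bone (rounded superellipse fully inside the
  frame, so its Canny contour closes into a single component and the ROI
  is well defined) over a soft-tissue background (level 110), with
  brighter cortical margins, regular trabecular banding
  (amplitude 24, period 30 px), a fine random texture field (sd 10), and
  a dark, smooth, straight **medullary canal** along the shaft axis
  (depth 45).
- **Cancerous**: the same bone plus a medullary lesion — a ragged
  ellipse (radial perturbation by low random harmonics, raggedness 0.45)
  sitting on the canal, filled with 4 spatially coherent gray-level
  compartments. The body compartments overlap the canal's intensity
  range; a small (~6% of area) necrotic core drops to near radio-black
  (`lesion_depth` 170 below the bone level, clipped at 5).

Per-image nuisance draws (bone level ±15, shaft width ±15%, exposure
gain 0.7–1.4 on texture amplitudes, noise 0.7–1.5×, canal width/depth,
lesion size/position) make the classes overlap in feature space the way
heterogeneous acquisitions do.

Design intent, and what the defaults were calibrated to produce:

- the lesion region has **lower Shannon entropy** than the matched
  region of a healthy phantom (few discrete compartment levels vs a
  continuous texture spread) — the region mask is generated for both
  labels at equal seed, giving exact matched controls;
- cancerous phantoms have **lower skewness**: the tiny dark core adds a
  third-moment term scaling as f·d³ while its variance footprint f·d²
  stays small, so σ³ normalization does not cancel the effect;
- first-order statistics alone separate the classes imperfectly
  (pooled 5-fold SVM accuracy in the high-80s at defaults), while the
  HOG block — sensitive to the ragged blob outline vs the straight canal
  and largely invariant to the exposure-gain nuisance thanks to per-cell
  normalization — raises accuracy in the large majority of seeds;
- the `high` effect-size preset (deeper, more ragged, fewer-level
  lesions, less noise) pushes pooled accuracy above 90%.

No direction is built in (or asserted) for the Hough-Gini feature: the
expected sign of that contrast is not established for this problem.

Every phantom is a pure function of its spec including the seed;
datasets derive per-image seeds from a master seed through a seed
sequence, so any size is reproducible. What the phantoms do **not**
model: projection geometry, scatter, anatomy of specific bones or tumor
types, non-lytic (sclerotic) lesions, multi-focal disease. Passing tests
on phantoms therefore shows the pipeline measures what it claims to
measure, not that it reaches any particular accuracy on clinical data.

## Numerical choices

- Median-filter borders: edge replication. Grayscale conversion: ITU-R
  601 weights; >8-bit images rescale linearly so dtype max → 255.
- Canny "fraction of gradient max" thresholds are converted to absolute
  thresholds using the Sobel magnitude of the Gaussian-smoothed image;
  the detector recomputes its own gradient internally, so the fractions
  are approximate with respect to that internal maximum.
- Sobel/Prewitt gradients below 1e−9 (on the [0,1] intensity scale) are
  treated as flat to avoid thresholding float rounding noise.
- GLCM quantization: `floor(v·levels/256)`, clipped to `levels−1`.
- ROI ties (equal component sizes) break by smallest (row_min, col_min).
- SVM hyperplane ties and random-forest 50/50 votes resolve to the
  cancerous class: for a screening aid, the conservative error is a
  false positive.
- Quartiles in feature summaries use linear interpolation.

## Test-suite problem sizes

The end-to-end experiment uses the 65/40 class split at 105 images per
dataset, ten seeded repetitions for the with-/without-HOG comparison and
one high-effect run; determinism is checked byte-for-byte on a
14-phantom dataset. Oracle-equivalence tests run on 8×8 images and
random vectors; these sizes keep the full suite at about a minute while
exercising every contract.
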