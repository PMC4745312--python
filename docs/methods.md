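# Methods

`cellcull` automates the quality-control step that precedes nanoscale optical
analysis of stained smear slides: finding the objects on a low-magnification
slide-map and deciding, per object, whether it is a *suitable* cell —
isolated, unfolded, debris-free, smooth-textured — or an unsuitable one
(debris-covered, folded, or overlapping cells, which must be excluded because
downstream spectroscopic statistics are corrupted by them). This note
documents the models, the defaults and the design choices, in the order the
pipeline runs.

## Synthetic scene model

Real annotated smear slide-maps are not redistributable, so the package ships
a seeded generator whose outputs exercise every stage. The scene model is
transmission imaging of Papanicolaou-stained cells: each object is an
absorbance field `A(x, y) ∈ [0, 1]` and the recorded pixel is
`background_level · illumination(x, y) · (1 − A·(1 − s_c))` per channel,
where `s_c` is the stain color. Cells are therefore darker than the bright
background, in 8-bit channels.

Phenotypes:

* **suitable** — one ellipse (axis ratio 1.0–1.25) with a smooth Gaussian
  nuclear shading and low texture noise (default SD 2 gray levels);
* **folded** — an elongated ellipse (ratio 1.7–2.3) with a darker ridge band
  across the body and a notched outline (a concavity);
* **debris** — an ellipse covered with high-contrast dark speckle;
* **overlapping** — two intersecting ellipses forming one connected object,
  darker in the overlap.

Unsuitable phenotypes use a higher texture noise SD (default 8 gray levels).
Illumination is a multiplicative low-order 2-D polynomial field spanning a
configurable fraction of the dynamic range (default 0.2); the blank
background image carries only this field, matching the flat-field-by-division
correction model. Object placement uses rejection sampling (1000 attempts per
object) with a 12 px clearance margin, so all planted objects are disjoint
and none touches a tile border. A small sensor noise (SD 1 gray level) is
added to scene tiles but not to the blank reference.

Default scene: a 2×2 grid of 1024×1280 px tiles holding 10 suitable and 10
unsuitable objects with radii 18–36 px. Default benchmark databases: 1000
training and 360 testing objects, half suitable in each, with the unsuitable
mix uniform over the three phenotypes.

What the generator does **not** emulate: photorealistic staining variation,
optical blur/PSF, chromatic aberration, partially-out-of-focus cells, slide
artifacts such as air bubbles, and the long tail of ambiguous borderline
objects a cytologist would argue about. The rendered classes are cleanly
separated by construction, so benchmark error rates near zero demonstrate
that the pipeline machinery works end to end — not that real smear data
would be classified with the same accuracy.

Determinism: every random quantity derives from one `SeedSequence` per scene
(sub-streams per object), so equal seeds give byte-identical images, tables
and reports.

## Slide-map assembly and illumination correction

Tiles are stitched row-major without blending or overlap. Shading is treated
as multiplicative, so correction divides by the blank background image and
rescales to a constant reference level (default 220); background pixels below
1/65535 of the dynamic range are clamped with a warning. Correction is
applied to the stitched map (per-tile correction is equivalent here because
tiles partition the scene). Grayscale conversion is the unweighted mean of
the three channels — the same convention the feature definitions use.

## Segmentation cascade

Order of operations: illumination correction → grayscale → bicubic
half-resolution downsampling → H-minima/H-maxima contrast flattening → edge
detection → morphological cleanup → full-resolution object extraction.

* **Downsampling** reduces each dimension to ⌈n/2⌉ with a bicubic kernel.
* **Contrast flattening** suppresses regional minima/maxima shallower than a
  depth `h` via morphological reconstruction; default
  `h_min = h_max = 0.05` of the dynamic range, chosen to remove texture noise
  while preserving the strong cell/background contrast of stained objects.
* **Edges** are the union (OR; AND selectable) of an Otsu-thresholded Sobel
  magnitude map and Laplacian-of-Gaussian zero crossings (σ = 2 px,
  magnitude threshold 0.75·mean |LoG|).
* **Cleanup** closes contours with a disk of radius 2, fills holes and drops
  components below `min_object_area` (400 px² at full resolution, rescaled at
  the half-resolution stage). Components touching the image border are
  dropped by default (they cannot be verified whole).
* **Extraction** upsamples the mask back to full resolution (nearest
  neighbor), labels 8-connected components, orders records by bounding-box
  corner and traces each boundary clockwise from the topmost-leftmost pixel
  (Moore neighborhood tracing).

Touching cells are deliberately not split: a clump is a single object that
the classifier should reject as overlapping. The cascade contains no
randomness.

## Features

Seven core features drive the classifier:

| feature | definition |
|---|---|
| eccentricity | `sqrt(1 − b²/a²)` of the moment-equivalent ellipse |
| solidity | area / convex-hull area |
| normalized variance | `σ²/μ²` of masked gray values |
| normalized kurtosis | `E[(x−μ)⁴]/σ⁴` (non-excess: Gaussian → 3) |
| entropy | `−Σ p log₂ p`, 256-bin masked histogram (bits, range [0, 8]) |
| GLCM energy | `Σ M²ᵢⱼ` of the summed co-occurrence matrix |
| Gabor variance | variance of the masked Gabor response, averaged over 0°/45°/90°/135° |

The co-occurrence matrix sums the eight compass directions at offset 5 px,
counts only pixel pairs that both lie inside the object mask, quantizes to 64
gray levels over [0, 255] and normalizes to total mass 1. The Gabor kernel is
the even (cosine) form `exp(−(x²/σx² + y²/σy²)/2)·cos(2πu(x cosθ + y sinθ))`
with σx = σy = 4 px and u = 0.1 cycles/px by default; crops are
reflection-padded before convolution so a constant crop yields exactly zero
variance. All intensity features are masked computations: pixels outside the
object never affect a value.

A wider registry (45 named features) fills out the standard categories —
size/shape, histogram, per-channel color, co-occurrence texture,
Fourier/Gabor texture, and topology proxies (Euler number, local extrema
density). The topology entries are stand-ins for an otherwise unspecified
category and are labeled non-canonical. Per-feature failures are recorded as
NaN (median-imputed at the table level) unless a core feature fails, which
invalidates the object.

## Nonparametric separability criterion

For two classes with samples `x_k^i`, each sample is compared against
inverse-distance weighted means of the other class (between-class scatter
`S_b`) and of its own class (within-class scatter `S_w`):

    w_kl ∝ d(x_k^i, x_l^j)^−1          (normalized over class j)
    M_j(x_k^i) = Σ_l w_kl x_l^j
    λ_k ∝ d(x_k^i, M_j(x_k^i))^−1      (normalized over class i)
    S_b = Σ_i P_i Σ_{j≠i} Σ_k (λ_k/n_i)(x_k^i − M_j)(x_k^i − M_j)ᵀ
    S_w = the j = i analogue
    F = trace(S_w^−1 S_b)

Conventions for the degenerate cases of inverse-distance weighting:

* a sample is **excluded from its own within-class weighted mean** — with the
  sample included, `M_i(x) = x` and `S_w` would be identically zero;
* coincident points share the weight mass equally;
* samples at zero distance from their weighted mean take the class's full
  `λ` mass, tie-shared.

The criterion is scalarized as `trace(S_w^{-1} S_b)` (determinant ratio
selectable); a relative ridge `1e-8 · tr(S_w)/d · I` is added to `S_w` when
its condition number exceeds 1e10. Degenerate candidate subsets (zero
within-class scatter, e.g. a constant feature) score `−∞` during the search.

**Distance metric.** Distances are computed after whitening the candidate
subset by its total covariance (a Mahalanobis metric). This makes `F`
*exactly invariant under any invertible affine transformation* of the feature
space — the natural requirement for a criterion that mixes features with
heterogeneous units — whereas per-feature z-scoring (selectable as
`metric="zscore"`) is only invariant to axis-aligned rescaling, and raw
Euclidean distances (`metric="raw"`) to rigid motions. The raw mode is also
what the oracle-equivalence tests use, since it evaluates the printed
formulas verbatim.

**Search.** Sequential floating forward selection: add the feature
maximizing `F` of the augmented subset, then, while removing a single feature
(other than the one just added) strictly improves on both the current `F`
and the best `F` previously seen at the smaller size, remove the best such
feature. The second condition is the standard guard that prevents
add/remove cycles. Ties break by column order; the search is deterministic.
Note that `F` is not monotone in subset size for this weighted criterion
(unlike the classical Fisher trace), so the trace of criterion values along
the search need not increase.

## Classification

The working classifier is an SVM with the Gaussian kernel
`exp(−‖u−v‖²/2σ²)`; linear and polynomial `(⟨u,v⟩ + a)^d` kernels are
available for comparison. Penalty `C` and scale `σ` are tuned by stratified
k-fold cross-validated accuracy (default 10 folds) over log grids
`C ∈ 2^{−5..15}` and `γ = 1/2σ² ∈ 2^{−15..3}` (step 2²). Features are
standardized inside the model pipeline, so scaler parameters are fit on
training folds only and test leakage is structurally impossible. Baselines:
kNN with k = 3 and a random forest with 500 trees and √p features per split.
Decision scores (signed SVM decision values; vote/probability fractions for
the baselines) are oriented so larger means more confidently suitable;
no probability calibration is applied because ROC analysis only needs a
ranking. Training data is balanced by construction, so no class weighting is
used.

## Evaluation

Error rate is misclassified/total; sensitivity is suitable-cell recall
(the positive class is `suitable`, switchable in principle by relabeling).
The ROC is a threshold sweep over the unique scores; AUC is the trapezoid
area, equal to pairwise concordance with ties counted ½. Confidence
intervals are stratified percentile bootstrap intervals (resampling within
each class; default B = 1000, 5th/95th percentiles).

The overtraining audit trains classifiers with the top-k selected features
for k = 1..K, records training, testing and leave-one-out errors, and tests
the train/test gap sequence for a systematically increasing trend with a
one-sided Kendall-tau test; p < 0.05 flags overtraining. LOOCV refits with
the tuned hyperparameters fixed (no per-fold retuning).

The effect-size utility is `(mean_a − mean_b)/sqrt(var_a + var_b)`, the form
used to compare diagnostic performance between optimal and suboptimal cell
populations.

## Benchmark

`run_benchmark` composes the stages. Two modes:

* **objects** (default and the mode used for the headline numbers) — objects
  are rendered directly from ground truth and featurized; this isolates the
  selection/classification stages from segmentation noise;
* **pipeline** — scenes are generated, segmented, matched to ground truth at
  IoU ≥ 0.5 for labels, then featurized.

The default run uses 1000 training / 360 testing objects (half suitable),
the full 45-feature registry, 7 selected features and an rbf-SVM tuned by
10-fold CV. On these defaults the rendered classes are essentially fully
separable, and the held-out sensitivity and AUC sit at or near 1.0 — at or
above the asymptotic values reported for comparable manually-labeled smear
data. All sub-seeds (generation, CV folds, shuffling, bootstrap) derive from
the single run seed.

**Negative control.** `shuffle_labels=True` permutes the labels of *both*
databases before selection/training. Permuting only the training labels is
not a usable control on this generator: the phenotype classes form separable
clusters, so a classifier fit to permuted labels still ranks test objects by
cluster with a random sign, giving a bimodal null rather than one centered
at AUC 0.5. Destroying the label-object association everywhere yields the
intended tight chance-level null.

**Problem sizes in the test suite.** The packaged tests run the full
1000/360 benchmark once for the headline checks, and use a size-reduced
benchmark (300 training / 160 testing objects) for the per-feature-count
LOOCV overtraining audit, which refits hundreds of classifiers. Unit tests
use smaller planted tables. These sizes are the package's documented choices
for a fast default suite; all are parameters.

## Known limitations

* The synthetic phenotypes are caricatures: real debris, folds and overlaps
  are continuous in severity, so real-data error rates will be higher than
  the benchmark's.
* The 45-feature registry stands in for a larger production feature bank;
  only the seven core features follow exact printed definitions.
* The criterion's inverse-distance weights make `F` non-monotone in subset
  size and noisy for very well-separated single features; the floating
  search mitigates but does not remove this.
* `pipeline` mode labels segmented objects by IoU matching against ground
  truth; unmatched detections are discarded rather than treated as a
  separate artifact class.
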