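# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Pixelwise colour segmentation

Each pixel is the 6-vector `(R, G, B, L*, a*, b*)`.  CIELAB is computed by
`skimage.color.rgb2lab` under the dominant convention — sRGB primaries, D65
white point, 8-bit channels scaled from [0, 255] — which is also the
convention of the MATLAB `rgb2lab` family.  Note a numerical quirk of that
published conversion: because its sRGB matrix is rounded independently of
the white point, pure white lands at `a*, b* ≈ ±2.5e-3` rather than exactly
0; the tests pin the convention at that accuracy.

The classifier is a plain (unregularised) multinomial logistic regression
in reference-class form: class *n* ("trellis", last in the canonical order
grape, rachis, trunk, shoot, leaf, gap, trellis — the choice is arbitrary
and cancels out of the probabilities) has implicit zero coefficients, and
each other class contributes one row of intercept-plus-weights.  Fitting is
delegated to `sklearn.LogisticRegression` with `C = inf`, tolerance 1e-8;
probabilities are always re-evaluated from the stored coefficients by the
package's own softmax-over-reference formula, so a saved model is
self-contained.  Two choices the problem statement leaves open:

- **Feature standardisation** (zero mean / unit variance from the training
  pixels) is applied before the fit and stored in the model.  It changes
  nothing statistically (the MLE is equivariant) but stabilises the
  optimiser; an optional ridge term exists for pathologically separable
  inputs and is off by default.
- **Argmax ties** break to the lowest class index.  Ties are measure-zero
  for continuous features; the rule only exists so segmentation is
  bit-reproducible.

One segmentation model belongs to one image set (variety/vineyard/camera).
Pooling sets mixes colour calibrations and measurably degrades per-class
accuracy, so the pipeline treats per-set models as first-class.

## Cluster detection

The grape layer is opened with a radius-3 disk (pixels at Euclidean
distance ≤ 3; note a true disk opening rounds right-angle corners — a
square is *not* exactly opening-invariant).  Connected components use
8-connectivity so diagonally touching berry groups stay whole, and
components under 100 px (configurable) are dropped as residue.

Candidates are encoded as bag-of-visual-words histograms.  The local
descriptors are 64-dimensional, upright, SURF-style blob features built on
scikit-image primitives: determinant-of-Hessian keypoints
(`blob_doh`, sigma 2–10 over 9 scales, threshold 0.002), a patch of
half-width `max(8, 5*sigma)` per keypoint resampled to 20×20, and per cell
of a 4×4 grid the four Haar-wavelet response sums
`(Σdx, Σ|dx|, Σdy, Σ|dy|)`, L2-normalised.  The detector parameters ride
along in the codebook archive; any 64-d blob descriptor can stand behind
the same interface.  The codebook is k-means (k-means++ init, fixed seed,
10 restarts) with k = 100 by default; a sweep helper evaluates the
held-out AUC over the grid {10, 50, 100, 150, 200}.  Histograms enter the
SVM as **raw counts** (the number of occurrences of each codeword); an L1
normalisation flag exists because RBF kernels are scale-sensitive, but it
is off by default.  The SVM uses
`K(x, x') = exp(-||x - x'||^2 / s^2)` with kernel scale `s = 24.628` and
box constraint `C = 1.4654`; both were originally tuned in `[1e-3, 1e3]`.
The fitted support vectors, dual coefficients and intercept are stored and
the decision function is re-evaluated in-package, so archives do not
depend on the fitting library's serialisation.  Candidates touching the
image border are kept: partial clusters count as positives.

Detector training mirrors the field workflow: candidates are extracted
automatically from the segmentation of the training scenes and labelled
against the known cluster boxes (IoU ≥ 0.3), then topped up with generated
candidate-style crops to 300 per class — the training-set size the method
was designed around.  With fewer than roughly a hundred crops per class
the SVM margin on unseen scenes becomes unreliable.

## Mask refinement

For each detected cluster the grape and rachis layers of the (margin-
padded, default 12 px, so stem rachis just outside the grape box is
retained) crop are refined in six steps: radius-2 disk openings of grape
and rachis; mask A = largest 8-connected component of the opened union;
mask B = union of the convex hulls of each grape component; final mask =
grape and rachis pixels in A and **inside B**, plus rachis components in A
outside B that are 8-adjacent to at least two grape components.

The "inside B" reading deserves a note: B is already a union of
per-component hulls, and taking a further global hull of B would make the
per-component construction irrelevant.  Keeping pixels inside the hull
*union* preserves the intent — berry groups keep their enclosed holes,
and only rachis that genuinely bridges two groups survives outside them.
An empty grape layer after the opening raises an explicit
"no cluster content" error and the candidate is skipped with a log entry.

## The 14 features

Areas are pixel counts.  Choices that fix otherwise ambiguous quantities:

- **Holes (AH)**: pixels of the convex hull of the final mask covered by
  neither grape nor rachis, as a fraction of the hull.
- **Perimeter (RDGrape, CSFGrape)**: the 4-direction Crofton estimator.
  A naive pixel-edge count measures a digitised circle at ~8r instead of
  2πr and would put the roundness of a circle near 0.62; Crofton recovers
  2πr within ~1% across radii 20–100, keeping `RD(circle) = 1` and
  `CSF(circle) = 4π` meaningful.  Hole boundaries are included.
- **Rotation**: the mask is rotated so the principal axis (leading
  eigenvector of the second central moments of the foreground
  coordinates) is vertical; nearest-neighbour resampling with a 0.5
  threshold keeps the mask binary; orientation is fixed by flipping so the
  centroid sits in the lower half of the bounding box.  Collinear
  foregrounds are rejected.
- **Widths**: W25/W50/W75 average the per-row foreground extent
  (`max_col - min_col + 1`) over rows whose normalised position lies
  within ±5% of the fraction, *measured on the final rotated mask*, and
  are divided by the cluster length so the width block is
  camera-distance-free (raw pixel widths are emitted alongside).  The
  aspect ratio AS uses the maximum row width over the length.
- **RR_in**: rachis pixels falling in holes of the flood-filled grape
  mask, over all rachis pixels — a deterministic operationalisation of
  "completely surrounded by grape".  With no rachis pixels, AR, RatioRG,
  RR_in and RR_out are 0 by convention.
- **R_AoM**: cluster area over the mean refined-cluster area of its set.
  At inference the current batch mean is the default; a training-set mean
  can be supplied instead.

Scale-free features (RD, CSF, AS, AH, W ratios) vary by <3% between a
shape and its 2× enlargement; the residual is pure digitisation.

## Rating regression

The rating model is `g(x) = f(x) + h(x)'β` with
`f ~ GP(0, σ_f² exp(-||x-x'||/ℓ))` — "exponential" covariance meaning
Matérn-1/2 — over standardised features, plus a constant basis (the
minimal faithful reading of an unspecified `h`; configurable to none).
Defaults: observation noise SD `σ = 0.83194` rating units, length scale
`ℓ = 91.5821` (dimensionless after standardisation).  The posterior is
exact: Cholesky of `σ_f²K + σ²I`, β by generalised least squares, and the
predictive variance carries the usual universal-kriging correction for the
estimated intercept.  The signal variance σ_f² is fitted by maximising the
marginal likelihood (bounded 1-d search on log σ_f²) unless supplied; this
matters because at ℓ ≈ 92 the correlation surface is nearly flat and the
fitted σ_f² restores the effective gradient `σ_f²/ℓ` that the data demand.
Reported ratings are clamped to the OIV span [1, 9] with the raw value
retained; **all evaluation metrics use the raw value**, so any systematic
under-estimation of very compact clusters remains visible.

Hyperparameter search uses sequential model-based optimisation: an initial
random quarter of the budget, then a GP surrogate with an ARD Matérn 5/2
kernel on the unit cube (declared axes on log scale) and an
expected-improvement acquisition over 1500 seeded candidates per step,
with a duplicate-avoidance rule (a proposal numerically identical to an
evaluated point falls through to the best exploratory candidate) standing
in for the "plus" escape of over-exploitation.  Exactly `budget`
evaluations run; non-finite objective values are recorded as failures and
excluded from the surrogate.

## Synthetic scenes: what they are and what they show

`fixtures.generate_scene` emulates night-time flash imagery of a VSP
fruiting zone.  Colours are per-class isotropic Gaussians (σ = 8 grey
levels) whose means are pairwise ≥ 60 levels apart in at least one
channel — dark purple grapes, straw-coloured rachis, black gaps, bright
trellis, two greens and a brown.  The background assigns trunk / shoot /
leaf / gap / trellis by quantile-slicing a smoothed random field, so the
configured mixture is met exactly (within one pixel) with spatially
coherent regions.

Clusters are unions of radius-5 berry disks grown on a rachis skeleton
(main stem with a stub above the hull, shoulder arms, interior branches;
stroke width 7 px so it survives the radius-2 opening).  The base layout
chains berries along an elliptical arc plus the stem at 1.4-radius spacing
— chosen so inter-berry necks (~7 px) survive the radius-3 detection
opening and each cluster stays one connected grape component — and random
tangent berries (minimum separation 1.1 r) are added until the **measured**
packing density, berry-union area over its convex-hull area, reaches the
target.  `packing_density` in a `ClusterRecord` is always the measured
value, and the OIV proxy is the fixed bijection `1 + 8·density`.  Loose
targets get proportionally larger ellipses (straggly clusters), and
scenes can add grape-coloured distractors (smooth blobs, stripes) as
detector negatives.

Limitations to keep in mind when reading green tests:

- **Density floor.**  A connected union of touching disks cannot be
  arbitrarily sparse at these raster scales; requesting densities down to
  0.2 yields measured values bottoming out near 0.27–0.35.  The recorded
  truth is the measured value, so correlations remain honest, but the very
  loosest OIV classes are under-represented.
- **Separability by construction.**  Class colours do not overlap, so the
  near-perfect segmentation scores demonstrate *recovery machinery*, not
  robustness to field colour confusion (white varieties, sunlit leaves).
- **No occlusion or cluster overlap.**  Planted clusters never intersect
  and nothing hides them; the known field failure modes (leaf occlusion,
  merged overlapping clusters) are out of the generator's scope.
- Berries are hard-thresholded anti-aliased disks; there is no specular
  highlight, bloom, or berry deformation — the cue that distinguishes the
  very highest compactness class in expert scoring.

## Problem sizes and determinism

The test suite and the acceptance analysis train on 480×480 scenes: six
training scenes (3 clusters + 2 distractors each), 500 labelled pixels per
class, 300+300 detector crops, and evaluate end-to-end on 18 fresh scenes
(54 clusters); the regression designs use the 95/100 split and the
195-sample leave-one-out.  These sizes were chosen so the whole analysis
reruns from scratch in a few minutes on one CPU.

Every stochastic step (scene generation, pixel sampling, k-means, CV
shuffles, the optimiser) is driven by named seeds in the configuration.
Model archives are JSON with inlined arrays, manifests carry counts and
seeds but no wall-clock data, and CSV/PNG writers are deterministic, so
any verb rerun with identical inputs and seeds reproduces its outputs
byte for byte.
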