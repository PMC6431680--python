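# Methods

## Scope and model

`famet` implements a single-cell image metrology for 3-channel
fluorescence data: one cell per field, red = actin (cell body), green =
vinculin (adhesion sites), blue = nucleus. All analysis happens in the 2D
maximum-intensity projection plane; z-stacks are supported only through
the projection. Physical units enter through a single calibration, the
pixel size in µm/px, which every area and distance metric carries.

## Segmentation workflow

Each channel is min–max rescaled to [0, 1] (the 8-bit conversion of the
typical acquisition pipeline is a linear rescale, so floats and integer
dtypes are treated uniformly), then:

1. **CLAHE** (`skimage.exposure.equalize_adapthist`), default clip limit
   0.005, tile = image/8. The clip limit is deliberately conservative:
   the vinculin channel contains a dim uniform cytosolic background, and
   an aggressive CLAHE lifts that background into the same intensity
   range as the adhesions, after which no global threshold can separate
   them. 0.005 equalizes the cell-body channels without destroying the
   cytosol/adhesion contrast. The value is exposed in
   `SegmentationParams`.
2. **Non-local means** (`skimage.restoration.denoise_nl_means`), patch 5,
   search window 11, strength 0.8× the noise sd estimated from the image.
   A strength of 0 disables the step.
3. **Otsu threshold.** For the adhesion channel the histogram is
   restricted to the (2-px-dilated) cell mask: the threshold must resolve
   cytosol vs adhesion, and when the cell occupies a small fraction of
   the field the full-frame histogram is dominated by the dark exterior
   and Otsu locks onto the wrong contrast. The whole image is binarized
   against the region-derived threshold. One numerical subtlety: skimage
   returns the *center* of the optimal histogram bin, while the discrete
   Otsu rule assigns that entire bin to the background class; we
   therefore cut at the bin's upper edge, which matters when a large
   number of identical values (e.g. a noise-free background) land in one
   bin.
4. **Conditional erosion**, one synchronous pass: a foreground pixel is
   removed iff the count of background pixels among its 8 neighbors is ≥
   the threshold (default 5). Out-of-image neighbors count as background.
   A single pass is the minimal reading of the procedure; an iterated
   variant can be built by composition.
5. **Hole filling** (`scipy.ndimage.binary_fill_holes`).

The cell and nucleus masks keep the largest 8-connected component
(single-cell assumption). The adhesion channel gets a disk dilation
(radius 1 px) before the erosion — protecting thin adhesions — and its
components are triaged by area: background < 0.1 µm² ≤ nascent < 0.2 µm²
≤ mature, with the boundary area of exactly 0.2 µm² counted as mature.
Components not intersecting the 2-px-dilated cell mask are discarded
(adhesions sit at the periphery where the two masks may disagree by a
pixel). All masks are foreground = `True`.

## Morphometric metrics

* **Ellipticity** uses the affine moment invariant
  `J = (m20·m02 − m11²)/m00⁴` of central second-order moments; `J` equals
  `1/(16π²)` for every filled ellipse, so the metric folds around that
  peak: `16π²·J` if `J ≤ 1/(16π²)`, else `1/(16π²·J)`. It is 1 exactly
  for ellipses and, e.g., `144/(16π²) ≈ 0.912` for a square (closed form
  from the continuous moments `m20 = m02 = 1/12`).
* **Rectangularity** is area over the *axis-aligned* bounding box. The
  rotated minimum-area rectangle would be rotation invariant, but the
  axis-aligned convention matches how bounding boxes are reported by the
  interactive tools this workflow replaces; the rotation sensitivity is
  accepted and tested for.
* **Solidity** is area over convex-hull area (via `regionprops`), the
  concavity indicator that separates triangular-concave confined cells.
* **FA size / aspect ratio** per cell are the means over mature
  adhesions; the aspect ratio comes from the moment-equivalent ellipse.
  Degenerate (single-pixel or collinear) components get the minor axis
  floored at one pixel width and are flagged.

## Spatial statistics

The **E-function** of a cell is the empirical CDF of the Euclidean
distances from each mature-adhesion centroid to the nucleus centroid.
The **E-slope** is the zero-intercept least-squares fit over the n step
points `(d_(i), i/n)`: `slope = Σdᵢfᵢ/Σdᵢ²` (1/µm). Normalizing the
ordinate to a fraction (rather than a raw count) makes slopes comparable
across cells with different adhesion counts. The **G-function** is the
set of nearest-neighbor distances among mature-adhesion centroids
(exact, via a k-d tree, k = 2); its mean is the cell G-function (µm).
Both statistics are invariant under rigid motions of the centroid set;
ties in nearest-neighbor distance are harmless since only the value is
used. Cells need ≥ 1 mature adhesion at positive distance for the
E-slope and ≥ 2 for the G-function; cells failing this are flagged and
excluded from classification rather than imputed.

## Classification

Features I–VII are z-scored per column with the sample (n−1) standard
deviation, fit on the full task-restricted table before cross-validation
(the normalization is described as a preprocessing of all metrics; a
leakage-safe per-fold scaling mode exists and is what the permutation
sanity checks use). The classifier is a linear soft-margin SVM, C = 1
(exposed), one-vs-one majority vote for > 2 classes. Accuracy is
estimated with stratified k-fold CV (default k = 5, seeded); folds are
stratified because at ~22 cells per class an unstratified split can
starve a fold of a class — a non-stratified mode is available. Class
subsets and mergers (drop B; pool A+B+C against D) are expressed as label
maps applied before CV. Univariate feature relevance between two classes
is the one-way ANOVA F ratio (ties broken by declared column order);
heterogeneity is the CV% (sample sd over |mean|). Group comparisons use
one-way ANOVA plus Tukey HSD with 95% CIs (statsmodels).

## Synthetic scenes

The generator emulates the four confinement-class archetypes, each a
`ClassArchetype` of numeric ranges (all exposed, none hard-coded in the
renderer):

| class | outline | area µm² | FAs | FA size ln(µm²) | elongation | placement |
|-------|---------|----------|-----|------------------|------------|-----------|
| A | ellipse (AR 1.8–2.8, mild wobble) | 600–1000 | 25–45 | ln 0.45, σ 0.7 | 2.0–3.5 | body-wide |
| B | lamellar blob, per-scene wobble *and* stretch | 200–1200 | 6–45 | ln 0.5, σ 0.9 | 1.2–3.5 | body-wide |
| C | small blob | 120–320 | 5–14 | ln 0.3, σ 0.9 | 1.2–2.4 | edge-biased (1.5 µm decay) |
| D | triangle with inward-bowed edges | 400–800 | 15–30 | ln 0.9, σ 1.0 | 1.0–1.6 | perinuclear (σ 3 µm) |

The ranges realize the qualitative class structure: C is the smallest;
D's concave triangle gives solidity ≈ 0.73 and the lowest
rectangularity; D's adhesions are the largest, roundest, most clustered
and most perinuclear; and B is the high-variance mixture — its
intra-class variance multiplier (2.5, the largest) widens both the
wobble-amplitude and the stretch range per scene, so B draws run from
A-like spread ellipses to C-like small blobs. That overlap is what makes
the 4-class task measurably harder than the 3-class task while the
binary ABC-vs-D contrast stays easy, the characteristic accuracy
ordering of this assay.

Rendering: the cell outline (a 720-point polygon in µm, scaled to the
drawn area, randomly rotated, rejected and redrawn up to 25 times if it
would touch the image border) is rasterized; the nucleus is an ellipse
(0.22× cell area, clipped to 35–130 µm²) placed at the deepest interior
point and shrunk to fit. The red channel is the cell mask with blurred
random-chord "fiber" texture (0.45–0.8); blue is the nucleus at 0.85;
green stamps each adhesion as a filled ellipse (intensity 0.75–1.0) over
a cytosolic background (default 0.08) restricted to the cell, with
adhesion positions drawn per the placement rule (edge-biased placement
excludes the nucleus footprint, a cell's adhesions being visible at its
periphery) and overlapping stamps rejected so ground truth stays
unambiguous. Additive Gaussian noise (default sd 0.03) goes everywhere;
`z_planes > 1` replicates the plane with exponential attenuation around
an integer focal plane so projection is exercised without 3D geometry.
Ground truth records the rendered (post-rasterization) masks, centroids,
areas and maturity bins. Scenes are bit-reproducible from (archetype,
config, seed); population seeds are spawned per scene from the master
seed.

Defaults: 448×448 px at 0.15 µm/px (a 67 µm field; pixel area
0.0225 µm², so the 0.1/0.2 µm² triage cutoffs fall at 5 and 9 pixels and
all three bins are populated). A study is 22 cells per class (88 cells),
the scale at which the acceptance run and tests operate.

What the generator does *not* emulate: optics (no PSF, no Poisson
photon noise), multi-cell fields, true 3D geometry, actin-fiber
anisotropy coupled to adhesion orientation, intensity gradients and
bleaching. Passing tests therefore demonstrate the correctness and
stability of the *metrology* under controlled conditions, not
segmentation robustness on real microscopy data; on real images the
CLAHE/NLM parameters in particular should be re-examined.

## Numerical choices and degenerate inputs

* Otsu on a constant image (or region) raises — no threshold exists.
* Conditional erosion treats out-of-image neighbors as background.
* A cell with no adhesions yields an empty adhesion list, not an error;
  features IV–VII become missing and the cell is dropped from
  classification with a logged reason.
* Singleton groups report sd 0 by convention in population summaries.
* CV% requires a nonzero mean and n ≥ 2.
* All randomness flows through `numpy.random.default_rng` seeds; the SVM
  itself is deterministic given folds.

## Known limitations

* Rectangularity's axis-alignment makes it orientation sensitive; for
  randomly oriented cells it is a noisier feature by design.
* The dilation step in adhesion segmentation inflates small components —
  objects near the triage boundaries can change bins relative to their
  pre-dilation area, and adjacent adhesions closer than ~2 px merge.
* Z-scoring fit on the full table before CV leaks a small amount of
  scale information across folds; the effect is negligible at these
  sample sizes, and the per-fold mode exists where it matters
  (permutation tests).
* The E-slope is a summary of a CDF by a single ray through the origin;
  cells whose adhesion distances are strongly bimodal are poorly
  described by it.
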