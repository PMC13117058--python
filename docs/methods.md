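# Methods

This note documents the models, conventions and numerical choices behind
`paintseg`, in the spirit of the methods documentation of scanpy or
statsmodels: what each stage assumes, which parameters matter, and what
the synthetic fixtures do and do not demonstrate.

## Coordinate and naming conventions

Pixel coordinates are 0-based `(row, column)` with the origin at the top
left. In feature names, `X` is the column coordinate and `Y` the row
coordinate (the CellProfiler convention). Images are identified by the
fused name `<plate>-<RowCol>-<site>` (e.g. `BR00116991-A02-5`) on a
384-well layout (rows A–P, columns 1–24); parsing accepts 1- or 2-digit
columns and always emits the zero-padded form. The default site is 5, the
central field of a 3 × 3 acquisition grid — border fields are avoided
because objects there are routinely cut open by the frame.

The standard subset manifest assigns 28 hit, 19 diverse-non-hit, 10
positive-control and 64 negative-control wells (121 wells/plate) in
row-major order, identically on every plate; 23 plates give 2783 images.
Channel files are discovered through an explicit name → path mapping
rather than a hard-coded raw-filename dialect, so the package is agnostic
to how an acquisition center lays out its TIFFs.

## Ground-truth mask preparation

Outline annotations encode each object's border as value 255 on a 0
background. Mask recovery proceeds as: (1) invert the outline; (2) label
the interior regions as **4-connected** components — outline strokes are
8-connected, and 4-connectivity of the interiors is exactly what an
8-connected stroke seals, preventing diagonal leakage between adjacent
objects; (3) remove every region touching the image border (this deletes
the exterior background and frame-cut objects in one rule) and every
region below `min_area` (default 15 px, residual slivers between
strokes); an optional expected object count can be cross-checked when a
reference segmentation provides one; (4) dilate each instance by a square
structuring element of side `2r + 1` to reclaim the border pixels, with

```
r = max(1, round(0.5 + sqrt(mean_area) / 50))
```

— 1 px for typical cells (mean area ≲ 5000 px), growing slowly with
object size. Pixels claimed by several dilated instances go to the
instance whose nearest original pixel is closest (Euclidean), ties to the
lower label: deterministic and independent of processing order. Dilation
never reassigns original pixels, so instances never shrink or merge.

The centered ROI crop uses offset `floor((dim − size)/2)` per axis
(e.g. a 960 × 960 window at offset (60, 60) in a 1080 × 1080 frame);
objects straddling the crop are truncated, not dropped.

## Instance segmentation from confidence maps

The segmentation contract is two probability images per class (cell,
nucleus): a **class map** scoring object interiors and a **border map**
scoring boundaries, both in [0, 1]. Maps can come from any trained model
via float32/16-bit TIFFs; no network is bundled. Post-processing:

* foreground = `class_map >= class_threshold` (default 0.5);
* seeds = connected components of `class_map − border_map >= seed_margin`
  (default 0.3) inside the foreground — object cores where area evidence
  clearly dominates border evidence;
* marker-based watershed floods the border map from the seeds within the
  foreground, so touching instances split along border ridges; foreground
  unreachable from any seed is kept as its own connected components
  rather than silently dropped.

Raising `class_threshold` can only shrink the foreground (monotone), and
the output labels always partition the thresholded foreground.

A classical baseline generator stands in where no model output exists:
nuclei from the DNA channel, cells from `max(RNA, DNA)` (the RNA stain
covers cytoplasm and nucleoli but dims over chromatin), each smoothed
(Gaussian σ = 2 px), min–max rescaled, and softly thresholded by mapping
the sub-/supra-Otsu ranges linearly onto [0, 0.5] and [0.5, 1]; border
maps are the normalized Sobel gradient of the class map. This baseline is
a genuinely usable segmenter on clean data and doubles as a test driver.

A `semantic` cell mode labels the thresholded cell foreground as plain
connected components and leaves all instance separation to the
nucleus-guided refinement — useful when a model produces reliable cell
*area* but unreliable cell *borders*.

## Nucleus-guided refinement

Both operators assume predominantly mononuclear cells and use the
**rounded nucleus centroid pixel** as the ownership test (a nucleus
belongs to the cell its centroid lies in; centroids on background attach
to no cell). Rounding is half-up (`floor(x + 0.5)`) for determinism.

**Splitting.** A cell owning ≥ 2 centroids is partitioned by assigning
each of its pixels to the nearest owned centroid (Euclidean, ties to the
lower nucleus label). Parts get fresh labels above the current maximum.
For concave cells the nearest-centroid rule can produce geometrically
disconnected parts; they are deliberately kept as one label — the rule is
a stated assignment, not a re-segmentation. The operator is idempotent:
after one pass every part contains exactly its own centroid.

**Fragment handling.** A cell with no centroid and area below `min_area`
is a fragment. Default `min_area` is 0.4 × the median area of nucleated
cells in the same image (fallback 100 px when none exists) — tied to the
image's own size distribution rather than a fixed pixel count. An
isolated fragment (no 8-connected neighboring cell) is noise and is
deleted. Otherwise the fragment merges into the neighboring cell with the
**lowest mean border confidence along the shared interface** (interface =
pixels of either region 8-adjacent to the other); weak border evidence
between two regions is evidence they are one object. Ties go to the
longest interface, then the lower label. Fragments are processed in
ascending label order against the evolving mask, and passes repeat to a
fixpoint, so the result is idempotent and never retains a small anucleate
cell — a single pass cannot guarantee that when a fragment merges into
another still-small fragment.

Cytoplasm is derived per object as the cell's pixels not covered by
nucleus foreground, labels copied from the cell mask, so
`area(cell) = area(nucleus ∩ cell) + area(cytoplasm)` holds exactly.

## Feature extraction

The catalog is configuration-driven; for C channels, S granularity
scales, B radial bins and O texture offsets the column count is closed
form: AreaShape 25 + 30 Zernike, Correlation 7·C(C−1)/2, Granularity S·C,
Intensity 15·C, Location 2 + 4·C, Neighbors 5, RadialDistribution 3·B·C,
Texture 13·C·O. Defaults: the five fluorescent channels, Zernike degree
9, 16 granularity scales, 4 radial bins, 8 texture levels at offset 3,
neighbor distance 5 px. Conventions fixed where multiple dialects exist:

* **Perimeter** is the corner-corrected boundary path length (axial step
  1, diagonal √2; `skimage.measure.perimeter`, 4-neighborhood), which
  keeps `FormFactor = 4πA/P²` within [0.9, 1.05] for digital disks.
  `Compactness = 2π·E[d²]/A` is 1 for a filled disk. Feret diameters come
  from the convex hull of pixel *corner* points (never degenerate, even
  for single-pixel or collinear objects). Radii are distance-to-boundary
  statistics from the exact Euclidean distance transform.
* **Zernike magnitudes** map the object onto the unit disk via its
  centroid and minimum enclosing pixel-center radius and integrate the
  basis at pixel centers with area element `1/R²`; a solid disk gives
  `|A00| ≈ 1` and near-zero higher orders (up to a rim-digitization
  residue that decays with radius). Magnitudes are rotation invariant.
* **Intensity**: quantiles use linear interpolation; MAD is the median
  absolute deviation from the median; edge pixels are object pixels with
  a non-object 4-neighbor; MassDisplacement is the distance between the
  binary and intensity-weighted centroids (0 for zero total intensity).
* **Correlation** (7 per channel pair): Pearson (0 under zero variance),
  regression slope of b on a, overlap coefficient, Manders M1/M2 with
  Otsu thresholds computed within the object (a constant channel counts
  entirely as signal), and intensity-fraction coefficients K1/K2.
* **Granularity**: iterative grayscale openings with disk radii 1..S;
  element i is the percentage of the object's original mean intensity
  removed at scale i. Non-object pixels are pre-filled with their nearest
  object pixel's value so the spectrum probes texture, not the mask
  silhouette (a constant object yields an exactly zero spectrum), and
  successive openings are clamped pixelwise to the previous one because
  digital disks are not perfectly nested (increments stay ≥ 0).
* **RadialDistribution**: pixels bin by `d_center/(d_center + d_edge)`
  with `d_edge` the exact EDT to background — `r/R` for a disk, so a
  uniform disk's four rings carry intensity fractions ≈ 1/16, 3/16, 5/16,
  7/16. RadialCV is the coefficient of variation of mean intensity over 8
  angular wedges (empty wedges excluded).
* **Texture**: per-object min–max quantization to 8 levels (constant
  objects map to level 0); symmetric normalized co-occurrence matrices at
  0°/45°/90°/135°, pairs counted only when both pixels are in the object;
  the 13 Haralick statistics (log base 2; zero-variance statistics
  defined 0) averaged over directions with at least one pair.
* **Neighbors**: neighbor count within a disk expansion, percent of
  boundary pixels within the distance of another object,
  first/second-closest centroid distances, and the angle subtended at the
  centroid by the two closest neighbors.

`extract_all` emits one row per (object, compartment); objects with an
empty compartment (a nucleus filling its cell leaves no cytoplasm) get
all-zero rows, keeping tables rectangular. Rows are keyed by
(plate, well, site, compartment, object_id); column order is the
catalog's, so repeated runs are bit-identical.

## Evaluation, QC and prioritization

Instance matching enumerates all ground-truth/prediction label pairs with
nonzero overlap and accepts pairs in descending IoU (ties: lower labels)
at an inclusive threshold, default 0.5. At thresholds ≥ 0.5 a prediction
can exceed the threshold against at most one ground-truth object (both
masks are internally disjoint), so greedy matching coincides with optimal
maximum-cardinality matching — verified against a Hungarian oracle in the
tests. Metrics follow the count formulas above; `AP = TP/(TP+FP+FN)` is
deliberately the Jaccard-style detection score, not ranked-precision AP.
Because summary "IoU" figures in the literature may mean either, reports
include both the mean matched-pair IoU and the pixelwise foreground IoU
without claiming either reading.

Feature QC aligns objects by key, min–max normalizes each feature with
the **reference** column's bounds (a zero-range reference feature
contributes residual 0 where equal, 1 where different), and pools squared
and absolute residuals per feature group; a z-score normalization would
weight heavy-tailed features differently and is left as an alternative.
Prioritization scans features in descending variance (ties: catalog
order) and keeps a feature iff its |Pearson r| with every kept feature is
below the threshold (default 0.9); zero-variance features are always
dropped. The retained fraction is data-dependent by construction.

## Synthetic scenes

Scenes place non-overlapping elliptical cells (semi-axes 16–28 px by
default) with a concentric elliptical nucleus at 0.40–0.55 linear scale;
rendering puts DNA in nuclei, RNA over cytoplasm + nucleoli, ER/AGP/Mito
as band-limited cytoplasmic texture, and brightfield as edge-weighted
gradients, with Poisson shot noise plus additive Gaussian read noise
(σ = 120 on the 16-bit scale) clipped to [0, 65535]. One RNG stream is
derived per (seed, plate, well, site), so manifests of scenes are
reproducible element-wise. The default canvas is 512 × 512 for speed;
size is a parameter.

Two defect types can be planted to exercise refinement: a fraction of
cells drawn as merged two-lobed blobs with two nuclei (the as-drawn mask
holds the merge, the reference mask the lobe-wise split), and small
anucleate fragment blobs added as extra labels. Ideal confidence maps
(class = 1 inside objects, border = 1 on 1-px boundaries, optionally
blurred) let tests drive the watershed with a perfect model.

Scenes do **not** emulate staining heterogeneity, illumination gradients,
debris, apoptotic morphology or compound phenotypes. Passing the closure
tests (ideal maps → segmentation → refinement → AP = 1.0) therefore
validates the algorithmic correctness of the post-processing chain, not
segmentation performance on real microscopy — the latter depends on the
trained model supplying the confidence maps.

## Problem sizes and determinism

The test suite runs on 128–512 px scenes with 4–12 cells and reduced
feature catalogs where full defaults are not the point; the acceptance
script uses three 512 px scenes with 10 cells each and the full default
catalog. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); hypothesis property tests are bounded and
seeded by the framework. Reruns of any stage with the same configuration
and seed produce byte-identical artifacts.

## Known limitations

* 2-D masks only; no 3-D or time-lapse support.
* The correlation group omits Costes-style automated thresholding.
* Greedy matching is only provably optimal at IoU thresholds ≥ 0.5.
* The nearest-centroid split is a partition rule, not a boundary model —
  it will not trace a realistic membrane between touching cells.
* The baseline confidence generator is intensity-driven and will
  under-segment overlapping nuclei in dense real-world fields.
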