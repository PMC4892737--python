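# Methods

This note documents the conventions, parameter choices and assumptions
behind `phenopipe`, in the order data flows through the package.

## Image model and coordinates

Images are (H, W, 3) uint8 arrays in **red, green, blue** order everywhere
in memory; file readers convert on the way in (grayscale is promoted to
three channels, alpha is dropped) and writers emit lossless PNG.
Coordinates are 0-based and row-major: y is the row index, x the column.
Regions of interest are `[ystart, yend, xstart, xend]`, **half-open on both
axes**, so `crop(img, [2, 5, 3, 7])` yields a 3 × 4 image whose pixel
(0, 0) is input pixel (2, 3).

## Segmentation operators

* **color_filter(image, expr, roi=None)** keeps pixels satisfying a
  boolean predicate over `r`, `g`, `b` and blackens the rest. The
  expression grammar supports integer literals, `+ - * /` with standard
  precedence (division real-valued), the six comparisons, and
  `and/or/not`. The background fill is exactly (0, 0, 0); since pure black
  fails any strict channel comparison such as `g > b`, filtering is
  idempotent, and `to_binary` (foreground ⇔ any channel > 0) is exact
  rather than threshold-dependent.
* **Connectivity is 8-connected** for all component analysis: thin plant
  organs (tillers, leaf tips) frequently touch only diagonally. A
  contour's *area is its pixel count* (filled component), not a polygonal
  boundary area — this makes every area reproducible against a flood-fill
  oracle; other tools that measure polygon areas may differ slightly.
* **contour_chop(image, min_area)** removes components with area
  **strictly less than** the threshold (so `min_area=0` is the identity and
  removal is monotone in the threshold). **contour_cut(image, min_area,
  padding=0)** crops to the bounding box of components **strictly
  greater** than the threshold; it is pure cropping — small components
  inside the box survive. When nothing qualifies it raises an
  "empty plant" error carrying the observed component areas, so users can
  pick a sensible threshold. The strict-vs-inclusive choices are
  conventions fixed here and tested; the boundary case (area equal to the
  threshold) is asymmetric between the two operators by design.
* **morphological_open** operates on the binary support with a square
  structuring element (default 3 × 3, 1 iteration; pixels outside the
  image count as background), then blackens pixels whose support
  disappeared. Opening is idempotent and only ever shrinks the foreground.

## Trait catalog

Raw moments `M_ij = Σ x^i y^j` (i, j ≤ 3) are computed over foreground
pixels with weight 1 (binary masks, not intensity-weighted) in exact
integer arithmetic; when `n · d^6` could exceed 2⁶² the summation falls
back to Python bignums, so moments never overflow silently.

The **convex hull is discrete**: hull vertices come from Andrew's monotone
chain over the integer pixel centers, and the hull *area* is the count of
pixel centers inside or on the hull (exact integer point-in-polygon tests).
Consequently `density = area / hull_area` is exactly 1 for any filled
convex shape, and every hull figure is reproducible by brute force.

The composite catalog (one row per plant-day, from two side views 90°
apart plus one top view) uses these formulas, all defined in
`traits.TRAIT_FORMULAS` so they can be audited or overridden:

| trait | formula |
|---|---|
| Height_SV, Width_SV | side-view bounding box (pixels) |
| CA_SV, Area_TV | foreground pixel counts |
| PSA | CA of side view 0 + CA of side view 90 (summed, never averaged) |
| CH_SV, CH_TV | hull lattice areas |
| Den1_* | area / hull area |
| Den2_* | area / bounding-box area |
| Den3_* | 4π · area / hull-perimeter² (compactness against a circle) |
| GH1 | Width_SV / Height_SV |
| GH2 | (centroid row within the bbox + 1) / Height_SV ∈ (0, 1] |
| GH3 | √(minor/major eigenvalue of side-view second central moments) |
| GH4 | top-view eccentricity √(1 − minor/major) |
| M00–M33 per view | raw moments, suffixed `_SV0`, `_SV90`, `_TV` |

The three density variants normalise by hull, bounding box and hull
perimeter respectively; which enclosing reference a given facility's
"density" uses varies between tools, so all three are provided and named
explicitly. Color histograms default to 8 bins per channel (width 32 over
[0, 256)); counts are over foreground pixels only and proportions are
flagged undefined on an empty mask.

## Crawler

Path templates are ordered path components mixing literals with `{name}`
captures (`{name:regex}` to constrain one); a template must capture at
least `id` and `imtype`. Non-matching files are counted and reported,
never silently dropped, so parsed + skipped = total files. Timestamps are
normalised to ISO-8601 when they match a known format and otherwise stored
verbatim with an `unparsed-timestamp` flag. The metadata CSV join is a
left join keyed on the plant id: images without metadata survive and are
counted; duplicate keys in the CSV are an error. Two files binding the
same (id, timestamp, imtype, angle) are both kept, each flagged
`duplicate-key`. The images table is keyed on file path, so re-crawling
the same tree is idempotent.

## Workflow engine

Dependencies between jobs are inferred from **named slot wiring** — each
job declares which slots it reads and writes, with `raw` reserved for the
image on disk — never from list order, so a template's job list may be
written in any order. Validation reports *all* violations at once
(unknown operation, dangling input, duplicate output slot, cycle, bad
config), each naming template, job and field.

Execution is an in-process thread-pool scheduler honouring the same
template contract a distributed grid executor would; grid middleware is
environment, not method, so none is generated. One worker database per
image record mirrors the write-locally-then-aggregate pattern of cluster
execution and makes aggregation testable. A failed task blocks only its
descendants (marked `skipped`); everything else proceeds, because images
are independent and one bad file should not stop a run. Aggregation
verifies the workers share one schema, copies rows in sorted order (hence
byte-identical output under worker permutation) and never mutates a row.
All trait values are pure functions of the input image, so the final
database is invariant to concurrency level and completion order; this is
asserted at concurrency 1 vs 8 in the tests.

Each `run` writes a date-and-time-stamped directory containing the final
SQLite database (tables `images`, `traits`, `tasks`), verbatim copies of
the three templates, the metadata CSV, saved final PNGs and the worker
databases; re-runs never touch earlier directories.

## Statistics

* **Adjusted means** fit the additive fixed-effects model
  `trait ~ genotype + experiment` by least squares and evaluate each
  genotype at the unweighted average of experiment effects. On balanced
  data this equals the raw genotype mean (asserted to 1e−10). Genotype is
  deliberately treated as a *fixed* effect: a random-effects adjusted mean
  would shrink toward the grand mean by an amount that depends on variance
  components this package does not estimate, and the fixed-effect version
  is exactly reproducible. Users wanting shrinkage should fit a mixed
  model in a dedicated package.
* **Clustering** is complete-linkage agglomeration on Euclidean distances.
  Standardisation is **off by default**: moment vectors are clustered at
  their native scale (M00 and M33 differ by many orders of magnitude, and
  height-threshold cuts are defined on that scale); a `standardize` flag
  z-scores columns when wanted. Distance ties are broken deterministically
  by observation order. Dendrograms export to Newick with branch lengths
  derived from merge heights.
* **One-way ANOVA** uses the explicit between/within sum-of-squares
  decomposition (cross-checked against an independent implementation in
  the tests); groups need ≥ 2 observations each.

## Synthetic fixtures

The generator emulates the controlled imaging conditions the pipeline
assumes: a single green-dominant plant (every plant pixel satisfies
`g > b` by construction) on a uniform blue (70, 90, 200) or white
background that fails the predicate, a 12-row pot band, and small debris
blobs. The plant is a vertical stem plus straight leaves rasterised as a
boolean mask *first*; all ground truth (count, bbox, moments, hull area,
histogram) derives from that exact mask, and the plant is composited last
so every mask pixel is visible. Defaults: 200 × 200 canvas, stem 90 px
tall and 3 px thick, 5 leaves of 15–45 px, 3 debris blobs of radius 1–3 —
roughly the proportions of a young cereal seedling in a side-view frame,
scaled down from multi-megapixel platform images to keep the suite fast.

Debris defaults to colors failing `g > b`, so the background-removal stage
alone cleans it; `hard_noise=True` produces green-like debris that
survives the filter and is removable only by `contour_chop`, exercising
the noise-reduction stage non-trivially (the generator records each
blob's area so thresholds can be chosen against ground truth). Debris is
kept ≥ 2 px clear of the plant so components never merge.

What the fixtures do **not** emulate: shadows and specular highlights,
blur from plant movement, occlusion by pot or support structures,
overlapping organs, perspective distortion, and color gradients across the
background. Passing the exact-recovery tests therefore shows the operator
chain is *correct*, not that the default `g > b` rule is sufficient for
any particular real imaging setup — on real data the filter expression and
area thresholds must be tuned on representative images, which is precisely
what the template workflow is for.

`generate_trait_table` plants k multivariate-normal groups (unit
within-group σ, consecutive means `effect_size` apart along the first
trait) for clustering and ANOVA calibration; at `effect_size=0` the ANOVA
type-I error is checked against the binomial 95% interval over 400
replicates.

## Problem sizes and numerical notes

The test suite and acceptance script run at desk scale by choice: 50–200
synthetic plants per segmentation check, 200–500 random masks against the
brute-force oracles (≤ 64 × 64 and ≤ 12 × 12 respectively), an 18-image
tree (2 plants × 3 days × 3 views) for the end-to-end workflow and a
210-file tree for the crawler round trip, 20 planted tables for clustering
and 400 replicates for calibration. Segmentation, moments, component
areas, hull areas and PSA are asserted *exactly* (integer equality);
floating-point comparisons (adjusted means, ANOVA against the independent
oracle) use absolute tolerances stated in each test. Degenerate inputs are
defined rather than undefined wherever possible: empty masks give all-zero
moments and empty contour lists, a fully-background image propagates
through every operator except `contour_cut`, which raises; empty-mask
centroids, dimensions and hulls raise with a clear message.

## Known limitations

* No fluorescence-specific calibration or hyperspectral support; no
  mean-shift segmentation; no GUI.
* The trait catalog's Den/GH formulas are this package's documented
  conventions; other tools using the same trait *names* may compute them
  differently, so cross-tool comparisons should be made at the formula
  level.
* The scheduler is single-machine; scaling beyond one node is out of
  scope, though the per-worker-database aggregation contract is the same
  one a distributed deployment would use.
* Mixed-model (random-genotype) adjusted means and GWAS are out of scope.
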