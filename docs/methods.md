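# Methods

`lhseg` identifies dye-labeled hematopoietic stem cells (HSCs) in
multi-channel 3D fluorescence stacks of mouse calvarium bone marrow and
measures their minimum 3D distances to two niche components: GFP+
osteoblasts and second-harmonic (SHG) bone collagen.  This note
describes the models and procedures, the parameters that matter, the
synthetic data used to validate them, and the numerical conventions.

## Image model

A stack is a set of channels on a common `(z, y, x)` voxel grid with
physical calibration `(dx, dy, sd)` in micrometers: square in-plane
pixels (0.4–1.2 um typical) and a much coarser z step (1–5 um; one
slice = one voxel in z).  All geometry is computed in pixel units with
the z index scaled by `sd/dx`, and converted to micrometers only when
reported.  Intensities are non-negative; 8-bit data is typical but
nothing depends on the bit depth.

## Local-heterogeneity segmentation (LH-SEG)

Segmentation runs on each 2D slice independently: depth-dependent
signal loss makes adjacent slices systematically dimmer, and any 3D
operation would bias edges in z.  Three steps per slice and channel:

1. **Smoothing.** One 3x3 Gaussian convolution (`preprocess.sigma`,
   default 0.4 px; reflect borders).  The small kernel reduces the
   pixel-level heterogeneity that would fragment region merging while
   moving edges by well under a pixel.  The kernel size is fixed; only
   sigma is configurable.

2. **Multi-resolution region merging.**  Every pixel starts as a
   segment; adjacent segments merge while the *fusion cost* — the
   increase in area-weighted color standard deviation plus a shape term
   mixing compactness (`perimeter/sqrt(area)`) and smoothness
   (`perimeter / bounding-box perimeter`) — stays below the square of
   the scale parameter `alpha`.  Merging is *mutual best fitting*:
   segments are scanned in a seeded random permutation, and a pair
   merges only if each is the other's cheapest admissible partner (ties
   to the lowest segment id).  Larger `alpha` gives fewer, larger
   segments; the final count is non-increasing in `alpha`.  The
   incremental bookkeeping (area, channel sums and sums of squares,
   perimeter via shared-border contraction, bounding boxes) is verified
   in the test suite against a naive implementation that recomputes
   every statistic from raw pixel sets.

3. **Mean-difference-to-neighborhood (MDN) merging.**  After step 2 an
   object of interest is typically split into several segments (bright
   core, dimmer rim, intensity tiers of an osteoblast cluster).  The
   MDN of a segment is the weighted mean signed difference between its
   mean intensity and those of the segments within a distance `d`;
   a segment whose |MDN| is below a class threshold `T` merges with its
   most-similar neighbor, in rounds, until every region stands out from
   its neighborhood by at least `T`.  Conventions:

   * Neighbor weights default to shared-border length; the literal
     reading (weight = absolute mean difference) is available as
     `weighting="intensity_diff"`.
   * `d` is object-adaptive by default: the effective radius
     `perimeter/(2*pi)` of the segment, clamped to >= 1 px, so small
     cells consult a tight neighborhood and large structures a wide
     one.  A fixed `d` is available per class.
   * An admissible merge partner must itself differ by less than `T` in
     mean intensity.  Without this guard a region squeezed between a
     much brighter and a much darker neighbor has a small *cancelling*
     MDN and would be absorbed by whichever side happens to be closer
     in intensity — in practice dim osteoblast tiers would vanish into
     the background.
   * Merging decisions use |MDN|; the reported statistic is signed.

   Surviving regions are split into foreground and background by mean
   intensity (class-specific cutoff; an Otsu threshold over region
   means is the parameter-free fallback), and foreground regions below
   `min_object_area` pixels are discarded as unanalyzable debris.  A
   slice that collapses to a single region is all background.

### Per-class defaults

One parameter set is used for all datasets (that is the point of the
method); the shipped values were calibrated once on the synthetic
benchmark suite and follow the qualitative logic that bright
low-heterogeneity dye objects need a high `T` and tight `d`, while
large heterogeneous osteoblast clusters and bone need a lower `T` and
wide `d`:

| class      | alpha | T (MDN) | d            | min area | foreground cutoff |
|------------|-------|---------|--------------|----------|-------------------|
| did        | 15    | 90      | auto         | 5 px     | 60                |
| osteoblast | 20    | 40      | 8 px fixed   | 20 px    | 30                |
| bone       | 30    | 40      | 12 px fixed  | 20 px    | 40                |

Shape weight 0.1, compactness weight 0.5, scan seed 0 everywhere.  All
values are plain config data (`PipelineConfig`).

## z-linking

2D objects in adjacent slices belong to the same 3D object when their
(y, x) footprints overlap by at least `overlap_fraction` (default 0.1)
of the smaller footprint; the transitive closure defines the 3D
objects.  In the limit `overlap_fraction -> 0` this is exactly
face-connected 3D component labeling (verified against it).  Objects
absent from an intermediate slice break the link by default
(`max_gap = 0`); single-slice objects (coarse z steps) are retained and
flagged.  For tiled mosaics, objects split by a tile seam are re-joined
by 4-adjacency within each slice before linking.

## Features and classification

Each 3D dye-channel object gets a deterministic feature vector:
physical volume and surface area (marching-cubes mesh over the voxel
mask, anisotropic spacing), sphericity, border roughness (surface area
over sphere-equivalent area), elongation (sqrt of extreme eigenvalue
ratio of the physical coordinate covariance), max protrusion ratio,
bounding-box compactness, convex-hull solidity, intensity mean/SD/skew,
and per-slice gray-level co-occurrence contrast and homogeneity
(offset 1 px, four directions, volume-averaged).  The protrusion ratio
is the longest radial excursion beyond the volume-equivalent radius,
in units of the equivalent diameter: a value above 1 means a
protrusion longer than the object's own main diameter — the hallmark
of debris, versus the sub-diameter uropod of a migratory cell.
Degenerate conventions (single voxel: sphericity 1, protrusion 0,
elongation 1) are fixed so tiny objects never produce NaN.

Objects are classified into HSC-Class-1 (round, smooth), HSC-Class-2
(uropod-bearing), and False-HSC (debris/aggregate) by a CART decision
tree grown with Gini impurity and pruned by minimal cost-complexity,
with pruning strength selected by 3-fold cross-validation.  The tree is
implemented in-house rather than delegated to a library for one
substantive reason: with training sets of 2/5/11 objects, many features
split the training data perfectly, and the choice among these tied
splits decides generalization.  Library implementations break such
ties arbitrarily (effectively at random); here ties go to the split
with the widest *relative* margin (gap between the separated groups
divided by the feature's value spread at the node), then to the
alphabetically first feature.  A reference CART implementation serves
as an independent cross-check in the tests, never as the classifier.
Leaf ties resolve by the fixed class order HSC1 < HSC2 < FALSE.  Models
serialize to JSON (feature names and thresholds), keeping the selected
features inspectable.

The built-in default model is trained on curated synthetic archetypes
at the study's training sizes — 2 round cells, 5 uropod-bearing cells,
11 debris objects — chosen to tile each class's shape-parameter range
(annotators pick training objects representative of the spectrum, not
at random).  The archetype renders are passed through the segmentation
pipeline before featurization, so the model is trained on the same
kind of imperfect masks it will classify; debris annotations are drawn
from everything segmentation produces (cores *and* protrusion
fragments), spanning the size spectrum.

## 3D localization

Object surfaces are the voxels with at least one of six face neighbors
outside the object.  The minimum distance between a cell and a target
class is the global minimum over all surface-voxel pairs of

    dist = sqrt(dx_px^2 + dy_px^2 + (dz_slices * sd/dx)^2)

i.e. the z index is scaled into x/y pixel units before the Euclidean
norm; multiplying by `dx` converts to micrometers (requires square
in-plane pixels; anisotropic in-plane data must be resampled first).
The search is KD-tree accelerated and verified exactly against the
exhaustive all-pairs scan.  Face-touching objects report exactly 0,
matching the manual benchmarking convention.  Witness points (nearest
voxel on each side) are reported for visual QC.  Cells with no target
object in the volume yield infinite-distance records that summaries
exclude with a logged count.

## Evaluation framework

* Mask accuracy: pixel tallies TP/FP/FN of automated vs manual masks,
  Jaccard `TP/(TP+FP+FN)`, precision `TP/(TP+FP)`, recall
  `TP/(TP+FN)`.  The benchmark protocol is 2D (a chosen slice); a 3D
  variant with identical arithmetic exists for synthetic volumes but is
  not the benchmark.
* Distance accuracy: an automated measure matches its manual
  counterpart when they differ by at most 5 um (the error margin of
  manual 3D measurement; boundary inclusive), and
  `%Error = 100 * |n_benchmark - n_matched| / n_benchmark`.
* Display rounding: precision/recall to two decimals, percent error to
  one; machine outputs keep raw floats.

## Synthetic scenes

The generator emulates the imaging regime the method was designed for,
at desk scale (96 x 96 px in-plane, 4–12 slices; real stacks are
512 x 512 and up — the reduction is purely computational, chosen to
keep the full validation suite in the minutes range on one CPU):

* dye channel: bright (~200/255) roundish cells of radius 3.2–4.3 um,
  some with a uropod 0.45–0.75x the cell diameter; debris with cores
  of 1.8–2.8 um and 1–2 thin protrusions 1.6–2.6x the core diameter;
  background autofluorescence (~8);
* osteoblast channel: clusters of 2–3 polygonal patches in three
  intensity tiers (200/140/80), the heterogeneity that defeats global
  thresholds;
* bone channel: a slab with ellipsoidal cavities (~150).

Rendering uses sub-voxel partial-volume coverage (3x3x3 subsampling of
the continuous object surfaces) so the 50% isophote coincides with the
truth boundary, exactly as sampled fluorescence behaves; truth masks
are the voxels whose centers lie inside the surface.  Signal decays as
`exp(-k * depth_um)` (k = 0.01/um default) and Gaussian read noise
(SD 5 on the 8-bit scale) is added last, with optional Poisson shot
noise.  Placement is mask-based with a 2 px in-plane / 1 slice z
clearance so objects never touch (doublets are out of scope), except
for the explicit touching cell–osteoblast pair used to exercise the
zero-distance rule.  Each scene ships truth label masks per channel
and a truth table with classes, centroids, and brute-force surface
distances.

The 10-scene benchmark suite varies z step over 1–5 um (slice count
adjusted to keep total depth ~16 um), brightness 0.7–1.3x, attenuation
0.005–0.015/um, and debris load 2–6 — the acquisition variability the
single-parameter-set claim is about.

What the scenes do **not** contain: optical PSF blur, scattering
artifacts, motion, cell doublets and dividing cells, and non-specific
staining gradients.  Passing the synthetic benchmarks therefore bounds
performance from above; it demonstrates correctness of the machinery
and adequacy of the parameter logic, not field performance on real
stacks.

## Numerical and design notes

* All randomness (segmentation scan order, classifier CV folds, scene
  content) is owned by explicit seeds; the pipeline is a pure function
  of (stack, config, seeds) and reruns bit-identically.
* 4-connectivity in-plane and 6-connectivity in 3D throughout, so
  thin structures cannot leak diagonally.
* Fusion costs and MDN values compare with strict `<` against their
  thresholds; cost ties during merging resolve toward the lowest
  segment id.
* Segment statistics are maintained incrementally (sums and sums of
  squares); population (not sample) standard deviations are used.
* Sphericity and solidity are clamped to <= 1 (discretization can push
  the raw ratios slightly past the continuum bound).
* Known limitations: touching cells of the same channel merge into one
  object (explicitly out of scope); the per-slice design can split a
  cell whose footprint vanishes in an intermediate slice unless
  `zlink.max_gap` is raised; pure-Python region merging processes a
  512 x 512 slice in seconds, so mosaics should use the tiled path.
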