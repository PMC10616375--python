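# Methods

## Scope and model of the data

`henuclei` implements a whole-slide H&E analysis pipeline at desk scale:
patch preprocessing, multi-task nuclei instance segmentation with
flow-field post-processing, nucleus typing, nuclear morphometrics,
panoptic-quality evaluation with bootstrap confidence intervals, and a
downstream feature-vs-ploidy correlation analysis. Real tumour slides and
their pathologist annotations are not redistributable, so the package
ships a first-class synthetic-data module that generates ground-truthed
H&E-like patches and cohort tables; every other module is specified,
tested and exercised against that ground truth.

Five nucleus classes are used throughout: neoplastic, inflammatory,
connective, dead, and (non-neoplastic) epithelial, encoded 1..5 with 0 as
background.

## Synthetic scenes

A scene is a set of elliptical nuclei rendered on a pale eosin-pink
background (default RGB 233/206/216), with per-class hematoxylin-like
colours, per-nucleus intensity jitter (+/-10 8-bit units) and i.i.d.
Gaussian pixel noise (sigma = 6). Nuclei are placed by rejection
sampling: a candidate ellipse is accepted only if it overlaps previously
placed nuclei by at most `max_overlap_fraction` (default 0.15) of its own
area and steals at most that fraction of any victim's area; contested
pixels belong to the later-placed nucleus, so the label map is
single-valued like real H&E instance masks. Axis ranges are full axis
lengths in pixels (defaults 14-30 major, 9-18 minor at the default
256x256 / 100-nucleus scene), sized so that a default scene reaches about
33% nucleus coverage with frequent touching pairs. The default class mix
(38/18/36/0.1/7.9%) follows the cell-type distribution reported for
annotated ovarian-carcinoma validation regions. Placement failure after
200 tries per nucleus raises an "overcrowded" error rather than silently
under-filling.

What the generator does *not* model: chromatin texture, stain variation
between slides, out-of-focus blur, pen marks, scanner point-spread, and
stromal eosin texture (the background is a flat colour). Tests passing
on these scenes therefore demonstrate the correctness of the machinery
(targets, recovery, metrics, statistics), not segmentation performance on
real tissue.

Because the background is flat, HSV-saturation tissue detection marks
only the nuclei themselves (~10-15% of a covered patch), not the
"tissue" region; callers tiling synthetic pseudo-slides should set
`min_tissue_fraction` around 0.02-0.05 instead of the real-tissue default
0.1.

## Preprocessing

`tile_image` partitions an image into a row-major grid of patches
(default 1250 px, the pipeline's native patch size), non-overlapping by
default, with reduced-size remainder patches at the right/bottom edges so
patch footprints exactly cover the image. `tissue_mask` applies Otsu's
threshold to the HSV saturation channel (stained tissue is saturated,
glass is not) and removes specks below 16 px. `filter_patches` keeps a
patch iff tissue fraction >= `min_tissue_fraction` (default 0.1) AND
grayscale standard deviation >= `min_std` (default 5); each rejection
records which filter fired. The two-filter design is deliberately
minimal and replaceable; filtering is monotone in both thresholds.

## Segmentation network

The network follows the HoVer-Net family contract — one shared encoder,
three task-specific decoders — emitting per-pixel foreground probability,
a 6-way class distribution, and a (distance, flow) field pair. It is a
small fully convolutional net implemented directly in numpy with
hand-written backpropagation: two encoder stages (3->C->C, then a single
2x average-pool downsampling into 2C channels), and per decoder an
upsample + 3x3 convolution fused with a 1x1 skip projection of the
full-resolution encoder features, one 3x3 mid convolution, and a 1x1
head. Default width C = 16. Convolutions use im2col + matmul; gradients
are verified against central differences in the test suite. Training
uses Adam (lr 5e-3) on float32, full patches, batch size 4, 300 epochs
by default — about 2.5 minutes on one CPU for 8 patches of 64x64.

Losses: sigmoid cross-entropy for the foreground head, softmax
cross-entropy for the class head, and mean-squared error for the distance
(regressed as dist/5 to balance head magnitudes) and flow heads, the flow
loss averaged over foreground pixels only. This is simpler than the
Omnipose objective; it is sufficient for the desk-scale training runs the
package targets.

`predict_image` performs tiled whole-image inference: tiles overlap by
2*margin (default margin 8 px, comfortably larger than the receptive
field), only each tile's central region is kept, and the image is
reflect-padded at borders; for a fully convolutional net the stitched
fields are identical to monolithic inference away from the outer border.
All stochasticity (weight initialisation) flows from `ModelConfig.seed`;
training is deterministic, and checkpoints (a single `.npz` with the
config embedded) reload to bit-identical outputs.

## Flow post-processing

Training targets: per instance, the Euclidean distance transform to the
instance's own boundary, computed inside a 1-px-padded bounding box so
touching nuclei do not bleed into each other; the flow is the
central-difference gradient of the Gaussian-smoothed (sigma 1) distance,
normalised to unit length on foreground. The Euclidean transform is used
instead of an eikonal field: it is cheaper and has the same single-sink
structure at nucleus scale (very elongated or non-convex objects are
where the two differ).

Recovery: every foreground pixel is advected by forward Euler,
`x <- x + step * flow(round(x))`, with nearest-pixel lookup (no bilinear
interpolation), step 1.0, 200 steps, clamped to the image. Terminal
positions are binned to pixels; the hit bins are dilated by
`merge_radius` (2 px) and 8-connected components of the dilated sink mask
define instances, labelled 1..n in raster order of their first sink bin.
Instances below `min_area` (10 px^2) are removed. The whole module is
deterministic.

Known failure mode, preserved intentionally: a very large nucleus whose
smoothed distance field has several well-separated maxima can fragment
into multiple detections; the pipeline still detects at least one
instance per such nucleus, and a regression test pins this behaviour.

Nucleus typing: an instance's class is the argmax over the five cell
classes of the summed per-pixel class probabilities inside it, ties
broken to the lowest class index.

## Morphometrics

Eight features per nucleus: area (pixel count, or shoelace area on the
polygon path), perimeter (Crofton, or ring length), major/minor axis
(moment-matched ellipse), eccentricity sqrt(1-(b/a)^2), aspect ratio a/b,
solidity (area / convex hull area), and volume. Volume is defined as the
prolate spheroid swept by rotating the moment ellipse about its major
axis, V = (4/3) pi (major/2) (minor/2)^2 — an explicit interpretation of
"nuclear volume" from a 2-D section, stated here because no standard
definition exists. Degenerate (line/point) instances get a 1-px minor
axis floor and a `degenerate` flag; eccentricity and aspect ratio are
recomputed from the floored axes so the internal identities always hold.
Units are pixels; a `microns_per_pixel` scalar converts lengths, areas
and volumes.

Composition summaries report per-class counts, percentages and the
Shannon index H = -sum p_i ln p_i (nats by default; the log base is a
parameter). Per-sample summaries take the median and unbiased (n-1)
variance of each feature over **neoplastic nuclei only**, matching how
tumour samples are summarised for the ploidy analysis; a sample with no
neoplastic nuclei is an error, never a silent zero.

## Panoptic evaluation

Matching uses pixel IoU with the strict threshold IoU > 0.5; above half
overlap the matching is provably unique, so no assignment algorithm is
needed (the test suite still checks equality with an exhaustive optimal
assignment oracle on 500 random map pairs). Matching is class-aware by
default, with a class-agnostic "all" mode, and a class subset can exclude
rare classes from scoring entirely (both prediction and ground truth).
Then DQ = TP/(TP + FP/2 + FN/2), SQ = mean IoU over matched pairs,
PQ = DQ*SQ. A class with no instances on either side has *undefined*
metrics, reported as None rather than 0 to avoid biasing summaries.

Bootstrap CIs resample the evaluated regions (ROIs) with replacement,
n = 200 rounds by default, recompute pooled TP/FP/FN and IoUs per round,
and take 2.5/97.5 percentiles. The resampling unit is the ROI, not the
cell — per-cell resampling would break instance pairing. Rounds where a
class vanishes are dropped for that class with a logged count.

## Ploidy analysis

Spearman's rho is the Pearson correlation of mid-ranks; the two-sided
p-value uses the t approximation t = rho sqrt((n-2)/(1-rho^2)) on n-2 df
(the default of common statistical software at cohort sizes around
n = 47), with an exact permutation p available for n <= 10. The one-way
fixed-effects ANOVA of ploidy on the three anatomical sites (omentum,
peritoneum, tubo-ovarian) computes between/within sums of squares
directly, with F = 0, p = 1 for a flat ploidy column. Long-format tables
repeat ploidy per feature row and are deduplicated by sample first.

Outlier handling is caller-specified by sample id only (mirroring the
exclusion of slides with technical artifacts after visual inspection);
no automatic rule is implemented, and exclusions are always recorded in
the reports. No multiple-testing correction is applied across the
feature x statistic tests; p-values are raw.

The synthetic cohort generator draws (ploidy, median, variance) through
a Gaussian copula: the target Spearman rho maps to the latent Pearson
correlation r = 2 sin(pi rho / 6), exact for bivariate normals, so the
population Spearman equals `true_rho` and the comonotone limit rho = 1
is exact at any n. Defaults follow the cohort analysed downstream: 47
samples split 18/12/17 across the three sites, site labels independent
of ploidy, ploidy uniform on 1.5-6.

## Pipeline

`pipeline.run` executes tile -> filter -> tiled inference -> flow
post-processing -> GeoJSON export -> morphometrics CSV -> composition
JSON, and writes a manifest recording the config, seed, per-stage counts
and every output file. Predicted fields from all kept patches are
stitched into canvas-sized arrays and post-processed *once*, so nuclei
straddling patch borders are recovered as single instances rather than
per-patch fragments (the cost is holding ~10 float fields of the full
canvas in memory, acceptable at the image sizes this package targets).
The GeoJSON polygon file is the hand-off between segmentation and
feature extraction: polygons are orders of magnitude smaller than label
masks at slide scale.

Coordinate convention (the source material never states one): x = column,
y = row, 0-based; a pixel is the half-open unit box [x, x+1) x [y, y+1),
polygon vertices lie on the box lattice, exterior rings are
counter-clockwise, holes are filled before tracing (nuclei are simply
connected by assumption). Rasterisation tests a pixel's centre, making
the GeoJSON round trip exact for lattice polygons. Class names use the
QuPath dialect under `properties.classification.name`, matched
case-insensitively with "non-neoplastic epithelial" accepted for
epithelial. Label masks persist as 16-bit PNG (>255 nuclei per patch);
patches as `x{col}_y{row}.png`.

## Problem sizes and numerical choices

The shipped experiments are sized for a single CPU: training uses 8
patches of 64x64 with ~8 nuclei each (2-3 minutes for 300 epochs);
flow-recovery and evaluation scenes are 256x256 with 100 nuclei;
ploidy calibration uses 200-500 replicate cohorts of n = 47. The
acceptance script (`scripts/acceptance.py`) re-runs all of these from a
single `--seed` and reports: ground-truth flow round-trip PQ (~0.99),
tiny-overfit PQ (~1.0), held-out PQ/DQ/SQ on unseen scenes from the same
distribution (~0.95/0.99/0.96) with a 200-round bootstrap CI, mean
recovered Spearman rho at truth 0.5 (~0.49), power (~0.96) and type-I
error (~0.04-0.06) at alpha = 0.05, and the site-ANOVA type-I rate
(~0.05). Numerical tie-breaks are fixed everywhere (lowest class index
on type ties, raster order for instance labels, later-feature-wins on
polygon overlap) so all outputs are reproducible bit-for-bit under a
fixed seed.

## Limitations

- The network is desk-scale by design; it demonstrates the multi-task
  contract and post-processing, not state-of-the-art segmentation.
- Euclidean distance targets diverge from eikonal fields on strongly
  non-convex nuclei; large nuclei can fragment (see above).
- Tissue detection is a two-filter minimum, with no stain normalisation
  or artifact (blur/pen) detection.
- The synthetic stain model is flat-colour; colour-based class heads
  will find real H&E much harder than these scenes.
- MIRAX/OME pyramid decoding and scanner metadata are out of scope;
  inputs are plain raster images.
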