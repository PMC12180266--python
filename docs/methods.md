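# Methods

This note records the models, conventions and numerical choices behind each
metric family, what the synthetic generators do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## Coordinate and data conventions

All coordinates are µm, origin at the image top-left, x rightward, y
downward.  A mask pixel (row *i*, col *j*) covers the half-open square
[j·s, (j+1)·s) × [i·s, (i+1)·s) for pixel size *s*, so every point belongs
to exactly one pixel and transcript-to-cell assignment is unambiguous.
Platform dialects are declarative column maps (generic, MC-like,
Merscope-like, Xenium-like); MC-style files carry pixel coordinates and
require an explicit pixel size at load time.  z is a plane index where the
source records discrete planes and µm otherwise; conversion needs an
explicit plane spacing.  Background-probe records stay in the transcript
table (specificity needs their coordinates) but are excluded from
cell-by-gene matrices unless requested.

## Sensitivity

Spatial bins are squares of side (d/2)·√π, the square of equal area to a
circular spot of diameter d (48.74 µm for d = 55 µm).  The grid anchors at
the data bounding-box minimum — the choice is arbitrary in principle, and a
data-driven anchor makes results deterministic without configuration.  Bins
are half-open; empty bins inside the bounding box are kept so that count
distributions are not truncated.  Features are genes with count > 0.

Per-cell medians carry a standard error from a 1,000-replicate seeded
bootstrap; the median's SE has no convenient closed form at small n and the
bootstrap is assumption-free.  Cross-platform gene means are compared on
log₁₀(mean + 0.01): per-gene means span orders of magnitude and the log
stabilizes low expressors; the pseudocount (configurable) keeps zero-mean
genes finite while perturbing means ≥ 0.1 by < 5 %.  Detection-efficiency
anchoring multiplies the iST/reference fold range by the reference assay's
known efficiency range and clips at 1; it inherits the assumption that
panel composition effects average out across samples.

## Specificity

The global FDR is evaluated on raw whole-tissue call totals
(segmentation-free), so it is invariant to record order and tiling.  It
equals the mean per-background-probe call count expressed as a fraction of
the mean per-target-gene call count; equal per-probe rates give exactly
100 %.

Moran's I uses dense inverse-distance weights w_ij = 1/d_ij between cell
centroids with zero diagonal and **no row standardization** — the weight
construction is "1 divided by the distance matrix" and row scaling would
change the statistic.  Coincident centroids are an error (named pair), as
the weight is undefined.  The implementation is the direct quadratic form
(the O(n²) weight matrix is computed once per dataset and shared across
probes); it matches an explicit double-sum oracle to 1e-10 and reproduces
the closed forms I = −1 at n = 2 and permutation mean −1/(n−1).  Zero-
variance probes have no measurable spatial signal and yield NaN.

Min–max scaling of Moran's I to [0, 1] uses all probes of one dataset
(targets and backgrounds jointly) so both kinds share one axis.

Median NN distance is the median over a probe's calls of the Euclidean
distance to the nearest other call (kd-tree).  For a homogeneous Poisson
process of intensity λ the median is √(ln 2/(πλ)) — the quantitative
signature of a spatially random (background-like) probe.

Low-confidence classification: probes with valid Moran's I and NN distance
are split into four equal-count strata by scaled Moran's I (the stratum
boundaries of the original analysis are not derivable from first
principles, so equal-count quantile bins are the default and the count is
configurable).  Within a stratum the threshold is the q = 0.95 quantile of
the *background* probes' median NN distances (all probes of the stratum if
it has no background).  A target is flagged iff its NN distance exceeds the
threshold (background-like randomness) **and** its total count is within
the background range.  Both conditions are required by design: the whole
point of the spatial criterion is to rescue low-count but spatially
structured probes, and a high-count probe is never flagged regardless of
pattern.  Raising q raises thresholds, so the flag count is monotone
non-increasing in q.  The flag direction and q are configurable because the
opposite convention (flagging the lowest NN quantile) appears in informal
descriptions of such filters; the direction used here is the one under
which spatially random probes fail.

The nuclear fraction is the fraction of calls on labeled mask pixels;
z-plane histograms flag truncation when an edge plane exceeds half the
modal plane's count (configurable), the signature of a stack clipping the
axial extent of the sample.

## Optical metrics

FWHM: the peak is the (interior) maximum sample of a 1-D profile through
the detected intensity maximum — no sub-pixel refinement, matching the
extract-pixels-at-peak procedure.  The baseline is the smaller of the two
profile end samples (a zero baseline would overestimate widths on offset
backgrounds; a fitted background is overkill for short profiles), and the
two half-maximum crossings are linearly interpolated.  The measure is
exactly invariant to positive affine intensity maps.  On a Gaussian sampled
at ≥ 3 points per FWHM the interpolation bias is ≈ 1 %.  Bead summaries
report median ± MAD per axis over beads, with the in-plane figure pooling
x and y widths; beads whose profile touches a stack face are skipped.

SNR/SBR operate on 21-sample line profiles after subtracting the darkest
image pixel.  The background annulus is the 10 outermost samples
(|x| > 5); σ_bg is the sample standard deviation (ddof = 1).  σ_bg = 0 and
µ_bg ≤ 0 are errors, not values.

## Stitch deduplication

Tile-grid lines are the multiples of the tile size inside the data extent,
in x and y.  Per line: same-gene pairs with both members within the window
and on opposite sides are candidates, drawn from genes with fewer than
`max_copies` (400) calls in the window.  The consensus shift is estimated
from the pair offsets of genes occurring at least `min_occurrences` (10)
times in the window: offsets are binned at 1-unit resolution, the modal bin
must hold at least 3 pairs, and the consensus is refined to the
component-wise median of the offsets in that bin.  Pairs matching the
consensus within 0.5 units per axis (and 1.0 in z when present) are
collapsed greedily in order of offset error, removing the member farther
from the line.  The half-unit matching tolerance is deliberate: stitching
shifts are globally consistent, so true duplicates match the sub-pixel
consensus almost exactly, while a full-pixel box admits a measurable rate
of coincidental same-gene matches at realistic border densities.  The
minimum-vote rule makes the operation idempotent in practice: on
duplicate-free data no offset bin accumulates enough support to form a
consensus.  Either member of a pair is "the duplicate" — the algorithm
cannot and need not distinguish which record came from which tile — so
recovery is assessed as one-member-per-planted-pair removed.

## Neighborhood enrichment

The graph is exact Euclidean 10-NN on cell centroids (kd-tree, ties broken
by smaller index).  The observed statistic for the ordered pair (a, b) is
the count of type-b cells in the neighbor lists of type-a cells; the raw
count (rather than per-cell compositions) weights every neighbor slot
equally and keeps the null analytically simple.  The null permutes labels
over cells with the graph fixed (default 10,000 permutations; the suites
use 1,000, which resolves p ≥ 1e-3 and is sufficient for calibration
checks at α = 0.05).  z = (obs − mean)/sd over the null; two-sided p with
add-one correction, so p ∈ (0, 1]; pairs with zero null variance are
masked, not errors.  BH adjustment (statsmodels) controls the FDR across
all pairs; non-significant pairs carry a mask flag.  Enrichment is
directional and the z matrix is not symmetrized.

## Synthetic data: what it does and does not emulate

The tissue generator reproduces the statistical structure the metrics
rely on: a hard-core point process of nuclei (minimum separation twice the
4 µm nucleus radius, so rendered labels never touch), disc nodules
defining a nodular vs internodular compartment with distinct cell types
and marker panels, per-cell detected counts Poisson(ε·λ_g) under a global
detection efficiency ε (default 0.35, the anchored iST estimate),
transcript positions uniform in the nuclear disc, and background probes as
homogeneous spatial Poisson processes — the null under which technical
false positives are randomly distributed.  Defaults describe a dense
1 mm² pediatric-tumor-like field (1,500 nuclei/mm², nodules of 120–180 µm
radius, background probes at a few hundred calls/mm² so their counts
bracket low expressors).  One seed sequence spawns an independent child
stream per component (placement, typing, counts, positions, background),
so each layer is reproducible on its own.

Not emulated: cell shape beyond discs, cytoplasmic transcripts, optical
crowding, autofluorescence, segmentation errors, probe-sequence effects
and panel-design biases.  Passing suites therefore demonstrate the
*estimators* are correct under their stated models, not that any platform
meets a particular number on real tissue.

Bead stacks render separable 3-D Gaussians plus Gaussian read noise; bead
centers snap to voxel centers by default because the measurement pipeline
deliberately has no sub-pixel refinement, and an off-center brightest
voxel would bias the half-maximum level by up to ~6 % at 108-nm pixels —
the snapped geometry isolates the estimator's own error (≈ 1 %).

Spot profiles realize the requested SNR/SBR in each profile's *sample*
statistics: the background noise vector is standardized to exact sample
mean µ_bg and sd σ_bg = µ_bg(SBR−1)/SNR before scaling, and the center is
SBR·µ_bg.  SNR and SBR are defined through those sample statistics, and a
construction that only matched them in expectation would make the
prescribed (I(0) − µ̂)/σ̂ estimator read ≈ 9 % high at 10 background
samples (E[σ/s] for 9 df) — a property of the estimator, not of the
optics, and exactly what a calibration fixture should exclude.
SBR ≤ 1 or SNR ≤ 0 imply σ_bg ≤ 0 and are rejected; σ_bg → 0 is the
degenerate limit of the sample-sd estimator.

## Problem sizes

The test and acceptance suites run the discrimination study on 0.64 mm²
fields (~770 cells, 25 background probes, 20 replicates), deduplication on
24,000 transcripts over two 2144-px tiles (three rates × three seeds),
bead recovery on six beads per stack at 300/470/600 nm, and neighborhood
calibration on 400 cells × 1,000 permutations × 20 replicates — sizes at
which every stochastic check has comfortable statistical margin while the
whole suite completes in well under a minute of compute per family.

## Known limitations

* Moran's I uses a dense O(n²) weight matrix; practical to a few thousand
  cells per dataset, beyond which a truncated or sparse weighting would be
  needed (and would change the statistic).
* The NN-distance threshold direction assumes background probes are the
  most spatially random population; panels whose backgrounds cluster
  (e.g. from optical artifacts) would need the configurable direction.
* The dedup consensus assumes one dominant shift per tile border; borders
  with mixed shifts (nonrigid stitching) would need per-segment consensus.
* `knn_graph` resolves distance ties beyond the k-th neighbor only within
  an 8-candidate lookahead; exact-tie geometries deeper than that (large
  perfect lattices) may deviate from the brute-force order.
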