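# Methods

This note documents the models, estimators and design choices behind
`actincap`, and what the synthetic benchmarks do and do not establish about
real micrographs.

## Coordinate and image conventions

Rasters are row-major with the origin at the top-left; `x` is the column
index and `y` the row index, so `y` increases downward and fiber slopes
carry image-coordinate signs. Generated images are 8-bit (binarization
maps foreground to the maximum level 255); 16-bit input is accepted by the
segmentation stage.

## Segmentation

**Binarization.** Fixed-threshold binarization applies `pixel >= t -> 255,
else 0`. When no threshold is supplied, Otsu's criterion derives `t` from
the intensity histogram; a constant image has no Otsu threshold and raises
a degenerate-histogram error rather than guessing. The default is Otsu
because the generator (and real plates) vary staining intensity between
fields, while the fixed rule is honored verbatim when a threshold is given.

**Morphology.** Erosion, dilation, opening and closing with a disk
footprint (radius >= 1 px), applied in caller-specified order. Opening with
radius 2 is the default recipe to cut 1-px bridges between touching nuclei.

**Nucleus objects.** 8-connected foreground components; components below
`min_area` (default 100 px², calibrated to nuclei at 20× magnification,
where a 40-px-diameter nucleus covers ~1250 px²) are dropped, and
border-touching components are excluded by default since their area and
perimeter are truncated. The perimeter uses the Crofton (intercept-count)
estimator: a raw boundary-step count biases the circularity of digital
disks well below 1, while Crofton keeps a radius-20 disk within ~0.5% of
the continuous value. Digital circularity can slightly exceed 1, so values
are clipped to (0, 1.05], never rescaled. "Form factor" is treated as a
synonym of circularity.

**Cytoplasm partition.** The actin foreground is split between cells by
nearest-nucleus assignment via an exact Euclidean distance transform — a
watershed-style partition with nucleus footprints as seeds. A nucleus with
no actin foreground beyond its own footprint keeps the footprint as its
region and is flagged `low_quality`; downstream it contributes zero fibers.

## Fiber detection and dispersion statistics

Straight segments are detected with a seeded probabilistic Hough transform
restricted to the per-cell binary foreground (defaults: accumulator
threshold 10, `min_length` 20 px, `max_gap` 3 px, chosen for 2-px-wide
fibers at 20×). Near-collinear duplicate detections are suppressed by
keeping the longest segment and discarding others whose midpoint lies
within 3 px (1.5× the rendered stroke width) of it at an axial angle
difference below 7.5°. Two true fibers closer than the stroke width are
physically merged in the image and cannot be told apart; the benchmarks
therefore require >= 9 of 10 recovered, not all 10.

**Slope SD.** The per-cell statistic is the *population* standard
deviation (divisor N) of fiber slopes, exactly as defined, with
`slope = (y1 - y2)/(x1 - x2)`. Slopes diverge near vertical, so segments
with `|x1 - x2| <= 1 px` are flagged vertical, excluded from slope
statistics and counted separately; with fewer than two usable slopes the
statistic is a missing-value marker (NaN), never 0. Slope SD is
translation-invariant and invariant under uniform scaling.

**Angle dispersion.** Because slope SD is unbounded and blows up for
near-vertical bundles, a bounded circular statistic on axial data is
reported alongside: orientations are doubled (identifying θ with θ+180°),
the mean resultant length R of the doubled angles is formed, and the
angular deviation `sqrt(2(1 - R))` is halved back to the axial scale and
reported in degrees. This definition was chosen over the alternative
`sqrt(-2 ln R)` because it is bounded (≈40.5° at the axial-uniform limit),
which keeps the statistic usable as a clustering feature; for tight bundles
the two agree to first order.

## Apical (z-stack) metrics

Stacks follow the basal / middle / apical convention: plane 0 basal, the
middle plane carries the nucleus, the last plane is apical; extra planes
are background. The apical profile samples the apical plane along the
nucleus major axis (principal axis of the footprint's pixel covariance),
restricted to the nuclear footprint, returning the linescan mean and peak.
Border-clipped nuclei raise instead of returning truncated linescans. The
actin-cap area is the apical actin foreground overlapping the nuclear
footprint; plain 2D inputs fall back to whole-cell fiber statistics with
apical metrics left missing.

## Actin network complexity

The six per-cell fiber-network descriptors — fiber count, total fiber
length, mean fiber length, angle dispersion, fiber density (total length /
region area), and pairwise fiber-intersection count — are a
reconstruction: the underlying feature set of the original analyses is not
public, so this particular six-vector is this package's own definition.
They are z-scored across the cohort and projected on their first principal
component, with the sign oriented so higher scores mean denser, more
complex networks (positive association with fiber count); tertile labels
low/medium/high are attached. Published threshold-based percentages for
this feature are not reproduced, as the thresholds are not defined
anywhere recoverable.

## CAP score and severity

`CAP = age × (CAG − 30) / 6.49`, the "Fneur" parameterization in which a
score near 100 corresponds to expected clinical onset. The constants are
verified in the test suite by an independent least-squares fit of the
two-parameter form `age × (CAG − L)/K` over the bundled 28-donor reference
table, recovering L = 30 and K = 6.49 and reproducing every reference
score to four decimals. Severity cut-offs are CAP < 90 Premanifest,
90 ≤ CAP ≤ 114 Mild (boundaries inclusive), CAP > 114 Severe; they
reproduce all 28 reference labels (6/10/12). CAG ≤ 30 or age ≤ 0 are
errors, not scores.

## Group statistics, embedding, clustering, trends

Mann–Whitney U tests are two-sided and run on per-well or per-sample
medians (missing values excluded per feature). The exact U-distribution is
used for pooled n ≤ 12 without ties; otherwise the tie-corrected normal
approximation with continuity correction. Two identical constant groups
return p = 1 with a degenerate flag. No multiple-testing correction is
applied by default; a Benjamini–Hochberg helper is provided.

PCA z-scores features by default, drops zero-variance features with a
warning, and reports per-component explained-variance ratios. k-means uses
k = 3 by default with 50 seeded restarts (best inertia kept), and reports
per-cluster feature means plus per-group composition percentages (each
cluster row sums to 100). Trend analysis is ordinary least squares of a
per-sample feature average on CAP score, with optional envelope lines on
per-sample maxima/minima and severity-subgroup mean points.

## Motility

Tracks are linked greedily: candidate links between consecutive frames are
sorted by distance and accepted under per-frame exclusivity, links longer
than `max_disp` are never made, unlinked detections start new tracks, and
tracks shorter than `min_track_length` (default 10 frames) are dropped.
Greedy rather than optimal assignment is deliberate: at sparse plating
densities ambiguous assignments are rare and the greedy rule is easy to
verify. Defaults follow a 10-minute frame interval. Metrics: total path
length (sum of step lengths), net displacement (first-to-last distance),
mean speed (total/elapsed), and directionality (net/total, defined as 0
for a zero-length path). Directionality conventions differ between
tracking tools; net/total is this package's definition.

## Synthetic generator

The generator is the validation instrument, so its defaults encode the
study conditions the measurements are specified against: 512×512 fields,
nuclei of semi-axes (20, 20) px at intensity 200, 10 fibers per cell of
length 40–80 px at intensity 180 rendered as 2-px anti-aliased segments,
Gaussian background (mean 8, SD 5, clipped to [0, 255]), and a 50/50
apical/basal fiber split. Ground truth is exact: the true circularity of a
rendered ellipse is computed from the continuous ellipse perimeter
(complete elliptic integral), true slopes as tan(angle) with near-vertical
angles (within 2° of 90°) excluded and flagged, and per-plane fiber
assignments recorded per segment. Identical spec and seed produce
bit-identical rasters. Disjoint placement retries up to a bound and then
raises.

Migration tracks are persistent random walks with exact step length; the
per-step turning angle is uniform on `[−π(1−p), π(1−p)]`, so persistence
p = 1 is ballistic and p = 0 an uncorrelated walk. This reproduces the
ballistic and diffusive limits used in validation but is not a fitted
model of fibroblast motility.

**What passing synthetic benchmarks shows — and what it does not.** The
benchmarks establish estimator correctness: exact formula identities,
parameter recovery (nucleus counts 100/100 fields at background SD ≤ 10;
monotone recovery of orientation dispersion; 1%-exact speed recovery), and
phenotype separability when the generative contrast is large. They do not
establish robustness to the features of real micrographs the generator
deliberately omits: optics (PSF blur, uneven illumination), chromatin
texture, curved or branching fibers, overlapping cells, and
photobleaching. Results on real data depend on threshold and Hough
parameter choices in ways these tests cannot certify.

## Problem sizes in the test and acceptance runs

Validation uses 256×256 to 512×512 fields with 1–5 cells, 30 cells per
dispersion level, 100 seeded fields for count recovery, and 200-track
ensembles for the diffusive motility limit — sizes chosen so the full
suite runs in well under a minute while keeping every Monte-Carlo margin
wide (each stochastic criterion passes with a comfortable buffer, not at
its edge). The reference-cohort computations (CAP scores, severity
counts) are exact and independent of problem size.
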