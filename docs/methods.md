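# Methods

`vasculodyn` quantifies the spatiotemporal dynamics of pseudo-vascular
networks — the interconnected polygonal tube patterns that VM-competent
cancer cells (and endothelial cells) form on basement-membrane gels in
vitro. This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Morphometry

A well-quadrant image is reduced to a skeleton graph and parameterised by
20 named scalar features ("vectorial objects").

**Preprocessing.** The frame is cropped to a central square (default
1000×1000 px at 2.82 µm/px) because the gel meniscus at the well periphery
suppresses tube formation and distorts features. Grayscale input is
contrast-stretched so that 0.35% of pixels saturate at each histogram tail
and thresholded with Otsu's method; already-binary input passes through the
crop unchanged. A constant image raises an explicit no-contrast error.

**Skeleton graph.** The mask is thinned to a one-pixel, 8-connected
skeleton (topology-preserving; `skimage.morphology.skeletonize`). Pixels
are classified by 8-neighbour count: one neighbour = extremity, two = slab,
three or more = junction. Adjacent junction pixels are merged into single
nodes: the exact pixel configuration at a junction is an artefact of
thinning, and merging prevents spurious two-pixel nodes. Edges are maximal
slab runs between anchors; their arc length sums axial steps as 1 px and
diagonal steps as √2 px (geometric length) times the pixel size. Edges are
classified by their anchors: node–node = *segment*, node–extremity =
*branch*, extremity–extremity = *isolated segment*. Multiple direct pixel
adjacencies between the same two node clusters collapse to one edge — they
are a single physical junction contact, and counting them separately would
fabricate faces the image does not contain. A junction-free ring is traced
as a closed loop and counted with the segments.

**Meshes.** A mesh is an enclosed background region. Background is
labelled with 4-connectivity (the dual of 8-connected foreground) and
flood-filled from the frame border; unreached regions are meshes, with
area counted in background pixels times the pixel area. This is robust to
nesting and never double-counts skeleton pixels.

**Master subgraph.** Master segments/junctions — the mesh-supporting
scaffold — are defined as the 2-core of the network multigraph: iteratively
strip every vertex of degree < 2 (self-loops count twice). Note the 2-core
retains bridges that connect two cycles; we accept this deliberately, since
pruning criteria based on cycle membership alone are unstable under small
topology changes.

**The 20 objects.** Counts: extremities, nodes, junction pixels, master
junctions, segments, master segments, branches, isolated segments, pieces
(connected components), meshes. Lengths (µm): total, per edge class,
master-segment, branching length (total minus isolated), and the branching
interval (master-segment length per master junction; 0 when no master
junctions). Areas: total mesh area (µm²), mean mesh size, and the mesh
index, defined here as total mesh area over analysed area (dimensionless).
Each definition is individually overridable through the object registry
(`morphometry.DEFAULT_REGISTRY`), because alternative conventions exist for
the derived ratios. Two objects — the numbers of isolated segments and of
pieces — are dominated by detached debris (unattached cells, matrix
macromolecules) in real images and are excluded from scoring by default,
leaving 18.

## Trajectory model

Within a well, the four imaged quadrants are technical replicates and are
averaged per timepoint; the well is the biological unit. The well-level
series y(t) of each object is modelled by a third-degree polynomial

y_i = β₀ + β₁ t_i + β₂ t_i² + β₃ t_i³ + ε_i.

A cubic is the lowest-order polynomial that follows the one-peak /
one-trough shapes of transient network formation without per-dataset basis
selection (spline bases would need tuning per cell line and object, which
unequal numbers of timepoints make awkward). Three estimators are provided:

- **ols** — ordinary least squares (conditional mean; outlier-sensitive);
- **robust** — bisquare M-estimation at 90% normal efficiency (tuning
  constant c = 3.8827), started from the median regression with the
  normalised MAD of its residuals as a fixed scale. Fixing the scale keeps
  the redescending ψ from imploding; the iteration stops when coefficients
  change by < 1e-9 relative, and reports an explicit convergence error
  (with the iteration count) after 500 iterations;
- **quantile** — median regression (τ = 0.5), solved as a linear program
  (HiGHS). At even n the median fit can be non-unique; the solver's
  canonical vertex makes the result reproducible, and this is documented
  rather than hidden.

Scores use the **ols** fit by default; the estimator is a configuration
switch, and on clean data the three agree within sampling error.

For score computation, all wells of a cell line are pooled into a single
fit per object (one curve per cell line enters the scores); per-well fits
remain available for diagnostics. Pooled and per-well fitting are related
by exact affine reparameterisation of the design, which is tested.

## Transformations and scores

**Time standardisation.** Cell lines form and dissolve networks on very
different schedules, so each line's analysis window (t_l, t_u) — a
configuration input per cell line — is mapped affinely onto a common range
(τ_l, τ_u), default (0, 1).

**Z-normalisation.** Objects live on incommensurate scales (counts, µm,
µm²), so well-level values are z-scored within a stratum using the sample
(n−1) standard deviation. The default stratum is **(cell line, object),
pooled over wells and timepoints**: this makes the transformed data mean-0,
unit-variance per object while preserving the temporal signal that the
scores measure. A per-timepoint stratification (`strata="object_time"`) is
also implemented; note that on balanced designs it re-centres every
timepoint to zero and therefore annihilates the pooled fit — it is exposed
for sensitivity analysis, not as a default. Degenerate strata (single
observation or zero spread) map to 0 and are flagged.

**Dissimilarity.** For cell lines j, k and one object, the integrated
discrepancy is d_jk = ∫ |ĝ_j(t) − ĝ_k(t)| dt over the standardised window.
The integrand is a cubic, so the integral is computed exactly: real roots
of the difference inside the window partition it into sign-constant
pieces, and the signed antiderivative is summed in absolute value. The
integration domain is the standardised window [τ_l, τ_u] — the fits are not
defined beyond it. The per-object dissimilarity score sums d_jk over all
cell-line pairs; d is a genuine metric on fitted curves (tested, including
the triangle inequality).

**Spread and stability.** The spread of an object is the attained range
max ĝ − min ĝ of the fitted standardised curve over the window, computed
analytically (window endpoints plus real roots of the derivative
quadratic; the quadratic roots use the cancellation-stable form, with a
relative threshold that demotes a floating-point-zero leading coefficient
— the naive formula silently loses interior extrema when β₃ ≈ 1e−14). A
cell line's stability score is the sum of its 18 retained spreads; lower
means more stable. A sensitivity variant — integrated discrepancy between
the curve and the horizontal line at its mean level — is provided as
`scoring.mean_discrepancy_stability`.

## Hierarchical bootstrap

Uncertainty respects the nesting: per cell line, wells are resampled with
replacement (original number of wells), then within each drawn well its
quadrants are resampled with replacement (original per-well count). For
every replicate, well averages, both transformations, the pooled fits and
all scores are recomputed from scratch, and **all objects are evaluated on
the same resampled dataset** — the between-object Spearman correlation of
bootstrap dissimilarity scores is only meaningful under joint resampling.
Intervals are equal-tailed percentile intervals of the B bootstrap values
(default B = 4000, level 95%), using linear-interpolation empirical
quantiles. Everything is deterministic given the seed.

Two implementations share one draw sequence: a generic path that rebuilds
a feature table and applies any statistic, and a vectorised path for the
balanced OLS pipeline (dense well×quadrant×time×object arrays, batched
root-finding via companion-matrix eigenvalues). Their outputs agree to
1e-8 and are tested against each other; large-B runs use the vectorised
path.

Calibration: in simulation (three cell lines, 9 wells × 4 quadrants × 10
timepoints, well-intercept sd 0.5, noise sd 1.0, B = 500, 200 repeats),
nominal 95% intervals for dissimilarity scores cover the population truth
at close to nominal rate. Intervals for stability scores are conservative:
a range statistic is biased upward under resampling, so its percentile
intervals over-cover. The population truth plugs the generative mean
curves and the population moments of pooled well-level observations into
the same transformation arithmetic.

## Drug screen and growth metrics

Treated and vehicle-control wells are compared per (compound,
concentration, object) at a fixed timepoint with a Welch t-test on
square-root-transformed well averages (counts and areas are right-skewed
with mean-linked variance). Default objects are the mesh-related trio:
number of meshes, mean mesh size, total mesh area. Significance stars use
0.05 / 0.01 / 0.001 / 0.0001; no correction across concentrations or
objects is applied by default (an optional Holm adjustment is available).
If both groups are constant with equal means the result is reported as no
difference (t = 0, p = 1) rather than undefined.

Doubling time is 1/slope of a least-squares fit of log₂(confluence) on
time over the exponential phase, taken as confluence ≤ 0.8 (configurable):
the plateau near full confluence otherwise biases the slope down. The
Spearman correlation between doubling times and network time windows
summarises each window by one scalar — midpoint by default; the convention
(midpoint | width | upper | lower) is always recorded in the result and
never substituted silently.

## Synthetic data

**Network images.** A Voronoi tessellation of near-Poisson-disk random
seeds, clipped to the frame, has the qualitative look and the exactly
enumerable topology of a segmented pseudo-vascular network: convex meshes
bounded by thin tubes. Four distant ghost seeds bound every real cell, so
all ridges are finite before clipping. Ground truth (mesh, extremity,
junction, component counts; face areas; edge lengths) is computed on the
vector geometry — faces by both planar-Euler counting (E − V + C) and
polygonisation, which must agree — never on pixels, so the rasteriser is
tested against an independent oracle. Edges are drawn with Bresenham lines
and dilated to the stroke width (default 3 px ≈ 8.5 µm tubes at
2.82 µm/px). Geometry the rasteriser cannot resolve — vertices closer than
stroke + 3 px, a vertex near a non-incident edge, or a face without
interior clearance of stroke/2 + 2.5 px — raises a degenerate-geometry
error; callers draw a fresh seed. Because validated faces are guaranteed
that interior clearance, enclosed background slivers smaller than
(stroke + 1)² px, which integer rasterisation can create where strokes
meet at shallow angles, are filled as artefacts. Defaults (512² px,
12 seeds, stroke 3) give mesh sizes a few hundred µm across, matching the
scale of observed meshes.

**Degradation.** Network dissolution is emulated by erasing a fraction of
skeleton segments. Removal sets are nested under a seed-fixed permutation
(so foreground is monotone non-increasing in the fraction and fraction 0
is the exact identity); each removed segment is painted out at its local
tube radius from the distance transform, sparing pixels that kept
segments still claim.

**Trajectories.** Feature tables are drawn from the cubic model used for
fitting: per (cell line, object) true coefficients, one Gaussian intercept
per (well, object) shared by that well's quadrants, i.i.d. Gaussian
observation noise, equally spaced timepoints in each line's window. No
published quantitative noise model exists for replicate variability in
this assay, so the defaults — 9 wells (triplicate wells over three
experiments), 4 quadrants, intercept sd 0.5 and noise sd 1.0 on the
object's scale — are the package's own choice of a realistic regime, and
the bootstrap's two resampling levels are both consequential under them.

**What passing tests do and do not show.** The generators establish
correctness of the bookkeeping (exact topology recovery, exact noiseless
coefficient recovery, interval calibration under the stated noise model).
They do not establish robustness to phase-contrast segmentation errors,
meniscus artefacts, debris, uneven illumination, or missing images — real
data enter through the same feature-table interface after the user's own
QC.

## Problem sizes in the test suite

Tests run the full algorithms at reduced scale: bootstrap calibration uses
B = 500 over 200 simulated experiments; topology exactness uses 50
generated networks at 384²; integral/extrema oracles use 100 random cubic
pairs against a 10⁶-point Riemann sum and a refined 10⁴-point grid search.
The default B = 4000 runs through the identical code path.

## Known limitations

- The skeleton-based morphometry under-describes wide tubular formations
  (patterned-matrix-type structures); features are only as good as the
  input segmentation.
- Windows (t_l, t_u) are configuration inputs; the package does not infer
  them from the data.
- The pooled-fit-per-cell-line convention is the score definition; per-well
  fitting is available but scores from it are not the default output.
- Percentile intervals only (no BCa/studentised); stability intervals are
  conservative (see above).
- The quantile estimator's LP solution at even n is canonical-vertex
  dependent, hence reproducible but one of several minimisers.
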