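# Methods

This note documents the models, conventions, and numerical choices
behind `mitoscope`, and what the synthetic benchmarks do and do not
establish about real microscopy data.

## Image model and segmentation

Images are 2D intensity grids with 0-based (row, col) coordinates, row
increasing downward, and a pixel-size attribute (default 0.05 µm, a
SIM-scale sampling; all lengths are reported in pixels, with µm
conversion left to the caller). 8-bit conversion is per-image min–max
linear rescaling; a constant image maps to zero. Threshold
segmentation uses a strict rule — a pixel is foreground iff its 8-bit
value exceeds the threshold (default 127) — so a uniform value-127
image yields zero objects. Connected components are labeled under
8-connectivity by default (diagonal limbs of thin fluorescent
structures stay whole), configurable to 4. Labels are always compacted
to consecutive 1..N, and externally supplied masks (e.g. from a
deep-learning segmenter) are ingested by the same path: binary masks
are component-labeled, labeled masks are compacted and any label whose
pixels are disconnected is split.

Pseudo-color rendering paints each object one color: its mean 8-bit
intensity is piecewise-linearly interpolated between color-map anchors
(default blue→green→yellow→red at 0/85/170/255; anchors are
configurable), computed in floating point and rounded half-up to
integer RGB, making renders byte-reproducible. Skeleton overlays
dilate the skeleton once with a 3×3 kernel and draw it in pure red;
morphotype outlines draw the 1-px boundary (foreground pixels with a
background 4-neighbor) in class colors (network orange, rod blue, dot
green).

## Skeleton topology

Objects are thinned with Guo–Hall morphological thinning, which
preserves homotopy, followed by a simple-point cleanup that deletes one
pixel (crossing-number criterion) from any residual 2×2 block where a
topology-preserving deletion exists. The only 2×2 blocks that can
survive are thick junctions whose four pixels each carry a separate
limb; these are accepted and merged into a single junction node. Any
other 2×2 block in an input skeleton raises an error with the offending
coordinates.

Pixel adjacency is 8-connected with one correction: a diagonal link is
dropped when the two pixels share an axial common neighbor, so
staircase corners do not create spurious 3-cycles. Node pixels are
those of pruned degree ≠ 2; mutually adjacent degree-≥3 pixels form one
junction node (raw degree counts would double-count thick junctions).
Edges are traced through degree-2 chains; geodesic length adds 1 per
axial and √2 per diagonal step. Components with no node pixel are pure
cycles and are anchored at an arbitrary pixel with a self-loop edge.
Loop count is the cyclomatic number E − V + C of the resulting
multigraph, which for a homotopy-preserving thinning equals the number
of holes in the object.

Branch count is the number of edges incident to at least one junction
node, so unbranched rods and dots have branch count 0 — the form the
morphotype rules expect. "Mean branch length" averages all edge
lengths. "Mean branch angle" is the circular mean (period 180°) of
edge chord orientations, i.e. of the straight segment joining an edge's
terminal nodes; an alternative reading (inter-branch angles at
junctions) exists, and the chord convention was chosen because it is
defined for every edge, junction or not. A minimum-branch-length
pruning filter exists but defaults to off.

## Morphometry

Area is the pixel count; perimeter uses the Crofton 4-direction
estimator, which is nearly unbiased for smooth shapes and markedly more
scale-stable than chain-code perimeters on staircase boundaries (with
the chain-code estimator, the circularity of a width-4 capsule drifts
by more than 0.05 under a doubling of scale; with Crofton it stays
within half that). Ellipse axes come from second central moments with
the 1/12 per-pixel variance correction; axes are clamped to ≥ 1 px so
one-pixel-wide bars keep a finite elongation ratio, and a single pixel
is major = minor = 1 by convention. Roundness = 4A/(πa²) with a the
moment-ellipse major axis (a Feret-diameter denominator would be a
defensible alternative; the moment ellipse is smoother on small
objects). Form factor is circularity 4πA/P² — with this orientation
compact dots score high and ragged networks low, which fixes the
direction of the dot-vs-network contrast; values may exceed 1 by a few
discretization percent on near-perfect discs and are not clipped.
Roundness is clipped at 1. "Length" is total skeleton path length (the
major axis is available as an alternative via the features table).

## Morphotype rules

The three decision rules (network: branch ≥ 1; dot: ratio < 2 and
roundness > 0.25; rod: ratio ≥ 2 and roundness ≤ 0.25) do not tile the
unbranched feature plane: (ratio < 2, roundness ≤ 0.25) and (ratio ≥ 2,
roundness > 0.25) match nothing. Such objects are assigned the class
whose single violated rule is closest to its boundary in normalized
units (|ratio − 2|/2 vs |roundness − 0.25|/0.25) and flagged
`rule_gap`, so no object is silently dropped and the gap population is
auditable. Both thresholds are configuration parameters.

## Biomarker bound fraction

"Bound fraction" is a normalized per-object mean intensity. The
default normalization divides the object mean by the 99.5th percentile
of foreground intensities in the same image and clips to [0, 1]; the
high-percentile reference is robust to isolated hot pixels, and a
foreground-maximum mode is available. The MMP reporter is two-channel,
so a ratiometric mode computes mean(aggregate)/(mean(aggregate) +
mean(monomer)), which is invariant to common channel scaling. The
normalization mode is recorded in every measurement. Normalization is
per-image; a per-experiment baseline would require propagating a shared
reference across images and is intentionally left to the caller.
Statistics use the sample (n−1) standard deviation throughout;
histograms default to 20 bins on [0, 1]; group comparisons use the
classical equal-variance two-sample t-test with Welch as an option; no
multiple-testing correction is applied inside the module.

## Tracking and motility

Linking is greedy mutual-nearest-neighbor between consecutive frames
within a gate (default 15 px/frame, default frame interval 1 s):
deterministic, no gap closing, unmatched detections start new tracks.
Optimal (Hungarian) assignment is available as an option. Speed is the
mean Euclidean step divided by the frame interval; directionality is
net displacement over path length; displacement is start-to-end
distance. These are the standard definitions; no formula is canonical
in the literature for "directionality", and the chosen ratio is 1
exactly for straight co-directed motion and 0 for closed trajectories.

## State classifier

The feature table inner-joins per-object products on the object id;
motility columns may be missing for untracked objects and are kept with
a missingness indicator. The random forest uses 500 trees, √p features
per split, no depth cap, and a mandatory seed; trees consume raw
features (scale-invariant), while k-means and PCA operate on z-scored
features. Splits and cross-validation folds are stratified by
condition — plain random splitting is the minimal reading of the
protocol, but stratification stabilizes small-class folds at no cost to
the 7:3 contract. AUC is computed from the ROC curve and equals the
Mann–Whitney pairwise-concordance probability with ties counted half;
the multi-class severity mode (control/mild/moderate/severe, treated as
four mutually exclusive single labels) reports the unweighted mean of
one-vs-rest AUCs. Feature importances are normalized impurity
decreases by default (permutation importance behind a flag). K-means
has no native probabilities; soft assignments are a softmax of negative
squared distances to the centroids scaled by the mean within-cluster
squared distance, a documented interpretation that yields rows summing
to 1 and can be appended to the table as one extra feature.

## Probe calibration

The calibration fit is ordinary least squares of log₁₀ intensity on
log₁₀ viscosity; R² = 1 − SSres/SStot. The log base is configurable
and R² and LOD are base-invariant for these definitions. The limit of
detection is 3σ/|k| with σ the sample (n−1) standard deviation of
replicate blank intensities on the raw scale (a log-scale blank sd is
available behind a flag) and k the fitted slope. A two-point series
fits exactly and warns that it is under-determined.

## Synthetic data: what it emulates, and what it does not

The generator renders resolved, non-overlapping organelles: dots are
filled discs; rods are capsules (rectangle with semicircular caps), the
simplest branchless elongated region; networks are star skeletons — a
hub with ≥ 3 arms — dilated to a width, with each requested loop closed
by a chord between two adjacent arm tips so that every loop adds
exactly one independent cycle. Chord loops (rather than tangent rings)
keep network edge lengths comparable to arm lengths, so rods retain
the longer mean branch length that distinguishes the two classes.
Placement is rejection sampling with ≤ 100 retries per object and a
minimum separation (default 3 px). Object pixels draw i.i.d. from a
per-object normal intensity model, plus additive Gaussian scene noise,
clipped to the dtype range — adequate for testing thresholding and
mean-intensity quantification. Shape parameters from
`random_shape_spec` keep a ≥ 10% margin from the morphotype decision
boundaries so the intended class is recoverable.

Condition cohorts plant Gaussian mean shifts per feature, expressed in
sd units; with L levels, level i is shifted by effect · sd · i/(L−1) so
the extreme contrast equals the stated effect. The default baseline
(e.g. viscosity fraction 0.45 ± 0.12, solidity 0.82 ± 0.08, speed
2.0 ± 0.6 px/s) and stress response (viscosity the strongest riser at
+1.0 sd, ROS +0.7, MMP −0.7, shapes rounder and less branched, motility
−0.6 sd, dot-ward shift of class probabilities) encode the qualitative
physiology of hypoxic stress at effect sizes typical of strong
single-organelle contrasts; no quantitative per-condition distributions
are published for these readouts, so these defaults are the package's
own study conditions, fixed once. A global `effect_scale` multiplier
expresses null (0) and graded cohorts without touching the defaults.
Time-lapses are persistent random walks with exact step length: at
persistence 1 the heading never changes; at 0 it is redrawn uniformly
each step, giving the closed-form E|R| = step·√n·√π/2 used as an
oracle.

None of this emulates optics (no PSF, no photon noise model), 3D
structure, organelle contact or fusion/fission, or the probe's
photophysics. Passing tests therefore establish the correctness of the
measurement and learning machinery on known ground truth — not the
biological performance of any classifier on live-cell images, whose
headline metrics depend on data that cannot be regenerated here.

## Problem sizes and numerical details

The test suite and the acceptance script run at desk scale: 300 shapes
for morphotype recovery, 100 skeletons for topology-oracle equivalence,
500 shapes for morphometry bounds, cohorts of 1000 objects per
condition (10–20 seeds) with 100-tree forests for classifier
calibration and fusion ordering, the full 10,000-row table for the 7:3
split contract, 100 seeds for calibration recovery, and 1000 null
simulations for t-test calibration. Scale-invariance checks use discs
(radius 6 → 12) and width-6 capsules; thinner shapes are dominated by
hull/perimeter discretization bias and are covered by bound checks
instead. Determinism everywhere comes from explicit
`numpy.random.default_rng` seeds; renders and forests are bit- and
prediction-reproducible per seed.
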