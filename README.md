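# mitoscope

Single-mitochondrion morphology–function analysis for fluorescence
microscopy.

Mitochondria within one cell are strikingly heterogeneous: under stress
such as hypoxia, elongated networks fragment into rods and dots while
per-organelle biomarkers — matrix viscosity, reactive oxygen species
(ROS), and mitochondrial membrane potential (MMP) — shift in concert.
`mitoscope` is a toolkit for researchers who image mitochondria with
super-resolution (e.g. SIM) or confocal microscopes and want to quantify
that heterogeneity organelle by organelle rather than cell by cell. It
takes a raw image plus a segmentation mask — its own threshold
segmenter, or a drop-in mask from an external deep-learning model — and
produces per-object shape, topology, morphotype, biomarker, and motility
features, then fuses them into a machine-learning readout of
physiological state.

## What it computes

**Skeleton topology.** Each object is thinned to a one-pixel skeleton
and converted into a multigraph of endpoints (degree 1), junctions
(degree ≥ 3, with mutually adjacent junction pixels merged into one
node), and traced edges. The number of independent loops is the
cyclomatic number *E* − *V* + *C*.

**Morphometry.** Area *A*, Crofton perimeter *P*, moment-ellipse axes
(*a* ≥ *b*), solidity (*A*/hull area), extent (*A*/bounding box),
roundness = 4*A*/(π*a*²), form factor (circularity) = 4π*A*/*P*², and
total skeleton length.

**Morphotype rules.** Each mitochondrion is classed as
*network* (branch count ≥ 1), *dot* (unbranched, *a*/*b* < 2,
roundness > 0.25), or *rod* (unbranched, *a*/*b* ≥ 2, roundness ≤ 0.25);
objects in the rule gap are assigned by nearest normalized margin and
flagged.

**Biomarker bound fraction.** Per-object normalized mean intensity of a
biomarker channel, in [0, 1]: mean over the mask divided by a per-image
99.5th-percentile reference, or the ratiometric form
agg/(agg + monomer) for the two-channel MMP reporter. Condition-level
summaries report CV = σ/μ, histograms, and Shapiro–Wilk normality;
morphology–function relationships use Pearson's *r* and two-tailed
*t*-tests.

**Motility.** Greedy mutual-nearest-neighbor tracking, then per-track
speed, net displacement, and directional persistence
(= displacement/path length ∈ [0, 1]).

**State classification.** A random forest (500 trees, √p features per
split) on the fused feature table, with stratified 7:3 splits, ROC/AUC
(equal to the Mann–Whitney concordance probability), impurity-decrease
feature importances, stratified 5-fold cross-validation, one-vs-rest
macro-AUC for 4-level severity labels, and k-means (k = 2)
subpopulation analysis with silhouette, PCA, and soft assignment
probabilities usable as an extra feature.

**Probe calibration.** Log–log OLS fit of emission intensity vs
viscosity (slope *k*, *R*²) and limit of detection LOD = 3σ/|*k*| from
replicate blanks.

Every stage is testable without any data download through the built-in
synthetic generator (`mitoscope.synthetic`), which renders seeded scenes
of dot/rod/network shapes with ground-truth masks, condition-shifted
feature cohorts, persistent-random-walk time-lapses, and calibration
series.

## Worked example

```python
import numpy as np
from mitoscope import synthetic as syn, imaging as im
from mitoscope.pipeline import analyze_objects

rng = np.random.default_rng(0)
shapes = [syn.random_shape_spec(k, rng)
          for k in ["dot"]*2 + ["rod"]*2 + ["network"]*2]
scene = syn.render_scene(syn.SceneSpec(shapes, canvas=(400, 400), seed=0))
mask = im.segment_by_threshold(im.to_8bit(scene.image))
table = analyze_objects(mask, scene.image)
print(table[["object_id", "area_px2", "ratio_major_minor", "roundness",
             "solidity", "branch_count", "loops", "morphotype",
             "viscosity_fraction"]].round(3).to_string(index=False))
```

prints

```
 object_id  area_px2  ratio_major_minor  roundness  solidity  branch_count  loops morphotype  viscosity_fraction
         1      88.0              1.000      0.992     1.000             0      0        dot               0.977
         2     426.0              1.182      0.425     0.514             7      1    network               0.976
         3     134.0              5.750      0.164     0.893             0      0        rod               0.975
         4     163.0              1.021      0.973     0.953             0      0        dot               0.975
         5     285.0              1.159      0.540     0.578             7      1    network               0.976
         6      37.0              3.951      0.236     0.881             0      0        rod               0.975
```

Reading the rows: the two compact objects (near-unit axis ratio, high
roundness and solidity, no branches) are classed as dots; the two
elongated unbranched objects (ratio ≥ 2, roundness ≤ 0.25) as rods; the
two branched objects (7 branch edges, one closed loop each) as
networks. The viscosity fractions are near 1 because all planted object
intensities sit at the per-image reference.

The same stages are available from the shell:

```bash
mitoscope simulate scene --seed 3 --out demo/
mitoscope segment demo/scene_image.tif --out demo/mask.tif
mitoscope features demo/mask.tif --image demo/scene_image.tif --out demo/features.csv
mitoscope simulate cohort --seed 3 --n 5000 --out demo/cohort.csv
mitoscope train demo/cohort.csv --seed 3 --out demo/report.json
```

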