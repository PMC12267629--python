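# Methods

This note records the models, parameter choices and numerical decisions
behind `hypdisp`, and what the synthetic validation does and does not show.

## Hyperbolic representation of connectomes

A binary, symmetric, loop-free connectome on N atlas nodes is mapped to
polar coordinates (r, θ) on the unit disk by coalescent embedding:

* **RA weighting.** Every edge gets
  ω_ij = (d_i + d_j + d_i·d_j) / (1 + CN_ij) with binary degrees d and
  common-neighbor counts CN. ω is used directly as an edge *length* in the
  geodesic computation: an edge inside a densely interconnected
  neighborhood (high CN) is short, a bridge between hubs with no shared
  neighbors is long relative to its degree product. This maps
  "topologically important" onto "geodesically close", which is what the
  planar projection preserves.
* **Projection.** All-pairs weighted shortest paths (Dijkstra via
  `scipy.sparse.csgraph`) followed by classical MDS (double-centered
  −½D², top-2 eigenpairs of the symmetrized Gram matrix). Eigenvector
  sign indeterminacy is fixed by requiring non-negative coordinates for
  the lexicographically smallest node ids, so embeddings are bit-stable
  across runs.
* **Angles.** Raw angles atan2(y, x) are replaced by uniformly spaced ones
  in the same circular order (ties broken by node id). Only the order of
  the projection is kept; its metric distortions are discarded.
* **Radii.** Nodes are ranked i = 1..N by descending degree (ties by node
  id); r_i = (2/ζ)(β ln i + (1−β) ln N), then divided by r_N so the disk
  has unit radius. Defaults ζ = 1, β = 0.9, giving a radial band
  [0.1, 1.0]; radii depend only on the degree sequence.

Degree-0 nodes (possible after a simulated resection) carry no geodesic
information. They are excluded from the projection, flagged, ranked last,
and placed at a caller-supplied fallback angle — in the pipeline, the angle
of the same node in the subject's pre-surgery embedding. Disconnected
post-surgery graphs are embedded by replacing infinite cross-component
geodesics with 1.05 × the largest finite geodesic, which keeps the MDS
finite with minimal rank distortion.

## Distance, alignment, displacement

Distances between disk points use the hyperbolic law of cosines, evaluated
in the cancellation-free form cosh d − 1 = 2 sinh²(Δr/2) +
2 sinh r_a sinh r_b sin²(Δθ/2) with a log1p-based arccosh. The naive
cosh·cosh − sinh·sinh·cos form loses ~1e−8 absolute precision near
coincident points, which matters because alignment residuals sum N such
distances.

Embeddings are aligned to a single healthy-control reference by minimizing
the summed displacement over a rotation; because MDS can flip chirality
between subjects, the reflected embedding (θ → 2π − θ) is evaluated too
and kept only if strictly better. The loss can be multimodal, so a
1024-point rotation grid is scanned before golden-section refinement; the
tolerance is 1e−9 rad because the loss is V-shaped at the optimum and the
residual scales like N × (angle error). Radii are never changed by
alignment — no Procrustes scaling.

HypDisp(i) is the hyperbolic distance between node i's aligned pre- and
post-surgery positions. Both embeddings of a patient are aligned to the
same control reference rather than post-to-pre; distances are taken on the
rescaled unit-disk coordinates throughout, a consistency choice — all
downstream comparisons are relative, so the absolute curvature scale is
immaterial.

## Interpolation and group statistics

Scores are interpolated on a G×G grid over [−1, 1]² (pixel centers;
out-of-disk pixels discarded; G = 80): pixel value = inverse-distance
weighted mean of the k = 20 hyperbolically nearest nodes at pre-surgery
positions, weights 1/d^α with α = 0.1. Small α gives near-uniform weights
and a smooth map. k-th-rank ties break by node id; a pixel coinciding with
a node takes that node's score (the α > 0 limit). Pixel values are convex
combinations of node scores, hence bounded by the score range.

Group comparison is a two-sided equal-variance Student's t test per in-disk
pixel (configurable to Welch); p ≤ 0.05 inclusive; no multiple-comparison
correction across pixels — out-of-sample control is delegated to the
leave-one-out wrapper. Zero-variance pixels get p = 1 and a flag. ROI
components are labeled under 8-connectivity by default (4 exposed).
Analyses are stratified by surgery side: left-surgery patients are
compared on their own disk, right-surgery patients on theirs.

A node is "in the ROI" when its position's containing pixel is significant
(no sub-pixel interpolation of the mask); discriminant nodes are those in
the ROI for ≥ 80% of the stratum's patients. The resected-node report
lists nodes losing ≥ 40% of their pre-surgery connections.

## Prediction

Per leave-one-patient-out fold, the ROI is recomputed from training
patients only; the feature is the median interpolated score over all ROI
pixels; the model is a plain maximum-likelihood logistic regression with
intercept on that single feature (on perfectly separated training features
it falls back to a tiny ridge penalty, 1e−6, and flags the fold). Folds
whose training ROI is empty, or whose side stratum lacks two training
patients per class, get the uninformative probability 0.5 and a flag. A
training class-prevalence prior was rejected for this purpose: with one
patient held out, the prior is deterministically lower when the held-out
patient is favorable than when they are poor, anti-correlating probability
with label.

Balanced accuracy thresholds probabilities at 0.5 (favorable positive).
AUC uses the Mann–Whitney formulation with half-credit ties. Whole-cohort
metrics pool the out-of-fold probabilities of the side-stratified models;
per-side metrics are reported where both classes exist. The whole
procedure is repeated over several control references (mean ± SD).

The rewiring control randomizes each patient's pre-surgery network by
double-edge swaps (exact degree preservation, no self-loops or
multi-edges, best-effort when the target fraction of changed edges is
unreachable), re-applies the original resection mask, and reruns the
pipeline. At rewiring fraction 0 it returns the untouched cohort, so
metrics match the baseline bit-for-bit.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **Shared atlas.** One set of true coordinates per cohort — radii
  quasi-uniform in hyperbolic area up to disk radius R, angles uniform in
  [0, π) for the left hemisphere, [π, 2π) for the right — with per-subject
  Gaussian jitter (0.05 rad angular, 0.05·R radial). The shared atlas is
  essential, not cosmetic: real subjects share one parcellation, and both
  the cross-subject alignment step and the pixel-level group statistics
  presuppose that node positions are comparable across subjects. With
  fully independent per-subject coordinates, alignment to a reference is
  ill-posed (rotation/reflection modes become degenerate) and pixelwise
  group maps carry no shared geometry.
* **Edges.** Independent per subject with the Fermi rule
  p = 1/(1 + exp((d_hyp − R)/(2T))), temperature T = 0.1 (strong
  clustering, heavy-tailed degrees). R is calibrated once per
  configuration by bisection so the expected mean degree on the atlas
  coordinates hits the target (default 12 at N = 114); expected degree
  decreases with R. Disconnected samples are repaired by connecting each
  minor component's highest-degree node to the hyperbolically nearest
  giant-component node.
* **Resection.** The resection_size = 10 nodes of the operated hemisphere
  closest in atlas angle to the hemisphere's sector center (π/2 left,
  3π/2 right) — a compact sector, identical across same-side subjects,
  like a standardized anterior temporal resection. Each resected node
  loses round(fraction × degree) incident edges at random (default 0.9);
  edges are never added.
* **Outcome effect.** For poor-outcome patients only, a fraction
  (default 0.6) of the edges incident to the contralateral mirror sector
  is re-paired with resected-sector edges by degree-preserving swaps
  ((a,b),(c,d) → (a,c),(b,d) with a contralateral, c resected): the poor
  group's pre-surgery networks carry abnormal coupling between the
  contralateral sector and the future resection zone, which surgery then
  severs. This models an epileptogenic network extending beyond the
  planned resection — the clinical hypothesis for surgical failure — and
  makes the group difference appear in the displacement maps away from
  the resection site. An alternative effect confined to the contralateral
  sector's own edges was implemented and measured first: because both the
  pre and the post network inherit it identically, it produces *no*
  pre-vs-post displacement difference and is undetectable by this
  pipeline by construction.
* **Cohort.** Defaults: 16 favorable / 8 poor patients (half operated on
  each side, outcomes interleaved so both strata keep both classes) and 5
  controls. All randomness flows from one master seed through spawned
  per-subject seeds; cohorts are byte-reproducible.

## What the synthetic validation shows — and does not

Passing tests show the machinery is correct (formula-level oracles,
metric axioms, planted-geometry recovery with circular correlation ≥ 0.9,
exact leakage control) and that the full pipeline detects a planted
contralateral abnormality (out-of-fold AUC ≥ 0.8 in ≥ 80% of cohorts at
effect 0.6) while degrading toward chance on degree-preserving rewired
networks. They do not show that real pre/post connectomes behave like
Fermi-rule geometric graphs, that real effect sizes resemble the planted
one, or that tractography noise resembles coordinate jitter.

Two null-calibration properties fail by design of the procedure itself and
are deliberately left failing in the acceptance tests rather than patched:

* Under a no-effect null, the out-of-fold AUC distribution is wider and
  left-skewed relative to the nominal chance band [0.3, 0.7] (≈ 55% of
  seeds inside at the default cohort size). Per-fold ROI *selection*
  followed by evaluation on the held-out patient is a textbook source of
  selection-induced anti-learning; it worsens, not improves, with larger
  cohorts. The pixelwise type-I rate itself is nominal (significant-pixel
  fraction 0.043 ± 0.023 under the null).
* Null cohorts frequently yield non-empty discriminant-node sets: with a
  shared atlas, any chance ROI that overlaps node positions contains
  those nodes for ≥ 80% of patients, because patients' positions nearly
  coincide. The positional consistency that makes discriminant nodes
  meaningful under a real effect makes them non-empty under the null.

Interpreting discriminant nodes therefore requires the rewiring control
and effect-size context, not the raw node list alone.

## Problem sizes in the shipped checks

The test suite and acceptance script run reduced replicate counts chosen
as the package's own defaults for desk-scale validation: 20 null cohorts
and 10 planted cohorts at N = 114 with 24 patients each, 20 graphs for
angle recovery, 3 reference replicates, 3 full-rewiring cohorts; the
acceptance script uses 1 planted and 5 null cohorts per master seed.
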