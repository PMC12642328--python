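# Methods

This note documents the models and procedures implemented in `glandscape`,
the defaults and why they were chosen, the numerical details, and what the
synthetic benchmarks do and do not demonstrate.

## Cell-level QC and normalization

Cells arrive as one row per segmented cell with coordinates (pixel-centered,
0-based, x = column, y = row — the same convention as the gland masks),
compartment, raw marker intensities, and QC fields. Retention requires all
of:

* epithelial nucleus count in [1, 2] (one clearly segmented nucleus, at most
  two);
* each epithelial sub-compartment area (nucleus, membrane, cytoplasm) in
  (10, 1500] px — the lower bound is strict ("greater than 10"), the upper
  inclusive;
* whole-cell area in [50, 3500] px for epithelial and [30, 1500] px for
  stromal cells (both bounds inclusive — "between" is read inclusively);
* cyclic-registration quality score strictly above 0.85 (0 = no
  registration, 1 = perfect);
* epithelial cells must pass marker-specific registration QC for both basal
  markers (p63, CK5) before classification.

Rules are conjunctive; the QC report counts removals per rule, and a cell
failing several rules is counted once in the total. QC is idempotent.

Intensities are transformed as `log2(v + pseudocount)` with pseudocount 1.0
(a reference-free default that maps v = 0 to 0), then median-centered per
core and marker. Median-centering is the minimal batch correction consistent
with reference-free processing; it is monotone, so within-core ranks are
preserved, and it can be disabled (`median_center=False`). Manual
signal review of intensity outliers cannot be automated; an optional
quantile cap stands in for it and is off by default.

## Marker gating by Gaussian mixture EM

Per marker, log2 intensities are modeled as `f(x) = Σ_k π_k N(x|μ_k, σ_k²)`
with K = 2 by default (K = 3 supported for markers with an intermediate
population; the choice is the user's, guided by the histogram). EM runs the
standard E-step (posterior responsibilities γ_ik, computed in log space) and
M-step (weighted moment updates) until the relative log-likelihood change
falls below ε = 1e-8 or 1,000 iterations. Numerical choices:

* **Initialization** is quantile-based — component means at the
  (2k−1)/(2K) quantiles, equal weights, pooled variance — because it is
  deterministic: an annotation-free pipeline should give the same answer on
  the same data every time. A seeded k-means initialization is available.
* **Variance floor** at 1e-6 of the total variance prevents a component
  from collapsing onto a single point.
* Components whose weight falls below 1e-6 are pruned with a warning.
* The log-likelihood is asserted non-decreasing at every iteration. Note
  that a relative log-likelihood change below ε bounds one further EM
  step's parameter drift only at the √ε scale (the likelihood is locally
  quadratic), which the test suite checks at 10·√ε.

A cell is **positive** when the posterior argmax is the component with the
largest mean — the foreground population sits at the high end of the
histogram. A cell exactly at a posterior crossing is called negative; the
tie is measure-zero and the convention is fixed for reproducibility.

Basal markers combine by logical OR: positivity for p63 or CK5 marks a
basal (N-CE) cell; epithelial double negatives are CE; stromal cells are
"stroma". Immune phenotypes from binary calls: T_reg = CD3+CD4+FOXP3+,
T_H = CD3+CD4+FOXP3− (disjoint by default — the overlapping convention in
which every T_reg also counts as T_H is available via
`th_excludes_treg=False`), macrophage = CD68+; priority
T_reg > T_H > macrophage when definitions overlap.

## Gland modeling

Cells map to glands by the mask label at their rounded pixel position.
Per gland:

* **Eligibility.** A gland qualifies for shape modeling iff it contains at
  least one N-CE cell and its area/N-CE-count ratio is at most
  25,000 px per cell. A gland too large for its N-CE count is more
  plausibly a CE-dominated gland with a few scattered basal-positive cells
  than a true benign gland; such glands are CE. The ratio is read as
  area/count (exclude when it *exceeds* the threshold), which is the only
  direction under which sparsely populated structures are excluded.
* **Ordering.** The Euclidean MST of the gland's N-CE cells is built; the
  ordering is the tree's diameter path (double traversal), with off-path
  cells inserted after their nearest path vertex. This yields one
  continuous ordering along the gland contour even when the tree branches.
* **Principal curve.** Alternating steps: fit cubic regression splines
  x(t), y(t) at df = 8 (df = number of spline coefficients; 4 interior
  knots at quantiles of t; df is lowered to n−1, minimum 2, for tiny
  glands, with the spline order dropping below cubic when df < 4) against
  the current projection parameters, then re-project all points onto the
  densely sampled curve (20 samples per point) to update t. Iteration
  stops on relative residual improvement < 1e-4, on non-improvement, or at
  30 iterations; the best curve so far is kept, so the reported residual
  trace is non-increasing. Curves are fitted open: a ring-shaped rim yields
  an open curve covering the ring with a seam. df = 8 trades fidelity to
  gland morphology against over-smoothing.
* **Band.** The curve polyline is dilated by a 10 px Euclidean half-width
  with round caps (true per-segment perpendicular strips leave wedge gaps
  at vertices). Membership is distance-to-polyline ≤ 10 px, boundary
  inclusive. Epithelial cells inside the band are (re)labeled N-CE,
  epithelial cells in the gland but outside the band CE. The relabel is
  restricted to epithelial cells so immune phenotypes are never
  overwritten. Cells outside every gland keep their mixture-model labels.
* Gland area is the pixel count of its mask label; the centroid is the
  unweighted mean of the label's pixel coordinates.

## Spatial features

All geometry is computed in pixels; conversion to micrometres (default
0.325 μm/px = 6.5 μm camera pixel / 20× objective, overridable) happens at
output only.

* **Cell-centric (point view):** distance from each T cell to the nearest
  CE-gland centroid within the same core (cores are disjoint images).
  Undefined when the core has no CE gland; such cores are unusable and are
  excluded before patient summaries.
* **Region-centric (shape view):** CD68+ cells are clustered by DBSCAN with
  eps = alpha (default 30 px ≈ 10 μm, about one cell-neighborhood) and
  min_samples = 5, then each cluster is wrapped in an alpha shape —
  Delaunay triangles with circumradius ≤ alpha, unioned. Using the same
  radius for clustering and concavity keeps one spatial scale. The
  reference construction for these regions does not pin its parameters, so
  both are exposed in config. Gland boundaries for this view are
  polygonized mask contours (CE glands have no fitted curve). Distance is
  the minimum boundary-to-boundary separation, or 0 with an infiltration
  flag when the polygons overlap (checked by two predicates: intersection
  or containment).
* **Patient summaries:** medians of T-cell distances pooled over the
  patient's usable cores; mean of natural-log MD-region areas;
  infiltration events counted. Patients with no T cells of a phenotype get
  a missing median and are excluded from that phenotype's survival
  analysis rather than imputed; patients with no usable core are dropped
  with a warning.

## Outcome statistics

* Permutation χ²: observed Pearson statistic; null by shuffling grade
  labels over cells (10,000 shuffles by default); add-one correction
  `p = (1 + #{perm ≥ obs})/(1 + n_perm)`, so p is never 0 and is bit-exact
  reproducible from the seed. Cell-level shuffles match the primary
  analysis; a per-core block shuffle acknowledging within-core correlation
  is a planned option.
* Benjamini–Hochberg step-up for each family of tests.
* Two-sided permutation test on |median difference| for AMACR between CE
  and N-CE, with the fold change reported as the ratio of medians on the
  linear scale (log2 alongside); undefined when a median is nonpositive.
* Kruskal–Wallis (tie-corrected) for grade trends; all-identical data give
  H = 0, p = 1.
* Kaplan–Meier per group with a two-group log-rank test (lifelines), the
  feature dichotomized at the cohort median with value ≥ median in the
  "far" group. Patients without recurrence are censored at last follow-up;
  the synthetic cohort applies administrative censoring at a fixed horizon
  (default 60 months).

## Synthetic tissue: what it emulates, and what it does not

The generator produces, per core: perturbed-circle glands at the scale of
real prostate acini (radius 120–200 px ≈ 40–65 μm at 0.325 μm/px, so the
25,000 px/cell eligibility ratio behaves as it does on tissue); benign
glands as a basal-cell ring just inside the boundary (rim width 6 px,
within the 10 px band); CE glands filled with basal-negative,
AMACR-positive cells; stromal cells outside glands; T cells placed at a
configurable normal distance beyond gland boundaries; macrophages in a few
dense clusters (so MD regions exist); and per-marker intensities from a
two-component Gaussian in log2 space, stored linearly as `2^x − 1` so the
log2(v+1) transform recovers them exactly. Default marker components sit
~6 pooled sd apart — basal and immune lineage markers in multiplexed IF
are close to on/off — while the classifier's stress tests use the 4-sd
floor of the well-separated regime explicitly. Geometry, each cell
population, and intensities draw from named sub-streams of one seed, so
enlarging one population does not perturb another, and outputs are
byte-reproducible.

Cohorts add a per-patient latent feature (the immune placement distance),
exponential recurrence times with hazard `h0 · m(feature)` (baseline
0.02/month), administrative censoring, and grade groups at configurable
proportions. With `cores_per_patient = 0` only the clinical table is
generated — the fast path used for survival-test calibration.

The generator intentionally matches the classifier's generative family
(two-component Gaussians in log space) so parameter recovery is a fair,
well-posed test. Consequences for interpretation: passing tests show the
pipeline recovers truth *when its model assumptions hold and populations
are well separated*. Real tissue violates these in ways the generator does
not emulate — heavy-tailed and overlapping intensity distributions,
autofluorescence, segmentation errors spilling signal between neighbors,
glands that touch or share basal rims, tangential gland sections, and
spatially correlated QC failures. Accuracy numbers from the synthetic
benchmarks are therefore upper bounds, not estimates of performance on
tissue.

## Problem sizes and defaults used by the checks

The test suite and acceptance script use: EM recovery at n = 5,000;
classifier end-to-end on a ~2,900-cell core (dense CE glands keep EM
parameter noise small, as in pooled cohort fits); gland accuracy over 4
cores / 20 glands; MST optimality on 50 five-point instances against
exhaustive enumeration; curve checks on a 40-point line and a noisy
200-point 3/4 circle; band membership on 1,000 points against a 50-vertex
polyline; type-I calibration with 500 null simulations at 399 permutations
each (the permutation count affects p-value granularity, not validity — the
10,000-shuffle default is used for data analysis); log-rank power with 100
cohorts of 400 patients; and a 3-patient end-to-end determinism run
compared byte-for-byte. 

## Known limitations

* The principal curve is open; a periodic fit for complete rings would
  remove the seam and is a natural extension.
* BIC-based automatic choice of K is not implemented; K is a user choice
  (2 or 3).
* The alpha-shape takes the largest polygon when a cluster's triangles are
  disconnected; holes in MD regions are not preserved.
* Block (per-core) permutation for the composition tests is not yet
  implemented; cell-level shuffles ignore within-core correlation.
* The Kruskal–Wallis p-value uses the χ² approximation, inaccurate for
  very small groups.
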