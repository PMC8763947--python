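# Methods

`pdxnet` reimplements, as a tested pipeline, the computational analysis of a
preclinical NSCLC patient-derived xenograft (PDX) cohort: expression
normalization, marker-cutoff histology classification, single-sample
enrichment of a nine-gene paracrine signaling set with a permutation
over-representation test, expression-based clustering linked to therapy
resistance, and RECIST efficacy/tolerability analysis of caliper trials.
Because no raw cohort is distributed with the package, a synthetic-data
module generates inputs with the statistical structure the analysis assumes.

## Synthetic cohorts

**Expression.** Counts are negative-binomial around log-normal gene
baselines: gene baselines are drawn as `log2 mu_i ~ N(5, 2)`, each sample
carries a sequencing-depth factor `exp(N(0, 0.3))`, and counts follow
`NB(mean = mu_ij, dispersion = 0.1)` (variance `mu + 0.1 mu^2`), the standard
bulk RNA-seq noise model at a typical biological dispersion. Structure is
additive on the log2 scale of the mean:

* two histology clusters (default 26 "A" vs 12 "B" of 38 samples), driven by
  a block of `n_cluster_genes = 300` genes shifted by `cluster_shift = 2`
  log2 units in cluster A — histology affects broad expression programs, so
  a single marker gene cannot (and should not) drive full-matrix clustering;
* the squamous marker gene (TP63), pinned at a low baseline of 5.5 log2
  units and shifted by `marker_shift = 8` in cluster A. The baseline is
  pinned rather than drawn because the downstream classification cutoff
  (12) is an absolute-scale rule; the default shift places the marker-high
  cluster clearly above the cutoff while count noise keeps the separation
  imperfect in smaller effect settings;
* the nine-gene target set (CXCL12, CXCR4, EGF, EGFR, HGF, KDR, MET, PTGS2,
  VEGFA) shifted by `target_shift = 2` in a resistant subgroup
  (default 12/38 of samples, marked with prior best response PD).

The generator emulates mean shifts, overdispersed counts and depth
variation. It does **not** emulate gene–gene correlation beyond the shared
cluster blocks, gene-specific dispersion trends, batch structure, or any
mouse-versus-graft read mixture; passing tests therefore demonstrate
correctness of the computations and sensible behaviour under a plausible
generative model, not performance on real tumor data.

**Trials.** Each animal's true volume is `V0 * exp(g * t)` with `V0`
uniform on 150–200 mm³ (the randomization volume of the emulated design)
and a per-group daily rate `g`. Measurements multiply the true volume by
log-normal noise with median 1 and CV = 0.05 (realistic caliper error),
then are decomposed into a (length, width) pair with fixed aspect ratio
width = 0.8 × length, chosen so `length * width^2 / 2` reconstructs the
noisy volume exactly. Body weight is a Gaussian random walk
(`sd = 0.1 g/day`) around a 26 g baseline, with an optional per-group drift
to exercise the tolerability flag. Measurement days default to twice weekly
over four 7-day cycles (day 0–28).

## Normalization

Size factors use the median-of-ratios construction: for each gene with
strictly positive counts in every sample (the standard eligibility rule —
a single zero makes the geometric mean zero), the ratio of each sample's
count to the gene's geometric mean is formed, and the sample's factor is
the median ratio. The transform is `log2(count / size_factor + 1)`, which
is monotone, maps zero counts to zero and equals
`log2(count) - log2(size_factor)` to within 1e-3 for counts ≥ 1e4, i.e. it
is on the log2 scale for large counts. This simple shifted-log transform is
the package's design choice for variance handling; it does not attempt the
dispersion-trend-based variance stabilization some pipelines use, and none
of the downstream statistics here depend on that distinction.

Note one exactness caveat: rescaling one sample's column rescales every
gene's geometric mean by a common factor, so the "doubling a column doubles
its size factor" equivariance holds exactly on *ratios* of size factors,
and that is what the tests assert.

## Marker classification

Samples are called marker-positive when expression ≥ cutoff (default 12;
the threshold value itself is positive — the boundary convention follows
the ≥ rule, with the cutoff exposed as a parameter). Sensitivity and
specificity come with exact Clopper–Pearson 95% intervals:
`low = Beta(alpha/2; x, n-x+1)`, `high = Beta(1-alpha/2; x+1, n-x)`, with
the boundary conventions low = 0 at x = 0 and high = 1 at x = n. The exact
interval was chosen because it reproduces the reference intervals for the
cohort tallies (23/26 → [0.70; 0.98], 12/12 → [0.74; 1.00]) at
nearest-value rounding to two decimals, and its conservative coverage is
verifiable by direct simulation. Proportions are held at full precision
internally and rounded only at reporting.

## Single-sample enrichment and permutation test

The per-sample score is a GSVA-style statistic:

* kernel CDF `z_ij = (1/n) sum_k Phi((x_ij - x_ik)/h_i)` with per-gene
  bandwidth `h_i = s_i/4` (sample standard deviation, floored at 1e-8 so
  constant genes yield all-tied z = 0.5 rather than an error);
* per sample, genes ordered by decreasing z, ties broken by lexicographic
  gene symbol for reproducibility; centered rank statistic
  `r_ij = |p/2 - rank_ij|`;
* a random walk over the ordering stepping up `|r|^tau / sum_set |r|^tau`
  at set genes (tau = 1 default; tau = 0 gives the classical unweighted KS
  statistic) and down `1/(p-k)` otherwise. Default scoring is `max_diff`
  (max positive deviation + min negative deviation); `max_dev` (deviation
  of largest magnitude) is a flag. In `max_dev`, magnitude near-ties within
  1e-12 resolve to the positive deviation so summation order cannot flip
  the sign. If every hit weight is zero (all hits exactly at rank p/2),
  steps fall back to uniform 1/k.

The walk is evaluated only at hit positions: between hits it decreases
linearly, so its extrema occur immediately before/after hits or at the
endpoints (value 0). This gives O(k) scoring per sample after
preprocessing and is property-tested against a literal O(p) step-by-step
walk.

The permutation test computes rank statistics once, then scores `I` random
sets of size |S| drawn uniformly without replacement from the full universe
(members of S are *not* excluded by default; exclusion is a flag). Per
sample, `exceed = #{F >= E}`; the default smoothed p-value is
`(1 + exceed)/(1 + I)`, which is never zero and lies in [1/(I+1), 1]. A
`verbatim` mode reports `#{E > F}/I` — the complementary ratio, near 1 for
over-represented sets — retained because both directions of the ratio are
in circulation; the smoothed form is the one used as a significance
p-value. Cohort-level "scaled" scores divide by the maximum absolute score
(max-abs scaling, a flagged default; all-zero scores pass through with a
warning).

Calibration is checked by simulation: on a fully null cohort (all shifts
zero, so the target set is exchangeable with random sets) the smoothed
p-values across samples are uniform by a Kolmogorov–Smirnov test; on a
cohort with the target set shifted by 4 log2 units in a resistant
subgroup, essentially all resistant samples reach p ≤ 0.01. These runs use
2,000 genes × 200 samples and I = 2,000 — sizes chosen so the whole
calibration completes in seconds while leaving the test well-powered; the
statistic itself is O(k log p) per permutation and sample, so cohort-scale
runs (19,096 genes, I = 100,000) remain routine.

## Clustering

Samples (columns) are clustered agglomeratively with complete linkage on
Euclidean distances over the full gene space; merge heights are
non-decreasing by complete-linkage monotonicity, and the tree is checked
against an exhaustive brute-force agglomeration on small instances. The
two main clusters come from a fixed k = 2 cut (maxclust criterion).
Cluster numbering follows decreasing size — cluster 1 is the larger —
since dendrogram left/right order is not meaningful. Per-cluster resistant
percentages are recomputed from integer counts at reporting time with
nearest-integer rounding (halves up): 7/16 → 44%, 5/22 → 23%.

## RECIST efficacy

Volumes are `V = length * width^2 / 2`; if a record has width > length the
axes are swapped with a warning. RTV is `V_t / V_0` with `V_0` at day 0
(randomization); the series is unit-invariant. Best response over the
evaluation window (default: all measured days):

* **CR** — nadir RTV ≤ 0.05. The emulated criteria define no numeric CR
  bound, so near-complete regression is used, configurable; no printed
  rate depends on it.
* **PR** — nadir RTV ≤ 0.7 (≥ 30% reduction).
* **PD** — max RTV ≥ 1.2 (≥ 20% increase). Progression is assessed
  against baseline, not against the nadir as in clinical RECIST 1.1,
  because the emulated volume criteria define the increase from baseline.
* **SD** — neither bound crossed.

"Best response" means the best category achieved: a nadir at 0.7 or below
yields PR even if the tumor later regrows past 1.2, which makes the call
monotone — lowering any single RTV value never worsens the category
(property-tested). ORR = (CR+PR)/n and CBR = (CR+PR+SD)/n as
nearest-integer percentages, always recomputed from the category counts.
A `diameter` metric flag applies the same thresholds to the longest axis
instead of the volume, for designs that track the longest diameter;
volume is the default. Tolerability is the maximum relative body-weight
loss from day 0, flagged at ≥ 5% by default.

## Pipeline

The `pdxnet` CLI chains the stages (`simulate`, `normalize`, `classify`,
`enrich`, `cluster`, `respond`, `run`, `report`) from one YAML config with
a mandatory root seed. Per-stage seeds are split deterministically from
the root via a seed sequence, so stages re-run in isolation reproduce
their outputs, and a run's manifest (seed, parameter echo, stage status)
fully determines reproduction. Any stage failure aborts with the stage
name; the manifest written at that point is marked incomplete.

## Limitations

* The generator's effect sizes and noise levels are free parameters of the
  emulation, not estimates fitted to any real cohort.
* The permutation test's null shares random sets across samples (as the
  construction prescribes), which introduces mild dependence between
  per-sample p-values; the calibration check treats them as independent.
* No multiple-testing correction across samples is applied — significance
  is reported per sample.
* Clustering recovers the generated histology partition only when the
  histology-driven block dominates noise; no stability analysis
  (bootstrap, consensus) is performed.
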