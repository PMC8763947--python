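# pdxnet

Analysis pipeline for preclinical NSCLC patient-derived xenograft (PDX)
cohorts. It is aimed at computational biologists running PDX panel studies
who need, in one tested package: bulk RNA-seq count normalization, histology
classification from a marker-gene cutoff with exact binomial confidence
intervals, single-sample gene-set enrichment of a paracrine "tumorigenic
network" signature with a permutation over-representation test,
expression-based hierarchical clustering related to therapy resistance, and
RECIST best-response / tolerability analysis of caliper tumor-volume
trajectories. A synthetic-cohort generator with known structure stands in
for non-shareable biobank data and backs all validation.

## The statistics at the core

**Normalization.** Median-of-ratios size factors
`s_j = median_i ( k_ij / (prod_l k_il)^(1/n) )` over genes with all-positive
counts, then `x_ij = log2(k_ij / s_j + 1)` (log2 scale for large counts).

**Marker diagnostics.** Positive call when `x >= cutoff` (default 12);
sensitivity/specificity with exact Clopper–Pearson intervals from Beta
quantiles, `[Beta_{α/2}(x, n−x+1), Beta_{1−α/2}(x+1, n−x)]`.

**Single-sample enrichment (GSVA-style).** Per gene, a Gaussian-kernel CDF
statistic `z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with bandwidth
`h_i = s_i/4`; per sample, genes are ranked by decreasing z and given the
centered rank statistic `r = |p/2 − rank|`. A KS-like random walk steps up
`|r|^τ / Σ_set |r|^τ` at set genes and down `1/(p−k)` elsewhere; the score E
is the sum of the maximal positive and minimal negative deviation. The
permutation test scores `I` random same-size sets per sample and reports the
smoothed p-value `(1 + #{F ≥ E}) / (1 + I)`.

**Clustering.** Complete linkage on Euclidean distances between sample
columns over all genes; k = 2 cut; per-cluster resistant fraction as a
rounded percentage.

**Efficacy.** `V = length × width² / 2`, RTV = V_t/V₀; best response per
RECIST-style volume thresholds (PR: nadir ≤ 0.7, PD: max ≥ 1.2, SD
otherwise, CR: nadir ≤ 0.05), ORR = (CR+PR)/n, CBR = (CR+PR+SD)/n; body
weight loss from baseline flagged at ≥ 5%.

Details, conventions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the full study arc on a
generated 2,000-gene × 38-sample cohort (26 marker-high squamous-like vs 12
adenocarcinoma-like samples, 12 resistant) and a two-arm caliper trial:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_normalize_expression.py
python analysis/03_marker_diagnostics.py
python analysis/04_gene_set_enrichment.py
python analysis/05_cluster_resistance.py
python analysis/06_recist_efficacy.py
```

Output of the run (tables land in `results/analysis/`):

```
confusion: tp=26 fp=0 tn=12 fn=0
sensitivity 1.00 CI [0.87; 1.00]
specificity 1.00 CI [0.74; 1.00]

12/38 samples with set over-representation at p <= 0.01
  thereof resistant: 12 of 12 resistant samples in the cohort
scaled enrichment scores span [-0.89, 1.00]

         n_total  n_resistant  percent_resistant
cluster
1             26           10                 38
2             12            2                 17
k=2 cut agrees with generated histology for 100% of samples

             n  CR  PR  SD  PD  orr_pct  cbr_pct
group
combination  3   0   3   0   0      100      100
placebo      3   0   0   0   3        0        0
tolerability: 0/6 animals with >= 5% body-weight loss
```

Reading it: the marker cutoff recovers the generated histology perfectly on
this cohort (the specificity interval [0.74; 1.00] is the exact bound for
12/12 — small denominators keep exact intervals wide); the nine-gene set is
significantly over-represented exactly in the resistant subgroup; the k = 2
expression cut reproduces the histology split; and the simulated
combination arm responds (ORR 100%) while placebo progresses.

The same stages run from one config via the CLI:

```bash
pdxnet simulate --outdir demo --seed 17
pdxnet respond --trial demo/trial.csv --out-calls demo/calls.csv
pdxnet run --config config.yaml
```

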