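# Methods

This note records the statistical models implemented in `crosspipe`, the
parameter defaults and why they were chosen, what the synthetic data
emulate, and the numerical and design decisions a maintainer would want to
know. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline grid

A pipeline is a pair (filtering, method). Filtering ∈ {filtered,
unfiltered}; method ∈ {tmm-limma, vsn-limma, voom-limma, log2quant-limma,
edger, deseq2}; the grid has 12 members. The four `*-limma` methods
normalize the counts and fit a moderated-t linear model; the two count
methods fit negative-binomial GLMs to the raw counts (they perform their
own internal scaling). Every pipeline emits, per contrast and gene, a log2
fold change, a t-like statistic, a p-value, and a Benjamini–Hochberg
adjusted p-value; all pipelines are BH-adjusted within (pipeline,
contrast). Contrasts are fitted on the subset of samples belonging to
their two groups; a "rest" denominator pools all non-numerator groups into
one level, giving a two-level design `[1, indicator(numerator)]` with
optional additive categorical covariate dummies (off by default, as
covariate usage is dataset-specific).

## Filtering

**Expression filter.** The design-aware rule popularised by edgeR's
`filterByExpr`: a gene is kept iff its CPM exceeds
`min_count · 1e6 / median(library sizes)` in at least k samples *and* its
total count is ≥ `min_total_count`, where k is the smallest group size,
softened for large groups (k = large_n + min_prop·(n_min − large_n) when
n_min > large_n). Defaults: min_count 10, min_total_count 15, large_n 10,
min_prop 0.7 — the rule's canonical defaults. Comparisons use a 1e-14
guard so a k that is mathematically integral but floats slightly off
behaves like the integer. The mask is invariant to sample and gene order
and was verified to agree exactly with the reference implementation on a
simulated fixture during development.

**Contrast signal filter.** Enrichment scores computed from a contrast
with almost no differential signal are noise; contrasts with fewer than
`min_de_genes` (default 30) genes at BH-adjusted p < alpha (default 0.05
— the threshold behind the "30 DE genes" count is a documented choice, as
conventions vary) are excluded from the consistency modules. Because the
count varies by pipeline, the default retention rule drops a contrast
globally when it fails in the majority of pipelines, so every pipeline
shares one contrast set for pairwise comparison; a per-pipeline rule is
selectable.

## Normalization

* **TMM** (`tmm_factors`): scaling factors from a doubly trimmed
  (30% of each M tail, 5% of each A tail), precision-weighted mean of
  log-ratios against a reference sample (the column whose upper-quartile
  CPM is closest to the mean upper quartile), normalized to product 1.
  TMM corrects composition bias; sequencing depth is absorbed by the
  library sizes inside `log_cpm`.
* **log-CPM** (`log_cpm`): log2((count + 0.5) / (lib·factor + 1) · 1e6).
  The prior count 0.5 keeps zeros finite and matches the convention of
  the moderated-t lineage.
* **Quantile-log** (`quantile_normalize_log`): log2(count+1), then each
  column's sorted values are replaced by the across-sample mean of order
  statistics; tied entries receive the mean of their tied target
  quantiles (average ranks interpolated into the target). Log-then-
  quantile order follows the microarray lineage of the method; note that
  with ties the output multisets can differ slightly between columns —
  exact multiset equality holds for tie-free columns.
* **glog VST** (`glog_vst`): per-sample median-of-ratios calibration
  followed by h(x) = log2((x + √(x² + c²))/2) with a single scale c per
  dataset, chosen by bounded 1-D search (c ∈ [1e-3, 1e4]) to minimize the
  absolute Spearman correlation between row means and row standard
  deviations. This is a deliberately simplified, "vsn-like" transform:
  the reference tool fits per-sample affine parameters by robust maximum
  likelihood, whereas a scalar c preserves the variance-stabilization
  contract (monotone per sample, log-like for large counts) with far less
  machinery. On structureless data the objective is flat in c and the
  fitted scale is arbitrary — harmless, since any c then stabilizes
  equally well.
* **voom** (`voom_transform`): log-CPM values plus per-observation
  weights. Per-gene sqrt(residual sd) from an OLS fit on the design is
  smoothed against average log2 count by lowess (span 0.5); each
  observation's weight is the trend prediction at its fitted log-count
  raised to −4, with predictions clamped to the trend's support at the
  extremes to avoid extrapolated negative variances.

## Differential expression

**Moderated t** (`fit_moderated_lm`). Per-gene (optionally weighted)
least squares; residual variances are shrunk by empirical Bayes,
s̃²ᵍ = (d₀s₀² + dᵍs²ᵍ)/(d₀+dᵍ), with (d₀, s₀²) estimated by the method of
moments on log residual variances (digamma/trigamma moment equations,
inverse trigamma by Newton). t = lfc / (s̃ᵍ√v_c) with v_c the contrast's
unscaled variance, referred to a t distribution on d₀+dᵍ df. In the
degenerate branch where the observed log-variance spread is below the
theoretical χ² spread, the prior df is infinite and the prior variance is
set to the geometric mean of the observed variances, making
equal-variance inputs an exact fixed point of the moderation (the
textbook moment estimator would instead apply the E[log χ²] bias
correction there). All-constant genes report stat 0, p 1, flagged.

**NB Wald engine** (`nb_wald_engine`). Median-of-ratios size factors;
per-gene NB dispersions maximize a Cox–Reid adjusted profile likelihood
(fitted means from a pilot fit at dispersion 0.1; dispersion grid of 41
log-spaced points on [1e-4, 10]); a mean-dispersion trend a₀ + a₁/μ is
fitted by least squares and genewise values are shrunk toward it on the
log scale with 10 prior df against the residual df. The GLM itself is a
log-link NB fitted by IRLS, vectorized across genes; the Wald statistic
lfc/SE is referred to the normal distribution and treated downstream as
t-like.

**NB quasi-likelihood engine** (`nb_ql_engine`). As above but on TMM
effective library sizes; quasi-dispersions (residual deviance / df) are
squeezed by the same moment machinery as the moderated linear model, and
the 1-df contrast is tested by F = Wald²/s̃², p from F(1, d₀+dᵍ). The
reported statistic is sign(lfc)·√F, so t² = F and ranking by |stat|
equals ranking by F.

Both count engines are "-style" reimplementations: no outlier
replacement, no independent filtering, no fold-change shrinkage. The grid
treats engines as interchangeable producers of t-like statistics, and
those refinements would change none of the concordance questions the tool
asks. During development the Wald statistics agreed with the reference
tool at rank correlation ≈ 0.98 on simulated data (effect estimates to
~0.01 on well-expressed genes); the moderated-t path agrees with its
reference to machine precision and the tests pin an IRLS-at-fixed-
dispersion oracle at 1e-6. Genes with all-zero counts in a contrast are
excluded from fitting and reported with lfc 0, stat 0, p 1.

## Enrichment (ulm)

For each gene set with ≥ `min_size` (default 5) member genes present in
the pipeline's gene universe: regress the per-gene t-like statistics on
the membership-weight vector (signed weights supported; non-members 0)
with an intercept, over the *full* universe of genes that pipeline
reports. The activity score is the slope's t-value (df = universe − 2);
p is two-sided. The universe deliberately differs between filtered and
unfiltered pipelines — that difference is precisely the effect the tool
measures. TF-style regulons default to signed weights (+1 activation,
−1 repression); `--unsigned` collapses them to binary membership. The
statistic column (never lfc or p) is the enrichment input.

## Consistency metrics

Spearman ρ (average ranks for ties) per contrast and unordered pipeline
pair, on the intersection of items; pairs sharing fewer than 3 items are
skipped. The similarity index uses per-tail intersections,
(|top∩top| + |bottom∩bottom|)/2N: with a pooled-union definition a
sign-flipped ranking could score 1, contradicting the requirement that a
score of 1 mean "same top and same bottom". Tail sizes: N = 15 (TF-like),
5 (hallmark-like), 3 (pathway-like), matched by resource-name substring,
and floor(5% · shared genes) in gene space. Ties in tail selection break
by item id, making outputs reproducible. Aggregation to per-pair and
per-pipeline values is the unweighted mean over retained contrasts
(per-contrast-then-average; pooled-across-contrasts is available via
`pooled=True`). Group comparisons (e.g. filtered vs unfiltered values)
use the one-sided Wilcoxon rank-sum test — exact when the pooled sample
is ≤ 20 and tie-free, normal approximation with tie correction otherwise
— with BH correction across a family of comparisons.

## Benchmarks

Pseudobulk profiles are per-(sample, cell type) sums of cell-level
counts; pseudobulks with < 10 cells or < 1000 total counts are dropped,
and unlabeled cells are discarded first. Marker truth: in one-vs-rest
contrasts, the marker set of the contrast's own cell type is the positive
among all marker sets. TF truth: binding-score rows are processed in
globally descending score order (ties by TF id) and each TF is assigned
to the first cell type claiming it, at most k = 10 per cell type — the
simplest rule consistent with "top-k by binding affinity" plus the
uniqueness constraint, so contested cell types may end with fewer than k.
Perturbation truth: each contrast's mapped gene set(s) are positives
among the union of mapped sets. Instances are pooled across contrasts
within a scope, ranked by activity score (ties by instance id), and
scored by tie-aware AUROC (Mann–Whitney formulation) and AUPRC in the
average-precision formulation — trapezoidal interpolation of PR curves is
biased, average precision is not.

## Synthetic data

`simulate_bulk_counts` draws NB counts with variance μ + φμ², log-normal
per-gene baselines around `baseline_mu`, log-normal library factors with
given CV (default 0.3), planted log2 fold changes on chosen genes in the
perturbed group, and a `low_count_fraction` stratum with baseline means
near 1 emulating the detection floor the expression filter targets.
`simulate_cell_counts` adds per-cell-type marker over-expression
(default 8-fold) so the pseudobulk + marker-truth loop closes.
`make_toy_collections` mimics the shapes of the common resources:
14 pathway-like sets, 50 hallmark-like sets, 30 signed TF-like regulons,
all ≥ 5 genes.

What the generators do *not* emulate: empirical mean-variance curves of
real platforms, correlated genes, batch structure, compositional shifts,
or zero-inflation beyond NB sampling. Passing tests therefore demonstrate
correctness of the machinery and the direction of filtering effects under
controlled noise, not the published effect sizes from real cohorts —
which depend on external data and are out of scope.

Two scenario presets define the stress tests:

* **Low-signal decoupling** — 30 independent two-group contrasts (4 vs
  4), planted |lfc| = 0.5 on one hallmark-like set each, 40% low-count
  genes, dispersion 0.3: weak signal on a noisy floor, the regime where
  filtering should raise cross-pipeline agreement in set space.
* **Shallow-profile perturbation benchmark** — 18 contrasts (3 vs 3) at
  baseline mean 5 with 70% of genes near zero and dispersion 0.6; 60% of
  contrasts are responsive (lfc 1.2 on the mapped set), the rest null,
  candidate universe of 6 mapped sets (prevalence 1/6). The shallow depth
  puts most of the transcriptome at the detection floor, the regime in
  which unfiltered pipelines are degraded by floor noise and filtering
  should improve AUROC/AUPRC. An earlier deep-bulk parameterization
  (baseline mean 200) saturated every pipeline and discriminated nothing;
  the preset was recalibrated to this regime, which is the one the
  benchmark is about.

Problem sizes throughout (600–2000 genes, 3–5 samples per group, 18–30
contrasts, 100 recovery replicates) were chosen so each simulation answers
its question in seconds to a few minutes on one CPU.

## Numerical choices and edge cases

* IRLS: log-link, working-response updates, η clipped to ±30, convergence
  at max|Δβ| < 1e-8 or 30 iterations; singular normal equations fall back
  to the pseudoinverse.
* Dispersion grid: 41 points, argmax without refinement — dispersion
  enters downstream only through mildly varying weights, and a ~12%
  grid spacing is below the noise of the estimate at these sample sizes.
* Inverse trigamma: Newton iterations with the standard asymptotic
  starting point; prior df capped at 1e6 when referring t/F statistics
  (indistinguishable from the normal/χ² limit).
* BH adjustment is applied within (pipeline, contrast) families.
* Determinism: every stochastic generator takes an explicit integer seed;
  no global RNG state is consumed. Re-running a configuration reproduces
  outputs byte-identically.
* Degenerate inputs: empty matrices, single groups, all-constant genes,
  all-zero genes, single-sample quantile normalization, sets below
  min_size, universes too small for the requested tails, and single-class
  benchmark labels all raise typed errors or return flagged null results,
  as documented per function.

## Known limitations

* The glog VST is dataset-calibrated with one scale parameter, not the
  full per-sample affine robust fit of the reference tool; its outputs
  are comparable in contract (variance stabilization) but not numerically.
* The NB engines' p-values rely on normal/F reference distributions
  without the reference tools' outlier handling; at very small n both are
  approximate (the test suite checks calibration only at n = 5 vs 5).
* Covariates enter designs additively as categorical dummies; no
  continuous covariates, interactions, or random effects.
* Single-cell data are supported only through pseudobulk aggregation.
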