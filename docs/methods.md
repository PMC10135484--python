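# Methods

## Count model of the synthetic cohort

`syndata.generate_cohort` draws UMI counts from a negative binomial via
a gamma–Poisson mixture: for gene *g* and cell *c*,
`count ~ Poisson(Gamma(θ, μ(g,c)/θ))` with dispersion θ
(`nb_dispersion`, default 2.0 — moderate over-dispersion typical of
droplet data). The mean factorizes as

```
μ(g,c) = base(g) · batch(g, sample(c)) · program(g,c) · label(g,c) · lib(c)
```

* `base(g)` — baseline means are log-normal: background genes
  LN(ln 0.2, 1.0) (wide, realistic sparsity), planted program genes
  LN(ln 0.5, 0.3) (a narrower, slightly higher band so the
  nonzero-expression module-cell rule has a stable footing), optional
  constitutive subtype markers LN(ln 0.4, 0.4).
* `batch` — per-sample, per-gene multiplicative log-normal offsets with
  σ = `batch_sd` (default 0.15), the simplest structure the consensus
  step must average out.
* `program` — `effect_size` (default 6) on a program's genes in cells
  where that program is active, 1 elsewhere. Activity is binary per
  cell; exactly `round(fraction · n_cells)` cells are active per
  program (default fraction 0.35), sampled without replacement.
* `lib(c)` — per-cell log-normal library factor, σ = `library_sd`
  (default 0.3), so normalization is non-trivial.

**Subtypes as program preference.** Cell subtypes are not given
separate constitutive marker blocks by default. Instead each program
has a *home* subtype whose cells receive `program_home_weight`
(default 4) times the sampling weight when active cells are drawn, so
programs are enriched ~3-fold in their home subtype. Subtype markers
are therefore the home program's genes, which makes the downstream
pipeline self-consistent: the gene universe built from subtype markers
is the planted program genes, and per-sample NMF factors correspond to
programs. Constitutive markers can be planted in addition
(`cluster_marker_size`, `cluster_marker_fold`) for experiments that
need subtype identity independent of programs.

**What the generator does not emulate:** doublets, ambient RNA,
mitochondrial pathology, graded (non-binary) program activity, gene-gene
correlation beyond the planted blocks, and realistic anatomy in the
spot grid. Passing tests therefore demonstrate correctness of the
procedures under the stated statistical model, not performance on real
tissue.

## Canonical study conditions

The canonical cohort used by the test suite and the reproduction
script: 12 samples of 150–400 cells (spanning both rank regimes of the
cell-count rule), 1,000 genes, 4 disjoint 50-gene programs,
`effect_size` 6, activity fraction 0.35, `batch_sd` 0.15. Planted-module
recovery is summarized as the mean top-20 Jaccard between discovered
modules and each program's top-20 genes by expected baseline
expression, under optimal one-to-one matching (so one module cannot
absorb two programs).

## Preprocessing

* QC keeps a cell iff detected genes ≥ 300 AND total UMIs ≤ 50,000 AND
  mitochondrial fraction < 0.05 (the 5% criterion is read as an upper
  bound, the standard convention). The report records the first failed
  criterion per removed cell.
* HVG selection ranks genes by the variance of clipped standardized
  values (clip at √n_cells). The log-variance vs log-mean trend is
  fitted with a quadratic polynomial in log10 space — a deliberately
  simple smoother standing in for a loess fit; with fewer than three
  distinct gene means the per-gene standard deviation is used directly.
  Ties are broken by gene id.
* log2 fold changes are `log2((m₁+ε)/(m₂+ε))` with
  `m = mean(expm1(lognormalized))` and pseudocount ε = 1/scale_factor
  (exposed as a parameter, since conventions differ between toolchains).
* The Wilcoxon rank-sum test uses the exact U distribution when both
  groups are ≤25 and untied, and the normal approximation with tie and
  continuity correction otherwise (R's `wilcox.test` convention). The
  Bonferroni family is all genes tested in all clusters of one call —
  the most conservative reading.
* Markers are only tested for genes detected in ≥10% of either group
  (configurable), which avoids degenerate rank configurations.

## Signature scoring

The binned-control score cuts genes into 24 equal-frequency bins by
mean expression and samples 100 control genes per signature gene from
its bin (with replacement only when the bin is smaller), one shared RNG
per call. Missing signature genes are dropped with a warning; fewer
than half present is an error. `exclude_query_genes=True` removes the
union of the query signatures' genes from the control pools: when one
signature's genes are condition-dependent, they otherwise contaminate
the expression-matched control pools of the *other* signatures scored
in the same call and induce spurious anti-correlated group differences.
Group comparisons of multiple related signatures should use this mode
(the disease-association analysis does).

## Consensus NMF

* Multiplicative updates on the Frobenius loss, `max_iter` 500, `tol`
  1e-5 on the relative loss change, uniform random initialization from
  the seed, W columns rescaled to unit L2 norm with the scale absorbed
  into H. The loss trace is recorded every iteration and is
  non-increasing by construction; all-zero rows are dropped and
  re-inserted as zero loadings.
* The cell-count rule maps <100 cells → excluded, 100–300 → rank 6,
  >300 → rank 8; the boundary n = 300 falls in the low band (literal
  reading of the rule). All fields are configurable.
* Consensus distance is `1 − Pearson r` over gene loadings; linkage is
  average (UPGMA), robust for correlation distances; complete linkage
  is available. `k` is a parameter (the reference workflow chose it
  manually from the dendrogram; the dendrogram is always exportable as
  Newick so users can re-cut).
* Module definitions average L1-normalized member loadings (samples
  with different cell counts and ranks contribute comparably) and take
  the top-20 genes, ties broken by gene id.
* "Expressed" in the ≥70% module-cell rule means a nonzero normalized
  value — the only parameter-free reading; the threshold fraction is
  a parameter and genes absent from the matrix shrink the denominator.

## Group tests and dependency

Differential expression between disease and control cells is always
region-matched. Cross-disorder sharing uses exact-subset (UpSet)
decomposition; group PCA standardizes the columns of the
group × top-DEG mean matrix and decomposes by SVD. Module dependency
is Spearman over per-cell module scores with the r ≥ 0.3 / r ≤ −0.3,
p < 0.05 classification; a per-sample-mean granularity is available by
aggregating scores before the call.

Per-cell group tests pool cells across samples and therefore assume no
residual between-sample variation under the null: with thousands of
cells per side, genuine per-sample batch offsets (or library-size
composition shifts induced by a strongly boosted program) are reliably
detected, which is a pseudoreplication property of all cell-level
two-group tests, not an artifact of this implementation. The null
calibrations consequently permute labels at the cell level (the
exchangeable null), and the planted disease-shift experiment sets
`batch_sd = 0`, uses a 2,000-gene background so the boosted program is
a small fraction of the library, and scores with
`exclude_query_genes=True`.

## Proteomics

Complete-case filtering removes, while any missing value remains, the
single protein or sample with the most missing entries (ties prefer
proteins); the removal order is logged. This worst-first greedy keeps
~95% of proteins at 2% MCAR missingness on a 200×60 table, whereas
dropping every incomplete protein outright would keep ~30%. Module
abundance scores are means of per-protein z-scores — the simplest
scale-free composite for a pre-normalized abundance table; per-module
validation requires ≥ half the genes matched, with explicit per-module
exception counts (e.g. a small module whose few proteins are
functionally coherent). Correlations are Spearman over all samples
(pooled); within-status correlation can be obtained by subsetting the
score table before the call.

## Statistical tolerances in the tests

Monte-Carlo assertions use explicit envelopes: family-wise error under
permutation is compared against the ~99% binomial envelope of the
nominal 0.05 level (6/50 replicates), per-test rejection rates against
a 3-standard-error band, and the null trait-correlation false-positive
rate against [0.03, 0.07] at n = 4,800 tests. Planted-effect recovery
thresholds (Jaccard ≥ 0.6, sensitivity/specificity ≥ 0.8, ≥90%
detection over 50 replicates) are met with margin under the canonical
conditions above. Experiment sizes (e.g. 5 cohort seeds for recovery,
50 replicates for detection rates, 200 for trait calibration) were
chosen to keep each experiment's Monte-Carlo error well below its
assertion margin.

## Known limitations

* The NMF rank rule and the consensus k are taken as given; no model
  selection is performed.
* The quadratic mean–variance trend slightly under-ranks planted
  program genes relative to a loess fit; HVG recovery on the canonical
  cohort is ~89% in the top 30% of genes.
* The exact-permutation agreement of the rank-sum test is checked on
  untied data; with heavy ties at n ≤ 8 the two-sided "exact" p is
  definition-dependent and the asymptotic approximation can deviate
  near p = 1.
* MCAR missingness in the synthetic proteome is hardest on
  complete-case filtering when rows and columns carry similar missing
  loads; real TMT missingness is structured (batch-wise), which the
  generator does not emulate.
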