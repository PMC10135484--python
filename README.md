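# astromod

Consensus discovery and cross-omics validation of astrocyte
co-expression modules in multi-sample single-cell cohorts.

## The problem

Astrocyte transcriptional programs — reactive states, ECM remodeling,
stress/inflammation, ion homeostasis — recur across individuals, brain
regions and disorders, but any single scRNA-seq sample is too noisy and
too batch-laden to define them. `astromod` implements the
consensus-factorization strategy for that setting:

1. **QC and preprocessing** — drop cells with <300 detected genes,
   >50,000 UMIs or ≥5% mitochondrial UMIs; log-normalize
   (`ln(1 + 10⁴·count/libsize)`); select highly variable genes; detect
   one-vs-rest subtype markers (Wilcoxon rank-sum, log2FC > 0.25,
   Bonferroni-adjusted p < 0.05).
2. **Per-sample NMF** — build a gene universe from strong subtype
   markers (log2FC > 0.6), then factorize each sample's normalized
   universe matrix `X ≈ WH` (multiplicative updates on the Frobenius
   loss). The rank follows the cell count: samples with <100 cells are
   excluded, 100–300 cells → rank 6, >300 cells → rank 8. Every column
   of `W` is one *submodule*.
3. **Consensus clustering** — pool all submodules, compute pairwise
   `1 − Pearson r` over gene loadings, cluster hierarchically (average
   linkage), cut the tree into *k* consensus modules, and define each
   module by the top 20 genes of its averaged L1-normalized loadings.
   A cell is a *module cell* iff it expresses ≥70% of a module's genes.
4. **Statistics** — binned-control signature scoring of cells and
   spatial spots (score = mean expression of signature genes minus
   expression-matched controls), region annotation by argmax score,
   Kruskal–Wallis condition comparisons, region-matched case-vs-control
   differential expression with cross-disorder shared-set (UpSet)
   logic and group-level PCA, and pairwise module dependency by
   Spearman correlation (co-occurrent at r ≥ 0.3, exclusive at
   r ≤ −0.3, p < 0.05).
5. **Protein-level validation** — complete-case filtering of a protein
   abundance table, module↔protein matching (validated at ≥half
   coverage, with explicit per-module exceptions), per-sample module
   abundance scores (mean per-protein z-score), Spearman correlations
   with neuropathological/cognitive traits, and case-status Wilcoxon
   comparisons.

Everything is exercised on a built-in synthetic cohort generator
(`astromod.syndata`) that plants known programs, cell subtypes, batch
effects, spatial regions and a module-correlated proteome, so every
step can be scored against ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the
canonical synthetic cohort (12 samples of 150–400 cells, 1,000 genes,
4 disjoint 50-gene programs at 6-fold effect):

```bash
python analysis/01_simulate_cohort.py
python analysis/03_discover_modules.py
```

prints

```
cohort: 12 samples, 2980 cells, 1000 genes, 4 planted programs
universe: 200 genes; 78 submodules -> 4 modules
  program  top20_jaccard
0      P1          0.739
1      P2          0.739
2      P3          0.667
3      P4          0.818
```

i.e. the marker-derived gene universe contains exactly the 200 planted
program genes, the 12 per-sample factorizations yield 78 submodules
(rank 6 or 8 each), and the four consensus modules recover the planted
programs with top-20 Jaccard 0.67–0.82. The module-cell rule then
calls activity per cell at ~0.97 sensitivity and ~0.96 specificity
against the planted truth. Scripts 04–07 continue with dependency
classification (a planted co-occurring pair at r = 0.70, an exclusive
pair at r = −0.45), spatial region annotation (99.5% of 400 spots
correct), cross-disorder DE (all 10 planted shared genes recovered),
and proteomic validation (the planted early AsymAD shift detected at
p = 3e-5 in the shifted module only).

The same operations are available as a CLI
(`astromod simulate|preprocess|score|modules|deg|proteo`), reading and
writing MatrixMarket/TSV/GMT files.

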