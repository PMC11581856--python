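# Methods

This note records the models, defaults, and design decisions behind
`immunosubtype`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic cohort generator

The generator exists so that every pipeline stage can be exercised against
a known ground truth. It emulates the statistical structure the analyses
assume, not any particular dataset.

**Bulk expression.** Each sample belongs to one of two latent subgroups —
G1 (immune-high, monocytic) or G2 (immune-low, granulocytic) — with default
prevalences 0.45/0.55, chosen near the roughly 45/55 split reported for
immune subgroups in AML cohorts. A sample's cell-type mixing fractions are
Dirichlet draws with subgroup-specific concentration parameters (default
G1: (12, 3, 6, 4, 2), G2: (3, 14, 3, 3, 4) over monocyte, granulocyte,
T cell, B cell, stromal), so G1 is monocyte-rich and immune-rich and G2
granulocyte-rich. Expected expression is
`library_size × Σ_t fraction_t × normalized signature_t`, and observed
counts are negative-binomial with variance μ + μ²/θ (default θ = 10, a
typical bulk RNA-seq overdispersion; θ = ∞ is accepted and gives the
Poisson, i.e. zero-overdispersion, limit). Cell-type signatures are a
shared lognormal baseline with a disjoint block of 100 marker genes per
type up-weighted 12-fold; with the baseline's σ = 0.5 the top-50 genes of
each signature are its own markers, which makes `export_gene_sets`
deterministic and informative.

**Clinical covariates.** Survival is exponential (Weibull shape 1) with a
planted G1-vs-G2 hazard ratio (default 2, matching the magnitude of the
subgroup effect reported for AML immune subgroups; baseline hazard
0.02/month, uniform censoring on (0, 60) months). Mutation flags are
Bernoulli with per-subgroup frequencies; the defaults (FLT3 0.38/0.18,
DNMT3A 0.34/0.18, NPM1 0.30/0.06) are the published per-subgroup mutation
frequencies in the TCGA AML cohort, so the contingency machinery is tested
at realistic effect sizes. Drug AUCs are affine in the sample's immune
mixing fraction with Gaussian noise whose variance is solved analytically
so that the population correlation equals the configured target (defaults
±0.5 for three named drugs, matching the magnitude of reported
drug–immune-score correlations; higher AUC = more resistant ex vivo).

**Single cells.** Cells are drawn per type around the same signatures with
per-cell library sizes uniform in (1000, 3000); malignancy is a per-type
flag (monocyte and granulocyte by default); percent-mitochondrial values
are uniform on (0, 8) so the quality-control filter at 5% has work to do.

**What the generator does not emulate** — batch effects, doublets, ambient
RNA, FAB-subtype-specific programs, gene–gene correlation beyond the
mixture structure, and realistic zero inflation. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
performance on real sequencing data.

## Immune scoring

ssGSEA follows the rank-based running-sum form: per sample, genes are
ranked by expression (average ranks on ties), and the score accumulates the
difference between the in-set ECDF weighted by rank^α (α = 0.25) and the
unweighted out-of-set ECDF. Scores are *not* rescaled to any published
affine calibration; they are comparable within a cohort only. Abundance
estimation is plain NNLS per sample over the signature genes — a
deliberate, transparent stand-in for heavier deconvolution machinery; the
TIS consumes whatever abundance table the caller supplies. Quartile
grouping uses k = round-half-up(q·n), the only common rounding rule
consistent with both published group sizes (43 of 173 and 64 of 255).

## Consensus clustering

Base clustering is k-means (10 restarts) on per-gene standardized
expression, resampling 80% of samples without replacement (the field's common consensus-clustering defaults).
Consensus entries are co-cluster counts over co-sample counts; pairs never
co-sampled (vanishingly rare at ≥1000 resamples) get consensus 0 and a
counter. k is selected as the largest k whose relative delta-area gain is
≥ 0.1 *and* whose minimum cluster-consensus is ≥ 0.9 — the 0.9 floor is the
common cluster-stability heuristic, and on the synthetic cohorts it
correctly rejects the semi-stable sub-splits of the continuous mixing
gradients that a looser floor admits. Final assignments cut an
average-linkage tree on 1 − M; the cluster with the higher mean immune
score is G1, which fixes the label orientation reproducibly (ties fall
back to cluster size, with a warning).

## Differential expression and RRA

The DE engine is Welch's t-test on log₂-CPM with Benjamini–Hochberg
adjustment. This is a deliberate choice: the pipeline's contract only
needs per-cohort *rankings*, the target cohorts ship normalized rather
than raw counts (which undermines count-model assumptions), and a
negative-binomial engine is explicitly out of scope. RRA aggregates
up- and down-regulated rankings in two separate runs (standard RRA
practice); genes absent from a list receive the worst normalized rank 1.
The beta score is the exact binomial tail P(Bin(k, r₍ⱼ₎) ≥ j) — verified
in the suite against Monte-Carlo order statistics — and the reported score
is the Bonferroni-corrected minimum, which is conservative under the null
(also verified by simulation).

## Co-expression networks

Unsigned adjacency with default soft power β = 4 (the power reported for published AML immune co-expression
networks); scale-free fit is the R² of a log–log regression of
binned connectivity frequency (10 equal-width bins). Modules come from a
*static* cut of the average-linkage tree on 1 − TOM (cut height 0.95,
minimum module size 10): simpler and deterministic where the dynamic
hybrid cut is an implementation detail nothing downstream depends on.
Module names are assigned by decreasing size with lexicographic
tie-breaks, so labels do not depend on input order. Eigengenes are first
principal components sign-aligned to the module mean profile. Key genes
require membership in a module with |cor(eigengene, immune score)| ≥ 0.6
and p < 0.001 (both published immune-specific modules, |r| = 0.61 and
0.88, would qualify) plus GS ≥ 0.2 and MM ≥ 0.8 (the WGCNA tutorial
convention). Outlier samples can
be removed beforehand by standardized sample connectivity < −2.5.

## Signature mapping and the differentiation score

`bulk_signature_scores` drops genes with total count < 35, z-scores each
gene across samples (population SD), and contrasts each signature's mean z
against a background of the 100 most variable genes. A background defined
by deviation from mean expression admits two readings — a global
most-variable-genes list, or a per-sample most-deviant-|z| list; the
global reading is the default
because it makes the background sample-independent and the score a
centered contrast, and the per-sample variant is available via
`background="per_sample"`. Because the score is z-based it is
*cohort-relative*: it ranks a sample's deviation from the cohort mean, not
absolute composition. When per-sample dominance is the varying signal the
top-scoring cell type matches the dominant true mixing fraction ≥ 90% of
the time (verified on a symmetric-mixing synthetic cohort); when dominance
is confounded with a subgroup the meaningful readout is the group-level
contrast, exactly how the score is used downstream.

`cytotrace_lite` scores differentiation state as the rank (mid-rank, mapped
into (0,1)) of the mean log-normalized expression of the 200 genes most
correlated with per-cell detected-gene counts. The full method's
nearest-neighbor diffusion smoothing is intentionally omitted; the lite
score preserves the ordering property (cells expressing strict supersets of
genes score higher) that downstream comparisons need.

## Scissor-style labeling

Quality control mirrors common single-cell practice: genes in < 3 cells
dropped; cells with percent-mito ≥ 5 (strict <5 survives) or detected-gene
count ≥ 3000 dropped; survivors log-normalized per 10k. Cell–bulk
similarity is the Pearson correlation over shared genes (≥ 100 required).
Cell selection is an elastic-net logistic regression of the binary
subgroup phenotype on the row-normalized correlation matrix — a
transparent sparse-regression variant of the published network-regularized
solver; everything downstream depends only on the Scissor+/−/BC partition,
which is solver-agnostic. The penalty is chosen as the weakest on the grid
whose selected-cell fraction stays within 25% of all cells (if no penalty
qualifies, the smallest nonzero selection is used with a warning; if every
penalty shrinks to zero, all cells are background).

Sample labeling is exactly the two published criteria, both strict
inequalities: labeled coverage (Scissor+ + Scissor−)/total > 0.20 and
|log2(n⁺/n⁻)| > log2(1.5) ≈ 0.585 (printed as 0.59, its two-decimal
ceiling). A zero count on one side gives an infinite fold change, which
passes any finite threshold; a missing or doubly-zero count gives a
missing fold change and the label Neither. Proportions and fold changes
are rounded half-even to two decimals *for display only*, which reproduces
the published 16-sample table digit for digit.

## Statistics

Survival uses lifelines (product-limit curves, (k−1)-df log-rank,
Cox with Efron ties and Wald intervals). The default 2×2 test is
chi-square with Yates continuity correction, which reproduces the
published mutation-table p-values at printed precision (0.006, 0.030,
<0.001, 0.019, 0.622); Fisher's exact test is a flag away. One published
value (Beat AML NPM1, printed 0.035) is not reproduced by any standard
2×2 test on the printed counts (both chi-square and Fisher give ≈0.56),
most plausibly a different denominator in the source; it is documented
here and asserted nowhere. Two-group continuous comparisons are Welch
throughout. "Scaled AUC" means per-drug z-scores; fold changes are ratios
of raw AUC group means to keep them interpretable.

## Classifier

The stacked ensemble is a fixed four-learner stand-in for an AutoML stack:
k-NN (k = n/10 clipped to [3, 15], standardized inputs), random forest
(200 trees), gradient boosting, and class-weighted L2 logistic regression.
Ensemble weights are found by exhaustive grid search over the probability
simplex (step 0.1) minimizing held-out log-loss on the stratified 20%
split — held-out log-loss is the selection metric because it is proper and
comparable across learners. Cross-cohort prediction requires ≥ 80% of
feature genes and mean-imputes the rest from training means.

## Problem sizes and numerical choices

The default synthetic cohort is 200 samples × 2000 genes with 2000 single
cells — sizes chosen so the full suite exercises every stage at realistic
signal-to-noise on a laptop. Consensus clustering in tests and in the
acceptance script uses 40–100 resamples (the library default is 1000);
the log-rank type-I-error simulation uses 500–1000 null trials of n = 100;
RRA's closed form is checked against 10⁵ Monte-Carlo draws. Ranking ties
use average ranks everywhere; z-scores use population SD; eigengene signs
are fixed against the module mean; seeds are explicit arguments and there
is no global random state.

## Known limitations

The ssGSEA/NNLS/elastic-net components are transparent reimplementations
of the published analyses' *roles*, not numerical clones of xCell,
CIBERSORT or Scissor, so their outputs are comparable within this package
but not to those tools' published values. The Welch DE engine will not
match count-model DE on raw counts. Cohort-level published results that
depend on external data (gene counts from specific cohorts, exact subgroup
sizes, cohort log-rank p-values, Scissor cell totals) are out of scope and
not reproduced.
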