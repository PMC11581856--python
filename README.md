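# immunosubtype

Immune-based molecular subgrouping of acute myeloid leukemia (AML)
transcriptomes.

AML bone marrow is not just blasts: the tumor microenvironment carries
immune and stromal cells whose abundance varies widely between patients and
tracks prognosis and drug response. `immunosubtype` implements, as a tested
and reusable library, the analysis pipeline that turns bulk and single-cell
RNA-seq into immune-based patient subgroups:

- **Immune scoring** — single-sample gene-set enrichment (ssGSEA) immune and
  stromal scores; NNLS deconvolution of cell-type abundances against a
  signature matrix; the T cell infiltration score
  TIS = Σ of six T-subset abundances (CD8⁺, CD4⁺ naïve, CD4⁺ memory, Tfh,
  Treg, γδ); quartile high/low grouping.
- **Subgroup discovery** — consensus clustering: subsampled k-means, the
  consensus matrix M(i,j) = co-cluster count / co-sample count, CDF/delta-area
  diagnostics and cluster-consensus stability, with the immune-high cluster
  labeled G1 and the immune-low cluster G2.
- **Key-gene selection** — weighted co-expression networks: unsigned
  adjacency a_ij = |cor(x_i,x_j)|^β, topological overlap
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), module eigengenes,
  gene significance GS = |cor(gene, immune score)| and module membership
  MM = cor(gene, eigengene).
- **Robust differential expression** — Welch DE per cohort plus Robust Rank
  Aggregation: for normalized ranks r₍₁₎ ≤ … ≤ r₍ₖ₎ across k cohorts the
  beta score b_j = P(Binomial(k, r₍ⱼ₎) ≥ j), ρ = min_j b_j, and the reported
  score min(1, k·ρ).
- **Single-cell ↔ bulk** — Scissor-style labeling: sparse logistic
  regression of the bulk subgroup phenotype on the sample × cell correlation
  matrix yields Scissor+/Scissor−/background cells; samples whose labeled
  cells exceed 20% coverage and a 1.5-fold (|log2 FC| > log2 1.5) imbalance
  become G1- or G2-featured. Plus signature-score projection of cell-type
  programs onto bulk samples and a lite per-cell differentiation score.
- **Association statistics** — Kaplan–Meier/log-rank, multivariate Cox
  (Efron ties), Yates-corrected chi-square and Fisher contingency tests,
  ANOVA + Tukey HSD, Pearson correlation, and the drug-sensitivity screen
  rule (|fold change| > 1.5 and p < 0.05 on scaled AUC).
- **Subgroup classifier** — a stacked ensemble (k-NN, random forest,
  gradient boosting, penalized logistic) with simplex weights fitted on a
  stratified 80/20 split, for transferring subgroups to new cohorts.
- **Synthetic cohorts** — a generator planting two latent subgroups
  (immune-high/monocytic G1 vs immune-low/granulocytic G2) through
  Dirichlet cell-type mixtures, negative-binomial counts, group-dependent
  mutation frequencies and survival hazards, and drug AUCs with a
  controlled correlation to immune content, so every stage is testable
  without any download.

## Worked example

```python
from immunosubtype import io, scoring, subgroups, synthetic

cfg = synthetic.SimConfig(seed=1)          # 200 samples, 2000 genes
bulk = synthetic.generate_bulk_cohort(cfg)
sets = synthetic.export_gene_sets(cfg)

lognorm = io.lognormalize(bulk.expression)
scores = scoring.immune_stromal_scores(lognorm, sets["immune"], sets["stromal_set"])

result = subgroups.consensus_cluster(lognorm.values, k_range=[2, 3, 4],
                                     n_resamples=50, seed=1)
k = subgroups.select_k(result)
labels = subgroups.assign_subgroups(result, k, immune_scores=scores["immune_score"])
```

prints, via the obvious summaries:

```
chosen k: 2
subgroup sizes: {'G2': 110, 'G1': 90}
mean immune score G1: 908.1  G2: 742.9
ARI vs planted truth: 1.00
```

The delta-area/cluster-consensus rule picks k = 2; the cluster with the
higher mean ssGSEA immune score is named G1; and the recovered assignment
matches the generator's planted subgroups exactly (adjusted Rand index
1.0). A command-line interface (`immunosubtype simulate|score|subgroup|
keygenes|rradeg|sigmap|scissor|stats|classify`) chains the same stages over
TSV/MTX/GMT files.

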