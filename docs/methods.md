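# Methods

This note documents the models and procedures implemented in `scdrx`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Preprocessing and clustering

Quality control keeps cells expressing ≥200 genes with a mitochondrial
count fraction below 30% (genes identified by a configurable symbol
prefix, default `MT-`, the human convention), and genes detected in ≥3 of
the *surviving* cells — cell filters run first, then the gene filter, and
the combined filter is idempotent. Each cell is scaled to 10,000 total
counts and transformed by ln(1+x); this is exactly invertible given the
stored per-cell totals, which is how `subcluster` recovers raw counts to
re-run the full chain on a cell subset.

Highly variable genes are selected by dispersion ranking within mean bins
(Seurat flavor, 2,000 genes by default — the HVG count and neighbor count
are workflow parameters, not derived quantities). Scaling clips z-scores
at ±10 to bound outlier leverage. PCA uses 20 components (reduced with a
warning when the rank is lower); the kNN graph uses 15 neighbors.

Louvain clustering runs igraph's multilevel modularity optimization with
a resolution parameter, seeded for determinism; labels are renumbered by
descending cluster size so label ids are stable across runs. MAGIC
imputation and Harmony batch correction are deliberately out of scope;
the pipeline operates on the uncorrected embedding.

## Automatic resolution selection

For each resolution on the grid (default 0.4–1.4, step 0.2), five random
80% cell subsets are drawn without replacement; each subset is
re-clustered after recomputing neighbors on the subset's PCA embedding
(the embedding itself is not recomputed — stability is measured for the
partition, not the projection). The co-clustering frequency of a cell
pair is the number of repetitions where the pair co-clustered divided by
the number where both cells were sampled. The full-data partition at that
resolution is scored by the mean silhouette with dissimilarity
`1 − frequency`; pairs never co-sampled are excluded from a cell's
silhouette terms rather than imputed, and singleton-cluster cells score 0.
A single-cluster partition has no silhouette and scores 0 with a warning.
The silhouette is computed against the full-data labels (not the
subsample labels): the quantity of interest is whether the full partition
keeps re-forming. Ties in the best score go to the smaller resolution —
the coarsest stable solution. Seeding: repetition *r* at grid index *g*
uses `seed + 1000·g + r`, so grids and repetitions are independent
streams.

## Annotation

Differential expression is one-vs-rest Welch's t-test per gene (Wilcoxon
available behind a flag) on log-normalized, unscaled values, with BH
adjustment; log2 fold changes compare cluster and rest means. Singleton
clusters are skipped with a warning. Cluster expression profiles (GEPs)
are arithmetic means of log-normalized expression over all genes.

Cell typing correlates each cluster GEP with each reference profile on
the shared genes — Spearman by default so the assignment is invariant to
monotone transformations of either side; fewer than 50 shared genes
triggers a warning. The reference panel is user-supplied (genes ×
reference samples); no atlas is bundled.

Enrichment is a local hypergeometric over-representation test: the query
is the set of DEGs with log2FC > 2 and raw and adjusted p < 0.01; the
background defaults to all genes in the DEG table; p-values are exact
hypergeometric upper tails with BH adjustment within each cluster.

The tumor-cluster rule needs a convention for "percentage": here a
cluster's tumor share is its fraction of all tumor-origin cells, likewise
for normal, and the cluster is selected when tumor share > 2 × normal
share (strict). This normalization makes the rule insensitive to the
overall tumor/normal ratio of the dataset; the threshold is configurable.

## Survival

Signatures are each cluster's top-20 DEGs restricted to genes the cohort
measures, back-filled from subsequent ranks so signature sizes stay
comparable (a shortfall is warned about). The activity score counts
signature genes with expression strictly above the cohort median — a
patient exactly at the median contributes 0, which also zeroes
constant-expression genes. Quartiles use linear-interpolation
percentiles; ties are included in the extreme groups, and all-equal
scores raise a "no separation" error rather than fabricating groups.

The log-rank statistic is the standard two-sample O−E chi-square with
hypergeometric variance (verified to machine precision against lifelines
in the tests); Kaplan–Meier curves come from lifelines. The hazard ratio
is (O_high/E_high)/(O_low/E_low) from the log-rank table — a deliberate
choice over a Cox fit so the reported HR is a direct function of the same
table as the p-value; no multiple-testing correction is applied across
clusters by default (a BH flag exists).

## Drug-response model

Responses are stored so that higher = more sensitive: −log(IC50) for
IC50-style screens, 1−AUC for AUC-style screens. The affine rescaling
`D' = 240·D − 120` moves 1−AUC from [0,1] to [−120,120] so both response
types present a comparable dynamic range to the same objective; it is
exactly invertible and predictions are reported back on the 1−AUC scale.

Feature genes are those whose expression correlates with the per-line
mean response (over drugs, NaN-aware) at |Pearson r| ≥ 0.2. The per-line
mean is the aggregation target because the kernel must track a line's
overall pharmacological disposition, not any single drug. A sample's
kernel feature vector is its Pearson correlation, over feature genes,
between its expression fold-change profile and each training line's
profile; fold changes are taken against the training panel's per-gene
mean for panel-like samples and against the dataset's own average for
single-cell data (correlation is invariant to the log base, so
natural-log single-cell values need no conversion). The feature dimension
is therefore the number of training lines.

The model predicts `ŝ_iu = b_i + q_i·(x_u W)` with per-drug bias b,
latent drug matrix Q (drugs × f) and projection W (d × f). There is no
per-sample bias and no global mean in the prediction: those terms cannot
be estimated for unseen samples such as cell clusters, so the objective

    L = 1/(2K) Σ_observed (s_iu − ŝ_iu)² + λ‖W‖² + λ‖Q‖²

omits them entirely (K = observed drug–line pairs; missing responses are
masked out). Optimization is full-batch Adam at learning rate 0.01 with
up to 100,000 epochs, early-stopping when the relative loss improvement
over 100 epochs falls below 1e-8; a non-finite loss aborts with advice to
lower the rate. W and Q start at N(0, 0.01²); b starts at the per-drug
mean response, which makes the λ→∞ limit degrade gracefully to per-drug
means. λ defaults to 0.01. At that default the regularization floor
intentionally shrinks the fit slightly; recovery tests that probe the
factorization itself use λ = 1e-4 where shrinkage is negligible.

Per-cluster prediction has two modes: `per_cell_mean` (predict every
cell, average within the cluster) and `cluster_wise` (one prediction from
the cluster-vs-rest fold-change profile). Drug filtering computes each
drug's Spearman correlation between predicted and observed training
responses and drops drugs strictly below the first quartile
(linear-interpolation percentile). Note that with the strict drop rule
the "keep ≥ 75%" guarantee holds for panel sizes not congruent to 2 mod
4; at n ≡ 2 (mod 4) the interpolated quartile can sit strictly between
order statistics and one extra drug falls below it.

Held-out evaluation splits off 24 lines (configurable), trains on the
remainder, predicts the held-out lines through their kernel features
against the training lines only, and reports the median absolute error
and Pearson r over observed pairs plus per-drug Spearman correlations.

## Combination search

The cluster signature matrix is the anti-log (expm1) of the cluster GEPs
restricted to the screen's gene space — non-negative, linear scale, as
bulk deconvolution requires. Deconvolution is constrained linear
regression: non-negative least squares per experiment, normalized to sum
to one (a stand-in honoring the same input/output contract as
reference-based bulk deconvolution services). Control proportions are
averaged over all control experiments.

A subpopulation is a kill candidate when `1 − p_treated/p_control`
exceeds 0.90, and confirmed only if every same-compound, same-unit
experiment at a strictly higher concentration shows a reduction ≥ 0.75
(vacuously confirmed when no higher dose exists; mismatched units skip
the check with a warning). The 90% rule is applied per experiment, not
per compound, so the same compound can kill at one dose and not another.
Subpopulations with zero control proportion are excluded with a warning.

The greedy search maximizes coverage: each step picks the perturbation
killing the most not-yet-killed subpopulations; ties break by the total
reduction summed over *all* subpopulations (the literal efficacy
definition — note renormalization can make untargeted subpopulations'
reductions negative, which the sum includes); perturbations tied on both
criteria branch into separate plans, capped at 64 plans, with a
deterministic lexicographic candidate order by (compound, concentration).
On disjoint kill sets greedy coverage is provably optimal, which the
tests exploit by comparing against exhaustive search.

## Synthetic generators

All generators are deterministic given their seed and write/read through
the same formats and readers as real data.

*Counts*: log-normal gene abundances; each cluster up-regulates a
disjoint marker block 4-fold; log-normal library sizes around depth
5,000; negative-binomial sampling with dispersion 0.5 (variance
m + 0.5m²). The defaults (150 cells/cluster, 20 markers, 4×) were chosen
once so that the documented recovery properties (ARI ≥ 0.9 end-to-end)
hold; they emulate well-separated subpopulations and do *not* model
doublets, ambient RNA, batch effects or continuous trajectories — passing
tests show pipeline correctness on separable structure, not robustness to
those artifacts.

*Drug panel*: latent line factors z drive responses
`s = b + q·z + ε` with ε scaled to `noise_sd` × sd(signal), and a block
of response-linked genes. Each linked gene's loading mixes a guaranteed
component along the mean drug-loading direction (so each gene tracks
overall response, making threshold-based feature selection meaningful)
with an orthogonal random component (so the gene block jointly encodes
the full latent space — with purely axis-aligned loadings the
correlation kernel loses factor magnitude and held-out recovery is
structurally capped). Gene-level noise sd 0.3 on a unit-variance signal.

*Perturbation screen*: treated proportions multiply targeted
subpopulations by (1 − reduction) and renormalize; profiles are signature
mixtures plus optional Gaussian noise. Because of renormalization a
planted abundance reduction r yields a proportion reduction below r when
the killed mass is large; fixtures that exercise the 90% rule use planted
reductions high enough that the proportion reduction still clears it.

*Survival cohort*: each cluster has a Bernoulli(½) latent high/low
activity per patient; signature genes express baseline + 1.5 when active
(noise sd 0.6); event times are exponential with the hazard multiplied by
the hazard ratio for patients active in the effect cluster; censoring is
independent exponential tuned to the requested censored fraction.

## Problem sizes

The test suite and the acceptance script run the workflow at the sizes
documented above: five 750-cell matrices for clustering and resolution
selection, 60-line × 25-drug panels with 24 held-out lines over five
seeds for the drug model, 100-gene × 5-subpopulation screens, and 100 +
100 survival cohorts of 200 patients for power and null calibration —
sizes at which every property is measurable in seconds per instance.

## Known limitations

- Louvain on a kNN graph inherits its resolution limit; very small
  subpopulations below the neighbor count can be absorbed.
- The robustness score compares against full-data labels; it certifies
  reproducibility of a partition, not biological truth.
- The kernel representation discards fold-change magnitude by
  construction (correlations are scale-free), so two samples with
  proportional profiles are indistinguishable.
- NNLS deconvolution assumes the signature matrix spans the bulk
  profiles; unmodelled cell types bias proportions toward the nearest
  signatures.
- The greedy combination search is optimal only for disjoint kill sets;
  for overlapping sets it is a heuristic (as is maximum-coverage greedy
  generally).
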