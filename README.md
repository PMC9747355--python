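# scdrx

From a single-cell RNA-seq count matrix to drug-repurposing candidates:
`scdrx` identifies tumor cell subpopulations, scores their prognostic
impact against a bulk survival cohort, predicts each subpopulation's drug
sensitivity with a latent-factor recommender trained on cell-line drug
screens, and proposes minimal drug combinations that eliminate the most
subpopulations in a perturbation screen.

It is aimed at computational biologists who have a tumor scRNA-seq dataset
and want a single, scriptable workflow from raw counts to ranked drugs and
combination suggestions, with every stage available as a plain Python
function.

## What it computes

**Clustering.** Standard single-cell preprocessing (cells with ≥200 genes,
genes in ≥3 cells, mitochondrial fraction <30%; depth normalization to
10,000 counts and ln(1+x); highly variable genes scaled to z-scores; PCA
on 20 components; kNN graph; Louvain communities). The clustering
resolution can be chosen automatically: for each value on a grid
([0.4, 1.4] in steps of 0.2 by default) the data are re-clustered on five
random 80% subsamples, and the full-data partition is scored by the mean
silhouette on the dissimilarity `1 − co-clustering frequency`. The most
reproducible resolution wins.

**Annotation.** One-vs-rest differential expression per cluster, local
hypergeometric gene-set enrichment (log2FC > 2, p and BH-adjusted p < 0.01)
against a GMT library, rank-correlation cell typing against a reference
expression panel, and a tumor-cluster rule: a cluster is flagged when its
share of tumor-origin cells exceeds twice its share of normal-origin cells.

**Survival.** For each cluster, its top-20 marker genes form a signature.
A patient's *activity score* counts signature genes expressed above the
cohort median; top- vs bottom-quartile patients are compared with
Kaplan–Meier curves, the log-rank test, and a hazard ratio
(O_high/E_high)/(O_low/E_low) from the log-rank table.

**Drug response.** A bias-free matrix-factorization model on kernel
features. A sample is represented by its Pearson correlations, over
feature genes (|r| ≥ 0.2 with response), between its expression
fold-change profile and each training cell line's profile; the model

    ŝ_iu = b_i + q_i · (x_u W)

is fit by minimizing `1/(2K) Σ (s_iu − ŝ_iu)² + λ‖W‖² + λ‖Q‖²` with Adam
(learning rate 0.01, up to 100,000 epochs, early stopping). IC50-style
(−log IC50) and AUC-style screens are both supported; 1−AUC responses are
rescaled by `D' = 240·D − 120`. Per-cluster predictions come from either
the mean of per-cell predictions or a direct cluster-vs-rest fold-change
profile, and drugs whose training-set Spearman falls below the first
quartile are dropped.

**Combination search.** Bulk profiles of a compound screen are deconvolved
into subpopulation proportions (non-negative least squares against the
cluster signature matrix, normalized to sum to 1). A subpopulation is
*killed* by a perturbation when its proportion falls >90% vs controls,
confirmed by ≥75% reductions at all higher doses of the same compound.
A greedy search then picks, step by step, the perturbation killing the
most not-yet-killed subpopulations (ties by total reduction; exact ties
branch into alternative plans).

All five data sources (counts, drug panel, survival cohort, perturbation
screen) have truth-labelled synthetic generators in `scdrx.simulate`, so
the whole workflow runs and is tested without any download.

## Worked example

```bash
python examples/01_cluster_and_auto_resolution.py
```

```
clusters found at resolution 1.0: 5
adjusted Rand index vs planted labels: 0.938

resolution grid (higher score = more reproducible partition):
 resolution    score  n_clusters
        0.4 0.965070           5
        0.6 0.979384           5
        0.8 0.956757           5
        1.0 0.938489           5
        1.2 0.932737           5
        1.4 0.918001           6

chosen resolution: 0.6 (most stable partition under 80% subsampling)
```

The generator planted five subpopulations; the pipeline recovers them
(ARI 0.94 against the planted labels) and the subsampling score peaks at a
resolution yielding exactly five clusters — higher resolutions start to
shatter stable groups (six clusters at 1.4, lower score).

The other examples cover annotation (`02`), survival (`03` — the planted
3× hazard cluster surfaces with p ≈ 8e-8 and hazard ratio ≈ 2.9), the
drug-response model (`04` — held-out Pearson r ≈ 0.96) and the
combination search (`05` — the greedy plan kills all targetable
subpopulations in three steps).

A thin CLI mirrors the library (`scdrx cluster|annotate|survival|drugrec|
combo|simulate|run`); `scdrx run --config cfg.json --outdir DIR` executes
the configured stages into a resumable bundle directory with a manifest.

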