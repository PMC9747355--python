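"""Cluster annotation: differential expression, gene-set enrichment,
correlation-based cell typing and tumor-cluster selection.

Differential expression ranks genes per cluster one-vs-rest.  Enrichment
is a local hypergeometric over-representation test against a GMT gene-set
library with Benjamini–Hochberg correction — no web service involved.
Cell types are assigned by rank correlation of each cluster's mean
expression profile (GEP) against a user-supplied reference panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_degs",
    "cluster_gep",
    "annotate_cell_types",
    "parse_gmt",
    "enrich",
    "select_tumor_clusters",
]


def rank_degs(
    adata: AnnData,
    cluster_key: str = "cluster",
    method: str = "t-test",
) -> pd.DataFrame:
    """One-vs-rest differential expression for every cluster.

    Welch t-test by default (``method="wilcoxon"`` for the rank-sum
    alternative) on the log-normalized full gene space (``adata.raw`` when
    present), with log2 fold change of cluster vs rest means and BH-adjusted
    p-values.  Returns a tidy frame: cluster, gene, rank, score,
    log2_fold_change, p_value, adj_p_value.  Clusters of size 1 are skipped
    with a warning.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"no clustering {cluster_key!r} in adata.obs")
    counts = adata.obs[cluster_key].value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least two clusters with two or more cells")
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        warnings.warn(f"skipping singleton clusters: {singletons}")
    groups = [str(c) for c in counts.index[counts >= 2]]
    ad = adata.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            ad, cluster_key, groups=groups, method=method, use_raw=ad.raw is not None
        )
    frames = []
    for g in groups:
        df = sc.get.rank_genes_groups_df(ad, group=g)
        df = df.rename(
            columns={
                "names": "gene",
                "scores": "score",
                "logfoldchanges": "log2_fold_change",
                "pvals": "p_value",
                "pvals_adj": "adj_p_value",
            }
        )
        df.insert(0, "cluster", g)
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["cluster", "gene", "rank", "score", "log2_fold_change", "p_value", "adj_p_value"]
    ]


def cluster_gep(adata: AnnData, cluster_key: str = "cluster") -> pd.DataFrame:
    """Mean log-normalized expression per cluster (clusters × genes).

    Uses the unscaled full gene space from ``adata.raw`` when present.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"no clustering {cluster_key!r} in adata.obs")
    from .preprocess import _dense

    if adata.raw is not None:
        X = _dense(adata.raw.X)
        genes = adata.raw.var_names
    else:
        X = _dense(adata.X)
        genes = adata.var_names
    labels = adata.obs[cluster_key].astype(str)
    df = pd.DataFrame(X, index=labels.to_numpy(), columns=genes)
    gep = df.groupby(level=0, observed=True).mean()
    gep.index.name = "cluster"
    return gep


def annotate_cell_types(
    gep: pd.DataFrame,
    reference: pd.DataFrame,
    cell_types: dict | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Assign each cluster the best-correlated reference profile.

    ``gep`` is clusters × genes; ``reference`` is genes × reference
    samples.  Correlation (Spearman by default, ``method="pearson"``
    optional) is computed on the shared genes; the argmax profile names the
    cell type (via ``cell_types`` when a sample → type map is given).
    """
    shared = gep.columns.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between query and reference")
    if len(shared) < 50:
        warnings.warn(f"only {len(shared)} shared genes with reference")
    q = gep[shared].T.astype(float)          # genes × clusters
    r = reference.loc[shared].astype(float)  # genes × refs
    if method == "spearman":
        q = q.rank(axis=0)
        r = r.rank(axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    corr = pd.DataFrame(
        np.corrcoef(q.to_numpy().T, r.to_numpy().T)[: q.shape[1], q.shape[1]:],
        index=gep.index,
        columns=reference.columns,
    )
    best = corr.idxmax(axis=1)
    rows = []
    for cluster, ref_name in best.items():
        rows.append(
            {
                "cluster": cluster,
                "reference_name": ref_name,
                "cell_type": (cell_types or {}).get(ref_name, ref_name),
                "correlation": float(corr.loc[cluster, ref_name]),
            }
        )
    return pd.DataFrame(rows)


def parse_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set library: term, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def enrich(
    deg_table: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    lfc_min: float = 2.0,
    p_max: float = 0.01,
    adj_p_max: float = 0.01,
    background: int | list | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of DEGs in each gene set.

    The query per cluster consists of genes with log2 fold change above
    ``lfc_min`` and both raw and adjusted p-value below their thresholds.
    ``background`` may be a gene list or a size; by default all genes in
    the DEG table form the universe.  P-values are the exact hypergeometric
    upper tail, BH-adjusted within each cluster.
    """
    if background is None:
        universe = set(deg_table["gene"])
        M = len(universe)
    elif isinstance(background, int):
        universe = None
        M = background
    else:
        universe = set(background)
        M = len(universe)
    rows = []
    for cluster, df in deg_table.groupby("cluster", observed=True):
        sel = df[
            (df["log2_fold_change"] > lfc_min)
            & (df["p_value"] < p_max)
            & (df["adj_p_value"] < adj_p_max)
        ]
        query = set(sel["gene"])
        if universe is not None:
            query &= universe
        if not query:
            warnings.warn(f"cluster {cluster}: no DEGs pass enrichment thresholds")
            continue
        N = len(query)
        cluster_rows = []
        for term, members in gene_sets.items():
            members_u = set(members) & universe if universe is not None else set(members)
            n = len(members_u)
            k = len(query & members_u)
            p = stats.hypergeom.sf(k - 1, M, n, N) if n else 1.0
            cluster_rows.append(
                {
                    "cluster": cluster,
                    "term": term,
                    "overlap_count": k,
                    "term_size": n,
                    "query_size": N,
                    "p_value": float(min(p, 1.0)),
                }
            )
        sub = pd.DataFrame(cluster_rows)
        sub["adj_p_value"] = multipletests(sub["p_value"], method="fdr_bh")[1]
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=[
                "cluster", "term", "overlap_count", "term_size",
                "query_size", "p_value", "adj_p_value",
            ]
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["cluster", "p_value"], ignore_index=True
    )


def select_tumor_clusters(
    clusters: pd.Series,
    origin: pd.Series,
    ratio_threshold: float = 2.0,
) -> list[str]:
    """Clusters over-represented among tumor-origin cells.

    For each cluster the tumor share (cells of tumor origin in the cluster
    divided by all tumor-origin cells) is compared with the analogous
    normal share; the cluster is selected when the tumor share strictly
    exceeds ``ratio_threshold`` times the normal share.  ``origin`` maps
    every cell to ``"tumor"`` or ``"normal"``.
    """
    clusters = clusters.astype(str)
    origin = origin.reindex(clusters.index)
    if origin.isna().any():
        missing = origin.index[origin.isna()].tolist()[:5]
        raise ValueError(f"cells without origin label, e.g. {missing}")
    bad = set(origin.unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"origin labels must be 'tumor'/'normal', got {sorted(bad)}")
    n_tumor = (origin == "tumor").sum()
    n_normal = (origin == "normal").sum()
    if n_tumor == 0 or n_normal == 0:
        raise ValueError("need both tumor and normal cells to compare composition")
    selected = []
    for c in sorted(clusters.unique()):
        in_c = clusters == c
        tumor_share = (in_c & (origin == "tumor")).sum() / n_tumor
        normal_share = (in_c & (origin == "normal")).sum() / n_normal
        if tumor_share > ratio_threshold * normal_share:
            selected.append(c)
    return selected
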