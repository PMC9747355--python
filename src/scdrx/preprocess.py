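"""Quality filtering, normalization, reduction and graph clustering.

The standard single-cell workflow: remove low-quality cells and rarely
detected genes, depth-normalize and log-transform, restrict to highly
variable genes scaled to zero mean / unit variance, embed with PCA, build a
k-nearest-neighbor graph and partition it with Louvain community detection.
All steps operate on :class:`anndata.AnnData`; raw counts are preserved in
``layers["counts"]`` and the full log-normalized matrix in ``.raw`` so that
downstream differential expression and profile averaging see unscaled data.
"""

from __future__ import annotations

import random
import warnings

import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "filter_cells_genes",
    "normalize_log",
    "select_hvg_scale",
    "pca_neighbors",
    "cluster_louvain",
    "preprocess_and_cluster",
    "subcluster",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def filter_cells_genes(
    adata: AnnData,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    max_mito_frac: float = 0.30,
    mito_prefix: str = "MT-",
) -> AnnData:
    """Remove low-quality cells, then rarely detected genes.

    A cell is kept when it expresses at least ``min_genes_per_cell`` genes
    and its mitochondrial count fraction (genes whose symbol starts with
    ``mito_prefix``) is below ``max_mito_frac``.  A gene is kept when it is
    detected in at least ``min_cells_per_gene`` of the *surviving* cells —
    cell filters are applied first, then the gene filter.
    """
    X = _dense(adata.X)
    if X.size == 0:
        raise ValueError("empty count matrix")
    n_genes = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    is_mito = adata.var_names.str.startswith(mito_prefix)
    mito = X[:, is_mito].sum(axis=1) if is_mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep_cells = (n_genes >= min_genes_per_cell) & (mito_frac < max_mito_frac)
    if not keep_cells.any():
        raise ValueError("all cells removed by quality filtering")
    sub = adata[keep_cells].copy()
    n_cells = (_dense(sub.X) > 0).sum(axis=0)
    keep_genes = n_cells >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("all genes removed by quality filtering")
    return sub[:, keep_genes].copy()


def normalize_log(adata: AnnData, target_sum: float = 10_000.0) -> AnnData:
    """Scale each cell to ``target_sum`` total counts, then apply ln(1+x).

    Raw counts are stashed in ``layers["counts"]``.  Cells with zero total
    counts cannot be normalized and raise an error naming the first one.
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts and cannot be normalized")
    adata = adata.copy()
    adata.layers["counts"] = X.copy()
    adata.obs["total_counts"] = totals
    adata.X = np.log1p(X / totals[:, None] * target_sum)
    adata.uns["normalization"] = {
        "target_sum": float(target_sum),
        "normalized": True,
        "log_transformed": True,
        "scaled": False,
    }
    return adata


def select_hvg_scale(
    adata: AnnData,
    n_top_genes: int = 2000,
    max_value: float = 10.0,
) -> AnnData:
    """Restrict to highly variable genes and scale genes to z-scores.

    Highly variable genes are chosen by dispersion-based ranking (Seurat
    flavor).  After subsetting, each gene is centered to mean zero and
    scaled to unit variance, with values clipped at ``max_value`` to bound
    outlier leverage.  The full log-normalized matrix is kept in ``.raw``.
    """
    if not adata.uns.get("normalization", {}).get("log_transformed"):
        raise ValueError("select_hvg_scale expects log-normalized input")
    adata = adata.copy()
    n_top = min(n_top_genes, adata.n_vars)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    n_hvg = int(adata.var["highly_variable"].sum())
    if n_hvg < 2:
        raise ValueError(f"only {n_hvg} highly variable genes found; need at least 2")
    adata.raw = adata
    adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata, max_value=max_value)
    adata.uns["normalization"]["scaled"] = True
    return adata


def pca_neighbors(
    adata: AnnData,
    n_pcs: int = 20,
    k_neighbors: int = 15,
    seed: int = 0,
) -> AnnData:
    """Embed cells with PCA and build a symmetrized kNN graph on the top PCs.

    When ``n_pcs`` exceeds the matrix rank it is reduced with a warning.
    The graph weights (``obsp["connectivities"]``) feed Louvain clustering.
    """
    max_pcs = min(adata.n_obs - 1, adata.n_vars - 1)  # arpack needs strict <
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank; reduced to {max_pcs}")
        n_pcs = max_pcs
    sc.pp.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(
        adata,
        n_neighbors=min(k_neighbors, adata.n_obs - 1),
        n_pcs=n_pcs,
        random_state=seed,
    )
    return adata


def cluster_graph(
    adjacency: sp.spmatrix,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Louvain community detection on a weighted adjacency matrix.

    Runs igraph's multilevel modularity optimization at the given
    resolution, seeded for determinism.  Labels are integers from 0,
    renumbered by descending community size.
    """
    adjacency = sp.csr_matrix(adjacency)
    n = adjacency.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    coo = sp.triu(adjacency, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    weights = coo.data.tolist()
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=weights or None, resolution=resolution)
    labels = np.asarray(part.membership)
    # stable ids: largest community first, size ties broken by old id
    order = sorted(
        np.unique(labels), key=lambda c: (-(labels == c).sum(), c)
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[v] for v in labels])


def cluster_louvain(
    adata: AnnData,
    resolution: float = 1.0,
    seed: int = 0,
    key_added: str = "cluster",
) -> AnnData:
    """Cluster cells by Louvain on the neighbor graph; labels in ``obs``."""
    if "connectivities" not in adata.obsp:
        raise ValueError("no neighbor graph; run pca_neighbors first")
    labels = cluster_graph(adata.obsp["connectivities"], resolution, seed)
    adata.obs[key_added] = pd.Categorical(labels.astype(str))
    adata.uns[key_added] = {"resolution": float(resolution), "seed": int(seed)}
    return adata


def preprocess_and_cluster(
    counts: AnnData,
    resolution: float = 1.0,
    *,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    max_mito_frac: float = 0.30,
    mito_prefix: str = "MT-",
    target_sum: float = 10_000.0,
    n_top_genes: int = 2000,
    n_pcs: int = 20,
    k_neighbors: int = 15,
    seed: int = 0,
) -> AnnData:
    """Full chain: filter → normalize → HVG/scale → PCA/kNN → Louvain."""
    adata = filter_cells_genes(
        counts, min_genes_per_cell, min_cells_per_gene, max_mito_frac, mito_prefix
    )
    adata = normalize_log(adata, target_sum)
    adata = select_hvg_scale(adata, n_top_genes)
    adata = pca_neighbors(adata, n_pcs, k_neighbors, seed)
    return cluster_louvain(adata, resolution, seed)


def subcluster(
    adata: AnnData,
    cluster_ids,
    resolution: float = 1.0,
    cluster_key: str = "cluster",
    **kwargs,
) -> AnnData:
    """Re-run the whole analysis chain on the cells of selected clusters.

    HVGs, PCA and the neighbor graph are recomputed on the subset's raw
    counts, so fine structure within the selection can emerge.
    """
    cluster_ids = [str(c) for c in np.atleast_1d(cluster_ids)]
    if cluster_key not in adata.obs:
        raise ValueError(f"no clustering {cluster_key!r} in adata.obs")
    known = set(adata.obs[cluster_key].astype(str))
    missing = [c for c in cluster_ids if c not in known]
    if missing:
        raise ValueError(f"unknown cluster ids: {missing}")
    mask = adata.obs[cluster_key].astype(str).isin(cluster_ids).to_numpy()
    if not mask.any():
        raise ValueError("empty cluster selection")
    counts = _recover_counts(adata)[mask]
    return preprocess_and_cluster(counts, resolution, **kwargs)


def _recover_counts(adata: AnnData) -> AnnData:
    """Reconstruct raw counts over all genes from the log-normalized ``.raw``.

    The ln(1+x) depth normalization is invertible given each cell's total
    count (kept in ``obs["total_counts"]``); values are rounded back to
    integers to undo floating-point drift.
    """
    if adata.raw is None or "total_counts" not in adata.obs:
        raise ValueError("analysis lacks .raw / total_counts; cannot recover counts")
    target = adata.uns["normalization"]["target_sum"]
    totals = adata.obs["total_counts"].to_numpy()
    X = np.rint(np.expm1(_dense(adata.raw.X)) * totals[:, None] / target)
    return AnnData(
        X=X,
        obs=adata.obs[[]].copy(),
        var=pd.DataFrame(index=adata.raw.var_names),
    )
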