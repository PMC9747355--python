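"""Automatic clustering-resolution selection by subsampling robustness.

For each candidate resolution, the cells are repeatedly subsampled (by
default 5 repetitions of a random 80% subset drawn without replacement),
each subset is re-clustered, and the co-clustering frequency of every cell
pair is recorded.  The dissimilarity ``1 - frequency`` then scores the
full-data clustering with the mean silhouette: a partition whose clusters
keep re-forming under subsampling earns a score near 1, an unstable one
near 0.  The resolution with the highest score wins; ties go to the
smaller (coarser) resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData

from .preprocess import cluster_graph, cluster_louvain

__all__ = [
    "CoClusterMatrix",
    "ResolutionScore",
    "coclustering",
    "robustness_score",
    "choose_resolution",
]

DEFAULT_GRID = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4)


@dataclass
class CoClusterMatrix:
    """Pairwise co-clustering frequencies under subsampling.

    ``frequency[i, j]`` is the fraction of repetitions in which cells i and
    j landed in the same cluster, among repetitions where both were
    sampled (NaN where a pair was never co-sampled);
    ``n_pairs_observed[i, j]`` counts those repetitions.
    """

    frequency: np.ndarray
    n_pairs_observed: np.ndarray

    def distance(self) -> np.ndarray:
        return 1.0 - self.frequency


@dataclass
class ResolutionScore:
    resolution: float
    score: float
    n_clusters: int


def _subsample_labels(adata: AnnData, idx: np.ndarray, resolution: float, seed: int,
                      k_neighbors: int, n_pcs: int) -> np.ndarray:
    """Cluster a cell subset: neighbors recomputed on the subset embedding."""
    sub = AnnData(X=np.zeros((idx.size, 1)))
    sub.obsm["X_pca"] = np.asarray(adata.obsm["X_pca"])[idx, :n_pcs]
    sc.pp.neighbors(
        sub,
        n_neighbors=min(k_neighbors, idx.size - 1),
        use_rep="X_pca",
        random_state=seed,
    )
    return cluster_graph(sub.obsp["connectivities"], resolution, seed)


def coclustering(
    adata: AnnData,
    resolution: float,
    n_reps: int = 5,
    frac: float = 0.8,
    seed: int = 0,
    k_neighbors: int = 15,
) -> CoClusterMatrix:
    """Co-clustering frequency matrix over random cell subsets.

    Each repetition draws ``frac`` of the cells uniformly without
    replacement, re-clusters them at ``resolution`` (repetition ``r`` uses
    seed ``seed + r``), and tallies which observed pairs co-cluster.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if "X_pca" not in adata.obsm:
        raise ValueError("no PCA embedding; run pca_neighbors first")
    n = adata.n_obs
    n_pcs = np.asarray(adata.obsm["X_pca"]).shape[1]
    co = np.zeros((n, n))
    obs = np.zeros((n, n), dtype=int)
    n_sub = max(2, int(round(frac * n)))
    for r in range(n_reps):
        rep_seed = seed + r
        rng = np.random.default_rng(rep_seed)
        idx = np.sort(rng.choice(n, size=min(n_sub, n), replace=False))
        labels = _subsample_labels(adata, idx, resolution, rep_seed, k_neighbors, n_pcs)
        same = labels[:, None] == labels[None, :]
        co[np.ix_(idx, idx)] += same
        obs[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        freq = np.where(obs > 0, co / np.maximum(obs, 1), np.nan)
    return CoClusterMatrix(frequency=freq, n_pairs_observed=obs)


def robustness_score(
    cocluster: CoClusterMatrix,
    full_labels,
    resolution: float = float("nan"),
) -> ResolutionScore:
    """Mean silhouette of the full-data clustering on 1 − frequency.

    Silhouette terms use only observed pairs; cells without any observed
    within- or between-cluster pair are excluded, and singleton-cluster
    cells score 0.  With a single cluster the silhouette is undefined and
    the score is reported as 0 with a warning.
    """
    labels = np.asarray(full_labels)
    D = cocluster.distance()
    observed = cocluster.n_pairs_observed > 0
    uniq = np.unique(labels)
    if uniq.size < 2:
        warnings.warn("single cluster: silhouette undefined, score set to 0")
        return ResolutionScore(resolution, 0.0, int(uniq.size))
    n = labels.size
    sil = np.full(n, np.nan)
    for i in range(n):
        mask_obs = observed[i].copy()
        mask_obs[i] = False
        same = (labels == labels[i]) & mask_obs
        if (labels == labels[i]).sum() == 1:
            sil[i] = 0.0  # singleton cluster
            continue
        if not same.any():
            continue
        a = D[i, same].mean()
        b = np.inf
        for c in uniq:
            if c == labels[i]:
                continue
            other = (labels == c) & mask_obs
            if other.any():
                b = min(b, D[i, other].mean())
        if not np.isfinite(b):
            continue
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    score = float(np.nanmean(sil)) if np.isfinite(sil).any() else 0.0
    return ResolutionScore(resolution, score, int(uniq.size))


def choose_resolution(
    adata: AnnData,
    grid=DEFAULT_GRID,
    n_reps: int = 5,
    frac: float = 0.8,
    seed: int = 0,
    k_neighbors: int = 15,
    cluster_key: str = "cluster",
) -> tuple[float, pd.DataFrame]:
    """Pick the resolution with the highest subsampling robustness score.

    Returns the winning resolution (ties broken toward the smaller value)
    and a table with one row per grid value: resolution, score, n_clusters.
    The full-data clustering at the winner is written to
    ``adata.obs[cluster_key]``.
    """
    grid = sorted(float(g) for g in np.atleast_1d(grid))
    if not grid:
        raise ValueError("resolution grid is empty")
    rows = []
    labels_at = {}
    for g, res in enumerate(grid):
        cluster_louvain(adata, res, seed=seed, key_added=cluster_key)
        labels = adata.obs[cluster_key].to_numpy()
        labels_at[res] = labels
        cc = coclustering(
            adata, res, n_reps=n_reps, frac=frac,
            seed=seed + 1000 * g, k_neighbors=k_neighbors,
        )
        rows.append(robustness_score(cc, labels, resolution=res))
    table = pd.DataFrame(
        [(r.resolution, r.score, r.n_clusters) for r in rows],
        columns=["resolution", "score", "n_clusters"],
    )
    best_idx = int(table["score"].round(12).idxmax())  # idxmax → first (lowest res) on ties
    best = float(table.loc[best_idx, "resolution"])
    adata.obs[cluster_key] = pd.Categorical(labels_at[best])
    adata.uns[cluster_key] = {"resolution": best, "seed": int(seed), "auto": True}
    return best, table
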