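"""Differential expression, enrichment and tumor-cluster selection.

Ranks marker genes per cluster, tests a tiny gene-set library for
over-representation among strong markers, and applies the composition rule
that flags clusters over-represented among tumor-origin cells.
"""

import numpy as np
import pandas as pd

import scdrx
from scdrx.annotate import enrich, rank_degs, select_tumor_clusters

adata, truth = scdrx.simulate_counts(
    n_cells=450, n_genes=800, k_clusters=3, seed=0
)
res = scdrx.preprocess_and_cluster(adata, resolution=1.0, seed=0)

degs = rank_degs(res)
top = degs[degs["rank"] <= 3]
print("top 3 marker genes per cluster:")
print(top[["cluster", "gene", "log2_fold_change", "adj_p_value"]]
      .to_string(index=False))

# gene sets: one matching cluster 0's planted markers, one random
marker_set = truth.truth["markers"]["0"]
rng = np.random.default_rng(0)
library = {
    "planted_program": marker_set,
    "random_set": list(rng.choice(adata.var_names, 20, replace=False)),
}
enr = enrich(degs, library)
print("\nenrichment (hypergeometric, BH-adjusted):")
print(enr[["cluster", "term", "overlap_count", "p_value", "adj_p_value"]]
      .head(6).to_string(index=False))

# pretend cells from blob 0 came from tumor tissue
origin = pd.Series(
    np.where(pd.Series(truth.truth["labels"],
                       index=adata.obs_names).loc[res.obs_names] == 0,
             "tumor", "normal"),
    index=res.obs_names,
)
tumor = select_tumor_clusters(res.obs["cluster"], origin, ratio_threshold=2)
print(f"\nclusters >2x over-represented among tumor-origin cells: {tumor}")
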