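import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import scdrx


@pytest.fixture(scope="session")
def blob_adata():
    """Three-cluster synthetic counts with planted markers (450 cells)."""
    adata, truth = scdrx.simulate_counts(
        n_cells=450, n_genes=800, k_clusters=3, seed=0
    )
    return adata, truth


@pytest.fixture(scope="session")
def processed(blob_adata):
    """The blob fixture pushed through the full preprocessing + clustering chain."""
    adata, truth = blob_adata
    res = scdrx.preprocess_and_cluster(adata.copy(), resolution=1.0, seed=0)
    return res, truth


@pytest.fixture(scope="session")
def noiseless_panel():
    """Drug screen generated from the latent-factor model with no noise."""
    panel, truth = scdrx.simulate_drug_panel(
        n_lines=60, n_drugs=25, f_true=4, noise_sd=0.0, seed=0
    )
    return panel, truth


@pytest.fixture(scope="session")
def toy_signature():
    """Random positive signature matrix: 80 genes x 4 subpopulations."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.uniform(0.5, 5.0, size=(80, 4)),
        index=[f"G{i:03d}" for i in range(80)],
        columns=list("ABCD"),
    )


def random_counts_adata(n_cells=300, n_genes=500, seed=0, n_mito=5):
    """Sparse-ish random counts with a few mitochondrial genes."""
    rng = np.random.default_rng(seed)
    X = rng.poisson(rng.uniform(0.05, 2.0, size=n_genes), size=(n_cells, n_genes))
    genes = [f"MT-{i}" if i < n_mito else f"GENE{i}" for i in range(n_genes)]
    return AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )
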