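"""Readers and writers for the formats the workflow consumes and emits."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData

from .combo import PerturbationScreen
from .drugrec import DrugPanel
from .survival import SurvivalCohort

__all__ = [
    "read_counts",
    "read_dense_counts",
    "read_10x_mtx",
    "write_clustering",
    "read_drug_panel",
    "read_survival_cohort",
    "read_perturbation_screen",
]


def read_10x_mtx(directory) -> AnnData:
    """10x-style Matrix Market triplet: matrix.mtx + barcodes + features."""
    adata = sc.read_10x_mtx(Path(directory))
    adata.X = np.asarray(adata.X.todense()) if hasattr(adata.X, "todense") else adata.X
    return adata


def read_dense_counts(path, sep: str = "\t") -> AnnData:
    """Dense genes × cells table → AnnData (cells × genes)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene identifiers in counts table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate cell identifiers in counts table")
    return AnnData(
        X=df.T.to_numpy(dtype=np.int64),
        obs=pd.DataFrame(index=df.columns),
        var=pd.DataFrame(index=df.index),
    )


def read_counts(path) -> AnnData:
    """Counts from a 10x directory or a dense genes × cells TSV/CSV."""
    path = Path(path)
    if path.is_dir():
        return read_10x_mtx(path)
    sep = "," if path.suffix == ".csv" else "\t"
    return read_dense_counts(path, sep=sep)


def write_clustering(adata: AnnData, path, cluster_key: str = "cluster"):
    """Two-column TSV: cell_id, cluster."""
    out = pd.DataFrame(
        {"cell_id": adata.obs_names, "cluster": adata.obs[cluster_key].astype(str)}
    )
    out.to_csv(path, sep="\t", index=False)


def _read_table(path):
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_drug_panel(expression_path, response_path, response_scale: str = "gdsc") -> DrugPanel:
    """Lines × genes expression and lines × drugs response tables."""
    expr = _read_table(expression_path)
    resp = _read_table(response_path)
    resp = resp.reindex(expr.index)
    return DrugPanel(expression=expr, response=resp, response_scale=response_scale)


def read_survival_cohort(expression_path, clinical_path) -> SurvivalCohort:
    """Genes × patients expression and a (patient, time, event) table."""
    expr = _read_table(expression_path).T  # stored genes × patients
    clin = pd.read_csv(
        clinical_path, sep="," if str(clinical_path).endswith(".csv") else "\t"
    )
    clin = clin.set_index(clin.columns[0])
    return SurvivalCohort(
        expression=expr,
        time=clin["time"].astype(float),
        event=clin["event"].astype(int),
    )


def read_perturbation_screen(meta_path, gep_path) -> PerturbationScreen:
    """Long-format experiment metadata plus genes × experiments profiles."""
    meta = pd.read_csv(meta_path, sep="\t")
    meta["is_control"] = meta["is_control"].astype(bool)
    gep = _read_table(gep_path)
    return PerturbationScreen(meta=meta, gep=gep)


def write_screen(screen: PerturbationScreen, meta_path, gep_path):
    screen.meta.to_csv(meta_path, sep="\t", index=False)
    screen.gep.to_csv(gep_path, sep="\t")
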