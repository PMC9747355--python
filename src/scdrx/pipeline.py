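"""End-to-end orchestration with a persistent analysis bundle.

A run is described by a single JSON-able config (validated up front with
field-path error messages) and materialized into a bundle directory: one
subfolder of outputs per stage plus a manifest recording every stage's
parameters and input hashes.  Re-running with an unchanged config skips
completed stages, so the bundle doubles as a resumable cache.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ValidationError

from . import annotate as _annotate
from . import autores as _autores
from . import combo as _combo
from . import drugrec as _drugrec
from . import io as _io
from . import preprocess as _pre
from . import survival as _survival

__all__ = ["PipelineConfig", "AnalysisBundle", "run_pipeline"]

log = logging.getLogger("scdrx")


class ClusterStage(BaseModel):
    input: Optional[str] = None          # 10x dir or dense TSV; None → error
    resolution: Optional[float] = None   # None + auto_resolution → grid search
    auto_resolution: bool = False
    grid: list[float] = [0.4, 0.6, 0.8, 1.0, 1.2, 1.4]
    n_reps: int = 5
    subsample_frac: float = 0.8
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_frac: float = 0.30
    mito_prefix: str = "MT-"
    target_sum: float = 10_000.0
    n_top_genes: int = 2000
    n_pcs: int = 20
    k_neighbors: int = 15
    seed: int = 0


class AnnotateStage(BaseModel):
    gmt: Optional[str] = None
    reference: Optional[str] = None       # genes × reference samples TSV
    tumor_origin: Optional[str] = None    # TSV: cell_id, origin
    ratio_threshold: float = 2.0
    lfc_min: float = 2.0
    p_max: float = 0.01
    adj_p_max: float = 0.01


class SurvivalStage(BaseModel):
    bulk: str
    clinical: str
    top_n: int = 20


class DrugrecStage(BaseModel):
    panel_expression: str
    panel_response: str
    scale: str = "gdsc"
    latent_dim: int = 10
    lam: float = 0.01
    learning_rate: float = 0.01
    max_epochs: int = 100_000
    min_abs_corr: Optional[float] = None  # set → feature-gene selection
    mode: str = "per_cell_mean"
    seed: int = 0


class ComboStage(BaseModel):
    screen_meta: str
    screen_gep: str
    reference_panel: Optional[str] = None  # genes × lines TSV for assignment
    reference_line: Optional[str] = None
    kill_threshold: float = 0.90
    consistency_threshold: float = 0.75


class PipelineConfig(BaseModel):
    cluster: ClusterStage
    annotate: Optional[AnnotateStage] = None
    survival: Optional[SurvivalStage] = None
    drugrec: Optional[DrugrecStage] = None
    combo: Optional[ComboStage] = None


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path) -> str:
    p = Path(path)
    h = hashlib.sha256()
    if p.is_dir():
        for f in sorted(p.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


class AnalysisBundle:
    """Directory of stage outputs plus a manifest of parameters and hashes."""

    def __init__(self, directory):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )

    def stage_dir(self, name: str) -> Path:
        d = self.dir / name
        d.mkdir(exist_ok=True)
        return d

    def is_current(self, name: str, fingerprint: str) -> bool:
        rec = self.manifest["stages"].get(name)
        return rec is not None and rec["fingerprint"] == fingerprint

    def record(self, name: str, fingerprint: str, params: dict, outputs: list[str]):
        self.manifest["stages"][name] = {
            "fingerprint": fingerprint,
            "params": params,
            "outputs": outputs,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    # stage outputs the later stages reload
    def load_adata(self):
        import anndata

        return anndata.read_h5ad(self.stage_dir("cluster") / "analysis.h5ad")

    def load_degs(self) -> pd.DataFrame:
        return pd.read_csv(self.stage_dir("annotate") / "degs.tsv", sep="\t")

    def load_gep(self) -> pd.DataFrame:
        return pd.read_csv(self.stage_dir("annotate") / "gep.tsv", sep="\t", index_col=0)


def run_pipeline(config, outdir) -> AnalysisBundle:
    """Execute the configured stages into an analysis bundle.

    ``config`` is a dict or :class:`PipelineConfig`.  Validation errors are
    raised with field paths before any computation.  Stages run in order
    cluster → annotate → survival → drugrec → combo; each is skipped when
    the bundle already holds its outputs under an identical fingerprint.
    """
    if not isinstance(config, PipelineConfig):
        try:
            config = PipelineConfig.model_validate(config)
        except ValidationError as err:
            paths = "; ".join(
                ".".join(map(str, e["loc"])) + ": " + e["msg"] for e in err.errors()
            )
            raise ValueError(f"invalid pipeline config — {paths}") from None
    bundle = AnalysisBundle(outdir)
    _stage_cluster(config.cluster, bundle)
    if config.annotate is not None or config.survival or config.drugrec or config.combo:
        _stage_annotate(config.annotate or AnnotateStage(), bundle)
    if config.survival is not None:
        _stage_survival(config.survival, bundle)
    if config.drugrec is not None:
        _stage_drugrec(config.drugrec, bundle)
    if config.combo is not None:
        _stage_combo(config.combo, bundle)
    return bundle


def _fingerprint(stage_model: BaseModel, input_paths: list) -> str:
    return _hash_obj(
        {
            "params": stage_model.model_dump(),
            "inputs": {str(p): _hash_file(p) for p in input_paths if p},
        }
    )


def _stage_cluster(cfg: ClusterStage, bundle: AnalysisBundle):
    if cfg.input is None:
        raise ValueError("cluster.input is required (10x directory or dense TSV)")
    fp = _fingerprint(cfg, [cfg.input])
    if bundle.is_current("cluster", fp):
        log.info("cluster: up to date, skipping")
        return
    log.info("cluster: reading %s", cfg.input)
    counts = _io.read_counts(cfg.input)
    adata = _pre.filter_cells_genes(
        counts, cfg.min_genes_per_cell, cfg.min_cells_per_gene,
        cfg.max_mito_frac, cfg.mito_prefix,
    )
    adata = _pre.normalize_log(adata, cfg.target_sum)
    adata = _pre.select_hvg_scale(adata, cfg.n_top_genes)
    adata = _pre.pca_neighbors(adata, cfg.n_pcs, cfg.k_neighbors, cfg.seed)
    out = bundle.stage_dir("cluster")
    if cfg.auto_resolution:
        best, table = _autores.choose_resolution(
            adata, cfg.grid, cfg.n_reps, cfg.subsample_frac, cfg.seed, cfg.k_neighbors
        )
        table.to_csv(out / "resolution_scores.tsv", sep="\t", index=False)
        log.info("cluster: auto-resolution chose %.2f", best)
    else:
        _pre.cluster_louvain(adata, cfg.resolution or 1.0, cfg.seed)
    _io.write_clustering(adata, out / "clustering.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata.write_h5ad(out / "analysis.h5ad")
    bundle.record("cluster", fp, cfg.model_dump(), ["clustering.tsv", "analysis.h5ad"])


def _stage_annotate(cfg: AnnotateStage, bundle: AnalysisBundle):
    fp = _hash_obj(
        {"params": cfg.model_dump(),
         "upstream": bundle.manifest["stages"]["cluster"]["fingerprint"]}
    )
    if bundle.is_current("annotate", fp):
        log.info("annotate: up to date, skipping")
        return
    adata = bundle.load_adata()
    out = bundle.stage_dir("annotate")
    degs = _annotate.rank_degs(adata)
    degs.to_csv(out / "degs.tsv", sep="\t", index=False)
    gep = _annotate.cluster_gep(adata)
    gep.to_csv(out / "gep.tsv", sep="\t")
    outputs = ["degs.tsv", "gep.tsv"]
    if cfg.reference:
        ref = pd.read_csv(cfg.reference, sep="\t", index_col=0)
        ann = _annotate.annotate_cell_types(gep, ref)
        ann.to_csv(out / "cell_types.tsv", sep="\t", index=False)
        outputs.append("cell_types.tsv")
    if cfg.gmt:
        sets = _annotate.parse_gmt(cfg.gmt)
        enr = _annotate.enrich(degs, sets, cfg.lfc_min, cfg.p_max, cfg.adj_p_max)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        outputs.append("enrichment.tsv")
    if cfg.tumor_origin:
        origin = pd.read_csv(cfg.tumor_origin, sep="\t", index_col=0).iloc[:, 0]
        tumor = _annotate.select_tumor_clusters(
            adata.obs["cluster"], origin, cfg.ratio_threshold
        )
        (out / "tumor_clusters.json").write_text(json.dumps(tumor))
        outputs.append("tumor_clusters.json")
    bundle.record("annotate", fp, cfg.model_dump(), outputs)


def _stage_survival(cfg: SurvivalStage, bundle: AnalysisBundle):
    fp = _hash_obj(
        {"params": cfg.model_dump(),
         "inputs": {p: _hash_file(p) for p in [cfg.bulk, cfg.clinical]},
         "upstream": bundle.manifest["stages"]["annotate"]["fingerprint"]}
    )
    if bundle.is_current("survival", fp):
        log.info("survival: up to date, skipping")
        return
    cohort = _io.read_survival_cohort(cfg.bulk, cfg.clinical)
    degs = bundle.load_degs()
    table = _survival.survival_analysis(cohort, degs, n=cfg.top_n)
    out = bundle.stage_dir("survival")
    table.to_csv(out / "survival.tsv", sep="\t", index=False)
    bundle.record("survival", fp, cfg.model_dump(), ["survival.tsv"])


def _stage_drugrec(cfg: DrugrecStage, bundle: AnalysisBundle):
    fp = _hash_obj(
        {"params": cfg.model_dump(),
         "inputs": {p: _hash_file(p) for p in [cfg.panel_expression, cfg.panel_response]},
         "upstream": bundle.manifest["stages"]["cluster"]["fingerprint"]}
    )
    if bundle.is_current("drugrec", fp):
        log.info("drugrec: up to date, skipping")
        return
    panel = _io.read_drug_panel(cfg.panel_expression, cfg.panel_response, cfg.scale)
    if cfg.scale == "prism":
        panel.response.loc[:, :] = _drugrec.scale_prism(panel.response.to_numpy())
    feature_genes = None
    if cfg.min_abs_corr is not None:
        feature_genes = _drugrec.select_feature_genes(
            panel.expression, panel.response, cfg.min_abs_corr
        )
    model = _drugrec.train(
        panel, f=cfg.latent_dim, lam=cfg.lam, learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs, seed=cfg.seed, feature_genes=feature_genes,
    )
    adata = bundle.load_adata()
    from .preprocess import _dense

    cells = pd.DataFrame(
        _dense(adata.raw.X), index=adata.obs_names, columns=adata.raw.var_names
    )
    shared = [g for g in model.feature_genes if g in cells.columns]
    if not shared:
        raise ValueError("no overlap between panel feature genes and single-cell genes")
    model.feature_genes = shared
    result = _drugrec.predict_cells(
        model, panel, cells, adata.obs["cluster"], mode=cfg.mode
    )
    retained = _drugrec.filter_drugs(model, panel)
    out = bundle.stage_dir("drugrec")
    model.save(out / "model")
    result.sensitivity[retained].to_csv(out / "sensitivity.tsv", sep="\t")
    result.response.to_csv(out / "response.tsv", sep="\t")
    bundle.record(
        "drugrec", fp, cfg.model_dump(),
        ["model", "sensitivity.tsv", "response.tsv"],
    )


def _stage_combo(cfg: ComboStage, bundle: AnalysisBundle):
    fp = _hash_obj(
        {"params": cfg.model_dump(),
         "inputs": {p: _hash_file(p) for p in [cfg.screen_meta, cfg.screen_gep]},
         "upstream": bundle.manifest["stages"]["annotate"]["fingerprint"]}
    )
    if bundle.is_current("combo", fp):
        log.info("combo: up to date, skipping")
        return
    screen = _io.read_perturbation_screen(cfg.screen_meta, cfg.screen_gep)
    gep = bundle.load_gep()
    signature = _combo.build_signature_matrix(gep, screen.gep.index)
    if cfg.reference_panel:
        ref = pd.read_csv(cfg.reference_panel, sep="\t", index_col=0)
        pooled = pd.Series(
            signature.mean(axis=1), index=signature.index
        )
        line, r = (
            (cfg.reference_line, float("nan"))
            if cfg.reference_line
            else _combo.assign_reference_line(pooled, ref)
        )
        screen.reference_line = line
        log.info("combo: reference line %s (r=%.3f)", line, r)
    props = _combo.deconvolve(screen, signature)
    kills = _combo.call_killed(
        props, screen, cfg.kill_threshold, cfg.consistency_threshold
    )
    plans = _combo.greedy_combination(kills)
    out = bundle.stage_dir("combo")
    props.to_csv(out / "proportions.tsv", sep="\t")
    kills.reductions.to_csv(out / "kill_table.tsv", sep="\t")
    (out / "plans.json").write_text(
        json.dumps([p.to_dict() for p in plans], indent=1)
    )
    bundle.record(
        "combo", fp, cfg.model_dump(),
        ["proportions.tsv", "kill_table.tsv", "plans.json"],
    )
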