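"""Truth-labelled synthetic data for every stage of the workflow.

These generators emulate the four external data sources the pipeline
consumes — a 10x-style count matrix, a cell-line drug screen, a bulk
survival cohort and a bulk perturbation screen — with known ground truth
(cluster labels, planted markers, latent factors, hazard multipliers,
kill patterns) so the whole workflow can be exercised and validated
without any download.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData

from .combo import PerturbationScreen
from .drugrec import DrugPanel
from .survival import SurvivalCohort

__all__ = [
    "SyntheticTruth",
    "simulate_counts",
    "simulate_drug_panel",
    "simulate_perturbation_screen",
    "simulate_survival_cohort",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generator run; reproducible from (name, seed, params)."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "params": self.params,
                "truth": self.truth,
            },
            default=default,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "SyntheticTruth":
        d = json.loads(s)
        return cls(d["generator"], d["seed"], d["params"], d["truth"])

    def save(self, path):
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        return cls.from_json(Path(path).read_text())


def simulate_counts(
    n_cells: int = 750,
    n_genes: int = 2000,
    k_clusters: int = 5,
    n_markers_per_cluster: int = 20,
    depth: float = 5000.0,
    dispersion: float = 0.5,
    marker_fold: float = 4.0,
    seed: int = 0,
) -> tuple[AnnData, SyntheticTruth]:
    """Negative-binomial counts with planted cluster markers.

    Gene abundances are log-normal; each cluster up-regulates its own
    disjoint marker set by ``marker_fold``; per-cell library sizes vary
    log-normally around ``depth``.  Counts are NB with dispersion
    ``dispersion`` (variance m + dispersion·m²).  Truth records cluster
    labels and marker assignments.
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be at least 1")
    if k_clusters * n_markers_per_cluster > n_genes:
        raise ValueError("not enough genes for the requested marker sets")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base /= base.sum()
    markers = {
        str(c): list(range(c * n_markers_per_cluster, (c + 1) * n_markers_per_cluster))
        for c in range(k_clusters)
    }
    profiles = np.tile(base, (k_clusters, 1))
    for c in range(k_clusters):
        profiles[c, markers[str(c)]] *= marker_fold
        profiles[c] /= profiles[c].sum()
    labels = np.repeat(np.arange(k_clusters), int(np.ceil(n_cells / k_clusters)))[:n_cells]
    lib = depth * rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    mean = lib[:, None] * profiles[labels]
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    adata = AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(
            {"true_cluster": pd.Categorical(labels.astype(str))},
            index=[f"cell{i:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=gene_ids),
    )
    truth = SyntheticTruth(
        generator="simulate_counts",
        seed=seed,
        params={
            "n_cells": n_cells, "n_genes": n_genes, "k_clusters": k_clusters,
            "n_markers_per_cluster": n_markers_per_cluster, "depth": depth,
            "dispersion": dispersion, "marker_fold": marker_fold,
        },
        truth={
            "labels": labels.tolist(),
            "markers": {c: [gene_ids[i] for i in idx] for c, idx in markers.items()},
        },
    )
    return adata, truth


def simulate_drug_panel(
    n_lines: int = 60,
    n_drugs: int = 25,
    n_genes: int = 300,
    f_true: int = 4,
    noise_sd: float = 0.0,
    n_linked_genes: int = 30,
    gene_noise_sd: float = 0.3,
    response_scale: str = "gdsc",
    seed: int = 0,
) -> tuple[DrugPanel, SyntheticTruth]:
    """Drug screen drawn from the latent-factor model's own form.

    Latent line factors z_u drive the responses
    s_iu = b_i + q_i·z_u + ε (ε of sd ``noise_sd`` × sd(signal)) and a
    block of response-linked genes: each linked gene mixes a guaranteed
    component along the mean drug-loading direction (so the gene tracks
    overall response) with an orthogonal random loading (so the gene
    block, jointly, encodes the full latent space), plus gene-level noise.
    ``f_true=0`` degenerates to pure per-drug biases.  Truth stores z, q,
    b, the loading matrix and the linked-gene names.
    """
    if f_true > min(n_lines, n_drugs):
        raise ValueError("f_true must not exceed min(n_lines, n_drugs)")
    if n_linked_genes > n_genes:
        raise ValueError("n_linked_genes exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    lines = [f"line{i:03d}" for i in range(n_lines)]
    drugs = [f"drug{i:03d}" for i in range(n_drugs)]
    z = rng.normal(size=(n_lines, max(f_true, 1)))
    expr = rng.normal(loc=8.0, scale=1.0, size=(n_lines, n_genes))
    b = rng.normal(size=n_drugs)
    link = np.array([], dtype=int)
    V = np.zeros((max(f_true, 1), n_linked_genes))
    if f_true > 0:
        q = rng.normal(loc=0.8, scale=1.0, size=(n_drugs, f_true))
        signal = b[None, :] + z[:, :f_true] @ q.T
        if n_linked_genes > 0:
            link = np.arange(n_linked_genes)
            q_bar = q.mean(axis=0)
            q_hat = q_bar / np.linalg.norm(q_bar)
            for j in link:
                align = rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3)
                ortho = rng.normal(size=f_true)
                ortho -= (ortho @ q_hat) * q_hat
                V[:, j] = align * q_hat + 0.6 * ortho
            expr[:, link] = (
                8.0
                + z[:, :f_true] @ V
                + rng.normal(scale=gene_noise_sd, size=(n_lines, n_linked_genes))
            )
    else:
        q = np.zeros((n_drugs, 1))
        signal = np.tile(b, (n_lines, 1))
    sd = signal.std() if signal.std() > 0 else 1.0
    response = signal + rng.normal(scale=noise_sd * sd, size=signal.shape)
    panel = DrugPanel(
        expression=pd.DataFrame(expr, index=lines, columns=genes),
        response=pd.DataFrame(response, index=lines, columns=drugs),
        response_scale=response_scale,
    )
    truth = SyntheticTruth(
        generator="simulate_drug_panel",
        seed=seed,
        params={
            "n_lines": n_lines, "n_drugs": n_drugs, "n_genes": n_genes,
            "f_true": f_true, "noise_sd": noise_sd,
            "n_linked_genes": n_linked_genes, "gene_noise_sd": gene_noise_sd,
        },
        truth={
            "z": z[:, :max(f_true, 1)].tolist(),
            "q": q.tolist(),
            "b": b.tolist(),
            "loadings": V.tolist(),
            "linked_genes": [genes[i] for i in link],
        },
    )
    return panel, truth


def simulate_perturbation_screen(
    signature: pd.DataFrame,
    base_proportions,
    kill_patterns: dict,
    doses=(1.0, 10.0),
    noise_sd: float = 0.0,
    n_controls: int = 2,
    seed: int = 0,
) -> tuple[PerturbationScreen, SyntheticTruth]:
    """Bulk perturbation screen with planted subpopulation kills.

    ``signature``: genes × subpopulations (linear scale).
    ``base_proportions``: control mixture summing to 1.
    ``kill_patterns``: compound → (list of subpopulation ids, list of
    per-dose reduction fractions aligned with ``doses``).  Treated
    proportions multiply the targeted subpopulations by (1 − reduction)
    and renormalize; each bulk profile is the signature mixture plus
    Gaussian noise of sd ``noise_sd`` × sd(signal).
    """
    subs = list(signature.columns)
    base = np.asarray(base_proportions, dtype=float)
    if base.size != len(subs):
        raise ValueError("base_proportions length must match signature columns")
    if not np.isclose(base.sum(), 1.0):
        raise ValueError("base_proportions must sum to 1")
    doses = list(doses)
    for compound, (targets, reductions) in kill_patterns.items():
        if len(reductions) != len(doses):
            raise ValueError(f"{compound}: need one reduction per dose")
        if any(r > 1 for r in reductions):
            raise ValueError(f"{compound}: reduction cannot exceed 1")
        unknown = set(targets) - set(subs)
        if unknown:
            raise ValueError(f"{compound}: unknown subpopulations {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    A = signature.to_numpy(dtype=float)
    sd_signal = (A @ base).std() or 1.0
    rows, geps, true_props = [], {}, {}
    for i in range(n_controls):
        eid = f"ctrl{i}"
        rows.append((eid, "DMSO", 0.0, "uM", True))
        geps[eid] = A @ base + rng.normal(scale=noise_sd * sd_signal, size=A.shape[0])
        true_props[eid] = base.tolist()
    for compound in sorted(kill_patterns):
        targets, reductions = kill_patterns[compound]
        for dose, reduction in zip(doses, reductions):
            eid = f"{compound}@{dose:g}"
            props = base.copy()
            for s in targets:
                props[subs.index(s)] *= 1.0 - reduction
            total = props.sum()
            if total == 0:
                raise ValueError(f"{compound}: all subpopulations eliminated")
            props /= total
            rows.append((eid, compound, float(dose), "uM", False))
            geps[eid] = A @ props + rng.normal(
                scale=noise_sd * sd_signal, size=A.shape[0]
            )
            true_props[eid] = props.tolist()
    meta = pd.DataFrame(
        rows, columns=["experiment_id", "compound", "concentration", "unit", "is_control"]
    )
    gep = pd.DataFrame(geps, index=signature.index)
    gep = gep.clip(lower=0.0)
    screen = PerturbationScreen(meta=meta, gep=gep)
    truth = SyntheticTruth(
        generator="simulate_perturbation_screen",
        seed=seed,
        params={
            "doses": doses, "noise_sd": noise_sd, "n_controls": n_controls,
            "base_proportions": base.tolist(),
        },
        truth={
            "kill_patterns": {
                c: {"targets": list(t), "reductions": list(map(float, r))}
                for c, (t, r) in kill_patterns.items()
            },
            "proportions": true_props,
        },
    )
    return screen, truth


def simulate_survival_cohort(
    n_patients: int = 200,
    signatures: dict[str, list[str]] | None = None,
    effect_cluster: str | None = None,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    base_hazard: float = 0.1,
    activity_effect: float = 1.5,
    expr_noise_sd: float = 0.6,
    n_background_genes: int = 50,
    seed: int = 0,
) -> tuple[SurvivalCohort, SyntheticTruth]:
    """Bulk cohort whose survival is tied to one cluster's signature.

    Each patient carries a latent high/low activity state per cluster
    (Bernoulli 1/2); signature genes express baseline + ``activity_effect``
    when active, with Gaussian noise.  Event times are exponential with
    hazard ``base_hazard``, multiplied by ``hazard_ratio`` when the
    patient is active for ``effect_cluster``.  Censoring is independent
    exponential tuned so roughly ``censor_rate`` of patients are censored
    (``censor_rate=0`` disables it).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if signatures is None:
        signatures = {
            str(c): [f"s{c}_{i:02d}" for i in range(20)] for c in range(3)
        }
    if effect_cluster is None:
        effect_cluster = next(iter(signatures))
    if effect_cluster not in signatures:
        raise ValueError(f"effect_cluster {effect_cluster!r} not in signatures")
    rng = np.random.default_rng(seed)
    patients = [f"P{i:04d}" for i in range(n_patients)]
    activity = {
        c: rng.integers(0, 2, size=n_patients) for c in signatures
    }
    cols = {}
    for c, genes in signatures.items():
        for g in genes:
            cols[g] = (
                10.0
                + activity_effect * activity[c]
                + rng.normal(scale=expr_noise_sd, size=n_patients)
            )
    for i in range(n_background_genes):
        g = f"bg{i:03d}"
        cols[g] = 10.0 + rng.normal(scale=1.0, size=n_patients)
    expression = pd.DataFrame(cols, index=patients)
    hazard = base_hazard * np.where(activity[effect_cluster] == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        mean_rate = hazard.mean()
        cens_rate = mean_rate * censor_rate / max(1e-12, 1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / cens_rate, size=n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n_patients, dtype=int)
    cohort = SurvivalCohort(
        expression=expression,
        time=pd.Series(time, index=patients),
        event=pd.Series(event, index=patients),
    )
    truth = SyntheticTruth(
        generator="simulate_survival_cohort",
        seed=seed,
        params={
            "n_patients": n_patients, "hazard_ratio": hazard_ratio,
            "censor_rate": censor_rate, "base_hazard": base_hazard,
            "activity_effect": activity_effect, "expr_noise_sd": expr_noise_sd,
        },
        truth={
            "effect_cluster": effect_cluster,
            "signatures": {c: list(g) for c, g in signatures.items()},
            "activity": {c: a.tolist() for c, a in activity.items()},
        },
    )
    return cohort, truth
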