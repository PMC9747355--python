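"""Latent-factor drug-response prediction from expression kernel features.

A recommender-style bilinear model trained on a cell-line drug screen.
Each sample u is represented by kernel features x_u: its Pearson
correlations, over feature genes, between its expression fold-change
profile (relative to the training panel's per-gene mean) and each training
line's profile.  The model places drugs and samples in a shared
f-dimensional latent space:

    s_hat_iu = b_i + q_i . p_u,      p_u = x_u W

with per-drug bias b_i, latent drug vectors q_i (rows of Q) and a
projection W from kernel space (d = number of training lines) to the
latent space.  Sample-bias and global-mean terms are deliberately absent:
they cannot be estimated for unseen samples such as cell clusters, so the
objective is

    L = 1/(2K) * sum_observed (s_iu - s_hat_iu)^2
        + lambda * ||W||^2 + lambda * ||Q||^2

with K the number of observed drug–line pairs (missing responses are
masked).  Training is full-batch Adam with early stopping on relative loss
change.  GDSC-style panels store response as -log(IC50); PRISM-style
panels store 1-AUC affinely rescaled by D' = 240*D - 120 so its dynamic
range suits the same objective.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DrugPanel",
    "DrugModel",
    "HoldoutResult",
    "scale_prism",
    "inverse_scale_prism",
    "select_feature_genes",
    "kernel_features",
    "train",
    "predict_panel",
    "predict_cells",
    "filter_by_quartile",
    "filter_drugs",
    "evaluate_holdout",
]


@dataclass
class DrugPanel:
    """Training screen: line expression and per-drug response.

    ``expression``: lines × genes (log-scale values); ``response``: lines ×
    drugs, NaN for unmeasured pairs.  ``response_scale`` tags the
    convention: ``"gdsc"`` for -log(IC50), ``"prism"`` for scaled 1-AUC.
    """

    expression: pd.DataFrame
    response: pd.DataFrame
    response_scale: str = "gdsc"

    def __post_init__(self):
        if not self.expression.index.equals(self.response.index):
            raise ValueError("expression and response must share the same lines")
        if self.response_scale not in ("gdsc", "prism"):
            raise ValueError("response_scale must be 'gdsc' or 'prism'")

    @property
    def lines(self) -> pd.Index:
        return self.expression.index

    @property
    def drugs(self) -> pd.Index:
        return self.response.columns


def scale_prism(D):
    """Affine rescaling of 1-AUC drug response: D' = 240*D - 120."""
    return 240.0 * np.asarray(D, dtype=float) - 120.0


def inverse_scale_prism(D_scaled):
    """Inverse of :func:`scale_prism`: D = (D' + 120) / 240."""
    return (np.asarray(D_scaled, dtype=float) + 120.0) / 240.0


def select_feature_genes(
    expression: pd.DataFrame,
    response: pd.DataFrame,
    min_abs_corr: float = 0.2,
) -> list[str]:
    """Genes whose expression tracks drug response across lines.

    Correlates each gene with the per-line mean response (over drugs,
    NaN-aware) and keeps genes with |Pearson r| at or above the threshold.
    Constant genes have undefined correlation and are excluded.
    """
    if len(expression) < 3:
        raise ValueError("need at least 3 lines to correlate")
    target = response.mean(axis=1, skipna=True).reindex(expression.index)
    X = expression.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    keep = np.abs(r) >= min_abs_corr
    keep &= np.isfinite(r)
    genes = expression.columns[keep].tolist()
    if not genes:
        raise ValueError(
            f"no gene reaches |r| >= {min_abs_corr}; lower the threshold"
        )
    return genes


def _fold_change(expr: pd.DataFrame, reference: pd.Series) -> np.ndarray:
    """Expression fold-change profile: log-scale values minus a reference mean."""
    return expr.to_numpy(dtype=float) - reference.to_numpy(dtype=float)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray, names) -> np.ndarray:
    """Pearson correlation of every row of A against every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(Ac, axis=1)
    sb = np.linalg.norm(Bc, axis=1)
    bad = np.flatnonzero(sa == 0)
    if bad.size:
        raise ValueError(f"zero-variance fold-change profile for sample {names[bad[0]]!r}")
    if (sb == 0).any():
        raise ValueError("zero-variance fold-change profile in the training panel")
    return (Ac @ Bc.T) / np.outer(sa, sb)


@dataclass
class KernelFeatures:
    """Sample representation: correlations to every training line."""

    x: pd.DataFrame                  # samples × training lines
    fold_change_reference: pd.Series # per-gene mean used for the FC profile


def kernel_features(
    query_expression: pd.DataFrame,
    panel: DrugPanel,
    feature_genes: list[str],
    reference: pd.Series | None = None,
) -> KernelFeatures:
    """Kernel features of query samples against the training panel.

    Fold-change profiles are expression minus a per-gene reference mean —
    the panel mean by default, or a caller-supplied reference (e.g. the
    query's own average for single-cell data; Pearson correlation is
    invariant to the log base, so natural-log single-cell values work
    unchanged).  Feature genes must be present in both query and panel.
    """
    missing = [g for g in feature_genes if g not in query_expression.columns]
    if missing:
        raise KeyError(f"feature genes missing from query: {missing[:5]}")
    missing = [g for g in feature_genes if g not in panel.expression.columns]
    if missing:
        raise KeyError(f"feature genes missing from panel: {missing[:5]}")
    panel_expr = panel.expression[feature_genes]
    panel_ref = panel_expr.mean(axis=0)
    if reference is None:
        reference = panel_ref
    else:
        reference = reference.reindex(feature_genes)
    Fq = _fold_change(query_expression[feature_genes], reference)
    Ft = _fold_change(panel_expr, panel_ref)
    x = _rowwise_pearson(Fq, Ft, list(query_expression.index))
    return KernelFeatures(
        x=pd.DataFrame(x, index=query_expression.index, columns=panel.lines),
        fold_change_reference=panel_ref,
    )


@dataclass
class DrugModel:
    """Trained bias-free latent-factor model (see module docstring)."""

    W: np.ndarray                 # d × f projection
    Q: np.ndarray                 # drugs × f latent drug matrix
    b_q: np.ndarray               # per-drug bias
    mu: float                     # overall mean response (diagnostic only)
    f: int
    lam: float
    feature_genes: list[str]
    line_ids: list[str]           # training lines defining kernel space
    drug_ids: list[str]
    fold_change_reference: pd.Series
    response_scale: str
    config: dict = field(default_factory=dict)
    loss_trace: np.ndarray | None = None

    def predict_from_kernel(self, x: np.ndarray) -> np.ndarray:
        """s_hat = b_q + (x W) Q^T — no sample bias, no global mean."""
        return self.b_q[None, :] + (np.asarray(x) @ self.W) @ self.Q.T

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "W.tsv", self.W, delimiter="\t")
        np.savetxt(directory / "Q.tsv", self.Q, delimiter="\t")
        np.savetxt(directory / "b_q.tsv", self.b_q, delimiter="\t")
        self.fold_change_reference.to_csv(
            directory / "fold_change_reference.tsv", sep="\t", header=["mean"]
        )
        meta = {
            "mu": self.mu, "f": self.f, "lam": self.lam,
            "feature_genes": self.feature_genes, "line_ids": self.line_ids,
            "drug_ids": self.drug_ids, "response_scale": self.response_scale,
            "config": self.config,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "DrugModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        ref = pd.read_csv(directory / "fold_change_reference.tsv", sep="\t", index_col=0)[
            "mean"
        ]
        return cls(
            W=np.atleast_2d(np.loadtxt(directory / "W.tsv", delimiter="\t")),
            Q=np.atleast_2d(np.loadtxt(directory / "Q.tsv", delimiter="\t")),
            b_q=np.atleast_1d(np.loadtxt(directory / "b_q.tsv", delimiter="\t")),
            mu=meta["mu"], f=meta["f"], lam=meta["lam"],
            feature_genes=meta["feature_genes"], line_ids=meta["line_ids"],
            drug_ids=meta["drug_ids"], fold_change_reference=ref,
            response_scale=meta["response_scale"], config=meta["config"],
        )


def train(
    panel: DrugPanel,
    f: int = 10,
    lam: float = 0.01,
    learning_rate: float = 0.01,
    max_epochs: int = 100_000,
    seed: int = 0,
    feature_genes: list[str] | None = None,
    tol: float = 1e-8,
    patience: int = 100,
) -> DrugModel:
    """Fit the latent-factor model by full-batch Adam.

    ``feature_genes`` defaults to all panel genes.  The latent dimension
    ``f`` is capped at the number of training lines.  Early stopping
    triggers when the relative loss change over ``patience`` epochs falls
    below ``tol``; a NaN loss aborts with advice to lower the learning
    rate.  The per-epoch loss trace is kept on the returned model.
    """
    if feature_genes is None:
        feature_genes = panel.expression.columns.tolist()
    f = int(min(f, len(panel.lines)))
    if f < 1:
        raise ValueError("latent dimension must be at least 1")
    kf = kernel_features(panel.expression, panel, feature_genes)
    X = kf.x.to_numpy()                        # n_lines × d (d = n_lines)
    S = panel.response.to_numpy(dtype=float)   # n_lines × n_drugs
    mask = np.isfinite(S)
    K = int(mask.sum())
    if K == 0:
        raise ValueError("no observed drug-line responses")
    S0 = np.where(mask, S, 0.0)
    d = X.shape[1]
    n_drugs = S.shape[1]
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 0.01, size=(d, f))
    Q = rng.normal(0.0, 0.01, size=(n_drugs, f))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        b = np.nanmean(S, axis=0)
    b = np.where(np.isfinite(b), b, 0.0)
    mu = float(S0.sum() / K)

    # Adam state
    m = {k: 0.0 for k in "WQb"}
    v = {k: 0.0 for k in "WQb"}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses = np.empty(max_epochs)
    n_done = 0
    for epoch in range(max_epochs):
        P = X @ W                              # lines × f
        pred = b[None, :] + P @ Q.T
        resid = np.where(mask, pred - S0, 0.0)
        loss = (resid ** 2).sum() / (2 * K) + lam * (W ** 2).sum() + lam * (Q ** 2).sum()
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); try a smaller learning rate"
            )
        losses[epoch] = loss
        n_done = epoch + 1
        if epoch >= patience:
            prev = losses[epoch - patience]
            if prev > 0 and (prev - loss) / prev < tol:
                break
        g = resid / K
        gW = X.T @ (g @ Q) + 2 * lam * W
        gQ = g.T @ P + 2 * lam * Q
        gb = g.sum(axis=0)
        t = epoch + 1
        for key, theta, grad in (("W", W, gW), ("Q", Q, gQ), ("b", b, gb)):
            m[key] = beta1 * m[key] + (1 - beta1) * grad
            v[key] = beta2 * v[key] + (1 - beta2) * grad ** 2
            mhat = m[key] / (1 - beta1 ** t)
            vhat = v[key] / (1 - beta2 ** t)
            theta -= learning_rate * mhat / (np.sqrt(vhat) + eps)
    return DrugModel(
        W=W, Q=Q, b_q=b, mu=mu, f=f, lam=lam,
        feature_genes=list(feature_genes),
        line_ids=panel.lines.tolist(),
        drug_ids=panel.drugs.tolist(),
        fold_change_reference=kf.fold_change_reference,
        response_scale=panel.response_scale,
        config={
            "learning_rate": learning_rate, "max_epochs": max_epochs,
            "seed": seed, "tol": tol, "patience": patience,
        },
        loss_trace=losses[:n_done].copy(),
    )


def predict_panel(
    model: DrugModel,
    panel: DrugPanel,
    query_expression: pd.DataFrame,
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Predicted response for arbitrary samples given the training panel."""
    kf = kernel_features(query_expression, panel, model.feature_genes, reference)
    x = kf.x[model.line_ids].to_numpy()
    out = model.predict_from_kernel(x)
    return pd.DataFrame(out, index=query_expression.index, columns=model.drug_ids)


@dataclass
class ClusterDrugResponse:
    """Per-cluster predicted response and derived sensitivity score."""

    response: pd.DataFrame      # clusters × drugs, model scale
    sensitivity: pd.DataFrame   # clusters × drugs, higher = more sensitive
    mode: str
    response_scale: str


def predict_cells(
    model: DrugModel,
    panel: DrugPanel,
    cell_expression: pd.DataFrame,
    clusters: pd.Series,
    mode: str = "per_cell_mean",
) -> ClusterDrugResponse:
    """Predict drug response of cell clusters.

    ``per_cell_mean``: each cell's fold change is taken against the average
    over all cells, each cell is predicted, and predictions are averaged
    within each cluster.  ``cluster_wise``: each cluster's fold change is
    its mean expression minus the mean over all other clusters' cells, and
    one prediction is made per cluster.  For PRISM-scale models the
    sensitivity score is the inverse-scaled 1-AUC (higher = more
    sensitive); for GDSC-scale models it is the predicted -log(IC50).
    """
    clusters = clusters.reindex(cell_expression.index).astype(str)
    if clusters.isna().any():
        raise ValueError("cells without cluster label")
    genes = [g for g in model.feature_genes if g in cell_expression.columns]
    if not genes:
        raise ValueError("no overlap between model feature genes and cell genes")
    if mode == "per_cell_mean":
        ref = cell_expression[genes].mean(axis=0)
        per_cell = predict_panel(model, panel, cell_expression, reference=ref)
        resp = per_cell.groupby(clusters.to_numpy()).mean()
    elif mode == "cluster_wise":
        rows = {}
        for c in sorted(clusters.unique()):
            in_c = (clusters == c).to_numpy()
            if in_c.sum() == 0 or (~in_c).sum() == 0:
                raise ValueError(f"cluster {c}: cannot form cluster-vs-rest contrast")
            fc_ref = cell_expression.loc[~in_c, genes].mean(axis=0)
            q = cell_expression.loc[in_c, genes].mean(axis=0).to_frame().T
            q.index = [c]
            rows[c] = predict_panel(model, panel, q, reference=fc_ref).iloc[0]
        resp = pd.DataFrame(rows).T
    else:
        raise ValueError("mode must be 'per_cell_mean' or 'cluster_wise'")
    resp.index.name = "cluster"
    if model.response_scale == "prism":
        sens = pd.DataFrame(
            inverse_scale_prism(resp.to_numpy()), index=resp.index, columns=resp.columns
        )
    else:
        sens = resp.copy()  # response already stored as -log(IC50)
    return ClusterDrugResponse(
        response=resp, sensitivity=sens, mode=mode,
        response_scale=model.response_scale,
    )


def filter_by_quartile(coefficients: pd.Series) -> list[str]:
    """Keep entries at or above the first quartile of the coefficients.

    The quartile uses linear-interpolation percentiles; only entries
    strictly below it are dropped.  NaN coefficients are never dropped
    (no evidence either way).  Fewer than 4 entries: no filtering.
    """
    coefficients = pd.Series(coefficients, dtype=float)
    if len(coefficients) < 4:
        warnings.warn("fewer than 4 drugs: quartile filtering skipped")
        return coefficients.index.tolist()
    finite = coefficients.dropna()
    q1 = np.percentile(finite, 25)
    keep = coefficients.isna() | (coefficients >= q1)
    return coefficients.index[keep].tolist()


def filter_drugs(model: DrugModel, panel: DrugPanel) -> list[str]:
    """Drop drugs the model ranks poorly on its own training lines.

    Per drug, the Spearman correlation between predicted and observed
    response across lines is computed; drugs strictly below the first
    quartile (linear interpolation) of these coefficients are dropped.
    Panels with fewer than 4 drugs are returned unfiltered with a warning.
    """
    drugs = list(model.drug_ids)
    if len(drugs) < 4:
        warnings.warn("fewer than 4 drugs: quartile filtering skipped")
        return drugs
    pred = predict_panel(model, panel, panel.expression)
    coeffs = {}
    for drug in drugs:
        obs = panel.response[drug]
        ok = obs.notna()
        if ok.sum() < 3:
            coeffs[drug] = np.nan
            continue
        coeffs[drug] = stats.spearmanr(pred.loc[ok, drug], obs[ok]).statistic
    return filter_by_quartile(pd.Series(coeffs))


@dataclass
class HoldoutResult:
    median_abs_error: float
    pearson_r: float
    per_drug_spearman: pd.Series
    predictions: pd.DataFrame
    holdout_lines: list[str]


def evaluate_holdout(
    panel: DrugPanel,
    n_holdout: int = 24,
    f: int = 10,
    lam: float = 0.01,
    learning_rate: float = 0.01,
    max_epochs: int = 100_000,
    seed: int = 0,
    feature_genes: list[str] | None = None,
) -> HoldoutResult:
    """Held-out-line evaluation of the drug-response model.

    Splits off ``n_holdout`` lines, trains on the remainder, predicts the
    held-out lines through their kernel features against the training
    lines, and reports the median absolute error and Pearson r over
    observed pairs (plus per-drug Spearman correlations).
    """
    n_lines = len(panel.lines)
    if n_holdout >= n_lines:
        raise ValueError("n_holdout must be smaller than the number of lines")
    rng = np.random.default_rng(seed)
    hold_idx = np.sort(rng.choice(n_lines, size=n_holdout, replace=False))
    hold = panel.lines[hold_idx]
    keep = panel.lines.difference(hold, sort=False)
    train_panel = DrugPanel(
        panel.expression.loc[keep], panel.response.loc[keep], panel.response_scale
    )
    model = train(
        train_panel, f=f, lam=lam, learning_rate=learning_rate,
        max_epochs=max_epochs, seed=seed, feature_genes=feature_genes,
    )
    pred = predict_panel(model, train_panel, panel.expression.loc[hold])
    obs = panel.response.loc[hold]
    mask = obs.notna()
    diffs = (pred - obs).abs().to_numpy()[mask.to_numpy()]
    p = pred.to_numpy()[mask.to_numpy()]
    o = obs.to_numpy()[mask.to_numpy()]
    pearson = float(stats.pearsonr(p, o).statistic) if p.size > 1 else np.nan
    per_drug = {}
    for drug in panel.drugs:
        ok = mask[drug]
        if ok.sum() >= 3 and obs.loc[ok, drug].nunique() > 1:
            per_drug[drug] = float(
                stats.spearmanr(pred.loc[ok, drug], obs.loc[ok, drug]).statistic
            )
        else:
            per_drug[drug] = np.nan
    return HoldoutResult(
        median_abs_error=float(np.median(diffs)),
        pearson_r=pearson,
        per_drug_spearman=pd.Series(per_drug),
        predictions=pred,
        holdout_lines=hold.tolist(),
    )
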