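"""Prognostic scoring of cell clusters against a bulk survival cohort.

Each cluster contributes a signature of its top differentially expressed
genes (20 by default).  A patient's activity score for a cluster counts
how many signature genes that patient expresses strictly above the
cohort-wide median — an integer in [0, signature size].  Patients in the
top and bottom quartiles of a cluster's scores form high- and
low-expressing groups whose survival is compared with Kaplan–Meier curves
and the two-sample log-rank test; the hazard ratio is the ratio of
observed/expected event counts from the log-rank table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "SurvivalCohort",
    "KMResult",
    "signature_genes",
    "activity_scores",
    "stratify",
    "km_logrank",
    "survival_analysis",
]


@dataclass
class SurvivalCohort:
    """Bulk expression (patients × genes) with right-censored follow-up."""

    expression: pd.DataFrame
    time: pd.Series
    event: pd.Series

    def __post_init__(self):
        self.time = self.time.reindex(self.expression.index)
        self.event = self.event.reindex(self.expression.index).astype(int)
        if self.time.isna().any() or self.event.isna().any():
            raise ValueError("time/event missing for some patients")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicate patient identifiers")
        if not set(self.event.unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def patients(self) -> pd.Index:
        return self.expression.index


@dataclass
class KMResult:
    statistic: float
    p_value: float
    hazard_ratio: float
    n_high: int
    n_low: int
    observed: dict = field(default_factory=dict)   # group -> O
    expected: dict = field(default_factory=dict)   # group -> E
    curves: dict = field(default_factory=dict)     # group -> (times, survival)


def signature_genes(
    deg_table: pd.DataFrame,
    cohort_genes,
    n: int = 20,
) -> dict[str, list[str]]:
    """Top-``n`` DEGs per cluster, restricted to genes the cohort measures.

    Genes absent from the cohort are back-filled from the next DEG ranks so
    every signature keeps a comparable size; a shortfall is reported with a
    warning and clusters with no usable gene are dropped.
    """
    cohort_genes = set(cohort_genes)
    signatures: dict[str, list[str]] = {}
    for cluster, df in deg_table.groupby("cluster", observed=True):
        ranked = df.sort_values("rank")["gene"]
        usable = [g for g in ranked if g in cohort_genes][:n]
        if not usable:
            warnings.warn(f"cluster {cluster}: no signature gene found in cohort")
            continue
        if len(usable) < n:
            warnings.warn(
                f"cluster {cluster}: signature truncated to {len(usable)}/{n} genes"
            )
        signatures[str(cluster)] = usable
    if not signatures:
        raise ValueError("no cluster has any usable signature gene")
    return signatures


def activity_scores(
    cohort: SurvivalCohort,
    signatures: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-patient, per-cluster count of signature genes above cohort median.

    Strictly above: a patient sitting exactly at a gene's median scores 0
    for that gene.
    """
    expr = cohort.expression
    medians = expr.median(axis=0)
    scores = {}
    for cluster, genes in signatures.items():
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            raise KeyError(f"signature genes missing from cohort: {missing}")
        above = expr[genes].gt(medians[genes], axis=1)
        scores[cluster] = above.sum(axis=1).astype(int)
    return pd.DataFrame(scores, index=expr.index)


def stratify(scores: pd.Series) -> pd.Series:
    """Split patients into high / low / excluded by score quartiles.

    High: score at or above the 75th percentile; low: at or below the
    25th (linear-interpolation percentiles, ties included in the extreme
    groups).  All-equal scores admit no separation and raise an error.
    """
    s = scores.astype(float)
    if s.size < 8:
        raise ValueError("need at least 8 patients to stratify by quartiles")
    if s.nunique() == 1:
        raise ValueError("no separation: all activity scores are equal")
    q1, q3 = np.percentile(s, [25, 75])
    out = pd.Series("excluded", index=s.index, dtype=object)
    out[s >= q3] = "high"
    out[s <= q1] = "low"
    if q1 == q3:
        out[(s >= q3) & (s <= q1)] = "excluded"
    return out


def _logrank_table(time, event, is_group1):
    """Two-sample log-rank O/E/V sums over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(is_group1, dtype=bool)
    O1 = E1 = V = 0.0
    O2 = E2 = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        n2 = n - n1
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        e1 = d * n1 / n
        O1 += d1
        E1 += e1
        O2 += d - d1
        E2 += d - e1
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return O1, E1, O2, E2, V


def km_logrank(
    cohort: SurvivalCohort,
    groups: pd.Series,
) -> KMResult:
    """Kaplan–Meier curves and log-rank comparison of high vs low groups.

    ``groups`` assigns each patient "high", "low" or "excluded".  The
    hazard ratio is (O_high/E_high)/(O_low/E_low) from the log-rank table;
    the statistic is the usual chi-square with 1 df.
    """
    groups = groups.reindex(cohort.patients)
    mask = groups.isin(["high", "low"]).to_numpy()
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise ValueError("both high and low groups must be non-empty")
    time = cohort.time.to_numpy()[mask]
    event = cohort.event.to_numpy()[mask]
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    is_high = (groups[mask] == "high").to_numpy()
    O1, E1, O2, E2, V = _logrank_table(time, event, is_high)
    statistic = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p_value = float(stats.chi2.sf(statistic, df=1)) if V > 0 else 1.0
    if E1 > 0 and E2 > 0 and O2 > 0:
        hr = (O1 / E1) / (O2 / E2)
    else:
        hr = np.nan
    curves = {}
    for name, sel in [("high", is_high), ("low", ~is_high)]:
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=name)
        sf = kmf.survival_function_
        curves[name] = (sf.index.to_numpy(), sf[name].to_numpy())
    return KMResult(
        statistic=float(statistic),
        p_value=p_value,
        hazard_ratio=float(hr),
        n_high=int(is_high.sum()),
        n_low=int((~is_high).sum()),
        observed={"high": O1, "low": O2},
        expected={"high": E1, "low": E2},
        curves=curves,
    )


def survival_analysis(
    cohort: SurvivalCohort,
    deg_table: pd.DataFrame,
    n: int = 20,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-cluster signature stratification and log-rank comparison.

    Returns one row per cluster: p-value, hazard ratio, group sizes and
    activity-score quartile bounds.  Raw log-rank p-values by default;
    ``adjust=True`` adds BH-corrected values across clusters.
    """
    signatures = signature_genes(deg_table, cohort.expression.columns, n=n)
    activity = activity_scores(cohort, signatures)
    rows = []
    for cluster in activity.columns:
        try:
            groups = stratify(activity[cluster])
            res = km_logrank(cohort, groups)
        except ValueError as err:
            warnings.warn(f"cluster {cluster}: {err}")
            rows.append(
                {"cluster": cluster, "p_value": np.nan, "hazard_ratio": np.nan,
                 "statistic": np.nan, "n_high": 0, "n_low": 0,
                 "n_signature_genes": len(signatures[cluster])}
            )
            continue
        rows.append(
            {
                "cluster": cluster,
                "p_value": res.p_value,
                "hazard_ratio": res.hazard_ratio,
                "statistic": res.statistic,
                "n_high": res.n_high,
                "n_low": res.n_low,
                "n_signature_genes": len(signatures[cluster]),
            }
        )
    out = pd.DataFrame(rows)
    if adjust and out["p_value"].notna().any():
        from statsmodels.stats.multitest import multipletests

        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["adj_p_value"] = adj
    return out
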