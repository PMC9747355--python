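"""Combined-treatment prediction from a bulk perturbation screen.

A perturbation screen measures bulk expression after treating a reference
cell line with compounds at one or more concentrations, plus untreated
controls.  Each bulk profile is deconvolved into subpopulation proportions
against a signature matrix built from the single-cell cluster profiles
(constrained linear deconvolution: non-negative least squares with
sum-to-one normalization).  A subpopulation counts as "killed" by a
perturbation when its proportion drops by more than 90% relative to the
controls, confirmed by a ≥75% reduction in every same-compound experiment
at a strictly higher concentration.  A greedy search then assembles
minimal drug combinations: at each step pick the perturbation killing the
most not-yet-killed subpopulations, break ties by total reduction summed
over all subpopulations, and branch when perturbations tie on both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "PerturbationScreen",
    "KillTable",
    "CombinationPlan",
    "DEFAULT_REFERENCE_LINES",
    "assign_reference_line",
    "build_signature_matrix",
    "deconvolve",
    "call_killed",
    "greedy_combination",
]

DEFAULT_REFERENCE_LINES = (
    "A375", "A549", "HCC515", "HEPG2", "HT29", "MCF7", "PC3", "YAPC",
)


@dataclass
class PerturbationScreen:
    """Perturbation experiments on one reference line.

    ``meta``: one row per experiment — experiment_id, compound,
    concentration, unit, is_control.  ``gep``: genes × experiments bulk
    profiles on anti-log (linear) scale.
    """

    meta: pd.DataFrame
    gep: pd.DataFrame
    reference_line: str | None = None

    def __post_init__(self):
        required = {"experiment_id", "compound", "concentration", "unit", "is_control"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"screen metadata missing columns: {sorted(missing)}")
        self.meta = self.meta.set_index("experiment_id", drop=False) \
            if self.meta.index.name != "experiment_id" else self.meta
        if not self.meta["is_control"].any():
            raise ValueError("screen has no control experiment")
        treated = self.meta[~self.meta["is_control"].astype(bool)]
        if (treated["concentration"] <= 0).any():
            raise ValueError("treated concentrations must be positive")
        unknown = set(self.meta["experiment_id"]) - set(self.gep.columns)
        if unknown:
            raise ValueError(f"experiments without expression profile: {sorted(unknown)[:5]}")

    @property
    def controls(self) -> pd.Index:
        return self.meta.index[self.meta["is_control"].astype(bool)]

    @property
    def treated(self) -> pd.Index:
        return self.meta.index[~self.meta["is_control"].astype(bool)]


def assign_reference_line(
    query_gep: pd.Series,
    reference_geps: pd.DataFrame,
) -> tuple[str, float]:
    """Best-correlated reference line for a pooled single-cell profile.

    Pearson correlation on shared genes against each panel column
    (genes × lines); ties go to the first line in column order.
    """
    shared = query_gep.index.intersection(reference_geps.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between query and reference panel")
    q = query_gep[shared].to_numpy(dtype=float)
    best_name, best_r = None, -np.inf
    for name in reference_geps.columns:
        r = np.corrcoef(q, reference_geps.loc[shared, name].to_numpy(dtype=float))[0, 1]
        if np.isfinite(r) and r > best_r:
            best_name, best_r = name, r
    if best_name is None:
        raise ValueError("no reference line yields a finite correlation")
    return best_name, float(best_r)


def build_signature_matrix(
    gep: pd.DataFrame,
    screen_genes=None,
) -> pd.DataFrame:
    """Signature matrix (genes × subpopulations) from cluster GEPs.

    Cluster mean log-normalized expression is moved to the anti-log scale
    (expm1, non-negative) to match bulk screen profiles, optionally
    restricted to the screen's gene space.
    """
    sig = np.expm1(gep.T.astype(float))  # genes × clusters
    if screen_genes is not None:
        shared = sig.index.intersection(pd.Index(screen_genes))
        if len(shared) == 0:
            raise ValueError("no shared genes between signature and screen")
        sig = sig.loc[shared]
    sig.columns = gep.index.astype(str)
    return sig


def deconvolve(
    screen: PerturbationScreen | pd.DataFrame,
    signature: pd.DataFrame,
) -> pd.DataFrame:
    """Estimate subpopulation proportions in each bulk profile.

    Non-negative least squares per experiment against the signature
    columns, normalized to sum to one.  Requires at least as many shared
    genes as subpopulations; a rank-deficient signature yields a warning
    (the solution may not be unique).
    """
    gep = screen.gep if isinstance(screen, PerturbationScreen) else screen
    shared = signature.index.intersection(gep.index)
    k = signature.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared genes for {k} subpopulations"
        )
    A = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < k:
        warnings.warn("signature matrix is rank-deficient; proportions may be non-unique")
    out = {}
    for exp_id in gep.columns:
        w, _ = nnls(A, gep.loc[shared, exp_id].to_numpy(dtype=float))
        total = w.sum()
        out[exp_id] = w / total if total > 0 else np.full(k, 1.0 / k)
    return pd.DataFrame(out, index=signature.columns).T


@dataclass
class KillTable:
    """Per-perturbation subpopulation reductions and killed calls.

    ``reductions``: treated experiments × subpopulations, 1 − treated
    proportion / control proportion.  ``killed`` maps experiment_id to the
    frozenset of confirmed-killed subpopulations.
    """

    reductions: pd.DataFrame
    killed: dict[str, frozenset] = field(default_factory=dict)
    meta: pd.DataFrame | None = None

    @property
    def efficacy(self) -> pd.Series:
        """Sum of reductions across all subpopulations per perturbation."""
        return self.reductions.sum(axis=1)


def call_killed(
    proportions: pd.DataFrame,
    screen: PerturbationScreen,
    kill_threshold: float = 0.90,
    consistency_threshold: float = 0.75,
) -> KillTable:
    """Call killed subpopulations with dose-consistency confirmation.

    Control proportions are the mean over all control experiments;
    subpopulations absent from controls are excluded with a warning.  A
    subpopulation is a kill candidate when its reduction exceeds
    ``kill_threshold``, and confirmed only if every experiment with the
    same compound and unit at a strictly higher concentration shows a
    reduction of at least ``consistency_threshold`` (vacuously confirmed
    when no higher dose exists).
    """
    ctrl = proportions.loc[screen.controls].mean(axis=0)
    usable = ctrl > 0
    if not usable.all():
        warnings.warn(
            f"subpopulations with zero control proportion excluded: "
            f"{list(ctrl.index[~usable])}"
        )
    subs = ctrl.index[usable]
    treated = screen.treated
    red = 1.0 - proportions.loc[treated, subs].div(ctrl[subs], axis=1)
    meta = screen.meta.loc[treated]
    killed: dict[str, frozenset] = {}
    warned_units = set()
    for exp_id in treated:
        row = meta.loc[exp_id]
        cands = [s for s in subs if red.loc[exp_id, s] > kill_threshold]
        if not cands:
            killed[exp_id] = frozenset()
            continue
        same = meta[(meta["compound"] == row["compound"]) & (meta.index != exp_id)]
        unit_mismatch = same[same["unit"] != row["unit"]]
        if len(unit_mismatch) and row["compound"] not in warned_units:
            warnings.warn(
                f"compound {row['compound']}: concentration units differ across "
                "experiments; consistency check restricted to matching units"
            )
            warned_units.add(row["compound"])
        higher = same[
            (same["unit"] == row["unit"])
            & (same["concentration"] > row["concentration"])
        ].index
        confirmed = []
        for s in cands:
            if all(red.loc[h, s] >= consistency_threshold for h in higher):
                confirmed.append(s)
        killed[exp_id] = frozenset(confirmed)
    return KillTable(reductions=red, killed=killed, meta=meta)


@dataclass
class CombinationPlan:
    """One greedy combination: ordered perturbations with their new kills."""

    steps: list[dict] = field(default_factory=list)

    @property
    def cumulative_killed(self) -> frozenset:
        out: set = set()
        for s in self.steps:
            out |= s["newly_killed"]
        return frozenset(out)

    @property
    def total_efficacy(self) -> float:
        return float(sum(s["efficacy"] for s in self.steps))

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "experiment_id": s["experiment_id"],
                    "compound": s["compound"],
                    "concentration": s["concentration"],
                    "newly_killed": sorted(s["newly_killed"]),
                    "efficacy": s["efficacy"],
                }
                for s in self.steps
            ],
            "cumulative_killed": sorted(self.cumulative_killed),
            "total_efficacy": self.total_efficacy,
        }


def greedy_combination(
    kill_table: KillTable,
    max_plans: int = 64,
) -> list[CombinationPlan]:
    """Greedy maximum-coverage search for minimal drug combinations.

    Repeatedly selects the perturbation killing the most not-yet-killed
    subpopulations; ties are broken by the greater total reduction summed
    over all subpopulations, and perturbations tied on both branch into
    separate plans.  Stops when no perturbation adds a kill.  Returns an
    empty list (with a notice) when nothing is killed at all.
    """
    eff = kill_table.efficacy
    perts = sorted(
        kill_table.killed,
        key=lambda e: (
            (kill_table.meta.loc[e, "compound"], kill_table.meta.loc[e, "concentration"])
            if kill_table.meta is not None else (str(e),)
        ),
    )
    if all(len(kill_table.killed[e]) == 0 for e in perts):
        warnings.warn("no perturbation kills any subpopulation; empty plan")
        return []

    plans: list[CombinationPlan] = []

    def expand(remaining_killable: frozenset, steps: list[dict], used: set):
        if len(plans) >= max_plans:
            return
        newly = {
            e: kill_table.killed[e] & remaining_killable
            for e in perts if e not in used
        }
        best_n = max((len(v) for v in newly.values()), default=0)
        if best_n == 0:
            plans.append(CombinationPlan(steps=list(steps)))
            return
        cands = [e for e, v in newly.items() if len(v) == best_n]
        best_eff = max(eff[e] for e in cands)
        winners = [e for e in cands if eff[e] == best_eff]
        for e in winners:
            meta_row = (
                kill_table.meta.loc[e]
                if kill_table.meta is not None
                else {"compound": e, "concentration": np.nan}
            )
            step = {
                "experiment_id": e,
                "compound": meta_row["compound"],
                "concentration": meta_row["concentration"],
                "newly_killed": frozenset(newly[e]),
                "efficacy": float(eff[e]),
            }
            expand(remaining_killable - newly[e], steps + [step], used | {e})

    all_killable = frozenset().union(*kill_table.killed.values())
    expand(frozenset(all_killable), [], set())
    return plans
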