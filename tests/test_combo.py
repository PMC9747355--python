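"""Deconvolution, kill calling with dose consistency, greedy combinations."""

import itertools

import numpy as np
import pandas as pd
import pytest

import scdrx
from scdrx.combo import (
    KillTable,
    PerturbationScreen,
    assign_reference_line,
    build_signature_matrix,
    call_killed,
    deconvolve,
    greedy_combination,
)
from scdrx.simulate import simulate_perturbation_screen


def make_screen(gep_cols, meta_rows, genes):
    meta = pd.DataFrame(
        meta_rows,
        columns=["experiment_id", "compound", "concentration", "unit", "is_control"],
    )
    gep = pd.DataFrame(gep_cols, index=genes)
    return PerturbationScreen(meta=meta, gep=gep)


class TestAssignReferenceLine:
    def _panel(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(0, 10, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=["A375", "HEPG2", "MCF7", "PC3"],
        )

    def test_exact_profile_matches_itself(self):
        ref = self._panel()
        name, r = assign_reference_line(ref["MCF7"], ref)
        assert name == "MCF7"
        assert r == pytest.approx(1.0)

    def test_tie_broken_by_column_order(self):
        ref = self._panel()
        ref["HEPG2"] = ref["A375"]  # exact duplicate
        name, _ = assign_reference_line(ref["A375"], ref)
        assert name == "A375"

    def test_noisy_profiles_assigned_correctly(self):
        rng = np.random.default_rng(1)
        ref = self._panel(seed=1)
        for line in ref.columns:
            noisy = ref[line] + rng.normal(0, 0.5, len(ref))
            name, _ = assign_reference_line(noisy, ref)
            assert name == line

    def test_no_shared_genes_raises(self):
        ref = self._panel()
        query = pd.Series([1.0], index=["zz"])
        with pytest.raises(ValueError, match="no shared genes"):
            assign_reference_line(query, ref)


class TestDeconvolve:
    def test_exact_mixture_recovered(self, toy_signature):
        sig = toy_signature
        weights = np.array([0.2, 0.3, 0.5, 0.0])
        bulk = sig.to_numpy() @ weights
        screen_gep = pd.DataFrame({"e0": bulk}, index=sig.index)
        props = deconvolve(screen_gep, sig)
        np.testing.assert_allclose(props.loc["e0"], weights, atol=1e-6)

    def test_pure_signature_gives_unit_proportion(self, toy_signature):
        sig = toy_signature
        screen_gep = pd.DataFrame({"e0": sig["B"]}, index=sig.index)
        props = deconvolve(screen_gep, sig)
        assert props.loc["e0", "B"] == pytest.approx(1.0, abs=1e-9)

    def test_proportions_nonnegative_and_normalized(self, toy_signature):
        rng = np.random.default_rng(0)
        sig = toy_signature
        bulk = {}
        for i in range(6):
            w = rng.dirichlet(np.ones(4))
            bulk[f"e{i}"] = sig.to_numpy() @ w + rng.normal(0, 0.1, len(sig))
        props = deconvolve(pd.DataFrame(bulk, index=sig.index), sig)
        assert (props.to_numpy() >= 0).all()
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_noisy_mixture_error_small(self, toy_signature):
        """At 5% noise the mean absolute proportion error stays below 0.05."""
        sig = toy_signature
        base = [0.25, 0.25, 0.25, 0.25]
        kills = {"d1": (["A"], [0.95, 0.96])}
        screen, truth = simulate_perturbation_screen(
            sig, base, kills, noise_sd=0.05, seed=0
        )
        props = deconvolve(screen, sig)
        want = np.array([truth.truth["proportions"][e] for e in props.index])
        err = np.abs(props.to_numpy() - want).mean()
        assert err < 0.05

    def test_too_few_shared_genes_raises(self, toy_signature):
        sig = toy_signature
        gep = pd.DataFrame({"e0": [1.0, 2.0]}, index=sig.index[:2])
        with pytest.raises(ValueError, match="shared genes"):
            deconvolve(gep, sig)

    def test_rank_deficient_signature_warns(self):
        sig = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]},
            index=["g0", "g1", "g2"],
        )
        gep = pd.DataFrame({"e0": [1.0, 2.0, 3.0]}, index=sig.index)
        with pytest.warns(UserWarning, match="rank-deficient"):
            deconvolve(gep, sig)


def props_screen(prop_rows, meta_rows, subs=("A", "B", "C")):
    """Build (proportions, screen) directly for kill-rule tests."""
    genes = [f"g{i}" for i in range(len(subs))]
    meta = pd.DataFrame(
        meta_rows,
        columns=["experiment_id", "compound", "concentration", "unit", "is_control"],
    )
    gep = pd.DataFrame(
        {r[0]: np.ones(len(genes)) for r in meta_rows}, index=genes
    )
    screen = PerturbationScreen(meta=meta, gep=gep)
    props = pd.DataFrame(prop_rows, index=[r[0] for r in meta_rows],
                         columns=list(subs))
    return props, screen


class TestCallKilled:
    def test_single_dose_kill_called(self):
        props, screen = props_screen(
            [[0.20, 0.40, 0.40], [0.01, 0.55, 0.44]],
            [("c0", "DMSO", 0.0, "uM", True), ("e1", "drugX", 1.0, "uM", False)],
        )
        kt = call_killed(props, screen)
        assert kt.killed["e1"] == frozenset({"A"})
        assert kt.reductions.loc["e1", "A"] == pytest.approx(1 - 0.01 / 0.20)

    def test_inconsistent_higher_dose_vetoes_kill(self):
        """A 95% reduction is rejected when the higher dose shows only 60%."""
        props, screen = props_screen(
            [[0.20, 0.40, 0.40], [0.01, 0.55, 0.44], [0.08, 0.48, 0.44]],
            [("c0", "DMSO", 0.0, "uM", True),
             ("lo", "drugX", 1.0, "uM", False),
             ("hi", "drugX", 10.0, "uM", False)],
        )
        kt = call_killed(props, screen)
        assert kt.reductions.loc["lo", "A"] > 0.9
        assert kt.reductions.loc["hi", "A"] < 0.75
        assert kt.killed["lo"] == frozenset()

    def test_consistent_higher_dose_confirms_kill(self):
        props, screen = props_screen(
            [[0.20, 0.40, 0.40], [0.01, 0.55, 0.44], [0.04, 0.52, 0.44]],
            [("c0", "DMSO", 0.0, "uM", True),
             ("lo", "drugX", 1.0, "uM", False),
             ("hi", "drugX", 10.0, "uM", False)],
        )
        kt = call_killed(props, screen)
        assert kt.killed["lo"] == frozenset({"A"})

    def test_matches_bruteforce_rule_application(self):
        rng = np.random.default_rng(0)
        subs = list("ABCD")
        meta_rows = [("c0", "DMSO", 0.0, "uM", True)]
        compounds = ["d1", "d2", "d3"]
        for c in compounds:
            for dose in (1.0, 10.0):
                meta_rows.append((f"{c}@{dose}", c, dose, "uM", False))
        rows = [rng.dirichlet(np.ones(4))]
        for _ in range(len(meta_rows) - 1):
            rows.append(rng.dirichlet(np.ones(4)))
        props, screen = props_screen(rows, meta_rows, subs=subs)
        kt = call_killed(props, screen, kill_threshold=0.5,
                         consistency_threshold=0.3)
        ctrl = props.iloc[0]
        for eid, compound, dose, unit, is_ctrl in meta_rows[1:]:
            red = 1 - props.loc[eid] / ctrl
            expected = set()
            for s in subs:
                if red[s] <= 0.5:
                    continue
                ok = True
                for eid2, c2, dose2, *_ in meta_rows[1:]:
                    if c2 == compound and dose2 > dose:
                        r2 = 1 - props.loc[eid2, s] / ctrl[s]
                        if r2 < 0.3:
                            ok = False
                if ok:
                    expected.add(s)
            assert kt.killed[eid] == frozenset(expected), eid

    def test_zero_control_subset_excluded(self):
        props, screen = props_screen(
            [[0.0, 0.6, 0.4], [0.0, 0.05, 0.95]],
            [("c0", "DMSO", 0.0, "uM", True), ("e1", "drugX", 1.0, "uM", False)],
        )
        with pytest.warns(UserWarning, match="zero control"):
            kt = call_killed(props, screen)
        assert "A" not in kt.reductions.columns


def kill_table_from_sets(kills: dict, efficacies: dict) -> KillTable:
    subs = sorted({s for v in kills.values() for s in v} | {"zz"})
    red = pd.DataFrame(0.0, index=list(kills), columns=subs)
    for e, eff in efficacies.items():
        red.loc[e, "zz"] = eff  # park the efficacy in a spare column
        for s in kills[e]:
            red.loc[e, s] = 0.95
            red.loc[e, "zz"] -= 0.95
    meta = pd.DataFrame(
        {"experiment_id": list(kills), "compound": list(kills),
         "concentration": 1.0, "unit": "uM", "is_control": False}
    ).set_index("experiment_id", drop=False)
    return KillTable(
        reductions=red,
        killed={e: frozenset(v) for e, v in kills.items()},
        meta=meta,
    )


def exhaustive_best_coverage(kills: dict) -> int:
    """Maximum number of subpopulations killable by any perturbation subset."""
    best = 0
    perts = list(kills)
    for r in range(len(perts) + 1):
        for combo in itertools.combinations(perts, r):
            cov = set().union(*(kills[p] for p in combo)) if combo else set()
            best = max(best, len(cov))
    return best


class TestGreedyCombination:
    def test_single_killer_single_step(self):
        kt = kill_table_from_sets({"p": {"A", "B"}}, {"p": 1.9})
        plans = greedy_combination(kt)
        assert len(plans) == 1
        assert len(plans[0].steps) == 1
        assert plans[0].cumulative_killed == frozenset({"A", "B"})

    def test_three_set_example_matches_exhaustive_oracle(self):
        """Greedy plan equals the brute-force optimum on the A/B/C toy."""
        kills = {"A": {"1", "2"}, "B": {"3"}, "C": {"2", "3"}}
        effs = {"A": 1.9, "B": 0.95, "C": 1.9}
        kt = kill_table_from_sets(kills, effs)
        plans = greedy_combination(kt)
        # step 1 must kill max over singles; final coverage = exhaustive max
        best_single = max(len(v) for v in kills.values())
        for plan in plans:
            assert len(plan.steps[0]["newly_killed"]) == best_single
            assert len(plan.cumulative_killed) == exhaustive_best_coverage(kills)
        # C beats B on efficacy for the second step
        assert plans[0].steps[0]["experiment_id"] == "A"
        assert plans[0].steps[1]["experiment_id"] == "C"

    def test_ties_branch_into_separate_plans(self):
        kills = {"p1": {"A"}, "p2": {"A"}, "p3": {"B"}}
        effs = {"p1": 0.95, "p2": 0.95, "p3": 0.5}
        plans = greedy_combination(kill_table_from_sets(kills, effs))
        firsts = {p.steps[0]["experiment_id"] for p in plans}
        assert firsts == {"p1", "p2"}
        assert len(plans) == 2
        for p in plans:
            assert p.cumulative_killed == frozenset({"A", "B"})

    def test_steps_add_disjoint_new_kills(self):
        rng = np.random.default_rng(0)
        subs = [f"s{i}" for i in range(6)]
        kills, effs = {}, {}
        for i in range(5):
            k = set(rng.choice(subs, size=rng.integers(1, 4), replace=False))
            kills[f"p{i}"] = k
            effs[f"p{i}"] = float(rng.uniform(0, 3))
        plans = greedy_combination(kill_table_from_sets(kills, effs))
        for plan in plans:
            seen = set()
            for step in plan.steps:
                assert not (step["newly_killed"] & seen)
                assert step["newly_killed"]
                seen |= step["newly_killed"]
            assert plan.cumulative_killed == frozenset(seen)

    def test_disjoint_kill_sets_reach_exhaustive_optimum(self):
        kills = {f"p{i}": {f"s{i}a", f"s{i}b"} for i in range(4)}
        effs = {p: 1.9 for p in kills}
        plans = greedy_combination(kill_table_from_sets(kills, effs))
        assert len(plans[0].cumulative_killed) == exhaustive_best_coverage(kills)
        assert len(plans[0].steps) == 4

    def test_nothing_killed_returns_empty_with_notice(self):
        kt = kill_table_from_sets({"p": set()}, {"p": 0.0})
        with pytest.warns(UserWarning, match="no perturbation kills"):
            plans = greedy_combination(kt)
        assert plans == []


class TestRoundTrip:
    def test_planted_kills_recovered_noiselessly(self, toy_signature):
        """Generator → deconvolution → kill calling reproduces the truth."""
        sig = toy_signature
        base = [0.3, 0.3, 0.2, 0.2]
        # planted reductions act on abundances; after renormalization the
        # measured proportion reductions must still clear the 90% threshold
        kills = {
            "d1": (["A", "B"], [0.97, 0.98]),
            "d2": (["C"], [0.95, 0.96]),
            "d3": (["D"], [0.93, 0.95]),
        }
        screen, _ = simulate_perturbation_screen(sig, base, kills, seed=0)
        props = deconvolve(screen, sig)
        kt = call_killed(props, screen)
        for compound, (targets, _) in kills.items():
            for eid in kt.killed:
                if eid.startswith(compound):
                    assert kt.killed[eid] == frozenset(targets), eid

    def test_disjoint_compound_kills_covered_in_three_steps(self, toy_signature):
        sig = toy_signature
        base = [0.25, 0.25, 0.25, 0.25]
        kills = {
            "d1": (["A"], [0.95, 0.96]),
            "d2": (["B"], [0.95, 0.96]),
            "d3": (["C", "D"], [0.95, 0.96]),
        }
        screen, _ = simulate_perturbation_screen(sig, base, kills, seed=1)
        props = deconvolve(screen, sig)
        plans = greedy_combination(call_killed(props, screen))
        assert plans
        assert plans[0].cumulative_killed == frozenset("ABCD")
        assert len(plans[0].steps) == 3

    def test_empty_kill_patterns_yield_empty_table(self, toy_signature):
        sig = toy_signature
        screen, _ = simulate_perturbation_screen(
            sig, [0.25, 0.25, 0.25, 0.25], {}, seed=2
        )
        props = deconvolve(screen, sig)
        kt = call_killed(props, screen)
        assert all(len(v) == 0 for v in kt.killed.values())


class TestSignatureMatrix:
    def test_antilog_and_gene_restriction(self, processed):
        res, _ = processed
        gep = scdrx.annotate.cluster_gep(res)
        screen_genes = gep.columns[:50]
        sig = build_signature_matrix(gep, screen_genes)
        assert sig.shape == (50, gep.shape[0])
        assert (sig.to_numpy() >= 0).all()
        np.testing.assert_allclose(
            sig.iloc[:, 0].to_numpy(),
            np.expm1(gep.iloc[0, :50].to_numpy()), atol=1e-12,
        )
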