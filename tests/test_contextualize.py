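"""Normalization, threshold selection, GPR scoring, extraction, gap-fill."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neurogem import (
    MetabolicModel,
    Metabolite,
    ProtectedSet,
    Reaction,
    aggregate_by_group,
    extract_submodel,
    fba,
    gapfill_protected,
    quantile_normalize,
    score_reactions,
    select_threshold,
    simulate_expression,
)
from neurogem.contextualize import UnimodalError
from neurogem.synthetic_data import mixture_density_minimum


class TestQuantileNormalize:
    def test_permuted_columns_map_to_same_values(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        df = pd.DataFrame({"s1": col, "s2": rng.permutation(col)})
        out = quantile_normalize(df)
        assert sorted(out["s1"]) == pytest.approx(sorted(out["s2"]))
        # ranks preserved within each column
        assert (out["s1"].rank() == df["s1"].rank()).all()

    def test_single_gene_maps_to_row_mean(self):
        df = pd.DataFrame([[3.0, 5.0, 10.0]], index=["g"], columns=list("abc"))
        out = quantile_normalize(df)
        assert (out.loc["g"] == 6.0).all()

    def test_matches_brute_force_order_statistics_oracle(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(5, 4)),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(4)])
        # oracle: explicit sort/average, then place by rank
        arr = df.to_numpy()
        ref = np.sort(arr, axis=0).mean(axis=1)
        expected = np.empty_like(arr)
        for j in range(4):
            order = np.argsort(arr[:, j])
            for rank, i in enumerate(order):
                expected[i, j] = ref[rank]
        out = quantile_normalize(df)
        assert out.to_numpy() == pytest.approx(expected)

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(df)


class TestAggregateByGroup:
    def _profile(self, ages):
        n = len(ages) // 2
        prof, _ = simulate_expression(10, n, seed=0)
        prof.age[:] = ages
        return prof

    def test_sample_outside_age_window_excluded(self):
        prof, _ = simulate_expression(10, 2, seed=0)
        prof.age[:] = [2.0, 7.0, 14.0, 56.0]
        med = aggregate_by_group(prof, (2, 14))
        # control group: only the 14-year-old remains
        ctl_cols = [s for s in prof.values.columns
                    if prof.group[s] == "control" and prof.age[s] <= 14]
        assert len(ctl_cols) == 1
        assert med["control"].equals(prof.values[ctl_cols[0]])

    def test_median_matches_sort_oracle(self):
        prof, _ = simulate_expression(15, 5, seed=2)
        prof.age[:] = 10.0
        med = aggregate_by_group(prof, (2, 14))
        for group in ("ASD", "control"):
            cols = prof.group[prof.group == group].index
            for g in prof.values.index:
                vals = sorted(prof.values.loc[g, cols])
                n = len(vals)
                oracle = (vals[n // 2] if n % 2 else
                          0.5 * (vals[n // 2 - 1] + vals[n // 2]))
                assert med[group][g] == pytest.approx(oracle)

    def test_empty_group_after_filter_names_group(self):
        prof, _ = simulate_expression(10, 3, seed=0)
        prof.age[prof.group == "ASD"] = 40.0
        with pytest.raises(ValueError, match="ASD"):
            aggregate_by_group(prof, (2, 14))


class TestSelectThreshold:
    def test_recovers_analytic_minimum(self):
        mix = {"low_mean": 6.0, "high_mean": 11.0, "low_sd": 0.8,
               "high_sd": 0.8, "weight": 0.5}
        truth = mixture_density_minimum(mix)
        rng = np.random.default_rng(123)
        comp = rng.random(10_000) < 0.5
        x = np.where(comp, rng.normal(6.0, 0.8, 10_000),
                     rng.normal(11.0, 0.8, 10_000))
        assert abs(select_threshold(x) - truth) < 0.15

    def test_symmetric_mixture_selects_midpoint(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(8, 1, 5000)])
        assert select_threshold(x) == pytest.approx(4.0, abs=0.3)

    def test_single_gaussian_raises_unimodal(self):
        rng = np.random.default_rng(1)
        with pytest.raises(UnimodalError):
            select_threshold(rng.normal(5, 1, 5000))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="100"):
            select_threshold(np.arange(50))


class TestScoreReactions:
    def test_and_or_examples(self, brain_model):
        expr = {"G_HK1": 8, "G_PFKM": 10, "G_PKM": 12,
                "G_LDHA": 8, "G_LDHB": 12}
        ss = score_reactions(brain_model, expr)
        assert ss.scores["GLYC"] == 8  # AND -> min
        assert ss.scores["LDH"] == 12  # OR -> max

    def test_no_evidence_reactions_are_sentinel_not_scored(self, brain_model):
        ss = score_reactions(brain_model, {})
        assert "ATPM" in ss.no_evidence
        assert "EX_glc" in ss.no_evidence
        assert ss.scores == {}

    def test_matches_brute_force_tree_evaluation(self):
        """Randomized rules over 3 genes agree with exhaustive evaluation."""
        rules = ["(a AND b) OR c", "a OR (b AND c)", "a AND b AND c",
                 "(a OR b) AND (b OR c)"]
        oracles = [
            lambda v: max(min(v["a"], v["b"]), v["c"]),
            lambda v: max(v["a"], min(v["b"], v["c"])),
            lambda v: min(v["a"], v["b"], v["c"]),
            lambda v: min(max(v["a"], v["b"]), max(v["b"], v["c"])),
        ]
        mets = [Metabolite(id="X_c", compartment="c")]
        for rule, oracle in zip(rules, oracles):
            model = MetabolicModel(
                metabolites=mets,
                reactions=[Reaction(id="R", stoich={"X_c": 1}, lb=0, ub=1,
                                    gene_rule=rule)])
            for vals in itertools.product([2.0, 5.0, 9.0], repeat=3):
                v = dict(zip("abc", vals))
                assert score_reactions(model, v).scores["R"] == oracle(v)


def _chain_model(extra_path=False):
    """EX_A -> T_A -> R1(A->B) -> DM_B, optional redundant 2-step path."""
    mets = [Metabolite(id="A_e", compartment="e"),
            Metabolite(id="A_c", compartment="c"),
            Metabolite(id="B_c", compartment="c")]
    rxns = [
        Reaction(id="EX_A", stoich={"A_e": -1}, lb=-10, ub=0),
        Reaction(id="T_A", stoich={"A_e": -1, "A_c": 1}, lb=0, ub=10,
                 gene_rule="gT"),
        Reaction(id="R1", stoich={"A_c": -1, "B_c": 1}, lb=0, ub=10,
                 gene_rule="g1"),
        Reaction(id="DM_B", stoich={"B_c": -1}, lb=0, ub=10),
    ]
    if extra_path:
        mets.append(Metabolite(id="C_c", compartment="c"))
        rxns += [
            Reaction(id="R2a", stoich={"A_c": -1, "C_c": 1}, lb=0, ub=10,
                     gene_rule="g2a"),
            Reaction(id="R2b", stoich={"C_c": -1, "B_c": 1}, lb=0, ub=10,
                     gene_rule="g2b"),
        ]
    return MetabolicModel(metabolites=mets, reactions=rxns, id="chain")


def _enumerate_best(model, scores, protected, objective, delta=1e-3):
    """Exhaustive 2^k oracle: best-scoring feasible reaction subset."""
    from neurogem.model_core import stoichiometric_matrix
    from scipy.optimize import linprog

    rxns = model.reactions
    forced = set(protected.reaction_ids) | set(objective)
    optional = [r.id for r in rxns if r.id not in forced]
    S = stoichiometric_matrix(model).to_numpy()
    theta = scores.threshold

    def weight(rid):
        if rid in scores.no_evidence or rid not in scores.scores:
            return -0.1
        return scores.scores[rid] - theta

    best_score, best_sets = -np.inf, []
    for k in range(len(optional) + 1):
        for combo in itertools.combinations(optional, k):
            keep = forced | set(combo)
            bounds = []
            for r in rxns:
                if r.id in keep:
                    lb = max(r.lb, delta) if r.id in objective else r.lb
                    bounds.append((lb, r.ub))
                else:
                    bounds.append((0.0, 0.0))
            res = linprog(np.zeros(len(rxns)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=bounds, method="highs")
            if res.status != 0:
                continue
            total = sum(weight(rid) for rid in keep)
            if total > best_score + 1e-12:
                best_score, best_sets = total, [keep]
            elif abs(total - best_score) <= 1e-12:
                best_sets.append(keep)
    return best_score, best_sets


class TestExtractSubmodel:
    def test_chain_with_high_scores_fully_retained(self):
        model = _chain_model()
        scores = score_reactions(model, {"gT": 10, "g1": 10}, threshold=5)
        out = extract_submodel(model, scores, ProtectedSet({"EX_A"}),
                               objective=["DM_B"], gapfill=False)
        assert set(out.reactions_by_id) == {"EX_A", "T_A", "R1", "DM_B"}

    def test_redundant_low_score_path_dropped(self):
        model = _chain_model(extra_path=True)
        expr = {"gT": 10, "g1": 10, "g2a": 2, "g2b": 2}
        scores = score_reactions(model, expr, threshold=5)
        protected = ProtectedSet({"EX_A"})
        out = extract_submodel(model, scores, protected, objective=["DM_B"],
                               gapfill=False)
        assert "R2a" not in out.reactions_by_id
        assert "R2b" not in out.reactions_by_id
        assert {"T_A", "R1"} <= set(out.reactions_by_id)
        best_score, best_sets = _enumerate_best(model, scores, protected, ["DM_B"])
        assert set(out.reactions_by_id) in best_sets

    def test_matches_exhaustive_enumeration_on_small_models(self):
        """MILP selection equals the best feasible subset by 2^k search."""
        model = _chain_model(extra_path=True)
        for theta in (1.0, 5.0, 9.0, 11.0):
            expr = {"gT": 10, "g1": 4, "g2a": 8, "g2b": 8}
            scores = score_reactions(model, expr, threshold=theta)
            protected = ProtectedSet({"EX_A"})
            out = extract_submodel(model, scores, protected, objective=["DM_B"],
                                   gapfill=False)
            best_score, best_sets = _enumerate_best(
                model, scores, protected, ["DM_B"])
            got = sum(
                (scores.scores[rid] - theta if rid in scores.scores else -0.1)
                for rid in out.reactions_by_id)
            assert got == pytest.approx(best_score, abs=1e-9)
            assert set(out.reactions_by_id) in best_sets

    def test_protected_reaction_below_threshold_retained(self):
        model = _chain_model(extra_path=True)
        expr = {"gT": 10, "g1": 10, "g2a": 1, "g2b": 1}
        scores = score_reactions(model, expr, threshold=5)
        out = extract_submodel(model, scores, ProtectedSet({"EX_A", "R2a"}),
                               objective=["DM_B"], gapfill=False)
        assert "R2a" in out.reactions_by_id

    def test_raising_threshold_never_adds_reactions(self, brain_model):
        prof, _ = simulate_expression(
            len(brain_model.genes), 4, seed=6,
            gene_ids=sorted(brain_model.genes))
        med = aggregate_by_group(prof)["control"]
        protected = ProtectedSet(
            {"GLS", "GLNS", "GAD", "ATPM"}
            | {r.id for r in brain_model.exchange_reactions()})
        kept_prev = None
        for theta in (7.0, 8.5, 10.0):
            scores = score_reactions(brain_model, med, threshold=theta)
            out = extract_submodel(brain_model, scores, protected,
                                   objective=["GLS", "GLNS", "GAD"],
                                   gapfill=False)
            kept = set(out.reactions_by_id)
            if kept_prev is not None:
                assert kept <= kept_prev
            kept_prev = kept

    def test_extracted_model_feasible_for_objective(self, brain_model):
        prof, _ = simulate_expression(
            len(brain_model.genes), 4, seed=8,
            gene_ids=sorted(brain_model.genes))
        med = aggregate_by_group(prof)["ASD"]
        protected = ProtectedSet(
            {"GLS", "GLNS", "GAD", "ATPM"}
            | {r.id for r in brain_model.exchange_reactions()})
        scores = score_reactions(brain_model, med, threshold=8.5)
        out = extract_submodel(brain_model, scores, protected,
                               objective=["GLS", "GLNS", "GAD"])
        sol = fba(out, {"GLS": 1.0, "GLNS": 1.0, "GAD": 1.0}, "max")
        assert sol.status == "optimal"
        assert sol.objective_value >= 1e-3 - 1e-9


class TestGapfill:
    def test_missing_protected_reaction_restored(self, brain_model):
        pruned = brain_model.subset(
            [r.id for r in brain_model.reactions if r.id != "GLNS"])
        protected = ProtectedSet({"GLS", "GLNS", "GAD"})
        filled = gapfill_protected(pruned, brain_model, protected)
        assert "GLNS" in filled.reactions_by_id

    def test_complete_model_unchanged_and_idempotent(self, brain_model):
        protected = ProtectedSet({"GLS", "GLNS", "GAD"})
        once = gapfill_protected(brain_model, brain_model, protected)
        assert set(once.reactions_by_id) == set(brain_model.reactions_by_id)
        pruned = brain_model.subset(
            [r.id for r in brain_model.reactions if r.id not in ("GLNS", "GLNt")])
        f1 = gapfill_protected(pruned, brain_model, protected)
        f2 = gapfill_protected(f1, brain_model, protected)
        assert set(f1.reactions_by_id) == set(f2.reactions_by_id)

    def test_boundary_support_of_protected_metabolites_restored(self, brain_model):
        keep = [r.id for r in brain_model.reactions
                if r.id not in ("GLNt", "EX_gln")]
        pruned = brain_model.subset(keep)
        filled = gapfill_protected(pruned, brain_model,
                                   ProtectedSet({"GLS", "GLNS", "GAD"}))
        assert "GLNt" in filled.reactions_by_id  # transport for gln_c
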