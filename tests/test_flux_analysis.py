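"""FBA, loopless correction, FVA, and physiological constraint application."""

import numpy as np
import pytest

from neurogem import (
    MetabolicModel,
    Metabolite,
    PhysiologicalConstraints,
    Reaction,
    apply_physiological_constraints,
    csf_to_flux,
    fba,
    fva,
    loopless_correct,
    write_model,
)
from neurogem.model_core import stoichiometric_matrix


class TestCsfToFlux:
    def test_arithmetic_example(self):
        assert csf_to_flux(100.0, 0.00035, 100.0) == pytest.approx(3.5e-4)

    def test_zero_concentration_gives_zero_bound(self):
        assert csf_to_flux(0.0, 0.01, 50.0) == 0.0

    def test_linearity_in_flow(self):
        assert csf_to_flux(20.0, 0.002, 10.0) == pytest.approx(
            2 * csf_to_flux(20.0, 0.001, 10.0))

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            csf_to_flux(1.0, 1.0, 0.0)


def _pc(**over):
    kwargs = dict(cmr_glu=0.3, o2_glu_ratio=5.6, o2_min=0.1,
                  atp_maintenance=(10.0, 40.0))
    kwargs.update(over)
    return PhysiologicalConstraints(**kwargs)


class TestApplyConstraints:
    def test_exchange_bounds_follow_ratio_rule(self, respiration_model):
        out = apply_physiological_constraints(respiration_model, _pc())
        glc = out.reaction("EX_glc")
        assert (glc.lb, glc.ub) == (-0.3, -0.3)
        o2 = out.reaction("EX_o2")
        assert o2.lb == pytest.approx(-5.6 * 0.3)
        assert o2.ub == pytest.approx(-0.1)

    def test_atp_maintenance_bounds_applied(self, respiration_model):
        out = apply_physiological_constraints(respiration_model, _pc())
        atpm = out.reaction("ATPM")
        assert (atpm.lb, atpm.ub) == (10.0, 40.0)

    def test_vmax_caps_upper_bound(self, brain_model):
        pc = _pc(vmax={"GLS": 0.7})
        out = apply_physiological_constraints(brain_model, pc)
        assert out.reaction("GLS").ub == 0.7

    def test_csf_metabolite_sets_uptake_bound(self, brain_model):
        pc = _pc(csf={"gln_e": 500.0}, csf_flow=0.00035, tissue_mass=100.0)
        out = apply_physiological_constraints(brain_model, pc)
        assert out.reaction("EX_gln").lb == pytest.approx(-500 * 0.00035 / 100)

    def test_csf_metabolite_absent_is_skipped_not_error(self, brain_model, caplog):
        pc = _pc(csf={"unobtainium_e": 5.0})
        with caplog.at_level("WARNING"):
            apply_physiological_constraints(brain_model, pc)
        assert any("unobtainium_e" in rec.message for rec in caplog.records)

    def test_missing_mapped_reaction_is_error(self, respiration_model):
        pc = _pc(reaction_map={"atp_maintenance": "NOPE"})
        with pytest.raises(KeyError, match="NOPE"):
            apply_physiological_constraints(respiration_model, pc)

    def test_application_is_idempotent(self, respiration_model):
        once = apply_physiological_constraints(respiration_model, _pc())
        twice = apply_physiological_constraints(once, _pc())
        for r1, r2 in zip(once.reactions, twice.reactions):
            assert (r1.lb, r1.ub) == (r2.lb, r2.ub)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            _pc(atp_maintenance=(40.0, 10.0))
        with pytest.raises(ValueError):
            _pc(o2_min=99.0)


class TestFBA:
    def test_textbook_optimum(self, aerobic_unit_glucose):
        sol = fba(aerobic_unit_glucose, {"ATPM": 1.0}, "max")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(36.0, abs=1e-6)

    def test_steady_state_and_bounds_hold(self, aerobic_unit_glucose):
        sol = fba(aerobic_unit_glucose, {"ATPM": 1.0}, "max")
        S = stoichiometric_matrix(aerobic_unit_glucose).to_numpy()
        v = np.array([sol.fluxes[r.id] for r in aerobic_unit_glucose.reactions])
        assert np.abs(S @ v).max() < 1e-6
        for r in aerobic_unit_glucose.reactions:
            assert r.lb - 1e-9 <= sol.fluxes[r.id] <= r.ub + 1e-9

    def test_zero_objective_is_optimal_zero(self, respiration_model):
        sol = fba(respiration_model, {}, "max")
        assert sol.status == "optimal"
        assert sol.objective_value == 0.0

    def test_unsatisfiable_demand_is_infeasible(self, respiration_model):
        m = respiration_model.copy()
        ex = m.reaction("EX_glc")
        ex.lb = ex.ub = 0.0
        ex.reversible = False
        atpm = m.reaction("ATPM")
        atpm.lb = 10.0
        sol = fba(m, {"ATPM": 1.0}, "max")
        assert sol.status == "infeasible"

    def test_matches_cobra_reference_on_fixtures(
            self, aerobic_unit_glucose, brain_model, tmp_path):
        """Independent oracle: cobrapy optimum on the same SBML export."""
        cobra = pytest.importorskip("cobra")
        from cobra.io import read_sbml_model

        for model, obj in ((aerobic_unit_glucose, ["ATPM"]),
                           (brain_model, ["GLS", "GLNS", "GAD"])):
            ours = fba(model, {r: 1.0 for r in obj}, "max")
            path = tmp_path / f"{model.id}.xml"
            write_model(model, path)
            cm = read_sbml_model(str(path))
            # cobra strips the SBML "R_" prefix on read
            cm.objective = {cm.reactions.get_by_id(r): 1.0 for r in obj}
            ref = cm.optimize()
            assert ref.status == "optimal"
            assert ours.objective_value == pytest.approx(
                ref.objective_value, abs=1e-6)


def _cycle_model():
    """Through-path A→B plus a 3-reaction internal cycle A→B→C→A."""
    mets = [Metabolite(id="A_e", compartment="e"),
            Metabolite(id="B_e", compartment="e"),
            Metabolite(id="A_c", compartment="c"),
            Metabolite(id="B_c", compartment="c"),
            Metabolite(id="C_c", compartment="c")]
    rxns = [
        Reaction(id="EX_A", stoich={"A_e": -1}, lb=-1, ub=0),
        Reaction(id="T_A", stoich={"A_e": -1, "A_c": 1}, lb=0, ub=10),
        Reaction(id="R_AB", stoich={"A_c": -1, "B_c": 1}, lb=0, ub=10),
        Reaction(id="R_BC", stoich={"B_c": -1, "C_c": 1}, lb=0, ub=10),
        Reaction(id="R_CA", stoich={"C_c": -1, "A_c": 1}, lb=0, ub=10),
        Reaction(id="T_B", stoich={"B_c": -1, "B_e": 1}, lb=0, ub=10),
        Reaction(id="EX_B", stoich={"B_e": -1}, lb=0, ub=10),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, id="cycle3")


CYCLE_IDS = ("R_AB", "R_BC", "R_CA")


def _circulation(sol):
    """Component of the flux along the cycle's null-space direction
    (1,1,1)/sqrt(3) on R_AB, R_BC, R_CA — analytic for this fixture."""
    v = np.array([sol.fluxes[r] for r in CYCLE_IDS])
    # through-flux uses R_AB only; circulation is the common min along the loop
    return float(v @ np.ones(3) / np.sqrt(3) - sol.fluxes["R_AB"] / np.sqrt(3))


class TestLooplessCorrect:
    def test_circulating_cycle_flux_removed(self):
        model = _cycle_model()
        base = fba(model, {"EX_B": 1.0}, "max")
        assert base.objective_value == pytest.approx(1.0, abs=1e-9)
        # manufacture a feasible solution carrying circulation t around the loop
        loopy = base.fluxes.copy()
        for rid in CYCLE_IDS:
            loopy[rid] += 5.0
        from neurogem.flux_analysis import FluxSolution

        sol = FluxSolution(fluxes=loopy, objective_value=base.objective_value,
                           status="optimal")
        assert _circulation(sol) > 1.0
        fixed = loopless_correct(model, sol, objective={"EX_B": 1.0})
        assert abs(_circulation(fixed)) < 1e-8
        assert fixed.fluxes["R_BC"] == pytest.approx(0.0, abs=1e-8)
        assert fixed.fluxes["R_CA"] == pytest.approx(0.0, abs=1e-8)
        assert fixed.objective_value == pytest.approx(
            base.objective_value, abs=1e-6)

    def test_loop_free_solution_unchanged(self, aerobic_unit_glucose):
        sol = fba(aerobic_unit_glucose, {"ATPM": 1.0}, "max")
        fixed = loopless_correct(aerobic_unit_glucose, sol,
                                 objective={"ATPM": 1.0})
        assert fixed.objective_value == pytest.approx(
            sol.objective_value, abs=1e-6)
        # total |v| can only shrink
        tot = sum(abs(v) for v in sol.fluxes.values())
        tot_fixed = sum(abs(v) for v in fixed.fluxes.values())
        assert tot_fixed <= tot + 1e-6

    def test_corrected_solution_still_feasible(self):
        model = _cycle_model()
        base = fba(model, {"EX_B": 1.0}, "max")
        loopy = {r: base.fluxes[r] + (3.0 if r in CYCLE_IDS else 0.0)
                 for r in base.fluxes}
        from neurogem.flux_analysis import FluxSolution

        fixed = loopless_correct(
            model, FluxSolution(loopy, base.objective_value, "optimal"),
            objective={"EX_B": 1.0})
        S = stoichiometric_matrix(model).to_numpy()
        v = np.array([fixed.fluxes[r.id] for r in model.reactions])
        assert np.abs(S @ v).max() < 1e-6
        for r in model.reactions:
            assert r.lb - 1e-8 <= fixed.fluxes[r.id] <= r.ub + 1e-8


class TestFVA:
    def test_atp_demand_range_collapses_at_gamma_1(self, aerobic_unit_glucose):
        res = fva(aerobic_unit_glucose, {"ATPM": 1.0}, gamma=1.0)
        lo, hi = res.ranges["ATPM"]
        assert lo == pytest.approx(36.0, abs=1e-6)
        assert hi == pytest.approx(36.0, abs=1e-6)

    def test_blocked_reaction_range_is_zero(self):
        model = _cycle_model()
        model.metabolites.append(Metabolite(id="D_c", compartment="c"))
        model.reactions.append(
            Reaction(id="R_dead", stoich={"C_c": -1, "D_c": 1}, lb=0, ub=10))
        res = fva(model, {"EX_B": 1.0}, gamma=0.0)
        assert res.ranges["R_dead"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_gamma_1_ranges_nest_inside_gamma_09(self, aerobic_unit_glucose):
        tight = fva(aerobic_unit_glucose, {"ATPM": 1.0}, gamma=1.0)
        loose = fva(aerobic_unit_glucose, {"ATPM": 1.0}, gamma=0.9)
        for rid, (lo, hi) in tight.ranges.items():
            llo, lhi = loose.ranges[rid]
            assert llo <= lo + 1e-6 and hi <= lhi + 1e-6

    def test_fba_optimum_lies_inside_ranges(self, aerobic_unit_glucose):
        sol = fba(aerobic_unit_glucose, {"ATPM": 1.0}, "max")
        res = fva(aerobic_unit_glucose, {"ATPM": 1.0}, gamma=1.0)
        for rid, (lo, hi) in res.ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_midpoint_of_each_range_feasible(self):
        """FVA ranges contain a feasible point (LP re-check at midpoint)."""
        model = _cycle_model()
        res = fva(model, {"EX_B": 1.0}, gamma=1.0)
        from neurogem.flux_analysis import _solve_lp

        S = stoichiometric_matrix(model).to_numpy()
        for rid, (lo, hi) in res.ranges.items():
            mid = 0.5 * (lo + hi)
            bounds = []
            for r in model.reactions:
                if r.id == rid:
                    bounds.append((mid - 1e-6, mid + 1e-6))
                else:
                    bounds.append((r.lb, r.ub))
            lp = _solve_lp(np.zeros(len(model.reactions)), S,
                           np.zeros(S.shape[0]), bounds)
            assert lp.status == 0

    def test_loopless_fva_strips_cycle_circulation(self):
        model = _cycle_model()
        plain = fva(model, {"EX_B": 1.0}, gamma=1.0, loopless=False)
        clean = fva(model, {"EX_B": 1.0}, gamma=1.0, loopless=True)
        # without the loop constraint the cycle reactions can reach ub=10;
        # looplessly they carry only the through-path flux
        assert plain.ranges["R_BC"][1] > 1.0
        assert clean.ranges["R_BC"][1] == pytest.approx(0.0, abs=1e-8)
        assert clean.ranges["R_AB"][1] == pytest.approx(1.0, abs=1e-6)
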