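"""The RBA linear program: hand-solvable instances, growth maximization,
forced-flux scenarios and structural invariants."""

import numpy as np
import pytest

from necalloc import rba, synth
from necalloc.calibration import KappTable

from conftest import growth_lp_oracle, make_tiny_instance


class TestTinyInstance:
    """One uptake enzyme (k_app 100/hr, 1000 aa) against a 1 mmol aa budget:
    max flux = 100 * (1/1000) = 0.1, so mu_max = 0.1 with 1 mmol X per gDCW."""

    def test_feasibility_boundary(self, tiny_instance):
        net, kapp, budgets = tiny_instance
        for mu, expected in [(0.05, True), (0.1, True), (0.2, False)]:
            sol = rba.solve_feasible(
                rba.build_rba_problem(net, kapp, mu, budgets=budgets), "none")
            assert sol.feasible is expected

    def test_minimal_enzyme_allocation(self, tiny_instance):
        net, kapp, budgets = tiny_instance
        sol = rba.solve_feasible(
            rba.build_rba_problem(net, kapp, 0.1, budgets=budgets))
        assert sol.enzymes["E_UP"] == pytest.approx(0.001, rel=1e-6)

    def test_growth_maximization(self, tiny_instance):
        net, kapp, budgets = tiny_instance
        sol = rba.maximize_growth(net, kapp, budgets=budgets)
        assert sol.mu == pytest.approx(0.1, abs=2e-4)

    def test_budget_doubling_doubles_growth(self):
        net, kapp, budgets = make_tiny_instance(pool=2.0)
        sol = rba.maximize_growth(net, kapp, budgets=budgets)
        assert sol.mu == pytest.approx(0.2, abs=2e-4)

    def test_matches_parametric_lp_oracle(self, tiny_instance):
        net, kapp, budgets = tiny_instance
        oracle_mu = growth_lp_oracle(net, kapp, budgets)
        sol = rba.maximize_growth(net, kapp, budgets=budgets)
        assert sol.mu == pytest.approx(oracle_mu, abs=2e-4)

    def test_duplicate_isoenzymes_leave_optimum_unchanged(self):
        net1, kapp, budgets = make_tiny_instance()
        net2, _, _ = make_tiny_instance(duplicate_isoenzyme=True)
        sol1 = rba.maximize_growth(net1, kapp, budgets=budgets)
        sol2 = rba.maximize_growth(net2, kapp, budgets=budgets)
        assert sol2.mu == pytest.approx(sol1.mu, abs=2e-4)
        assert sol2.objective == pytest.approx(sol1.objective, rel=1e-6)

    def test_infeasible_mu_has_no_payload(self, tiny_instance):
        net, kapp, budgets = tiny_instance
        sol = rba.solve_feasible(
            rba.build_rba_problem(net, kapp, 0.5, budgets=budgets))
        assert sol.status == "infeasible"
        assert not sol.fluxes and not sol.enzymes

    def test_mu_zero_without_maintenance_trivially_feasible(self, tiny_instance):
        net, kapp, budgets = tiny_instance
        sol = rba.solve_feasible(
            rba.build_rba_problem(net, kapp, 0.0, budgets=budgets))
        assert sol.feasible
        assert all(abs(v) < 1e-9 for v in sol.fluxes.values())


def test_pseudo_reactions_get_no_capacity_constraint(toy_network, toy_kapp):
    problem = rba.build_rba_problem(toy_network, toy_kapp, 0.1)
    capacity_names = [n for n in problem.ub_names if n.startswith("capacity")]
    for rxn in toy_network.reactions:
        if rxn.pseudo:
            assert not any(rxn.id in n for n in capacity_names)


def test_missing_kapp_error_names_reaction(toy_network):
    sparse = KappTable.from_values({"ED": 1000.0})
    with pytest.raises(rba.RBAError, match="FRUt"):
        rba.build_rba_problem(toy_network, sparse, 0.1)


def test_feasibility_monotone_in_mu(toy_network, toy_kapp, toy_machineries,
                                    toy_budgets, toy_conditions):
    cond = toy_conditions["fructose"]
    grid = np.linspace(0.0, 0.8, 20)
    feasible = [
        rba.solve_feasible(
            rba.build_rba_problem(toy_network, toy_kapp, mu, cond,
                                  toy_machineries, toy_budgets), "none").feasible
        for mu in grid
    ]
    # once infeasible, stays infeasible
    first_infeasible = feasible.index(False) if False in feasible else len(grid)
    assert all(feasible[:first_infeasible])
    assert not any(feasible[first_infeasible:])


def test_capacity_saturation_at_minimal_enzyme_optimum(
        toy_network, toy_kapp, toy_machineries, toy_budgets, toy_conditions):
    """Every expressed enzyme is fully used in a minimal-enzyme solution:
    at least one direction of its reaction runs at v = k_app * [E]."""
    for cond in toy_conditions.values():
        sol = rba.maximize_growth(toy_network, toy_kapp, cond,
                                  toy_machineries, toy_budgets)
        for rid, alts in toy_network.gpr.items():
            conc = sum(sol.enzymes[a] for a in alts)
            if conc <= 1e-9:
                continue
            cap = toy_kapp.value(rid, "fwd") * conc
            v = abs(sol.fluxes.get(rid, 0.0))
            assert v == pytest.approx(cap, rel=1e-5), rid


def test_mass_balance_at_optimum(toy_network, toy_kapp, toy_machineries,
                                 toy_budgets, toy_conditions):
    sol = rba.maximize_growth(toy_network, toy_kapp, toy_conditions["fructose"],
                              toy_machineries, toy_budgets)
    for met in toy_network.internal_metabolites():
        net_flux = sum(
            rxn.stoichiometry.get(met.id, 0.0) * sol.fluxes[rxn.id]
            for rxn in toy_network.reactions
        )
        assert abs(net_flux) < 1e-6, met.id


def test_substrate_choice_selects_pathway(toy_network, toy_kapp, toy_machineries,
                                          toy_budgets, toy_conditions):
    """Growth on the fructose-like substrate runs the ED route with zero CBB
    flux; growth on formate requires CO2 fixation through the CBB route."""
    fru = rba.maximize_growth(toy_network, toy_kapp, toy_conditions["fructose"],
                              toy_machineries, toy_budgets)
    assert fru.fluxes["ED"] > 1.0
    assert abs(fru.fluxes.get("CBB", 0.0)) < 1e-6
    formate = rba.maximize_growth(toy_network, toy_kapp, toy_conditions["formate"],
                                  toy_machineries, toy_budgets)
    assert formate.fluxes["CBB"] > 0.5
    assert abs(formate.fluxes.get("ED", 0.0)) < 1e-6


def test_growth_on_formate_needs_cbb(toy_kapp, toy_machineries, toy_budgets,
                                     toy_conditions):
    net = synth.gen_toy_network(synth.ToyNetworkConfig(include_cbb=False))
    kapp = synth.toy_kapp_true(net)
    sol = rba.maximize_growth(net, kapp, toy_conditions["formate"],
                              toy_machineries, toy_budgets)
    assert sol.mu < 1e-3  # no carbon entry from formate without CO2 fixation


def test_ribosome_increases_with_growth_rate(toy_network, toy_kapp,
                                             toy_machineries, toy_budgets,
                                             toy_conditions):
    cond = toy_conditions["fructose"]
    ribo = []
    for mu in (0.05, 0.1, 0.15, 0.2, 0.25, 0.3):
        sol = rba.solve_feasible(rba.build_rba_problem(
            toy_network, toy_kapp, mu, cond, toy_machineries, toy_budgets))
        assert sol.feasible
        ribo.append(sol.machineries["ribosome"])
    assert all(b >= a - 1e-12 for a, b in zip(ribo, ribo[1:]))


class TestForcedFlux:
    def test_zero_forcing_matches_unforced_optimum(
            self, toy_network, toy_kapp, toy_machineries, toy_budgets):
        cond = synth.toy_forced_condition()
        free = rba.maximize_growth(toy_network, toy_kapp, cond,
                                   toy_machineries, toy_budgets)
        forced, summ = rba.simulate_forced_flux(
            toy_network, toy_kapp, cond, {"CBB": 0.0},
            toy_machineries, toy_budgets)
        assert forced.mu == pytest.approx(free.mu, abs=2e-4)

    def test_forced_co2_fixation_never_helps(
            self, toy_network, toy_kapp, toy_machineries, toy_budgets):
        """Raising forced CBB flux on the fructose-like substrate leaves growth
        rate and biomass yield non-increasing and net CO2 emission
        non-decreasing."""
        cond = synth.toy_forced_condition()
        mus, yields, co2 = [], [], []
        for f in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0):
            _, summ = rba.simulate_forced_flux(
                toy_network, toy_kapp, cond, {"CBB": f},
                toy_machineries, toy_budgets)
            mus.append(summ["mu"])
            yields.append(summ["yield_gdcw_per_g"])
            co2.append(summ["net_co2_emission"])
        tol = 5e-4
        assert all(b <= a + tol for a, b in zip(mus, mus[1:]))
        assert all(b <= a + tol for a, b in zip(yields, yields[1:]))
        assert all(b >= a - tol for a, b in zip(co2, co2[1:]))

    def test_forcing_beyond_supply_is_infeasible(
            self, toy_network, toy_kapp, toy_machineries, toy_budgets):
        sol, _ = rba.simulate_forced_flux(
            toy_network, toy_kapp, synth.toy_forced_condition(),
            {"CBB": 500.0}, toy_machineries, toy_budgets)
        assert sol.status == "infeasible"

    def test_forcing_outside_bounds_rejected(self, toy_network, toy_kapp):
        with pytest.raises(rba.RBAError, match="outside bounds"):
            rba.build_rba_problem(toy_network, toy_kapp, 0.1,
                                  forced={"CBB": -1.0})
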