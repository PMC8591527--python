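"""k_app estimation, flux sampling and ensemble bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from necalloc import calibration, rba, synth
from necalloc.calibration import FluxSamples, KappEntry, KappTable


@pytest.fixture(scope="module")
def chemostat_data(toy_network, toy_kapp, toy_machineries, toy_budgets,
                   toy_conditions):
    """Noiseless proteomes + flux samples for all three substrate conditions."""
    samples, proteomes, solutions = {}, {}, {}
    for i, (name, cond) in enumerate(sorted(toy_conditions.items())):
        sol = rba.solve_feasible(rba.build_rba_problem(
            toy_network, toy_kapp, cond.dilution_rate, cond, toy_machineries,
            toy_budgets))
        assert sol.feasible
        solutions[name] = sol
        prot, _ = synth.gen_proteome(sol, toy_network, noise_cv=0.0,
                                     n_replicates=1, seed=10 + i,
                                     machineries=toy_machineries)
        proteomes[name] = prot.mean
        fixed = {cond.substrate_exchange: sol.fluxes[cond.substrate_exchange]}
        samples[name] = calibration.sample_flux_space(
            toy_network, cond, n_samples=200, seed=20 + i, fixed_fluxes=fixed)
    return samples, proteomes, solutions


def scipy_fva(network, condition, fixed_growth, reaction):
    """Independent FVA oracle: min/max one net flux under S v = 0 and bounds,
    via scipy linprog directly on the stoichiometric matrix."""
    rxns = network.reactions
    col = {r.id: i for i, r in enumerate(rxns)}
    n = len(rxns)
    internal = [m.id for m in network.metabolites if not m.boundary]
    A_eq = np.zeros((len(internal), n))
    for j, r in enumerate(rxns):
        for met, coef in r.stoichiometry.items():
            if met in internal:
                A_eq[internal.index(met), j] = coef
    bounds = []
    mu = condition.dilution_rate
    for r in rxns:
        lb, ub = r.lower_bound, r.upper_bound
        if r.reversible and lb >= 0:
            lb = -ub
        if r.id in condition.exchange_bounds:
            lb, ub = condition.exchange_bounds[r.id]
        if r.id == network.biomass_reaction and fixed_growth:
            lb = ub = mu
        if r.id == network.phb_reaction and fixed_growth:
            lb = ub = network.phb_demand * mu
        if r.id == network.maintenance_reaction and fixed_growth:
            lb = network.maintenance.ngam + network.maintenance.gam * mu
        bounds.append((lb, ub))
    out = {}
    for sense, sign in (("min", 1.0), ("max", -1.0)):
        c = np.zeros(n)
        c[col[reaction]] = sign
        res = linprog(c, A_eq=A_eq, b_eq=np.zeros(len(internal)), bounds=bounds,
                      method="highs")
        assert res.success
        out[sense] = res.x[col[reaction]]
    return out


class TestFluxSampling:
    def test_samples_satisfy_mass_balance(self, chemostat_data, toy_network):
        samples, _, _ = chemostat_data
        fs = samples["fructose"]
        internal = [m.id for m in toy_network.metabolites]
        S = pd.DataFrame(0.0, index=internal, columns=fs.samples.columns)
        for r in toy_network.reactions:
            for met, coef in r.stoichiometry.items():
                S.loc[met, r.id] = coef
        residual = fs.samples.to_numpy() @ S.to_numpy().T
        assert np.abs(residual).max() < 1e-6

    def test_envelope_within_independent_fva(self, toy_network, toy_conditions):
        """The sampled envelope must lie inside FVA bounds computed by an
        independent scipy formulation (and the cobra FVA must agree)."""
        cond = toy_conditions["fructose"]
        fs = calibration.sample_flux_space(toy_network, cond, n_samples=100,
                                           seed=0)
        for rid in ("ED", "TCA", "OXP"):
            oracle = scipy_fva(toy_network, cond, True, rid)
            assert fs.envelope.loc[rid, "max"] <= oracle["max"] + 1e-6
            assert fs.envelope.loc[rid, "min"] >= oracle["min"] - 1e-6
            assert fs.fva.loc[rid, "max"] == pytest.approx(oracle["max"], abs=1e-5)
            assert fs.fva.loc[rid, "min"] == pytest.approx(oracle["min"], abs=1e-5)

    def test_fixed_seed_reproduces_samples(self, toy_network, toy_conditions):
        cond = toy_conditions["fructose"]
        a = calibration.sample_flux_space(toy_network, cond, 50, seed=5,
                                          with_fva=False)
        b = calibration.sample_flux_space(toy_network, cond, 50, seed=5,
                                          with_fva=False)
        assert a.samples.equals(b.samples)

    def test_infeasible_condition_rejected(self, toy_network, toy_conditions):
        cond = toy_conditions["formate"]
        bad = type(cond)(cond.name, dict(cond.exchange_bounds, EX_for=(0.0, 0.0)),
                         cond.dilution_rate, cond.substrate_exchange)
        with pytest.raises(ValueError, match="infeasible"):
            calibration.sample_flux_space(toy_network, bad, 10)


class TestEstimateKapp:
    def test_single_condition_arithmetic(self, toy_network):
        """Flux envelope max 10 with 0.002 mmol/gDCW of enzyme -> 5000/hr."""
        env = pd.DataFrame({"min": [0.0], "max": [10.0]}, index=["ED"])
        fs = FluxSamples("fructose", pd.DataFrame(), env)
        proteome = {"edd": 0.002, "eda": 0.002}
        table = calibration.estimate_kapp({"fructose": fs},
                                          {"fructose": proteome}, toy_network)
        assert table.value("ED") == pytest.approx(5000.0)
        assert table.entries[("ED", "fwd")].provenance == "fitted"

    def test_recovers_truth_from_noiseless_proteomes(self, chemostat_data,
                                                     toy_network, toy_kapp):
        samples, proteomes, _ = chemostat_data
        est = calibration.estimate_kapp(samples, proteomes, toy_network)
        for (rid, d), entry in est.entries.items():
            if entry.provenance != "fitted":
                continue
            assert entry.kapp == pytest.approx(toy_kapp.value(rid, d), rel=0.05), rid

    def test_unmeasured_enzyme_gets_median_fill(self, toy_network):
        env = pd.DataFrame({"min": [0.0, 0.0], "max": [10.0, 4.0]},
                           index=["ED", "TCA"])
        fs = FluxSamples("fructose", pd.DataFrame(), env)
        proteome = {"edd": 0.002, "eda": 0.002}  # TCA protein unmeasured
        table = calibration.estimate_kapp({"fructose": fs},
                                          {"fructose": proteome}, toy_network)
        assert table.entries[("TCA", "fwd")].provenance == "median_filled"
        assert table.value("TCA") == pytest.approx(5000.0)  # median of fits

    def test_scale_consistency(self, chemostat_data, toy_network):
        """Doubling every measured abundance halves every fitted k_app."""
        samples, proteomes, _ = chemostat_data
        est1 = calibration.estimate_kapp(samples, proteomes, toy_network)
        doubled = {c: p * 2.0 for c, p in proteomes.items()}
        est2 = calibration.estimate_kapp(samples, doubled, toy_network)
        for key, e1 in est1.entries.items():
            if e1.provenance == "fitted":
                assert est2.entries[key].kapp == pytest.approx(e1.kapp / 2.0,
                                                               rel=1e-9)

    def test_condition_mismatch_rejected(self, chemostat_data, toy_network):
        samples, proteomes, _ = chemostat_data
        with pytest.raises(ValueError, match="align"):
            calibration.estimate_kapp(samples,
                                      {"fructose": proteomes["fructose"]},
                                      toy_network)

    def test_nothing_estimable_rejected(self, toy_network):
        env = pd.DataFrame({"min": [0.0], "max": [0.0]}, index=["ED"])
        fs = FluxSamples("fructose", pd.DataFrame(), env)
        with pytest.raises(ValueError, match="no k_app"):
            calibration.estimate_kapp({"fructose": fs}, {"fructose": {}},
                                      toy_network)


class TestKappEnsemble:
    def test_each_draw_is_complete(self, toy_kapp):
        draws = calibration.sample_kapp_ensemble(toy_kapp, n=10, seed=0)
        assert len(draws) == 10
        for d in draws:
            assert set(d.entries) == set(toy_kapp.entries)

    def test_degenerate_distribution_reproduces_input(self):
        table = KappTable.from_values({"A": 100.0, "B": 100.0})
        draws = calibration.sample_kapp_ensemble(table, n=5, seed=1)
        for d in draws:
            assert all(e.kapp == 100.0 for e in d.entries.values())

    def test_fixed_seed_reproduces_ensemble(self, toy_kapp):
        a = calibration.sample_kapp_ensemble(toy_kapp, n=5, seed=2)
        b = calibration.sample_kapp_ensemble(toy_kapp, n=5, seed=2)
        for da, db in zip(a, b):
            assert {k: e.kapp for k, e in da.entries.items()} == \
                   {k: e.kapp for k, e in db.entries.items()}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibration.sample_kapp_ensemble(KappTable(), n=1)


@pytest.fixture(scope="module")
def ensemble_solutions(toy_network, toy_kapp, toy_machineries, toy_budgets,
                       toy_conditions):
    draws = calibration.sample_kapp_ensemble(toy_kapp, n=5, seed=3)
    return {
        name: [rba.maximize_growth(toy_network, k, cond, toy_machineries,
                                   toy_budgets) for k in draws]
        for name, cond in sorted(toy_conditions.items())
    }


class TestUtilizedReactionCounts:
    def test_set_algebra(self, ensemble_solutions):
        summary = calibration.count_utilized_reactions(ensemble_solutions)
        for cond_set in summary.per_condition.values():
            assert summary.core <= cond_set <= summary.union
        for cond, uniq in summary.condition_unique.items():
            for other, s in summary.per_condition.items():
                if other != cond:
                    assert not (uniq & s)

    def test_counts_match_brute_force_recount(self, ensemble_solutions):
        summary = calibration.count_utilized_reactions(ensemble_solutions)
        # recount from the stored flux dictionaries with explicit loops
        union, core = set(), None
        for sols in ensemble_solutions.values():
            for sol in sols:
                active = {r for r, v in sol.fluxes.items() if abs(v) > 1e-6}
                union |= active
                core = active if core is None else core & active
        assert summary.union == union
        assert summary.core == core

    def test_single_solution_degenerate_ensemble(self, ensemble_solutions):
        one = {"fructose": ensemble_solutions["fructose"][:1]}
        summary = calibration.count_utilized_reactions(one)
        active = ensemble_solutions["fructose"][0].active_reactions()
        assert summary.union == summary.core == active

    def test_union_monotone_in_ensemble_size(self, ensemble_solutions):
        sizes = []
        for n in (1, 3, 5):
            subset = {c: sols[:n] for c, sols in ensemble_solutions.items()}
            sizes.append(len(calibration.count_utilized_reactions(subset).union))
        assert sizes == sorted(sizes)
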