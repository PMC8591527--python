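import numpy as np
import pytest
from scipy.optimize import linprog

from necalloc import synth
from necalloc.calibration import KappTable
from necalloc.network import (
    CompartmentBudget,
    EnzymeSpec,
    Metabolite,
    Reaction,
    ReactionNetwork,
)


@pytest.fixture(scope="session")
def toy_network():
    return synth.gen_toy_network()


@pytest.fixture(scope="session")
def toy_kapp(toy_network):
    return synth.toy_kapp_true(toy_network)


@pytest.fixture(scope="session")
def toy_machineries():
    return synth.toy_machineries()


@pytest.fixture(scope="session")
def toy_budgets():
    return synth.toy_budgets()


@pytest.fixture(scope="session")
def toy_conditions():
    return synth.toy_conditions()


def make_tiny_instance(kapp_value=100.0, enzyme_length=1000, pool=1.0,
                       duplicate_isoenzyme=False):
    """One uptake reaction feeding biomass precursor X: max flux =
    kapp * pool / length, so mu_max = kapp * pool / length with biomass
    demanding 1 mmol X per gDCW."""
    enzymes = {"E_UP": EnzymeSpec("E_UP", {"upA": 1}, enzyme_length)}
    alts = ["E_UP"]
    if duplicate_isoenzyme:
        enzymes["E_UP2"] = EnzymeSpec("E_UP2", {"upB": 1}, enzyme_length)
        alts = ["E_UP", "E_UP2"]
    net = ReactionNetwork(
        metabolites=[Metabolite("x_e"), Metabolite("x_c")],
        reactions=[
            Reaction("EX_x", {"x_e": -1.0}, lower_bound=-1000.0, upper_bound=0.0,
                     pseudo=True),
            Reaction("UP", {"x_e": -1.0, "x_c": 1.0}),
            Reaction("BIOMASS", {"x_c": -1.0}, pseudo=True),
        ],
        gpr={"UP": alts},
        enzymes=enzymes,
        proteins={"upA": enzyme_length, "upB": enzyme_length},
        biomass={"x_c": 1.0},
    )
    kapp = KappTable.from_values({"UP": kapp_value})
    budgets = [CompartmentBudget("cytoplasm", pool)]
    return net, kapp, budgets


@pytest.fixture()
def tiny_instance():
    return make_tiny_instance()


def growth_lp_oracle(network, kapp, budgets, condition=None):
    """Independent oracle for small instances WITHOUT machinery and with
    growth-rate-independent budgets: because the only mu-dependence is then
    the biomass flux, mu can be a plain LP variable and growth maximization
    is a single linear program (no bisection).

    Variables: [mu, v_fwd..., E...]; maximize mu.
    """
    rxns = [r for r in network.reactions]
    enz_ids = sorted({e for alts in network.gpr.values() for e in alts})
    n = 1 + len(rxns) + len(enz_ids)
    col_v = {r.id: 1 + i for i, r in enumerate(rxns)}
    col_e = {e: 1 + len(rxns) + i for i, e in enumerate(enz_ids)}

    A_eq, b_eq = [], []
    internal = [m.id for m in network.metabolites if not m.boundary]
    for met in internal:
        row = np.zeros(n)
        for r in rxns:
            if met in r.stoichiometry:
                row[col_v[r.id]] += r.stoichiometry[met]
        # biomass flux is mu itself: substitute v_bio = mu
        A_eq.append(row)
        b_eq.append(0.0)
    # tie biomass reaction flux to mu
    row = np.zeros(n)
    row[col_v[network.biomass_reaction]] = 1.0
    row[0] = -1.0
    A_eq.append(row)
    b_eq.append(0.0)

    A_ub, b_ub = [], []
    for rid, alts in network.gpr.items():
        row = np.zeros(n)
        row[col_v[rid]] = 1.0
        for eid in alts:
            row[col_e[eid]] = -kapp.value(rid, "fwd")
        A_ub.append(row)
        b_ub.append(0.0)
    for budget in budgets:
        assert budget.fraction.slope == 0 and budget.non_enzymatic.slope == 0
        row = np.zeros(n)
        for eid in enz_ids:
            if network.enzymes[eid].compartment == budget.compartment:
                row[col_e[eid]] = network.enzymes[eid].length
        A_ub.append(row)
        b_ub.append(budget.capacity(0.0))

    bounds = [(0, None)]
    for r in rxns:
        lb, ub = r.lower_bound, r.upper_bound
        if condition is not None and r.id in condition.exchange_bounds:
            lb, ub = condition.exchange_bounds[r.id]
        bounds.append((lb, ub))
    bounds.extend([(0, None)] * len(enz_ids))

    c = np.zeros(n)
    c[0] = -1.0
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=bounds,
                  method="highs")
    assert res.success, res.message
    return res.x[0]
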