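"""Resource balance analysis (RBA) as an explicit linear program.

At a fixed growth rate mu the cell model is linear: steady-state mass balance
couples fluxes; each flux needs enzyme via its apparent catalytic rate
(v <= k_app * [E]); translation of all protein needs ribosomes (and analogous
machinery couplings); and enzymes plus machinery must fit into growth-rate
dependent compartment protein budgets.  Growth maximization is a bisection on
mu over the feasibility of this LP.  The reported solution at any mu is the
one minimizing total enzyme amino acids ("minimal required enzyme abundance"),
which is the reference against which enzyme utilization is defined.

Fluxes are split into non-negative forward/backward directions so every
capacity constraint stays linear with unambiguous sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import Condition, Machinery, CompartmentBudget, ReactionNetwork

#: |v| below this is treated as zero flux (mmol gDCW^-1 hr^-1)
FLUX_TOL = 1e-6
#: default bisection tolerance on mu (hr^-1)
MU_TOL = 1e-4
#: slack below which an inequality is reported as binding
BINDING_TOL = 1e-6


class RBAError(Exception):
    pass


@dataclass
class RBAProblem:
    """The assembled LP at fixed mu (linprog standard form)."""

    mu: float
    var_names: list[str]
    flux_cols: dict[tuple[str, str], int]  # (reaction, "fwd"/"bwd") -> column
    enzyme_cols: dict[str, int]
    machinery_cols: dict[str, int]
    A_ub: np.ndarray
    b_ub: np.ndarray
    ub_names: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    eq_names: list[str]
    bounds: list[tuple[float, float | None]]
    c_min_enzyme: np.ndarray
    network: ReactionNetwork = None
    condition: Condition | None = None

    @property
    def n_vars(self) -> int:
        return len(self.var_names)


@dataclass
class RBASolution:
    status: str  # "optimal" | "infeasible" | "error"
    mu: float
    fluxes: dict[str, float] = field(default_factory=dict)  # net flux per reaction
    flux_by_direction: dict[tuple[str, str], float] = field(default_factory=dict)
    enzymes: dict[str, float] = field(default_factory=dict)  # mmol gDCW^-1
    machineries: dict[str, float] = field(default_factory=dict)
    binding_constraints: list[str] = field(default_factory=list)
    objective: float = float("nan")  # total enzyme+machinery amino acids
    condition: str | None = None
    message: str = ""

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"

    def active_reactions(self, flux_tol: float = FLUX_TOL) -> set[str]:
        return {r for r, v in self.fluxes.items() if abs(v) > flux_tol}


def _effective_bounds(rxn, condition: Condition | None) -> tuple[float, float]:
    if condition is not None and rxn.id in condition.exchange_bounds:
        return condition.exchange_bounds[rxn.id]
    lb = rxn.lower_bound
    if rxn.reversible and lb >= 0.0:
        lb = -rxn.upper_bound
    return lb, rxn.upper_bound


def build_rba_problem(
    network: ReactionNetwork,
    kapp,
    mu: float,
    condition: Condition | None = None,
    machineries: list[Machinery] = (),
    budgets: list[CompartmentBudget] = (),
    forced: dict[str, float] | None = None,
) -> RBAProblem:
    """Assemble the fixed-mu RBA linear program.

    ``kapp`` is any object with ``value(reaction_id, direction)`` returning the
    apparent catalytic rate in hr^-1 (see :class:`necalloc.calibration.KappTable`).
    ``forced`` pins net fluxes of the given reactions with equality rows.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    forced = dict(forced or {})

    var_names: list[str] = []
    flux_cols: dict[tuple[str, str], int] = {}
    enzyme_cols: dict[str, int] = {}
    machinery_cols: dict[str, int] = {}
    bounds: list[tuple[float, float | None]] = []

    for rxn in network.reactions:
        lb, ub = _effective_bounds(rxn, condition)
        if rxn.id == network.biomass_reaction:
            lb = ub = mu
        elif rxn.id == network.phb_reaction:
            lb = ub = network.phb_demand * mu
        elif rxn.id == network.maintenance_reaction:
            lb = max(lb, network.maintenance.ngam + network.maintenance.gam * mu)
            if lb > ub:
                raise RBAError(
                    f"maintenance demand {lb:.4g} exceeds upper bound of {rxn.id}"
                )
        if rxn.id in forced:
            v = forced[rxn.id]
            if not (lb - 1e-12 <= v <= ub + 1e-12):
                raise RBAError(
                    f"forced flux {v} for {rxn.id} outside bounds [{lb}, {ub}]"
                )
        flux_cols[(rxn.id, "fwd")] = len(var_names)
        var_names.append(f"v_fwd[{rxn.id}]")
        bounds.append((max(0.0, lb), max(0.0, ub)))
        if lb < 0:
            flux_cols[(rxn.id, "bwd")] = len(var_names)
            var_names.append(f"v_bwd[{rxn.id}]")
            bounds.append((max(0.0, -ub), -lb))

    for rid in network.enzymatic_reactions():
        for eid in network.gpr[rid]:
            if eid not in enzyme_cols:
                enzyme_cols[eid] = len(var_names)
                var_names.append(f"E[{eid}]")
                bounds.append((0.0, None))

    for mach in machineries:
        machinery_cols[mach.id] = len(var_names)
        var_names.append(f"M[{mach.id}]")
        bounds.append((0.0, None))

    n = len(var_names)
    eq_rows, b_eq, eq_names = [], [], []
    ub_rows, b_ub, ub_names = [], [], []

    # (i) steady-state mass balance over internal metabolites
    met_row = {m.id: i for i, m in enumerate(network.internal_metabolites())}
    S = np.zeros((len(met_row), n))
    for rxn in network.reactions:
        for met, coef in rxn.stoichiometry.items():
            i = met_row.get(met)
            if i is None:
                continue
            S[i, flux_cols[(rxn.id, "fwd")]] += coef
            if (rxn.id, "bwd") in flux_cols:
                S[i, flux_cols[(rxn.id, "bwd")]] -= coef
    for met, i in met_row.items():
        eq_rows.append(S[i])
        b_eq.append(0.0)
        eq_names.append(f"mass_balance[{met}]")

    # forced net fluxes
    for rid, v in forced.items():
        row = np.zeros(n)
        row[flux_cols[(rid, "fwd")]] = 1.0
        if (rid, "bwd") in flux_cols:
            row[flux_cols[(rid, "bwd")]] = -1.0
        eq_rows.append(row)
        b_eq.append(v)
        eq_names.append(f"forced[{rid}]")

    # (ii) enzyme capacity per reaction direction
    for rid in network.enzymatic_reactions():
        alts = network.gpr[rid]
        for d in ("fwd", "bwd"):
            if (rid, d) not in flux_cols:
                continue
            try:
                k = kapp.value(rid, d)
            except KeyError as exc:
                raise RBAError(f"no k_app for reaction {rid} direction {d}") from exc
            row = np.zeros(n)
            row[flux_cols[(rid, d)]] = 1.0
            for eid in alts:
                row[enzyme_cols[eid]] -= k
            ub_rows.append(row)
            b_ub.append(0.0)
            ub_names.append(f"capacity[{rid},{d}]")

    enzyme_len = {eid: network.enzymes[eid].length for eid in enzyme_cols}
    mach_by_id = {m.id: m for m in machineries}
    reserve = sum(b.reserve(mu) for b in budgets)

    # (iii) machinery capacity couplings
    for mach in machineries:
        row = np.zeros(n)
        rhs = 0.0
        if mach.demand_kind == "protein":
            coeff = mu * mach.demand_coeff
            for eid, col in enzyme_cols.items():
                row[col] += coeff * enzyme_len[eid]
            for mid, col in machinery_cols.items():
                row[col] += coeff * mach_by_id[mid].length
            rhs = -coeff * reserve
        else:  # fixed demand per gDCW, scaled by mu
            rhs = -mu * mach.demand_coeff
        row[machinery_cols[mach.id]] -= mach.rate
        ub_rows.append(row)
        b_ub.append(rhs)
        ub_names.append(f"machinery[{mach.id}]")

    # (iv) compartment protein budgets
    for budget in budgets:
        row = np.zeros(n)
        for eid, col in enzyme_cols.items():
            if network.enzymes[eid].compartment == budget.compartment:
                row[col] = enzyme_len[eid]
        for mid, col in machinery_cols.items():
            if mach_by_id[mid].compartment == budget.compartment:
                row[col] = mach_by_id[mid].length
        if np.any(row):
            ub_rows.append(row)
            b_ub.append(budget.capacity(mu))
            ub_names.append(f"budget[{budget.compartment}]")

    c = np.zeros(n)
    for eid, col in enzyme_cols.items():
        c[col] = enzyme_len[eid]
    for mid, col in machinery_cols.items():
        c[col] = mach_by_id[mid].length

    return RBAProblem(
        mu=mu,
        var_names=var_names,
        flux_cols=flux_cols,
        enzyme_cols=enzyme_cols,
        machinery_cols=machinery_cols,
        A_ub=np.array(ub_rows) if ub_rows else np.zeros((0, n)),
        b_ub=np.array(b_ub),
        ub_names=ub_names,
        A_eq=np.array(eq_rows) if eq_rows else np.zeros((0, n)),
        b_eq=np.array(b_eq),
        eq_names=eq_names,
        bounds=bounds,
        c_min_enzyme=c,
        network=network,
        condition=condition,
    )


def solve_feasible(problem: RBAProblem, objective: str = "min_total_enzyme") -> RBASolution:
    """Solve the fixed-mu LP.

    ``objective="none"`` is a pure feasibility check; ``"min_total_enzyme"``
    returns, among feasible solutions, one minimizing total enzyme plus
    machinery amino acids (the predicted minimal abundance).
    """
    if objective not in ("none", "min_total_enzyme"):
        raise ValueError(f"unknown objective {objective!r}")
    c = problem.c_min_enzyme if objective == "min_total_enzyme" else np.zeros(problem.n_vars)
    res = linprog(
        c,
        A_ub=problem.A_ub if len(problem.b_ub) else None,
        b_ub=problem.b_ub if len(problem.b_ub) else None,
        A_eq=problem.A_eq if len(problem.b_eq) else None,
        b_eq=problem.b_eq if len(problem.b_eq) else None,
        bounds=problem.bounds,
        method="highs",
    )
    cond = problem.condition.name if problem.condition else None
    if res.status == 2:
        return RBASolution(status="infeasible", mu=problem.mu, condition=cond,
                           message=res.message)
    if not res.success:
        return RBASolution(status="error", mu=problem.mu, condition=cond,
                           message=res.message)

    x = res.x
    flux_by_dir = {key: float(x[col]) for key, col in problem.flux_cols.items()}
    fluxes: dict[str, float] = {}
    for (rid, d), v in flux_by_dir.items():
        fluxes[rid] = fluxes.get(rid, 0.0) + (v if d == "fwd" else -v)
    enzymes = {eid: float(x[col]) for eid, col in problem.enzyme_cols.items()}
    machineries = {mid: float(x[col]) for mid, col in problem.machinery_cols.items()}

    binding = []
    if len(problem.b_ub):
        slack = problem.b_ub - problem.A_ub @ x
        scale = np.maximum(1.0, np.abs(problem.b_ub))
        for name, s, sc in zip(problem.ub_names, slack, scale):
            if s <= BINDING_TOL * sc:
                binding.append(name)

    return RBASolution(
        status="optimal",
        mu=problem.mu,
        fluxes=fluxes,
        flux_by_direction=flux_by_dir,
        enzymes=enzymes,
        machineries=machineries,
        binding_constraints=binding,
        objective=float(problem.c_min_enzyme @ x),
        condition=cond,
    )


def _feasible_at(network, kapp, mu, condition, machineries, budgets, forced=None) -> bool:
    problem = build_rba_problem(
        network, kapp, mu, condition, machineries, budgets, forced=forced
    )
    return solve_feasible(problem, objective="none").feasible


def maximize_growth(
    network: ReactionNetwork,
    kapp,
    condition: Condition | None = None,
    machineries: list[Machinery] = (),
    budgets: list[CompartmentBudget] = (),
    tol_mu: float = MU_TOL,
    mu_cap: float = 10.0,
    forced: dict[str, float] | None = None,
) -> RBASolution:
    """Largest feasible growth rate by bisection (monotone-feasibility contract).

    Returns the minimal-enzyme solution at the largest feasible mu found
    within ``tol_mu``.
    """
    if not _feasible_at(network, kapp, 0.0, condition, machineries, budgets, forced):
        raise RBAError("RBA problem infeasible at mu = 0")
    lo, hi = 0.0, max(10 * tol_mu, 0.05)
    while hi < mu_cap and _feasible_at(network, kapp, hi, condition, machineries, budgets, forced):
        lo, hi = hi, hi * 2.0
    while hi - lo > tol_mu:
        mid = 0.5 * (lo + hi)
        if _feasible_at(network, kapp, mid, condition, machineries, budgets, forced):
            lo = mid
        else:
            hi = mid
    problem = build_rba_problem(
        network, kapp, lo, condition, machineries, budgets, forced=forced
    )
    sol = solve_feasible(problem, objective="min_total_enzyme")
    if not sol.feasible:  # numerically marginal at lo: back off by one tolerance
        problem = build_rba_problem(
            network, kapp, max(0.0, lo - tol_mu), condition, machineries, budgets,
            forced=forced,
        )
        sol = solve_feasible(problem, objective="min_total_enzyme")
    return sol


def growth_summary(
    solution: RBASolution,
    network: ReactionNetwork,
    condition: Condition,
    co2_exchange: str = "EX_co2",
) -> dict[str, float]:
    """Report mu, substrate uptake q_S (g gDCW^-1 hr^-1), biomass yield
    (gDCW per g substrate) and net CO2 exchange flux (positive = emission)."""
    ex = condition.substrate_exchange
    uptake = -solution.fluxes.get(ex, 0.0) if ex else float("nan")
    mass = network.substrate_mass.get(ex, float("nan")) if ex else float("nan")
    q_s = uptake * mass
    co2_net = solution.fluxes.get(co2_exchange, 0.0)
    return {
        "mu": solution.mu,
        "uptake_flux": uptake,
        "q_s": q_s,
        "yield_gdcw_per_g": solution.mu / q_s if q_s > 0 else float("nan"),
        "net_co2_emission": co2_net,
    }


def simulate_forced_flux(
    network: ReactionNetwork,
    kapp,
    condition: Condition,
    forced: dict[str, float],
    machineries: list[Machinery] = (),
    budgets: list[CompartmentBudget] = (),
    tol_mu: float = MU_TOL,
) -> tuple[RBASolution, dict[str, float]]:
    """Maximize growth with the given net fluxes pinned by equality constraints.

    Returns the solution and its growth summary (mu, yield, net CO2 exchange).
    An infeasible forcing yields a solution with status "infeasible".
    """
    try:
        sol = maximize_growth(
            network, kapp, condition, machineries, budgets, tol_mu=tol_mu,
            forced=forced,
        )
    except RBAError as exc:
        sol = RBASolution(status="infeasible", mu=0.0,
                          condition=condition.name, message=str(exc))
    if not sol.feasible:
        return sol, {"mu": float("nan"), "q_s": float("nan"),
                     "yield_gdcw_per_g": float("nan"),
                     "net_co2_emission": float("nan"), "uptake_flux": float("nan")}
    return sol, growth_summary(sol, network, condition)
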