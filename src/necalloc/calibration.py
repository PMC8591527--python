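"""Apparent catalytic rate (k_app) calibration and the randomized-k_app ensemble.

k_app links flux to enzyme demand (v = k_app * [E]).  It is estimated per
reaction direction as the maximum flux per unit measured enzyme over all
conditions, where flux envelopes come from uniform sampling of the feasible
flux polytope (flux sampling analysis) with growth fixed to the chemostat
dilution rate.  Reactions with no flux or no measured enzyme receive the
median of the fitted distribution, flagged as median-filled.

The randomized ensemble re-draws every reaction's k_app from the pooled
empirical distribution of fitted values; solving the growth model over such an
ensemble yields the sets of reactions that are utilizable at all
(union), always (core), or only under one substrate (condition-unique).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Condition, ReactionNetwork

FLUX_TOL = 1e-6


@dataclass
class KappEntry:
    kapp: float  # hr^-1
    provenance: str  # "fitted" | "median_filled" | "truth" | "sampled"
    condition: str | None = None  # condition of the maximizing flux

    def __post_init__(self) -> None:
        if not self.kapp > 0:
            raise ValueError("k_app must be positive")


@dataclass
class KappTable:
    """Per-reaction-direction apparent catalytic rates with provenance."""

    entries: dict[tuple[str, str], KappEntry] = field(default_factory=dict)

    def value(self, reaction: str, direction: str = "fwd") -> float:
        return self.entries[(reaction, direction)].kapp

    def get(self, reaction: str, direction: str = "fwd", default=None):
        entry = self.entries.get((reaction, direction))
        return entry.kapp if entry else default

    def fitted_values(self) -> np.ndarray:
        return np.array(
            [e.kapp for e in self.entries.values() if e.provenance == "fitted"]
        )

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_values(cls, values: dict, provenance: str = "fitted") -> "KappTable":
        """Build from {(reaction, direction): kapp} or {reaction: kapp}."""
        entries = {}
        for key, v in values.items():
            rxn, d = key if isinstance(key, tuple) else (key, "fwd")
            entries[(rxn, d)] = KappEntry(float(v), provenance)
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": r, "direction": d, "kapp_hr": e.kapp,
             "provenance": e.provenance, "condition": e.condition}
            for (r, d), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["reaction", "direction", "kapp_hr",
                                           "provenance", "condition"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "KappTable":
        df = pd.read_csv(path, sep="\t")
        entries = {}
        for _, row in df.iterrows():
            cond = row.get("condition")
            entries[(row["reaction"], row["direction"])] = KappEntry(
                float(row["kapp_hr"]), str(row["provenance"]),
                None if pd.isna(cond) else str(cond),
            )
        return cls(entries)


# ---------------------------------------------------------------------------
# flux sampling


@dataclass
class FluxSamples:
    """Sampled feasible flux vectors of one condition plus their envelope."""

    condition: str
    samples: pd.DataFrame  # rows: samples, columns: reactions (net flux)
    envelope: pd.DataFrame  # index: reactions, columns: min, max
    fva: pd.DataFrame | None = None  # independent FVA bounds, same layout


def _condition_model(
    network: ReactionNetwork,
    condition: Condition,
    fix_growth: bool = True,
    fixed_fluxes: dict[str, float] | None = None,
    flux_slack: float = 0.001,
):
    """Build a cobra model of the metabolic polytope under a condition.

    Growth is fixed to the dilution rate, maintenance to its demand, and any
    ``fixed_fluxes`` (e.g. the measured substrate uptake of a chemostat) to a
    +/- ``flux_slack`` relative band, mirroring measurement precision.
    """
    from .io import to_cobra

    model = to_cobra(network)
    for rid, (lb, ub) in condition.exchange_bounds.items():
        model.reactions.get_by_id(rid).bounds = (lb, ub)
    mu = condition.dilution_rate
    if fix_growth:
        model.reactions.get_by_id(network.biomass_reaction).bounds = (mu, mu)
        if network.phb_reaction:
            v = network.phb_demand * mu
            model.reactions.get_by_id(network.phb_reaction).bounds = (v, v)
        m = network.maintenance.ngam + network.maintenance.gam * mu
        model.reactions.get_by_id(network.maintenance_reaction).bounds = (
            m, m * (1 + flux_slack) + 1e-9)
    for rid, v in (fixed_fluxes or {}).items():
        slack = abs(v) * flux_slack + 1e-9
        model.reactions.get_by_id(rid).bounds = (v - slack, v + slack)
    return model


def sample_flux_space(
    network: ReactionNetwork,
    condition: Condition,
    n_samples: int = 1000,
    seed: int = 0,
    fixed_fluxes: dict[str, float] | None = None,
    flux_slack: float = 0.001,
    thinning: int = 100,
    with_fva: bool = True,
) -> FluxSamples:
    """Uniform-target sampling of the feasible flux polytope (ACHR hit-and-run
    with warm-up), with growth fixed to the condition's dilution rate.

    Returns the sample matrix, the per-reaction min/max envelope, and (by
    default) independently computed FVA bounds as a cross-check.
    """
    from cobra.flux_analysis import flux_variability_analysis
    from cobra.sampling import ACHRSampler

    model = _condition_model(network, condition, fixed_fluxes=fixed_fluxes,
                             flux_slack=flux_slack)
    sol = model.optimize()
    if sol.status != "optimal":
        raise ValueError(f"condition {condition.name} is infeasible")
    try:
        sampler = ACHRSampler(model, thinning=thinning, seed=seed)
        samples = sampler.sample(n_samples)
    except ValueError:
        # fully determined polytope (all fluxes pinned by the chemostat
        # constraints): the unique feasible point is the sample
        samples = pd.DataFrame(
            np.tile(sol.fluxes.to_numpy(), (n_samples, 1)),
            columns=sol.fluxes.index,
        )
    envelope = pd.DataFrame({"min": samples.min(axis=0), "max": samples.max(axis=0)})
    fva = None
    if with_fva:
        fva = flux_variability_analysis(model, fraction_of_optimum=0.0)
        fva = fva.rename(columns={"minimum": "min", "maximum": "max"})
    return FluxSamples(condition=condition.name, samples=samples,
                       envelope=envelope, fva=fva)


# ---------------------------------------------------------------------------
# enzyme abundance allocation and k_app estimation


def enzyme_concentrations(
    network: ReactionNetwork, protein_conc: pd.Series | dict
) -> dict[str, float]:
    """Translate measured protein abundances into per-enzyme concentrations.

    A protein shared by several enzymes has its abundance split equally among
    them; an enzyme's concentration is limited by its scarcest subunit
    (abundance / copies).  Enzymes with any unmeasured subunit get NaN.
    """
    conc = dict(protein_conc)
    n_uses: dict[str, int] = {}
    for enz in network.enzymes.values():
        for p in enz.composition:
            n_uses[p] = n_uses.get(p, 0) + 1
    out: dict[str, float] = {}
    for eid, enz in network.enzymes.items():
        parts = []
        for p, copies in enz.composition.items():
            if p not in conc or pd.isna(conc[p]):
                parts = None
                break
            parts.append(conc[p] / n_uses[p] / copies)
        out[eid] = min(parts) if parts else float("nan")
    return out


def reaction_enzyme_concentrations(
    network: ReactionNetwork, protein_conc: pd.Series | dict
) -> dict[str, float]:
    """Measured enzyme concentration per reaction: sum over GPR alternatives."""
    per_enzyme = enzyme_concentrations(network, protein_conc)
    out = {}
    for rid in network.enzymatic_reactions():
        vals = [per_enzyme[eid] for eid in network.gpr[rid]]
        vals = [v for v in vals if not pd.isna(v)]
        out[rid] = sum(vals) if vals else float("nan")
    return out


def estimate_kapp(
    samples: dict[str, FluxSamples],
    proteomes: dict[str, "pd.Series | dict"],
    network: ReactionNetwork,
    envelope: str = "samples",
    flux_tol: float = FLUX_TOL,
) -> KappTable:
    """Estimate k_app as the maximum flux per unit enzyme over all conditions.

    ``proteomes`` maps condition -> per-protein mean abundance (mmol gDCW^-1);
    conditions must match the keys of ``samples``.  ``envelope`` selects the
    flux bound source: the sampled envelope (default) or the FVA cross-check
    (``"fva"``).  Reaction directions with no flux or no measured enzyme get
    the median of the fitted distribution, flagged ``median_filled``.
    """
    if set(samples) != set(proteomes):
        raise ValueError("conditions of samples and proteomes do not align")
    if envelope not in ("samples", "fva"):
        raise ValueError("envelope must be 'samples' or 'fva'")

    conc_by_cond = {
        cond: reaction_enzyme_concentrations(network, prot)
        for cond, prot in proteomes.items()
    }
    entries: dict[tuple[str, str], KappEntry] = {}
    pending: list[tuple[str, str]] = []
    for rxn in network.reactions:
        rid = rxn.id
        if not network.gpr.get(rid):
            continue
        directions = ["fwd"]
        if rxn.reversible or rxn.lower_bound < 0:
            directions.append("bwd")
        for d in directions:
            best, best_cond = 0.0, None
            for cond, fs in samples.items():
                env = fs.fva if envelope == "fva" else fs.envelope
                if env is None or rid not in env.index:
                    continue
                vmax = env.loc[rid, "max"] if d == "fwd" else -env.loc[rid, "min"]
                conc = conc_by_cond[cond].get(rid, float("nan"))
                if vmax > flux_tol and conc > 0 and not pd.isna(conc):
                    k = vmax / conc
                    if k > best:
                        best, best_cond = k, cond
            if best > 0:
                entries[(rid, d)] = KappEntry(best, "fitted", best_cond)
            else:
                pending.append((rid, d))

    fitted = [e.kapp for e in entries.values()]
    if not fitted:
        raise ValueError("no k_app could be fitted from the given data")
    med = float(np.median(fitted))
    for key in pending:
        entries[key] = KappEntry(med, "median_filled")
    return KappTable(entries)


def sample_kapp_ensemble(
    kapp: KappTable, n: int = 200, seed: int = 0
) -> list[KappTable]:
    """Randomized-k_app ensemble: each draw reassigns every reaction direction
    a value resampled with replacement, independently per reaction, from the
    empirical distribution of fitted k_app values."""
    if not len(kapp):
        raise ValueError("empty k_app table")
    pool = kapp.fitted_values()
    if pool.size == 0:
        pool = np.array([e.kapp for e in kapp.entries.values()])
    rng = np.random.default_rng(seed)
    keys = sorted(kapp.entries)
    out = []
    for _ in range(n):
        draw = rng.choice(pool, size=len(keys), replace=True)
        out.append(
            KappTable({k: KappEntry(float(v), "sampled") for k, v in zip(keys, draw)})
        )
    return out


# ---------------------------------------------------------------------------
# ensemble bookkeeping


@dataclass
class UtilizationEnsembleSummary:
    """Sets of reactions carrying flux across an ensemble of simulations."""

    per_condition: dict[str, set[str]]
    union: set[str]
    core: set[str]
    condition_unique: dict[str, set[str]]

    @property
    def counts(self) -> dict[str, int]:
        out = {"union": len(self.union), "core": len(self.core)}
        for cond, s in sorted(self.per_condition.items()):
            out[f"used_{cond}"] = len(s)
        out["unique_total"] = sum(len(s) for s in self.condition_unique.values())
        return out


def count_utilized_reactions(
    solutions: dict[str, list], flux_tol: float = FLUX_TOL
) -> UtilizationEnsembleSummary:
    """Summarize which reactions carry flux in an ensemble of RBA solutions
    grouped by condition.

    A reaction is "used" in a condition if |v| > flux_tol in at least one
    ensemble member; "core" if used in every simulation of every condition;
    "condition-unique" if used in exactly one condition's set.
    """
    per_condition: dict[str, set[str]] = {}
    core: set[str] | None = None
    for cond, sols in solutions.items():
        used: set[str] = set()
        for sol in sols:
            if not sol.feasible:
                raise ValueError(f"infeasible solution in ensemble for {cond}")
            active = sol.active_reactions(flux_tol)
            used |= active
            core = active if core is None else core & active
        per_condition[cond] = used
    union = set().union(*per_condition.values()) if per_condition else set()
    unique = {
        cond: {
            r for r in s
            if not any(r in other for c2, other in per_condition.items() if c2 != cond)
        }
        for cond, s in per_condition.items()
    }
    return UtilizationEnsembleSummary(
        per_condition=per_condition, union=union, core=core or set(),
        condition_unique=unique,
    )
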