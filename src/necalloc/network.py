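"""Metabolic network container with gene-protein-reaction map and proteome-related
annotations.

The network is the shared input of the growth model, the flux sampler and the
calibration step.  It is deliberately close to a constraint-based (FBA) model --
stoichiometry, reversibility, bounds -- extended with the quantities a resource
balance analysis needs: enzyme composition and size, macromolecular machinery,
and growth-rate-dependent compartment protein budgets.

Concentration and flux units follow the gDCW convention of bacterial physiology:
fluxes in mmol gDCW^-1 hr^-1, enzyme/machinery concentrations in mmol gDCW^-1,
protein pools in mmol amino acids gDCW^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

# mean amino-acid residue mass, g mol^-1
MEAN_RESIDUE_MASS = 110.0


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    boundary: bool = False
    #: electron content per unit (degree of reduction x carbon for C species,
    #: 2 for NADH-like carriers, -4 for O2); used by the electron-balance audit
    electrons: float = 0.0


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    #: pseudo reactions (exchange, biomass, maintenance, demand) carry no enzyme
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower bound > upper bound")


@dataclass
class EnzymeSpec:
    """One catalytically sufficient protein complex (a single GPR alternative)."""

    id: str
    composition: dict[str, int]  # gene/protein -> subunit copies
    length: int  # total amino acids per complex
    compartment: str = "cytoplasm"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"enzyme {self.id}: length must be positive")

    @property
    def mw(self) -> float:
        """Molecular weight in g mmol^-1."""
        return self.length * MEAN_RESIDUE_MASS / 1000.0


@dataclass
class Machinery:
    """Macromolecular machine (ribosome, chaperone, RNA/DNA polymerase).

    ``rate`` is process units per hour per machine (ribosome: amino acids
    polymerised hr^-1).  ``demand_kind`` selects what the machine must keep up
    with at growth rate mu:

    - ``"protein"``: demand = mu * demand_coeff * total protein amino-acid
      concentration (ribosome: coeff 1; chaperone: the folded fraction)
    - ``"fixed"``: demand = mu * demand_coeff (e.g. RNA nucleotides per gDCW)
    """

    id: str
    composition: dict[str, int]
    length: int  # amino acids per machine
    rate: float  # units hr^-1 per machine
    demand_kind: str = "protein"
    demand_coeff: float = 1.0
    compartment: str = "cytoplasm"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"machinery {self.id}: rate must be positive")
        if self.demand_kind not in ("protein", "fixed"):
            raise ValueError(f"machinery {self.id}: unknown demand kind {self.demand_kind}")


@dataclass
class LinearModel:
    """Fraction model intercept + slope * mu, clipped to [0, 1] on evaluation."""

    intercept: float
    slope: float = 0.0

    def __call__(self, mu: float) -> float:
        return min(1.0, max(0.0, self.intercept + self.slope * mu))


@dataclass
class CompartmentBudget:
    """Protein budget of one compartment as a function of growth rate.

    The enzyme+machinery capacity of compartment c is
    ``fraction(mu) * (1 - non_enzymatic(mu)) * pool`` in mmol amino acids
    gDCW^-1, where ``pool`` is the total cellular protein pool.
    """

    compartment: str
    pool: float  # mmol amino acids gDCW^-1 (total cell protein)
    fraction: LinearModel = field(default_factory=lambda: LinearModel(1.0))
    non_enzymatic: LinearModel = field(default_factory=lambda: LinearModel(0.0))

    def capacity(self, mu: float) -> float:
        return self.fraction(mu) * (1.0 - self.non_enzymatic(mu)) * self.pool

    def reserve(self, mu: float) -> float:
        """Non-enzymatic protein of this compartment, mmol aa gDCW^-1."""
        return self.fraction(mu) * self.non_enzymatic(mu) * self.pool


@dataclass
class Maintenance:
    ngam: float = 0.0  # non-growth associated ATP, mmol gDCW^-1 hr^-1
    gam: float = 0.0  # growth associated ATP, mmol gDCW^-1 (per unit mu)


@dataclass
class Condition:
    """A growth condition: substrate bounds and the chemostat dilution rate."""

    name: str
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    dilution_rate: float = 0.1
    #: id of the limiting substrate exchange reaction (used for yield reporting)
    substrate_exchange: str | None = None


@dataclass
class ReactionNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    #: reaction id -> list of enzyme ids (isoenzyme alternatives)
    gpr: dict[str, list[str]] = field(default_factory=dict)
    enzymes: dict[str, EnzymeSpec] = field(default_factory=dict)
    #: gene/protein -> length in amino acids
    proteins: dict[str, int] = field(default_factory=dict)
    #: biomass composition, metabolite -> mmol per gDCW
    biomass: dict[str, float] = field(default_factory=dict)
    biomass_reaction: str = "BIOMASS"
    maintenance: Maintenance = field(default_factory=Maintenance)
    maintenance_reaction: str = "ATPM"
    #: growth-rate-coupled PHB demand, mmol gDCW^-1 per unit mu
    phb_demand: float = 0.0
    phb_reaction: str | None = None
    #: grams per flux unit of substrate exchanges (for yield in gDCW / g)
    substrate_mass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - met_ids
            if missing:
                raise ValueError(
                    f"reaction {rxn.id} references undeclared metabolites {sorted(missing)}"
                )
        for coef in self.biomass.values():
            if coef < 0:
                raise ValueError("biomass coefficients must be >= 0")
        for rid, alts in self.gpr.items():
            for eid in alts:
                if eid not in self.enzymes:
                    raise ValueError(f"reaction {rid}: unknown enzyme {eid}")

    # -- lookups -----------------------------------------------------------
    @property
    def reaction_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def metabolite_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.boundary]

    def enzymatic_reactions(self) -> list[str]:
        return [r.id for r in self.reactions if self.gpr.get(r.id)]

    def genes(self) -> list[str]:
        out: set[str] = set()
        for enz in self.enzymes.values():
            out.update(enz.composition)
        return sorted(out)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "metabolites": [asdict(m) for m in self.metabolites],
            "reactions": [asdict(r) for r in self.reactions],
            "gpr": self.gpr,
            "enzymes": {
                eid: asdict(e) for eid, e in sorted(self.enzymes.items())
            },
            "proteins": self.proteins,
            "biomass": self.biomass,
            "biomass_reaction": self.biomass_reaction,
            "maintenance": asdict(self.maintenance),
            "maintenance_reaction": self.maintenance_reaction,
            "phb_demand": self.phb_demand,
            "phb_reaction": self.phb_reaction,
            "substrate_mass": self.substrate_mass,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionNetwork":
        return cls(
            metabolites=[Metabolite(**m) for m in data["metabolites"]],
            reactions=[Reaction(**r) for r in data["reactions"]],
            gpr={k: list(v) for k, v in data.get("gpr", {}).items()},
            enzymes={
                eid: EnzymeSpec(**e) for eid, e in data.get("enzymes", {}).items()
            },
            proteins=dict(data.get("proteins", {})),
            biomass=dict(data.get("biomass", {})),
            biomass_reaction=data.get("biomass_reaction", "BIOMASS"),
            maintenance=Maintenance(**data.get("maintenance", {})),
            maintenance_reaction=data.get("maintenance_reaction", "ATPM"),
            phb_demand=data.get("phb_demand", 0.0),
            phb_reaction=data.get("phb_reaction"),
            substrate_mass=dict(data.get("substrate_mass", {})),
        )

    @classmethod
    def from_json(cls, source) -> "ReactionNetwork":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        return cls.from_dict(data)

    # -- audits ------------------------------------------------------------
    def electron_imbalance(self) -> dict[str, float]:
        """Electron-balance audit: sum of electron contents over each
        non-pseudo reaction's stoichiometry.  Balanced chemistry gives 0."""
        electrons = {m.id: m.electrons for m in self.metabolites}
        out = {}
        for rxn in self.reactions:
            if rxn.pseudo:
                continue
            out[rxn.id] = sum(
                coef * electrons.get(met, 0.0) for met, coef in rxn.stoichiometry.items()
            )
        return out
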