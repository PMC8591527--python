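"""Synthetic data generators with known ground truth.

Every analysis stage in this package (growth modelling, k_app calibration,
utilization scoring, essentiality classification, fitness scoring) is exercised
on data produced here, so each generator emulates the statistical structure the
corresponding analysis assumes:

- a toy metabolic network with lumped central-carbon pathways of a facultative
  chemolithoautotroph (ED glycolysis, CBB cycle, TCA, formate dehydrogenase,
  oxidative phosphorylation, PHB synthesis) whose stoichiometry is
  electron-balanced so that gratuitous CO2 refixation cannot pay for itself;
- steady-state chemostat proteomes derived from RBA solutions under
  multiplicative lognormal noise, with per-enzyme "excess factors" that create
  known under-utilization;
- transposon insertion libraries with a bimodal per-gene insertion-rate
  structure (essential vs non-essential);
- barcode count matrices drifting under exponential selection with known
  per-gene fitness.

Carbon species are tracked in C-mmol so that degree-of-reduction bookkeeping is
per C-mol; NADH carries 2 electrons, O2 accepts 4.  The fructose-like substrate
has degree of reduction 4.0 per C-mol and biomass 4.12 per C-mol (40 C-mmol
precursor + 2.4 mmol NADH per gDCW), so extra CO2 fixation always costs more
reducing power than it returns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import KappTable
from .network import (
    CompartmentBudget,
    Condition,
    EnzymeSpec,
    LinearModel,
    Machinery,
    Maintenance,
    Metabolite,
    Reaction,
    ReactionNetwork,
)

# protein lengths (amino acids) of the toy genes
_PROTEIN_LENGTHS = {
    "fruT": 450, "forT": 380, "sucT": 420,
    "edd": 450, "eda": 450,
    "sdhA": 820,
    "fdsA": 1000, "fdhS": 550,
    "cbbL": 470, "cbbS": 110, "prk": 290,
    "tcaL": 1500,
    "oxpL": 2000,
    "phaC": 590,
}

#: ground-truth apparent catalytic rates of the toy network, hr^-1
TOY_KAPP_TRUE = {
    "FRUt": 30000.0, "FORt": 25000.0, "SUCt": 25000.0,
    "ED": 12000.0, "SCD": 14000.0, "FDH": 18000.0,
    "CBB": 14000.0, "TCA": 20000.0, "OXP": 45000.0, "PHBS": 8000.0,
}


@dataclass
class ToyNetworkConfig:
    n_substrates: int = 3  # fructose-like, formate-like, succinate-like
    include_cbb: bool = True
    include_phb: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_substrates <= 3:
            raise ValueError("n_substrates must be 1-3")


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic dataset."""

    kapp_true: dict = field(default_factory=dict)  # reaction -> hr^-1 (or enzyme map)
    essential_genes: set = field(default_factory=set)
    fitness_true: dict = field(default_factory=dict)  # gene -> F (log2 units)
    utilization_true: dict = field(default_factory=dict)  # enzyme -> percent


def _met(mid, electrons=0.0):
    return Metabolite(id=mid, compartment="c", electrons=electrons)


def gen_toy_network(config: ToyNetworkConfig | None = None) -> ReactionNetwork:
    """Build the toy central-carbon network (deterministic for a fixed seed).

    Every internal conversion is electron-balanced; the only unbalanced rows
    are pseudo reactions (exchanges, biomass, maintenance).
    """
    config = config or ToyNetworkConfig()
    substrates = ["fructose", "formate", "succinate"][: config.n_substrates]

    mets = [
        _met("pre_c", 4.0),   # biomass precursor, carbohydrate-level reduction
        _met("co2_c", 0.0),
        _met("nadh_c", 2.0),
        _met("atp_c", 0.0),
        _met("o2_c", -4.0),
    ]
    rxns: list[Reaction] = []
    gpr: dict[str, list[str]] = {}
    enzymes: dict[str, EnzymeSpec] = {}

    def enzymatic(rid, stoich, enz_specs, lb=0.0, ub=1000.0):
        rxns.append(Reaction(rid, stoich, lower_bound=lb, upper_bound=ub))
        gpr[rid] = [e.id for e in enz_specs]
        for e in enz_specs:
            enzymes[e.id] = e

    def pseudo(rid, stoich, lb=0.0, ub=1000.0):
        rxns.append(Reaction(rid, stoich, lower_bound=lb, upper_bound=ub, pseudo=True))

    def complex_length(comp):
        return sum(_PROTEIN_LENGTHS[g] * n for g, n in comp.items())

    def enzyme(eid, comp, compartment="cytoplasm"):
        return EnzymeSpec(eid, comp, complex_length(comp), compartment)

    if "fructose" in substrates:
        mets.append(_met("fru_c", 4.0))
        mets.append(_met("fru_e", 4.0))
        pseudo("EX_fru", {"fru_e": -1.0}, lb=-1000.0, ub=0.0)
        enzymatic("FRUt", {"fru_e": -1.0, "fru_c": 1.0},
                  [enzyme("E_FRUt", {"fruT": 1}, "membrane")])
        # lumped ED glycolysis: fructose -> precursor + CO2 + NADH + ATP
        enzymatic("ED", {"fru_c": -1.0, "pre_c": 5 / 6, "co2_c": 1 / 6,
                         "nadh_c": 1 / 3, "atp_c": 0.5},
                  [enzyme("E_ED", {"edd": 1, "eda": 1})])
    if "formate" in substrates:
        mets.append(_met("for_c", 2.0))
        mets.append(_met("for_e", 2.0))
        pseudo("EX_for", {"for_e": -1.0}, lb=-1000.0, ub=0.0)
        enzymatic("FORt", {"for_e": -1.0, "for_c": 1.0},
                  [enzyme("E_FORt", {"forT": 1}, "membrane")])
        # formate dehydrogenase, two isoenzymes
        enzymatic("FDH", {"for_c": -1.0, "co2_c": 1.0, "nadh_c": 1.0},
                  [enzyme("E_FDH_fds", {"fdsA": 1}),
                   enzyme("E_FDH_fdh", {"fdhS": 1})])
    if "succinate" in substrates:
        mets.append(_met("suc_c", 3.5))
        mets.append(_met("suc_e", 3.5))
        pseudo("EX_suc", {"suc_e": -1.0}, lb=-1000.0, ub=0.0)
        enzymatic("SUCt", {"suc_e": -1.0, "suc_c": 1.0},
                  [enzyme("E_SUCt", {"sucT": 1}, "membrane")])
        enzymatic("SCD", {"suc_c": -1.0, "pre_c": 0.75, "co2_c": 0.25,
                          "nadh_c": 0.25, "atp_c": 0.25},
                  [enzyme("E_SCD", {"sdhA": 1})])

    mets.append(_met("co2_e", 0.0))
    mets.append(_met("o2_e", -4.0))
    pseudo("EX_co2", {"co2_e": -1.0}, lb=-1000.0, ub=1000.0)
    pseudo("EX_o2", {"o2_e": -1.0}, lb=-1000.0, ub=0.0)
    pseudo("CO2t", {"co2_e": -1.0, "co2_c": 1.0}, lb=-1000.0, ub=1000.0)
    pseudo("O2t", {"o2_e": -1.0, "o2_c": 1.0}, lb=0.0, ub=1000.0)

    if config.include_cbb:
        # lumped CBB cycle: CO2 + 2 NADH + 3 ATP -> precursor
        enzymatic("CBB", {"co2_c": -1.0, "nadh_c": -2.0, "atp_c": -3.0,
                          "pre_c": 1.0},
                  [enzyme("E_CBB", {"cbbL": 2, "cbbS": 2, "prk": 1})])
    # lumped TCA: precursor -> CO2 + 2 NADH + ATP/2
    enzymatic("TCA", {"pre_c": -1.0, "co2_c": 1.0, "nadh_c": 2.0, "atp_c": 0.5},
              [enzyme("E_TCA", {"tcaL": 1})])
    # oxidative phosphorylation: NADH + 1/2 O2 -> 2 ATP
    enzymatic("OXP", {"nadh_c": -1.0, "o2_c": -0.5, "atp_c": 2.0},
              [enzyme("E_OXP", {"oxpL": 1}, "membrane")])

    biomass = {"pre_c": 40.0, "nadh_c": 2.4}  # degree of reduction 4.12 per C-mol
    pseudo("BIOMASS", {m: -c for m, c in biomass.items()}, lb=0.0, ub=1000.0)
    pseudo("ATPM", {"atp_c": -1.0}, lb=0.0, ub=1000.0)

    phb_reaction = None
    phb_demand = 0.0
    if config.include_phb:
        mets.append(_met("phb_c", 4.5))
        enzymatic("PHBS", {"pre_c": -1.0, "nadh_c": -0.25, "phb_c": 1.0},
                  [enzyme("E_PHBS", {"phaC": 1})])
        pseudo("EX_phb", {"phb_c": -1.0}, lb=0.0, ub=1000.0)
        phb_reaction = "PHBS"
        phb_demand = 3.0  # mmol gDCW^-1 per unit mu

    substrate_mass = {  # g per C-mmol (formate: per mmol, C1)
        "EX_fru": 0.030, "EX_for": 0.046, "EX_suc": 0.0295,
    }
    return ReactionNetwork(
        metabolites=mets,
        reactions=rxns,
        gpr=gpr,
        enzymes=enzymes,
        proteins=dict(_PROTEIN_LENGTHS),
        biomass=biomass,
        biomass_reaction="BIOMASS",
        maintenance=Maintenance(ngam=3.0, gam=90.0),
        maintenance_reaction="ATPM",
        phb_demand=phb_demand,
        phb_reaction=phb_reaction,
        substrate_mass={k: v for k, v in substrate_mass.items()
                        if any(k.endswith(s[:3]) for s in substrates)},
    )


def toy_kapp_true(network: ReactionNetwork) -> KappTable:
    """Ground-truth k_app table for the toy network."""
    flat = {(rid, "fwd"): TOY_KAPP_TRUE[rid] for rid in network.enzymatic_reactions()}
    return KappTable.from_values(flat, provenance="truth")


def toy_machineries() -> list[Machinery]:
    """Macromolecular machines with rates in the range of published bacterial
    values (ribosome ~10 aa/s; polymerases scaled to fixed RNA/DNA demand)."""
    return [
        Machinery("ribosome", {"rpl": 55, "rps": 35}, length=7500,
                  rate=36000.0, demand_kind="protein", demand_coeff=1.0),
        Machinery("chaperone", {"groL": 14}, length=3500,
                  rate=30000.0, demand_kind="protein", demand_coeff=0.1),
        Machinery("rna_polymerase", {"rpoB": 2, "rpoC": 1}, length=3500,
                  rate=198000.0, demand_kind="fixed", demand_coeff=0.588),
        Machinery("dna_polymerase", {"dnaE": 4}, length=4000,
                  rate=2.16e6, demand_kind="fixed", demand_coeff=0.097),
    ]


def toy_budgets(pool: float = 6.18) -> list[CompartmentBudget]:
    """Compartment protein budgets: 6.18 mmol aa gDCW^-1 total pool split by
    growth-rate-dependent cytoplasm/membrane fractions, with declining
    non-enzymatic fractions (cells shed reserve proteome as they grow faster)."""
    return [
        CompartmentBudget("cytoplasm", pool,
                          fraction=LinearModel(0.73, 0.02),
                          non_enzymatic=LinearModel(0.55, -0.25)),
        CompartmentBudget("membrane", pool,
                          fraction=LinearModel(0.25, -0.02),
                          non_enzymatic=LinearModel(0.40, -0.10)),
    ]


def toy_conditions() -> dict[str, Condition]:
    """Substrate-limited chemostat conditions (uptake caps generous enough
    that the protein budget, not transport, limits growth)."""
    return {
        "fructose": Condition(
            "fructose", {"EX_fru": (-24.0, 0.0), "EX_for": (0.0, 0.0),
                         "EX_suc": (0.0, 0.0)},
            dilution_rate=0.25, substrate_exchange="EX_fru"),
        "succinate": Condition(
            "succinate", {"EX_suc": (-32.0, 0.0), "EX_fru": (0.0, 0.0),
                          "EX_for": (0.0, 0.0)},
            dilution_rate=0.25, substrate_exchange="EX_suc"),
        "formate": Condition(
            "formate", {"EX_for": (-60.0, 0.0), "EX_fru": (0.0, 0.0),
                        "EX_suc": (0.0, 0.0)},
            dilution_rate=0.05, substrate_exchange="EX_for"),
    }


def toy_forced_condition(uptake_cap: float = 10.0) -> Condition:
    """Fructose condition for forced CO2-fixation scenarios: the uptake cap is
    low enough that substrate supply (not the protein budget) limits growth,
    so the carbon input stays pinned while forced CBB flux diverts energy --
    the toy equivalent of simulating at a fixed fructose uptake rate."""
    return Condition(
        "fructose_forced",
        {"EX_fru": (-uptake_cap, 0.0), "EX_for": (0.0, 0.0), "EX_suc": (0.0, 0.0)},
        dilution_rate=0.25, substrate_exchange="EX_fru",
    )


# ---------------------------------------------------------------------------
# proteomes


@dataclass
class ProteomeMeasurement:
    """Per-protein abundances (mmol gDCW^-1) across replicates of a condition."""

    condition: str
    data: pd.DataFrame  # rows: proteins, columns: replicate_1..n

    @property
    def mean(self) -> pd.Series:
        return self.data.mean(axis=1)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def gen_proteome(
    solution,
    network: ReactionNetwork,
    noise_cv: float = 0.1,
    n_replicates: int = 4,
    seed: int = 0,
    excess: dict[str, float] | None = None,
    machineries: list[Machinery] = (),
    machinery_excess: dict[str, float] | None = None,
    condition: str | None = None,
) -> tuple[ProteomeMeasurement, GroundTruth]:
    """Synthesize a measured proteome from an RBA solution.

    Per-protein abundance is the RBA-predicted abundance times mean-1
    lognormal noise with the given CV.  ``excess`` inflates individual enzymes
    (factor >= 1), creating a known utilization of 100/excess percent.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    excess = dict(excess or {})
    machinery_excess = dict(machinery_excess or {})
    for eid, f in {**excess, **machinery_excess}.items():
        if f < 1.0:
            raise ValueError(f"excess factor for {eid} must be >= 1")

    rng = np.random.default_rng(seed)
    protein_conc: dict[str, float] = {}
    utilization_true: dict[str, float] = {}
    for eid, conc in solution.enzymes.items():
        factor = excess.get(eid, 1.0)
        if conc > 0:
            utilization_true[eid] = 100.0 / factor
        for prot, copies in network.enzymes[eid].composition.items():
            protein_conc[prot] = protein_conc.get(prot, 0.0) + copies * conc * factor
    mach_by_id = {m.id: m for m in machineries}
    for mid, conc in getattr(solution, "machineries", {}).items():
        if mid not in mach_by_id:  # machinery proteins not requested
            continue
        factor = machinery_excess.get(mid, 1.0)
        if conc > 0:
            utilization_true[mid] = 100.0 / factor
        for prot, copies in mach_by_id[mid].composition.items():
            protein_conc[prot] = protein_conc.get(prot, 0.0) + copies * conc * factor

    proteins = sorted(protein_conc)
    base = np.array([protein_conc[p] for p in proteins])
    noise = _lognormal_noise(rng, noise_cv, (len(proteins), n_replicates))
    data = pd.DataFrame(
        base[:, None] * noise,
        index=proteins,
        columns=[f"replicate_{i + 1}" for i in range(n_replicates)],
    )
    name = condition or (solution.condition or "condition")
    return (
        ProteomeMeasurement(condition=name, data=data),
        GroundTruth(utilization_true=utilization_true),
    )


# ---------------------------------------------------------------------------
# transposon insertion libraries


@dataclass
class InsertionTable:
    """Per-gene transposon insertion data along a replicon."""

    genes: pd.DataFrame  # columns: gene, order, length_bp
    positions: dict[str, np.ndarray]  # gene -> insertion positions (ORF fraction)

    @property
    def counts(self) -> pd.Series:
        return pd.Series(
            {g: len(self.positions[g]) for g in self.genes["gene"]}, name="n_insertions"
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.genes.copy()
        out["n_insertions"] = self.counts.loc[out["gene"]].to_numpy()
        out["positions"] = [
            ";".join(f"{p:.6f}" for p in self.positions[g]) for g in out["gene"]
        ]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InsertionTable":
        positions = {}
        for _, row in df.iterrows():
            raw = row.get("positions", "")
            positions[row["gene"]] = (
                np.array([float(x) for x in str(raw).split(";") if x not in ("", "nan")])
                if isinstance(raw, str) and raw
                else np.zeros(0)
            )
        return cls(genes=df[["gene", "order", "length_bp"]].copy(), positions=positions)


def gen_insertion_library(
    n_genes: int = 500,
    frac_essential: float = 0.1,
    mean_rate: float = 16.0,  # insertions per kb (dense pooled library)
    essential_rate_ratio: float = 0.02,
    seed: int = 0,
    gene_effect_shape: float = 10.0,
) -> tuple[InsertionTable, GroundTruth]:
    """Simulate a dense transposon library with bimodal insertion rates.

    Gene lengths are lognormal (median ~0.95 kb); per-gene insertion counts are
    Poisson with rate length_kb * mean_rate * a gamma-distributed gene effect
    (mean 1), scaled down by ``essential_rate_ratio`` for essential genes.
    Insertion positions are uniform within the ORF so the central-80% filter is
    exercisable.
    """
    if not 0 < frac_essential < 1:
        raise ValueError("frac_essential must be in (0, 1)")
    if essential_rate_ratio >= 1:
        raise ValueError("essential_rate_ratio must be < 1")
    rng = np.random.default_rng(seed)
    names = [f"gene_{i:04d}" for i in range(n_genes)]
    lengths = np.clip(
        rng.lognormal(mean=np.log(950.0), sigma=0.35, size=n_genes), 150, 6000
    ).astype(int)
    n_ess = int(round(frac_essential * n_genes))
    essential = set(rng.choice(names, size=n_ess, replace=False))
    effect = rng.gamma(shape=gene_effect_shape, scale=1.0 / gene_effect_shape,
                       size=n_genes)
    rates = lengths / 1000.0 * mean_rate * effect
    ratio = np.array([essential_rate_ratio if g in essential else 1.0 for g in names])
    counts = rng.poisson(rates * ratio)
    positions = {g: np.sort(rng.uniform(0.0, 1.0, size=c)) for g, c in zip(names, counts)}
    table = InsertionTable(
        genes=pd.DataFrame({"gene": names, "order": np.arange(n_genes),
                            "length_bp": lengths}),
        positions=positions,
    )
    return table, GroundTruth(essential_genes=essential)


# ---------------------------------------------------------------------------
# barcode counts


@dataclass
class BarcodeCounts:
    """Barcode-per-mutant read counts across samples."""

    barcodes: pd.DataFrame  # columns: barcode, gene, position + one column per sample
    samples: pd.DataFrame  # columns: sample, condition, replicate, generations

    def sample_columns(self) -> list[str]:
        return list(self.samples["sample"])


def gen_barcode_counts(
    fitness_true: dict[str, float],
    mutants_per_gene: int | dict[str, int] = 6,
    depth: int = 1_000_000,
    generations: tuple[float, ...] = (0.0, 8.0, 16.0),
    g_ref: float = 8.0,
    seed: int = 0,
    condition: str = "competition",
    abundance_sigma: float = 0.7,
) -> tuple[BarcodeCounts, GroundTruth]:
    """Simulate a pooled competition assay read out by barcode sequencing.

    Barcode relative abundance at generation g is proportional to the initial
    abundance times 2**(F_true * g / g_ref); each sample is a multinomial draw
    of ``depth`` reads.  F_true is the log2 fold change accrued at the
    reference generation count ``g_ref`` (the first post-selection sampling).
    """
    if 0.0 not in generations:
        raise ValueError("generations must include 0")
    rng = np.random.default_rng(seed)
    rows = []
    log_a0 = []
    fvals = []
    for gene in sorted(fitness_true):
        n_mut = mutants_per_gene[gene] if isinstance(mutants_per_gene, dict) else mutants_per_gene
        if n_mut <= 0:
            warnings.warn(f"fitness specified for {gene} but zero mutants; skipped")
            continue
        for i in range(n_mut):
            rows.append((f"{gene}_bc{i:02d}", gene, float(rng.uniform(0, 1))))
            log_a0.append(rng.normal(0.0, abundance_sigma))
            fvals.append(fitness_true[gene])
    barcodes = pd.DataFrame(rows, columns=["barcode", "gene", "position"])
    log_a0 = np.array(log_a0)
    fvals = np.array(fvals)

    sample_rows = []
    for g in generations:
        log_a = log_a0 + np.log(2.0) * fvals * g / g_ref
        p = np.exp(log_a - log_a.max())
        p /= p.sum()
        name = f"{condition}_g{g:g}"
        barcodes[name] = rng.multinomial(depth, p)
        sample_rows.append((name, condition, 1, g))
    samples = pd.DataFrame(sample_rows,
                           columns=["sample", "condition", "replicate", "generations"])
    return (
        BarcodeCounts(barcodes=barcodes, samples=samples),
        GroundTruth(fitness_true=dict(fitness_true)),
    )
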