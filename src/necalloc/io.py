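"""Readers and writers: JSON network dialect, SBML (via cobrapy), TSV tables.

The JSON dialect is the full-fidelity format (it carries enzyme compositions,
machinery, budgets-relevant annotations); SBML Level 3 with fbc covers the
constraint-based core (stoichiometry, bounds, gene-product associations) so a
real genome-scale model can be read in place of the toy network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from .network import EnzymeSpec, Metabolite, Reaction, ReactionNetwork

log = logging.getLogger("necalloc")

DEFAULT_PROTEIN_LENGTH = 350  # aa, used for genes without annotation


def to_cobra(network: ReactionNetwork):
    """Convert to a cobra.Model (metabolic core + GPR; enzyme data dropped)."""
    import cobra

    model = cobra.Model("necalloc")
    mets = {}
    for m in network.metabolites:
        cm = cobra.Metabolite(m.id, compartment=m.compartment or "c")
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id)
        lb = r.lower_bound
        if r.reversible and lb >= 0:
            lb = -r.upper_bound
        cr.bounds = (lb, r.upper_bound)
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in network.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: c for m, c in r.stoichiometry.items()}
        )
        alts = network.gpr.get(r.id)
        if alts:
            terms = []
            for eid in alts:
                genes = sorted(network.enzymes[eid].composition)
                terms.append("( " + " and ".join(genes) + " )" if len(genes) > 1
                             else genes[0])
            model.reactions.get_by_id(r.id).gene_reaction_rule = " or ".join(terms)
    return model


def from_cobra(model, protein_lengths: dict[str, int] | None = None) -> ReactionNetwork:
    """Build a ReactionNetwork from a cobra model.

    Enzyme specs are reconstructed from the GPR: each OR-alternative becomes an
    enzyme whose subunits are the AND-ed genes (1 copy each), with lengths from
    ``protein_lengths`` or a default.
    """
    protein_lengths = dict(protein_lengths or {})
    mets = [Metabolite(m.id, m.compartment or "c") for m in model.metabolites]
    rxns, gpr, enzymes, proteins = [], {}, {}, {}
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            raise ValueError(f"reaction {r.id}: malformed bounds")
        rxns.append(Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            reversible=r.lower_bound < 0,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            pseudo=not r.genes,
        ))
        rule = r.gene_reaction_rule
        if rule:
            alts = []
            for i, term in enumerate(rule.split(" or ")):
                genes = [g.strip("() ") for g in term.split(" and ")]
                genes = [g for g in genes if g]
                if not genes:
                    raise ValueError(f"reaction {r.id}: malformed GPR {rule!r}")
                comp = {g: 1 for g in genes}
                for g in genes:
                    proteins.setdefault(
                        g, protein_lengths.get(g, DEFAULT_PROTEIN_LENGTH))
                eid = f"E_{r.id}" if len(rule.split(' or ')) == 1 else f"E_{r.id}_{i}"
                enzymes[eid] = EnzymeSpec(
                    eid, comp, sum(proteins[g] for g in genes))
                alts.append(eid)
            gpr[r.id] = alts
    return ReactionNetwork(
        metabolites=mets, reactions=rxns, gpr=gpr, enzymes=enzymes,
        proteins=proteins,
    )


def read_network(path, dialect: str | None = None,
                 protein_lengths: dict[str, int] | None = None) -> ReactionNetwork:
    """Read a network from the JSON dialect or SBML (auto-detected by suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if dialect == "json":
        return ReactionNetwork.from_json(path)
    if dialect == "sbml":
        import cobra

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(str(path))
        return from_cobra(model, protein_lengths)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_network(network: ReactionNetwork, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if dialect == "json":
        network.to_json(path)
    elif dialect == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(network), str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# TSV helpers


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration tree (for run manifests)."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)
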