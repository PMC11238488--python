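"""Genome-scale metabolic network (GSMN) I/O and model preparation.

The in-memory representation is a light, explicit container (stoichiometry
dicts, flux bounds, GPR trees, pathway annotation) built from, and written
back through, cobrapy's SBML reader/writer — so any SBML level 2/3 model
with fbc- or note-encoded gene associations can be used.

Model preparation implements the maintenance-biomass rewrite used for
non-proliferating differentiated cells (e.g. primary human hepatocytes):
DNA-replication precursors are removed from the biomass reaction, the
remaining substrate coefficients are rescaled so the reaction still
produces one unit of biomass, and a positive lower bound forces the
maintenance cost to be paid in every feasible flux state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import cobra
from cobra.io import read_sbml_model, write_sbml_model

from .gpr import GPRExpression, gpr_genes, gpr_to_string, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "read_sbml",
    "write_sbml",
    "prepare_maintenance_biomass",
    "read_id_list",
    "write_id_list",
]


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """One biochemical reaction.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    substrate, positive = product). A reaction is reversible iff its lower
    bound is negative.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GPRExpression | None = None
    pathway: str | None = None
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def substrates(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A GSMN: metabolites, reactions, genes and pathway annotation."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    id: str = "model"

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def pathway_of(self) -> dict[str, str]:
        return {r.id: r.pathway for r in self.reactions.values() if r.pathway}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites={m: replace(v) for m, v in self.metabolites.items()},
            reactions={r: v.copy() for r, v in self.reactions.items()},
            genes=set(self.genes),
            id=self.id,
        )

    def validate(self) -> None:
        """Check referential integrity; raises ValueError on violation."""
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id}: lower bound exceeds upper bound")
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValueError(f"reaction {rxn.id} references unknown metabolite {met}")
            missing = gpr_genes(rxn.gpr) - self.genes
            if missing:
                raise ValueError(f"reaction {rxn.id} GPR references unknown genes {sorted(missing)}")


def _from_cobra(cm: cobra.Model) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    for met in cm.metabolites:
        model.metabolites[met.id] = Metabolite(met.id, met.name or "", met.compartment or "")
    for rxn in cm.reactions:
        rule = rxn.gene_reaction_rule or ""
        try:
            gpr = parse_gpr(rule)
        except Exception as exc:  # noqa: BLE001 - re-raise with reaction context
            raise ValueError(f"cannot parse GPR of reaction {rxn.id!r}: {rule!r}") from exc
        model.reactions[rxn.id] = Reaction(
            id=rxn.id,
            stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
            gpr=gpr,
            pathway=rxn.subsystem or None,
            name=rxn.name or "",
        )
        model.genes |= gpr_genes(gpr)
    return model


def _to_cobra(model: MetabolicModel) -> cobra.Model:
    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
            for m in model.metabolites.values()
        ]
    )
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id, name=rxn.name, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cr = cm.reactions.get_by_id(rxn.id)
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()})
        cr.gene_reaction_rule = gpr_to_string(rxn.gpr)
        if rxn.pathway:
            cr.subsystem = rxn.pathway
    return cm


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    GPRs are taken from fbc geneProductAssociations when present, with
    cobrapy's fallback to note-encoded GENE_ASSOCIATION strings for older
    level-2 models. Reactions without a rule get an empty GPR.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm = read_sbml_model(str(path))
    return _from_cobra(cm)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML level 3 with fbc gene associations."""
    write_sbml_model(_to_cobra(model), str(path))


def prepare_maintenance_biomass(
    model: MetabolicModel,
    biomass_id: str,
    dna_precursor_ids: Iterable[str],
    maintenance_lb: float = 1.0,
    correction: Callable[[dict[str, float], dict[str, float]], dict[str, float]] | None = None,
) -> MetabolicModel:
    """Rewrite the biomass reaction as a cell-maintenance reaction.

    DNA precursors are dropped (coefficient set to 0) and the remaining
    substrate coefficients are corrected so the rewritten reaction still
    consumes the same total absolute substrate mass per unit of biomass.
    The default correction multiplies every remaining substrate coefficient
    by S/S', where S (S') is the sum of absolute substrate coefficients
    before (after) zeroing; pass ``correction`` to substitute another rule
    mapping (remaining substrates, dropped substrates) -> new coefficients.
    Finally the reaction's lower bound is forced to ``maintenance_lb`` so
    every feasible flux state pays the maintenance cost.

    Returns a modified copy; no other reaction is touched.
    """
    if biomass_id not in model.reactions:
        raise KeyError(f"biomass reaction {biomass_id!r} not in model")
    out = model.copy()
    biomass = out.reactions[biomass_id]
    substrates = biomass.substrates
    dropped: dict[str, float] = {}
    for met in dna_precursor_ids:
        if met not in substrates:
            warnings.warn(f"{met!r} is not a substrate of {biomass_id!r}; skipped", stacklevel=2)
            continue
        dropped[met] = biomass.stoichiometry[met]
        biomass.stoichiometry[met] = 0.0
    remaining = biomass.substrates
    if dropped and remaining:
        if correction is None:
            s_before = sum(-c for c in remaining.values()) + sum(-c for c in dropped.values())
            s_after = sum(-c for c in remaining.values())
            scale = s_before / s_after
            corrected = {m: c * scale for m, c in remaining.items()}
        else:
            corrected = correction(dict(remaining), dict(dropped))
        biomass.stoichiometry.update(corrected)
    biomass.lower_bound = maintenance_lb
    if biomass.upper_bound < maintenance_lb:
        biomass.upper_bound = maintenance_lb
    return out


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line list (side compounds, exclusions)."""
    out = []
    for line in Path(path).read_text().splitlines():
        token = line.strip().split("\t")[0]
        if token and not token.startswith("#"):
            out.append(token)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))
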