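"""Synthetic inputs with known ground truth.

Small mass-balanced toy networks (chain, diamond, star, random-branched)
stand in for a genome-scale network: every designated route can carry
flux, boundary exchanges feed and drain the system, and parallel routes
create a known, exhaustively enumerable set of alternative optima.
Planted-shift solution matrices emulate the enumeration output of two
conditions whose activation frequencies differ by construction, and
synthetic z-score tables reproduce requested a-priori core sets through
the GPR layer. All generators are seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CoreSets, categorize_zscores, derive_core_sets
from .gpr import GeneLeaf, GprAnd, GprOr, gpr_genes
from .model_io import MetabolicModel, Metabolite, Reaction, write_sbml
from .solutions import SolutionSet

__all__ = [
    "ToySpec",
    "PlantedShiftSpec",
    "generate_toy_model",
    "generate_solution_sets",
    "generate_zscores",
]

TOPOLOGIES = ("chain", "diamond", "star", "random-branched")


@dataclass
class ToySpec:
    topology: str = "chain"
    n_reactions: int = 4
    reversibility_fraction: float = 0.0
    gpr_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if self.n_reactions < 2:
            raise ValueError("need at least two reactions (an uptake and a sink)")


@dataclass
class PlantedShiftSpec:
    n_reactions: int = 20
    n_solutions: int = 1000
    shifted: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_frequency: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for rid, (fc, ft) in self.shifted.items():
            if not (0 <= fc <= 1 and 0 <= ft <= 1):
                raise ValueError(f"frequencies for {rid} outside [0, 1]")
        if not 0 <= self.noise_frequency <= 1:
            raise ValueError("noise_frequency outside [0, 1]")


def _chain(n: int) -> list[Reaction]:
    # uptake -> A1 -> ... -> A_{n-1} -> sink
    rxns = [Reaction("R_uptake", {"M_A1": 1.0})]
    for i in range(1, n - 1):
        rxns.append(Reaction(f"R{i:02d}", {f"M_A{i}": -1.0, f"M_A{i + 1}": 1.0}))
    rxns.append(Reaction("R_sink", {f"M_A{n - 1}": -1.0}))
    return rxns


def _diamond(n: int) -> list[Reaction]:
    # uptake -> A, two parallel paths A -> ... -> B, B -> sink.
    # The uptake/sink capacity (1.5) is below twice the default activation
    # threshold (1.0), so at most one branch can be active per optimum: the
    # alternative optima are exactly the two branch choices.
    if n < 4 or n % 2:
        raise ValueError("diamond topology needs an even reaction count >= 4")
    k = (n - 2) // 2  # reactions per branch
    rxns = [Reaction("R_uptake", {"M_A": 1.0}, upper_bound=1.5)]
    for branch in (1, 2):
        prev = "M_A"
        for step in range(1, k + 1):
            product = "M_B" if step == k else f"M_X{branch}{step}"
            rxns.append(Reaction(f"R_b{branch}s{step}", {prev: -1.0, product: 1.0}))
            prev = product
    rxns.append(Reaction("R_sink", {"M_B": -1.0}, upper_bound=1.5))
    return rxns


def _star(n: int) -> list[Reaction]:
    # uptake feeds a hub reaction producing one metabolite per leaf sink
    if n < 3:
        raise ValueError("star topology needs at least three reactions")
    k = n - 2  # leaves
    hub_stoich: dict[str, float] = {"M_H": -1.0}
    rxns = [Reaction("R_uptake", {"M_H": 1.0})]
    for i in range(1, k + 1):
        hub_stoich[f"M_L{i}"] = 1.0
    rxns.append(Reaction("R_hub", hub_stoich))
    for i in range(1, k + 1):
        rxns.append(Reaction(f"R_leaf{i}", {f"M_L{i}": -1.0}))
    return rxns


def _random_branched(n: int, rng: np.random.Generator) -> list[Reaction]:
    # grow a random DAG of 1:1 conversions, then drain every terminal metabolite
    rxns = [Reaction("R_uptake", {"M_0": 1.0})]
    mets = ["M_0"]
    n_internal = max(0, n - 2)
    for i in range(n_internal):
        src = mets[int(rng.integers(len(mets)))]
        product = f"M_{i + 1}"
        rxns.append(Reaction(f"R{i + 1:02d}", {src: -1.0, product: 1.0}))
        mets.append(product)
    consumed = {m for r in rxns for m, c in r.stoichiometry.items() if c < 0}
    terminals = [m for m in mets if m not in consumed]
    for j, m in enumerate(terminals):
        rxns.append(Reaction(f"R_sink{j}" if j else "R_sink", {m: -1.0}))
    return rxns


def _assign_gprs(rxns: list[Reaction], density: float, rng: np.random.Generator) -> None:
    pool = [f"g{i:03d}" for i in range(1, 3 * len(rxns) + 1)]
    rng.shuffle(pool)
    cursor = 0
    for rxn in rxns:
        if rng.random() >= density:
            continue
        shape = rng.random()
        if shape < 0.5:
            rxn.gpr = GeneLeaf(pool[cursor])
            cursor += 1
        elif shape < 0.75:
            rxn.gpr = GprOr((GeneLeaf(pool[cursor]), GeneLeaf(pool[cursor + 1])))
            cursor += 2
        else:
            rxn.gpr = GprAnd((GeneLeaf(pool[cursor]), GeneLeaf(pool[cursor + 1])))
            cursor += 2


def generate_toy_model(spec: ToySpec, sbml_path: str | Path | None = None) -> MetabolicModel:
    """Build a flux-consistent toy network; optionally write it as SBML.

    Boundary exchanges (single-metabolite uptake and sink reactions) make
    every internal route feasible. ``reversibility_fraction`` of the
    internal conversions get a negative lower bound; ``gpr_density`` of
    all reactions get a GPR drawn from a synthetic gene pool (single
    gene, two-gene OR, or two-gene AND).
    """
    rng = np.random.default_rng(spec.seed)
    builder = {
        "chain": lambda: _chain(spec.n_reactions),
        "diamond": lambda: _diamond(spec.n_reactions),
        "star": lambda: _star(spec.n_reactions),
        "random-branched": lambda: _random_branched(spec.n_reactions, rng),
    }[spec.topology]
    rxns = builder()
    internal = [r for r in rxns if len(r.stoichiometry) > 1]
    for rxn in internal:
        if rng.random() < spec.reversibility_fraction:
            rxn.lower_bound = -1000.0
    _assign_gprs(rxns, spec.gpr_density, rng)
    model = MetabolicModel(id=f"toy_{spec.topology}")
    for rxn in rxns:
        for m in rxn.stoichiometry:
            model.metabolites.setdefault(m, Metabolite(m, name=m, compartment="c"))
        model.reactions[rxn.id] = rxn
        model.genes |= gpr_genes(rxn.gpr)
    model.validate()
    if sbml_path is not None:
        write_sbml(model, sbml_path)
    return model


def generate_solution_sets(
    spec: PlantedShiftSpec,
) -> tuple[SolutionSet, SolutionSet, pd.DataFrame]:
    """Sample control/treated binary solution matrices with planted shifts.

    Each reaction's activity column is an independent Bernoulli draw at
    its planted frequency (``noise_frequency`` on both sides unless the
    reaction is listed in ``shifted``). The truth table records the
    planted frequencies and whether the expected R2 = (f_ctrl - f_trt)^2
    exceeds the 0.2 DAR threshold.
    """
    rng = np.random.default_rng(spec.seed)
    reactions = [f"R{i + 1:03d}" for i in range(spec.n_reactions)]
    stray = set(spec.shifted) - set(reactions)
    if stray:
        raise ValueError(f"shifted reactions outside the universe: {sorted(stray)}")
    rows = []
    ctrl = np.empty((spec.n_solutions, spec.n_reactions), dtype=np.int8)
    trt = np.empty_like(ctrl)
    for j, rid in enumerate(reactions):
        fc, ft = spec.shifted.get(rid, (spec.noise_frequency, spec.noise_frequency))
        ctrl[:, j] = rng.random(spec.n_solutions) < fc
        trt[:, j] = rng.random(spec.n_solutions) < ft
        expected = (fc - ft) ** 2
        rows.append((rid, fc, ft, expected, expected > 0.2))
    truth = pd.DataFrame(
        rows, columns=["reaction", "f_ctrl", "f_trt", "expected_r2", "expected_dar"]
    ).set_index("reaction")
    return (
        SolutionSet(reactions, ctrl, condition="control"),
        SolutionSet(reactions, trt, condition="treated"),
        truth,
    )


def generate_zscores(
    model: MetabolicModel,
    target: CoreSets,
    seed: int = 0,
    samples: int = 1,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
) -> pd.DataFrame:
    """Synthesize a gene x sample z-score table realizing target core sets.

    Genes of a-priori active reactions are pushed above the high
    percentile, genes of a-priori inactive reactions below the low one,
    and everything else sits at zero; neutral filler genes are added so
    the percentile thresholds fall inside the neutral block. The output is
    verified by running the categorization and GPR evaluation on it; an
    unreachable target (contradictory gene requirements, or collateral
    reactions dragged into the core sets) raises ValueError.
    """
    rng = np.random.default_rng(seed)
    high_genes: set[str] = set()
    low_genes: set[str] = set()
    for rid in target.rh:
        high_genes |= gpr_genes(model.reactions[rid].gpr)
    for rid in target.rl:
        low_genes |= gpr_genes(model.reactions[rid].gpr)
    conflict = high_genes & low_genes
    if conflict:
        raise ValueError(f"contradictory gene requirements for: {sorted(conflict)}")
    neutral = model.genes - high_genes - low_genes
    # pad with inert filler genes so constrained genes stay outside the
    # interquartile range even when they dominate the model's gene set
    need_total = int(np.ceil(max(len(high_genes), len(low_genes), 1) / 0.24))
    n_filler = max(4, need_total - len(model.genes))
    fillers = [f"filler{i:03d}" for i in range(n_filler)]
    data: dict[str, list[float]] = {}
    for s in range(samples):
        col: dict[str, float] = {}
        for g in sorted(high_genes):
            col[g] = 3.0 + rng.random()
        for g in sorted(low_genes):
            col[g] = -3.0 - rng.random()
        for g in sorted(neutral) + fillers:
            col[g] = 0.0
        data[f"sample{s + 1}"] = col
    df = pd.DataFrame(data)
    df.index.name = "gene"
    for column in df.columns:
        cat = categorize_zscores(df[column], low_pct, high_pct)
        derived = derive_core_sets(model, cat)
        if derived.rh != target.rh or derived.rl != target.rl:
            raise ValueError(
                "target core sets are unreachable through the GPRs: "
                f"derived RH={sorted(derived.rh)}, RL={sorted(derived.rl)}"
            )
    return df
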