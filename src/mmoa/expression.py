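"""Transcriptome categorization and GPR evaluation.

Per-sample gene z-scores are trinarized with a percentile cutoff: genes
strictly below the low percentile are called lowly expressed (-1), genes
strictly above the high percentile highly expressed (+1), everything else
is neutral (0) and exerts no constraint on the modelling step. The default
25/75 cutoff leaves the middle half of the transcriptome unconstrained.

GPR rules are evaluated on these trinary calls with min over AND (a
complex needs all of its subunits) and max over OR (one isoenzyme
suffices): the result, again in {-1, 0, +1}, marks the reaction a-priori
inactive, unconstrained, or active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gpr import GeneLeaf, GprAnd, GPRExpression
from .model_io import MetabolicModel

__all__ = [
    "GeneCategorization",
    "CoreSets",
    "categorize_zscores",
    "categorize_table",
    "evaluate_gpr",
    "derive_core_sets",
    "read_zscores",
    "write_categorization",
]


@dataclass
class GeneCategorization:
    """gene id -> trinary expression call in {-1, 0, +1}."""

    values: dict[str, int]
    low_percentile: float = 25.0
    high_percentile: float = 75.0

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"categories must be -1/0/+1; got {bad}")

    def __getitem__(self, gene: str) -> int:
        return self.values.get(gene, 0)


@dataclass
class CoreSets:
    """A-priori active (RH) and inactive (RL) reaction sets."""

    rh: set[str] = field(default_factory=set)
    rl: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.rh & self.rl
        if overlap:
            raise ValueError(f"RH and RL overlap: {sorted(overlap)}")


def categorize_zscores(
    zscores: dict[str, float] | pd.Series,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
) -> GeneCategorization:
    """Trinarize one sample's gene z-scores at percentile cutoffs.

    Strict comparisons: a gene exactly at either percentile stays 0.
    Percentiles use numpy's linear interpolation over the sample's genes.
    """
    if isinstance(zscores, pd.Series):
        zscores = zscores.to_dict()
    if len(zscores) < 2:
        raise ValueError("need at least two genes to take percentiles")
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    for gene, z in zscores.items():
        if not np.isfinite(z):
            raise ValueError(f"non-finite z-score for gene {gene!r}")
    vec = np.fromiter(zscores.values(), dtype=float)
    p_low, p_high = np.percentile(vec, [low_pct, high_pct])
    values = {
        g: (-1 if z < p_low else (1 if z > p_high else 0)) for g, z in zscores.items()
    }
    return GeneCategorization(values, low_pct, high_pct)


def categorize_table(
    zscores: pd.DataFrame, low_pct: float = 25.0, high_pct: float = 75.0, per_sample: bool = True
) -> dict[str, GeneCategorization]:
    """Categorize a gene x sample z-score table, one call set per sample.

    With ``per_sample=False`` the percentile thresholds are computed once
    on the pooled table instead of per column.
    """
    out: dict[str, GeneCategorization] = {}
    if per_sample:
        for sample in zscores.columns:
            out[sample] = categorize_zscores(zscores[sample], low_pct, high_pct)
        return out
    pooled = zscores.to_numpy().ravel()
    p_low, p_high = np.percentile(pooled, [low_pct, high_pct])
    for sample in zscores.columns:
        vals = {
            g: (-1 if z < p_low else (1 if z > p_high else 0))
            for g, z in zscores[sample].items()
        }
        out[sample] = GeneCategorization(vals, low_pct, high_pct)
    return out


def evaluate_gpr(gpr: GPRExpression | None, cat: GeneCategorization) -> int:
    """Evaluate a GPR tree on trinary gene calls: min over AND, max over OR.

    A gene absent from the categorization counts as 0 (unconstrained); an
    empty GPR evaluates to 0.
    """
    if gpr is None:
        return 0
    if isinstance(gpr, GeneLeaf):
        return cat[gpr.gene]
    child_values = [evaluate_gpr(c, cat) for c in gpr.children]
    return min(child_values) if isinstance(gpr, GprAnd) else max(child_values)


def derive_core_sets(model: MetabolicModel, cat: GeneCategorization) -> CoreSets:
    """Map trinary gene calls through the GPRs to a-priori reaction sets.

    RH collects reactions whose GPR evaluates to +1, RL those evaluating
    to -1; reactions with a 0 evaluation or no GPR constrain nothing.
    """
    core = CoreSets()
    for rxn in model.reactions.values():
        if rxn.gpr is None:
            continue
        value = evaluate_gpr(rxn.gpr, cat)
        if value == 1:
            core.rh.add(rxn.id)
        elif value == -1:
            core.rl.add(rxn.id)
    return core


def read_zscores(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample z-score TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_categorization(cats: dict[str, GeneCategorization], path: str | Path) -> None:
    """Write per-sample trinary calls as a gene x sample TSV of {-1,0,1}."""
    genes = sorted({g for c in cats.values() for g in c.values})
    df = pd.DataFrame({s: [c[g] for g in genes] for s, c in cats.items()}, index=genes)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
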