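"""Differentially activated reactions (DARs) between solution sets.

Each condition's enumeration yields, per reaction, an activation frequency
f = (number of optimal solutions where the reaction is active) / (total
solutions). Conditions are compared reaction-wise with the squared
frequency difference

    R2 = (f_ctrl - f_trt)^2

and a reaction is called perturbed when R2 exceeds a threshold (default
0.2, i.e. a frequency shift of at least ~0.45). Loosely constrained
reactions flip state freely even between control conditions; to avoid
calling those, a per-reaction baseline noise — the median pairwise R2
among control conditions sharing vehicle and exposure time — must be
exceeded twofold for a perturbed reaction to survive as a DAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .solutions import SolutionSet

__all__ = [
    "ActivationFrequencies",
    "activation_frequency",
    "r2",
    "perturbed_reactions",
    "baseline_noise",
    "filter_dars",
    "dar_pipeline",
    "specificity_ratio",
    "pathway_ora",
    "write_dar_table",
]

R2_THRESHOLD = 0.2
NOISE_FACTOR = 2.0


@dataclass
class ActivationFrequencies:
    """Per-reaction activation frequency over one condition's solutions."""

    frequencies: dict[str, float]
    n_solutions: int

    def __getitem__(self, rid: str) -> float:
        return self.frequencies[rid]


def activation_frequency(solutions: SolutionSet) -> ActivationFrequencies:
    """Fraction of enumerated optima in which each reaction is active."""
    n = len(solutions)
    if n == 0:
        raise ValueError("cannot compute frequencies of an empty solution set")
    counts = solutions.matrix.sum(axis=0)
    return ActivationFrequencies(
        {r: float(c) / n for r, c in zip(solutions.reactions, counts)}, n
    )


def r2(f_ctrl: float, f_trt: float) -> float:
    """Squared activation-frequency difference; symmetric, in [0, 1]."""
    if not (0 <= f_ctrl <= 1 and 0 <= f_trt <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return (f_ctrl - f_trt) ** 2


def _common_universe(a: ActivationFrequencies, b: ActivationFrequencies) -> list[str]:
    if set(a.frequencies) != set(b.frequencies):
        raise ValueError("frequency tables cover different reaction universes")
    return list(a.frequencies)


def perturbed_reactions(
    freq_ctrl: ActivationFrequencies,
    freq_trt: ActivationFrequencies,
    threshold: float = R2_THRESHOLD,
) -> set[str]:
    """Reactions with R2 strictly above the threshold."""
    universe = _common_universe(freq_ctrl, freq_trt)
    return {r for r in universe if r2(freq_ctrl[r], freq_trt[r]) > threshold}


def baseline_noise(control_sets: list[SolutionSet]) -> dict[str, float]:
    """Median pairwise R2 among control conditions, per reaction.

    The caller groups the controls by vehicle and exposure time; at least
    two are required for the noise to be defined.
    """
    if len(control_sets) < 2:
        raise ValueError("baseline noise needs at least two control conditions")
    freqs = [activation_frequency(s) for s in control_sets]
    universe = list(freqs[0].frequencies)
    for f in freqs[1:]:
        _common_universe(freqs[0], f)
    noise = {}
    for rid in universe:
        pair_r2 = [r2(a[rid], b[rid]) for a, b in combinations(freqs, 2)]
        noise[rid] = float(np.median(pair_r2))
    return noise


def filter_dars(
    perturbed: set[str],
    freq_ctrl: ActivationFrequencies,
    freq_trt: ActivationFrequencies,
    noise: dict[str, float],
    factor: float = NOISE_FACTOR,
) -> pd.DataFrame:
    """Apply the baseline-noise filter and assemble the DAR table.

    A perturbed reaction is kept as a DAR iff its R2 is at least ``factor``
    times its baseline noise (reactions at exactly the bound are kept).
    Returns one row per reaction in the universe with columns: f_ctrl,
    f_trt, R2, noise, perturbed, dar, direction ('up' when the reaction is
    more frequently active under treatment; empty unless dar).
    """
    universe = _common_universe(freq_ctrl, freq_trt)
    missing = [r for r in perturbed if r not in noise]
    if missing:
        raise KeyError(f"no noise estimate for perturbed reaction(s): {sorted(missing)}")
    rows = []
    for rid in universe:
        fc, ft = freq_ctrl[rid], freq_trt[rid]
        stat = r2(fc, ft)
        is_pert = rid in perturbed
        is_dar = bool(is_pert and stat >= factor * noise[rid])
        direction = ("up" if ft > fc else "down") if is_dar else ""
        rows.append((rid, fc, ft, stat, noise.get(rid, np.nan), is_pert, is_dar, direction))
    return pd.DataFrame(
        rows, columns=["reaction", "f_ctrl", "f_trt", "R2", "noise", "perturbed", "dar", "direction"]
    ).set_index("reaction")


def dar_pipeline(
    ctrl: SolutionSet,
    trt: SolutionSet,
    control_sets: list[SolutionSet],
    threshold: float = R2_THRESHOLD,
    factor: float = NOISE_FACTOR,
) -> pd.DataFrame:
    """Frequencies -> perturbed calls -> noise filter, in one call."""
    freq_ctrl = activation_frequency(ctrl)
    freq_trt = activation_frequency(trt)
    perturbed = perturbed_reactions(freq_ctrl, freq_trt, threshold)
    noise = baseline_noise(control_sets)
    return filter_dars(perturbed, freq_ctrl, freq_trt, noise, factor)


def specificity_ratio(dars_by_condition: dict[str, set[str]]) -> dict[str, float | None]:
    """Share of each condition's DARs found in no other condition.

    Conditions with zero DARs get None (ratio undefined).
    """
    if len(dars_by_condition) < 2:
        raise ValueError("specificity needs at least two conditions")
    out: dict[str, float | None] = {}
    for cond, dars in dars_by_condition.items():
        if not dars:
            out[cond] = None
            continue
        others = set().union(*(d for c, d in dars_by_condition.items() if c != cond))
        out[cond] = len(dars - others) / len(dars)
    return out


def pathway_ora(
    dars: set[str],
    universe: set[str],
    pathway_of: dict[str, str],
    artificial: set[str] | None = None,
) -> pd.DataFrame:
    """Pathway over-representation of DARs by one-sided Fisher exact test.

    Artificial reactions (sink/pool/exchange) are removed from both the
    DAR list and the universe before testing — keeping them distorts the
    enrichment — unless ``artificial`` is None-equivalent empty. P-values
    are Benjamini-Hochberg corrected across pathways. Returns a table
    sorted by p with columns pathway, n_pathway, hits, p, q.
    """
    if not dars <= universe:
        raise ValueError("DARs must be a subset of the universe")
    artificial = artificial or set()
    universe = universe - artificial
    dars = dars - artificial
    if not dars:
        return pd.DataFrame(columns=["pathway", "n_pathway", "hits", "p", "q"])
    pathways = sorted({pathway_of[r] for r in universe if r in pathway_of})
    rows = []
    for pw in pathways:
        members = {r for r in universe if pathway_of.get(r) == pw}
        hits = len(dars & members)
        table = [
            [hits, len(dars) - hits],
            [len(members) - hits, len(universe) - len(dars) - len(members) + hits],
        ]
        _, p = fisher_exact(table, alternative="greater")
        rows.append((pw, len(members), hits, p))
    df = pd.DataFrame(rows, columns=["pathway", "n_pathway", "hits", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "pathway"]).reset_index(drop=True)


def write_dar_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
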