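"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own solver paths: feasibility is
checked with raw scipy LPs over exhaustively enumerated activity
patterns, distances with Floyd-Warshall, and Steiner minima by subset
enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import linprog


def _pattern_feasible(model, reactions, pattern, epsilon):
    mets = list(model.metabolites)
    met_idx = {m: i for i, m in enumerate(mets)}
    a_eq = np.zeros((len(mets), len(reactions)))
    for j, rid in enumerate(reactions):
        for m, c in model.reactions[rid].stoichiometry.items():
            a_eq[met_idx[m], j] = c
    rev_active = [j for j, rid in enumerate(reactions)
                  if pattern[j] == 1 and model.reactions[rid].lower_bound < 0]
    base = []
    for j, rid in enumerate(reactions):
        rxn = model.reactions[rid]
        if pattern[j] == 0:
            base.append((0.0, 0.0))
        elif rxn.lower_bound < 0:
            base.append(None)  # chosen per orientation below
        else:
            base.append((max(rxn.lower_bound, epsilon), rxn.upper_bound))
    for signs in itertools.product((1, -1), repeat=len(rev_active)):
        bounds = list(base)
        for s, j in zip(signs, rev_active):
            rxn = model.reactions[reactions[j]]
            bounds[j] = (epsilon, rxn.upper_bound) if s == 1 else (rxn.lower_bound, -epsilon)
        res = linprog(np.zeros(len(reactions)), A_eq=a_eq, b_eq=np.zeros(len(mets)),
                      bounds=bounds, method="highs")
        if res.status == 0:
            return True
    return False


def exhaustive_optima(model, core, epsilon=1.0):
    """All feasible activity patterns attaining the maximal consensus score."""
    reactions = list(model.reactions)
    best_score = -1
    best: list[tuple[int, ...]] = []
    idx = {r: i for i, r in enumerate(reactions)}
    forced_active = {i for i, r in enumerate(reactions)
                     if model.reactions[r].lower_bound > 0}
    for bits in itertools.product((0, 1), repeat=len(reactions)):
        if any(bits[i] == 0 for i in forced_active):
            continue
        if not _pattern_feasible(model, reactions, bits, epsilon):
            continue
        score = sum(bits[idx[r]] for r in core.rh) + sum(1 - bits[idx[r]] for r in core.rl)
        if score > best_score:
            best_score, best = score, [bits]
        elif score == best_score:
            best.append(bits)
    return reactions, best_score, set(best)


def floyd_warshall(graph: nx.Graph, nodes):
    """All-pairs unweighted shortest-path matrix by Floyd-Warshall."""
    order = list(graph.nodes)
    n = len(order)
    idx = {u: i for i, u in enumerate(order)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for u, v in graph.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return {(u, v): d[idx[u], idx[v]] for u in nodes for v in nodes}


def exact_steiner_size(graph: nx.Graph, terminals: set[str]) -> int:
    """Node count of an exact minimal connected subgraph containing terminals."""
    others = sorted(set(graph.nodes) - terminals)
    for extra in range(len(others) + 1):
        for subset in itertools.combinations(others, extra):
            nodes = terminals | set(subset)
            sub = graph.subgraph(nodes)
            if nx.is_connected(sub):
                return len(nodes)
    raise ValueError("terminals are not connected in the graph")
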