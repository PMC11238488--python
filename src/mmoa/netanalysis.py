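"""Reaction-graph analysis: distances, DAR clustering, Steiner subnetworks.

Reactions become graph nodes; a directed edge r_i -> r_j exists when a
metabolite produced by r_i is consumed by r_j. Hub "side compounds"
(water, protons, cofactors...) would connect nearly everything and are
removed before building edges, as are excluded reactions (blocked,
artificial sink/pool/exchange reactions). Path lengths on the undirected
view of this graph measure metabolic interdependency: DARs a few steps
apart likely belong to one modulated process. DARs are therefore
clustered on their pairwise shortest-path distance matrix (Ward linkage)
and each cluster is materialized as a minimal connected subnetwork via a
metric-closure (2-approximate) Steiner tree, scored by its DAR coverage.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linprog
from scipy.spatial.distance import squareform

from .model_io import MetabolicModel

__all__ = [
    "ReactionGraph",
    "ClusterAssignment",
    "Subnetwork",
    "build_reaction_graph",
    "pairwise_distances",
    "cluster_dars",
    "steiner_subnetwork",
    "coverage",
    "export_subnetwork",
    "default_exclusions",
]


@dataclass
class ReactionGraph:
    """Directed reaction graph plus its undirected view for distances."""

    directed: nx.DiGraph

    @property
    def undirected(self) -> nx.Graph:
        return self.directed.to_undirected(as_view=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.directed.nodes)


def _roles(rxn) -> tuple[set[str], set[str]]:
    """Metabolites the reaction can produce / consume, orientation-aware."""
    produced = set(rxn.products)
    consumed = set(rxn.substrates)
    if rxn.reversible:
        produced, consumed = produced | consumed, consumed | produced
    return produced, consumed


def build_reaction_graph(
    model: MetabolicModel,
    side_compounds: set[str] | None = None,
    excluded_reactions: set[str] | None = None,
) -> ReactionGraph:
    """Build the reaction graph, dropping side compounds and exclusions.

    Edge r_i -> r_j (i != j) iff some non-side metabolite is produced by
    r_i and consumed by r_j; reversible reactions contribute both
    orientations. Unknown ids in either list only raise a warning.
    """
    side = set(side_compounds or ())
    excluded = set(excluded_reactions or ())
    for label, stray in (("side compounds", side - set(model.metabolites)),
                         ("excluded reactions", excluded - set(model.reactions))):
        if stray:
            warnings.warn(f"unknown {label} ignored: {sorted(stray)}", stacklevel=2)
    g = nx.DiGraph()
    kept = [r for r in model.reactions.values() if r.id not in excluded]
    g.add_nodes_from(r.id for r in kept)
    produced_by: dict[str, list[str]] = {}
    consumed_by: dict[str, list[str]] = {}
    for rxn in kept:
        produced, consumed = _roles(rxn)
        for m in produced - side:
            produced_by.setdefault(m, []).append(rxn.id)
        for m in consumed - side:
            consumed_by.setdefault(m, []).append(rxn.id)
    reversible = {r.id for r in kept if r.reversible}
    for m, producers in produced_by.items():
        for ri in producers:
            for rj in consumed_by.get(m, ()):
                if ri == rj:
                    continue
                directions = [(ri, rj)]
                # a reversible partner can run the exchange the other way,
                # so the dependency is recorded in both directions
                if ri in reversible or rj in reversible:
                    directions.append((rj, ri))
                for u, v in directions:
                    if g.has_edge(u, v):
                        g.edges[u, v]["metabolites"].append(m)
                    else:
                        g.add_edge(u, v, metabolites=[m])
    for _, _, data in g.edges(data=True):
        data["metabolites"] = sorted(set(data["metabolites"]))
        data["label"] = data["metabolites"][0]
    return ReactionGraph(g)


def _bfs(adj: dict[str, list[str]], source: str) -> tuple[dict[str, int], dict[str, str]]:
    """Deterministic BFS (sorted adjacency): distances and parents."""
    dist = {source: 0}
    parent: dict[str, str] = {}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
    return dist, parent


def _sorted_adjacency(g: nx.Graph) -> dict[str, list[str]]:
    return {u: sorted(g.neighbors(u)) for u in g.nodes}


def pairwise_distances(graph: ReactionGraph, reactions: list[str]) -> pd.DataFrame:
    """Unweighted shortest-path distances between query reactions.

    Computed on the undirected view; unreachable pairs get inf. Query
    reactions absent from the graph (e.g. excluded upstream) are reported
    with a warning and skipped.
    """
    g = graph.undirected
    present = [r for r in reactions if r in g]
    missing = [r for r in reactions if r not in g]
    if missing:
        warnings.warn(f"reactions not in graph, skipped: {missing}", stacklevel=2)
    adj = _sorted_adjacency(g)
    mat = pd.DataFrame(np.inf, index=present, columns=present)
    for r in present:
        dist, _ = _bfs(adj, r)
        for other in present:
            if other in dist:
                mat.loc[r, other] = dist[other]
    return mat


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    linkage_matrix: np.ndarray
    n_clusters: int
    dropped_isolated: list[str] = field(default_factory=list)

    def members(self, label: int) -> set[str]:
        return {r for r, c in self.labels.items() if c == label}


def cluster_dars(matrix: pd.DataFrame, n_clusters: int) -> ClusterAssignment:
    """Ward hierarchical clustering of the DAR distance matrix.

    Reactions at infinite distance from every other reaction (isolated)
    are dropped first; any remaining infinite entry is replaced by the
    largest finite distance plus one so the linkage stays defined. The
    tree is cut into ``n_clusters`` groups, labelled 1..n_clusters.
    """
    values = matrix.to_numpy(dtype=float)
    off_diag = ~np.eye(len(values), dtype=bool)
    isolated = [(~np.isfinite(values[i][off_diag[i]])).all() for i in range(len(values))]
    dropped = [r for r, iso in zip(matrix.index, isolated) if iso]
    keep = [r for r, iso in zip(matrix.index, isolated) if not iso]
    if n_clusters > len(keep):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(keep)} retained reactions")
    sub = matrix.loc[keep, keep].to_numpy(dtype=float)
    if not np.isfinite(sub).all():
        cap = np.max(sub[np.isfinite(sub)]) + 1
        warnings.warn(f"replacing remaining infinite distances by {cap}", stacklevel=2)
        sub[~np.isfinite(sub)] = cap
    condensed = squareform(sub, checks=False)
    link = linkage(condensed, method="ward")
    flat = fcluster(link, t=n_clusters, criterion="maxclust")
    return ClusterAssignment(dict(zip(keep, (int(c) for c in flat))), link, n_clusters, dropped)


@dataclass
class Subnetwork:
    """A connected subnetwork spanning a DAR cluster."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    terminals: set[str]

    @property
    def added(self) -> set[str]:
        return self.nodes - self.terminals

    @property
    def coverage(self) -> float:
        return len(self.nodes & self.terminals) / len(self.nodes)


def _kruskal(edges: list[tuple[float, str, str]], nodes: list[str]) -> list[tuple[str, str]]:
    """MST with deterministic (weight, endpoints) tie-breaking."""
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for w, u, v in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            out.append((u, v))
    return out


def steiner_subnetwork(graph: ReactionGraph, terminals: set[str]) -> Subnetwork:
    """2-approximate minimal Steiner subnetwork over a DAR cluster.

    Metric-closure construction: complete graph over the terminals
    weighted by shortest-path distance, its minimum spanning tree, each
    closure edge expanded back into an actual shortest path, a spanning
    tree of the induced subgraph, and finally iterative pruning of
    non-terminal leaves. All tie-breaks are lexicographic on reaction ids,
    so the result is deterministic. Terminals outside the component
    holding the most terminals are dropped with a warning.
    """
    if not terminals:
        raise ValueError("empty terminal set")
    g = graph.undirected
    present = sorted(t for t in terminals if t in g)
    absent = sorted(terminals - set(present))
    if absent:
        warnings.warn(f"terminals not in graph, dropped: {absent}", stacklevel=2)
    if not present:
        raise ValueError("no terminal is present in the graph")
    adj = _sorted_adjacency(g)
    bfs_cache = {t: _bfs(adj, t) for t in present}
    # keep the component containing the most terminals (ties: smallest id)
    comp_of = {}
    for t in present:
        comp_of[t] = min(u for u in bfs_cache[t][0] if u in present)
    best = max(sorted(set(comp_of.values())), key=lambda c: sum(1 for t in present if comp_of[t] == c))
    kept = [t for t in present if comp_of[t] == best]
    unreachable = [t for t in present if comp_of[t] != best]
    if unreachable:
        warnings.warn(f"terminals unreachable from the main terminal component, dropped: {unreachable}",
                      stacklevel=2)
    if len(kept) == 1:
        return Subnetwork({kept[0]}, set(), set(kept))
    closure_edges = [
        (float(bfs_cache[u][0][v]), u, v)
        for i, u in enumerate(kept)
        for v in kept[i + 1:]
    ]
    mst = _kruskal(closure_edges, kept)
    nodes: set[str] = set(kept)
    for u, v in mst:
        dist, parent = bfs_cache[u]
        node = v
        while node != u:
            nodes.add(node)
            node = parent[node]
        nodes.add(u)
    induced = g.subgraph(nodes)
    tree_edges = _kruskal([(1.0, min(u, v), max(u, v)) for u, v in induced.edges], sorted(nodes))
    tree = nx.Graph(tree_edges)
    # prune non-terminal leaves until every leaf is a terminal
    terminal_set = set(kept)
    while True:
        leaves = [n for n in tree.nodes if tree.degree(n) <= 1 and n not in terminal_set]
        if not leaves:
            break
        tree.remove_nodes_from(leaves)
    return Subnetwork(set(tree.nodes), {tuple(sorted(e)) for e in tree.edges}, terminal_set)


def coverage(subnetwork: Subnetwork, dars: set[str]) -> float:
    """Fraction of the subnetwork's reactions that are DARs."""
    if not subnetwork.nodes:
        raise ValueError("empty subnetwork")
    return len(subnetwork.nodes & dars) / len(subnetwork.nodes)


def export_subnetwork(
    subnetwork: Subnetwork,
    model: MetabolicModel,
    dar_table: pd.DataFrame,
    out_prefix: str | Path,
    side_compounds: set[str] | None = None,
) -> dict[str, Path]:
    """Write node/edge TSVs and a bipartite reaction-metabolite GraphML.

    Node table: one row per subnetwork reaction and per non-side
    metabolite touched by those reactions, with DAR status ('up'/'down'
    from the DAR table, 'added' for connector reactions) and pathway.
    The GraphML holds the bipartite substrate/product graph.
    """
    side = set(side_compounds or ())
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dar_status: dict[str, str] = {}
    for rid in subnetwork.nodes:
        if rid in dar_table.index and bool(dar_table.loc[rid, "dar"]):
            dar_status[rid] = str(dar_table.loc[rid, "direction"])
        else:
            dar_status[rid] = "added"
    bip = nx.DiGraph()
    node_rows = []
    for rid in sorted(subnetwork.nodes):
        rxn = model.reactions[rid]
        bip.add_node(rid, kind="reaction", dar=dar_status[rid] != "added",
                     direction=dar_status[rid], pathway=rxn.pathway or "")
        node_rows.append((rid, "reaction", dar_status[rid] != "added", dar_status[rid],
                          rxn.pathway or ""))
        for m, c in rxn.stoichiometry.items():
            if m in side or c == 0:
                continue
            if m not in bip:
                bip.add_node(m, kind="metabolite", dar=False, direction="", pathway="")
            if c < 0:
                bip.add_edge(m, rid, role="substrate")
            else:
                bip.add_edge(rid, m, role="product")
    for m in sorted(n for n, d in bip.nodes(data=True) if d["kind"] == "metabolite"):
        node_rows.append((m, "metabolite", False, "", ""))
    nodes_df = pd.DataFrame(node_rows, columns=["id", "type", "dar", "direction", "pathway"])
    edges_df = pd.DataFrame(
        [(u, v, d["role"]) for u, v, d in bip.edges(data=True)],
        columns=["source", "target", "role"],
    )
    paths = {
        "nodes": prefix.with_name(prefix.name + "_nodes.tsv"),
        "edges": prefix.with_name(prefix.name + "_edges.tsv"),
        "graphml": prefix.with_name(prefix.name + ".graphml"),
    }
    nodes_df.to_csv(paths["nodes"], sep="\t", index=False)
    edges_df.to_csv(paths["edges"], sep="\t", index=False)
    nx.write_graphml(bip, paths["graphml"])
    return paths


def default_exclusions(
    model: MetabolicModel,
    solution_sets: list | None = None,
) -> set[str]:
    """Default excluded-reaction list for graph construction.

    Collects (a) artificial reactions — single-metabolite stoichiometry,
    i.e. exchange/sink/pool boundary reactions; (b) blocked reactions,
    detected by LP flux variability (max |v| = 0 under steady state); and
    (c) reactions inactive in every provided solution set.
    """
    excluded: set[str] = {r.id for r in model.reactions.values() if len(r.stoichiometry) <= 1}
    mets = list(model.metabolites)
    met_idx = {m: i for i, m in enumerate(mets)}
    rxns = list(model.reactions)
    a_eq = np.zeros((len(mets), len(rxns)))
    for j, rid in enumerate(rxns):
        for m, c in model.reactions[rid].stoichiometry.items():
            a_eq[met_idx[m], j] = c
    bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound) for r in rxns]
    for j, rid in enumerate(rxns):
        c = np.zeros(len(rxns))
        extremes = []
        for sign in (1.0, -1.0):
            c[j] = sign
            res = linprog(c, A_eq=a_eq, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
            extremes.append(res.fun if res.status == 0 else None)
            c[j] = 0.0
        if all(e is not None and abs(e) < 1e-9 for e in extremes):
            excluded.add(rid)
    if solution_sets:
        never: set[str] | None = None
        for s in solution_sets:
            inactive = {r for r, col in zip(s.reactions, s.matrix.T) if not col.any()}
            never = inactive if never is None else never & inactive
        excluded |= never or set()
    return excluded
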