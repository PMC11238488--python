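"""Reaction graph, distances, clustering, Steiner subnetworks, export."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mmoa import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ToySpec,
    build_reaction_graph,
    cluster_dars,
    coverage,
    default_exclusions,
    export_subnetwork,
    generate_toy_model,
    pairwise_distances,
    steiner_subnetwork,
)

from _oracles import exact_steiner_size, floyd_warshall


def model_from_reactions(reactions):
    model = MetabolicModel()
    for rxn in reactions:
        for m in rxn.stoichiometry:
            model.metabolites.setdefault(m, Metabolite(m))
        model.reactions[rxn.id] = rxn
    return model


def chain_model():
    return model_from_reactions([
        Reaction("R1", {"A": -1, "B": 1}),
        Reaction("R2", {"B": -1, "C": 1}),
    ])


class TestBuildGraph:
    def test_chain_single_labeled_edge(self):
        graph = build_reaction_graph(chain_model())
        assert set(graph.directed.edges) == {("R1", "R2")}
        assert graph.directed.edges["R1", "R2"]["label"] == "B"

    def test_side_compound_removes_edge(self):
        graph = build_reaction_graph(chain_model(), side_compounds={"B"})
        assert graph.directed.number_of_edges() == 0

    def test_reversible_consumer_adds_reverse_edge(self):
        model = chain_model()
        model.reactions["R2"].lower_bound = -1000
        graph = build_reaction_graph(model)
        assert set(graph.directed.edges) == {("R1", "R2"), ("R2", "R1")}

    def test_excluded_reaction_absent_with_incident_edges(self):
        graph = build_reaction_graph(chain_model(), excluded_reactions={"R2"})
        assert set(graph.directed.nodes) == {"R1"}
        assert graph.directed.number_of_edges() == 0

    def test_unknown_ids_warn(self):
        with pytest.warns(UserWarning, match="unknown side compounds"):
            build_reaction_graph(chain_model(), side_compounds={"nope"})


def linear_reaction_path(n):
    """R1 - R2 - ... - Rn as a reaction chain."""
    rxns = []
    for i in range(1, n + 1):
        rxns.append(Reaction(f"R{i}", {f"M{i - 1}": -1, f"M{i}": 1}))
    return model_from_reactions(rxns)


class TestDistances:
    def test_path_distance_two(self):
        graph = build_reaction_graph(linear_reaction_path(3))
        mat = pairwise_distances(graph, ["R1", "R3"])
        assert mat.loc["R1", "R3"] == 2

    def test_disconnected_pair_infinite(self):
        model = model_from_reactions([
            Reaction("R1", {"A": -1, "B": 1}),
            Reaction("R2", {"C": -1, "D": 1}),
        ])
        mat = pairwise_distances(build_reaction_graph(model), ["R1", "R2"])
        assert np.isinf(mat.loc["R1", "R2"])

    def test_matches_floyd_warshall_oracle(self):
        model = generate_toy_model(ToySpec(topology="random-branched", n_reactions=30, seed=4))
        graph = build_reaction_graph(model)
        nodes = sorted(graph.nodes)
        mat = pairwise_distances(graph, nodes)
        oracle = floyd_warshall(graph.undirected, nodes)
        for u, v in combinations(nodes, 2):
            assert mat.loc[u, v] == oracle[(u, v)]

    def test_symmetric_zero_diagonal(self):
        model = generate_toy_model(ToySpec(topology="random-branched", n_reactions=15, seed=2))
        graph = build_reaction_graph(model)
        nodes = sorted(graph.nodes)
        mat = pairwise_distances(graph, nodes)
        assert (np.diag(mat.to_numpy()) == 0).all()
        assert mat.equals(mat.T)

    def test_side_compound_removal_never_shortens_distances(self):
        model = generate_toy_model(ToySpec(topology="random-branched", n_reactions=20, seed=9))
        graph_full = build_reaction_graph(model)
        nodes = sorted(graph_full.nodes)
        base = pairwise_distances(graph_full, nodes)
        for side in list(model.metabolites)[:5]:
            pruned = pairwise_distances(build_reaction_graph(model, side_compounds={side}), nodes)
            assert (pruned.to_numpy() >= base.to_numpy() - 1e-12).all()

    def test_missing_query_warns_and_skips(self):
        graph = build_reaction_graph(linear_reaction_path(3))
        with pytest.warns(UserWarning, match="skipped"):
            mat = pairwise_distances(graph, ["R1", "ghost"])
        assert list(mat.index) == ["R1"]


def two_group_matrix():
    """Two tight 3-reaction groups, 10 apart."""
    names = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
    mat = pd.DataFrame(10.0, index=names, columns=names)
    for group in ("A", "B"):
        for i in range(3):
            for j in range(3):
                mat.loc[f"{group}{i}", f"{group}{j}"] = 0.0 if i == j else 1.0
    np.fill_diagonal(mat.values, 0.0)
    return mat


def best_two_partition(mat):
    """Exhaustive 2-partition minimizing within-cluster sum of squared distances."""
    names = list(mat.index)
    best, best_cost = None, np.inf
    for bits in range(1, 2 ** (len(names) - 1)):
        left = {names[0]} | {n for i, n in enumerate(names[1:], 1) if bits >> (i - 1) & 1}
        right = set(names) - left
        if not right:
            continue
        cost = sum(mat.loc[a, b] ** 2 for part in (left, right) for a, b in combinations(sorted(part), 2))
        if cost < best_cost:
            best_cost, best = cost, (left, right)
    return best


class TestClustering:
    def test_two_groups_recovered_exactly(self):
        mat = two_group_matrix()
        assignment = cluster_dars(mat, 2)
        got = {frozenset(assignment.members(1)), frozenset(assignment.members(2))}
        oracle = {frozenset(p) for p in best_two_partition(mat)}
        assert got == oracle == {frozenset({"A0", "A1", "A2"}), frozenset({"B0", "B1", "B2"})}

    def test_singletons_at_n_clusters_equals_n(self):
        mat = two_group_matrix()
        assignment = cluster_dars(mat, 6)
        assert sorted(assignment.labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_permutation_invariance_of_memberships(self):
        mat = two_group_matrix()
        perm = ["B1", "A0", "B2", "A2", "B0", "A1"]
        shuffled = mat.loc[perm, perm]
        a = cluster_dars(mat, 2)
        b = cluster_dars(shuffled, 2)
        parts_a = {frozenset(a.members(i)) for i in (1, 2)}
        parts_b = {frozenset(b.members(i)) for i in (1, 2)}
        assert parts_a == parts_b

    def test_isolated_rows_dropped_first(self):
        mat = two_group_matrix()
        mat.loc["lonely", :] = np.inf
        mat.loc[:, "lonely"] = np.inf
        mat.loc["lonely", "lonely"] = 0.0
        assignment = cluster_dars(mat, 2)
        assert assignment.dropped_isolated == ["lonely"]
        assert "lonely" not in assignment.labels

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_dars(two_group_matrix(), 7)


def star_model(k=3):
    rxns = [Reaction("R_uptake", {"M_H": 1.0})]
    stoich = {"M_H": -1.0}
    for i in range(1, k + 1):
        stoich[f"M_L{i}"] = 1.0
    rxns.append(Reaction("R_hub", stoich))
    for i in range(1, k + 1):
        rxns.append(Reaction(f"R_leaf{i}", {f"M_L{i}": -1.0}))
    return model_from_reactions(rxns)


class TestSteiner:
    def test_connected_path_terminals_cover_fully(self):
        graph = build_reaction_graph(linear_reaction_path(4))
        sub = steiner_subnetwork(graph, {"R1", "R2", "R3", "R4"})
        assert sub.nodes == {"R1", "R2", "R3", "R4"}
        assert sub.coverage == 1.0

    def test_star_adds_only_the_hub(self):
        graph = build_reaction_graph(star_model(3))
        sub = steiner_subnetwork(graph, {"R_leaf1", "R_leaf2", "R_leaf3"})
        assert sub.nodes == {"R_leaf1", "R_leaf2", "R_leaf3", "R_hub"}
        assert sub.added == {"R_hub"}
        size = exact_steiner_size(graph.undirected, {"R_leaf1", "R_leaf2", "R_leaf3"})
        assert len(sub.nodes) == size == 4

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_within_twice_exact_optimum_on_small_graphs(self, seed):
        model = generate_toy_model(ToySpec(topology="random-branched", n_reactions=12, seed=seed))
        graph = build_reaction_graph(model)
        g = graph.undirected
        comp = max(nx.connected_components(g), key=len)
        terminals = set(sorted(comp)[:3])
        sub = steiner_subnetwork(graph, terminals)
        assert terminals <= sub.nodes
        assert nx.is_connected(nx.Graph(list(sub.edges)) if sub.edges else nx.Graph([(n, n) for n in sub.nodes]))
        assert len(sub.nodes) <= 2 * exact_steiner_size(g, terminals)

    def test_unreachable_terminal_dropped_with_warning(self):
        model = model_from_reactions([
            Reaction("R1", {"A": -1, "B": 1}),
            Reaction("R2", {"B": -1, "C": 1}),
            Reaction("R9", {"X": -1, "Y": 1}),
        ])
        graph = build_reaction_graph(model)
        with pytest.warns(UserWarning, match="unreachable"):
            sub = steiner_subnetwork(graph, {"R1", "R2", "R9"})
        assert sub.nodes == {"R1", "R2"}

    def test_empty_terminals_rejected(self):
        with pytest.raises(ValueError):
            steiner_subnetwork(build_reaction_graph(chain_model()), set())


class TestCoverage:
    def test_worked_ratio(self):
        graph = build_reaction_graph(linear_reaction_path(4))
        sub = steiner_subnetwork(graph, {"R1", "R4"})
        assert sub.nodes == {"R1", "R2", "R3", "R4"}
        assert coverage(sub, {"R1", "R4"}) == pytest.approx(0.5)
        assert coverage(sub, set(sub.nodes)) == 1.0
        assert coverage(sub, set()) == 0.0


class TestExport:
    def make_table(self, dars):
        rows = [(r, 0.0, 1.0, 1.0, 0.0, True, True, "up") for r in dars]
        return pd.DataFrame(
            rows, columns=["reaction", "f_ctrl", "f_trt", "R2", "noise", "perturbed", "dar",
                           "direction"]).set_index("reaction")

    def test_graphml_round_trip_counts(self, tmp_path):
        model = linear_reaction_path(3)
        graph = build_reaction_graph(model)
        sub = steiner_subnetwork(graph, {"R1", "R2", "R3"})
        paths = export_subnetwork(sub, model, self.make_table({"R1", "R3"}), tmp_path / "sub")
        back = nx.read_graphml(paths["graphml"])
        nodes_df = pd.read_csv(paths["nodes"], sep="\t")
        assert back.number_of_nodes() == len(nodes_df)
        edges_df = pd.read_csv(paths["edges"], sep="\t")
        assert back.number_of_edges() == len(edges_df)

    def test_annotations_up_and_added(self, tmp_path):
        model = linear_reaction_path(3)
        graph = build_reaction_graph(model)
        sub = steiner_subnetwork(graph, {"R1", "R3"})  # R2 is a connector
        paths = export_subnetwork(sub, model, self.make_table({"R1", "R3"}), tmp_path / "sub")
        nodes = pd.read_csv(paths["nodes"], sep="\t").set_index("id")
        assert nodes.loc["R1", "direction"] == "up"
        assert nodes.loc["R2", "direction"] == "added"

    def test_node_table_counts_reactions_plus_metabolites(self, tmp_path):
        model = linear_reaction_path(3)
        graph = build_reaction_graph(model)
        sub = steiner_subnetwork(graph, {"R1", "R2", "R3"})
        paths = export_subnetwork(sub, model, self.make_table(set()), tmp_path / "sub",
                                  side_compounds={"M0"})
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        # 3 reactions + metabolites M1..M3 (M0 is a side compound)
        assert (nodes["type"] == "reaction").sum() == 3
        assert (nodes["type"] == "metabolite").sum() == 3


def test_default_exclusions_flags_boundary_and_blocked():
    model = model_from_reactions([
        Reaction("EX_a", {"A": 1.0}),
        Reaction("R1", {"A": -1, "B": 1}),
        Reaction("DM_b", {"B": -1.0}),
        Reaction("R_blocked", {"C": -1, "D": 1}),  # nothing makes C
    ])
    excluded = default_exclusions(model)
    assert {"EX_a", "DM_b", "R_blocked"} <= excluded
    assert "R1" not in excluded
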