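"""Dynamical network construction, communities, centralities and paths."""

import itertools

import networkx as nx
import numpy as np
import pytest

from modenet.correlation import CrossCorrelationMatrix
from modenet.fixtures import generate_reference_graph
from modenet.network import (
    DynamicalNetworkError,
    build_network,
    detect_communities,
    node_betweenness,
    path_length_histogram,
    suboptimal_paths,
)
from modenet.structures import ResidueKey


def make_dccm(matrix):
    n = len(matrix)
    keys = [ResidueKey("A", i + 1, "", "ALA") for i in range(n)]
    return CrossCorrelationMatrix(
        matrix=np.asarray(matrix, float), residue_keys=keys,
        n_frames=10, source_modes=[7],
    )


def frames_with_contacts(n, close_pairs, n_frames=10, close_fraction=1.0, spread=50.0):
    """Frame stack where listed pairs sit within 10 Å for the given
    fraction of frames and everyone else is far apart."""
    frames = np.zeros((n_frames, n, 3))
    base = np.arange(n)[:, None] * np.array([spread, 0.0, 0.0])
    for f in range(n_frames):
        coords = base.copy().astype(float)
        for a, b in close_pairs:
            if f < int(round(close_fraction * n_frames)):
                coords[b] = coords[a] + np.array([5.0, 0.0, 0.0])
            else:
                coords[b] = coords[a] + np.array([30.0, 0.0, 0.0])
        frames[f] = coords
    return frames


class TestBuildNetwork:
    def test_boundary_correlation_included(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 0.7
        dccm = make_dccm(c)
        frames = frames_with_contacts(2, [(0, 1)], close_fraction=0.8)
        net = build_network(dccm, frames)
        edge = net.edges[dccm.residue_keys[0], dccm.residue_keys[1]]
        assert edge["weight"] == pytest.approx(-np.log(0.7))
        assert edge["contact_fraction"] == pytest.approx(0.8)

    def test_contact_rule_conjunction(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 0.9
        dccm = make_dccm(c)
        frames = frames_with_contacts(2, [(0, 1)], close_fraction=0.5)
        net = build_network(dccm, frames)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 2  # isolated nodes retained

    def test_edge_set_matches_hand_enumeration(self):
        """6 residues with hand-set correlations and contacts."""
        rng = np.random.default_rng(3)
        c = np.eye(6)
        values = {(0, 1): 0.95, (1, 2): 0.75, (2, 3): 0.65, (3, 4): 0.9, (4, 5): 0.71}
        for (i, j), v in values.items():
            c[i, j] = c[j, i] = v
        contacts = [(0, 1), (1, 2), (3, 4)]  # pairs actually close
        dccm = make_dccm(c)
        frames = frames_with_contacts(6, contacts)
        net = build_network(dccm, frames)
        expected = {(0, 1), (1, 2), (3, 4)}  # |C|>=0.7 AND contact
        got = {
            (dccm.residue_keys.index(u), dccm.residue_keys.index(v))
            for u, v in net.edges
        }
        got = {tuple(sorted(p)) for p in got}
        assert got == expected

    def test_threshold_validation(self):
        dccm = make_dccm(np.eye(2))
        frames = frames_with_contacts(2, [])
        with pytest.raises(DynamicalNetworkError):
            build_network(dccm, frames, corr_threshold=1.5)
        with pytest.raises(DynamicalNetworkError):
            build_network(dccm, frames, dist_threshold=-1.0)

    def test_perfect_correlation_weight_finite(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 1.0
        net = build_network(make_dccm(c), frames_with_contacts(2, [(0, 1)]))
        weight = list(net.edges(data=True))[0][2]["weight"]
        assert 0 < weight < 1e-9


class TestCommunities:
    def test_barbell_split_recovered(self):
        graph = generate_reference_graph("barbell", {"m1": 12, "m2": 12})
        partition = detect_communities(graph, min_size=2)
        assert partition.n_communities == 2
        left = {partition.assignment[n] for n in range(12)}
        right = {partition.assignment[n] for n in range(12, 24)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_modularity_within_tolerance_of_bipartition_maximum(self):
        """On a 14-node barbell the chosen partition's modularity reaches
        the brute-force maximum over all bipartitions minus the 0.05
        correction allowance."""
        graph = generate_reference_graph("barbell", {"m1": 7, "m2": 7})
        partition = detect_communities(graph, min_size=2)
        nodes = list(graph.nodes)
        best = -1.0
        for mask in range(1, 2 ** (len(nodes) - 1)):
            side = [nodes[i] for i in range(len(nodes)) if mask >> i & 1]
            other = [n for n in nodes if n not in side]
            q = nx.community.modularity(graph, [side, other], weight="strength")
            best = max(best, q)
        assert partition.modularity >= best - 0.05

    def test_complete_graph_single_community(self):
        graph = nx.complete_graph(12)
        for u, v in graph.edges:
            graph[u][v]["weight"] = 1.0
            graph[u][v]["strength"] = 0.5
        partition = detect_communities(graph, min_size=2)
        assert partition.n_communities == 1

    def test_small_communities_pruned(self):
        graph = generate_reference_graph("barbell", {"m1": 4, "m2": 4})
        partition = detect_communities(graph, min_size=10)
        assert partition.n_communities == 0
        assert len(partition.pruned) == 8
        assert all(c == -1 for c in partition.assignment.values())

    def test_relabeling_invariance(self):
        graph = generate_reference_graph("barbell", {"m1": 6, "m2": 6})
        mapping = {n: f"node_{n:02d}" for n in graph.nodes}
        relabeled = nx.relabel_nodes(graph, mapping)
        p1 = detect_communities(graph, min_size=2)
        p2 = detect_communities(relabeled, min_size=2)
        for n in graph.nodes:
            for m in graph.nodes:
                same1 = p1.assignment[n] == p1.assignment[m]
                same2 = p2.assignment[mapping[n]] == p2.assignment[mapping[m]]
                assert same1 == same2

    def test_edgeless_network_all_unassigned(self):
        graph = nx.Graph()
        graph.add_nodes_from(range(5))
        with pytest.warns(UserWarning, match="edgeless"):
            partition = detect_communities(graph)
        assert all(c == -1 for c in partition.assignment.values())


class TestBetweenness:
    def test_path_graph_hand_enumeration(self):
        graph = generate_reference_graph("path", {"n": 4})
        result = node_betweenness(graph)
        assert result[0] == 0 and result[3] == 0
        assert result[1] == 2 and result[2] == 2

    def test_star_closed_form(self):
        n_leaves = 7  # center of a star with L leaves carries C(L, 2) pairs
        graph = generate_reference_graph("star", {"n": n_leaves})
        result = node_betweenness(graph)
        assert result[0] == n_leaves * (n_leaves - 1) / 2
        assert all(result[leaf] == 0 for leaf in range(1, n_leaves + 1))

    def test_random_graph_matches_brute_force(self):
        graph = generate_reference_graph("random", {"n": 9, "p": 0.45}, seed=7)
        result = node_betweenness(graph)
        brute = {n: 0.0 for n in graph.nodes}
        for s, t in itertools.combinations(graph.nodes, 2):
            paths = list(nx.all_shortest_paths(graph, s, t, weight="weight"))
            for path in paths:
                for node in path[1:-1]:
                    brute[node] += 1.0 / len(paths)
        for node in graph.nodes:
            assert result[node] == pytest.approx(brute[node], abs=1e-9)


class TestSuboptimalPaths:
    def test_exhausts_available_paths(self):
        graph = nx.Graph()
        graph.add_weighted_edges_from(
            [("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 2.0), ("b", "t", 2.0),
             ("s", "t", 5.0)]
        )
        ensemble = suboptimal_paths(graph, "s", "t", k=500)
        assert ensemble.n_paths == 3
        assert list(ensemble.lengths) == sorted(ensemble.lengths)
        assert ensemble.paths[0] == ("s", "a", "t")

    def test_top_k_matches_exhaustive_enumeration(self):
        graph = generate_reference_graph("random", {"n": 8, "p": 0.5}, seed=11)
        source, sink = 0, 7
        ensemble = suboptimal_paths(graph, source, sink, k=10)
        all_paths = []
        for path in nx.all_simple_paths(graph, source, sink):
            length = sum(
                graph[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
            )
            all_paths.append((length, tuple(str(n) for n in path), tuple(path)))
        all_paths.sort()
        expected = [p[2] for p in all_paths[:10]]
        assert list(ensemble.paths) == expected
        np.testing.assert_allclose(
            ensemble.lengths, [p[0] for p in all_paths[:10]], atol=1e-12
        )

    def test_optimal_path_equals_dijkstra(self):
        graph = generate_reference_graph("random", {"n": 9, "p": 0.5}, seed=3)
        ensemble = suboptimal_paths(graph, 0, 8, k=5)
        dijkstra = nx.dijkstra_path(graph, 0, 8, weight="weight")
        assert list(ensemble.optimal_path) == dijkstra

    def test_endpoint_degeneracy_is_one(self):
        graph = generate_reference_graph("random", {"n": 8, "p": 0.6}, seed=2)
        ensemble = suboptimal_paths(graph, 1, 6, k=50)
        assert ensemble.degeneracy[1] == 1.0
        assert ensemble.degeneracy[6] == 1.0
        assert all(0 < d <= 1 for d in ensemble.degeneracy.values())

    def test_disconnected_pair_explicit_empty(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=1.0)
        graph.add_edge("c", "d", weight=1.0)
        ensemble = suboptimal_paths(graph, "a", "c", k=10)
        assert ensemble.n_paths == 0
        assert ensemble.degeneracy == {}

    def test_same_source_sink_rejected(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=1.0)
        with pytest.raises(DynamicalNetworkError):
            suboptimal_paths(graph, "a", "a")


class TestHistogram:
    def test_equal_lengths_single_bin(self):
        graph = nx.Graph()
        graph.add_weighted_edges_from(
            [("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 1.0), ("b", "t", 1.0),
             ("s", "c", 1.0), ("c", "t", 1.0)]
        )
        ensemble = suboptimal_paths(graph, "s", "t", k=10)
        hist = path_length_histogram(ensemble, bin_width=0.5)
        assert hist["count"].sum() == ensemble.n_paths
        assert (hist["count"] > 0).sum() == 1

    def test_wide_bin_collapses_to_one(self):
        graph = generate_reference_graph("random", {"n": 8, "p": 0.6}, seed=5)
        ensemble = suboptimal_paths(graph, 0, 7, k=20)
        hist = path_length_histogram(ensemble, bin_width=1e6)
        assert len(hist) == 1 and hist["count"].iloc[0] == ensemble.n_paths

    def test_counts_match_direct_tally(self):
        graph = generate_reference_graph("random", {"n": 9, "p": 0.5}, seed=13)
        ensemble = suboptimal_paths(graph, 0, 8, k=40)
        width = 0.7
        hist = path_length_histogram(ensemble, bin_width=width)
        assert hist["count"].sum() == ensemble.n_paths
        for _, row in hist.iterrows():
            left, right = row["bin_left"], row["bin_right"]
            is_last = right == hist["bin_right"].iloc[-1]
            tally = sum(
                1 for l in ensemble.lengths
                if left <= l < right or (is_last and l == right)
            )
            assert row["count"] == tally
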