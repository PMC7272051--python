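"""Weighted residue networks, communities, centralities and path ensembles.

Nodes are Cα residues.  An edge joins residues i and j when their dynamic
cross-correlation satisfies ``|C(i,j)| >= 0.7`` and their Cα–Cα distance is
within 10 Å in at least 75% of the analyzed frames; its weight is
``-log|C(i,j)|``, so strongly coupled pairs are close in the path metric
and communication strength grows as path length shrinks.

Communities come from Girvan–Newman divisive clustering with a modularity
correction: among the dendrogram's partitions within 0.05 of the maximum
modularity, the one with the fewest communities is kept, and communities
below a minimum size are pruned.  Communication between chosen residue
pairs is characterized by the k = 500 shortest simple (sub)optimal paths
and the per-node degeneracy — the fraction of those paths that visit each
node.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CrossCorrelationMatrix
from .structures import ResidueKey

__all__ = [
    "DynamicalNetworkError",
    "CommunityPartition",
    "PathEnsemble",
    "build_network",
    "detect_communities",
    "node_betweenness",
    "suboptimal_paths",
    "path_length_histogram",
    "export_network_graphml",
]

CORR_THRESHOLD = 0.7
DIST_THRESHOLD = 10.0
FRAME_FRACTION = 0.75
MODULARITY_TOLERANCE = 0.05
MIN_COMMUNITY_SIZE = 10
N_SUBOPTIMAL_PATHS = 500
_LOG_CAP = 1.0 - 1e-12  # keeps -log|C| positive when synthetic data hits |C| = 1


class DynamicalNetworkError(ValueError):
    pass


def build_network(
    dccm: CrossCorrelationMatrix,
    frame_coords: np.ndarray,
    corr_threshold: float = CORR_THRESHOLD,
    dist_threshold: float = DIST_THRESHOLD,
    frame_fraction: float = FRAME_FRACTION,
) -> nx.Graph:
    """Residue interaction network from correlations plus persistent contact.

    ``frame_coords`` holds the selected-atom coordinates of every frame the
    DCCM was computed from, shape ``(n_frames, n_residues, 3)``.  Edge rule:
    ``|C| >= corr_threshold`` (boundary included) AND contact within
    ``dist_threshold`` Å in at least ``frame_fraction`` of the frames.
    Isolated nodes are retained.
    """
    if not 0 < corr_threshold <= 1:
        raise DynamicalNetworkError("correlation threshold must be in (0, 1]")
    if not 0 < frame_fraction <= 1:
        raise DynamicalNetworkError("frame fraction must be in (0, 1]")
    if dist_threshold <= 0:
        raise DynamicalNetworkError("distance threshold must be positive")
    coords = np.asarray(frame_coords, dtype=float)
    n = len(dccm.residue_keys)
    if coords.ndim != 3 or coords.shape[1] != n:
        raise DynamicalNetworkError("frame coordinates do not match the DCCM selection")
    graph = nx.Graph()
    for key in dccm.residue_keys:
        graph.add_node(key)
    # contact persistence over all frames
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (F, n, n)
    contact_fraction = np.mean(dist <= dist_threshold, axis=0)
    absC = np.abs(dccm.matrix)
    for i, j in itertools.combinations(range(n), 2):
        c = absC[i, j]
        if np.isnan(c) or c < corr_threshold:
            continue
        if contact_fraction[i, j] < frame_fraction:
            continue
        weight = float(-np.log(min(c, _LOG_CAP)))
        graph.add_edge(
            dccm.residue_keys[i],
            dccm.residue_keys[j],
            weight=weight,
            c=float(dccm.matrix[i, j]),
            strength=float(c),
            contact_fraction=float(contact_fraction[i, j]),
        )
    graph.graph["corr_threshold"] = corr_threshold
    graph.graph["dist_threshold"] = dist_threshold
    graph.graph["frame_fraction"] = frame_fraction
    return graph


@dataclass
class CommunityPartition:
    assignment: dict  # node -> community id; -1 when pruned/unassigned
    modularity: float
    n_communities: int
    pruned: list = field(default_factory=list)
    couplings: dict = field(default_factory=dict)  # (ci, cj) -> relative strength
    max_modularity: float = float("nan")

    def members(self, community: int) -> list:
        return sorted(n for n, c in self.assignment.items() if c == community)

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("residue\tcommunity\n")
            for node in sorted(self.assignment):
                fh.write(f"{node}\t{self.assignment[node]}\n")


def _deterministic_most_valuable_edge(graph: nx.Graph):
    """Highest weighted edge betweenness; ties broken by sorted edge key."""
    centrality = nx.edge_betweenness_centrality(graph, weight="weight")
    best = max(centrality.values())
    ties = [e for e, c in centrality.items() if c >= best - 1e-12]
    return min(ties, key=lambda e: tuple(sorted((str(e[0]), str(e[1])))))


def _partition_sequence(graph: nx.Graph):
    """Girvan–Newman dendrogram: the initial component split plus every
    partition produced by successive highest-betweenness edge removal."""
    base = tuple(sorted((sorted(c, key=str) for c in nx.connected_components(graph)), key=str))
    yield base
    yield from nx.community.girvan_newman(
        graph, most_valuable_edge=_deterministic_most_valuable_edge
    )


def detect_communities(
    network: nx.Graph,
    modularity_tolerance: float = MODULARITY_TOLERANCE,
    min_size: int = MIN_COMMUNITY_SIZE,
) -> CommunityPartition:
    """Girvan–Newman communities with the fewest-communities correction.

    Modularity is evaluated with correlation magnitude (``strength``) as
    the connection weight.  Among all partitions in the dendrogram whose
    modularity is within ``modularity_tolerance`` of the maximum, the one
    with the fewest communities wins (highest modularity breaks ties).
    Communities smaller than ``min_size`` are pruned: their members are
    reported but assigned community id −1.
    """
    if network.number_of_edges() == 0:
        warnings.warn("edgeless network: every node unassigned", stacklevel=2)
        return CommunityPartition(
            assignment={n: -1 for n in network.nodes},
            modularity=float("nan"),
            n_communities=0,
            pruned=sorted(network.nodes, key=str),
        )
    candidates = []  # (n_communities, modularity, partition)
    for partition in _partition_sequence(network):
        communities = [set(c) for c in partition]
        q = nx.community.modularity(network, communities, weight="strength")
        candidates.append((len(communities), q, communities))
    q_max = max(q for _, q, _ in candidates)
    eligible = [c for c in candidates if c[1] >= q_max - modularity_tolerance]
    n_comm, q_chosen, chosen = min(eligible, key=lambda c: (c[0], -c[1]))
    assignment: dict = {}
    pruned: list = []
    community_ids: dict[int, int] = {}
    next_id = 0
    for raw_id, members in enumerate(sorted(chosen, key=lambda c: str(sorted(c, key=str)))):
        if len(members) < min_size:
            pruned.extend(members)
            for node in members:
                assignment[node] = -1
        else:
            community_ids[raw_id] = next_id
            for node in members:
                assignment[node] = next_id
            next_id += 1
    couplings = _community_couplings(network, assignment)
    return CommunityPartition(
        assignment=assignment,
        modularity=q_chosen,
        n_communities=next_id,
        pruned=sorted(pruned, key=str),
        couplings=couplings,
        max_modularity=q_max,
    )


def _community_couplings(network: nx.Graph, assignment: dict) -> dict:
    """Summed |C| across each community pair, normalized by the largest."""
    sums: dict[tuple[int, int], float] = {}
    for u, v, data in network.edges(data=True):
        cu, cv = assignment.get(u, -1), assignment.get(v, -1)
        if cu < 0 or cv < 0 or cu == cv:
            continue
        key = (min(cu, cv), max(cu, cv))
        sums[key] = sums.get(key, 0.0) + data["strength"]
    if not sums:
        return {}
    top = max(sums.values())
    return {k: v / top for k, v in sums.items()}


def node_betweenness(network: nx.Graph) -> dict:
    """Unnormalized weighted-shortest-path betweenness centrality."""
    return nx.betweenness_centrality(network, normalized=False, weight="weight")


@dataclass
class PathEnsemble:
    source: ResidueKey
    sink: ResidueKey
    paths: list[tuple]  # node sequences, sorted by non-decreasing length
    lengths: np.ndarray  # summed edge weights
    k_requested: int
    degeneracy: dict = field(default_factory=dict)

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def optimal_path(self) -> tuple:
        return self.paths[0]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "source": str(self.source),
            "sink": str(self.sink),
            "k_requested": self.k_requested,
            "n_paths": self.n_paths,
            "paths": [
                {"length": round(float(l), 10), "nodes": [str(n) for n in p]}
                for p, l in zip(self.paths, self.lengths)
            ],
            "degeneracy": {str(n): round(float(d), 6) for n, d in
                           sorted(self.degeneracy.items(), key=lambda kv: str(kv[0]))},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _path_weight(network: nx.Graph, path: tuple) -> float:
    return float(sum(network[u][v]["weight"] for u, v in zip(path[:-1], path[1:])))


def suboptimal_paths(
    network: nx.Graph,
    source,
    sink,
    k: int = N_SUBOPTIMAL_PATHS,
) -> PathEnsemble:
    """The k lowest-total-weight simple paths between two residues.

    Paths are enumerated in non-decreasing length (Yen's algorithm); ties
    at the k-th length are resolved by lexicographic node order so the
    returned set is deterministic.  Node degeneracy — the fraction of the
    returned paths crossing each node — is 1 for source and sink by
    definition.  A disconnected pair yields an explicit empty ensemble.
    """
    if source == sink:
        raise DynamicalNetworkError("source and sink must differ")
    for node in (source, sink):
        if node not in network:
            raise DynamicalNetworkError(f"node {node} not in network")
    if not nx.has_path(network, source, sink):
        return PathEnsemble(
            source=source, sink=sink, paths=[], lengths=np.empty(0),
            k_requested=k, degeneracy={},
        )
    generator = nx.shortest_simple_paths(network, source, sink, weight="weight")
    collected: list[tuple] = []
    lengths: list[float] = []
    for path in generator:
        w = _path_weight(network, tuple(path))
        if len(collected) >= k and w > lengths[-1] + 1e-12:
            break
        collected.append(tuple(path))
        lengths.append(w)
        # keep draining while inside the tie class at the k-th length
    order = sorted(
        range(len(collected)),
        key=lambda i: (lengths[i], tuple(str(n) for n in collected[i])),
    )[:k]
    paths = [collected[i] for i in order]
    final_lengths = np.array([lengths[i] for i in order])
    visits: dict = {}
    for path in paths:
        for node in set(path):
            visits[node] = visits.get(node, 0) + 1
    degeneracy = {node: count / len(paths) for node, count in visits.items()}
    return PathEnsemble(
        source=source, sink=sink, paths=paths, lengths=final_lengths,
        k_requested=k, degeneracy=degeneracy,
    )


def path_length_histogram(ensemble: PathEnsemble, bin_width: float) -> pd.DataFrame:
    """Counts of path lengths per bin; counts sum to the ensemble size."""
    if ensemble.n_paths == 0:
        raise DynamicalNetworkError("empty path ensemble")
    if bin_width <= 0:
        raise DynamicalNetworkError("bin width must be positive")
    lo = float(ensemble.lengths.min())
    hi = float(ensemble.lengths.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # right-inclusive final edge
    counts, edges = np.histogram(ensemble.lengths, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def export_network_graphml(network: nx.Graph, path: str | Path) -> None:
    out = nx.Graph()
    for node, data in network.nodes(data=True):
        out.add_node(str(node), **data)
    for u, v, data in network.edges(data=True):
        out.add_edge(str(u), str(v), **data)
    nx.write_graphml(out, str(path))
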