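"""Motion fingerprints, Mantel similarity, and functional classification.

A mode's motion is fingerprinted as the Cα distance-difference matrix
``ΔM = M₊ − M_χ``: the pairwise Cα distance matrix of the structure
displaced +1 Å MRMS along the mode, minus that of the reference structure.
ΔM is invariant under rigid-body motion, so two modes are compared by how
they deform the internal geometry rather than by eigenvector overlap.

Fingerprints are compared with the Mantel test: Pearson correlation of the
vectorized upper triangles, with significance from simultaneous row/column
permutations of one matrix.  Pairs with ``|r| >= 0.6`` at ``p < 0.001`` are
considered the same motion; connected components of the resulting graph
across systems give the shared/unique classification.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .nma import ModeTrajectory
from .structures import CalphaSelection, ResidueKey, ResidueMapping

__all__ = [
    "MotionFingerprint",
    "MantelResult",
    "MotionClassification",
    "compute_fingerprint",
    "mantel_test",
    "align_fingerprints",
    "build_similarity_graph",
    "classify_motions",
    "redundancy_report",
    "similarity_matrix_frame",
    "export_graphml",
]

R_THRESHOLD = 0.6
P_THRESHOLD = 0.001
DEFAULT_PERMUTATIONS = 9999
EXHAUSTIVE_MAX_N = 7


class SimilarityError(ValueError):
    pass


@dataclass
class MotionFingerprint:
    """Distance-difference matrix identifying one mode's motion."""

    system_id: str
    mode_label: int
    delta: np.ndarray  # (n, n) symmetric, zero diagonal, Å
    residue_keys: list[ResidueKey]
    minus_plus_r: float | None = None  # corr of (M₋−M_χ) vs −(M₊−M_χ)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        n = len(self.residue_keys)
        if self.delta.shape != (n, n):
            raise SimilarityError("fingerprint dimensions do not match residue list")

    @property
    def node(self) -> tuple[str, int]:
        return (self.system_id, self.mode_label)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.delta), k=1)
        return self.delta[iu]


def _ca_distance_matrix(coord: np.ndarray, indices: np.ndarray) -> np.ndarray:
    return squareform(pdist(coord[indices]))


def compute_fingerprint(
    trajectory: ModeTrajectory,
    selection: CalphaSelection,
    system_id: str = "",
) -> MotionFingerprint:
    """ΔM = distances(+A frame) − distances(reference frame).

    The −A fingerprint is computed as well and its correlation with the +A
    fingerprint (after sign reversal) is recorded in ``minus_plus_r`` as a
    sanity check — for a harmonic displacement the two are identical up to
    sign, and strong disagreement flags heavy anharmonicity.
    """
    indices = np.asarray(selection.indices)
    if len(indices) < 3:
        raise SimilarityError("need at least three C-alpha positions")
    if indices.max() >= trajectory.frames.shape[1]:
        raise SimilarityError("selection does not match trajectory atoms")
    amplitude = float(trajectory.targets.max())
    ref = _ca_distance_matrix(trajectory.frame_at(0.0), indices)
    plus = _ca_distance_matrix(trajectory.frame_at(amplitude), indices)
    delta = plus - ref
    minus_plus_r: float | None = None
    if trajectory.targets.min() < 0:
        minus = _ca_distance_matrix(trajectory.frame_at(-amplitude), indices)
        delta_minus = minus - ref
        iu = np.triu_indices(len(indices), k=1)
        a, b = delta[iu], -delta_minus[iu]
        if a.std() > 0 and b.std() > 0:
            minus_plus_r = float(np.corrcoef(a, b)[0, 1])
    return MotionFingerprint(
        system_id=system_id,
        mode_label=trajectory.mode_label,
        delta=delta,
        residue_keys=list(selection.residue_keys),
        minus_plus_r=minus_plus_r,
    )


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    scheme: str  # "exhaustive" | "sampled"
    seed: int | None = None


def _corr_against(a_centered: np.ndarray, a_norm: float, b_vec: np.ndarray) -> float:
    b_centered = b_vec - b_vec.mean()
    denom = a_norm * np.linalg.norm(b_centered)
    return float(a_centered @ b_centered / denom)


def mantel_test(
    fp_a: MotionFingerprint | np.ndarray,
    fp_b: MotionFingerprint | np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    exhaustive_max_n: int = EXHAUSTIVE_MAX_N,
) -> MantelResult:
    """Mantel correlation between two symmetric matrices.

    ``r`` is the Pearson correlation of the strict upper triangles.  The
    p-value is two-sided on ``|r|`` under simultaneous row/column
    permutation of the second matrix: exhaustive enumeration of all ``n!``
    permutations when ``n <= exhaustive_max_n``, otherwise ``n_permutations``
    seeded draws with the add-one correction
    ``p = (1 + #{|r*| >= |r|}) / (1 + n_permutations)``.
    """
    mat_a = fp_a.delta if isinstance(fp_a, MotionFingerprint) else np.asarray(fp_a, float)
    mat_b = fp_b.delta if isinstance(fp_b, MotionFingerprint) else np.asarray(fp_b, float)
    if mat_a.shape != mat_b.shape or mat_a.ndim != 2 or mat_a.shape[0] != mat_a.shape[1]:
        raise SimilarityError("fingerprints must be square matrices of equal size")
    n = mat_a.shape[0]
    if n < 3:
        raise SimilarityError("Mantel test needs at least a 3x3 matrix")
    iu = np.triu_indices(n, k=1)
    vec_a = mat_a[iu]
    vec_b = mat_b[iu]
    if vec_a.std() == 0 or vec_b.std() == 0:
        raise SimilarityError("zero-variance fingerprint: Mantel r undefined")
    a_centered = vec_a - vec_a.mean()
    a_norm = float(np.linalg.norm(a_centered))
    r_obs = _corr_against(a_centered, a_norm, vec_b)

    if n <= exhaustive_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            r_star = _corr_against(a_centered, a_norm, mat_b[p[iu[0]], p[iu[1]]])
            if abs(r_star) >= abs(r_obs) - 1e-12:
                count += 1
            total += 1
        return MantelResult(
            r=r_obs, p_value=count / total, n_permutations=total,
            scheme="exhaustive", seed=None,
        )

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 512
    done = 0
    while done < n_permutations:
        size = min(chunk, n_permutations - done)
        perms = np.array([rng.permutation(n) for _ in range(size)])
        rows = perms[:, iu[0]]
        cols = perms[:, iu[1]]
        vecs = mat_b[rows, cols]  # (size, n_pairs)
        centered = vecs - vecs.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        r_stars = centered @ a_centered / (a_norm * norms)
        count += int(np.sum(np.abs(r_stars) >= abs(r_obs) - 1e-12))
        done += size
    p_value = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r=r_obs, p_value=p_value, n_permutations=n_permutations,
        scheme="sampled", seed=seed,
    )


def align_fingerprints(
    fp_a: MotionFingerprint,
    fp_b: MotionFingerprint,
    mapping: ResidueMapping,
) -> tuple[MotionFingerprint, MotionFingerprint]:
    """Restrict two fingerprints to their mapped common residues, in A's
    residue order, so they become Mantel-comparable."""
    index_a = {key: i for i, key in enumerate(fp_a.residue_keys)}
    index_b = {key: i for i, key in enumerate(fp_b.residue_keys)}
    rows_a: list[int] = []
    rows_b: list[int] = []
    keys: list[ResidueKey] = []
    for key_a, key_b in mapping.pairs:
        if key_a in index_a and key_b in index_b:
            rows_a.append(index_a[key_a])
            rows_b.append(index_b[key_b])
            keys.append(key_a)
    if len(keys) < 3:
        raise SimilarityError("fewer than three common residues after mapping")
    ia = np.asarray(rows_a)
    ib = np.asarray(rows_b)
    sub_a = MotionFingerprint(
        fp_a.system_id, fp_a.mode_label, fp_a.delta[np.ix_(ia, ia)], keys,
        fp_a.minus_plus_r,
    )
    sub_b = MotionFingerprint(
        fp_b.system_id, fp_b.mode_label, fp_b.delta[np.ix_(ib, ib)], keys,
        fp_b.minus_plus_r,
    )
    return sub_a, sub_b


def build_similarity_graph(
    fingerprints: list[MotionFingerprint],
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    mappings: dict[tuple[str, str], ResidueMapping] | None = None,
    test_all_pairs: bool = False,
) -> nx.Graph:
    """All-pairs Mantel comparison thresholded into a similarity graph.

    Nodes are ``(system_id, mode_label)``; an edge requires ``|r| >=
    r_threshold`` and ``p < p_threshold`` and carries both values.  The full
    signed correlation matrix is stored on the graph (``graph.graph["r_matrix"]``,
    a DataFrame) for table-style reporting.  Permutation p-values are by
    default only evaluated for pairs that already pass the ``|r|`` screen
    (the p of a sub-threshold pair cannot create an edge); set
    ``test_all_pairs`` to force the full quadratic permutation sweep.
    """
    if len(fingerprints) < 2:
        raise SimilarityError("need at least two fingerprints")
    nodes = [fp.node for fp in fingerprints]
    if len(set(nodes)) != len(nodes):
        raise SimilarityError("duplicate (system, mode) fingerprints")
    graph = nx.Graph()
    for fp in fingerprints:
        graph.add_node(fp.node, system=fp.system_id, mode=fp.mode_label)
    r_frame = pd.DataFrame(
        np.full((len(nodes), len(nodes)), np.nan),
        index=[f"{s}:{m}" for s, m in nodes],
        columns=[f"{s}:{m}" for s, m in nodes],
    )
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(len(fingerprints)), 2):
        fa, fb = fingerprints[i], fingerprints[j]
        if fa.system_id != fb.system_id and mappings:
            key = (fa.system_id, fb.system_id)
            rkey = (fb.system_id, fa.system_id)
            if key in mappings:
                fa, fb = align_fingerprints(fa, fb, mappings[key])
            elif rkey in mappings:
                fb, fa = align_fingerprints(fb, fa, mappings[rkey])
        pair_seed = int(rng.integers(0, 2**31 - 1))
        # screen on r first; run permutations only when the edge is possible
        iu = np.triu_indices(len(fa.delta), k=1)
        va, vb = fa.delta[iu], fb.delta[iu]
        if va.std() == 0 or vb.std() == 0:
            raise SimilarityError(
                f"zero-variance fingerprint for {fa.node} or {fb.node}"
            )
        r_quick = float(np.corrcoef(va, vb)[0, 1])
        r_frame.iloc[i, j] = r_frame.iloc[j, i] = r_quick
        if not test_all_pairs and abs(r_quick) < r_threshold:
            continue
        result = mantel_test(fa, fb, n_permutations=n_permutations, seed=pair_seed)
        if abs(result.r) >= r_threshold and result.p_value < p_threshold:
            graph.add_edge(
                fingerprints[i].node, fingerprints[j].node,
                r=result.r, p=result.p_value,
            )
    np.fill_diagonal(r_frame.values, 1.0)
    graph.graph["r_matrix"] = r_frame
    graph.graph["r_threshold"] = r_threshold
    graph.graph["p_threshold"] = p_threshold
    return graph


@dataclass
class MotionClassification:
    """Shared/unique labels for every (system, mode) node.

    A connected component spanning more than one system is a shared motion,
    tagged with the signaling outcomes its systems have in common; a
    component confined to one system is unique, tagged with the outcomes
    that distinguish that system from the rest of the panel.
    """

    node_class: dict[tuple[str, int], str]  # "shared" | "unique"
    node_component: dict[tuple[str, int], int]
    components: list[dict] = field(default_factory=list)
    phenotypes: dict[str, set] = field(default_factory=dict)

    def nodes_in_class(self, label: str) -> list[tuple[str, int]]:
        return sorted(n for n, c in self.node_class.items() if c == label)

    def shared_modes(self, system: str) -> list[int]:
        return sorted(
            m for (s, m), c in self.node_class.items()
            if s == system and c == "shared"
        )

    def unique_modes(self, system: str) -> list[int]:
        return sorted(
            m for (s, m), c in self.node_class.items()
            if s == system and c == "unique"
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "components": self.components,
            "nodes": [
                {
                    "system": s,
                    "mode": m,
                    "class": self.node_class[(s, m)],
                    "component": self.node_component[(s, m)],
                }
                for (s, m) in sorted(self.node_class)
            ],
            "phenotypes": {k: sorted(v) for k, v in self.phenotypes.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def redundancy_report(graph: nx.Graph) -> list[list[tuple[str, int]]]:
    """Connected components of a (single-system) similarity graph —
    groups of mutually redundant modes."""
    return [sorted(c) for c in nx.connected_components(graph)]


def classify_motions(
    graph: nx.Graph,
    phenotype_map: dict[str, set | list],
) -> MotionClassification:
    """Label each motion shared or unique from the similarity graph.

    ``phenotype_map`` gives, per system, the set of signaling outcomes that
    system supports (e.g. WT supports both the trophic and the nociceptive
    response, the variant only the trophic one).  Shared components are
    tagged with the intersection of their systems' outcomes; unique
    components with the outcomes separating their system from the others.
    """
    systems = sorted({data["system"] for _, data in graph.nodes(data=True)})
    if len(systems) < 2:
        raise SimilarityError(
            "classification needs at least two systems; "
            "use redundancy_report for a single system"
        )
    missing = [s for s in systems if s not in phenotype_map]
    if missing:
        raise SimilarityError(f"phenotype map lacks systems: {missing}")
    phenotypes = {s: set(phenotype_map[s]) for s in systems}
    node_class: dict[tuple[str, int], str] = {}
    node_component: dict[tuple[str, int], int] = {}
    components: list[dict] = []
    for comp_id, nodes in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ):
        nodes = sorted(nodes)
        comp_systems = sorted({s for s, _ in nodes})
        if len(comp_systems) > 1:
            label = "shared"
            tags = sorted(set.intersection(*(phenotypes[s] for s in comp_systems)))
        else:
            label = "unique"
            sys_id = comp_systems[0]
            others = set().union(*(phenotypes[s] for s in systems if s != sys_id))
            tags = sorted(phenotypes[sys_id] ^ others)
        for node in nodes:
            node_class[node] = label
            node_component[node] = comp_id
        components.append(
            {
                "id": comp_id,
                "class": label,
                "systems": comp_systems,
                "outcome_tags": tags,
                "nodes": [list(n) for n in nodes],
                "edges": [
                    {"a": list(u), "b": list(v), "r": round(d["r"], 4)}
                    for u, v, d in graph.edges(nodes, data=True)
                    if u in set(nodes) and v in set(nodes)
                ],
            }
        )
    return MotionClassification(
        node_class=node_class,
        node_component=node_component,
        components=components,
        phenotypes=phenotypes,
    )


def similarity_matrix_frame(graph: nx.Graph) -> pd.DataFrame:
    """The full signed Mantel r matrix as a DataFrame (systems × modes)."""
    frame = graph.graph.get("r_matrix")
    if frame is None:
        raise SimilarityError("graph carries no similarity matrix")
    return frame


def export_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export with string node ids (``system:mode``)."""
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        out.add_node(f"{node[0]}:{node[1]}", **data)
    for u, v, data in graph.edges(data=True):
        out.add_edge(f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}", **data)
    nx.write_graphml(out, str(path))
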