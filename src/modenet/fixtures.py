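"""Synthetic coarse-grained test systems with engineered motion structure.

These generators build bead ("Cα-only") multi-chain complexes whose elastic
networks are fully known, so every pipeline stage can be exercised without
any external structure.  The dimer-of-dimers geometry mimics a 2:2
ligand/receptor complex: two central ligand chains in mutual contact, two
flanking receptor chains each touching one ligand chain but not each other,
so the receptor chains can only communicate through the ligand dimer.

A variant pair emulates a point mutation as a local spring perturbation:
a controlled fraction of the springs around one "mutation site" bead is
deleted, which perturbs a subset of the low-frequency modes while leaving
the rest essentially intact.  All generation is pure given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .nma import ENMTopology, enm_topology
from .structures import MolecularStructure, ResidueKey, ResidueMapping, map_residues

__all__ = [
    "FixtureSpec",
    "SpringPerturbation",
    "VariantPair",
    "generate_complex",
    "generate_variant_pair",
    "generate_reference_graph",
]

CARBON_MASS = 12.011


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a synthetic bead complex.

    geometry: "helix" (side-by-side helical chains), "lattice" (cubic
    grid), or "dimer_of_dimers" (2:2 complex layout, 4 chains).
    """

    geometry: str = "dimer_of_dimers"
    n_chains: int = 4
    beads_per_chain: int = 30
    seed: int = 0
    cutoff: float = 10.0
    spring_k: float = 1.0
    jitter: float = 0.25  # Å of seeded positional noise
    allow_disconnected: bool = False


def _helix(n: int, radius: float = 3.0, rise: float = 1.6, turn_deg: float = 100.0,
           origin: np.ndarray | None = None) -> np.ndarray:
    t = np.arange(n)
    ang = np.radians(turn_deg) * t
    xyz = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])
    if origin is not None:
        xyz = xyz + origin
    return xyz


def _chain_layout(spec: FixtureSpec) -> list[np.ndarray]:
    n = spec.beads_per_chain
    if spec.geometry == "helix":
        return [
            _helix(n, origin=np.array([9.0 * c, 0.0, 0.0]))
            for c in range(spec.n_chains)
        ]
    if spec.geometry == "lattice":
        coords = []
        side = int(np.ceil(n ** (1 / 3)))
        grid = 3.8 * np.array(
            [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
        )[:n]
        for c in range(spec.n_chains):
            coords.append(grid + np.array([side * 3.8 + 4.0, 0.0, 0.0]) * c)
        return coords
    if spec.geometry == "dimer_of_dimers":
        if spec.n_chains != 4:
            raise FixtureError("dimer_of_dimers requires exactly 4 chains")
        # ligand chains A/B central and touching; receptor chains C/D flank
        origins = [
            np.array([-4.0, 0.0, 0.0]),   # A (ligand)
            np.array([+4.0, 0.0, 0.0]),   # B (ligand)
            np.array([-11.5, 0.0, 0.0]),  # C (receptor, touches A only)
            np.array([+11.5, 0.0, 0.0]),  # D (receptor, touches B only)
        ]
        return [_helix(n, origin=o) for o in origins]
    raise FixtureError(f"unknown geometry {spec.geometry!r}")


def generate_complex(spec: FixtureSpec) -> tuple[MolecularStructure, ENMTopology]:
    """Build a bead complex and its elastic network.

    Beads are CA-named carbon particles, residues named ALA, chains labelled
    A, B, C, ... with sequential numbering from 1 within each chain.
    """
    rng = np.random.default_rng(spec.seed)
    chains = _chain_layout(spec)
    coord = np.concatenate(chains)
    coord = coord + rng.normal(0.0, spec.jitter, size=coord.shape)
    n_total = len(coord)
    from scipy.spatial.distance import pdist

    if n_total > 1 and pdist(coord).min() < 1.0:
        raise FixtureError("overlapping beads in generated complex")
    residues = []
    res_index = np.empty(n_total, dtype=int)
    pos = 0
    for c, chain_coord in enumerate(chains):
        chain_id = chr(ord("A") + c)
        for r in range(len(chain_coord)):
            residues.append(ResidueKey(chain_id, r + 1, "", "ALA"))
            res_index[pos] = len(residues) - 1
            pos += 1
    structure = MolecularStructure(
        serial=np.arange(1, n_total + 1),
        atom_name=np.full(n_total, "CA", dtype="U6"),
        element=np.full(n_total, "C", dtype="U2"),
        mass=np.full(n_total, CARBON_MASS),
        coord=coord,
        hetero=np.zeros(n_total, dtype=bool),
        res_index=res_index,
        residues=residues,
    )
    structure.validate()
    topology = enm_topology(coord, cutoff=spec.cutoff, k=spec.spring_k)
    if not spec.allow_disconnected and not _is_connected(topology):
        raise FixtureError("generated elastic network is disconnected")
    return structure, topology


def _is_connected(topology: ENMTopology) -> bool:
    if topology.n_springs == 0:
        return topology.n_atoms <= 1
    graph = nx.Graph()
    graph.add_nodes_from(range(topology.n_atoms))
    graph.add_edges_from(map(tuple, topology.pairs))
    return nx.is_connected(graph)


def densest_interface_bead(
    structure: MolecularStructure,
    topology: ENMTopology,
    chain_a: str = "A",
    chain_b: str = "C",
) -> ResidueKey:
    """The chain-A bead with the most springs to chain B — the natural
    'interface residue' of the generated complex (ties break to the lowest
    residue number)."""
    counts: dict[ResidueKey, int] = {}
    for i, j in topology.pairs:
        ri, rj = structure.res_index[i], structure.res_index[j]
        ki, kj = structure.residues[ri], structure.residues[rj]
        if {ki.chain_id, kj.chain_id} == {chain_a, chain_b}:
            key = ki if ki.chain_id == chain_a else kj
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise FixtureError(f"chains {chain_a} and {chain_b} share no contacts")
    return min(counts, key=lambda k: (-counts[k], k.res_id))


@dataclass(frozen=True)
class SpringPerturbation:
    """Local contact-topology change standing in for a point mutation.

    Springs with an endpoint within ``radius`` Å of the site bead are the
    perturbation's candidates.  With ``drop_interface`` (default), every
    spring that joins the site bead itself to another chain is deleted —
    the controlled part, modelling a substituted side chain that breaks
    its own inter-subunit contacts — and ``remove_fraction`` of the
    remaining candidates is deleted at random with the given seed."""

    site: ResidueKey
    remove_fraction: float = 0.3
    radius: float = 7.0
    seed: int = 0
    drop_interface: bool = True
    mutant_res_name: str = "TRP"
    allow_disconnected: bool = False


@dataclass
class VariantPair:
    wt: MolecularStructure
    variant: MolecularStructure
    wt_topology: ENMTopology
    variant_topology: ENMTopology
    mapping: ResidueMapping
    removed_springs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))


def generate_variant_pair(
    spec: FixtureSpec, perturbation: SpringPerturbation
) -> VariantPair:
    """Wild-type/variant pair differing only in local spring topology.

    The variant shares the wild-type coordinates; its residue at the
    mutation site is renamed so the residue mapping flags exactly one
    substitution, and springs around the site are deleted per the
    perturbation.  Ground truth about which modes survive is established
    by running the comparison pipeline, not asserted here.
    """
    wt, wt_topology = generate_complex(spec)
    site_idx = None
    for i, key in enumerate(wt.residues):
        if key == perturbation.site:
            site_idx = i
            break
    if site_idx is None:
        raise FixtureError(f"mutation site {perturbation.site} not in structure")
    site_atom = int(wt.residue_atoms(site_idx)[0])
    dist_to_site = np.linalg.norm(wt.coord - wt.coord[site_atom], axis=1)
    near = dist_to_site <= perturbation.radius
    candidate = np.nonzero(near[wt_topology.pairs[:, 0]] | near[wt_topology.pairs[:, 1]])[0]
    if len(candidate) == 0:
        raise FixtureError("perturbation touches no spring")
    chain_of = np.array(
        [wt.residues[r].chain_id for r in wt.res_index[wt_topology.pairs].reshape(-1)]
    ).reshape(-1, 2)
    crosses_chains = chain_of[:, 0] != chain_of[:, 1]
    rng = np.random.default_rng(perturbation.seed)
    null_perturbation = perturbation.remove_fraction == 0
    touches_site = (wt_topology.pairs[:, 0] == site_atom) | (
        wt_topology.pairs[:, 1] == site_atom
    )
    forced = (
        np.nonzero(touches_site & crosses_chains)[0]
        if perturbation.drop_interface and not null_perturbation
        else np.empty(0, int)
    )
    rest = candidate[~np.isin(candidate, forced)]
    n_remove = int(round(perturbation.remove_fraction * len(rest)))
    if not null_perturbation and len(forced) == 0:
        n_remove = max(1, n_remove)
    sampled = rng.choice(rest, size=n_remove, replace=False) if n_remove else np.empty(0, int)
    removed = np.concatenate([forced, sampled]).astype(int)
    var_topology = wt_topology.remove_springs(removed)
    if not perturbation.allow_disconnected and not _is_connected(var_topology):
        raise FixtureError("perturbation disconnects the elastic network")
    var_residues = list(wt.residues)
    var_residues[site_idx] = replace(
        wt.residues[site_idx], res_name=perturbation.mutant_res_name
    )
    variant = MolecularStructure(
        serial=wt.serial.copy(),
        atom_name=wt.atom_name.copy(),
        element=wt.element.copy(),
        mass=wt.mass.copy(),
        coord=wt.coord.copy(),
        hetero=wt.hetero.copy(),
        res_index=wt.res_index.copy(),
        residues=var_residues,
    )
    variant.validate()
    mapping = map_residues(wt, variant)
    return VariantPair(
        wt=wt,
        variant=variant,
        wt_topology=wt_topology,
        variant_topology=var_topology,
        mapping=mapping,
        removed_springs=wt_topology.pairs[removed],
    )


def generate_reference_graph(
    kind: str, params: dict | None = None, seed: int = 0
) -> nx.Graph:
    """Deterministic weighted graphs used as oracles for network analyses.

    kinds: "barbell" (params m1, m2 clique sizes), "path" (n), "star" (n
    leaves), "random" (n, p, weighted Erdős–Rényi, connected by
    construction).  Every edge carries ``weight`` (path metric) and
    ``strength`` (connection weight for modularity).
    """
    params = dict(params or {})
    if kind == "barbell":
        m1 = int(params.get("m1", 12))
        m2 = int(params.get("m2", 12))
        left = nx.complete_graph(m1)
        right = nx.relabel_nodes(nx.complete_graph(m2), {i: i + m1 for i in range(m2)})
        graph = nx.union(left, right)
        graph.add_edge(m1 - 1, m1)
    elif kind == "path":
        graph = nx.path_graph(int(params.get("n", 4)))
    elif kind == "star":
        graph = nx.star_graph(int(params.get("n", 5)))
    elif kind == "random":
        n = int(params.get("n", 9))
        p = float(params.get("p", 0.5))
        rng = np.random.default_rng(seed)
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    graph.add_edge(i, j)
        for i in range(n - 1):  # guarantee connectivity deterministically
            if not graph.has_edge(i, i + 1) and not nx.has_path(graph, i, i + 1):
                graph.add_edge(i, i + 1)
        for u, v in sorted(graph.edges):
            graph[u][v]["weight"] = float(rng.uniform(0.5, 1.5))
    else:
        raise FixtureError(f"unknown reference graph kind {kind!r}")
    for u, v in graph.edges:
        data = graph[u][v]
        data.setdefault("weight", 1.0)
        data["strength"] = float(np.exp(-data["weight"]))
    return graph
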