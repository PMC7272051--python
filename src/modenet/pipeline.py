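"""End-to-end orchestration: structures → modes → trajectories →
fingerprints → classification → per-class DCCM / networks / paths /
interactions, driven by a single configuration object.

Every stage writes its table- or figure-analogue artifact into the results
directory (similarity matrix, classification report, per-class correlation
maps, communities, centralities, path ensembles with length histograms,
degeneracy table, flexibility profiles, interaction diffs) plus a run
manifest with config echo, versions, derived seeds and output hashes.
Identical config and seed reproduce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import ModeGroup, compute_dccm, compute_group_rmsf
from .fixtures import (
    FixtureSpec,
    SpringPerturbation,
    generate_complex,
    generate_variant_pair,
)
from .interactions import (
    detect_hydrogen_bonds,
    detect_salt_bridges,
    diff_interactions,
    records_to_tsv,
)
from .network import (
    build_network,
    detect_communities,
    export_network_graphml,
    node_betweenness,
    path_length_histogram,
    suboptimal_paths,
)
from .nma import (
    ENMTopology,
    build_enm_hessian,
    compute_normal_modes,
    enm_topology,
    generate_mode_trajectory,
    transfer_mode_trajectory,
)
from .similarity import (
    build_similarity_graph,
    classify_motions,
    compute_fingerprint,
    export_graphml,
    mantel_test,
    redundancy_report,
)
from .structures import (
    MolecularStructure,
    ResidueKey,
    map_residues,
    read_structure,
    select_calpha,
    write_structure,
)

__all__ = [
    "RunConfig",
    "SystemConfig",
    "PipelineError",
    "run_pipeline",
    "run_transfer_experiment",
    "analyze_systems",
    "stage_seed",
]


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SystemConfig:
    id: str
    structure: str | None = None  # PDB path; None when synthetic
    phenotypes: list[str] = field(default_factory=list)
    model: int = 1


@dataclass
class NmaConfig:
    cutoff: float = 10.0
    spring_k: float = 1.0
    n_modes: int = 20  # analysis set: the 20 lowest non-trivial modes
    amplitude: float = 1.0  # Å MRMS
    n_frames: int = 21
    relax: bool = False
    restraint_k: float = 100.0
    max_iter: int = 500


@dataclass
class SimilarityConfig:
    r_threshold: float = 0.6
    p_threshold: float = 0.001
    n_permutations: int = 9999


@dataclass
class NetworkConfig:
    corr_threshold: float = 0.7
    dist_threshold: float = 10.0
    frame_fraction: float = 0.75
    modularity_tolerance: float = 0.05
    min_community_size: int = 10
    k_paths: int = 500
    path_endpoints: list[list[str]] = field(default_factory=list)  # ["C:15","D:15"]


@dataclass
class InteractionConfig:
    hbond_distance: float = 3.0
    hbond_angle: float = 20.0
    salt_bridge_distance: float = 3.2
    occupancy_threshold: float = 0.5


@dataclass
class SyntheticConfig:
    """When set, the systems are generated instead of read from disk:
    the first system id becomes the wild type, the second the variant."""

    geometry: str = "dimer_of_dimers"
    n_chains: int = 4
    beads_per_chain: int = 30
    jitter: float = 0.25
    # None = auto: the ligand bead with the densest receptor-chain contact
    # set, i.e. the generated complex's interface residue
    mutation_site: str | None = None
    remove_fraction: float = 0.3
    perturbation_radius: float = 7.0


@dataclass
class RunConfig:
    systems: list[SystemConfig] = field(default_factory=list)
    nma: NmaConfig = field(default_factory=NmaConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    synthetic: SyntheticConfig | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        systems = [SystemConfig(**s) for s in raw.get("systems", [])]
        cfg = cls(
            systems=systems,
            nma=NmaConfig(**raw.get("nma", {})),
            similarity=SimilarityConfig(**raw.get("similarity", {})),
            network=NetworkConfig(**raw.get("network", {})),
            interactions=InteractionConfig(**raw.get("interactions", {})),
            synthetic=(
                SyntheticConfig(**(raw["synthetic"] or {}))
                if raw.get("synthetic") is not None
                else None
            ),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.systems:
            raise PipelineError("config lists no systems")
        if len({s.id for s in self.systems}) != len(self.systems):
            raise PipelineError("duplicate system ids")
        if not 0 < self.similarity.r_threshold:
            raise PipelineError("similarity r threshold must be positive")
        if not 0 < self.similarity.p_threshold <= 1:
            raise PipelineError("similarity p threshold must be in (0, 1]")
        if not 0 < self.network.corr_threshold <= 1:
            raise PipelineError("network correlation threshold must be in (0, 1]")
        if not 0 < self.network.frame_fraction <= 1:
            raise PipelineError("network frame fraction must be in (0, 1]")
        if self.synthetic is not None and len(self.systems) != 2:
            raise PipelineError("synthetic mode generates exactly two systems")

    def to_dict(self) -> dict:
        data = asdict(self)
        return data


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one.

    Stages draw from independent streams keyed by name, so adding a stage
    never shifts another stage's randomness.  Kept below 2**31.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _parse_residue(token: str) -> ResidueKey:
    chain, _, rest = token.partition(":")
    num = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
    icode = rest[len(num):]
    return ResidueKey(chain, int(num), icode)


# --------------------------------------------------------------------------
# in-memory analysis
# --------------------------------------------------------------------------

@dataclass
class SystemAnalysis:
    system_id: str
    structure: MolecularStructure
    topology: ENMTopology
    mode_set: object
    selection: object
    trajectories: dict  # mode label -> ModeTrajectory
    fingerprints: list


@dataclass
class PipelineResult:
    config: RunConfig
    systems: dict  # id -> SystemAnalysis
    similarity_graph: nx.Graph
    classification: object | None
    mappings: dict
    class_reports: dict = field(default_factory=dict)
    transfer_report: dict | None = None
    warnings: list = field(default_factory=list)


def _load_systems(config: RunConfig) -> tuple[dict, dict]:
    """Return ({id: (structure, topology)}, {(a, b): mapping})."""
    out: dict = {}
    if config.synthetic is not None:
        syn = config.synthetic
        spec = FixtureSpec(
            geometry=syn.geometry,
            n_chains=syn.n_chains,
            beads_per_chain=syn.beads_per_chain,
            seed=stage_seed(config.seed, "fixture"),
            cutoff=config.nma.cutoff,
            spring_k=config.nma.spring_k,
            jitter=syn.jitter,
        )
        if syn.mutation_site is None:
            from .fixtures import densest_interface_bead, generate_complex

            probe, probe_topology = generate_complex(spec)
            site = densest_interface_bead(probe, probe_topology)
        else:
            site = _parse_residue(syn.mutation_site)
        pert = SpringPerturbation(
            site=site,
            remove_fraction=syn.remove_fraction,
            radius=syn.perturbation_radius,
            seed=stage_seed(config.seed, "perturbation"),
        )
        pair = generate_variant_pair(spec, pert)
        wt_id, var_id = config.systems[0].id, config.systems[1].id
        out[wt_id] = (pair.wt, pair.wt_topology)
        out[var_id] = (pair.variant, pair.variant_topology)
        mappings = {(wt_id, var_id): pair.mapping}
        return out, mappings
    for sys_cfg in config.systems:
        if sys_cfg.structure is None:
            raise PipelineError(f"system {sys_cfg.id}: no structure path and no synthetic block")
        structure = read_structure(sys_cfg.structure, model=sys_cfg.model)
        topology = enm_topology(structure.coord, config.nma.cutoff, config.nma.spring_k)
        out[sys_cfg.id] = (structure, topology)
    ids = [s.id for s in config.systems]
    mappings = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            mappings[(ids[i], ids[j])] = map_residues(out[ids[i]][0], out[ids[j]][0])
    return out, mappings


def analyze_systems(config: RunConfig) -> PipelineResult:
    """Run the in-memory pipeline: modes, trajectories, fingerprints,
    similarity graph and (for >= 2 systems) the motion classification."""
    systems_raw, mappings = _load_systems(config)
    nma_cfg = config.nma
    analyses: dict = {}
    for sys_id, (structure, topology) in systems_raw.items():
        hessian, _ = build_enm_hessian(structure, topology=topology)
        mode_set = compute_normal_modes(hessian, structure.mass, n_modes=nma_cfg.n_modes)
        selection = select_calpha(structure)
        trajectories = {}
        fingerprints = []
        for label in mode_set.labels:
            trj = generate_mode_trajectory(
                structure,
                mode_set,
                int(label),
                amplitude=nma_cfg.amplitude,
                n_frames=nma_cfg.n_frames,
                relax=nma_cfg.relax,
                topology=topology,
                restraint_k=nma_cfg.restraint_k,
                max_iter=nma_cfg.max_iter,
            )
            trajectories[int(label)] = trj
            fingerprints.append(compute_fingerprint(trj, selection, system_id=sys_id))
        analyses[sys_id] = SystemAnalysis(
            system_id=sys_id,
            structure=structure,
            topology=topology,
            mode_set=mode_set,
            selection=selection,
            trajectories=trajectories,
            fingerprints=fingerprints,
        )
    all_fps = [fp for a in analyses.values() for fp in a.fingerprints]
    graph = build_similarity_graph(
        all_fps,
        r_threshold=config.similarity.r_threshold,
        p_threshold=config.similarity.p_threshold,
        n_permutations=config.similarity.n_permutations,
        seed=stage_seed(config.seed, "mantel"),
        mappings=mappings,
    )
    classification = None
    if len(analyses) >= 2:
        phenotype_map = {s.id: set(s.phenotypes) for s in config.systems}
        classification = classify_motions(graph, phenotype_map)
    return PipelineResult(
        config=config,
        systems=analyses,
        similarity_graph=graph,
        classification=classification,
        mappings=mappings,
    )


def _mode_groups(result: PipelineResult) -> dict:
    """(system, class) -> ModeGroup over that system's modes of the class."""
    groups: dict = {}
    classification = result.classification
    if classification is None:
        return groups
    for sys_id, analysis in result.systems.items():
        for cls in ("shared", "unique"):
            labels = (
                classification.shared_modes(sys_id)
                if cls == "shared"
                else classification.unique_modes(sys_id)
            )
            if not labels:
                continue
            groups[(sys_id, cls)] = ModeGroup(
                group_id=f"{sys_id}_{cls}",
                trajectories=[analysis.trajectories[m] for m in labels],
                tag=cls,
            )
    return groups


def _default_endpoints(structure: MolecularStructure) -> list[tuple[ResidueKey, ResidueKey]]:
    """Midpoint residues of the last two chains (the 'receptor' chains of
    the dimer-of-dimers layout) as the default communication endpoints."""
    chains = structure.chains
    if len(chains) < 2:
        return []
    picks = []
    for chain in chains[-2:]:
        keys = [k for k in structure.residues if k.chain_id == chain]
        picks.append(keys[len(keys) // 2])
    return [tuple(picks)]


def _analyze_class(
    result: PipelineResult,
    sys_id: str,
    cls: str,
    group: ModeGroup,
    out_dir: Path,
    manifest: dict,
) -> dict:
    config = result.config
    analysis = result.systems[sys_id]
    selection = analysis.selection
    tag = f"{sys_id}_{cls}"
    dccm = compute_dccm(group, selection)
    dccm.to_csv(out_dir / f"dccm_{tag}.csv")
    dccm.to_heatmap(out_dir / f"dccm_{tag}.png", title=tag)
    rmsf = compute_group_rmsf(group, selection)
    rmsf.to_tsv(out_dir / f"rmsf_{tag}.tsv")
    frame_coords = np.concatenate(
        [trj.frames[:, selection.indices, :] for trj in group.trajectories]
    )
    net_cfg = config.network
    network = build_network(
        dccm,
        frame_coords,
        corr_threshold=net_cfg.corr_threshold,
        dist_threshold=net_cfg.dist_threshold,
        frame_fraction=net_cfg.frame_fraction,
    )
    export_network_graphml(network, out_dir / f"network_{tag}.graphml")
    partition = detect_communities(
        network,
        modularity_tolerance=net_cfg.modularity_tolerance,
        min_size=net_cfg.min_community_size,
    )
    partition.to_tsv(out_dir / f"communities_{tag}.tsv")
    centrality = node_betweenness(network)
    with open(out_dir / f"betweenness_{tag}.tsv", "w") as fh:
        fh.write("residue\tbetweenness\n")
        for node in sorted(centrality, key=str):
            fh.write(f"{node}\t{centrality[node]:.6f}\n")
    endpoints = [
        (_parse_residue(a), _parse_residue(b)) for a, b in net_cfg.path_endpoints
    ] or _default_endpoints(analysis.structure)
    ensembles = {}
    degeneracy_rows: dict = {}
    for source, sink in endpoints:
        if source not in network or sink not in network:
            warnings.warn(f"{tag}: endpoint {source} or {sink} not in network")
            continue
        ensemble = suboptimal_paths(network, source, sink, k=net_cfg.k_paths)
        pair_tag = f"{source}-{sink}".replace(":", "")
        ensemble.to_json(out_dir / f"paths_{tag}_{pair_tag}.json")
        if ensemble.n_paths:
            hist = path_length_histogram(ensemble, bin_width=_hist_bin(ensemble))
            hist.to_csv(out_dir / f"path_hist_{tag}_{pair_tag}.csv", index=False,
                        float_format="%.10g")
        ensembles[pair_tag] = ensemble
        for node, deg in ensemble.degeneracy.items():
            degeneracy_rows.setdefault(str(node), {})[pair_tag] = deg
    if degeneracy_rows:
        deg_frame = pd.DataFrame.from_dict(degeneracy_rows, orient="index").sort_index()
        deg_frame.to_csv(out_dir / f"degeneracy_{tag}.tsv", sep="\t",
                         float_format="%.6f", na_rep="0")
    # interactions over the class's concatenated frames
    int_cfg = config.interactions
    all_frames = np.concatenate([trj.frames for trj in group.trajectories])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hbonds = detect_hydrogen_bonds(
            analysis.structure, all_frames,
            distance_cutoff=int_cfg.hbond_distance,
            angle_cutoff=int_cfg.hbond_angle, tag=tag,
        )
        bridges = detect_salt_bridges(
            analysis.structure, all_frames,
            distance_cutoff=int_cfg.salt_bridge_distance, tag=tag,
        )
    records_to_tsv(hbonds + bridges, out_dir / f"interactions_{tag}.tsv")
    return {
        "dccm": dccm,
        "rmsf": rmsf,
        "network": network,
        "partition": partition,
        "betweenness": centrality,
        "ensembles": ensembles,
        "interactions": hbonds + bridges,
    }


def _hist_bin(ensemble) -> float:
    spread = float(ensemble.lengths.max() - ensemble.lengths.min())
    return max(spread / 20.0, 1e-6)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage and write all artifacts plus the run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest: dict = {
        "package": "modenet",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {
            name: stage_seed(config.seed, name)
            for name in ("fixture", "perturbation", "mantel", "transfer")
        },
        "config": config.to_dict(),
        "warnings": [],
        "outputs": {},
    }
    stage = "analysis"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = analyze_systems(config)
            stage = "structures_and_modes"
            for sys_id, analysis in result.systems.items():
                write_structure(analysis.structure, out_dir / f"structure_{sys_id}.pdb")
                _export_modes(analysis, out_dir / f"modes_{sys_id}.json")
            stage = "similarity"
            r_matrix = result.similarity_graph.graph["r_matrix"]
            r_matrix.to_csv(out_dir / "similarity_matrix.csv", float_format="%.6f")
            export_graphml(result.similarity_graph, out_dir / "similarity_graph.graphml")
            if result.classification is not None:
                result.classification.to_json(out_dir / "classification.json")
            else:
                redundancy = redundancy_report(result.similarity_graph)
                (out_dir / "redundancy.json").write_text(
                    json.dumps(
                        {"groups": [[list(map(str, n)) for n in grp]
                                    for grp in redundancy]},
                        indent=2,
                    )
                )
            stage = "class_analyses"
            for (sys_id, cls), group in _mode_groups(result).items():
                result.class_reports[(sys_id, cls)] = _analyze_class(
                    result, sys_id, cls, group, out_dir, manifest
                )
            stage = "interaction_diffs"
            _write_interaction_diffs(result, out_dir)
            manifest["warnings"] = sorted({str(w.message) for w in caught})
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    result.warnings = manifest["warnings"]
    for path in sorted(out_dir.iterdir()):
        if path.name == "manifest.json" or path.suffix == ".png":
            continue
        manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result


def _write_interaction_diffs(result: PipelineResult, out_dir: Path) -> None:
    """Pairwise gained/lost/kept interaction sets between the same motion
    class of different systems (e.g. the two systems' shared classes, or
    one system's lost-function class vs the other's novel class)."""
    threshold = result.config.interactions.occupancy_threshold
    reports = result.class_reports
    system_ids = list(result.systems)
    for cls in ("shared", "unique"):
        for i in range(len(system_ids)):
            for j in range(i + 1, len(system_ids)):
                a, b = system_ids[i], system_ids[j]
                if (a, cls) not in reports or (b, cls) not in reports:
                    continue
                mapping = result.mappings.get((a, b))
                diff = diff_interactions(
                    reports[(a, cls)]["interactions"],
                    reports[(b, cls)]["interactions"],
                    occupancy_threshold=threshold,
                    mapping=mapping,
                )
                (out_dir / f"interaction_diff_{cls}_{a}_vs_{b}.json").write_text(
                    json.dumps(diff, indent=2)
                )


def _export_modes(analysis: SystemAnalysis, path: Path) -> None:
    ms = analysis.mode_set
    payload = {
        "system": analysis.system_id,
        "n_trivial": int(ms.n_trivial),
        "labels": [int(x) for x in ms.labels],
        "eigenvalues": [float(x) for x in ms.eigenvalues],
        "eigenvectors": [[round(float(v), 10) for v in ms.eigenvectors[:, m]]
                         for m in range(ms.n_modes)],
    }
    path.write_text(json.dumps(payload))


def run_transfer_experiment(
    config: RunConfig,
    donor: str,
    acceptor: str,
    mode_class: str = "unique",
    result: PipelineResult | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Apply the donor system's modes of one class to the acceptor
    structure, relax under the acceptor's network, and test by Mantel
    whether each motion survives.

    Returns a report with per-mode transfer correlations and the
    preserved/lost split at the similarity thresholds.
    """
    if result is None:
        result = analyze_systems(config)
    if result.classification is None:
        raise PipelineError("transfer experiment needs a classified multi-system run")
    if donor not in result.systems or acceptor not in result.systems:
        raise PipelineError("donor or acceptor system not analyzed")
    if mode_class == "shared":
        labels = result.classification.shared_modes(donor)
    elif mode_class == "unique":
        labels = result.classification.unique_modes(donor)
    else:
        raise PipelineError(f"unknown mode class {mode_class!r}")
    donor_an = result.systems[donor]
    acceptor_an = result.systems[acceptor]
    mapping = result.mappings.get((donor, acceptor))
    reverse = False
    if mapping is None:
        mapping = result.mappings.get((acceptor, donor))
        reverse = mapping is not None
    if mapping is None:
        mapping = map_residues(donor_an.structure, acceptor_an.structure)
    if reverse:
        from .structures import ResidueMapping

        mapping = ResidueMapping(
            pairs=[(b, a) for a, b in mapping.pairs],
            mutations=[(b, a) for a, b in mapping.mutations],
            unmapped_a=mapping.unmapped_b,
            unmapped_b=mapping.unmapped_a,
        )
    sim_cfg = config.similarity
    nma_cfg = config.nma
    report = {
        "donor": donor,
        "acceptor": acceptor,
        "mode_class": mode_class,
        "modes": [],
        "n_preserved": 0,
        "n_lost": 0,
    }
    rng = np.random.default_rng(stage_seed(config.seed, "transfer"))
    for label in labels:
        # reference fingerprint from the donor's own *relaxed* trajectory,
        # so the comparison is relaxed-vs-relaxed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            donor_trj = generate_mode_trajectory(
                donor_an.structure,
                donor_an.mode_set,
                int(label),
                amplitude=nma_cfg.amplitude,
                n_frames=nma_cfg.n_frames,
                relax=True,
                topology=donor_an.topology,
                restraint_k=nma_cfg.restraint_k,
                max_iter=nma_cfg.max_iter,
            )
        original_fp = compute_fingerprint(
            donor_trj, donor_an.selection, system_id=donor
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            transferred = transfer_mode_trajectory(
                donor_an.mode_set,
                donor_an.structure,
                acceptor_an.structure,
                mapping,
                label,
                amplitude=nma_cfg.amplitude,
                n_frames=nma_cfg.n_frames,
                relax=True,
                topology_b=acceptor_an.topology,
                restraint_k=nma_cfg.restraint_k,
                max_iter=nma_cfg.max_iter,
            )
        transferred_fp = compute_fingerprint(
            transferred, acceptor_an.selection, system_id=f"h_{acceptor}"
        )
        if len(original_fp.residue_keys) != len(transferred_fp.residue_keys):
            from .similarity import align_fingerprints

            original_fp, transferred_fp = align_fingerprints(
                original_fp, transferred_fp, mapping
            )
        res = mantel_test(
            original_fp,
            transferred_fp,
            n_permutations=sim_cfg.n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        preserved = abs(res.r) >= sim_cfg.r_threshold and res.p_value < sim_cfg.p_threshold
        report["modes"].append(
            {
                "mode": int(label),
                "mantel_r": round(res.r, 6),
                "p_value": res.p_value,
                "preserved": bool(preserved),
                "converged": bool(transferred.converged.all()),
            }
        )
        report["n_preserved" if preserved else "n_lost"] += 1
    if not labels:
        report["note"] = "empty mode class"
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
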