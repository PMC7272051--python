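"""Hydrogen-bond and salt-bridge detection with occupancy statistics.

Interactions are detected frame by frame with geometric criteria — a 3.0 Å
donor–acceptor distance and a 20° deviation-from-linearity cutoff for
hydrogen bonds, a 3.2 Å side-chain oxygen–nitrogen distance for salt
bridges — then aggregated into an occupancy: the exact fraction of frames
in which the interaction holds.  An interaction is called high-occupancy
when it holds in at least half the frames.

Structures without explicit hydrogens (bead models, unprotonated PDBs)
fall back to a heavy-atom criterion: the donor–acceptor distance test
alone, with the angle test skipped and the record flagged accordingly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structures import MolecularStructure, ResidueKey, ResidueMapping

__all__ = [
    "InteractionRecord",
    "detect_hydrogen_bonds",
    "detect_salt_bridges",
    "diff_interactions",
    "records_to_tsv",
]

HBOND_DISTANCE = 3.0  # Å donor-acceptor
HBOND_ANGLE = 20.0  # degrees off linear D-H...A
SALT_BRIDGE_DISTANCE = 3.2  # Å side-chain O...N
HIGH_OCCUPANCY = 0.5  # inclusive
_COVALENT_H = 1.25  # Å, D-H bond detection

ANIONIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
CATIONIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
    "HSP": {"ND1", "NE2"},
    "HIP": {"ND1", "NE2"},
}


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # "hbond" | "salt_bridge"
    donor_residue: ResidueKey
    acceptor_residue: ResidueKey
    donor_atom: str
    acceptor_atom: str
    occupancy: float
    angle_checked: bool = True
    intra_residue: bool = False
    tag: str = ""

    @property
    def residue_pair_key(self) -> tuple[str, str, str]:
        return (self.kind, str(self.donor_residue), str(self.acceptor_residue))


def _frame_coords(
    structure: MolecularStructure, frames: Sequence[np.ndarray] | np.ndarray | None
) -> np.ndarray:
    if frames is None:
        return structure.coord[None]
    coords = np.asarray(frames, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != structure.n_atoms:
        raise ValueError("frames do not match structure atom count")
    return coords


def _polar_heavy_atoms(structure: MolecularStructure) -> np.ndarray:
    return np.nonzero(np.isin(structure.element, ["N", "O"]))[0]


def _attached_hydrogens(structure: MolecularStructure, heavy: int) -> list[int]:
    atoms = structure.residue_atoms(structure.res_index[heavy])
    hydro = [a for a in atoms if structure.element[a] == "H"]
    return [
        a for a in hydro
        if np.linalg.norm(structure.coord[a] - structure.coord[heavy]) <= _COVALENT_H
    ]


def detect_hydrogen_bonds(
    structure: MolecularStructure,
    frames: Sequence[np.ndarray] | np.ndarray | None = None,
    distance_cutoff: float = HBOND_DISTANCE,
    angle_cutoff: float = HBOND_ANGLE,
    include_intra_residue: bool = False,
    tag: str = "",
) -> list[InteractionRecord]:
    """Per-frame hydrogen bond detection aggregated to occupancy.

    A bond holds in a frame when the donor–acceptor distance is at most
    ``distance_cutoff`` and, if the donor carries a resolvable hydrogen,
    some D–H...A angle deviates from linearity by at most ``angle_cutoff``
    degrees.  ``frames`` defaults to the structure's own coordinates
    (single frame).  Hydrogen assignment uses the reference geometry.
    """
    coords = _frame_coords(structure, frames)
    n_frames = len(coords)
    polar = _polar_heavy_atoms(structure)
    if len(polar) == 0:
        warnings.warn("no N/O atoms: no hydrogen bond candidates", stacklevel=2)
        return []
    has_hydrogens = bool(np.any(structure.element == "H"))
    donors: dict[int, list[int]] = {}
    for heavy in polar:
        hs = _attached_hydrogens(structure, heavy) if has_hydrogens else []
        if hs or not has_hydrogens:
            donors[int(heavy)] = hs
    records = []
    for d, hydrogens in donors.items():
        for a in polar:
            a = int(a)
            if a == d:
                continue
            same_residue = structure.res_index[d] == structure.res_index[a]
            if same_residue and not include_intra_residue:
                continue
            hits = 0
            for f in range(n_frames):
                dist = np.linalg.norm(coords[f][d] - coords[f][a])
                if dist > distance_cutoff:
                    continue
                if hydrogens:
                    ok = False
                    for h in hydrogens:
                        v1 = coords[f][d] - coords[f][h]
                        v2 = coords[f][a] - coords[f][h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if 180.0 - angle <= angle_cutoff:
                            ok = True
                            break
                    if not ok:
                        continue
                hits += 1
            if hits:
                records.append(
                    InteractionRecord(
                        kind="hbond",
                        donor_residue=structure.residues[structure.res_index[d]],
                        acceptor_residue=structure.residues[structure.res_index[a]],
                        donor_atom=str(structure.atom_name[d]),
                        acceptor_atom=str(structure.atom_name[a]),
                        occupancy=hits / n_frames,
                        angle_checked=bool(hydrogens),
                        intra_residue=bool(same_residue),
                        tag=tag,
                    )
                )
    return records


def detect_salt_bridges(
    structure: MolecularStructure,
    frames: Sequence[np.ndarray] | np.ndarray | None = None,
    distance_cutoff: float = SALT_BRIDGE_DISTANCE,
    tag: str = "",
) -> list[InteractionRecord]:
    """Side-chain anionic O (Asp/Glu) vs cationic N (Lys/Arg/His) pairs
    within ``distance_cutoff``, per frame, aggregated to occupancy."""
    coords = _frame_coords(structure, frames)
    n_frames = len(coords)
    anions: list[int] = []
    cations: list[int] = []
    for i in range(structure.n_atoms):
        res = structure.residues[structure.res_index[i]]
        name = str(structure.atom_name[i])
        if name in ANIONIC_ATOMS.get(res.res_name, ()):
            anions.append(i)
        if name in CATIONIC_ATOMS.get(res.res_name, ()):
            cations.append(i)
    records = []
    for o in anions:
        for nn in cations:
            hits = 0
            for f in range(n_frames):
                if np.linalg.norm(coords[f][o] - coords[f][nn]) <= distance_cutoff:
                    hits += 1
            if hits:
                records.append(
                    InteractionRecord(
                        kind="salt_bridge",
                        donor_residue=structure.residues[structure.res_index[nn]],
                        acceptor_residue=structure.residues[structure.res_index[o]],
                        donor_atom=str(structure.atom_name[nn]),
                        acceptor_atom=str(structure.atom_name[o]),
                        occupancy=hits / n_frames,
                        angle_checked=False,
                        tag=tag,
                    )
                )
    return records


def diff_interactions(
    records_a: Iterable[InteractionRecord],
    records_b: Iterable[InteractionRecord],
    occupancy_threshold: float = HIGH_OCCUPANCY,
    mapping: ResidueMapping | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Gained/lost/kept high-occupancy interactions keyed by residue pair.

    Occupancy at the threshold counts as high (the minimum is inclusive).
    With a residue mapping, B's residues are translated into A's keys
    before comparison.
    """
    translate: dict[str, str] = {}
    if mapping is not None:
        translate = {str(kb): str(ka) for ka, kb in mapping.pairs}

    def keys(records, translate_b=False):
        out = set()
        for rec in records:
            if rec.occupancy < occupancy_threshold:
                continue
            kd, ka = str(rec.donor_residue), str(rec.acceptor_residue)
            if translate_b:
                kd = translate.get(kd, kd)
                ka = translate.get(ka, ka)
            out.add((rec.kind, kd, ka))
        return out

    set_a = keys(records_a)
    set_b = keys(records_b, translate_b=mapping is not None)
    return {
        "kept": sorted(set_a & set_b),
        "lost": sorted(set_a - set_b),
        "gained": sorted(set_b - set_a),
    }


def records_to_tsv(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(
            "kind\tdonor_residue\tdonor_atom\tacceptor_residue\t"
            "acceptor_atom\toccupancy\tangle_checked\ttag\n"
        )
        for rec in sorted(records, key=lambda r: (r.kind, str(r.donor_residue),
                                                  str(r.acceptor_residue))):
            fh.write(
                f"{rec.kind}\t{rec.donor_residue}\t{rec.donor_atom}\t"
                f"{rec.acceptor_residue}\t{rec.acceptor_atom}\t"
                f"{rec.occupancy:.6f}\t{int(rec.angle_checked)}\t{rec.tag}\n"
            )


def diff_to_json(diff: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(diff, indent=2))
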