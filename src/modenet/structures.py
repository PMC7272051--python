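"""Molecular structures, selections and residue mapping.

Structures are stored as flat atom arrays grouped into residues and chains,
with author residue numbering (the numbering printed in the PDB file) as the
public coordinate system.  PDB I/O is delegated to biotite; the containers
here only add the residue bookkeeping and invariants the downstream analyses
rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .elements import element_mass

WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP", "DOD", "SOL"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation/terminal variants
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}


class StructureError(ValueError):
    """Raised when a structure violates its invariants or cannot be read."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue: chain id, author residue number, insertion code.

    The residue name is carried for reporting but does not participate in
    identity, so a point substitution maps onto the same key.
    """

    chain_id: str
    res_id: int
    ins_code: str = ""
    res_name: str = field(default="", compare=False)

    def __str__(self) -> str:  # e.g. "A:221" or "A:221A"
        return f"{self.chain_id}:{self.res_id}{self.ins_code}"


@dataclass
class MolecularStructure:
    """Atoms with coordinates and masses, grouped into residues and chains.

    Parameters
    ----------
    serial, atom_name, element, mass, coord, hetero
        Per-atom annotation arrays (coord has shape ``(n_atoms, 3)`` in Å).
    res_index
        Per-atom index into ``residues``.
    residues
        Ordered :class:`ResidueKey` list; atoms of one residue are contiguous.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    coord: np.ndarray
    hetero: np.ndarray
    res_index: np.ndarray
    residues: list[ResidueKey]

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.res_index = np.asarray(self.res_index, dtype=int)

    # -- basic properties -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        """Ordered unique chain identifiers."""
        seen: list[str] = []
        for key in self.residues:
            if key.chain_id not in seen:
                seen.append(key.chain_id)
        return seen

    def residue_atoms(self, i: int) -> np.ndarray:
        """Atom indices of residue ``i``."""
        return np.nonzero(self.res_index == i)[0]

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`StructureError`."""
        if self.n_atoms == 0:
            raise StructureError("structure has no atoms")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        if not np.all(self.mass > 0):
            raise StructureError("non-positive atomic mass")
        if self.res_index.min() < 0 or self.res_index.max() >= self.n_residues:
            raise StructureError("atom points to a non-existent residue")
        seen: set[ResidueKey] = set()
        for key in self.residues:
            if key in seen:
                raise StructureError(f"duplicate residue key {key}")
            seen.add(key)
        # residue numbers strictly increasing within each chain
        per_chain: dict[str, tuple[int, str]] = {}
        for key in self.residues:
            prev = per_chain.get(key.chain_id)
            cur = (key.res_id, key.ins_code)
            if prev is not None and cur <= prev:
                raise StructureError(
                    f"residue order not increasing in chain {key.chain_id} at {key}"
                )
            per_chain[key.chain_id] = cur

    def with_coord(self, coord: np.ndarray) -> "MolecularStructure":
        """Copy of this structure with replaced coordinates."""
        coord = np.asarray(coord, dtype=float)
        if coord.shape != self.coord.shape:
            raise StructureError("coordinate shape mismatch")
        return replace(self, coord=coord.copy())

    # -- biotite bridge ---------------------------------------------------
    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = np.array(
            [self.residues[i].chain_id for i in self.res_index], dtype="U4"
        )
        arr.res_id = np.array(
            [self.residues[i].res_id for i in self.res_index], dtype=int
        )
        arr.ins_code = np.array(
            [self.residues[i].ins_code for i in self.res_index], dtype="U1"
        )
        arr.res_name = np.array(
            [self.residues[i].res_name for i in self.res_index], dtype="U5"
        )
        arr.atom_name = np.asarray(self.atom_name, dtype="U6")
        arr.element = np.asarray(self.element, dtype="U2")
        arr.hetero = np.asarray(self.hetero, dtype=bool)
        return arr


def _from_atom_array(arr: struc.AtomArray) -> MolecularStructure:
    n = arr.array_length()
    residues: list[ResidueKey] = []
    res_index = np.empty(n, dtype=int)
    current: tuple | None = None
    for i in range(n):
        ident = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]))
        if ident != current:
            key = ResidueKey(*ident, res_name=str(arr.res_name[i]))
            if key in residues:
                raise StructureError(f"duplicate residue key {key}")
            residues.append(key)
            current = ident
        res_index[i] = len(residues) - 1
    masses = np.array([element_mass(e) for e in arr.element], dtype=float)
    serial = np.arange(1, n + 1)
    structure = MolecularStructure(
        serial=serial,
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        element=np.asarray(arr.element, dtype="U2"),
        mass=masses,
        coord=np.asarray(arr.coord, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
        res_index=res_index,
        residues=residues,
    )
    structure.validate()
    return structure


def read_structure(
    path: str | Path,
    model: int = 1,
    keep_waters: bool = False,
) -> MolecularStructure:
    """Read one model from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer.
    Waters are dropped unless ``keep_waters`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructureError(f"{path} contains no coordinate records")
    if not 1 <= model <= n_models:
        raise StructureError(f"model {model} not in file ({n_models} models)")
    arr = pdb.get_structure(model=model, altloc="occupancy")
    if arr.array_length() == 0:
        raise StructureError(f"{path} contains no ATOM/HETATM records")
    if not keep_waters:
        arr = arr[~np.isin(arr.res_name, list(WATER_NAMES))]
        if arr.array_length() == 0:
            raise StructureError(f"{path} contains only water")
    return _from_atom_array(arr)


def write_structure(
    structure: MolecularStructure | Sequence[MolecularStructure],
    path: str | Path,
) -> None:
    """Write a structure, or a sequence of frames sharing one topology, as a
    (multi-MODEL) PDB file."""
    frames = [structure] if isinstance(structure, MolecularStructure) else list(structure)
    if not frames:
        raise StructureError("nothing to write")
    template = frames[0].to_atom_array()
    if len(frames) == 1:
        out = template
    else:
        out = struc.AtomArrayStack(len(frames), template.array_length())
        for cat in template.get_annotation_categories():
            out.set_annotation(cat, template.get_annotation(cat))
        for k, frame in enumerate(frames):
            if frame.n_atoms != frames[0].n_atoms:
                raise StructureError("frames differ in atom count")
            out.coord[k] = frame.coord.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(out)
    pdb.write(str(Path(path)))


class CalphaSelection(NamedTuple):
    """Ordered Cα atom indices plus the residues that lack a CA atom."""

    indices: np.ndarray
    residue_keys: list[ResidueKey]
    missing: list[ResidueKey]


def select_calpha(structure: MolecularStructure) -> CalphaSelection:
    """One CA atom index per polymer residue, in residue order.

    Hetero groups and waters are excluded.  Residues without a CA atom are
    reported in ``missing`` rather than raising; an empty selection is legal.
    """
    indices: list[int] = []
    keys: list[ResidueKey] = []
    missing: list[ResidueKey] = []
    for i, key in enumerate(structure.residues):
        atoms = structure.residue_atoms(i)
        if structure.hetero[atoms].all():
            continue
        if key.res_name in WATER_NAMES:
            continue
        ca = [a for a in atoms if structure.atom_name[a] == "CA"]
        if ca:
            indices.append(ca[0])
            keys.append(key)
        else:
            missing.append(key)
    if not indices:
        warnings.warn("empty C-alpha selection", stacklevel=2)
    return CalphaSelection(np.array(indices, dtype=int), keys, missing)


@dataclass
class ResidueMapping:
    """Residue correspondence between two systems, keyed by
    (chain, number, insertion code); substitutions are flagged as mutations."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    mutations: list[tuple[ResidueKey, ResidueKey]]
    unmapped_a: list[ResidueKey]
    unmapped_b: list[ResidueKey]

    @property
    def n_mapped(self) -> int:
        return len(self.pairs)

    def coverage(self, n_reference: int) -> float:
        """Fraction of ``n_reference`` residues that are mapped."""
        return self.n_mapped / n_reference if n_reference else 0.0


def map_residues(a: MolecularStructure, b: MolecularStructure) -> ResidueMapping:
    """Pair residues of two structures by (chain, number, insertion code).

    Residues present in only one structure go to the unmapped lists; pairs
    whose residue names differ are additionally flagged as mutations.
    """
    if not (set(a.chains) & set(b.chains)):
        raise StructureError("structures share no chain identifiers")
    b_lookup = {key: key for key in b.residues}
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    mutations: list[tuple[ResidueKey, ResidueKey]] = []
    unmapped_a: list[ResidueKey] = []
    matched_b: set[ResidueKey] = set()
    for key in a.residues:
        other = b_lookup.get(key)
        if other is None:
            unmapped_a.append(key)
            continue
        pairs.append((key, other))
        matched_b.add(other)
        if key.res_name != other.res_name:
            mutations.append((key, other))
    unmapped_b = [key for key in b.residues if key not in matched_b]
    return ResidueMapping(pairs, mutations, unmapped_a, unmapped_b)
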