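"""Shared fixtures: small bead systems and structures built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from modenet.fixtures import FixtureSpec, SpringPerturbation, generate_complex, generate_variant_pair
from modenet.nma import build_enm_hessian, compute_normal_modes
from modenet.structures import (
    MolecularStructure,
    ResidueKey,
    select_calpha,
)


def make_bead_structure(coord, chain_id="A", res_name="ALA", element="C", mass=12.011):
    """Bead structure with one CA atom per residue at the given coordinates."""
    coord = np.asarray(coord, dtype=float)
    n = len(coord)
    residues = [ResidueKey(chain_id, i + 1, "", res_name) for i in range(n)]
    structure = MolecularStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "CA", dtype="U6"),
        element=np.full(n, element, dtype="U2"),
        mass=np.full(n, mass),
        coord=coord,
        hetero=np.zeros(n, dtype=bool),
        res_index=np.arange(n),
        residues=residues,
    )
    structure.validate()
    return structure


def make_atomic_structure(atoms):
    """Structure from explicit atom tuples:
    (chain, resnum, resname, atom_name, element, xyz)."""
    residues = []
    res_index = []
    names, elements, coords = [], [], []
    for chain, resnum, resname, name, element, xyz in atoms:
        key = ResidueKey(chain, resnum, "", resname)
        if not residues or residues[-1] != key:
            residues.append(key)
        res_index.append(len(residues) - 1)
        names.append(name)
        elements.append(element)
        coords.append(xyz)
    from modenet.elements import element_mass

    n = len(names)
    structure = MolecularStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.array(names, dtype="U6"),
        element=np.array(elements, dtype="U2"),
        mass=np.array([element_mass(e) for e in elements]),
        coord=np.array(coords, dtype=float),
        hetero=np.zeros(n, dtype=bool),
        res_index=np.array(res_index),
        residues=residues,
    )
    structure.validate()
    return structure


@pytest.fixture(scope="session")
def bead_cloud_20():
    """Random connected 20-bead cloud (seeded)."""
    rng = np.random.default_rng(11)
    coord = rng.uniform(0, 12, size=(20, 3))
    return make_bead_structure(coord)


@pytest.fixture(scope="session")
def small_complex():
    """Small connected dimer-of-dimers bead complex (12 beads/chain)."""
    spec = FixtureSpec(beads_per_chain=12, seed=3)
    return generate_complex(spec)


@pytest.fixture(scope="session")
def small_complex_modes(small_complex):
    structure, topology = small_complex
    hessian, _ = build_enm_hessian(structure, topology=topology)
    return compute_normal_modes(hessian, structure.mass, n_modes=10)


@pytest.fixture(scope="session")
def variant_pair_small():
    """Variant pair with an interface spring perturbation, small scale."""
    spec = FixtureSpec(beads_per_chain=12, seed=3)
    pert = SpringPerturbation(site=ResidueKey("A", 6), remove_fraction=0.4, seed=3)
    return generate_variant_pair(spec, pert)


@pytest.fixture(scope="session")
def calpha(small_complex):
    structure, _ = small_complex
    return select_calpha(structure)
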