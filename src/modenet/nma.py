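"""Elastic-network normal modes and mode-displaced pseudo-trajectories.

The Hessian is pluggable: any symmetric ``3N x 3N`` matrix can be fed to
:func:`compute_normal_modes`.  The default supplied here is the anisotropic
elastic network model (ANM): particles within a distance cutoff are joined
by Hookean springs at their reference separation, so the reference geometry
is the energy minimum and the six rigid-body motions are exact zero modes.

Modes are numbered the way the structural-dynamics literature prints them:
trivial (rigid-body) modes occupy labels ``1..n_trivial``, so for a connected
three-dimensional network the first internal mode is mode 7.

Pseudo-trajectories displace the structure along one mode at fixed
mass-weighted RMS (MRMS) amplitudes.  With relaxation enabled each frame is
gradient-minimized under the (anharmonic in Cartesian coordinates) ENM
energy plus a harmonic restraint on the MRMS coordinate along the mode
direction, with net translation/rotation removed afterwards — a
deterministic stand-in for low-temperature MD plus minimization that serves
the same purpose: letting the structure relax off the strictly harmonic
displacement while the imposed amplitude is held.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.spatial import cKDTree

from .geometry import superpose
from .structures import MolecularStructure, ResidueMapping, select_calpha

__all__ = [
    "ENMTopology",
    "ModeSet",
    "ModeTrajectory",
    "enm_topology",
    "hessian_from_topology",
    "build_enm_hessian",
    "enm_energy",
    "enm_gradient",
    "compute_normal_modes",
    "generate_mode_trajectory",
    "transfer_mode_trajectory",
]

DEFAULT_CUTOFF = 10.0  # Å
DEFAULT_SPRING_K = 1.0  # kcal/mol/Å^2 (arbitrary uniform units)
ZERO_MODE_FACTOR = 1e-8


class NMAError(ValueError):
    pass


@dataclass
class ENMTopology:
    """Spring list of an elastic network: particle pairs, equilibrium
    lengths (Å) and per-spring force constants."""

    n_atoms: int
    pairs: np.ndarray  # (n_springs, 2) int
    r0: np.ndarray  # (n_springs,) float
    k: np.ndarray  # (n_springs,) float

    @property
    def n_springs(self) -> int:
        return len(self.pairs)

    def remove_springs(self, spring_indices: np.ndarray) -> "ENMTopology":
        keep = np.ones(self.n_springs, dtype=bool)
        keep[np.asarray(spring_indices, dtype=int)] = False
        return ENMTopology(self.n_atoms, self.pairs[keep], self.r0[keep], self.k[keep])


def enm_topology(
    coord: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    k: float = DEFAULT_SPRING_K,
) -> ENMTopology:
    """Build the spring list: all pairs within ``cutoff`` Å."""
    coord = np.asarray(coord, dtype=float)
    if len(coord) < 2:
        raise NMAError("need at least two particles")
    if cutoff <= 0:
        raise NMAError("cutoff must be positive")
    tree = cKDTree(coord)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
        return ENMTopology(len(coord), pairs, np.empty(0), np.empty(0))
    r0 = np.linalg.norm(coord[pairs[:, 1]] - coord[pairs[:, 0]], axis=1)
    if np.any(r0 <= 1e-9):
        bad = pairs[r0 <= 1e-9][0]
        raise NMAError(f"particles {bad[0]} and {bad[1]} are at zero distance")
    return ENMTopology(len(coord), pairs, r0, np.full(len(pairs), float(k)))


def hessian_from_topology(coord: np.ndarray, topology: ENMTopology) -> np.ndarray:
    """Analytic ANM Hessian at the topology's equilibrium geometry.

    Off-diagonal superblocks are ``-k * r̂ r̂ᵀ``; diagonal superblocks are
    minus the sum of the row's off-diagonal blocks, which enforces
    translational invariance exactly.
    """
    coord = np.asarray(coord, dtype=float)
    n = topology.n_atoms
    hessian = np.zeros((3 * n, 3 * n))
    for (i, j), kij in zip(topology.pairs, topology.k):
        rij = coord[j] - coord[i]
        dist = np.linalg.norm(rij)
        if dist <= 1e-9:
            raise NMAError(f"particles {i} and {j} are at zero distance")
        u = rij / dist
        block = -kij * np.outer(u, u)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def build_enm_hessian(
    structure: MolecularStructure,
    cutoff: float = DEFAULT_CUTOFF,
    k: float = DEFAULT_SPRING_K,
    topology: ENMTopology | None = None,
) -> tuple[np.ndarray, ENMTopology]:
    """ANM Hessian (and the spring topology it came from) for a structure.

    A pre-built ``topology`` (e.g. a perturbed variant network) overrides
    the cutoff contact rule.
    """
    if topology is None:
        topology = enm_topology(structure.coord, cutoff=cutoff, k=k)
    return hessian_from_topology(structure.coord, topology), topology


def enm_energy(coord: np.ndarray, topology: ENMTopology) -> float:
    """ENM potential ``sum over springs of 0.5 k (|r_ij| - r0)^2``."""
    coord = np.asarray(coord, dtype=float)
    if topology.n_springs == 0:
        return 0.0
    d = np.linalg.norm(coord[topology.pairs[:, 1]] - coord[topology.pairs[:, 0]], axis=1)
    return float(0.5 * np.sum(topology.k * (d - topology.r0) ** 2))


def enm_gradient(coord: np.ndarray, topology: ENMTopology) -> np.ndarray:
    """Cartesian gradient of :func:`enm_energy`, shape ``(n_atoms, 3)``."""
    coord = np.asarray(coord, dtype=float)
    grad = np.zeros_like(coord)
    if topology.n_springs == 0:
        return grad
    i, j = topology.pairs[:, 0], topology.pairs[:, 1]
    rij = coord[j] - coord[i]
    d = np.linalg.norm(rij, axis=1)
    # force magnitude k (d - r0) along the bond
    coeff = (topology.k * (d - topology.r0) / d)[:, None]
    np.add.at(grad, j, coeff * rij)
    np.add.at(grad, i, -coeff * rij)
    return grad


@dataclass
class ModeSet:
    """Low-frequency eigenpairs of the mass-weighted Hessian.

    ``eigenvectors[:, m]`` is orthonormal in mass-weighted coordinates; the
    Cartesian displacement pattern is ``M^(-1/2) v``.  ``labels`` follow the
    trivial-modes-first numbering (first internal mode = ``n_trivial + 1``).
    """

    eigenvalues: np.ndarray  # non-trivial, ascending
    eigenvectors: np.ndarray  # (3N, n_modes), mass-weighted orthonormal
    masses: np.ndarray  # per atom, amu
    n_trivial: int
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    trivial_eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = self.n_trivial + 1 + np.arange(len(self.eigenvalues))

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def index_of(self, label: int) -> int:
        hits = np.nonzero(self.labels == label)[0]
        if len(hits) == 0:
            raise NMAError(f"no mode labelled {label}")
        return int(hits[0])

    def vector(self, label: int) -> np.ndarray:
        """Mass-weighted eigenvector of the labelled mode (length 3N)."""
        return self.eigenvectors[:, self.index_of(label)]

    def cartesian_displacement(self, label: int) -> np.ndarray:
        """Cartesian displacement pattern ``M^(-1/2) v``, shape (N, 3)."""
        v = self.vector(label).reshape(-1, 3)
        return v / np.sqrt(self.masses)[:, None]


def compute_normal_modes(
    hessian: np.ndarray,
    masses: np.ndarray,
    n_modes: int = 20,
    zero_tolerance_factor: float = ZERO_MODE_FACTOR,
) -> ModeSet:
    """Solve the mass-weighted eigenproblem ``H v = omega^2 M v``.

    Returns the ``n_modes`` lowest non-trivial modes.  Trivial modes are
    those with eigenvalue below ``zero_tolerance_factor`` times the largest
    eigenvalue.  Eigenvector signs are fixed so each mode's
    largest-magnitude component is positive, making the result
    reproducible run to run.
    """
    hessian = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise NMAError("Hessian is not symmetric")
    if np.any(masses <= 0):
        raise NMAError("masses must be strictly positive")
    n3 = hessian.shape[0]
    if n3 != 3 * len(masses):
        raise NMAError("Hessian size does not match 3 x n_atoms")
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    mass_weighted = hessian * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    mass_weighted = 0.5 * (mass_weighted + mass_weighted.T)
    eigvals, eigvecs = scipy.linalg.eigh(mass_weighted)
    tol = zero_tolerance_factor * max(eigvals.max(), 1e-30)
    n_trivial = int(np.sum(eigvals < tol))
    if n_modes > n3 - n_trivial:
        raise NMAError(
            f"requested {n_modes} modes but only {n3 - n_trivial} non-trivial available"
        )
    sel = slice(n_trivial, n_trivial + n_modes)
    vals = eigvals[sel].copy()
    vecs = eigvecs[:, sel].copy()
    for m in range(vecs.shape[1]):
        imax = int(np.argmax(np.abs(vecs[:, m])))
        if vecs[imax, m] < 0:
            vecs[:, m] = -vecs[:, m]
    return ModeSet(
        eigenvalues=vals,
        eigenvectors=vecs,
        masses=masses,
        n_trivial=n_trivial,
        trivial_eigenvalues=eigvals[:n_trivial].copy(),
    )


@dataclass
class ModeTrajectory:
    """Frames displaced along one mode at fixed MRMS targets.

    ``frames`` has shape ``(n_frames, n_atoms, 3)``; ``targets`` are the
    signed MRMS displacements (Å) and include 0, whose frame equals the
    reference.  ``converged`` is all-True when relaxation is off.
    """

    mode_label: int
    reference: MolecularStructure
    frames: np.ndarray
    targets: np.ndarray
    achieved: np.ndarray
    relaxed: bool
    converged: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_at(self, target: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.targets - target)))
        if abs(self.targets[idx] - target) > 1e-9:
            raise NMAError(f"no frame at MRMS displacement {target}")
        return self.frames[idx]

    def frame_structures(self) -> list[MolecularStructure]:
        return [self.reference.with_coord(c) for c in self.frames]

    def to_pdb(self, path) -> None:
        """Write the trajectory as a multi-MODEL PDB file."""
        from .structures import write_structure

        write_structure(self.frame_structures(), path)


def _mrms(coord: np.ndarray, ref: np.ndarray, masses: np.ndarray) -> float:
    delta2 = np.sum((coord - ref) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * delta2) / np.sum(masses)))


def _relax_frame(
    start: np.ndarray,
    ref: np.ndarray,
    masses: np.ndarray,
    mw_unit: np.ndarray,
    topology: ENMTopology,
    target: float,
    restraint_k: float,
    max_iter: int,
    grad_tol: float,
) -> tuple[np.ndarray, bool]:
    """Gradient-based minimization of the ENM energy with the MRMS mode
    coordinate restrained.

    The restrained coordinate is the signed mass-weighted projection of
    the displacement onto the mode direction divided by the square root of
    the total mass — for the pure harmonic displacement it equals the
    signed MRMS target exactly, so the restraint starts at zero and the
    frame relaxes only in the directions orthogonal to the imposed motion.
    The relaxed frame is superposed back onto the reference.
    """
    sqrt_m = np.sqrt(masses)
    sqrt_total = np.sqrt(masses.sum())
    direction = mw_unit.reshape(-1, 3)

    def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
        x = flat.reshape(-1, 3)
        energy = enm_energy(x, topology)
        grad = enm_gradient(x, topology)
        proj = float(np.sum(sqrt_m[:, None] * (x - ref) * direction)) / sqrt_total
        energy += 0.5 * restraint_k * (proj - target) ** 2
        grad = grad + restraint_k * (proj - target) * sqrt_m[:, None] * direction / sqrt_total
        return energy, grad.ravel()

    result = scipy.optimize.minimize(
        objective,
        start.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": grad_tol, "ftol": 1e-12},
    )
    x = superpose(result.x.reshape(-1, 3), ref, weights=masses)
    converged = bool(result.success) or float(np.linalg.norm(objective(result.x)[1])) < 10 * grad_tol
    return x, converged


def _trajectory_from_direction(
    structure: MolecularStructure,
    mw_direction: np.ndarray,
    mode_label: int,
    amplitude: float,
    n_frames: int,
    relax: bool,
    topology: ENMTopology | None,
    restraint_k: float,
    max_iter: int,
    grad_tol: float,
) -> ModeTrajectory:
    if n_frames < 3 or n_frames % 2 == 0:
        raise NMAError("n_frames must be odd and >= 3 so the reference frame is included")
    masses = structure.mass
    v = np.asarray(mw_direction, dtype=float)
    norm = np.linalg.norm(v)
    if norm <= 1e-12:
        raise NMAError("zero displacement direction")
    v = v / norm
    # Cartesian direction: x = x0 + s*sqrt(total mass) * M^(-1/2) v gives MRMS == |s|
    cart = (v.reshape(-1, 3) / np.sqrt(masses)[:, None]) * np.sqrt(masses.sum())
    targets = np.linspace(-amplitude, amplitude, n_frames)
    targets[n_frames // 2] = 0.0
    ref = structure.coord
    frames = np.empty((n_frames, structure.n_atoms, 3))
    achieved = np.empty(n_frames)
    converged = np.ones(n_frames, dtype=bool)
    if relax and topology is None:
        raise NMAError("relaxation requires the ENM topology")
    for f, s in enumerate(targets):
        x = ref + s * cart
        if relax and abs(s) > 1e-12:
            x, ok = _relax_frame(
                x, ref, masses, v, topology, s, restraint_k, max_iter, grad_tol
            )
            converged[f] = ok
            if not ok:
                warnings.warn(
                    f"relaxation did not fully converge at MRMS {s:+.3f} "
                    f"(mode {mode_label})",
                    stacklevel=2,
                )
        frames[f] = x
        achieved[f] = _mrms(x, ref, masses)
    return ModeTrajectory(
        mode_label=mode_label,
        reference=structure,
        frames=frames,
        targets=targets,
        achieved=achieved,
        relaxed=relax,
        converged=converged,
    )


def generate_mode_trajectory(
    structure: MolecularStructure,
    mode_set: ModeSet,
    mode_label: int,
    amplitude: float = 1.0,
    n_frames: int = 21,
    relax: bool = False,
    topology: ENMTopology | None = None,
    restraint_k: float = 100.0,
    max_iter: int = 500,
    grad_tol: float = 1e-4,
) -> ModeTrajectory:
    """Displace a structure along one labelled mode at equally spaced MRMS
    targets in ``[-amplitude, +amplitude]`` (Å).

    ``relax=False`` yields the pure harmonic displacement, exactly
    antisymmetric about the reference frame; ``relax=True`` additionally
    minimizes each frame under the ENM energy with the MRMS amplitude
    restrained (see module docstring).
    """
    return _trajectory_from_direction(
        structure,
        mode_set.vector(mode_label),
        mode_label,
        amplitude,
        n_frames,
        relax,
        topology,
        restraint_k,
        max_iter,
        grad_tol,
    )


def transfer_mode_trajectory(
    mode_set_a: ModeSet,
    structure_a: MolecularStructure,
    structure_b: MolecularStructure,
    mapping: ResidueMapping,
    mode_label: int,
    coverage_min: float = 0.9,
    amplitude: float = 1.0,
    n_frames: int = 21,
    relax: bool = True,
    topology_b: ENMTopology | None = None,
    restraint_k: float = 100.0,
    max_iter: int = 500,
    grad_tol: float = 1e-4,
) -> ModeTrajectory:
    """Apply system A's mode direction to system B and regenerate the
    trajectory under B's own elastic network.

    A's Cα-restricted displacement pattern is re-indexed onto B through the
    residue mapping (unmapped B residues get zero displacement), converted
    to B's mass-weighted coordinates, renormalized, and used as the
    displacement direction.  Relaxation (on by default) is what lets B's
    network reshape — or fail to support — the borrowed motion.
    """
    sel_a = select_calpha(structure_a)
    sel_b = select_calpha(structure_b)
    key_to_a = {key: idx for key, idx in zip(sel_a.residue_keys, sel_a.indices)}
    key_to_b = {key: idx for key, idx in zip(sel_b.residue_keys, sel_b.indices)}
    pair_lookup = dict(mapping.pairs)
    cart_a = mode_set_a.cartesian_displacement(mode_label)
    direction_b = np.zeros((structure_b.n_atoms, 3))
    n_covered = 0
    for key_a, atom_a in key_to_a.items():
        key_b = pair_lookup.get(key_a)
        if key_b is None or key_b not in key_to_b:
            continue
        direction_b[key_to_b[key_b]] = cart_a[atom_a]
        n_covered += 1
    coverage = n_covered / max(len(key_to_b), 1)
    if coverage < coverage_min:
        raise NMAError(
            f"mapping covers {coverage:.1%} of acceptor C-alpha positions "
            f"(minimum {coverage_min:.0%})"
        )
    mw_direction = (direction_b * np.sqrt(structure_b.mass)[:, None]).ravel()
    if topology_b is None and relax:
        topology_b = enm_topology(structure_b.coord)
    return _trajectory_from_direction(
        structure_b,
        mw_direction,
        mode_label,
        amplitude,
        n_frames,
        relax,
        topology_b,
        restraint_k,
        max_iter,
        grad_tol,
    )
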