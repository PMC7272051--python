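# Methods

## Problem setting

Multi-signaling ("biased") receptor complexes can activate distinct
downstream pathways, and single point mutations in the ligand can knock out
one pathway while sparing another. The working hypothesis implemented here
is that each signaling outcome is driven by a distinct *collective motion*
of the complex, so a function-breaking mutation should selectively delete
the motions tied to the lost outcome. modenet operationalizes this as a
comparative normal-mode workflow: compute low-frequency modes for each
system (wild type and variants), fingerprint what each mode does to the
internal geometry, decide across systems which motions are the *same*
motion, and read function off the phenotype annotations — motions present
in all systems belong to the outcomes all systems support; motions unique
to one system belong to the outcomes that distinguish it.

## Elastic-network normal modes

The Hessian is pluggable; the shipped default is the anisotropic elastic
network model (ANM). Particles within a cutoff (default 10 Å) are joined
by Hookean springs at their observed separation with a uniform force
constant (default k = 1, arbitrary energy/Å² units — only mode shapes and
relative stiffness matter downstream, none of the analyses depend on the
absolute frequency scale). The mass-weighted eigenproblem
H v = ω² M v is solved densely (`scipy.linalg.eigh` after the M^(-1/2)
similarity transform). Modes are numbered in the convention of the
structural-dynamics literature: the six rigid-body modes are modes 1–6, so
the first internal mode is mode 7. The zero-mode tolerance is 1e-8 times
the largest eigenvalue; a disconnected network correctly yields more than
six trivial modes. Eigenvector sign is fixed (largest-magnitude component
positive) so results are bit-reproducible.

This replaces an all-atom force-field normal mode calculation. That is a
deliberate, loudly-declared substitution: the comparative machinery
downstream (fingerprints, Mantel clustering, classification, networks) is
Hessian-agnostic, and a Cα-level ENM is the field-standard desk-scale
model for low-frequency collective motions. What is lost is the direct
influence of the mutated side chain's chemistry on the mode directions;
in the synthetic systems that influence is reintroduced explicitly as a
contact-topology perturbation (below).

## Mode pseudo-trajectories

Each analyzed mode generates a pseudo-trajectory: 21 frames at equally
spaced mass-weighted RMS (MRMS) displacements in [−1, +1] Å (amplitude and
frame count configurable; the frame count is a smoothing choice for the
correlation statistics, not a physical parameter). With relaxation off, a
frame is the exact harmonic displacement x = x₀ + s·√(ΣM)·M^(−1/2)v, whose
MRMS equals the target by construction.

With relaxation on, each frame is minimized under the ENM energy — which
is anharmonic in Cartesian coordinates, since spring energies depend on
distances — plus a harmonic restraint (default weight 100 energy/Ų)
holding the *MRMS coordinate along the mode*: the signed mass-weighted
projection of the displacement onto the mode direction, divided by the
square root of the total mass. For the pure harmonic displacement this
coordinate equals the target exactly, so relaxation starts with zero
restraint energy and moves the frame only in directions orthogonal to the
imposed motion. Minimization is gradient-based (L-BFGS-B, default 500
iterations, gradient tolerance 1e-4), followed by a mass-weighted
superposition onto the reference to remove residual net
translation/rotation. Restraining the projection rather than the scalar
MRMS magnitude is essential: a magnitude-only restraint leaves the
direction free, and at full convergence every frame would slide to the
softest mode of the network, erasing exactly the distinction the transfer
experiment is designed to measure. Non-converged frames are flagged and
warned about, not fatal.

## Motion fingerprints and Mantel similarity

A mode's fingerprint is ΔM = M₊ − M_χ: the Cα pairwise-distance matrix of
the +1 Å frame minus that of the reference. It is invariant under rigid
motion and under which end of the eigenvector is called "+" only up to
global sign, so similarity is thresholded on |r|. The −1 Å fingerprint is
computed as a consistency check (its sign-flipped correlation with ΔM is
reported; it approaches 1 in the linear regime and degrades gracefully
with anharmonicity) but is not analyzed further.

Fingerprints are compared with the Mantel test: Pearson correlation of
the strict upper triangles, significance by simultaneous row/column
permutation of one matrix. Permutations are exhaustive for matrices up to
7×7 and sampled otherwise (default 9999 draws, seeded, with the add-one
correction so p is never 0; 9999 is the smallest round count whose minimum
attainable p lies below the 0.001 decision threshold). Because the
off-diagonal multiset is permutation-invariant, each permuted correlation
is a single dot product; permutations are vectorized in chunks. The full
signed r matrix is retained for table-style reporting; permutation p's are
evaluated for pairs that pass the |r| screen, since a sub-threshold pair
cannot become an edge (a flag restores the full quadratic sweep).

Two modes describe the same motion when |r| ≥ 0.6 and p < 0.001. Motions
are clustered as connected components of the thresholded graph — the
simplest rule consistent with treating "same motion" as a transitive
judgment — and classified: components spanning systems are shared (tagged
with the intersection of their systems' outcomes), single-system
components are unique (tagged with the symmetric difference against the
rest of the panel). Cross-system comparisons are restricted to mapped
common Cα positions via the residue mapping; substituted residues keep
their Cα and stay in the comparison.

## Motion transfer (the hQ experiment)

To test whether a variant *could* perform a wild-type-only motion, the
donor's Cα displacement pattern is re-indexed onto the acceptor through
the residue mapping (unmapped positions frozen), renormalized in the
acceptor's mass metric, and used to generate a relaxed trajectory under
the acceptor's own elastic network. The donor reference fingerprint is
recomputed with identical relaxation settings so the comparison is
relaxed-vs-relaxed. A motion "survives" when the transferred fingerprint
still matches the original at the similarity thresholds. Mechanically,
relaxation lets the acceptor network reshape the borrowed displacement:
directions the acceptor supports stay put (near-critical points of the
restrained energy), directions it does not support collapse in amplitude
and rotate toward the acceptor's own soft subspace, destroying the match.

## Correlation maps and flexibility

The cross-correlation map over a motion class is computed on the
concatenated frames of all the class's trajectories (each mode contributes
equal frame counts), after least-squares superposition onto the reference
on the Cα selection — a no-op for harmonic trajectories, a safeguard for
relaxed ones. C(i,j) is the normalized covariance of displacement vectors
about the ensemble mean; zero-fluctuation atoms get NaN rows and an
explicit flag rather than silent zeros. Reported coupling bins: |C| ≥ 0.7
strong, ≥ 0.5 moderate (reporting vocabulary only; configurable).

Group flexibility is, per atom: the squared deviation from the initial
structure averaged over each mode's frames and over the atom's three
degrees of freedom, then averaged over the group's modes, then rooted.
Duplicating a group member leaves the profile unchanged.

## Dynamical networks, communities, paths

Network nodes are Cα residues; an edge requires |C(i,j)| ≥ 0.7 *and*
Cα–Cα distance ≤ 10 Å in ≥ 75% of the same concatenated frames used for
the class map. Edge weight is −log|C| (|C| capped at 1−1e-12 so weights
stay positive when synthetic data saturates), making strong coupling short
in the path metric, so communication strength rises as path length falls
by construction.

Communities: Girvan–Newman divisive clustering (highest weighted edge
betweenness removed iteratively; ties broken lexicographically for
determinism). Modularity is evaluated with |C| as the connection weight —
the distance-like −log|C| would invert the meaning of "strong" — while
betweenness and paths use −log|C| as distance. Among all dendrogram
partitions within 0.05 of the maximum modularity, the one with the fewest
communities is chosen (the anti-fragmentation correction); communities
under 10 nodes are pruned to unassigned. Inter-community coupling is the
summed |C| over crossing edges, normalized by the largest such sum.

Communication between chosen residue pairs is profiled with the k = 500
shortest simple paths (networkx's Yen enumeration, with the tie class at
the k-th length drained and sorted so the returned set is deterministic),
their length histogram, and node degeneracy — the fraction of returned
paths through each node, 1 at source and sink by definition. A
disconnected pair returns an explicit empty ensemble.

## Interactions

Hydrogen bonds: donor–acceptor (N/O) distance ≤ 3.0 Å and D–H···A
deviation from linearity ≤ 20°, any covalent hydrogen on the donor
qualifying; the angle convention (deviation of the angle at H from 180°)
is a documented choice. Structures without hydrogens — bead models,
unprotonated PDBs — fall back to the distance test alone, flagged per
record. Salt bridges: side-chain carboxylate O (Asp/Glu) to side-chain
cationic N (Lys/Arg/His) within 3.2 Å. Occupancy is the exact fraction of
frames satisfied; "high occupancy" means ≥ 0.5, boundary included.
Interaction diffs between classes/systems are keyed by residue pair after
mapping.

## Synthetic study systems

The generator builds what the method needs to be tested against: pairs of
multi-chain elastic networks that share most low-frequency modes and
differ in a controlled subset. The default geometry is a 2:2
dimer-of-dimers — four 30-bead helical chains, two central "ligand" chains
in mutual contact, two flanking "receptor" chains each touching one ligand
chain and *not* each other — so receptor-receptor communication must
transit the ligand dimer, giving chain-blocked correlation maps,
inter-chain community couplings, and receptor-to-receptor path ensembles
meaningful shapes. Beads are CA-named carbons at ~helical spacing with
0.25 Å seeded jitter to break degeneracies.

The variant is the wild type with a local contact perturbation at a
mutation site (default: the ligand bead with the densest contact set to a
receptor chain, i.e. the complex's interface residue, chosen from the
generated geometry): every spring joining the site bead to another chain
is deleted — the controlled part, a substituted side chain breaking its
own inter-subunit contacts — plus a seeded random 30% of the remaining
springs within 7 Å of the site. Purely random deletion was rejected as a
design: it leaves disruption to chance (some realizations spare the
interface entirely), whereas the deterministic interface component
reliably yields the target regime of mostly-shared/some-disrupted modes
(typically 14–17 of 20 shared) across seeds. The variant's residue at the
site is renamed so the residue mapping flags exactly one substitution.

What the generator does not emulate: side-chain chemistry, solvent,
realistic mass heterogeneity, sequence effects, or experimental noise in
coordinates. Tests passing on these systems show the *pipeline* is
correct and that the motion-loss logic behaves as designed on networks
with engineered ground truth; they do not certify conclusions about any
real receptor.

## Determinism and seeds

A single global seed fans out to per-stage seeds through
SHA-256(f"{seed}:{stage}") mod 2³¹−1, so adding a stage never shifts
another stage's stream. All generators are pure functions of (spec, seed);
Girvan–Newman and path ties are broken lexicographically; eigenvector
signs are pinned. Identical config + seed reproduces numeric outputs
byte-for-byte (PNG renderings and the timestamped event log excluded).

## Problem sizes and defaults

The shipped study configuration analyzes 120-bead complexes (4×30), the
20 lowest internal modes per system, 21-frame trajectories at ±1 Å MRMS,
9999 Mantel permutations, and 500-path ensembles — sizes chosen so the
full study (including the transfer experiment) completes in a few minutes
on one CPU while keeping every analysis stage in its intended regime.
Relaxation is off in the default classification pass (harmonic
fingerprints are sufficient to separate shared from disrupted modes and
keep the pass fast) and always on in the transfer experiment, where it is
the mechanism being probed.

## Known limitations

- The ENM Hessian ignores side-chain chemistry; mutations enter only as
  topology perturbations. Real mutation effects that act through charge
  or packing without changing contacts are invisible.
- Connected-component clustering can chain weakly-related motions through
  intermediates; the full r matrix is exported so users can inspect
  borderline edges.
- The k-shortest-path ensemble reports exactly k paths; the realized
  length range is reported rather than a fixed offset above the optimum.
- Heavy-atom hydrogen-bond fallback cannot distinguish donors from
  acceptors and skips the angle criterion; records carry the flag.
- Single-system runs produce redundancy reports only; classification
  requires at least two phenotype-annotated systems by construction.
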