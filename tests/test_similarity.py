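"""Motion fingerprints, Mantel test, similarity graph and classification."""

import itertools

import numpy as np
import pytest

from modenet.nma import ModeTrajectory, generate_mode_trajectory
from modenet.similarity import (
    MotionFingerprint,
    SimilarityError,
    build_similarity_graph,
    classify_motions,
    compute_fingerprint,
    mantel_test,
    redundancy_report,
)
from modenet.structures import select_calpha

from conftest import make_bead_structure


def make_trajectory(structure, frames, targets, label=7):
    frames = np.asarray(frames, dtype=float)
    return ModeTrajectory(
        mode_label=label,
        reference=structure,
        frames=frames,
        targets=np.asarray(targets, dtype=float),
        achieved=np.array([np.nan] * len(frames)),
        relaxed=False,
        converged=np.ones(len(frames), dtype=bool),
    )


def random_symmetric(n, rng):
    m = rng.normal(size=(n, n))
    m = m + m.T
    np.fill_diagonal(m, 0.0)
    return m


def fp(matrix, system="s", mode=7):
    n = len(matrix)
    keys = make_bead_structure(np.column_stack([np.arange(n) * 4.0,
                                                np.zeros(n), np.zeros(n)])).residues
    return MotionFingerprint(system, mode, matrix, keys)


class TestFingerprint:
    def test_zero_amplitude_gives_zero_matrix(self):
        structure = make_bead_structure([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        trj = make_trajectory(structure, [structure.coord] * 3, [-1.0, 0.0, 1.0])
        sel = select_calpha(structure)
        delta = compute_fingerprint(trj, sel).delta
        np.testing.assert_array_equal(delta, 0.0)

    def test_rigid_translation_is_invisible(self):
        structure = make_bead_structure([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        shift = np.array([1.3, -0.7, 2.0])
        trj = make_trajectory(
            structure,
            [structure.coord - shift, structure.coord, structure.coord + shift],
            [-1.0, 0.0, 1.0],
        )
        delta = compute_fingerprint(trj, select_calpha(structure)).delta
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_hand_computed_distance_changes(self):
        """One bead moved +1 Å along x: every entry equals the hand-computed
        distance change."""
        ref = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 3, 0]])
        moved = ref.copy()
        moved[0, 0] += 1.0
        structure = make_bead_structure(ref)
        trj = make_trajectory(structure, [2 * ref - moved, ref, moved], [-1, 0, 1])
        delta = compute_fingerprint(trj, select_calpha(structure)).delta
        d01 = abs(4.0 - 1.0) - 4.0  # beads 0-1 along x: 3 after, 4 before
        d02 = np.hypot(1.0, 3.0) - 3.0
        assert delta[0, 1] == pytest.approx(d01, abs=1e-12)
        assert delta[0, 2] == pytest.approx(d02, abs=1e-12)
        assert delta[1, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(delta, delta.T) and np.all(np.diag(delta) == 0)

    def test_minus_frame_consistency_reported(self, small_complex, small_complex_modes):
        """The M- fingerprint mirrors the M+ one; exactly so in the linear
        regime, strongly so at the working amplitude where second-order
        distance effects enter."""
        structure, _ = small_complex
        sel = select_calpha(structure)
        tiny = compute_fingerprint(
            generate_mode_trajectory(structure, small_complex_modes, 7, amplitude=0.05),
            sel,
        )
        assert tiny.minus_plus_r == pytest.approx(1.0, abs=1e-3)
        working = compute_fingerprint(
            generate_mode_trajectory(structure, small_complex_modes, 7), sel
        )
        assert working.minus_plus_r is not None and working.minus_plus_r > 0.5


class TestMantel:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(5)
        f = fp(random_symmetric(10, rng))
        assert mantel_test(f, f, n_permutations=99, seed=1).r == pytest.approx(1.0)
        neg = fp(-f.delta)
        assert mantel_test(f, neg, n_permutations=99, seed=1).r == pytest.approx(-1.0)

    def test_exhaustive_matches_manual_enumeration(self):
        """5x5 exhaustive p equals the fraction over all 120 permutations."""
        rng = np.random.default_rng(7)
        a, b = random_symmetric(5, rng), random_symmetric(5, rng)
        result = mantel_test(fp(a), fp(b))
        assert result.scheme == "exhaustive"
        assert result.n_permutations == 120
        iu = np.triu_indices(5, k=1)
        va = a[iu]
        r_obs = np.corrcoef(va, b[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(5)):
            p = np.asarray(perm)
            r_star = np.corrcoef(va, b[p[:, None], p[None, :]][iu])[0, 1]
            if abs(r_star) >= abs(r_obs) - 1e-12:
                count += 1
        assert result.p_value == pytest.approx(count / 120)
        assert result.r == pytest.approx(r_obs)

    def test_sampled_p_within_three_se_of_exhaustive(self):
        rng = np.random.default_rng(21)
        for trial in range(3):
            a, b = random_symmetric(6, rng), random_symmetric(6, rng)
            exact = mantel_test(fp(a), fp(b))
            sampled = mantel_test(
                fp(a), fp(b), n_permutations=10_000, seed=trial, exhaustive_max_n=0
            )
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
            assert abs(sampled.p_value - exact.p_value) <= 3 * se + 2e-4

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = random_symmetric(6, rng), random_symmetric(6, rng)
        r1 = mantel_test(fp(a), fp(b))
        r2 = mantel_test(fp(b), fp(a))
        assert r1.r == pytest.approx(r2.r)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(9)
        a, b = random_symmetric(8, rng), random_symmetric(8, rng)
        perm = rng.permutation(8)
        r_base = mantel_test(fp(a), fp(b), n_permutations=0, seed=0,
                             exhaustive_max_n=0)
        r_perm = mantel_test(
            fp(a[np.ix_(perm, perm)]), fp(b[np.ix_(perm, perm)]),
            n_permutations=0, seed=0, exhaustive_max_n=0,
        )
        assert r_base.r == pytest.approx(r_perm.r, abs=1e-12)

    def test_against_skbio_reference(self):
        """r and sampled p agree with scikit-bio's Mantel implementation."""
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(13)
        a, b = random_symmetric(12, rng), random_symmetric(12, rng)
        # make them correlated so p is informative
        b = 0.7 * a + 0.3 * b
        np.fill_diagonal(b, 0.0)
        ours = mantel_test(fp(a), fp(b), n_permutations=9999, seed=0)
        ref_r, ref_p, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b),
            method="pearson", permutations=9999, alternative="two-sided",
        )
        assert ours.r == pytest.approx(ref_r, abs=1e-10)
        assert ours.p_value == pytest.approx(ref_p, abs=0.02)

    def test_zero_variance_rejected(self):
        flat = np.zeros((5, 5))
        rng = np.random.default_rng(1)
        with pytest.raises(SimilarityError, match="zero-variance"):
            mantel_test(fp(flat), fp(random_symmetric(5, rng)))


class TestSimilarityGraph:
    def build_fps(self):
        rng = np.random.default_rng(30)
        mats = [random_symmetric(9, rng) for _ in range(3)]
        return [fp(m, system="a", mode=7 + i) for i, m in enumerate(mats)], mats

    def test_twin_systems_fully_linked(self):
        fps_a, mats = self.build_fps()
        fps_b = [fp(m, system="b", mode=7 + i) for i, m in enumerate(mats)]
        graph = build_similarity_graph(fps_a + fps_b, n_permutations=9999, seed=4)
        for i in range(3):
            assert graph.has_edge(("a", 7 + i), ("b", 7 + i))
            assert graph.edges[("a", 7 + i), ("b", 7 + i)]["r"] == pytest.approx(1.0)

    def test_impossible_threshold_gives_empty_edges(self):
        fps_a, mats = self.build_fps()
        fps_b = [fp(m, system="b", mode=7 + i) for i, m in enumerate(mats)]
        graph = build_similarity_graph(
            fps_a + fps_b, r_threshold=1.01, n_permutations=99, seed=4
        )
        assert graph.number_of_edges() == 0

    def test_orthogonal_modes_not_linked(self, small_complex, small_complex_modes):
        structure, _ = small_complex
        sel = select_calpha(structure)
        fps = []
        for label in (7, 8, 9):
            trj = generate_mode_trajectory(structure, small_complex_modes, label)
            fps.append(compute_fingerprint(trj, sel, system_id="x"))
        graph = build_similarity_graph(fps, n_permutations=9999, seed=0)
        assert graph.number_of_edges() == 0  # distinct modes, distinct motions


class TestClassification:
    def two_system_graph(self):
        rng = np.random.default_rng(50)
        shared = [random_symmetric(9, rng) for _ in range(2)]
        unique_a = random_symmetric(9, rng)
        fps = (
            [fp(m, "a", 7 + i) for i, m in enumerate(shared)]
            + [fp(unique_a, "a", 9)]
            + [fp(m, "b", 7 + i) for i, m in enumerate(shared)]
        )
        return build_similarity_graph(fps, n_permutations=9999, seed=2)

    def test_engineered_shared_and_unique_modes(self):
        graph = self.two_system_graph()
        result = classify_motions(
            graph, {"a": {"alpha", "beta"}, "b": {"alpha"}}
        )
        assert result.shared_modes("a") == [7, 8]
        assert result.unique_modes("a") == [9]
        # unique-to-a motion is tagged with the outcome only a supports
        unique_comp = [c for c in result.components if c["class"] == "unique"]
        assert unique_comp[0]["outcome_tags"] == ["beta"]
        shared_comp = [c for c in result.components if c["class"] == "shared"]
        assert all(c["outcome_tags"] == ["alpha"] for c in shared_comp)

    def test_all_modes_shared_single_component(self):
        rng = np.random.default_rng(8)
        m = random_symmetric(9, rng)
        fps = [fp(m, s, 7) for s in ("a", "b", "c")]
        graph = build_similarity_graph(fps, n_permutations=9999, seed=1)
        result = classify_motions(graph, {"a": {"x"}, "b": {"x"}, "c": {"x"}})
        assert len(result.components) == 1
        assert result.components[0]["class"] == "shared"
        assert result.nodes_in_class("unique") == []

    def test_no_cross_edges_all_unique(self):
        rng = np.random.default_rng(60)
        fps = [fp(random_symmetric(9, rng), s, 7) for s in ("a", "b")]
        graph = build_similarity_graph(fps, n_permutations=9999, seed=1)
        result = classify_motions(graph, {"a": {"x"}, "b": {"x"}})
        assert all(c["class"] == "unique" for c in result.components)

    def test_single_system_refused_with_redundancy_available(self):
        rng = np.random.default_rng(70)
        m = random_symmetric(9, rng)
        fps = [fp(m, "only", 7), fp(m, "only", 8)]
        graph = build_similarity_graph(fps, n_permutations=9999, seed=1)
        with pytest.raises(SimilarityError, match="two systems"):
            classify_motions(graph, {"only": {"x"}})
        groups = redundancy_report(graph)
        assert [("only", 7), ("only", 8)] in groups

    def test_classification_invariant_to_system_order(self):
        graph = self.two_system_graph()
        phen = {"a": {"alpha", "beta"}, "b": {"alpha"}}
        r1 = classify_motions(graph, phen)
        r2 = classify_motions(graph, dict(reversed(list(phen.items()))))
        assert r1.node_class == r2.node_class
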