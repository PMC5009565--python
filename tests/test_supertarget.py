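import numpy as np
import pytest

from dtilcm.rls import KernelFactorization
from dtilcm.supertarget import (
    acceptance_flags,
    build_supertarget_layer,
    build_union_adjacency,
    cluster_targets,
    mark_fake_interactions,
    top_k_neighbors,
    train_supertarget_classifiers,
)
from tests.conftest import make_similarity


def block_similarity(sizes, within=0.9, between=0.1):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    sim = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(sim, 1.0)
    return sim, labels


class TestClusterTargets:
    def test_separated_blocks_recovered(self):
        sim, labels = block_similarity([4, 3])
        part = cluster_targets(sim, cut_similarity=0.6)
        assert len(set(part)) == 2
        # same block -> same super-target
        for q in range(2):
            assert len(set(part[labels == q])) == 1

    def test_extreme_cut_gives_singletons(self, rng):
        sim = make_similarity(rng, 6) * 0.9  # all off-diagonals < 0.999
        np.fill_diagonal(sim, 1.0)
        part = cluster_targets(sim, cut_similarity=0.999)
        assert len(set(part)) == 6

    def test_matches_reference_average_linkage(self, rng):
        """Oracle: sklearn's agglomerative clustering on the same distances."""
        sklearn = pytest.importorskip("sklearn.cluster")
        for cut in (0.4, 0.6, 0.8):
            sim = make_similarity(rng, 12)
            part = cluster_targets(sim, cut_similarity=cut)
            dist = 1.0 - sim
            np.fill_diagonal(dist, 0.0)
            ref = sklearn.AgglomerativeClustering(
                n_clusters=None,
                metric="precomputed",
                linkage="average",
                distance_threshold=1.0 - cut,
            ).fit_predict(dist)
            # same partition up to label renaming
            pairs_ours = part[:, None] == part[None, :]
            pairs_ref = ref[:, None] == ref[None, :]
            np.testing.assert_array_equal(pairs_ours, pairs_ref)

    def test_cut_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            cluster_targets(np.eye(3), cut_similarity=1.5)

    def test_raising_cut_never_merges(self, rng):
        """Finer cuts refine the partition: clusters only split, never merge."""
        sim = make_similarity(rng, 10)
        coarse = cluster_targets(sim, cut_similarity=0.3)
        fine = cluster_targets(sim, cut_similarity=0.7)
        for q in set(fine):
            assert len(set(coarse[fine == q])) == 1


class TestUnionAdjacency:
    def test_or_of_columns(self):
        A = np.array([[1, 0], [0, 0], [0, 0], [1, 1]])
        B = build_union_adjacency(A, np.array([0, 0]))
        np.testing.assert_array_equal(B[:, 0], [1, 0, 0, 1])

    def test_singleton_column_copied(self, rng):
        A = rng.integers(0, 2, size=(5, 3))
        B = build_union_adjacency(A, np.array([0, 1, 2]))
        np.testing.assert_array_equal(B, A)

    def test_matches_brute_force_any_scan(self, rng):
        A = rng.integers(0, 2, size=(10, 8))
        part = rng.integers(0, 3, size=8)
        part[0:3] = [0, 1, 2]  # ensure every super-target exists
        B = build_union_adjacency(A, part)
        for i in range(10):
            for q in range(3):
                assert B[i, q] == int(any(A[i, j] for j in range(8) if part[j] == q))


class TestNeighbors:
    def test_ties_break_by_ascending_index(self):
        sim = np.full((4, 4), 0.5)
        np.fill_diagonal(sim, 1.0)
        nn = top_k_neighbors(sim, 2)
        np.testing.assert_array_equal(nn[0], [1, 2])
        np.testing.assert_array_equal(nn[3], [0, 1])

    def test_k_must_be_smaller_than_drug_count(self):
        with pytest.raises(ValueError):
            top_k_neighbors(np.eye(3), 3)


class TestFakeInteractions:
    def test_lone_interactor_is_fake(self):
        sim, _ = block_similarity([3, 3])
        B = np.zeros((6, 1), dtype=int)
        B[0, 0] = 1  # only one drug interacts with the super-target
        fake = mark_fake_interactions(B, sim, k=3)
        assert fake[0, 0] == 1

    def test_clique_has_no_fakes(self):
        sim, _ = block_similarity([4, 4])
        B = np.zeros((8, 1), dtype=int)
        B[:4, 0] = 1  # four mutually most-similar drugs all interact
        fake = mark_fake_interactions(B, sim, k=3)
        assert fake.sum() == 0

    def test_matches_double_loop_oracle(self, rng):
        m, Q, k = 12, 4, 3
        sim = make_similarity(rng, m)
        B = rng.integers(0, 2, size=(m, Q))
        fake = mark_fake_interactions(B, sim, k)
        nn = top_k_neighbors(sim, k)
        for q in range(Q):
            for u in range(m):
                if not B[u, q]:
                    assert fake[u, q] == 0
                    continue
                others = [v for v in range(m) if v != u and B[v, q]]
                expected = int(not any(v in others for v in nn[u]))
                assert fake[u, q] == expected

    def test_cleaning_never_creates_interactions(self, rng):
        sim = make_similarity(rng, 10)
        B = rng.integers(0, 2, size=(10, 3))
        fake = mark_fake_interactions(B, sim, 3)
        assert ((B - fake) >= 0).all()  # fake_mask subset of B


class TestAcceptance:
    def test_pair_of_mutual_neighbors_rejected(self):
        """Two interactors give each other at most one co-interacting neighbor:
        n-tilde = 1 < 3/2."""
        sim, _ = block_similarity([4, 4])
        B = np.zeros((8, 1), dtype=int)
        B[[0, 1], 0] = 1
        accepted, n_tilde = acceptance_flags(B, sim, k=3)
        assert n_tilde[0] == pytest.approx(1.0)
        assert not accepted[0]

    def test_four_mutual_interactors_accepted(self):
        sim, _ = block_similarity([4, 4])
        B = np.zeros((8, 1), dtype=int)
        B[:4, 0] = 1
        accepted, n_tilde = acceptance_flags(B, sim, k=3)
        assert n_tilde[0] == pytest.approx(3.0)
        assert accepted[0]

    def test_empty_super_target_rejected(self):
        sim, _ = block_similarity([3, 3])
        accepted, n_tilde = acceptance_flags(np.zeros((6, 2), dtype=int), sim, 3)
        assert not accepted.any() and (n_tilde == 0).all()

    def test_matches_brute_force(self, rng):
        m, Q, k = 11, 3, 3
        sim = make_similarity(rng, m)
        B = rng.integers(0, 2, size=(m, Q))
        accepted, n_tilde = acceptance_flags(B, sim, k)
        nn = top_k_neighbors(sim, k)
        for q in range(Q):
            interactors = [u for u in range(m) if B[u, q]]
            if not interactors:
                assert not accepted[q]
                continue
            counts = []
            for u in interactors:
                others = [v for v in interactors if v != u]
                counts.append(sum(1 for v in nn[u] if v in others))
            expected_nt = np.mean(counts)
            assert n_tilde[q] == pytest.approx(expected_nt)
            assert accepted[q] == (expected_nt >= k / 2)


class TestSupertargetClassifiers:
    def test_singleton_partition_collapses_to_per_target_models(self, rng):
        A = rng.integers(0, 2, size=(6, 4))
        K = make_similarity(rng, 6)
        factor = KernelFactorization(K, 0.5)
        st_models = train_supertarget_classifiers(A, K, 0.5)
        expected = factor.solve(A.astype(float))
        for q, m in enumerate(st_models):
            np.testing.assert_allclose(m.solved_weights, expected[:, q], atol=1e-10)

    def test_all_zero_column_scores_zero(self, rng):
        K = make_similarity(rng, 5)
        models = train_supertarget_classifiers(np.zeros((5, 1), dtype=int), K, 0.5)
        assert np.allclose(models[0].solved_weights, 0)

    def test_identity_kernel_closed_form(self):
        from dtilcm import score_rls

        models = train_supertarget_classifiers(
            np.array([[1], [0], [1]]), np.eye(3), 0.5
        )
        scores = score_rls(models[0], np.eye(3))
        np.testing.assert_allclose(scores, [1 / 1.5, 0.0, 1 / 1.5], atol=1e-12)


def test_layer_orders_cleaning_before_acceptance(rng):
    """The layer's acceptance flags are computed on the cleaned adjacency."""
    sd_sim = make_similarity(rng, 10)
    t_sim = make_similarity(rng, 6)
    A = rng.integers(0, 2, size=(10, 6))
    layer = build_supertarget_layer(A, sd_sim, t_sim, cut_similarity=0.6, k=3)
    np.testing.assert_array_equal(
        layer.cleaned, layer.union_adjacency & ~layer.fake_mask.astype(bool)
    )
    expected_accept, expected_nt = acceptance_flags(layer.cleaned, sd_sim, 3)
    np.testing.assert_array_equal(layer.accepted, expected_accept)
    np.testing.assert_allclose(layer.n_tilde, expected_nt)
    # a total partition: every target in exactly one super-target
    assert layer.partition.shape == (6,)
    assert set(layer.partition) == set(range(layer.n_super_targets))
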