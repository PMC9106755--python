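"""Dice similarity, UPGMA clustering and dendrogram diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from musadiv.similarity import (
    UndefinedSimilarityError,
    cophenetic_correlation,
    cut_at_similarity,
    shared_band_similarity,
    similarity_matrix,
    upgma,
)


class TestSharedBandSimilarity:
    def test_identical_lanes(self):
        assert shared_band_similarity([1, 1, 0, 1], [1, 1, 0, 1]) == 1.0

    def test_hand_enumeration(self):
        # a = #(1,1) = 2, n_a = n_b = 3 -> 2*2/6
        assert shared_band_similarity([1, 1, 0, 1], [1, 0, 1, 1]) == pytest.approx(
            2 / 3
        )

    def test_disjoint_lanes(self):
        assert shared_band_similarity([1, 0], [0, 1]) == 0.0

    def test_undefined_when_no_bands(self):
        with pytest.raises(UndefinedSimilarityError):
            shared_band_similarity([0, 0], [0, 0])

    def test_missing_excluded_pairwise(self):
        s = shared_band_similarity([1, np.nan, 1], [1, 1, 0])
        assert s == pytest.approx(2 * 1 / (2 + 1))

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1)),
            min_size=1,
            max_size=30,
        )
    )
    def test_bounded_symmetric_and_joint_absence_invariant(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        if not any(a) and not any(b):
            return
        s = shared_band_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == shared_band_similarity(b, a)
        assert s == shared_band_similarity(a + [0], b + [0])


class TestSimilarityMatrix:
    def test_unit_diagonal_and_oracle(self, hand_matrix):
        labels, S = similarity_matrix(hand_matrix)
        np.testing.assert_allclose(np.diag(S), 1.0)
        # brute-force check of every pair against the lane formula
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                assert S[i, j] == pytest.approx(
                    shared_band_similarity(
                        hand_matrix.values[i], hand_matrix.values[j]
                    )
                )

    def test_permutation_equivariance(self, hand_matrix):
        from musadiv.io_formats import BandMatrix

        labels, S = similarity_matrix(hand_matrix)
        perm = [2, 0, 4, 1, 3]
        m2 = BandMatrix(
            [hand_matrix.genotype_ids[i] for i in perm],
            list(hand_matrix.loci),
            hand_matrix.values[perm],
        )
        labels2, S2 = similarity_matrix(m2)
        np.testing.assert_allclose(S2, S[np.ix_(perm, perm)])

    def test_system_restriction(self, hand_matrix):
        labels, S = similarity_matrix(hand_matrix, system="ISSR")
        assert S.shape == (5, 5)
        assert S[0, 1] == pytest.approx(
            shared_band_similarity(
                hand_matrix.values[0, 3:], hand_matrix.values[1, 3:]
            )
        )


def _naive_upgma_cophenetic(D, labels):
    """Independent UPGMA: recompute cluster averages from the original D."""
    clusters = [[i] for i in range(len(labels))]
    C = np.zeros_like(D)
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[x] for j in clusters[y]])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                C[i, j] = C[j, i] = d
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return C


class TestUpgma:
    def test_forced_three_point_topology(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(D, ["A", "B", "C"])
        assert tree.merges[0, 2] == pytest.approx(0.2)  # branch height 0.1
        assert tree.merges[1, 2] == pytest.approx(0.6)  # branch height 0.3
        assert set(tree.merges[0, :2]) == {0, 1}

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_naive_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = rng.random((n, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [chr(65 + i) for i in range(n)]
        tree = upgma(D, labels)
        np.testing.assert_allclose(
            tree.cophenetic_matrix(), _naive_upgma_cophenetic(D, labels),
            atol=1e-8,
        )

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(42)
        pts = rng.random((8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = upgma(D, [f"L{i}" for i in range(8)])
        Z = linkage(squareform(D, checks=False), method="average")
        np.testing.assert_allclose(
            np.sort(tree.merges[:, 2]), np.sort(Z[:, 2]), atol=1e-10
        )

    def test_duplicates_merge_first_at_zero(self):
        D = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        tree = upgma(D, ["A", "B", "C"])
        assert tree.merges[0, 2] == 0.0
        assert set(tree.merges[0, :2]) == {0, 1}

    def test_identical_lanes_star_at_zero(self):
        D = np.zeros((4, 4))
        tree = upgma(D, list("ABCD"))
        assert (tree.merges[:, 2] == 0).all()

    def test_deterministic_under_label_order(self):
        # symmetric ties: output depends only on labels, not input order
        D = np.array(
            [[0, 0.4, 0.4, 0.8],
             [0.4, 0, 0.8, 0.4],
             [0.4, 0.8, 0, 0.4],
             [0.8, 0.4, 0.4, 0]]
        )
        labels = list("ABCD")
        t1 = upgma(D, labels)
        perm = [3, 1, 0, 2]
        t2 = upgma(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            t1.cophenetic_matrix(),
            t2.cophenetic_matrix()[np.ix_(inv, inv)],
        )

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            upgma(np.array([[0, 1.0], [0.5, 0]]), ["A", "B"])


class TestCutAtSimilarity:
    def test_extremes(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(D, ["A", "B", "C"])
        assert cut_at_similarity(tree, 1.0) == [["A"], ["B"], ["C"]]
        assert cut_at_similarity(tree, 0.0) == [["A", "B", "C"]]

    def test_intermediate_level(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(D, ["A", "B", "C"])
        assert cut_at_similarity(tree, 0.7) == [["A", "B"], ["C"]]

    def test_recovers_simulated_populations(self):
        from musadiv.synthetic import simulate_structured_bands

        for seed in range(10):
            m, truth = simulate_structured_bands(
                n_pops=2,
                sizes=(6, 6),
                primers=[("P1", "RAPD", 300)],
                F=0.4,
                seed=seed,
            )
            labels, S = similarity_matrix(m)
            tree = upgma(1.0 - S, labels)
            root = tree.merges[-1, 2]
            groups = cut_at_similarity(tree, 1.0 - root + 1e-9)
            want = sorted(
                sorted(g for g in labels if truth.assignment[g] == pop)
                for pop in ("SP1", "SP2")
            )
            assert groups == want


class TestCopheneticCorrelation:
    def test_perfectly_ultrametric(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(D, ["A", "B", "C"])
        assert cophenetic_correlation(tree, D) == pytest.approx(1.0)

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(1)
        pts = rng.random((5, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = upgma(D, list("ABCDE"))
        iu = np.triu_indices(5, 1)
        expected = np.corrcoef(D[iu], tree.cophenetic_matrix()[iu])[0, 1]
        assert cophenetic_correlation(tree, D) == pytest.approx(expected)

    def test_constant_distances_rejected(self):
        D = np.ones((3, 3)) - np.eye(3)
        tree = upgma(D, ["A", "B", "C"])
        with pytest.raises(ValueError, match="constant"):
            cophenetic_correlation(tree, D)
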