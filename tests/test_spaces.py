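import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpsem.spaces import (
    ComponentScores,
    EmbeddingSpace,
    TaxonomyTree,
    cosine_kernel,
    dual_transform,
    kernel_pca,
    path_similarity_matrix,
    top_scoring_words,
)


def space_of(matrix, words=None):
    matrix = np.asarray(matrix, dtype=float)
    words = words or [f"w{i}" for i in range(matrix.shape[0])]
    return EmbeddingSpace(words, matrix)


class TestCosineKernel:
    @pytest.mark.parametrize(
        "vi,vj,expected",
        [
            ([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], 1.0),  # parallel rows
            ([1.0, 0.0], [0.0, 1.0], 0.0),  # orthogonal
            ([1.0, 1.0], [-1.0, -1.0], -1.0),  # antipodal
        ],
    )
    def test_pairwise_values(self, vi, vj, expected):
        k = cosine_kernel(space_of([vi, vj]))
        assert k.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert k.values[0, 0] == 1.0 and k.values[1, 1] == 1.0

    def test_zero_row_error_names_word(self):
        sp = space_of([[1.0, 0.0], [0.0, 0.0]], words=["good", "degenerate"])
        with pytest.raises(ValueError, match="degenerate"):
            cosine_kernel(sp)

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_row_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(5, 4)) + 0.1
        k1 = cosine_kernel(space_of(m))
        m2 = m.copy()
        m2[2] *= scale
        k2 = cosine_kernel(space_of(m2))
        np.testing.assert_allclose(k1.values, k2.values, atol=1e-10)


class TestDualTransform:
    def test_item_by_item_dimensionality(self):
        rng = np.random.default_rng(0)
        sp = space_of(rng.normal(size=(960, 300)))
        assert dual_transform(sp).values.shape == (960, 960)

    def test_orthonormal_rows_give_identity(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(6, 6)))
        sp = space_of(q[:, :4].T @ np.eye(6))  # 4 orthonormal rows in R^6
        np.testing.assert_allclose(dual_transform(sp).values, np.eye(4), atol=1e-10)

    def test_gram_matrix_is_psd(self):
        sp = space_of(np.random.default_rng(2).normal(size=(20, 7)))
        eigs = np.linalg.eigvalsh(dual_transform(sp).values)
        assert eigs.min() >= -1e-8


class TestPathSimilarity:
    def bfs_distance(self, newick, a, b):
        """Independent oracle: breadth-first shortest path on the tree graph."""
        import networkx as nx

        tree = TaxonomyTree.from_newick(newick)
        g = nx.Graph()
        for node in tree.root.traverse(include_self=True):
            for child in node.children:
                g.add_edge(id(node), id(child))
        tips = {t.name: id(t) for t in tree.root.tips()}
        return nx.shortest_path_length(g, tips[a], tips[b])

    @pytest.mark.parametrize(
        "pair,d",
        [(("cat", "dog"), 2), (("cat", "robin"), 3), (("dog", "robin"), 3)],
    )
    def test_explicit_tree_matches_bfs_oracle(self, pair, d):
        newick = "((cat,dog),robin);"
        assert self.bfs_distance(newick, *pair) == d
        tree = TaxonomyTree.from_newick(newick)
        sim = path_similarity_matrix(tree, ["cat", "dog", "robin"])
        i, j = [["cat", "dog", "robin"].index(w) for w in pair]
        assert sim.values[i, j] == pytest.approx(1.0 / (1.0 + d))

    def test_identical_leaf_similarity_is_one(self):
        tree = TaxonomyTree.from_newick("((cat,dog),robin);")
        sim = path_similarity_matrix(tree, ["cat", "dog", "robin"])
        np.testing.assert_array_equal(np.diag(sim.values), 1.0)

    def test_random_trees_match_bfs_oracle(self):
        import erpsem

        space, _ = erpsem.generate_embeddings(12, 6, 2, 4.0, seed=9)
        tree = erpsem.generate_taxonomy(space, fidelity=0.7, seed=9)
        sim = path_similarity_matrix(tree, space.words)
        newick = tree.to_newick()
        for i, j in [(0, 5), (3, 11), (2, 2), (7, 8)]:
            d = 0 if i == j else self.bfs_distance(newick, space.words[i], space.words[j])
            assert sim.values[i, j] == pytest.approx(1.0 / (1.0 + d))

    def test_values_in_unit_interval_and_one_iff_same_leaf(self):
        import erpsem

        space, _ = erpsem.generate_embeddings(20, 6, 2, 4.0, seed=3)
        tree = erpsem.generate_taxonomy(space, fidelity=1.0, seed=3)
        sim = path_similarity_matrix(tree, space.words)
        assert np.all(sim.values > 0) and np.all(sim.values <= 1)
        off = sim.values[~np.eye(20, dtype=bool)]
        assert np.all(off < 1)

    def test_missing_word_error(self):
        tree = TaxonomyTree.from_newick("((cat,dog),robin);")
        with pytest.raises(KeyError, match="wolf"):
            path_similarity_matrix(tree, ["cat", "wolf"])


class TestKernelPCA:
    def test_two_item_anticorrelated_kernel(self):
        # centered kernel unchanged; eigenvalues {2, 0}; scores +-1
        from erpsem.spaces import SimilarityMatrix

        kernel = SimilarityMatrix(["a", "b"], np.array([[1.0, -1.0], [-1.0, 1.0]]),
                                  kind="cosine")
        comp = kernel_pca(kernel, 2)
        np.testing.assert_allclose(comp.eigenvalues, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(comp.scores[:, 0], [1.0, -1.0], atol=1e-12)

    def test_identical_rows_give_zero_scores(self):
        sp = space_of(np.tile([1.0, 2.0, 3.0], (5, 1)))
        comp = kernel_pca(cosine_kernel(sp), 3)
        np.testing.assert_allclose(comp.scores, 0.0, atol=1e-8)

    def test_equals_linear_pca_on_unit_rows(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(20, 5))
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        comp = kernel_pca(cosine_kernel(space_of(m)), 4)
        # independent route: ordinary PCA scores of the row-centered matrix
        from sklearn.decomposition import PCA

        ref = PCA(n_components=4).fit_transform(m)
        for j in range(4):
            a, b = comp.scores[:, j], ref[:, j]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_columns_sum_to_zero_and_total_variance(self):
        sp = space_of(np.random.default_rng(5).normal(size=(30, 8)))
        kernel = cosine_kernel(sp)
        comp = kernel_pca(kernel, 30)
        np.testing.assert_allclose(comp.scores.sum(axis=0), 0.0, atol=1e-8)
        K = kernel.values
        Kc = K - K.mean(0) - K.mean(1)[:, None] + K.mean()
        assert comp.eigenvalues.sum() == pytest.approx(np.trace(Kc), abs=1e-8)

    def test_sign_convention_largest_entry_positive(self):
        sp = space_of(np.random.default_rng(6).normal(size=(15, 6)))
        comp = kernel_pca(cosine_kernel(sp), 5)
        for j in range(5):
            col = comp.scores[:, j]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_k_out_of_range(self):
        sp = space_of(np.random.default_rng(7).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            kernel_pca(cosine_kernel(sp), 6)


class TestTopScoringWords:
    def scores_of(self, values):
        values = np.asarray(values, dtype=float)
        words = [f"w{i+1}" for i in range(values.shape[0])]
        return ComponentScores(words, values, np.array([1.0]))

    def test_argmax_argmin(self):
        comp = self.scores_of([[3.0], [1.0], [-2.0]])
        pos, neg = top_scoring_words(comp, 0, m=1)
        assert pos == ["w1"] and neg == ["w3"]

    def test_disjoint_lists_on_spread_scores(self):
        rng = np.random.default_rng(8)
        comp = self.scores_of(rng.normal(size=(150, 1)))
        pos, neg = top_scoring_words(comp, 0, m=7)
        assert len(pos) == len(neg) == 7
        assert not set(pos) & set(neg)

    def test_full_m_lists_each_word_once(self):
        comp = self.scores_of(np.arange(9.0)[:, None] - 4.0)
        pos, neg = top_scoring_words(comp, 0, m=9)
        assert sorted(pos) == sorted(neg) == sorted(comp.words)

    def test_ties_break_by_word_order(self):
        comp = self.scores_of([[1.0], [1.0], [0.0]])
        pos, _ = top_scoring_words(comp, 0, m=2)
        assert pos == ["w1", "w2"]

    def test_component_out_of_range(self):
        comp = self.scores_of([[1.0], [2.0], [3.0]])
        with pytest.raises(IndexError):
            top_scoring_words(comp, 3, m=1)
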