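import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from embryomodes.cell_typing import (
    CellTypeAssignment,
    TypingConfig,
    assign_identities,
    consistency_score,
    find_informative_genes,
    hierarchical_typing,
    structured_cluster,
)
from embryomodes.io import CellRecord, ExpressionPosterior
from embryomodes.synthetic import make_topology, simulate_marker_posterior


class TestInformativeGenes:
    def test_bimodal_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        X = np.full((n, 5), 2.0) + 0.01 * rng.standard_normal((n, 5))
        X[:, 3] = labels * 3.0 + 0.05 * rng.standard_normal(n)
        ranked = find_informative_genes(X, labels)
        assert ranked[0][0] == 3

    def test_pure_noise_matches_permutation_null(self):
        """Scores on noise are distributed like scores with permuted labels."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 30))
        labels = np.repeat([0, 1, 2], 20)
        obs = [s for _, s in find_informative_genes(X, labels, top_k=30)]
        perm = [s for _, s in find_informative_genes(
            X, rng.permutation(labels), top_k=30)]
        from scipy.stats import mannwhitneyu
        assert mannwhitneyu(obs, perm).pvalue > 0.01

    def test_ranking_invariant_to_column_order(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 6))
        X[:, 2] += np.repeat([0, 4.0], 15)
        labels = np.repeat([0, 1], 15)
        r1 = find_informative_genes(X, labels)
        perm = [5, 4, 3, 2, 1, 0]
        r2 = find_informative_genes(X[:, perm], labels)
        mapped = sorted((perm[g], s) for g, s in r2)
        assert sorted(r1) == pytest.approx(mapped)

    def test_constant_matrix_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            out = find_informative_genes(np.ones((10, 3)), np.repeat([0, 1], 5))
        assert out == []


class TestStructuredCluster:
    def test_two_separated_clusters_recovered_balanced(self):
        rng = np.random.default_rng(3)
        rows, embryos, truth = [], [], []
        for e in range(2):
            for k in range(4):
                c = k % 2
                rows.append([4.0 * c, -4.0 * c] + list(0.05 * rng.standard_normal(2)))
                embryos.append(f"e{e}")
                truth.append(c)
        labels, info = structured_cluster(np.array(rows)[:, :2], embryos, 2, rng=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert not info["low_separation"]

    def test_per_embryo_balance_enforced(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((24, 3))
        embryos = np.repeat([f"e{i}" for i in range(3)], 8)
        labels, _ = structured_cluster(X, embryos, 4, rng=1)
        counts = {e: np.bincount(labels[embryos == e], minlength=4)
                  for e in np.unique(embryos)}
        ref = counts["e0"]
        for v in counts.values():
            np.testing.assert_array_equal(v, ref)

    def test_degenerate_input_flagged(self):
        X = np.ones((8, 2))
        labels, info = structured_cluster(X, ["e1"] * 4 + ["e2"] * 4, 2, rng=2)
        assert info["low_separation"]
        # split is arbitrary but balanced: same per-embryo counts everywhere
        c1 = np.bincount(labels[:4], minlength=2)
        c2 = np.bincount(labels[4:], minlength=2)
        np.testing.assert_array_equal(c1, c2)

    def test_incompatible_k_errors(self):
        with pytest.raises(ValueError, match="incompatible"):
            structured_cluster(np.ones((4, 1)), ["e1", "e1", "e2", "e2"], 3)


class TestConsistencyScore:
    def test_separated_clusters_deterministic_score_one(self):
        """eps = 0 and perfect separation: re-clustering is deterministic."""
        rng = np.random.default_rng(5)
        n_e = 4
        X, embryos = [], []
        for e in range(n_e):
            for k in range(4):
                X.append([6.0 * (k % 2)] + list(0.05 * rng.standard_normal(2)))
                embryos.append(f"e{e}")
        X = np.array(X)
        score, _ = consistency_score(X, np.zeros_like(X), embryos, 2,
                                     n_resamples=20, seed=0, n_null=5)
        assert score == pytest.approx(1.0)

    def test_separated_noisy_clusters_beat_null(self):
        rng = np.random.default_rng(15)
        X, embryos = [], []
        for e in range(4):
            for k in range(4):
                X.append([3.0 * (k % 2)] + list(0.3 * rng.standard_normal(2)))
                embryos.append(f"e{e}")
        X = np.array(X)
        eps = 0.3 * np.ones_like(X)
        score, null = consistency_score(X, eps, embryos, 2,
                                        n_resamples=20, seed=1, n_null=9)
        assert score > np.quantile(null, 0.95)

    def test_noise_score_within_null(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((24, 4))
        embryos = np.repeat([f"e{i}" for i in range(4)], 6)
        score, null = consistency_score(X, 0.1 * np.ones_like(X), embryos, 2,
                                        n_resamples=20, seed=1, n_null=19)
        assert null.min() - 0.5 < score < max(null.max() + 0.5, 1.0)

    def test_warns_on_few_resamples(self):
        X = np.random.default_rng(7).standard_normal((8, 2))
        with pytest.warns(UserWarning, match="n_resamples"):
            consistency_score(X, np.zeros_like(X), ["e1"] * 4 + ["e2"] * 4, 2,
                              n_resamples=5, n_null=2, seed=0)


class TestHierarchicalTyping:
    def test_planted_types_recovered(self, mirror16):
        post, truth = simulate_marker_posterior(mirror16, n_embryos=6, seed=11)
        cfg = TypingConfig(n_resamples=10, n_null=9, seed=0)
        asg = hierarchical_typing(post, cfg)
        pred = [asg.type_of[c.cell_id] for c in post.cells]
        true = [truth[c.cell_id] for c in post.cells]
        assert adjusted_rand_score(true, pred) == 1.0
        assert len(set(pred)) == 5

    def test_pure_noise_single_root(self, mirror16):
        post, _ = simulate_marker_posterior(mirror16, n_embryos=6, effect=0.0, seed=12)
        cfg = TypingConfig(n_resamples=10, n_null=9, seed=0)
        asg = hierarchical_typing(post, cfg)
        assert len(set(asg.type_of.values())) == 1
        assert not asg.tree.children

    def test_deterministic_at_fixed_seed(self, mirror16):
        post, _ = simulate_marker_posterior(mirror16, n_embryos=4, seed=13)
        cfg = TypingConfig(n_resamples=8, n_null=5, seed=3)
        a1 = hierarchical_typing(post, cfg)
        a2 = hierarchical_typing(post, cfg)
        assert a1.type_of == a2.type_of


class TestAssignIdentities:
    @staticmethod
    def make_assignment():
        # 2 leaves x 3 cells, gene m1 marks leaf T0, gene m2 marks leaf T1
        cells = [CellRecord(f"c{i}", "e0", 16) for i in range(6)]
        X = np.zeros((6, 3))
        X[:3, 0] = 5.0
        X[3:, 1] = 5.0
        post = ExpressionPosterior(X, np.zeros_like(X), ["m1", "m2", "junk"], cells)
        from embryomodes.cell_typing import ClusterNode
        root = ClusterNode(0, [f"c{i}" for i in range(6)])
        root.children = [ClusterNode(1, ["c0", "c1", "c2"]),
                         ClusterNode(2, ["c3", "c4", "c5"])]
        type_of = {f"c{i}": ("T0" if i < 3 else "T1") for i in range(6)}
        return CellTypeAssignment(type_of, root), post

    def test_markers_resolve_identities(self):
        asg, post = self.make_assignment()
        named = assign_identities(asg, post, {"a5.3-a5.4": ["m1"], "B5.1": ["m2"]})
        assert named.type_of["c0"] == "a5.3-a5.4"
        assert named.type_of["c3"] == "B5.1"

    def test_empty_marker_table_unassigned(self):
        asg, post = self.make_assignment()
        named = assign_identities(asg, post, {})
        assert set(named.type_of.values()) == {"unassigned"}

    def test_conflicting_claims_error(self):
        asg, post = self.make_assignment()
        # both leaves' best identity is the junk-marked one... construct a
        # table where both leaves rank the same identity top
        post.X[:, 2] = 1.0  # constant -> equal ranks for both leaves
        with pytest.raises(ValueError, match="claimed"):
            assign_identities(asg, post, {"only": ["m1", "m2"]})


class TestAdjustedRand:
    def test_matches_sklearn_oracle(self):
        from embryomodes.cell_typing import adjusted_rand
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            assert adjusted_rand(a, b) == pytest.approx(adjusted_rand_score(a, b))
        assert adjusted_rand([0, 0, 1], [1, 1, 0]) == 1.0
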