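import numpy as np
import pytest

from embryomodes.variance import (
    center_genes,
    decompose_maternal,
    decompose_zygotic,
    fit_temporal_projection,
    project_pcs,
    subtract_group_means,
    svd_rank_selection,
)


class TestCenterGenes:
    def test_column_arithmetic(self):
        np.testing.assert_allclose(center_genes(np.array([[1.0], [3.0]])),
                                   [[-1.0], [1.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 4))
        Y = center_genes(X)
        np.testing.assert_allclose(center_genes(Y), Y)


class TestGroupMeans:
    def test_single_group_equals_centering(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 3))
        Z, _ = subtract_group_means(X, ["g"] * 5)
        np.testing.assert_allclose(Z, center_genes(X))

    def test_group_means_zeroed(self):
        X = np.array([[2.0], [2.0], [-2.0], [-2.0]])
        Z, means = subtract_group_means(X, ["a", "a", "b", "b"])
        np.testing.assert_allclose(Z, 0.0)
        np.testing.assert_allclose(means["a"], [2.0])

    def test_nested_subtraction_leaves_both_means_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 3))
        mothers = ["m1"] * 6 + ["m2"] * 6
        embryos = [f"e{i // 3}" for i in range(12)]
        Z, _ = subtract_group_means(X, mothers)
        Z, _ = subtract_group_means(Z, embryos)
        for e in set(embryos):
            rows = [i for i, x in enumerate(embryos) if x == e]
            np.testing.assert_allclose(Z[rows].mean(axis=0), 0.0, atol=1e-10)
        for m in set(mothers):
            rows = [i for i, x in enumerate(mothers) if x == m]
            np.testing.assert_allclose(Z[rows].mean(axis=0), 0.0, atol=1e-10)

    def test_singleton_group_warns(self):
        with pytest.warns(UserWarning, match="single cell"):
            subtract_group_means(np.ones((2, 1)), ["a", "b"])


class TestTemporalProjection:
    def planted(self, noise_sd, seed=0, n_g=30):
        rng = np.random.default_rng(seed)
        embryos = np.repeat([f"e{i}" for i in range(3)], 4)
        types = np.tile(["tA", "tA", "tB", "tB"], 3)
        tau_true = np.array([-1.0, 0.0, 1.0])
        alpha = {"tA": rng.standard_normal(n_g), "tB": rng.standard_normal(n_g)}
        A = np.stack([alpha[t] for t in types])
        norm = np.linalg.norm(np.stack([alpha["tA"], alpha["tB"]]))
        Z = np.repeat(tau_true, 4)[:, None] * A + noise_sd * rng.standard_normal((12, n_g))
        return Z, embryos, types, tau_true, norm

    def test_planted_recovery_noise_free(self):
        Z, embryos, types, tau_true, _ = self.planted(0.0)
        tau, alpha, resid, info = fit_temporal_projection(Z, embryos, types)
        assert np.mean(resid**2) < 1e-18
        r = np.corrcoef(tau, tau_true)[0, 1]
        assert abs(r) > 0.9999

    def test_planted_recovery_with_noise(self):
        Z, embryos, types, tau_true, _ = self.planted(0.1)
        tau, _, _, _ = fit_temporal_projection(Z, embryos, types)
        assert abs(np.corrcoef(tau, tau_true)[0, 1]) > 0.99

    def test_zero_matrix(self):
        Z = np.zeros((4, 3))
        tau, alpha, resid, _ = fit_temporal_projection(
            Z, ["e1", "e1", "e2", "e2"], ["t", "t", "t", "t"])
        np.testing.assert_allclose(tau, 0.0)
        np.testing.assert_allclose(resid, 0.0)

    def test_never_increases_variance(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((8, 10))
        _, _, resid, _ = fit_temporal_projection(
            Z, np.repeat(["e1", "e2"], 4), np.tile(["a", "b"], 4))
        assert np.mean(resid**2) <= np.mean(Z**2) + 1e-12

    def test_gauge_conventions(self):
        Z, embryos, types, _, _ = self.planted(0.05, seed=3)
        tau, alpha, _, _ = fit_temporal_projection(Z, embryos, types)
        assert abs(tau.sum()) < 1e-8
        assert np.linalg.norm(alpha) == pytest.approx(1.0)
        assert alpha.flat[np.argmax(np.abs(alpha))] > 0


class TestRankSelection:
    def test_null_preserves_column_multisets(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((10, 4))
        # permuting rows per column preserves each column's sorted values
        perm = np.argsort(rng.random(Z.shape), axis=0)
        Znull = np.take_along_axis(Z, perm, axis=0)
        np.testing.assert_allclose(np.sort(Znull, axis=0), np.sort(Z, axis=0))

    def test_iid_noise_keeps_nothing(self):
        kept = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((30, 20))
            _, _, n_keep = svd_rank_selection(Z, n_perm=30, seed=seed + 100)
            kept.append(n_keep)
        assert np.mean(np.array(kept) == 0) >= 0.9

    def test_planted_spike_always_kept(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            u = rng.standard_normal((30, 1))
            v = rng.standard_normal((1, 20))
            Z = 10 * u @ v / np.sqrt(30 * 20) * np.sqrt(600) + rng.standard_normal((30, 20))
            _, _, n_keep = svd_rank_selection(Z, n_perm=30, seed=seed)
            assert n_keep >= 1

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            svd_rank_selection(np.eye(4), n_perm=5, seed=0)


class TestProjectPCs:
    def test_exact_rank_one_reconstruction(self):
        u = np.arange(1, 7, dtype=float)[:, None]
        v = np.array([[2.0, -1.0, 0.5]])
        Z = u @ v
        pcs, x = project_pcs(Z, 1)
        np.testing.assert_allclose(x @ pcs, Z, atol=1e-10)

    def test_projection_contracts_norm_and_orthonormal(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((9, 6))
        pcs, x = project_pcs(Z, 3)
        assert np.linalg.norm(x) <= np.linalg.norm(Z) + 1e-12
        np.testing.assert_allclose(pcs @ pcs.T, np.eye(3), atol=1e-10)

    def test_overlarge_n_keep_capped(self):
        with pytest.warns(UserWarning, match="capping"):
            pcs, _ = project_pcs(np.eye(3), 5)
        assert pcs.shape[0] == 3


class TestChains:
    def test_zygotic_chain_monotone_variance(self):
        rng = np.random.default_rng(8)
        n = 24
        X = rng.standard_normal((n, 10)) + 3.0
        types = np.tile(["a", "b", "c"], n // 3)
        embryos = np.repeat([f"e{i}" for i in range(4)], 6)
        Y = center_genes(X)
        Z, _ = subtract_group_means(Y, types)
        _, _, resid, _ = fit_temporal_projection(Z, embryos, types)
        v = [np.mean(X**2), np.mean(Y**2), np.mean(Z**2), np.mean(resid**2)]
        assert all(v[i + 1] <= v[i] + 1e-12 for i in range(3))

    def test_maternal_chain_residual_means_zero(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 5))
        mothers = np.repeat(["m1", "m2"], 6)
        embryos = np.repeat(["e1", "e2", "e3", "e4"], 3)
        dec = decompose_maternal(X, mothers, embryos, n_perm=20, seed=0)
        for e in np.unique(embryos):
            np.testing.assert_allclose(dec.Z[embryos == e].mean(axis=0), 0, atol=1e-10)

    def test_zygotic_chain_planted_recovery(self):
        """Planted type means and time recovered within 1% at low noise."""
        rng = np.random.default_rng(10)
        n_g, n_e = 40, 6
        types_list = ["a", "b"]
        mu = {t: rng.standard_normal(n_g) for t in types_list}
        alpha = {t: rng.standard_normal(n_g) for t in types_list}
        norm = np.linalg.norm(np.stack(list(alpha.values())))
        alpha = {t: a / norm for t, a in alpha.items()}
        tau = rng.standard_normal(n_e)
        tau -= tau.mean()
        rows, types, embryos = [], [], []
        for e in range(n_e):
            for t in types_list:
                for _ in range(4):
                    rows.append(mu[t] + tau[e] * alpha[t]
                                + 0.001 * rng.standard_normal(n_g))
                    types.append(t)
                    embryos.append(f"e{e}")
        X = np.array(rows)
        dec = decompose_zygotic(X, types, embryos, n_perm=20, seed=1, n_keep=1)
        r = np.corrcoef(dec.tau, tau)[0, 1]
        assert abs(r) > 0.99
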