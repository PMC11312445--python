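import numpy as np
import pytest

from embryomodes.covariance import (
    delta_statistic,
    inter_type_cov,
    intra_type_cov,
    resample_covariances,
    shuffle_test,
)


class TestInterTypeCov:
    def test_hand_arithmetic_one_embryo(self):
        """t = {x=1, x=-1}, t' = {x=2}: (1*2 + (-1)*2)/2 = 0."""
        x = np.array([[1.0], [-1.0], [2.0]])
        gamma = inter_type_cov(x, ["t", "t", "u"], ["e"] * 3)
        assert gamma[("t", "u")][0, 0] == pytest.approx(0.0)
        # and the same-type entry excludes the diagonal: 2 * (1 * -1) / 2
        assert gamma[("t", "t")][0, 0] == pytest.approx(-1.0)

    def test_zero_input_gives_zero(self):
        gamma = inter_type_cov(np.zeros((4, 2)), ["a", "a", "b", "b"], ["e"] * 4)
        np.testing.assert_allclose(gamma[("a", "b")], 0.0)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((12, 3))
        types = np.tile(["a", "b", "c"], 4)
        embryos = np.repeat(["e1", "e2"], 6)
        gamma = inter_type_cov(x, types, embryos)
        for ta in "abc":
            for tb in "abc":
                np.testing.assert_allclose(gamma[(ta, tb)], gamma[(tb, ta)].T)

    def test_missing_pair_flagged_nan(self):
        # types a and b never share an embryo
        x = np.ones((2, 1))
        gamma = inter_type_cov(x, ["a", "b"], ["e1", "e2"])
        assert np.isnan(gamma[("a", "b")]).all()


class TestIntraTypeCov:
    def test_single_cell_outer_product(self):
        C = intra_type_cov(np.array([[1.0, 2.0]]), ["t"], ["e"])
        np.testing.assert_allclose(C["t"], [[1, 2], [2, 4]])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 3))
        C = intra_type_cov(x, ["t"] * 20, ["e1"] * 10 + ["e2"] * 10)["t"]
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C)[0] >= -1e-12

    def test_empty_type_errors(self):
        with pytest.raises(ValueError):
            intra_type_cov(np.ones((1, 1)), ["a"], ["e"], types=["a", "b"])


class TestResampleCovariances:
    @staticmethod
    def _draw_factory(x, types, embryos, eps=0.0):
        def draw(rng):
            noisy = x + eps * rng.standard_normal(x.shape)
            return noisy, types, embryos
        return draw

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 2))
        types = np.tile(["a", "b"], 6)
        embryos = np.repeat(["e1", "e2", "e3"], 4)
        draw = self._draw_factory(x, types, embryos, eps=0.1)
        c1 = resample_covariances(draw, 3, 2, seed=5)
        c2 = resample_covariances(draw, 3, 2, seed=5)
        np.testing.assert_allclose(c1.intra["a"], c2.intra["a"])

    def test_draw_spread_shrinks_with_embryos(self):
        rng = np.random.default_rng(3)
        spreads = []
        for n_e in (4, 32):
            x = rng.standard_normal((4 * n_e, 1))
            types = np.tile(["a", "b"], 2 * n_e)
            embryos = np.repeat([f"e{i}" for i in range(n_e)], 4)
            cov = resample_covariances(self._draw_factory(x, types, embryos),
                                       4, 10, seed=7)
            vals = [d[1][("a", "b")][0, 0] for d in cov.draws]
            spreads.append(np.std(vals))
        assert spreads[1] < spreads[0]

    def test_percentile_intervals_bracket_point(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((20, 1))
        types = ["a", "b"] * 10
        embryos = np.repeat(["e1", "e2", "e3", "e4"], 5)
        cov = resample_covariances(self._draw_factory(x, types, embryos), 5, 5, seed=1)
        lo, _ = cov.percentile(1)
        hi, _ = cov.percentile(99)
        assert lo["a"][0, 0] <= cov.intra["a"][0, 0] <= hi["a"][0, 0]


class TestShuffleTest:
    def test_delta_arithmetic(self):
        assert delta_statistic(np.array([2.0]), np.array([1.0]),
                               np.array([0.5])) == pytest.approx(4.0)

    def test_delta_zero_when_gamma_equals_mean(self):
        assert delta_statistic(np.ones(3), np.ones(3), np.ones(3)) == 0.0

    @pytest.mark.parametrize("mode", ["within", "across"])
    def test_result_invariants(self, mode):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((24, 2))
        types = np.tile(["a", "b", "c"], 8)
        embryos = np.repeat(["e1", "e2", "e3", "e4"], 6)
        res = shuffle_test(x, types, embryos, mode, n_shuffles=30, seed=2)
        assert res.delta_observed >= 0
        assert 0 < res.p_value <= 1
        assert len(res.delta_null) == 30

    def test_across_shuffle_preserves_per_embryo_type_counts(self):
        from embryomodes.covariance import _encode, _shuffled_rows
        rng = np.random.default_rng(6)
        types = np.array(["a", "a", "b", "a", "a", "b"])
        embryos = np.array(["e1"] * 3 + ["e2"] * 3)
        t_idx, _ = _encode(types)
        e_idx, _ = _encode(embryos)
        perm = _shuffled_rows(rng, "across", t_idx, e_idx)
        # the type occupying each (embryo, slot) is unchanged
        np.testing.assert_array_equal(t_idx[perm], t_idx)

    def test_within_shuffle_preserves_embryo_row_multisets(self):
        from embryomodes.covariance import _encode, _shuffled_rows
        rng = np.random.default_rng(7)
        types = np.array(["a", "b", "c", "a", "b", "c"])
        embryos = np.array(["e1"] * 3 + ["e2"] * 3)
        t_idx, _ = _encode(types)
        e_idx, _ = _encode(embryos)
        perm = _shuffled_rows(rng, "within", t_idx, e_idx)
        np.testing.assert_array_equal(e_idx[perm], e_idx)
        assert sorted(perm[:3]) == [0, 1, 2] and sorted(perm[3:]) == [3, 4, 5]

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            shuffle_test(np.ones((4, 1)), ["a"] * 4, ["e1", "e1", "e2", "e2"],
                         "sideways", n_shuffles=5)

    def test_coupled_data_detected(self):
        """Strong within-embryo coupling gives the smallest possible p."""
        from embryomodes.synthetic import make_topology, neighbor_model, sample_embryos
        model = neighbor_model(make_topology("mirror16"))
        ds = sample_embryos(model, 14, seed=3)
        res = shuffle_test(ds.posterior.X, ds.type_labels, ds.embryo_labels,
                           "across", n_shuffles=100, seed=4)
        assert res.p_value == pytest.approx(1 / 101)
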