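import numpy as np
import pytest

from embryomodes.io import EmbryoGraph
from embryomodes.maxent import (
    ConstraintSpec,
    build_J,
    build_terms,
    embryo_wide_spec,
    fit_maxent,
    fit_quality,
    make_model,
    mode_decomposition,
    neighbor_spec,
    predict_type_covariances,
    rotation_baseline,
    sister_spec,
    state_dimension,
    targets_from_model,
)
from embryomodes.synthetic import make_topology, planted_sparse_model


def two_cell_graph():
    return EmbryoGraph(
        ["p", "q"], {"p": "tp", "q": "tq"},
        np.array([[0, 1], [1, 0]], dtype=bool),
        {}, {"p": "p", "q": "q"},
    )


class TestBuildJ:
    def test_identity_couplings_give_identity(self, mirror16):
        M = {t: np.eye(3) for t in mirror16.types}
        J = build_J(M, {}, {}, ConstraintSpec(), mirror16, 3)
        np.testing.assert_allclose(J, np.eye(48))

    def test_two_cell_symmetric_coupling(self):
        g = two_cell_graph()
        spec = ConstraintSpec(sym_terms=[("edge", np.array([[0, 1], [1, 0]]))])
        J = build_J({"tp": np.eye(1), "tq": np.eye(1)},
                    {"edge": np.array([[0.5]])}, {}, spec, g, 1)
        np.testing.assert_allclose(J, [[1, 0.5], [0.5, 1]])

    def test_directed_coupling_halved_and_one_sided(self):
        """Omega_12 = 1 with U upper-triangular: J couples (cell1, PC1) to
        (cell2, PC2) at u/2 and leaves (cell1, PC2)-(cell2, PC1) at zero."""
        g = two_cell_graph()
        u = 0.4
        spec = ConstraintSpec(dir_terms=[("d", np.array([[0, 1], [0, 0]]))])
        U = {"d": np.array([[0.0, u], [0.0, 0.0]])}
        J = build_J({"tp": np.eye(2), "tq": np.eye(2)}, {}, U, spec, g, 2)
        assert J[0, 3] == pytest.approx(u / 2)   # (cell1, PC1) x (cell2, PC2)
        assert J[1, 2] == 0.0                    # (cell1, PC2) x (cell2, PC1)
        np.testing.assert_allclose(J, J.T)

    def test_non_pd_rejected_with_eigenvalue(self):
        g = two_cell_graph()
        spec = ConstraintSpec(sym_terms=[("edge", np.array([[0, 1], [1, 0]]))])
        with pytest.raises(ValueError, match="eigenvalue"):
            build_J({"tp": np.eye(1), "tq": np.eye(1)},
                    {"edge": np.array([[2.0]])}, {}, spec, g, 1)

    def test_state_dimension(self):
        assert state_dimension(make_topology("mirror32"), 5) == 160


class TestPredictTypeCovariances:
    def test_identity_J(self, mirror16):
        M = {t: np.eye(2) for t in mirror16.types}
        model = make_model(ConstraintSpec(), mirror16, 2, M)
        intra, inter = predict_type_covariances(model)
        for t in mirror16.types:
            np.testing.assert_allclose(intra[t], np.eye(2))
        for (ta, tb), v in inter.items():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_two_cell_inversion_oracle(self):
        """J = [[1, .5], [.5, 1]] gives gamma~ = -0.5/0.75 = -2/3."""
        g = two_cell_graph()
        spec = ConstraintSpec(sym_terms=[("edge", np.array([[0, 1], [1, 0]]))])
        model = make_model(spec, g, 1, {"tp": np.eye(1), "tq": np.eye(1)},
                           {"edge": np.array([[0.5]])})
        intra, inter = predict_type_covariances(model)
        assert inter[("tp", "tq")][0, 0] == pytest.approx(-2 / 3)
        assert intra["tp"][0, 0] == pytest.approx(4 / 3)

    def test_symmetry_equivalent_cells_share_diagonal_blocks(self, mirror16):
        from embryomodes.synthetic import neighbor_model
        model = neighbor_model(mirror16)
        Sigma = model.Sigma
        # mirror partners are related by a J-preserving permutation
        mi = mirror16.mirror_index()
        d = model.n_pc
        for p in range(mirror16.n_cells):
            q = mi[p]
            np.testing.assert_allclose(Sigma[d * p:d * p + d, d * p:d * p + d],
                                       Sigma[d * q:d * q + d, d * q:d * q + d],
                                       atol=1e-10)


class TestFitMaxent:
    def test_single_cell_closed_form(self):
        """One type, no interactions: M = C^-1 to 1e-10."""
        g = EmbryoGraph(["p"], {"p": "t"}, np.zeros((1, 1), dtype=bool),
                        {}, {"p": "p"})
        from embryomodes.covariance import CovarianceSet
        C = np.array([[2.0, 0.3], [0.3, 1.0]])
        cov = CovarianceSet(["t"], {"t": C}, {("t", "t"): np.full((2, 2), np.nan)})
        model, report = fit_maxent(cov, ConstraintSpec(), g)
        np.testing.assert_allclose(model.M["t"], np.linalg.inv(C), atol=1e-10)
        assert report.converged

    def test_self_consistency_parameter_recovery(self, mirror16):
        """Statistics of a known model, same spec: parameters recovered."""
        true = planted_sparse_model(mirror16, n_pc=2, seed=3)
        terms = build_terms(true.spec, mirror16, 2)
        targets = targets_from_model(terms, true.J)
        model, report = fit_maxent(None, true.spec, mirror16, n_pc=2, targets=targets)
        for group, truth in (("M", true.M), ("S", true.S), ("U", true.U)):
            fitted = getattr(model, group)
            for k, v in truth.items():
                denom = max(np.max(np.abs(v)), 1e-12)
                assert np.max(np.abs(fitted[k] - v)) / denom < 1e-4

    def test_infeasible_intra_rejected(self, mirror16):
        from embryomodes.covariance import CovarianceSet
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # negative eigenvalue
        intra = {t: bad.copy() for t in mirror16.types}
        inter = {(a, b): np.zeros((2, 2)) for a in mirror16.types for b in mirror16.types}
        cov = CovarianceSet(mirror16.types, intra, inter)
        with pytest.raises(ValueError, match="positive"):
            fit_maxent(cov, neighbor_spec(mirror16), mirror16)


class TestFitQuality:
    def test_perfect_and_zero_prediction(self):
        emp_i = {"t": np.array([[1.0]])}
        emp_g = {("t", "u"): np.array([[2.0]]), ("u", "t"): np.array([[2.0]]),
                 ("u", "u"): np.array([[0.0]]), ("t", "t"): np.array([[0.0]])}
        assert fit_quality(emp_i, emp_g, emp_i, emp_g) == pytest.approx(1.0)
        zero_i = {"t": np.zeros((1, 1))}
        zero_g = {k: np.zeros((1, 1)) for k in emp_g}
        assert fit_quality(emp_i, emp_g, zero_i, zero_g) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        """C = (1, 2), C~ = (1, 1): eta = 1 - 1/5 = 0.8."""
        emp_i = {"t": np.array([[1.0]]), "u": np.array([[2.0]])}
        pred_i = {"t": np.array([[1.0]]), "u": np.array([[1.0]])}
        emp_g = {}
        assert fit_quality(emp_i, emp_g, pred_i, emp_g) == pytest.approx(0.8)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        emp_i = {"t": rng.standard_normal((2, 2))}
        pred_i = {"t": rng.standard_normal((2, 2))}
        e1 = fit_quality(emp_i, {}, pred_i, {})
        e2 = fit_quality({"t": 7 * emp_i["t"]}, {}, {"t": 7 * pred_i["t"]}, {})
        assert e1 == pytest.approx(e2)

    def test_all_zero_empirical_errors(self):
        with pytest.raises(ValueError, match="eta"):
            fit_quality({"t": np.zeros((1, 1))}, {}, {"t": np.ones((1, 1))}, {})


class TestSisterZeroStructure:
    def test_non_sister_inter_type_covariances_exactly_zero(self, mirror16):
        """Sister-only coupling: J block-diagonal over sister pairs, so the
        model predicts zero covariance for every non-sister type pair."""
        spec = sister_spec(mirror16)
        M = {t: np.eye(2) for t in mirror16.types}
        model = make_model(spec, mirror16, 2, M,
                           {"sister": -0.4 * np.eye(2)})
        intra, inter = predict_type_covariances(model)
        sisters = mirror16.sister
        type_of = mirror16.type_of
        sister_type_pairs = {frozenset((type_of[p], type_of[q]))
                             for p, q in sisters.items()}
        nonzero = {k for k, v in inter.items()
                   if not np.isnan(v).any() and np.max(np.abs(v)) > 1e-12}
        for ta, tb in nonzero:
            assert frozenset((ta, tb)) in sister_type_pairs


class TestModes:
    def test_diagonal_covariance_modes(self):
        J = np.diag([1 / 3.0, 1.0])
        modes = mode_decomposition(J)
        np.testing.assert_allclose(modes.eigenvalues, [3.0, 1.0])
        np.testing.assert_allclose(modes.variance_fractions, [0.75, 0.25])
        np.testing.assert_allclose(np.abs(modes.modes), np.eye(2), atol=1e-12)

    def test_trace_identity_and_orthonormality(self, mirror8):
        from embryomodes.synthetic import neighbor_model
        model = neighbor_model(mirror8)
        modes = mode_decomposition(model)
        np.testing.assert_allclose(modes.eigenvalues.sum(),
                                   np.trace(model.Sigma), rtol=1e-10)
        np.testing.assert_allclose(modes.modes.T @ modes.modes,
                                   np.eye(len(modes.eigenvalues)), atol=1e-10)

    def test_eigenvalues_descending_and_sign_convention(self, mirror8):
        from embryomodes.synthetic import neighbor_model
        modes = mode_decomposition(neighbor_model(mirror8))
        assert (np.diff(modes.eigenvalues) <= 1e-12).all()
        for b in range(modes.modes.shape[1]):
            col = modes.modes[:, b]
            assert col[np.argmax(np.abs(col))] > 0


class TestRotationBaseline:
    def test_identity_rotation_recovers_model_fraction(self):
        J = np.diag(1.0 / np.array([4.0, 2.0, 1.0, 0.5]))
        modes = mode_decomposition(J)
        # with R = I the fraction is the model's own top-k fraction; random
        # rotations of an isotropic model give exactly k/D instead
        frac_model = modes.variance_fractions[:2].sum()
        Phi = modes.modes[:, :2]
        Sigma = np.linalg.inv(J)
        f = np.einsum("db,de,eb->", Phi, Sigma, Phi) / np.trace(Sigma)
        assert f == pytest.approx(frac_model)

    def test_isotropic_mean_is_k_over_D(self):
        D, k = 10, 2
        J = np.eye(D)
        modes = mode_decomposition(J)
        fr = rotation_baseline(J, modes, k, n_rotations=200, seed=0)
        assert np.all((fr >= 0) & (fr <= 1))
        assert fr.mean() == pytest.approx(k / D, abs=1e-12)

    def test_anisotropic_mean_near_k_over_D(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((8, 8))
        J = A @ A.T + 8 * np.eye(8)
        modes = mode_decomposition(J)
        fr = rotation_baseline(J, modes, 3, n_rotations=400, seed=2)
        assert fr.mean() == pytest.approx(3 / 8, abs=0.05)


class TestMonteCarloAgreement:
    def test_predictions_match_sampling(self, mirror8):
        """Predicted type covariances agree with draws from N(0, J^-1)."""
        from embryomodes.synthetic import neighbor_model, sample_embryos
        model = neighbor_model(mirror8)
        intra, inter = predict_type_covariances(model)
        n = 20_000
        ds = sample_embryos(model, n, seed=9)
        from embryomodes.covariance import inter_type_cov, intra_type_cov
        emp_i = intra_type_cov(ds.posterior.X, ds.type_labels, ds.embryo_labels)
        emp_g = inter_type_cov(ds.posterior.X, ds.type_labels, ds.embryo_labels)
        se = 4.0 / np.sqrt(n)
        for t, v in intra.items():
            assert np.max(np.abs(emp_i[t] - v)) < 4 * se * np.max(np.abs(v) + 1)
        for k, v in inter.items():
            if not np.isnan(v).any():
                assert np.max(np.abs(emp_g[k] - v)) < 4 * se * np.max(np.abs(v) + 1)
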