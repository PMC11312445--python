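import numpy as np
import pytest

from embryomodes.maxent import build_terms, fit_maxent, targets_from_model
from embryomodes.sparse import (
    RegularizationConfig,
    candidate_terms,
    fit_regularized,
    forward_select,
    schulze_aggregate,
    stability_ranking,
)
from embryomodes.synthetic import make_topology, planted_sparse_model


class TestCandidateTerms:
    def test_toy4_enumeration(self, toy4):
        """3 contacts, 2 mirror pairs: the two side edges bundle into one
        specific term, the cross-midline edge into another."""
        spec = candidate_terms(toy4)
        assert [l for l, _ in spec.sym_terms] == ["embryo-wide", "neighbor", "sister"]
        assert len(spec.dir_terms) == 2

    def test_global_terms_always_present(self, mirror16):
        labels = candidate_terms(mirror16).labels
        assert {"embryo-wide", "neighbor", "sister"} <= set(labels)

    def test_specific_terms_mirror_closed(self, mirror16):
        mi = mirror16.mirror_index()
        for label, om in candidate_terms(mirror16).dir_terms:
            ps, qs = np.nonzero(om)
            pairs = set(zip(ps.tolist(), qs.tolist()))
            mirrored = {(int(mi[p]), int(mi[q])) for p, q in pairs}
            assert pairs == mirrored

    def test_specific_count_matches_contact_bundles(self, mirror16):
        # 7 side edges per side pair up L/R -> 7 bundles; 8 mirror edges are
        # self-bundles -> 8 more
        assert len(candidate_terms(mirror16).dir_terms) == 15


class TestFitRegularized:
    def test_zero_lambda_matches_unregularized(self, mirror16):
        true = planted_sparse_model(mirror16, n_pc=2, seed=3)
        terms = build_terms(true.spec, mirror16, 2)
        targets = targets_from_model(terms, true.J)
        theta_l1 = fit_regularized(targets, terms, lam=0.0)
        model, _ = fit_maxent(None, true.spec, mirror16, n_pc=2, targets=targets)
        from embryomodes.maxent import _params_to_theta
        theta_newton = _params_to_theta(terms, model.M, model.S, model.U)
        assert np.max(np.abs(theta_l1 - theta_newton)) < 1e-6

    def test_huge_lambda_zeroes_all_couplings(self, mirror16):
        true = planted_sparse_model(mirror16, n_pc=2, seed=3)
        terms = build_terms(true.spec, mirror16, 2)
        targets = targets_from_model(terms, true.J)
        theta = fit_regularized(targets, terms, lam=1e3 * np.max(np.abs(targets)))
        assert np.all(theta[terms.penalized] == 0.0)
        assert np.any(theta[~terms.penalized] != 0.0)

    def test_planted_support_recovered_from_exact_statistics(self):
        """On exact targets the L1 path keeps planted terms, drops the rest."""
        g = make_topology("mirror32")
        true = planted_sparse_model(g, n_pc=2, seed=1)
        cand = candidate_terms(g)
        terms = build_terms(cand, g, 2)
        targets = targets_from_model(terms, true.J)
        theta = fit_regularized(targets, terms, lam=0.05, tol=1e-5, max_iter=5000)
        from embryomodes.maxent import _theta_to_params
        _, S, U = _theta_to_params(terms, theta)
        nonzero = {k for k, v in {**S, **U}.items() if np.linalg.norm(v) > 1e-3}
        assert set(true.spec.labels) <= nonzero
        assert len(nonzero) <= len(true.spec.labels) + 2

    def test_solution_path_sparsity_shrinks(self, mirror16):
        """Stronger shrinkage yields (weakly) sparser endpoints.

        Exact monotonicity of the support in lambda does not hold for this
        candidate family -- the neighbor adjacency equals the sum of all
        specific bundles, so shrinking a global coupling can activate
        specific ones -- but the strongest penalty must give the sparsest
        fit and the weakest the densest.
        """
        g = make_topology("mirror32")
        true = planted_sparse_model(g, n_pc=2, seed=2)
        cand = candidate_terms(g)
        terms = build_terms(cand, g, 2)
        targets = targets_from_model(terms, true.J)
        thresh = RegularizationConfig().nonzero_threshold
        counts = []
        for lam in (0.02, 0.1, 0.5, 2.5):
            theta = fit_regularized(targets, terms, lam, tol=1e-5, max_iter=5000)
            counts.append(int(np.sum(np.abs(theta[terms.penalized]) > thresh)))
        assert counts[-1] == min(counts)
        assert max(counts) <= counts[0] + max(2, counts[0] // 4)


class TestStabilityRanking:
    def test_consistently_large_term_first_zero_term_last(self):
        draws = [{"big": 1.0 + 0.1 * i, "small": 0.05, "never": 0.0}
                 for i in range(5)]
        order, scores = stability_ranking(draws, nonzero_threshold=1e-4)
        assert order[0] == "big"
        assert order[-1] == "never"
        assert scores["never"] == 0.0

    def test_tie_broken_lexicographically(self):
        draws = [{"b": 1.0, "a": 1.0} for _ in range(3)]
        order, _ = stability_ranking(draws, nonzero_threshold=1e-4)
        assert order == ["a", "b"]

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            stability_ranking([{"a": 1.0}], 1e-4)


class TestSchulze:
    def test_identical_ballots(self):
        assert schulze_aggregate([["x", "y", "z"]] * 4) == ["x", "y", "z"]

    def test_single_ballot(self):
        assert schulze_aggregate([["q", "p", "r"]]) == ["q", "p", "r"]

    def test_three_candidate_majority(self):
        """A beats B 2-1, B beats C 3-0, A beats C 2-1 -> A > B > C."""
        ballots = [["A", "B", "C"], ["A", "B", "C"], ["B", "C", "A"]]
        assert schulze_aggregate(ballots) == ["A", "B", "C"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            schulze_aggregate([])


class TestForwardSelect:
    def test_planted_model_selected_and_eta_satisfied(self, mirror16):
        """Exact statistics from a planted model: forward selection reaches
        the eta target with the planted terms included."""
        from embryomodes.covariance import CovarianceSet
        from embryomodes.maxent import predict_type_covariances
        true = planted_sparse_model(mirror16, n_pc=2, seed=3)
        intra, inter = predict_type_covariances(true)
        cov = CovarianceSet(mirror16.types, intra, inter)
        cand = candidate_terms(mirror16)
        order = [*true.spec.labels, *(l for l in cand.labels
                                      if l not in true.spec.labels)]
        model, report, etas = forward_select(order, cov, mirror16,
                                             candidates=cand, eta_target=0.9)
        assert report.eta > 0.9
        assert set(model.spec.labels) <= set(order[:len(etas)])
        assert etas[-1] == report.eta

    def test_empty_order_errors(self, mirror16):
        with pytest.raises(ValueError):
            forward_select([], None, mirror16)


class TestRegularizationConfig:
    def test_grid_sorted_and_scaled(self):
        cfg = RegularizationConfig(n_lambdas=4)
        grid = cfg.grid(2.0)
        assert np.all(np.diff(grid) > 0)
        assert grid[0] == pytest.approx(2e-2)
        assert grid[-1] == pytest.approx(20.0)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            RegularizationConfig(n_draws=1)
        with pytest.raises(ValueError):
            RegularizationConfig(lambda_grid=(1.0, 0.1))
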