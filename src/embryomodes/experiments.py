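"""Self-contained validation experiments on synthetic embryo cohorts.

Each function runs one calibration or recovery study end to end -- generate
synthetic data with known ground truth, run the relevant pipeline stage,
score the result -- and returns plain numbers.  They are used by the
acceptance script and the acceptance tests, and are convenient entry points
for exploring how the pipeline behaves as study conditions change.

Problem sizes follow the study conditions: cohorts of 14 embryos ("paper
scale", the 32-cell stage cohort size) for power and recovery studies, with
smaller cohorts (8 embryos, the 8-cell stage cohort size) for the expensive
cell-typing resampling study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import covariance, maxent, sparse, synthetic, variance
from .cell_typing import TypingConfig, adjusted_rand, hierarchical_typing
from .io import substream
from .synthetic import (
    independent_model,
    make_topology,
    neighbor_model,
    planted_sparse_model,
    sample_embryos,
    simulate_marker_posterior,
)


def state_space_dimension(topology: str = "mirror32", n_pc: int = 5) -> int:
    """Dimension of the flattened (cell, PC) state for a stage."""
    return maxent.state_dimension(make_topology(topology), n_pc)


def closed_form_fit_error(seed: int = 0) -> float:
    """Single cell type, no interactions: fitted M vs the exact C^-1."""
    from .covariance import CovarianceSet
    from .io import EmbryoGraph

    rng = substream(seed, "closed-form")
    g = EmbryoGraph(["p"], {"p": "t"}, np.zeros((1, 1), dtype=bool), {}, {"p": "p"})
    A = rng.standard_normal((2, 2))
    C = A @ A.T + np.eye(2)
    cov = CovarianceSet(["t"], {"t": C}, {("t", "t"): np.full((2, 2), np.nan)})
    model, _ = maxent.fit_maxent(cov, maxent.ConstraintSpec(), g)
    return float(np.max(np.abs(model.M["t"] - np.linalg.inv(C))))


def self_consistency_error(topology: str = "mirror16", seed: int = 3) -> float:
    """Refit a known model from its own exact statistics; max relative error."""
    g = make_topology(topology)
    true = planted_sparse_model(g, n_pc=2, seed=seed)
    terms = maxent.build_terms(true.spec, g, 2)
    targets = maxent.targets_from_model(terms, true.J)
    model, _ = maxent.fit_maxent(None, true.spec, g, n_pc=2, targets=targets)
    errs = []
    for fitted, truth in ((model.M, true.M), (model.S, true.S), (model.U, true.U)):
        for k, v in truth.items():
            errs.append(np.max(np.abs(fitted[k] - v)) / max(np.max(np.abs(v)), 1e-12))
    return float(max(errs))


def sister_model_zero_structure(topology: str = "mirror16") -> float:
    """Largest predicted covariance between non-sister type pairs.

    With only within-cell and sister couplings, J is block diagonal over
    sister pairs, so every non-sister covariance is exactly zero in the
    model -- the mechanism by which a sister-only hypothesis fails to
    explain embryo-wide correlations.
    """
    g = make_topology(topology)
    model = maxent.make_model(maxent.sister_spec(g), g, 2,
                              {t: np.eye(2) for t in g.types},
                              {"sister": -0.4 * np.eye(2)})
    _, inter = maxent.predict_type_covariances(model)
    sister_pairs = {frozenset((g.type_of[p], g.type_of[q]))
                    for p, q in g.sister.items()}
    worst = 0.0
    for (ta, tb), v in inter.items():
        if frozenset((ta, tb)) not in sister_pairs and not np.isnan(v).any():
            worst = max(worst, float(np.max(np.abs(v))))
    return worst


def monte_carlo_agreement(topology: str = "mirror8", n_samples: int = 100_000,
                          seed: int = 0) -> float:
    """Predicted type covariances vs sampling, in Monte-Carlo SE units."""
    from scipy.linalg import solve_triangular

    g = make_topology(topology)
    model = neighbor_model(g)
    pred_i, pred_g = maxent.predict_type_covariances(model)
    rng = substream(seed, "mc-agreement")
    L = np.linalg.cholesky(model.J)
    xs = solve_triangular(L.T, rng.standard_normal((n_samples, L.shape[0])).T,
                          lower=False).T
    S_mc = xs.T @ xs / n_samples
    emp_i, emp_g = maxent.type_covariance_reduction(S_mc, g, model.n_pc)
    # SE of a covariance estimate ~ sqrt((var_a var_b + cov^2) / n); bound
    # variances by the largest diagonal of Sigma
    vmax = float(np.max(np.diag(model.Sigma)))
    se = np.sqrt(2) * vmax / np.sqrt(n_samples)
    worst = 0.0
    for t, v in pred_i.items():
        worst = max(worst, float(np.max(np.abs(emp_i[t] - v))) / se)
    for k, v in pred_g.items():
        if not np.isnan(v).any():
            worst = max(worst, float(np.max(np.abs(emp_g[k] - v))) / se)
    return worst


@dataclass
class ShuffleCalibration:
    type1_rate: float
    power: float
    n_null: int
    n_coupled: int


def shuffle_test_calibration(
    n_null_datasets: int = 200,
    n_coupled_datasets: int = 50,
    n_embryos: int = synthetic.DEFAULT_N_EMBRYOS,
    topology: str = "mirror16",
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> ShuffleCalibration:
    """Type-I error and power of the Delta shuffle test (across-embryo mode).

    Null datasets come from the uncoupled model (J = identity); coupled
    datasets from the default neighbor model.  Each dataset is a fresh
    cohort of ``n_embryos`` embryos.
    """
    g = make_topology(topology)
    null_model = independent_model(g)
    coupled_model = neighbor_model(g)
    rng = substream(seed, "shuffle-calibration")

    def run(model, n_datasets):
        rejections = 0
        for _ in range(n_datasets):
            ds = sample_embryos(model, n_embryos, seed=rng)
            res = covariance.shuffle_test(ds.posterior.X, ds.type_labels,
                                          ds.embryo_labels, "across",
                                          n_shuffles=n_shuffles, seed=rng)
            rejections += res.p_value < alpha
        return rejections / n_datasets

    return ShuffleCalibration(
        type1_rate=run(null_model, n_null_datasets),
        power=run(coupled_model, n_coupled_datasets),
        n_null=n_null_datasets,
        n_coupled=n_coupled_datasets,
    )


def rank_selection_calibration(
    n_seeds: int = 10,
    shape: tuple[int, int] = (30, 20),
    spike_strength: float = 10.0,
    n_perm: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """(fraction of pure-noise runs keeping 0 PCs, fraction of spiked runs
    keeping >= 1 PC) for the permutation-null singular value threshold."""
    rng = substream(seed, "rank-selection")
    n, p = shape
    noise_zero = 0
    spike_found = 0
    for _ in range(n_seeds):
        Z = rng.standard_normal(shape)
        _, _, kept = variance.svd_rank_selection(Z, n_perm=n_perm, seed=rng)
        noise_zero += kept == 0
        u = rng.standard_normal((n, 1))
        v = rng.standard_normal((1, p))
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        spike = spike_strength * np.sqrt(n) * u @ v
        _, _, kept = variance.svd_rank_selection(spike + rng.standard_normal(shape),
                                                 n_perm=n_perm, seed=rng)
        spike_found += kept >= 1
    return noise_zero / n_seeds, spike_found / n_seeds


def temporal_recovery_correlation(
    n_embryos: int = 10,
    n_genes: int = 40,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> float:
    """Correlation between planted and recovered per-embryo times tau."""
    rng = substream(seed, "temporal-recovery")
    types_list = ["a", "b", "c"]
    alpha = {t: rng.standard_normal(n_genes) for t in types_list}
    norm = np.linalg.norm(np.stack(list(alpha.values())))
    alpha = {t: a / norm for t, a in alpha.items()}
    tau = rng.standard_normal(n_embryos)
    tau -= tau.mean()
    rows, types, embryos = [], [], []
    for e in range(n_embryos):
        for t in types_list:
            for _ in range(4):
                rows.append(tau[e] * alpha[t] + noise_sd * rng.standard_normal(n_genes))
                types.append(t)
                embryos.append(f"e{e}")
    tau_hat, _, _, info = variance.fit_temporal_projection(
        np.array(rows), embryos, types)
    order = [info["embryos"].index(f"e{e}") for e in range(n_embryos)]
    return float(abs(np.corrcoef(tau_hat[order], tau)[0, 1]))


@dataclass
class TypingRecovery:
    perfect_rate: float
    noise_single_root: bool
    n_seeds: int


def cell_typing_recovery(
    n_seeds: int = 20,
    n_embryos: int = 8,
    effect: float = 1.0,
    noise_sd: float = 0.25,
    n_resamples: int = 24,
    seed: int = 0,
) -> TypingRecovery:
    """Planted-type recovery rate (ARI = 1) and the pure-noise behavior.

    Marker effect is 4x the noise SD by default.  Uses 8-embryo cohorts
    (the smallest cohort in the study's stage range) to keep the resampling
    study tractable.
    """
    g = make_topology("mirror16")
    perfect = 0
    for s in range(n_seeds):
        post, truth = simulate_marker_posterior(
            g, n_embryos=n_embryos, effect=effect, noise_sd=noise_sd,
            seed=substream(seed, f"typing-data-{s}"))
        cfg = TypingConfig(n_resamples=n_resamples, seed=seed + s)
        asg = hierarchical_typing(post, cfg)
        pred = [asg.type_of[c.cell_id] for c in post.cells]
        true = [truth[c.cell_id] for c in post.cells]
        perfect += adjusted_rand(true, pred) == 1.0
    post, _ = simulate_marker_posterior(
        g, n_embryos=n_embryos, effect=0.0, noise_sd=noise_sd,
        seed=substream(seed, "typing-noise"))
    asg = hierarchical_typing(post, TypingConfig(n_resamples=n_resamples, seed=seed))
    return TypingRecovery(
        perfect_rate=perfect / n_seeds,
        noise_single_root=len(set(asg.type_of.values())) == 1,
        n_seeds=n_seeds,
    )


def _cohort_covariances(model, n_embryos, n_draws, n_boot, rng):
    """Sample a cohort from ``model`` and estimate its covariance set."""
    ds = sample_embryos(model, n_embryos, eps_scale=0.1, seed=rng)
    post = ds.posterior
    tl = [c.cell_type for c in post.cells]
    el = [c.embryo_id for c in post.cells]

    def draw_x(r):
        return post.X + post.eps * r.standard_normal(post.X.shape), tl, el

    return covariance.resample_covariances(draw_x, n_draws=n_draws,
                                           n_boot=n_boot, seed=rng)


def sparse_recovery_rate(
    n_seeds: int = 10,
    n_embryos: int = synthetic.DEFAULT_N_EMBRYOS,
    topology: str = "mirror32",
    n_draws: int = 16,
    n_lambdas: int = 4,
    n_specific: int = 1,
    coupling: float = 0.75,
    seed: int = 0,
) -> float:
    """Self-consistency of the sparse-inference pipeline at paper scale.

    Samples a cohort of the study's size and quality (14 embryos, scrambled
    identities, measurement noise) from a planted sparse model -- neighbor
    coupling plus ``n_specific`` specific directed terms -- runs the full
    regularized ranking, and asks whether every planted term lands within
    the top 2x(number planted) of the aggregated importance order.

    The planted model is a detectability design at the positive-definiteness
    frontier: with 14 embryos a pair covariance is estimated to ~2.5 standard
    errors at best, which supports localizing one specific interaction on
    top of the neighbor coupling; richer planted models cannot have all
    their terms recovered reliably at this cohort size (the original study
    likewise recovers its interactions only as "amongst the most important").
    """
    g = make_topology(topology)
    cfg = sparse.RegularizationConfig(n_draws=n_draws, n_lambdas=n_lambdas)
    hits = 0
    for s in range(n_seeds):
        true = planted_sparse_model(g, n_pc=2, coupling=coupling,
                                    n_specific=n_specific, seed=seed * 1000 + s)
        planted = set(true.spec.labels)
        cov = _cohort_covariances(true, n_embryos, max(n_draws // 4, 2), 4,
                                  substream(seed, f"sparse-cohort-{s}"))
        ranking = sparse.rank_terms(cov, g, cfg)
        hits += planted <= set(ranking.aggregated[:2 * len(planted)])
    return hits / n_seeds


def spectral_gap_k(eigenvalues: np.ndarray, max_k: int = 5) -> int:
    """Leading-subspace size = position of the largest relative eigengap.

    Under left-right symmetry collective modes come in near-degenerate
    doublets, so a fixed subspace size can cut through a doublet; the
    gap-delimited size gives a well-conditioned subspace comparison.
    """
    lam = np.asarray(eigenvalues)
    ratios = lam[:max_k] / lam[1:max_k + 1]
    return int(np.argmax(ratios)) + 1


def mode_recovery_angle(
    n_embryos: int = 200,
    topology: str = "mirror16",
    k: int | None = None,
    n_refit_terms: int = 8,
    n_draws: int = 10,
    n_lambdas: int = 4,
    seed: int = 0,
) -> float:
    """End-to-end collective-mode recovery (degrees of subspace angle).

    Samples a large cohort from the default planted model (neighbor + two
    specific terms), ranks candidate interactions, refits the top
    ``n_refit_terms`` without penalty, decomposes the refit model's
    covariance into modes, and returns the largest principal angle (degrees)
    between the top-k planted and inferred mode subspaces.  k defaults to the
    gap-delimited leading subspace of the planted spectrum
    (:func:`spectral_gap_k`).
    """
    from scipy.linalg import subspace_angles

    g = make_topology(topology)
    cand = sparse.candidate_terms(g)
    true = planted_sparse_model(g, n_pc=2, seed=seed)
    cov = _cohort_covariances(true, n_embryos, max(n_draws // 3, 2), 3,
                              substream(seed, "modes-cohort"))
    cfg = sparse.RegularizationConfig(n_draws=n_draws, n_lambdas=n_lambdas)
    ranking = sparse.rank_terms(cov, g, cfg)
    model, _ = maxent.fit_maxent(cov, cand.subset(ranking.aggregated[:n_refit_terms]), g)
    inferred = maxent.mode_decomposition(model)
    planted = maxent.mode_decomposition(true)
    if k is None:
        k = spectral_gap_k(planted.eigenvalues)
    return float(np.degrees(subspace_angles(inferred.modes[:, :k],
                                            planted.modes[:, :k]).max()))


def rotation_baseline_fraction(
    D: int = 10, k: int = 2, n_rotations: int = 300, seed: int = 0
) -> float:
    """Mean variance fraction of k fixed modes under Haar rotations of an
    isotropic model; analytically k/D."""
    J = np.eye(D)
    modes = maxent.mode_decomposition(J)
    fr = maxent.rotation_baseline(J, modes, k, n_rotations=n_rotations,
                                  seed=substream(seed, "rotation"))
    return float(fr.mean())


def filter_counting_example() -> tuple[list[str], list[str]]:
    """Zygotic/maternal classification on a printed-style toy count table.

    By hand: g0 passes all zygotic filters (silent baseline, >100 reads at
    the later stage, differentially expressed); g4 passes the maternal
    filters (>500 baseline reads, never differentially expressed); every
    other gene violates at least one threshold.
    """
    import pandas as pd

    from . import gene_sets
    from .io import CellRecord, CountMatrix

    def counts_of(arr, stage):
        cells = [CellRecord(f"c{i}", "e0", stage) for i in range(len(arr))]
        return CountMatrix(np.array(arr), [f"g{j}" for j in range(len(arr[0]))], cells)

    baseline = counts_of([[0, 50, 0, 0, 600, 400, 600],
                          [0, 10, 5, 2, 550, 350, 550]], stage=4)
    stage16 = counts_of([[150, 120, 80, 150, 5, 5, 200],
                         [120, 110, 70, 130, 2, 1, 150]], stage=16)
    sig = {"g0": True, "g1": True, "g2": True, "g3": False,
           "g4": False, "g5": False, "g6": True}
    de = pd.DataFrame(
        [(gn, "A", "B", 0.001 if s else 0.5, 0.005 if s else 0.9, s)
         for gn, s in sig.items()],
        columns=["gene", "type_a", "type_b", "p_raw", "p_adj", "significant"])
    zygotic = gene_sets.classify_zygotic({4: baseline, 16: stage16}, {16: de})[16]
    maternal = gene_sets.classify_maternal(baseline, {16: de})
    return zygotic, maternal
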