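"""Sparse interaction-network inference.

The full candidate model -- embryo-wide, neighbor and sister couplings plus a
directed coupling for every mirror-bundled pair of cells in contact -- has
far more parameters than the data can constrain, so interactions are assumed
sparse.  An L1 penalty of strength lambda on every S and U coupling (M is
never penalized) is added to the moment-matching dual and solved by proximal
gradient with soft-thresholding, keeping J positive definite.  Fits are
repeated over covariance draws from the posterior/bootstrap ensemble;
candidate terms are ranked per lambda by how consistently non-zero their
couplings are, the per-lambda rankings are aggregated with the Schulze
beatpath method, and a final forward selection refits unregularized models
with the top-m terms until the fit quality eta exceeds its target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .covariance import CovarianceSet
from .io import EmbryoGraph
from .maxent import (
    ConstraintSpec,
    FitReport,
    MaxEntModel,
    _init_theta,
    _neg_logdet,
    _newton_fit,
    _theta_to_params,
    build_terms,
    constraint_targets,
    fit_maxent,
    fit_quality,
    predict_type_covariances,
)


@dataclass(frozen=True)
class RegularizationConfig:
    """Settings for the regularized-inference pipeline.

    The lambda grid is log-spaced (default 8 values over [1e-2, 10] times the
    median magnitude of the empirical covariances; below that range the
    penalty shrinks nothing, so the fit is slow and its ranking ballot is
    noise).  ``n_draws`` covariance
    replicates are fit per lambda; a coupling counts as non-zero when its
    Frobenius norm exceeds ``nonzero_threshold``.  Forward selection stops at
    the first model with eta > ``eta_target``.
    """

    lambda_grid: tuple[float, ...] = ()
    n_lambdas: int = 8
    lambda_range: tuple[float, float] = (1e-2, 10.0)
    n_draws: int = 100
    nonzero_threshold: float = 1e-4
    eta_target: float = 0.9

    def __post_init__(self) -> None:
        if self.lambda_grid and list(self.lambda_grid) != sorted(self.lambda_grid):
            raise ValueError("lambda_grid must be sorted ascending")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")

    def grid(self, cov_scale: float) -> np.ndarray:
        if self.lambda_grid:
            return np.asarray(self.lambda_grid, dtype=float)
        lo, hi = self.lambda_range
        return cov_scale * np.logspace(np.log10(lo), np.log10(hi), self.n_lambdas)


def candidate_terms(graph: EmbryoGraph) -> ConstraintSpec:
    """Full candidate set: three global terms plus specific contact terms.

    Global: embryo-wide (all pairs), neighbor (contact graph), sister.
    Specific: one directed adjacency Omega per contact pair, bundled with its
    left-right mirror image so the two sides share one coupling.
    """
    n = graph.n_cells
    sym_terms = [
        ("embryo-wide", (~np.eye(n, dtype=bool)).astype(int)),
        ("neighbor", graph.contact.astype(int)),
        ("sister", graph.sister_matrix().astype(int)),
    ]
    mi = graph.mirror_index()
    if np.all(mi == np.arange(n)):
        warnings.warn("mirror map is trivial; specific terms are unsymmetrized")
    seen: set[frozenset[tuple[int, int]]] = set()
    dir_terms = []
    for p in range(n):
        for q in range(p + 1, n):
            if not graph.contact[p, q]:
                continue
            # canonical bundle: the unordered pair and its mirror image
            key = frozenset({frozenset({p, q}), frozenset({int(mi[p]), int(mi[q])})})
            if key in seen:
                continue
            seen.add(key)
            om = np.zeros((n, n), dtype=int)
            om[p, q] = 1
            om[mi[p], mi[q]] = 1
            label = f"specific:{graph.cell_names[p]}-{graph.cell_names[q]}"
            dir_terms.append((label, om))
    return ConstraintSpec(sym_terms=sym_terms, dir_terms=dir_terms)


def fit_regularized(
    targets: np.ndarray,
    terms,
    lam: float,
    theta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 3000,
    strict: bool = True,
    penalty_weights: np.ndarray | None = None,
) -> np.ndarray:
    """L1-penalized moment matching by proximal gradient.

    Minimizes  -log det J(theta) + theta . targets + lambda * sum w |theta_SU|
    with soft-thresholding on the penalized (S, U) coordinates and
    backtracking that keeps J positive definite.  ``penalty_weights`` (one
    per parameter, default 1) standardize the penalty when constraint targets
    have very different sampling noise.  lambda = 0 reduces to the
    unregularized Newton solve.
    """
    if lam == 0:
        theta, converged, _ = _newton_fit(terms, targets, theta0=theta0)
        if not converged:
            raise RuntimeError("unregularized fit did not converge")
        return theta
    from .maxent import _chol, _nld_from_chol, _sigma_from_chol

    pen = terms.penalized
    w = np.ones(terms.n_params) if penalty_weights is None else np.asarray(penalty_weights)
    lam_w = lam * w
    theta = _init_theta(terms, targets) if theta0 is None else theta0.copy()

    def evaluate_g(th):
        """(smooth value, Cholesky factor) at th, or (None, None) if not PD."""
        L = _chol(terms.assemble_J(th))
        if L is None:
            return None, None
        return _nld_from_chol(L) + float(th @ targets), L

    def evaluate(th):
        g, L = evaluate_g(th)
        return (None, None) if g is None else (g, _sigma_from_chol(L))

    g, Sigma = evaluate(theta)
    if g is None:
        theta = _init_theta(terms, targets)
        g, Sigma = evaluate(theta)
    scale = max(float(np.max(np.abs(targets))), 1e-12)
    # diagonal-Hessian preconditioner: parameters touch very different
    # numbers of matrix entries, so a single scalar step conditions poorly
    diag = np.maximum(terms.hessian_diag(Sigma), 1e-8 * scale)
    mult = 1.0
    momentum = 0.0
    theta_prev = theta.copy()
    for it in range(max_iter):
        grad_t = targets - terms.statistics(Sigma)
        # KKT subgradient residual of the penalized dual at theta
        resid = grad_t.copy()
        on = pen & (theta != 0)
        resid[on] += lam_w[on] * np.sign(theta[on])
        off = pen & (theta == 0)
        resid[off] = np.sign(grad_t[off]) * np.maximum(np.abs(grad_t[off]) - lam_w[off], 0.0)
        if float(np.max(np.abs(resid))) < tol * scale:
            return theta
        # FISTA extrapolation (momentum reset on any failure/increase)
        if momentum > 0:
            y = theta + momentum * (theta - theta_prev)
            gy, Sigma_y = evaluate(y)
            if gy is None:
                y, gy, grad = theta, g, grad_t
            else:
                grad = targets - terms.statistics(Sigma_y)
        else:
            y, gy, grad = theta, g, grad_t
        accepted = False
        for _ in range(60):
            step = mult / diag
            cand = y - step * grad
            cand[pen] = np.sign(cand[pen]) * np.maximum(
                np.abs(cand[pen]) - step[pen] * lam_w[pen], 0.0
            )
            gc, L_c = evaluate_g(cand)
            if gc is not None:
                diff = cand - y
                bound = gy + float(grad @ diff) + float(diff @ (diag * diff)) / (2 * mult)
                if gc <= bound + 1e-12 * abs(gy):
                    accepted = True
                    break
            mult *= 0.5
        if not accepted:
            raise RuntimeError(f"proximal gradient stalled at iteration {it}")
        if gc + np.sum(lam_w[pen] * np.abs(cand[pen])) > g + np.sum(lam_w[pen] * np.abs(theta[pen])):
            momentum = 0.0  # adaptive restart
        else:
            momentum = min(0.95, (it + 1.0) / (it + 4.0))
        theta_prev, theta, g, Sigma = theta, cand, gc, _sigma_from_chol(L_c)
        mult = min(mult * 1.25, 4.0)
        if it % 50 == 49:
            diag = np.maximum(terms.hessian_diag(Sigma), 1e-8 * scale)
    resid = targets - terms.statistics(Sigma)
    msg = (f"regularized fit did not converge in {max_iter} iterations "
           f"(max gradient {np.max(np.abs(resid)):.3e})")
    if strict:
        raise RuntimeError(msg)
    warnings.warn(msg)
    return theta


def fit_regularized_lifted(
    targets: np.ndarray,
    terms,
    spec: ConstraintSpec,
    graph: EmbryoGraph,
    lam: float,
    theta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 3000,
    n_outer: int = 5,
    penalty_weights=None,
) -> np.ndarray:
    """L1 fit with the lift-bias correction loop.

    Targets built from type-level covariances dilute cross-type adjacency
    statistics; the outer loop adjusts them until the fitted model's own
    type-lifted statistics match the data, as in
    :func:`embryomodes.maxent.fit_maxent`.
    """
    from .maxent import lift_discrepancy

    theta = fit_regularized(targets, terms, lam, theta0=theta0, tol=tol,
                            max_iter=max_iter, penalty_weights=penalty_weights)
    adj = np.zeros_like(targets)
    scale = max(float(np.max(np.abs(targets))), 1e-12)
    for _ in range(n_outer):
        delta = lift_discrepancy(terms, spec, graph, terms.assemble_J(theta))
        if float(np.max(np.abs(delta - adj))) < 1e-4 * scale:
            break
        adj = delta
        theta = fit_regularized(targets - adj, terms, lam, theta0=theta,
                                tol=tol, max_iter=max_iter,
                                penalty_weights=penalty_weights)
    return theta


def _term_norms(terms, theta: np.ndarray, labels: list[str],
                adj_weight: dict[str, float] | None = None) -> dict[str, float]:
    """Importance norm of each candidate term's coupling block.

    The coupling Frobenius norm is weighted by the Frobenius norm of the
    term's adjacency (sqrt of its edge count), so the score measures the
    term's total contribution to the interaction matrix J: a global term
    with a small per-pair coupling applied to many pairs can matter as much
    as one strong specific pair.
    """
    _, S, U = _theta_to_params(terms, theta)
    out = {}
    for label in labels:
        block = S.get(label, U.get(label))
        w = adj_weight.get(label, 1.0) if adj_weight else 1.0
        out[label] = float(np.linalg.norm(block)) * w if block is not None else 0.0
    return out


@dataclass
class TermRanking:
    """Per-lambda rankings, stability scores, and the aggregated order."""

    per_lambda: dict[float, list[str]]
    scores: dict[float, dict[str, float]]
    aggregated: list[str]

    def __post_init__(self) -> None:
        for lam, order in self.per_lambda.items():
            if sorted(order) != sorted(self.aggregated):
                raise ValueError(f"ranking at lambda={lam} is not a permutation of candidates")


def stability_ranking(
    norms_per_draw: list[dict[str, float]], nonzero_threshold: float
) -> tuple[list[str], dict[str, float]]:
    """Rank terms by (fraction of draws non-zero) x (median coupling norm).

    Ties are broken lexicographically by term label.
    """
    if len(norms_per_draw) < 2:
        raise ValueError("need at least 2 draws for a stability ranking")
    labels = sorted(norms_per_draw[0])
    scores = {}
    for label in labels:
        vals = np.array([d[label] for d in norms_per_draw])
        frac = float(np.mean(vals > nonzero_threshold))
        scores[label] = frac * float(np.median(vals))
    order = sorted(labels, key=lambda l: (-scores[l], l))
    return order, scores


def schulze_aggregate(
    rankings: list[list[str]],
    scores: list[dict[str, float]] | None = None,
) -> list[str]:
    """Aggregate rankings with the Schulze beatpath method.

    Pairwise preferences d[a][b] count ballots ranking a above b; strongest
    beatpaths p are computed by Floyd-Warshall; candidates are ordered by the
    number of opponents they beat (p[a][b] > p[b][a]), remaining ties broken
    lexicographically.  When per-ballot ``scores`` are supplied, a ballot
    prefers a over b only if their scores differ strictly -- terms tied at
    zero express no preference rather than a spurious alphabetical one.
    """
    if not rankings or not rankings[0]:
        raise ValueError("empty candidate set")
    cands = sorted(rankings[0])
    for r in rankings:
        if sorted(r) != cands:
            raise ValueError("all rankings must order the same candidates")
    idx = {c: i for i, c in enumerate(cands)}
    m = len(cands)
    d = np.zeros((m, m), dtype=int)
    for bi, r in enumerate(rankings):
        if scores is not None:
            sc = scores[bi]
            for a in cands:
                for b in cands:
                    if a != b and sc[a] > sc[b]:
                        d[idx[a], idx[b]] += 1
        else:
            pos = {c: k for k, c in enumerate(r)}
            for a in cands:
                for b in cands:
                    if a != b and pos[a] < pos[b]:
                        d[idx[a], idx[b]] += 1
    p = np.where(d > d.T, d, 0)
    for k in range(m):
        np.maximum(p, np.minimum(p[:, k:k + 1], p[k:k + 1, :]), out=p)
        np.fill_diagonal(p, 0)
    wins = np.sum(p > p.T, axis=1)
    return sorted(cands, key=lambda c: (-wins[idx[c]], c))


def rank_terms(
    cov: CovarianceSet,
    graph: EmbryoGraph,
    config: RegularizationConfig | None = None,
    candidates: ConstraintSpec | None = None,
    n_pc: int | None = None,
) -> TermRanking:
    """Full ranking pipeline: L1 fits over draws and lambdas, then Schulze.

    Covariance replicates come from ``cov.draws`` (posterior x bootstrap); if
    the config requests more draws than available, the available ones are
    cycled.  Draws whose intra-type covariances are not positive definite are
    skipped with a warning (infeasible moment constraints).
    """
    config = config or RegularizationConfig()
    candidates = candidates if candidates is not None else candidate_terms(graph)
    if n_pc is None:
        n_pc = next(iter(cov.intra.values())).shape[0]
    terms = build_terms(candidates, graph, n_pc)
    labels = candidates.labels
    adj_weight = {l: float(np.sqrt(np.sum(a != 0)))
                  for l, a in [*candidates.sym_terms, *candidates.dir_terms]}
    point_targets = constraint_targets(terms, candidates, graph, cov.intra, cov.inter)
    cov_scale = float(np.median(np.abs(point_targets[~terms.penalized])))
    grid = config.grid(cov_scale)

    if not cov.draws:
        raise ValueError("CovarianceSet has no draws; run resample_covariances first")
    draw_targets = []
    for k in range(config.n_draws):
        intra, inter = cov.draws[k % len(cov.draws)]
        try:
            t = constraint_targets(terms, candidates, graph, intra, inter)
            _init_theta(terms, t)  # feasibility check (intra PD)
        except ValueError:
            warnings.warn(f"draw {k}: intra covariance not PD, skipped")
            continue
        draw_targets.append(t)
    if len(draw_targets) < 2:
        raise ValueError("fewer than 2 feasible covariance draws")



    per_lambda: dict[float, list[str]] = {}
    scores: dict[float, dict[str, float]] = {}
    warm_point: np.ndarray | None = None
    from .maxent import lift_discrepancy

    for lam in grid[::-1]:  # descending: heavily-shrunk fits are cheap starts
        warm_point = fit_regularized_lifted(point_targets, terms, candidates, graph,
                                            lam, theta0=warm_point,
                                            tol=1e-4, max_iter=5000)
        # the lift-bias correction is a property of the fitted model, not of
        # the draw noise, so it is computed once per lambda from the point fit
        adj = lift_discrepancy(terms, candidates, graph, terms.assemble_J(warm_point))
        norms_per_draw = []
        for t in draw_targets:
            # per-draw fits feed only the non-zero/stability ranking, so a
            # looser optimality tolerance suffices
            theta = fit_regularized(t - adj, terms, lam, theta0=warm_point,
                                    tol=1e-4, max_iter=5000, strict=False)
            norms_per_draw.append(_term_norms(terms, theta, labels, adj_weight))
        order, sc = stability_ranking(norms_per_draw, config.nonzero_threshold)
        per_lambda[float(lam)] = order
        scores[float(lam)] = sc
    aggregated = schulze_aggregate(list(per_lambda.values()),
                                   scores=[scores[lam] for lam in per_lambda])
    return TermRanking(per_lambda=per_lambda, scores=scores, aggregated=aggregated)


def forward_select(
    order: list[str],
    cov: CovarianceSet,
    graph: EmbryoGraph,
    candidates: ConstraintSpec | None = None,
    eta_target: float = 0.9,
    n_pc: int | None = None,
    max_terms: int | None = None,
) -> tuple[MaxEntModel, FitReport, list[float]]:
    """Smallest top-m model (unregularized refit) reaching eta > eta_target.

    L1 is used only for selection; the returned couplings are unpenalized
    moment matches.  Returns the model, its fit report, and the eta
    trajectory over m = 1, 2, ...; if the target is never reached within
    ``max_terms`` (default: all terms) the largest model tried is returned
    with a warning.
    """
    if not order:
        raise ValueError("empty term order")
    candidates = candidates if candidates is not None else candidate_terms(graph)
    limit = len(order) if max_terms is None else min(max_terms, len(order))
    etas: list[float] = []
    best = None
    for m in range(1, limit + 1):
        spec_m = candidates.subset(order[:m])
        model, report = fit_maxent(cov, spec_m, graph, n_pc=n_pc)
        etas.append(float(report.eta))
        best = (model, report)
        if report.eta > eta_target:
            return model, report, etas
    warnings.warn(f"eta target {eta_target} not reached with {limit} terms "
                  f"(best eta {max(etas):.3f}); returning the largest model tried")
    return best[0], best[1], etas
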