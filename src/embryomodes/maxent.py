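"""Maximum-entropy Gaussian models of cell-cell interaction.

Given a set of constrained covariance statistics -- the within-cell
covariance per cell type, and adjacency-averaged covariances between cells
linked by symmetric (Psi) or directed (Omega) adjacency matrices -- the
distribution of maximum entropy consistent with them is a zero-mean Gaussian
p(x) = N(0, J^-1) over the flattened (cell, PC) state, with

    J_(pi)(qj) = sum_t M^t_ij I^t_pq + sum_k S^k_ij Psi^k_pq
                 + 1/2 sum_k' (U^k'_ij Omega^k'_pq + U^k'_ji Omega^k'_qp),

where the couplings M (within-cell, per type), S (symmetric cell-cell) and U
(directed cell-cell) arise as Lagrange multipliers.  Fitting is moment
matching: the convex dual  h(theta) = -log det J(theta) + theta . c  is
minimized (Newton with PD-safeguarded backtracking), whose gradient is
exactly (target - model statistic).  Left-right symmetry is honoured by
construction: adjacencies supplied by the graph are mirror-symmetric, so
Eq.-style constraints average the two sides.

Flattening order is cell-major: state index = p * n_pc + i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .covariance import CovarianceSet
from .io import EmbryoGraph

PD_TOL = 1e-10
MATCH_RTOL = 1e-6  # relative residual at which moment matching counts as met


def state_dimension(graph: EmbryoGraph, n_pc: int) -> int:
    """Dimension of the flattened (cell, PC) state space."""
    return graph.n_cells * n_pc


# ---------------------------------------------------------------------------
# constraint specification
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSpec:
    """Which covariance statistics the model constrains.

    Intra-cell, per-type terms are always present.  ``sym_terms`` maps labels
    to symmetric 0/1 adjacency matrices (Psi); ``dir_terms`` to directed 0/1
    adjacencies (Omega).  Labels: 'embryo-wide', 'neighbor', 'sister', or
    'specific:p-q' for individual (mirror-bundled) cell pairs.
    """

    sym_terms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    dir_terms: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [l for l, _ in self.sym_terms] + [l for l, _ in self.dir_terms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate term labels")
        for label, psi in self.sym_terms:
            psi = np.asarray(psi)
            if not np.array_equal(psi, psi.T):
                raise ValueError(f"sym term {label!r}: Psi must be symmetric")
            if np.any(np.diag(psi)):
                raise ValueError(f"sym term {label!r}: Psi must have zero diagonal")
            if not np.all(np.isin(psi, [0, 1])):
                raise ValueError(f"sym term {label!r}: Psi must be 0/1")
        for label, om in self.dir_terms:
            om = np.asarray(om)
            if np.any(np.diag(om)):
                raise ValueError(f"dir term {label!r}: Omega must have zero diagonal")
            if not np.all(np.isin(om, [0, 1])):
                raise ValueError(f"dir term {label!r}: Omega must be 0/1")

    @property
    def labels(self) -> list[str]:
        return [l for l, _ in self.sym_terms] + [l for l, _ in self.dir_terms]

    def subset(self, labels: Sequence[str]) -> "ConstraintSpec":
        keep = set(labels)
        return ConstraintSpec(
            sym_terms=[(l, a) for l, a in self.sym_terms if l in keep],
            dir_terms=[(l, a) for l, a in self.dir_terms if l in keep],
        )


def embryo_wide_spec(graph: EmbryoGraph) -> ConstraintSpec:
    """All cells equally interacting: Psi_pq = 1 for every p != q."""
    n = graph.n_cells
    return ConstraintSpec(sym_terms=[("embryo-wide", ~np.eye(n, dtype=bool) + 0)])


def sister_spec(graph: EmbryoGraph) -> ConstraintSpec:
    """Only sister cells interacting."""
    return ConstraintSpec(sym_terms=[("sister", graph.sister_matrix().astype(int))])


def neighbor_spec(graph: EmbryoGraph) -> ConstraintSpec:
    """Only cells in spatial contact interacting."""
    return ConstraintSpec(sym_terms=[("neighbor", graph.contact.astype(int))])


# ---------------------------------------------------------------------------
# term bookkeeping: parameters and their basis matrices
# ---------------------------------------------------------------------------

@dataclass
class _Terms:
    """Flattened parameter list with sparse basis matrices.

    J(theta) = sum_alpha theta_alpha B_alpha.  For each parameter the basis
    entries are stored as (rows, cols, vals); constraint statistics are
    tr(Sigma B_alpha), so the dual gradient is target - statistic.
    """

    meta: list[tuple[str, str, int, int]]     # (kind, key, i, j)
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    param: np.ndarray                         # parameter index per entry
    D: int
    n_pc: int
    types: list[str]
    type_cells: dict[str, np.ndarray]
    penalized: np.ndarray                     # True for S/U parameters

    @property
    def n_params(self) -> int:
        return len(self.meta)

    @property
    def _B(self):
        """Cached sparse basis, one row per parameter over flattened (D, D)."""
        if getattr(self, "_B_cache", None) is None:
            from scipy import sparse
            self._B_cache = sparse.csr_matrix(
                (self.vals, (self.param, self.rows * self.D + self.cols)),
                shape=(self.n_params, self.D * self.D),
            )
        return self._B_cache

    def assemble_J(self, theta: np.ndarray) -> np.ndarray:
        return (self._B.T @ theta).reshape(self.D, self.D)

    def statistics(self, Sigma: np.ndarray) -> np.ndarray:
        return self._B @ Sigma.ravel()

    @property
    def _groups(self) -> list[np.ndarray]:
        """Cached entry indices per parameter."""
        if getattr(self, "_groups_cache", None) is None:
            self._groups_cache = [np.flatnonzero(self.param == a)
                                  for a in range(self.n_params)]
        return self._groups_cache

    def hessian_diag(self, Sigma: np.ndarray) -> np.ndarray:
        """Diagonal of the dual Hessian, tr(Sigma B_a Sigma B_a) per parameter.

        Uses tr(Sigma B Sigma B) = ||C^T B C||_F^2 with Sigma = C C^T, which
        is linear in each basis matrix's entry count.
        """
        C = np.linalg.cholesky(Sigma)
        out = np.zeros(self.n_params)
        M = np.empty((self.D, self.D))
        for a, ka in enumerate(self._groups):
            M[:] = 0.0
            np.add.at(M, self.rows[ka], self.vals[ka, None] * C[self.cols[ka]])
            out[a] = float(np.sum((C.T @ M) ** 2))
        return out

    def hessian(self, Sigma: np.ndarray) -> np.ndarray:
        """H_ab = tr(Sigma B_a Sigma B_b), computed entrywise.

        H_ab = sum_{k in a, l in b} v_k v_l Sigma[c_k, r_l] Sigma[c_l, r_k].
        """
        P = self.n_params
        H = np.zeros((P, P))
        Scr = Sigma  # alias
        for a in range(P):
            ka = self._groups[a]
            U1 = Scr[np.ix_(self.cols[ka], self.rows)]        # (Ka, N)
            U2 = Scr[np.ix_(self.cols, self.rows[ka])]        # (N, Ka)
            contrib = ((self.vals[ka][:, None] * U1) * U2.T).sum(axis=0) * self.vals
            H[a] = np.bincount(self.param, weights=contrib, minlength=P)
        return H


def build_terms(spec: ConstraintSpec, graph: EmbryoGraph, n_pc: int) -> _Terms:
    d = n_pc
    D = graph.n_cells * d
    types = graph.types
    type_cells = graph.type_indices()
    meta: list[tuple[str, str, int, int]] = []
    rows, cols, vals, param, penalized = [], [], [], [], []

    def add_entries(a: int, rs, cs, vs):
        rows.extend(rs)
        cols.extend(cs)
        vals.extend(vs)
        param.extend([a] * len(rs))

    # intra (M) terms: one symmetric d x d block per type
    for t in types:
        cells = type_cells[t]
        for i in range(d):
            for j in range(i, d):
                a = len(meta)
                meta.append(("intra", t, i, j))
                penalized.append(False)
                for p in cells:
                    if i == j:
                        add_entries(a, [p * d + i], [p * d + i], [1.0])
                    else:
                        add_entries(a, [p * d + i, p * d + j],
                                    [p * d + j, p * d + i], [1.0, 1.0])
    # symmetric (S) terms
    for label, psi in spec.sym_terms:
        ps, qs = np.nonzero(np.asarray(psi))
        for i in range(d):
            for j in range(i, d):
                a = len(meta)
                meta.append(("sym", label, i, j))
                penalized.append(True)
                if i == j:
                    add_entries(a, list(ps * d + i), list(qs * d + i), [1.0] * len(ps))
                else:
                    add_entries(a, list(ps * d + i) + list(ps * d + j),
                                list(qs * d + j) + list(qs * d + i),
                                [1.0] * (2 * len(ps)))
    # directed (U) terms: B_ij = 1/2 (Omega x E_ij + Omega^T x E_ji).
    # When Omega is itself symmetric only U + U^T enters J, so the coupling
    # is parameterized by its symmetric part (upper triangle) to keep the
    # moment-matching problem non-degenerate.
    for label, om in spec.dir_terms:
        om = np.asarray(om)
        ps, qs = np.nonzero(om)
        if np.array_equal(om, om.T):
            for i in range(d):
                for j in range(i, d):
                    a = len(meta)
                    meta.append(("dirsym", label, i, j))
                    penalized.append(True)
                    if i == j:
                        add_entries(a, list(ps * d + i), list(qs * d + i),
                                    [1.0] * len(ps))
                    else:
                        add_entries(a, list(ps * d + i) + list(ps * d + j),
                                    list(qs * d + j) + list(qs * d + i),
                                    [1.0] * (2 * len(ps)))
        else:
            for i in range(d):
                for j in range(d):
                    a = len(meta)
                    meta.append(("dir", label, i, j))
                    penalized.append(True)
                    add_entries(a, list(ps * d + i) + list(qs * d + j),
                                list(qs * d + j) + list(ps * d + i),
                                [0.5] * (2 * len(ps)))
    return _Terms(
        meta=meta,
        rows=np.array(rows, dtype=int),
        cols=np.array(cols, dtype=int),
        vals=np.array(vals, dtype=float),
        param=np.array(param, dtype=int),
        D=D,
        n_pc=d,
        types=types,
        type_cells=type_cells,
        penalized=np.array(penalized, dtype=bool),
    )


def _theta_to_params(terms: _Terms, theta: np.ndarray):
    d = terms.n_pc
    M = {t: np.zeros((d, d)) for t in terms.types}
    S: dict[str, np.ndarray] = {}
    U: dict[str, np.ndarray] = {}
    for a, (kind, key, i, j) in enumerate(terms.meta):
        if kind == "intra":
            M[key][i, j] = M[key][j, i] = theta[a]
        elif kind == "sym":
            S.setdefault(key, np.zeros((d, d)))
            S[key][i, j] = S[key][j, i] = theta[a]
        elif kind == "dirsym":
            U.setdefault(key, np.zeros((d, d)))
            U[key][i, j] = U[key][j, i] = theta[a]
        else:
            U.setdefault(key, np.zeros((d, d)))
            U[key][i, j] = theta[a]
    return M, S, U


def _params_to_theta(terms: _Terms, M: Mapping, S: Mapping, U: Mapping) -> np.ndarray:
    theta = np.zeros(terms.n_params)
    for a, (kind, key, i, j) in enumerate(terms.meta):
        src = {"intra": M, "sym": S, "dir": U, "dirsym": U}[kind]
        theta[a] = np.asarray(src[key])[i, j]
    return theta


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class MaxEntModel:
    """Fitted (or planted) maximum-entropy Gaussian interaction model."""

    spec: ConstraintSpec
    graph: EmbryoGraph
    n_pc: int
    M: dict[str, np.ndarray]
    S: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    J: np.ndarray

    @property
    def Sigma(self) -> np.ndarray:
        return np.linalg.inv(self.J)


def build_J(
    M: Mapping[str, np.ndarray],
    S: Mapping[str, np.ndarray],
    U: Mapping[str, np.ndarray],
    spec: ConstraintSpec,
    graph: EmbryoGraph,
    n_pc: int,
    check_pd: bool = True,
) -> np.ndarray:
    """Assemble the interaction matrix J from couplings per the model form."""
    d = n_pc
    n = graph.n_cells
    J = np.zeros((n * d, n * d))
    type_cells = graph.type_indices()
    for t, cells in type_cells.items():
        Mt = np.asarray(M[t])
        if not np.allclose(Mt, Mt.T):
            raise ValueError(f"M[{t!r}] must be symmetric")
        ind = np.zeros((n, n))
        ind[cells, cells] = 1.0
        J += np.kron(ind, Mt)
    for label, psi in spec.sym_terms:
        if label in S:
            Sk = np.asarray(S[label])
            if not np.allclose(Sk, Sk.T):
                raise ValueError(f"S[{label!r}] must be symmetric")
            J += np.kron(np.asarray(psi, dtype=float), Sk)
    for label, om in spec.dir_terms:
        if label in U:
            Uk = np.asarray(U[label])
            Om = np.asarray(om, dtype=float)
            J += 0.5 * (np.kron(Om, Uk) + np.kron(Om.T, Uk.T))
    if not np.allclose(J, J.T, atol=1e-12):
        raise ValueError("assembled J is not symmetric")
    if check_pd:
        lam_min = float(np.linalg.eigvalsh(J)[0])
        if lam_min <= PD_TOL:
            raise ValueError(f"J is not positive definite (smallest eigenvalue {lam_min:.3e})")
    return J


def make_model(
    spec: ConstraintSpec,
    graph: EmbryoGraph,
    n_pc: int,
    M: Mapping[str, np.ndarray],
    S: Mapping[str, np.ndarray] | None = None,
    U: Mapping[str, np.ndarray] | None = None,
    check_pd: bool = True,
) -> MaxEntModel:
    S = dict(S or {})
    U = dict(U or {})
    J = build_J(M, S, U, spec, graph, n_pc, check_pd=check_pd)
    return MaxEntModel(spec, graph, n_pc, {t: np.asarray(m, float) for t, m in M.items()},
                       S, U, J)


# ---------------------------------------------------------------------------
# prediction, fit quality, targets
# ---------------------------------------------------------------------------

def predict_type_covariances(
    model_or_J: MaxEntModel | np.ndarray,
    graph: EmbryoGraph | None = None,
    n_pc: int | None = None,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], np.ndarray]]:
    """Type-level covariances implied by the model: C~ (intra), gamma~ (inter).

    Sigma = J^-1; C~^t is the average diagonal d x d block over cells of type
    t; gamma~^tt' averages the off-diagonal blocks over cell pairs (p != q
    when t = t'), matching the empirical estimator so the two are directly
    comparable.
    """
    if isinstance(model_or_J, MaxEntModel):
        J, graph, d = model_or_J.J, model_or_J.graph, model_or_J.n_pc
    else:
        J, d = np.asarray(model_or_J), int(n_pc)
    try:
        cf = linalg.cho_factor(J)
    except linalg.LinAlgError as exc:
        raise ValueError("J is singular or not positive definite") from exc
    Sigma = linalg.cho_solve(cf, np.eye(J.shape[0]))
    return type_covariance_reduction(Sigma, graph, d)


def type_covariance_reduction(
    Sigma: np.ndarray, graph: EmbryoGraph, n_pc: int
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], np.ndarray]]:
    """Reduce a full (cell, PC) covariance to type-level (intra, inter).

    Applies the same averaging as the empirical estimators, so the output is
    directly comparable to measured covariances (works equally on a model
    Sigma or a Monte-Carlo estimate of it).
    """
    n, d = graph.n_cells, n_pc
    blocks = Sigma.reshape(n, d, n, d).transpose(0, 2, 1, 3)  # (p, q, i, j)
    tc = graph.type_indices()
    intra = {t: blocks[cells, cells].mean(axis=0) for t, cells in tc.items()}
    inter: dict[tuple[str, str], np.ndarray] = {}
    for ta, ca in tc.items():
        for tb, cb in tc.items():
            sub = blocks[np.ix_(ca, cb)]
            if ta == tb:
                m = len(ca)
                if m < 2:
                    inter[(ta, tb)] = np.full((d, d), np.nan)
                    continue
                mask = ~np.eye(m, dtype=bool)
                inter[(ta, tb)] = sub[mask].mean(axis=0)
            else:
                inter[(ta, tb)] = sub.reshape(-1, d, d).mean(axis=0)
    return intra, inter


def fit_quality(
    empirical_intra: Mapping[str, np.ndarray],
    empirical_inter: Mapping[tuple[str, str], np.ndarray],
    predicted_intra: Mapping[str, np.ndarray],
    predicted_inter: Mapping[tuple[str, str], np.ndarray],
    include_intra: bool = True,
) -> float:
    """eta = 1 - sum_a (C_a - C~_a)^2 / sum_a C_a^2 over the covariance set."""
    emp, pred = [], []
    if include_intra:
        for t in empirical_intra:
            emp.append(np.asarray(empirical_intra[t]).ravel())
            pred.append(np.asarray(predicted_intra[t]).ravel())
    types = sorted({t for t, _ in empirical_inter}, key=str)
    for a, ta in enumerate(types):
        for tb in types[a + 1:]:
            key = (ta, tb) if (ta, tb) in empirical_inter else (tb, ta)
            e = np.asarray(empirical_inter[key]).ravel()
            p = np.asarray(predicted_inter[key]).ravel()
            ok = ~(np.isnan(e) | np.isnan(p))
            emp.append(e[ok])
            pred.append(p[ok])
    emp_v = np.concatenate(emp)
    pred_v = np.concatenate(pred)
    denom = float(np.sum(emp_v**2))
    if denom == 0:
        raise ValueError("all-zero empirical covariance set: eta undefined")
    return 1.0 - float(np.sum((emp_v - pred_v) ** 2)) / denom


def targets_from_model(terms: _Terms, J: np.ndarray) -> np.ndarray:
    """Exact constraint statistics of an existing model (tr(Sigma B_a))."""
    Sigma = np.linalg.inv(J)
    return terms.statistics(Sigma)


def constraint_targets(
    terms: _Terms,
    spec: ConstraintSpec,
    graph: EmbryoGraph,
    intra: Mapping[str, np.ndarray],
    inter: Mapping[tuple[str, str], np.ndarray],
) -> np.ndarray:
    """Lift type-level covariances to constraint targets (tr(Sigma B) units).

    Cell identities within a type are unknown in the data, so the pair-level
    covariance <x_pi x_qj> entering an adjacency-averaged constraint is
    estimated by the type-level gamma^{t(p) t(q)}_ij.  Intra constraints use
    C^t directly.
    """
    d = terms.n_pc
    type_of_idx = np.array([terms.types.index(graph.type_of[c]) for c in graph.cell_names])
    adj = {label: np.asarray(a) for label, a in spec.sym_terms}
    adj.update({label: np.asarray(a) for label, a in spec.dir_terms})
    # pair-level covariance estimate per (p, q): gamma^{t(p) t(q)}
    gamma = np.empty((len(terms.types), len(terms.types), d, d))
    for a, ta in enumerate(terms.types):
        for b, tb in enumerate(terms.types):
            gamma[a, b] = inter[(ta, tb)]
    targets = np.empty(terms.n_params)
    for a, (kind, key, i, j) in enumerate(terms.meta):
        if kind == "intra":
            n_t = len(terms.type_cells[key])
            C = np.asarray(intra[key])
            targets[a] = n_t * (2 - (i == j)) * C[i, j]
        else:
            A = adj[key]
            ps, qs = np.nonzero(A)
            lam = gamma[type_of_idx[ps], type_of_idx[qs]]
            if kind in ("sym", "dirsym"):
                # tr(Sigma B) = sum_pq Psi_pq (Sigma_(pi)(qj) + Sigma_(pj)(qi))
                targets[a] = float(np.sum(lam[:, i, j]) + (np.sum(lam[:, j, i]) if i != j else 0))
            else:
                targets[a] = float(np.sum(lam[:, i, j]))
    return targets


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    eta: float | None
    matched: np.ndarray
    converged: bool
    iterations: int
    predicted_intra: dict | None = None
    predicted_inter: dict | None = None

    def __post_init__(self) -> None:
        if self.eta is not None and self.eta > 1 + 1e-12:
            raise ValueError("eta cannot exceed 1")


def _chol(J: np.ndarray) -> np.ndarray | None:
    """Lower Cholesky factor of J, or None if J is not PD."""
    try:
        return np.linalg.cholesky(J)
    except np.linalg.LinAlgError:
        return None


def _nld_from_chol(L: np.ndarray) -> float:
    return -2.0 * float(np.sum(np.log(np.diag(L))))


def _sigma_from_chol(L: np.ndarray) -> np.ndarray:
    """J^-1 from its Cholesky factor (LAPACK dpotri)."""
    inv, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:  # pragma: no cover - dpotri cannot fail on a valid factor
        return np.linalg.inv(L @ L.T)
    return np.tril(inv) + np.tril(inv, -1).T


def _neg_logdet(J: np.ndarray) -> float | None:
    """-log det J via Cholesky, or None if J is not PD."""
    L = _chol(J)
    return None if L is None else _nld_from_chol(L)


def _init_theta(terms: _Terms, targets: np.ndarray) -> np.ndarray:
    """Feasible start: M^t = inv(target intra covariance), S = U = 0."""
    d = terms.n_pc
    theta = np.zeros(terms.n_params)
    for t in terms.types:
        n_t = len(terms.type_cells[t])
        C = np.zeros((d, d))
        for a, (kind, key, i, j) in enumerate(terms.meta):
            if kind == "intra" and key == t:
                C[i, j] = C[j, i] = targets[a] / (n_t * (2 - (i == j)))
        lam = np.linalg.eigvalsh(C)
        if lam[0] <= 0:
            raise ValueError(
                f"empirical intra covariance for type {t!r} is not positive "
                f"definite (smallest eigenvalue {lam[0]:.3e}); constraints infeasible"
            )
        Minv = np.linalg.inv(C)
        for a, (kind, key, i, j) in enumerate(terms.meta):
            if kind == "intra" and key == t:
                theta[a] = Minv[i, j]
    return theta


def _newton_fit(
    terms: _Terms,
    targets: np.ndarray,
    theta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, bool, int]:
    """Minimize the dual h(theta) = -logdet J + theta . targets by Newton."""
    scale = max(float(np.max(np.abs(targets))), 1e-12)
    theta = _init_theta(terms, targets) if theta0 is None else theta0.copy()
    J = terms.assemble_J(theta)
    h = _neg_logdet(J)
    if h is None:
        raise ValueError("initial J not positive definite")
    h += float(theta @ targets)
    for it in range(max_iter):
        Sigma = np.linalg.inv(terms.assemble_J(theta))
        stats = terms.statistics(Sigma)
        grad = targets - stats
        if np.max(np.abs(grad)) < tol * scale:
            return theta, True, it
        H = terms.hessian(Sigma)
        # regularize mildly for numerical safety
        H[np.diag_indices_from(H)] += 1e-12 * np.trace(H) / len(H)
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = -grad / max(np.linalg.norm(H), 1.0)
        # backtracking line search keeping J PD (Armijo on the dual)
        gd = float(grad @ step)
        if gd >= 0:
            step = -grad
            gd = float(grad @ step)
        gamma = 1.0
        for _ in range(60):
            cand = theta + gamma * step
            hc = _neg_logdet(terms.assemble_J(cand))
            if hc is not None:
                hc += float(cand @ targets)
                if hc <= h + 1e-4 * gamma * gd:
                    break
            gamma *= 0.5
        else:
            # stalled line search (typically near-singular Hessian from
            # overlapping adjacencies); accept if within the matching tolerance
            Sigma = np.linalg.inv(terms.assemble_J(theta))
            resid = np.max(np.abs(targets - terms.statistics(Sigma)))
            return theta, bool(resid < MATCH_RTOL * scale), it
        theta, h = cand, hc
    Sigma = np.linalg.inv(terms.assemble_J(theta))
    converged = bool(np.max(np.abs(targets - terms.statistics(Sigma))) < MATCH_RTOL * scale)
    return theta, converged, max_iter


def lift_discrepancy(
    terms: _Terms, spec: ConstraintSpec, graph: EmbryoGraph, J: np.ndarray
) -> np.ndarray:
    """Difference between the model's type-lifted and exact constraint stats.

    Empirical targets are built from type-level covariances, which average
    each pair constraint over all same-type cell pairs; the model's exact
    statistic averages over the adjacency pairs only.  The difference is the
    systematic bias the lift introduces for this model.
    """
    pi, pg = predict_type_covariances(J, graph, terms.n_pc)
    lifted = constraint_targets(terms, spec, graph, pi, pg)
    return lifted - terms.statistics(np.linalg.inv(J))


def fit_maxent(
    cov: CovarianceSet | None,
    spec: ConstraintSpec,
    graph: EmbryoGraph,
    n_pc: int | None = None,
    targets: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    include_intra_in_eta: bool = True,
    lift_consistent: bool = True,
    n_outer: int = 30,
) -> tuple[MaxEntModel, FitReport]:
    """Fit couplings by moment matching.

    Targets come either from an empirical :class:`CovarianceSet` (type-level
    covariances lifted to pair constraints) or from an explicit target vector
    (e.g. the exact statistics of a known model).  With no interaction terms
    the solution is closed form, M^t = (C^t)^-1; otherwise the convex dual is
    minimized by Newton iteration with a PD-safeguarded backtracking line
    search.  Raises if the targets are infeasible (no PD J matches).

    When fitting from a CovarianceSet with ``lift_consistent`` (default), an
    outer fixed-point loop corrects the lift bias: cell identities are
    scrambled within a type, so pair constraints can only be estimated by
    type-level averages, which dilute cross-type adjacency statistics.  The
    loop adjusts targets until the model's own type-lifted statistics match
    the empirical ones, making the estimator consistent under scrambling.
    """
    if n_pc is None:
        if cov is None:
            raise ValueError("n_pc is required when fitting explicit targets")
        n_pc = next(iter(cov.intra.values())).shape[0]
    terms = build_terms(spec, graph, n_pc)
    from_cov = targets is None
    if from_cov:
        if cov is None:
            raise ValueError("either cov or targets must be given")
        targets = constraint_targets(terms, spec, graph, cov.intra, cov.inter)

    if not spec.sym_terms and not spec.dir_terms:
        theta = _init_theta(terms, targets)  # closed form: M = C^-1
        converged, iters = True, 0
    else:
        theta, converged, iters = _newton_fit(terms, targets, tol=tol, max_iter=max_iter)
        if converged and from_cov and lift_consistent:
            # damped fixed-point iteration on the lift-bias correction; if a
            # corrected target set becomes infeasible the last feasible fit
            # is kept (the correction is a refinement, not a requirement)
            scale = max(np.max(np.abs(targets)), 1e-12)
            adj = np.zeros_like(targets)
            best = (theta.copy(), adj.copy())
            for _ in range(n_outer):
                delta = lift_discrepancy(terms, spec, graph, terms.assemble_J(theta))
                if np.max(np.abs(delta - adj)) < 1e-9 * scale:
                    break
                adj = adj + 0.5 * (delta - adj)
                if np.max(np.abs(adj)) > 10 * scale:  # diverging correction
                    theta, adj = best
                    break
                try:
                    theta2, ok, it2 = _newton_fit(
                        terms, targets - adj, theta0=theta, tol=tol, max_iter=max_iter
                    )
                except (ValueError, RuntimeError):
                    ok = False
                iters += it2 if ok else 0
                if not ok:
                    theta, adj = best
                    break
                theta = theta2
                best = (theta.copy(), adj.copy())
            targets = targets - adj
        if not converged:
            Sigma = np.linalg.inv(terms.assemble_J(theta))
            resid = targets - terms.statistics(Sigma)
            raise RuntimeError(
                "moment matching did not converge; max residual "
                f"{np.max(np.abs(resid)):.3e} (targets may be infeasible)"
            )
    M, S, U = _theta_to_params(terms, theta)
    J = terms.assemble_J(theta)
    model = MaxEntModel(spec, graph, n_pc, M, S, U, J)
    Sigma = np.linalg.inv(J)
    matched = targets - terms.statistics(Sigma)
    eta = None
    pi = pg = None
    if cov is not None:
        pi, pg = predict_type_covariances(model)
        eta = fit_quality(cov.intra, cov.inter, pi, pg, include_intra=include_intra_in_eta)
    return model, FitReport(eta=eta, matched=matched, converged=converged,
                            iterations=iters, predicted_intra=pi, predicted_inter=pg)


# ---------------------------------------------------------------------------
# modes
# ---------------------------------------------------------------------------

@dataclass
class ModeSet:
    """Eigen-decomposition of the model covariance: collective modes."""

    eigenvalues: np.ndarray       # descending, >= 0
    modes: np.ndarray             # (D, D), column beta = mode phi^beta
    variance_fractions: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("covariance eigenvalues must be non-negative")
        if not np.isclose(self.variance_fractions.sum(), 1.0):
            raise ValueError("variance fractions must sum to 1")


def mode_decomposition(model_or_J: MaxEntModel | np.ndarray) -> ModeSet:
    """Collective modes: Sigma = sum_beta lambda_beta phi^beta (phi^beta)^T.

    Eigenvalues are sorted descending; each mode's sign is fixed so its
    largest-magnitude entry is positive.
    """
    J = model_or_J.J if isinstance(model_or_J, MaxEntModel) else np.asarray(model_or_J)
    Sigma = np.linalg.inv(J)
    lam, vec = np.linalg.eigh(Sigma)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    for b in range(vec.shape[1]):
        k = np.argmax(np.abs(vec[:, b]))
        if vec[k, b] < 0:
            vec[:, b] = -vec[:, b]
    return ModeSet(lam, vec, lam / lam.sum())


def rotation_baseline(
    model_or_J: MaxEntModel | np.ndarray,
    modes: ModeSet,
    k: int,
    n_rotations: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Variance fraction of the fixed top-k modes under Haar-random rotations.

    For each rotation R the model covariance becomes R Sigma R^T while the
    top-k modes are held fixed; the returned array holds the fraction of the
    rotated model's variance they explain.  For isotropic Sigma the mean is
    k/D analytically, quantifying how special the unrotated alignment is.
    """
    J = model_or_J.J if isinstance(model_or_J, MaxEntModel) else np.asarray(model_or_J)
    Sigma = np.linalg.inv(J)
    D = Sigma.shape[0]
    if k > D:
        raise ValueError("k exceeds state dimension")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Phi = modes.modes[:, :k]
    total = float(np.trace(Sigma))
    fractions = np.empty(n_rotations)
    for r in range(n_rotations):
        A = rng.standard_normal((D, D))
        Q, R = np.linalg.qr(A)
        Q *= np.sign(np.diag(R))  # Haar measure
        W = Q.T @ Phi             # rotated-frame coordinates of fixed modes
        fractions[r] = float(np.einsum("db,de,eb->", W, Sigma, W)) / total
    return fractions
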