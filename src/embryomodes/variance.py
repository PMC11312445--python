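"""Removal of known variance sources and signal-dimension selection.

Before collective fluctuations can be measured, expression must be stripped
of variance with known causes: gene means, mother-specific means (nu_mg),
embryo-specific means (eta_eg), cell-type means (mu_tg), and variation in
developmental staging, modelled as a per-embryo time tau_e along a per-type
tangent alpha_tg (a rank-1-per-type bilinear term fit by alternating least
squares).  What survives is compared against a permutation null that scrambles
each gene column independently across cells -- preserving every gene's
marginal distribution while destroying correlation -- to decide how many
singular components carry signal; cells are then projected onto those
principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class DecomposedExpression:
    """Residual matrix plus everything that was removed from it."""

    Z: np.ndarray
    removed: dict[str, object] = field(default_factory=dict)
    tau: np.ndarray | None = None
    alpha: np.ndarray | None = None
    pcs: np.ndarray | None = None   # (n_keep, genes), orthonormal rows
    x: np.ndarray | None = None     # (cells, n_keep) projection


def center_genes(X: np.ndarray) -> np.ndarray:
    """Subtract each gene's mean over all cells (column centering)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to center")
    return X - X.mean(axis=0, keepdims=True)


def subtract_group_means(
    Y: np.ndarray, grouping: Sequence
) -> tuple[np.ndarray, dict[object, np.ndarray]]:
    """Subtract per-group, per-gene means; returns residual and the means.

    Used for mother means (group = mother), embryo means (group = embryo)
    and cell-type means (group = type).  Singleton groups are zeroed out
    exactly and carry no residual information, which is flagged.
    """
    Y = np.asarray(Y, dtype=float)
    grouping = np.asarray(grouping)
    if len(grouping) != Y.shape[0]:
        raise ValueError("grouping must assign every cell")
    means: dict[object, np.ndarray] = {}
    Z = Y.copy()
    for g in np.unique(grouping):
        mask = grouping == g
        if mask.sum() == 1:
            warnings.warn(f"group {g!r} has a single cell; residual is exactly zero")
        mu = Y[mask].mean(axis=0)
        means[g] = mu
        Z[mask] -= mu
    return Z, means


def fit_temporal_projection(
    Z: np.ndarray,
    embryo_of: Sequence,
    type_of: Sequence,
    max_iter: int = 500,
    rtol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Fit Z_cg ~ tau_e(c) * alpha_t(c)g by alternating least squares.

    tau is one scalar per embryo (developmental time offset), alpha one
    tangent vector per (type, gene).  The model has a scale/sign gauge, fixed
    by ||alpha||_F = 1, sum_e tau_e = 0 (the mean is absorbed into cell-type
    means, which have already been removed), and the largest-magnitude alpha
    entry positive.

    Returns (tau, alpha, Z_residual, info); ``info`` holds embryo/type
    orderings and convergence diagnostics.
    """
    Z = np.asarray(Z, dtype=float)
    embryo_of = np.asarray(embryo_of)
    type_of = np.asarray(type_of)
    embryos = list(np.unique(embryo_of))
    types = list(np.unique(type_of))
    if len(embryos) < 2:
        raise ValueError("need at least 2 embryos to fit a temporal projection")
    e_idx = np.array([embryos.index(e) for e in embryo_of])
    t_idx = np.array([types.index(t) for t in type_of])
    n_e, n_t, n_g = len(embryos), len(types), Z.shape[1]

    rng_free = np.sqrt(np.mean(Z**2, axis=0))
    alpha = np.tile(rng_free / max(np.linalg.norm(rng_free), 1e-300), (n_t, 1))
    alpha /= max(np.linalg.norm(alpha), 1e-300)
    tau = np.zeros(n_e)
    prev = np.inf
    converged = False
    for it in range(max_iter):
        A = alpha[t_idx]                      # (cells, genes)
        num = np.einsum("cg,cg->c", Z, A)
        den = np.einsum("cg,cg->c", A, A)
        tau = np.bincount(e_idx, weights=num, minlength=n_e) / np.maximum(
            np.bincount(e_idx, weights=den, minlength=n_e), 1e-300
        )
        tc = tau[e_idx]
        for t in range(n_t):
            mask = t_idx == t
            denom = float(np.sum(tc[mask] ** 2))
            alpha[t] = (tc[mask] @ Z[mask]) / denom if denom > 0 else 0.0
        resid = Z - tc[:, None] * alpha[t_idx]
        var = float(np.mean(resid**2))
        if prev - var < rtol * max(prev, 1e-300):
            converged = True
            break
        prev = var
    if not converged:
        raise RuntimeError(
            f"temporal projection did not converge in {max_iter} iterations "
            f"(last residual variance {var:.3e})"
        )
    # gauge fixing
    tau = tau - tau.mean()  # the mean shift is a per-type mean, already removed
    scale = np.linalg.norm(alpha)
    if scale > 0:
        alpha = alpha / scale
        tau = tau * scale
    flat = np.argmax(np.abs(alpha))
    if alpha.flat[flat] < 0:
        alpha = -alpha
        tau = -tau
    Z_resid = Z - tau[e_idx][:, None] * alpha[t_idx]
    info = {"embryos": embryos, "types": types, "iterations": it + 1,
            "residual_variance": float(np.mean(Z_resid**2))}
    return tau, alpha, Z_resid, info


def svd_rank_selection(
    Z: np.ndarray, n_perm: int = 100, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Count singular values exceeding the permutation-null threshold.

    Each null draw permutes every gene column independently across cells,
    preserving marginals but destroying correlation.  The threshold is the
    largest singular value seen anywhere in the null ensemble; n_keep is the
    number of observed singular values above it.  (A mean-aggregated
    threshold would be crossed by structureless data about half the time;
    the ensemble maximum keeps that false-keep rate at ~1/(n_perm+1).)
    """
    Z = np.asarray(Z, dtype=float)
    if Z.size == 0:
        raise ValueError("empty matrix")
    if n_perm < 10:
        warnings.warn("n_perm < 10 gives an unstable null threshold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sv = np.linalg.svd(Z, compute_uv=False)
    null_max = np.empty(n_perm)
    n = Z.shape[0]
    for k in range(n_perm):
        perm = np.argsort(rng.random((n, Z.shape[1])), axis=0)
        Znull = np.take_along_axis(Z, perm, axis=0)
        null_max[k] = np.linalg.svd(Znull, compute_uv=False)[0]
    threshold = float(null_max.max())
    n_keep = int(np.sum(sv > threshold))
    return sv, null_max, n_keep


def project_pcs(Z: np.ndarray, n_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """Project onto the top-n_keep principal components of the residual.

    Returns (pcs, x) with ``pcs`` the orthonormal loading rows (n_keep x
    genes) and ``x = Z @ pcs.T`` the per-cell coordinates.  Singular values
    below the retained set are treated as noise and dropped.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    Z = np.asarray(Z, dtype=float)
    rank = min(Z.shape)
    if n_keep > rank:
        warnings.warn(f"n_keep={n_keep} exceeds rank {rank}; capping")
        n_keep = rank
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pcs = vt[:n_keep]
    return pcs, Z @ pcs.T


def decompose_zygotic(
    X: np.ndarray,
    type_of: Sequence,
    embryo_of: Sequence,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    n_keep: int | None = None,
) -> DecomposedExpression:
    """Full zygotic chain: center -> type means -> temporal projection -> PCs."""
    Y = center_genes(X)
    Z, mu = subtract_group_means(Y, type_of)
    tau, alpha, Z, t_info = fit_temporal_projection(Z, embryo_of, type_of)
    sv, null_max, auto_keep = svd_rank_selection(Z, n_perm=n_perm, seed=seed)
    keep = auto_keep if n_keep is None else n_keep
    dec = DecomposedExpression(Z=Z, removed={"mu_type": mu, "temporal": t_info,
                                             "singular_values": sv, "null_max": null_max,
                                             "n_keep_auto": auto_keep},
                               tau=tau, alpha=alpha)
    if keep >= 1:
        dec.pcs, dec.x = project_pcs(Z, keep)
    return dec


def decompose_maternal(
    X: np.ndarray,
    mother_of: Sequence,
    embryo_of: Sequence,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    n_keep: int | None = None,
) -> DecomposedExpression:
    """Maternal chain: center -> mother means -> embryo means -> PCs."""
    Y = center_genes(X)
    Z, nu = subtract_group_means(Y, mother_of)
    Z, eta = subtract_group_means(Z, embryo_of)
    sv, null_max, auto_keep = svd_rank_selection(Z, n_perm=n_perm, seed=seed)
    keep = auto_keep if n_keep is None else n_keep
    dec = DecomposedExpression(Z=Z, removed={"nu_mother": nu, "eta_embryo": eta,
                                             "singular_values": sv, "null_max": null_max,
                                             "n_keep_auto": auto_keep})
    if keep >= 1:
        dec.pcs, dec.x = project_pcs(Z, keep)
    return dec
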