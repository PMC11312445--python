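"""Intra- and inter-type covariance estimation and shuffle tests.

Because cell identities within a type are lost at dissociation, covariances
are only measurable at the cell-type level: the average covariance between a
cell of type t and a cell of type t' within the same embryo (gamma), and the
within-cell covariance averaged over cells of a type (C).  The expectation is
taken as the average over embryos of within-embryo pair averages; same-type
pairs exclude the c = c' diagonal.

Collective variation is detected by a permutation test on the deviation
statistic Delta = sum over components of ((gamma - gamma_bar) / sigma)^2,
where gamma_bar and sigma are the componentwise mean and SD over the shuffled
ensemble plus the unshuffled data.  Shuffling across embryos permutes cells
of the same type between embryos; shuffling within an embryo permutes the
expression rows among the cells of one embryo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


def _group_sums(x: np.ndarray, t_idx: np.ndarray, e_idx: np.ndarray,
                n_types: int, n_embryos: int):
    """Per-(embryo, type) sums, outer-product sums, and counts."""
    d = x.shape[1]
    S = np.zeros((n_embryos, n_types, d))
    P = np.zeros((n_embryos, n_types, d, d))
    N = np.zeros((n_embryos, n_types))
    np.add.at(S, (e_idx, t_idx), x)
    np.add.at(P, (e_idx, t_idx), x[:, :, None] * x[:, None, :])
    np.add.at(N, (e_idx, t_idx), 1.0)
    return S, P, N


def _cov_arrays(x: np.ndarray, t_idx: np.ndarray, e_idx: np.ndarray,
                n_types: int, n_embryos: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (intra, inter) covariance arrays.

    intra: (T, d, d) with nan where a type never occurs;
    inter: (T, T, d, d) averaged over embryos where both types are present
    (same-type entries average over ordered pairs c != c').
    """
    d = x.shape[1]
    S, P, N = _group_sums(x, t_idx, e_idx, n_types, n_embryos)
    with np.errstate(invalid="ignore", divide="ignore"):
        # intra: mean over cells within embryo, then over embryos with the type
        C_e = P / np.maximum(N, 1)[:, :, None, None]
        has = (N > 0).astype(float)
        intra = np.einsum("etij,et->tij", C_e, has) / np.maximum(
            has.sum(axis=0), 1
        )[:, None, None]
        intra[has.sum(axis=0) == 0] = np.nan

        # inter: outer(S_t, S_t') per embryo; diagonal-corrected when t == t'
        G = np.einsum("eti,euj->etuij", S, S)
        n_pairs = N[:, :, None] * N[:, None, :]
        for t in range(n_types):
            G[:, t, t] -= P[:, t]
            n_pairs[:, t, t] = N[:, t] * (N[:, t] - 1)
        valid = (n_pairs > 0).astype(float)
        G = np.where(n_pairs[:, :, :, None, None] > 0,
                     G / np.maximum(n_pairs, 1)[:, :, :, None, None], 0.0)
        denom = valid.sum(axis=0)
        inter = np.einsum("etuij,etu->tuij", G, valid) / np.maximum(denom, 1)[:, :, None, None]
        inter[denom == 0] = np.nan
    return intra, inter


def _encode(labels: Sequence, order: list | None = None) -> tuple[np.ndarray, list]:
    order = list(order) if order is not None else sorted(set(labels), key=str)
    lut = {v: i for i, v in enumerate(order)}
    return np.array([lut[v] for v in labels]), order


@dataclass
class CovarianceSet:
    """Empirical type-level covariances with resampling draws.

    ``intra[t]`` is the d x d within-cell covariance of type t; ``inter[(t,
    t')]`` the d x d covariance between a type-t and a type-t' cell of the
    same embryo.  ``draws`` holds (intra, inter) replicates from posterior
    resampling x embryo bootstrap.
    """

    types: list[str]
    intra: dict[str, np.ndarray]
    inter: dict[tuple[str, str], np.ndarray]
    draws: list[tuple[dict, dict]] = field(default_factory=list)

    def percentile(self, q: float) -> tuple[dict, dict]:
        """Componentwise percentile over draws (e.g. 25/75 for error bars)."""
        if not self.draws:
            raise ValueError("no draws available")
        intra_q = {
            t: np.percentile([d[0][t] for d in self.draws], q, axis=0) for t in self.types
        }
        inter_q = {
            k: np.percentile([d[1][k] for d in self.draws], q, axis=0) for k in self.inter
        }
        return intra_q, inter_q


def intra_type_cov(
    x: np.ndarray, type_of: Sequence, embryo_of: Sequence, types: list | None = None
) -> dict[str, np.ndarray]:
    """C^t_ij: per-cell outer products averaged over cells of type t and embryos."""
    x = np.asarray(x, dtype=float)
    t_idx, types = _encode(type_of, types)
    e_idx, embryos = _encode(embryo_of)
    intra, _ = _cov_arrays(x, t_idx, e_idx, len(types), len(embryos))
    out = {}
    for k, t in enumerate(types):
        if np.any(np.isnan(intra[k])):
            raise ValueError(f"type {t!r} has no cells")
        out[t] = intra[k]
    return out


def inter_type_cov(
    x: np.ndarray, type_of: Sequence, embryo_of: Sequence, types: list | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """gamma^tt'_ij: average within-embryo covariance between type-t and
    type-t' cells (ordered pairs, c != c' for t = t').

    Entries for pairs never co-present in an embryo are nan (flagged missing).
    """
    x = np.asarray(x, dtype=float)
    t_idx, types = _encode(type_of, types)
    e_idx, embryos = _encode(embryo_of)
    _, inter = _cov_arrays(x, t_idx, e_idx, len(types), len(embryos))
    return {(ta, tb): inter[a, b] for a, ta in enumerate(types) for b, tb in enumerate(types)}


def resample_covariances(
    draw_x: Callable[[np.random.Generator], tuple[np.ndarray, Sequence, Sequence]],
    n_draws: int,
    n_boot: int,
    seed: int | np.random.Generator,
    types: list | None = None,
) -> CovarianceSet:
    """Covariances with uncertainty from posterior resampling x bootstrap.

    ``draw_x(rng)`` must return one posterior draw already pushed through the
    pipeline: (x, type_labels, embryo_labels).  Each replicate pairs one
    posterior draw with one bootstrap resample of embryos (with replacement);
    the point estimate is the mean over replicates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_boot < 2:
        warnings.warn("n_boot < 2: no percentile intervals will be meaningful")
    draws: list[tuple[dict, dict]] = []
    types_seen = types
    for _ in range(n_draws):
        x, type_labels, embryo_labels = draw_x(rng)
        x = np.asarray(x, dtype=float)
        t_idx, types_seen = _encode(type_labels, types_seen)
        e_idx, embryos = _encode(embryo_labels)
        n_e = len(embryos)
        if n_e < 3:
            raise ValueError("need at least 3 embryos for the embryo bootstrap")
        cells_of = [np.flatnonzero(e_idx == e) for e in range(n_e)]
        for _ in range(max(n_boot, 1)):
            chosen = rng.integers(0, n_e, size=n_e)
            rows = np.concatenate([cells_of[e] for e in chosen])
            boot_e = np.concatenate(
                [np.full(len(cells_of[e]), k) for k, e in enumerate(chosen)]
            )
            intra, inter = _cov_arrays(x[rows], t_idx[rows], boot_e,
                                       len(types_seen), n_e)
            draws.append((
                {t: intra[k] for k, t in enumerate(types_seen)},
                {(ta, tb): inter[a, b]
                 for a, ta in enumerate(types_seen) for b, tb in enumerate(types_seen)},
            ))
    intra_pt = {t: np.nanmean([d[0][t] for d in draws], axis=0) for t in types_seen}
    inter_pt = {k: np.nanmean([d[1][k] for d in draws], axis=0) for k in draws[0][1]}
    return CovarianceSet(list(types_seen), intra_pt, inter_pt, draws)


@dataclass
class ShuffleTestResult:
    delta_observed: float
    delta_null: np.ndarray
    p_value: float
    mode: str
    gamma_bar: np.ndarray
    sigma: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        if self.delta_observed < 0:
            raise ValueError("Delta must be non-negative")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _shuffled_rows(rng, mode: str, t_idx: np.ndarray, e_idx: np.ndarray) -> np.ndarray:
    """Row permutation implementing one shuffle of the requested mode."""
    perm = np.arange(len(t_idx))
    if mode == "across":
        for t in np.unique(t_idx):
            rows = np.flatnonzero(t_idx == t)
            perm[rows] = rows[rng.permutation(len(rows))]
    elif mode == "within":
        for e in np.unique(e_idx):
            rows = np.flatnonzero(e_idx == e)
            perm[rows] = rows[rng.permutation(len(rows))]
    else:
        raise ValueError(f"mode must be 'within' or 'across', got {mode!r}")
    return perm


def shuffle_test(
    x: np.ndarray,
    type_of: Sequence,
    embryo_of: Sequence,
    mode: str,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    include_intra: bool = False,
) -> ShuffleTestResult:
    """Permutation test for collective variation via the Delta statistic.

    ``across`` permutes cells of the same cell type between embryos (each
    embryo keeps its per-type cell counts); ``within`` permutes the
    expression rows among the cells of each embryo (each embryo keeps its
    multiset of rows).  By default Delta sums over inter-type components
    (t != t', all PC pairs); set ``include_intra`` to add the intra-type
    covariances.  p = (1 + #{Delta_null >= Delta_obs}) / (n_shuffles + 1).
    """
    x = np.asarray(x, dtype=float)
    t_idx, types = _encode(type_of)
    e_idx, embryos = _encode(embryo_of)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T, d = len(types), x.shape[1]

    def components(xs: np.ndarray) -> np.ndarray:
        intra, inter = _cov_arrays(xs, t_idx, e_idx, T, len(embryos))
        parts = [inter[a, b].ravel() for a in range(T) for b in range(a + 1, T)]
        if include_intra:
            parts += [intra[t].ravel() for t in range(T)]
        return np.concatenate(parts) if parts else np.empty(0)

    gammas = np.empty((n_shuffles + 1, components(x).size))
    gammas[0] = components(x)
    for k in range(n_shuffles):
        gammas[k + 1] = components(x[_shuffled_rows(rng, mode, t_idx, e_idx)])

    keep = ~np.any(np.isnan(gammas), axis=0)
    gammas = gammas[:, keep]
    gamma_bar = gammas.mean(axis=0)
    sigma = gammas.std(axis=0, ddof=1)
    ok = sigma > 0
    if not np.all(ok):
        warnings.warn(f"{int(np.sum(~ok))} covariance components have zero "
                      "shuffle variance and were dropped from Delta")
    z = (gammas[:, ok] - gamma_bar[ok]) / sigma[ok]
    deltas = np.sum(z**2, axis=1)
    p = (1 + int(np.sum(deltas[1:] >= deltas[0]))) / (n_shuffles + 1)
    return ShuffleTestResult(
        delta_observed=float(deltas[0]),
        delta_null=deltas[1:],
        p_value=float(p),
        mode=mode,
        gamma_bar=gamma_bar,
        sigma=sigma,
        n_components=int(np.sum(ok)),
    )


def delta_statistic(gamma: np.ndarray, gamma_bar: np.ndarray, sigma: np.ndarray) -> float:
    """Delta = sum_k ((gamma_k - gamma_bar_k) / sigma_k)^2 over components."""
    gamma, gamma_bar, sigma = map(np.asarray, (gamma, gamma_bar, sigma))
    ok = sigma > 0
    return float(np.sum(((gamma[ok] - gamma_bar[ok]) / sigma[ok]) ** 2))
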