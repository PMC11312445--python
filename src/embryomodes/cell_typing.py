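"""Robust hierarchical cell-type identification.

Cell types in a fixed-lineage embryo obey three structural principles that
generic clustering ignores: (1) only a few genes discriminate between types,
so clustering happens on informative genes found from trial clusters; (2) a
true cell type has the same number of cells in every complete embryo, so
cluster assignment is balanced per embryo (solved as an optimal assignment of
each embryo's cells to cluster slots); (3) a true split must survive
perturbation -- resampling expression from its posterior and subsampling
embryos must reproduce the same clusters, and the resulting consistency score
must beat the score of null data in which cells are randomly reassigned to
embryos.  These principles are applied recursively: a node is split only if
some split is accepted against its null, otherwise it becomes a leaf (a cell
type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .io import ExpressionPosterior


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index between two flat partitions (vectorized)."""
    a = np.asarray(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(np.asarray(b), return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    C = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    comb = lambda x: (x * (x - 1) // 2).sum()
    sum_c = comb(C)
    sum_a, sum_b = comb(C.sum(axis=1)), comb(C.sum(axis=0))
    total = len(a) * (len(a) - 1) // 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_c - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# small k-means (numpy, seeded) used for trial clusters and initialization
# ---------------------------------------------------------------------------

def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
            n_init: int = 2, max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Plain k-means with k-means++ seeding; returns (labels, centroids)."""
    n = X.shape[0]
    best = (None, None, np.inf)
    for _ in range(n_init):
        centers = np.empty((k, X.shape[1]))
        centers[0] = X[rng.integers(n)]
        d2 = np.sum((X - centers[0]) ** 2, axis=1)
        for j in range(1, k):
            tot = d2.sum()
            probs = d2 / tot if tot > 0 else np.full(n, 1.0 / n)
            centers[j] = X[rng.choice(n, p=probs)]
            d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            dist = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            new = dist.argmin(axis=1)
            if np.array_equal(new, labels):
                labels = new
                break
            labels = new
            for j in range(k):
                mask = labels == j
                if mask.any():
                    centers[j] = X[mask].mean(axis=0)
        inertia = float(((X - centers[labels]) ** 2).sum())
        if inertia < best[2]:
            best = (labels.copy(), centers.copy(), inertia)
    return best[0], best[1]


# ---------------------------------------------------------------------------
# informative genes
# ---------------------------------------------------------------------------

def find_informative_genes(
    X: np.ndarray, trial_assignment: Sequence[int], top_k: int = 20
) -> list[tuple[int, float]]:
    """Rank genes by how well they discriminate between trial clusters.

    The score is the Kruskal-Wallis rank statistic across the trial clusters
    (for two clusters this is the squared standardized rank-sum).  Constant
    genes score zero; if every gene is constant an empty list is returned
    with a warning.  Returns (gene index, score) pairs, best first, at most
    ``top_k`` of them.
    """
    labels = np.asarray(trial_assignment)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 trial clusters")
    scores = np.zeros(X.shape[1])
    masks = [labels == g for g in groups]
    for gi in range(X.shape[1]):
        col = X[:, gi]
        if np.all(col == col[0]):
            continue
        try:
            scores[gi] = stats.kruskal(*[col[m] for m in masks]).statistic
        except ValueError:  # all values identical within the test
            scores[gi] = 0.0
    if np.all(scores == 0):
        warnings.warn("no informative genes: all columns constant")
        return []
    order = np.argsort(-scores, kind="stable")[:top_k]
    return [(int(g), float(scores[g])) for g in order if scores[g] > 0]


# ---------------------------------------------------------------------------
# balanced (structure-constrained) clustering
# ---------------------------------------------------------------------------

def _slot_counts(labels: np.ndarray, complete_embryos: list, embryo_ids: np.ndarray,
                 k: int, embryo_size: int) -> np.ndarray:
    """Integer cells-per-cluster-per-embryo by largest-remainder rounding."""
    mask = np.isin(embryo_ids, complete_embryos)
    raw = np.array([np.sum(labels[mask] == j) for j in range(k)], dtype=float)
    raw = raw / max(len(complete_embryos), 1)
    base = np.maximum(np.floor(raw).astype(int), 1)  # every cluster keeps a slot
    while base.sum() > embryo_size:
        base[np.argmax(base)] -= 1
    rem = raw - base
    while base.sum() < embryo_size:
        j = int(np.argmax(np.where(base > 0, rem, -np.inf)))
        base[j] += 1
        rem[j] -= 1
    return base


def structured_cluster(
    X: np.ndarray,
    embryo_ids: Sequence,
    k: int,
    rng: np.random.Generator | int = 0,
    max_iter: int = 30,
    init_centers: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """k clusters with equal per-embryo sizes across complete embryos.

    Complete embryos (those with the modal cell count) are assigned by
    solving, per embryo, an optimal assignment of cells to cluster slots
    against the current centroids; incomplete embryos are assigned to the
    nearest centroid.  Iterated to convergence.  Returns (labels, info);
    info flags low separation (degenerate input).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    embryo_ids = np.asarray(embryo_ids)
    uniq, counts = np.unique(embryo_ids, return_counts=True)
    embryo_size = int(np.max(counts))
    complete = [e for e, c in zip(uniq, counts) if c == embryo_size]
    if k > embryo_size:
        raise ValueError(f"k={k} incompatible with embryo size {embryo_size}: "
                         "no integer slot allocation exists")
    if init_centers is not None:
        centers = init_centers.copy()
        labels = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2).argmin(axis=1)
    else:
        labels, centers = _kmeans(X, k, rng)
    slots = _slot_counts(labels, complete, embryo_ids, k, embryo_size)
    slot_labels = np.repeat(np.arange(k), slots)
    rows_of = {e: np.flatnonzero(embryo_ids == e) for e in uniq}
    for _ in range(max_iter):
        new = labels.copy()
        for e in uniq:
            rows = rows_of[e]
            dist = ((X[rows, None, :] - centers[None]) ** 2).sum(axis=2)
            if e in complete:
                cost = dist[:, slot_labels]
                r, c = linear_sum_assignment(cost)
                new[rows[r]] = slot_labels[c]
            else:
                new[rows] = dist.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
    within = float(((X - centers[labels]) ** 2).sum())
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    info = {
        "slots": slots,
        "low_separation": total <= 0 or (total - within) / max(total, 1e-300) < 0.1,
    }
    return labels, info


# ---------------------------------------------------------------------------
# consistency scoring against an embryo-shuffled null
# ---------------------------------------------------------------------------

def _one_consistency(
    X: np.ndarray,
    eps: np.ndarray,
    embryo_ids: np.ndarray,
    k: int,
    n_resamples: int,
    subsample_frac: float,
    rng: np.random.Generator,
) -> float:
    """Mean ARI between the reference split and perturbed re-clusterings.

    Perturbation = one posterior draw plus a subsample of whole embryos
    (keeping the per-embryo balance constraint meaningful); agreement is the
    adjusted Rand index on the retained cells.
    """
    reference, _ = structured_cluster(X, embryo_ids, k, rng=rng)
    uniq = np.unique(embryo_ids)
    n_sub = max(2, int(np.ceil(subsample_frac * len(uniq))))
    aris = np.empty(n_resamples)
    for r in range(n_resamples):
        draw = X + eps * rng.standard_normal(X.shape)
        chosen = rng.choice(uniq, size=n_sub, replace=False)
        rows = np.flatnonzero(np.isin(embryo_ids, chosen))
        # each re-clustering runs the full algorithm (fresh initialization):
        # a robust split must survive perturbation *and* re-initialization
        lab, _ = structured_cluster(draw[rows], embryo_ids[rows], k, rng=rng)
        aris[r] = adjusted_rand(reference[rows], lab)
    return float(aris.mean())


def consistency_score(
    X: np.ndarray,
    eps: np.ndarray,
    embryo_ids: Sequence,
    k: int,
    n_resamples: int = 50,
    subsample_frac: float = 0.8,
    seed: int | np.random.Generator = 0,
    n_null: int = 19,
) -> tuple[float, np.ndarray]:
    """Split-consistency score and its embryo-shuffled null distribution.

    The score is the mean ARI over ``n_resamples`` perturbed re-clusterings
    against the reference split.  Each null replicate randomly reassigns
    cells to embryos (destroying the per-embryo type structure the balance
    constraint relies on) and is scored identically.  A split is accepted
    when the observed score exceeds the null's 95th percentile; with the
    default 19 null replicates that is the null maximum, giving an exact 5%
    false-accept rate under exchangeability.
    """
    if n_resamples < 20:
        warnings.warn("n_resamples < 20 gives an unstable consistency estimate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    embryo_ids = np.asarray(embryo_ids)
    score = _one_consistency(X, eps, embryo_ids, k, n_resamples, subsample_frac, rng)
    null_scores = np.empty(n_null)
    for b in range(n_null):
        shuffled = embryo_ids[rng.permutation(len(embryo_ids))]
        null_scores[b] = _one_consistency(X, eps, shuffled, k, n_resamples,
                                          subsample_frac, rng)
    return score, null_scores


# ---------------------------------------------------------------------------
# hierarchical typing
# ---------------------------------------------------------------------------

@dataclass
class ClusterNode:
    node_id: int
    cell_ids: list[str]
    children: list["ClusterNode"] = field(default_factory=list)
    informative_genes: list[tuple[str, float]] = field(default_factory=list)
    consistency: float | None = None
    null_threshold: float | None = None
    accepted: bool = False

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class CellTypeAssignment:
    type_of: dict[str, str]
    tree: ClusterNode


@dataclass(frozen=True)
class TypingConfig:
    """Knobs of the hierarchical typing algorithm (all config-exposed)."""

    ks: tuple[int, ...] = (2, 3, 4)
    top_k_genes: int = 20
    n_resamples: int = 50
    n_null: int = 19
    subsample_frac: float = 0.8
    null_quantile: float = 0.95
    min_consistency: float = 0.5
    seed: int = 0


def hierarchical_typing(
    posterior: ExpressionPosterior, config: TypingConfig | None = None
) -> CellTypeAssignment:
    """Recursive structure-constrained typing of all cells.

    At each node: trial clusters (plain k-means on all genes) propose
    informative genes; balanced clustering on those genes proposes a split
    for each candidate k; the split whose consistency score most exceeds its
    null threshold is accepted; recursion stops when nothing is accepted.
    Worst case (e.g. pure noise) the root itself is the single cell type.
    Deterministic for a fixed config seed.
    """
    config = config or TypingConfig()
    rng = np.random.default_rng(config.seed)
    embryo_ids = posterior.embryo_ids()
    cell_ids = np.array([c.cell_id for c in posterior.cells])
    counter = [0]

    def node_stat(X, eps, eids, candidates) -> tuple[float, int]:
        """max over candidate ks of the split-consistency score."""
        best_score, best_k = -np.inf, None
        for k, gidx in candidates:
            s = _one_consistency(X[:, gidx], eps[:, gidx], eids, k,
                                 config.n_resamples, config.subsample_frac, rng)
            if s > best_score:
                best_score, best_k = s, k
        return best_score, best_k

    def split(rows: np.ndarray) -> ClusterNode:
        node = ClusterNode(node_id=counter[0], cell_ids=list(cell_ids[rows]))
        counter[0] += 1
        X, eps, eids = posterior.X[rows], posterior.eps[rows], embryo_ids[rows]
        _, counts = np.unique(eids, return_counts=True)
        per_embryo = int(np.max(counts))
        # trial clusters and informative genes use expression only, so they
        # are identical for observed and embryo-shuffled data; the node
        # statistic is the max consistency score over candidate ks, compared
        # against the same maximum on shuffled nulls (one test per node)
        candidates = []
        for k in config.ks:
            if k > per_embryo or k > len(rows) - 1:
                continue
            trial, _ = _kmeans(X, k, rng)
            genes = find_informative_genes(X, trial, top_k=config.top_k_genes)
            if genes:
                candidates.append((k, [g for g, _ in genes], genes))
        if not candidates:
            return node
        cand_idx = [(k, gidx) for k, gidx, _ in candidates]
        score, k_best = node_stat(X, eps, eids, cand_idx)
        null_scores = np.empty(config.n_null)
        for b in range(config.n_null):
            shuffled = eids[rng.permutation(len(eids))]
            null_scores[b], _ = node_stat(X, eps, shuffled, cand_idx)
        threshold = float(np.quantile(null_scores, config.null_quantile))
        # a robust split must beat the null AND be reproduced outright: the
        # re-clusterings must agree with it in the majority of perturbations
        if not (score > threshold and score >= config.min_consistency):
            return node
        gidx = next(gi for k, gi, _ in candidates if k == k_best)
        genes = next(ge for k, _, ge in candidates if k == k_best)
        labels, _ = structured_cluster(X[:, gidx], eids, k_best, rng=rng)
        node.informative_genes = [(posterior.gene_ids[g], s) for g, s in genes]
        node.consistency = score
        node.null_threshold = threshold
        node.accepted = True
        for j in range(k_best):
            node.children.append(split(rows[labels == j]))
        return node

    tree = split(np.arange(len(cell_ids)))
    type_of: dict[str, str] = {}
    for i, leaf in enumerate(tree.leaves()):
        for cid in leaf.cell_ids:
            type_of[cid] = f"T{i}"
    return CellTypeAssignment(type_of=type_of, tree=tree)


# ---------------------------------------------------------------------------
# identity assignment from marker genes
# ---------------------------------------------------------------------------

def assign_identities(
    assignment: CellTypeAssignment,
    posterior: ExpressionPosterior,
    marker_table: Mapping[str, Sequence[str]],
) -> CellTypeAssignment:
    """Label leaves with canonical identities via marker-gene enrichment.

    For each leaf and gene, the leaf's mean expression is ranked across
    leaves; an identity's score for a leaf is the mean rank of its marker
    genes.  Each leaf takes the identity with the highest score; two leaves
    claiming the same identity is an error; leaves without discriminating
    markers stay 'unassigned'.  Invariant to leaf enumeration order.
    """
    leaves = assignment.tree.leaves()
    labels = sorted({assignment.type_of[c] for c in assignment.type_of})
    cells_by_label = {
        lab: [i for i, c in enumerate(posterior.cells)
              if assignment.type_of.get(c.cell_id) == lab]
        for lab in labels
    }
    means = np.array([posterior.X[cells_by_label[lab]].mean(axis=0) for lab in labels])
    ranks = stats.rankdata(means, axis=0)  # rank across leaves per gene
    new_names: dict[str, str] = {}
    claimed: dict[str, str] = {}
    for li, lab in enumerate(labels):
        best_id, best_score = None, -np.inf
        all_scores = []
        for identity in sorted(marker_table):
            markers = [posterior.gene_ids.index(g) for g in marker_table[identity]
                       if g in posterior.gene_ids]
            if not markers:
                continue
            s = float(ranks[li, markers].mean())
            all_scores.append(s)
            if s > best_score:
                best_id, best_score = identity, s
        if best_id is None or (len(all_scores) > 1 and np.allclose(all_scores, all_scores[0])):
            new_names[lab] = "unassigned"
            continue
        if best_id in claimed:
            raise ValueError(
                f"identity {best_id!r} claimed by leaves {claimed[best_id]!r} and {lab!r}"
            )
        claimed[best_id] = lab
        new_names[lab] = best_id
    type_of = {c: new_names[t] for c, t in assignment.type_of.items()}
    return CellTypeAssignment(type_of=type_of, tree=assignment.tree)
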