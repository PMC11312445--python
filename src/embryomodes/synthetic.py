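"""Synthetic embryo cohorts with known ground truth.

Real contact graphs come from segmented light-sheet imaging and are not
shipped here; these fixtures are stylized mirror-symmetric stand-ins with the
same structural properties (conserved cell types, symmetric contact graph,
involutive sister and left-right maps).  Generators emulate exactly the
statistical structure the analysis assumes -- zero-mean Gaussian collective
fluctuations from a known sparse interaction matrix, mother/embryo/time mean
effects, per-entry measurement noise, and scrambled cell identities within a
type -- and record complete ground truth so every pipeline stage can be
scored.

Default cohort size is 14 embryos ("paper scale"); power/calibration studies
use 200.  Default interaction strength is 0.3 (a strongly coupled regime in
which collective variation is unambiguous at paper-scale cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .io import CellRecord, CountMatrix, EmbryoGraph, ExpressionPosterior
from .maxent import ConstraintSpec, MaxEntModel, make_model, neighbor_spec

DEFAULT_N_EMBRYOS = 14
DEFAULT_COUPLING = 0.3


# ---------------------------------------------------------------------------
# fixture topologies
# ---------------------------------------------------------------------------

def _mirror_chain(n_per_side: int, side_types: Sequence[str]) -> EmbryoGraph:
    """Two mirror-image chains of cells with cross-midline contacts.

    Cells i and i+1 on the same side are in contact, as are the two mirror
    partners at each chain position; sisters are the consecutive same-side
    pairs (0,1), (2,3), ...
    """
    assert len(side_types) == n_per_side
    names = [f"c{i}-L" for i in range(n_per_side)] + [f"c{i}-R" for i in range(n_per_side)]
    n = 2 * n_per_side
    type_of = {}
    for i, t in enumerate(side_types):
        type_of[f"c{i}-L"] = t
        type_of[f"c{i}-R"] = t
    contact = np.zeros((n, n), dtype=bool)
    for side in (0, n_per_side):
        for i in range(n_per_side - 1):
            a, b = side + i, side + i + 1
            contact[a, b] = contact[b, a] = True
    for i in range(n_per_side):
        contact[i, n_per_side + i] = contact[n_per_side + i, i] = True
    sister = {}
    for side in ("L", "R"):
        for i in range(0, n_per_side - 1, 2):
            a, b = f"c{i}-{side}", f"c{i + 1}-{side}"
            sister[a] = b
            sister[b] = a
    mirror = {}
    for i in range(n_per_side):
        mirror[f"c{i}-L"] = f"c{i}-R"
        mirror[f"c{i}-R"] = f"c{i}-L"
    return EmbryoGraph(names, type_of, contact, sister, mirror)


def make_topology(name: str) -> EmbryoGraph:
    """Named fixture graphs.

    toy4:     4 cells, 2 mirror pairs, 2 types, 3 contacts.
    mirror8:  8 cells, 3 types of sizes (4, 2, 2).
    mirror16: 16 cells, 8 mirror pairs, 5 types of sizes (4, 2, 2, 4, 4).
    mirror32: 32 cells, 16 types, each a left-right pair.
    """
    if name == "toy4":
        names = ["a-L", "b-L", "a-R", "b-R"]
        type_of = {"a-L": "ta", "a-R": "ta", "b-L": "tb", "b-R": "tb"}
        contact = np.zeros((4, 4), dtype=bool)
        for a, b in [(0, 1), (2, 3), (0, 2)]:  # aL-bL, aR-bR, aL-aR
            contact[a, b] = contact[b, a] = True
        sister = {"a-L": "b-L", "b-L": "a-L", "a-R": "b-R", "b-R": "a-R"}
        mirror = {"a-L": "a-R", "a-R": "a-L", "b-L": "b-R", "b-R": "b-L"}
        return EmbryoGraph(names, type_of, contact, sister, mirror)
    if name == "mirror8":
        return _mirror_chain(4, ["t0", "t0", "t1", "t2"])
    if name == "mirror16":
        return _mirror_chain(8, ["t0", "t0", "t1", "t2", "t3", "t3", "t4", "t4"])
    if name == "mirror32":
        # like the real 32-cell stage, cell types are left-right pairs
        return _mirror_chain(16, [f"t{i}" for i in range(16)])
    raise ValueError(f"unknown topology {name!r}")


# ---------------------------------------------------------------------------
# ground-truth models
# ---------------------------------------------------------------------------

def neighbor_model(
    graph: EmbryoGraph, n_pc: int = 2, coupling: float = DEFAULT_COUPLING
) -> MaxEntModel:
    """Planted model with only spatial-neighbor interactions.

    J = I - coupling * (contact x I_d); negative off-diagonal J couplings
    produce positively correlated neighbors.
    """
    spec = neighbor_spec(graph)
    M = {t: np.eye(n_pc) for t in graph.types}
    S = {"neighbor": -coupling * np.eye(n_pc)}
    return make_model(spec, graph, n_pc, M, S)


def planted_sparse_model(
    graph: EmbryoGraph,
    n_pc: int = 2,
    coupling: float = 0.6,
    candidates: ConstraintSpec | None = None,
    specific_labels: Sequence[str] | None = None,
    n_specific: int = 2,
    seed: int = 0,
) -> MaxEntModel:
    """Neighbor coupling plus a few specific directed cell-pair couplings.

    Specific terms are drawn from the candidate set of the graph (contact
    pairs bundled with their mirror images), so the planted model lies inside
    the space the sparse-inference pipeline searches.  The default coupling
    strength is a detectability-threshold design: a covariance component is
    estimated with standard error ~ var(x)/sqrt(2 * n_embryos), about 0.2 at
    a paper-scale cohort of 14, so planted specific couplings are sized to
    induce pair covariances of ~3 standard errors while keeping J positive
    definite with a margin (smallest eigenvalue ~ 0.2).
    """
    from .sparse import candidate_terms  # local import to avoid a cycle

    candidates = candidates if candidates is not None else candidate_terms(graph)
    # default planted terms couple cells of *different* types with an
    # asymmetric adjacency: identities are scrambled within a type, so a
    # coupling between two same-type cells cannot be localized to one pair;
    # cross-type couplings are what the type-level covariances can resolve
    sis = graph.sister_matrix()

    def cells_of(om):
        ps, qs = np.nonzero(np.asarray(om))
        return set(ps.tolist()) | set(qs.tolist())

    def identifiable(om):
        om = np.asarray(om)
        ps, qs = np.nonzero(om)
        cross = all(graph.type_of[graph.cell_names[p]] != graph.type_of[graph.cell_names[q]]
                    for p, q in zip(ps, qs))
        non_sister = not any(sis[p, q] for p, q in zip(ps, qs))
        return cross and non_sister and not np.array_equal(om, om.T)

    pool = [(l, om) for l, om in candidates.dir_terms if identifiable(om)]
    if specific_labels is None:
        # planted couplings are separated (no shared or contacting cells), so
        # each one's covariance signature is attributable to its own pair
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(pool))
        chosen: list[str] = []
        used: set[int] = set()
        for i in order:
            label, om = pool[i]
            cells = cells_of(om)
            touching = {int(c) for c in cells} | {
                int(q) for c in cells for q in np.nonzero(graph.contact[c])[0]
            }
            if used & touching:
                continue
            chosen.append(label)
            used |= touching
            if len(chosen) == n_specific:
                break
        specific_labels = chosen
    spec = candidates.subset(["neighbor", *specific_labels])
    # anisotropic within-cell precision: real PC spectra decay, and exact
    # PC isotropy would make the model's collective modes pairwise
    # degenerate (ill-defined mode subspaces)
    M = {t: np.diag(np.linspace(1.0, 1.5, n_pc)) if n_pc > 1 else np.eye(1)
         for t in graph.types}
    S = {"neighbor": -0.25 * coupling * np.eye(n_pc)}
    # couple all PC channels, plus a directed PC1 -> PC2 component
    U_block = -coupling * np.eye(n_pc)
    U_block[0, min(1, n_pc - 1)] -= 0.5 * coupling
    U = {label: U_block.copy() for label in specific_labels}
    return make_model(spec, graph, n_pc, M, S, U)


def independent_model(graph: EmbryoGraph, n_pc: int = 2) -> MaxEntModel:
    """No cell-cell interactions: J = identity (uncoupled null)."""
    M = {t: np.eye(n_pc) for t in graph.types}
    return make_model(ConstraintSpec(), graph, n_pc, M)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Observed posterior (identity-scrambled) plus the full latent record.

    ``posterior`` mimics what sequencing delivers: per-cell rows carrying an
    embryo label and a cell-type label but not the cell's position.  ``truth``
    retains everything: the latent per-position signal, the permutation that
    scrambled it, and any planted mean components.
    """

    posterior: ExpressionPosterior
    truth: dict = field(default_factory=dict)

    @property
    def type_labels(self) -> np.ndarray:
        return np.array([c.cell_type for c in self.posterior.cells])

    @property
    def embryo_labels(self) -> np.ndarray:
        return np.array([c.embryo_id for c in self.posterior.cells])


def sample_embryos(
    model: MaxEntModel,
    n_embryos: int,
    eps_scale: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SyntheticDataset:
    """Sample embryos from p(x) = N(0, J^-1); one draw = one embryo.

    Optional i.i.d. Gaussian measurement noise of SD ``eps_scale`` is added
    per entry (and recorded as the posterior SD).  Within each embryo, cell
    positions are scrambled within their type, as in real dissociated data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    graph, d = model.graph, model.n_pc
    n, D = graph.n_cells, graph.n_cells * model.n_pc
    L = np.linalg.cholesky(model.J)
    z = rng.standard_normal((n_embryos, D))
    x = linalg.solve_triangular(L.T, z.T, lower=False).T.reshape(n_embryos, n, d)
    noise = eps_scale * rng.standard_normal(x.shape) if eps_scale > 0 else np.zeros_like(x)
    observed = x + noise

    tc = graph.type_indices()
    rows, cells, positions = [], [], []
    for e in range(n_embryos):
        perm = np.arange(n)
        for cells_t in tc.values():
            perm[cells_t] = rng.permutation(cells_t)
        for k, pos in enumerate(perm):
            rows.append(observed[e, pos])
            positions.append(pos)
            cells.append(CellRecord(
                cell_id=f"e{e}_c{k}",
                embryo_id=f"e{e}",
                stage=n,
                cell_type=graph.type_of[graph.cell_names[pos]],
            ))
    X = np.array(rows).reshape(-1, d) if rows else np.empty((0, d))
    eps = np.full_like(X, eps_scale)
    posterior = ExpressionPosterior(X, eps, [f"PC{i + 1}" for i in range(d)], cells)
    truth = {
        "x_latent": x,
        "position_of_row": np.array(positions, dtype=int),
        "model": model,
    }
    return SyntheticDataset(posterior, truth)


def add_structured_means(
    dataset: SyntheticDataset,
    mu: Mapping[str, np.ndarray] | None = None,
    tau_sd: float = 0.0,
    alpha: Mapping[str, np.ndarray] | None = None,
    mother_of: Mapping[str, str] | None = None,
    nu_sd: float = 0.0,
    eta_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SyntheticDataset:
    """Add planted mean structure on top of the collective fluctuations.

    Adds mu_t(c)g (cell-type means) and tau_e * alpha_t(c)g (developmental
    staging along a per-type tangent) and, when mother/embryo SDs are given,
    maternal-style nu_m(c)g and eta_eg mean shifts.  All planted components
    are recorded in ``truth``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    post = dataset.posterior
    X = post.X.copy()
    g = X.shape[1]
    types = sorted({c.cell_type for c in post.cells})
    embryos = sorted({c.embryo_id for c in post.cells})
    t_of = np.array([types.index(c.cell_type) for c in post.cells])
    e_of = np.array([embryos.index(c.embryo_id) for c in post.cells])
    truth = dict(dataset.truth)

    if mu is not None:
        mu_arr = np.array([np.asarray(mu[t]) for t in types])
        X += mu_arr[t_of]
        truth["mu"] = {t: np.asarray(mu[t]) for t in types}
    if tau_sd > 0:
        if alpha is None:
            raise ValueError("alpha (per-type tangent) required when tau_sd > 0")
        tau = tau_sd * rng.standard_normal(len(embryos))
        tau -= tau.mean()
        alpha_arr = np.array([np.asarray(alpha[t]) for t in types])
        X += tau[e_of][:, None] * alpha_arr[t_of]
        truth["tau"] = tau
        truth["alpha"] = {t: np.asarray(alpha[t]) for t in types}
        truth["embryo_order"] = embryos
    if nu_sd > 0:
        if mother_of is None:
            raise ValueError("mother_of required when nu_sd > 0")
        mothers = sorted(set(mother_of.values()))
        nu = nu_sd * rng.standard_normal((len(mothers), g))
        m_of = np.array([mothers.index(mother_of[c.embryo_id]) for c in post.cells])
        X += nu[m_of]
        truth["nu"] = {m: nu[i] for i, m in enumerate(mothers)}
        cells = [CellRecord(c.cell_id, c.embryo_id, c.stage,
                            mother_id=mother_of[c.embryo_id], cell_type=c.cell_type)
                 for c in post.cells]
    else:
        cells = list(post.cells)
    if eta_sd > 0:
        eta = eta_sd * rng.standard_normal((len(embryos), g))
        X += eta[e_of]
        truth["eta"] = {e: eta[i] for i, e in enumerate(embryos)}
    posterior = ExpressionPosterior(X, post.eps.copy(), list(post.gene_ids), cells)
    return SyntheticDataset(posterior, truth)


def simulate_marker_posterior(
    graph: EmbryoGraph,
    n_embryos: int = DEFAULT_N_EMBRYOS,
    n_noise_genes: int = 10,
    n_markers_per_type: int = 2,
    effect: float = 1.0,
    noise_sd: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionPosterior, dict[str, str]]:
    """Expression posterior with planted marker genes per cell type.

    Each type gets ``n_markers_per_type`` genes elevated by ``effect`` (in
    log units) in its cells; all genes carry i.i.d. Gaussian noise of SD
    ``noise_sd``, which is also reported as the posterior SD.  Cells are
    shuffled within each embryo so typing cannot exploit ordering.  Returns
    the posterior and the planted cell -> type truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    types = graph.types
    n_marker = len(types) * n_markers_per_type
    n_genes = n_marker + n_noise_genes
    gene_ids = [f"marker_{t}_{m}" for t in types for m in range(n_markers_per_type)]
    gene_ids += [f"noise_{i}" for i in range(n_noise_genes)]
    marker_cols = {t: [types.index(t) * n_markers_per_type + m
                       for m in range(n_markers_per_type)] for t in types}
    rows, cells, truth = [], [], {}
    for e in range(n_embryos):
        order = rng.permutation(graph.n_cells)
        for k, pos in enumerate(order):
            t = graph.type_of[graph.cell_names[pos]]
            mean = np.zeros(n_genes)
            mean[marker_cols[t]] = effect
            rows.append(mean + noise_sd * rng.standard_normal(n_genes))
            cid = f"e{e}_c{k}"
            cells.append(CellRecord(cell_id=cid, embryo_id=f"e{e}", stage=graph.n_cells))
            truth[cid] = t
    X = np.array(rows)
    post = ExpressionPosterior(X, np.full_like(X, noise_sd), gene_ids, cells)
    return post, truth


def simulate_counts(
    graph: EmbryoGraph,
    type_profiles: Mapping[str, np.ndarray],
    depth: float,
    dispersion: float,
    n_embryos: int,
    seed: int | np.random.Generator = 0,
    gene_ids: Sequence[str] | None = None,
    stage: int | None = None,
) -> CountMatrix:
    """Log-normal-Poisson counts around type-specific expression profiles.

    Per cell, the rate for gene g is depth * profile_t(c)g * LN(1, dispersion)
    (mean-one log-normal), and the count is Poisson at that rate.  depth = 0
    gives all-zero counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    types = graph.types
    profiles = np.array([np.asarray(type_profiles[t], dtype=float) for t in types])
    if np.any(profiles <= 0):
        raise ValueError("type profiles must be positive")
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    n_genes = profiles.shape[1]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_genes)]
    stage = stage if stage is not None else graph.n_cells
    counts, cells = [], []
    for e in range(n_embryos):
        for k, name in enumerate(graph.cell_names):
            t = types.index(graph.type_of[name])
            rate = depth * profiles[t]
            if dispersion > 0:
                rate = rate * np.exp(dispersion * rng.standard_normal(n_genes)
                                     - dispersion**2 / 2)
            counts.append(rng.poisson(rate))
            cells.append(CellRecord(cell_id=f"e{e}_c{k}", embryo_id=f"e{e}",
                                    stage=stage, cell_type=graph.type_of[name]))
    arr = np.array(counts, dtype=np.int64) if counts else np.empty((0, n_genes), dtype=np.int64)
    return CountMatrix(arr, gene_ids, cells)
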