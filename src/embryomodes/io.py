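"""Core data model and file I/O.

The pipeline exchanges three kinds of objects: integer count matrices with
per-cell metadata, per-cell/per-gene log-expression posteriors (mean plus an
independent Gaussian standard deviation), and embryo graphs describing the
stereotyped cell arrangement of a fixed-lineage embryo (cell types, contact
adjacency, sister pairs, left-right mirror pairs).  All matrices are oriented
cells x genes.  Readers validate invariants on load; writer/reader pairs are
exact inverses on valid objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ConsistencyError(ValueError):
    """Input files are individually readable but mutually inconsistent."""


# ---------------------------------------------------------------------------
# cell metadata and matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """Metadata for one sequenced cell.

    ``stage`` is the cell-stage of the embryo (8/16/32/64 in the real data;
    synthetic stages may use any positive integer).  ``mother_id`` groups
    embryos laid by the same mother; ``cell_type`` is filled in by the
    cell-typing stage.
    """

    cell_id: str
    embryo_id: str
    stage: int
    mother_id: str | None = None
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if not self.embryo_id:
            raise ValueError(f"cell {self.cell_id!r}: embryo_id must be non-empty")
        if self.stage <= 0:
            raise ValueError(f"cell {self.cell_id!r}: stage must be positive, got {self.stage}")


def _check_gene_ids(gene_ids: Sequence[str]) -> list[str]:
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"gene_ids not unique: {dupes[:5]}")
    return gene_ids


@dataclass
class CountMatrix:
    """Cells x genes matrix of non-negative integer read counts."""

    counts: np.ndarray
    gene_ids: list[str]
    cells: list[CellRecord]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = _check_gene_ids(self.gene_ids)
        if self.counts.shape != (len(self.cells), len(self.gene_ids)):
            raise ConsistencyError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.gene_ids)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def embryo_ids(self) -> np.ndarray:
        return np.array([c.embryo_id for c in self.cells])


@dataclass
class ExpressionPosterior:
    """Per-cell, per-gene log-expression posterior (mean ``X`` and SD ``eps``).

    This is the universal currency between pipeline stages: the output of the
    normalizer, the input to cell typing, variance decomposition, and
    covariance estimation.  Uncertainty is modelled as an independent Gaussian
    per entry.
    """

    X: np.ndarray
    eps: np.ndarray
    gene_ids: list[str]
    cells: list[CellRecord]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.X.shape != self.eps.shape:
            raise ValueError(f"X shape {self.X.shape} != eps shape {self.eps.shape}")
        if np.any(self.eps < 0):
            raise ValueError("eps must be non-negative")
        self.gene_ids = _check_gene_ids(self.gene_ids)
        if self.X.shape != (len(self.cells), len(self.gene_ids)):
            raise ConsistencyError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.cells)} cells x {len(self.gene_ids)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def embryo_ids(self) -> np.ndarray:
        return np.array([c.embryo_id for c in self.cells])

    def with_types(self, type_of: dict[str, str]) -> "ExpressionPosterior":
        """Return a copy whose cells carry type labels from ``type_of``."""
        cells = [replace(c, cell_type=type_of.get(c.cell_id, c.cell_type)) for c in self.cells]
        return ExpressionPosterior(self.X.copy(), self.eps.copy(), list(self.gene_ids), cells)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionPosterior":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionPosterior(self.X[:, idx], self.eps[:, idx], list(genes), list(self.cells))


@dataclass
class EmbryoGraph:
    """Stereotyped structure of one embryo stage.

    ``cell_names`` are the canonical per-embryo identities (labels only;
    all computation uses 0-based indices).  ``contact`` is the symmetric
    boolean cell-cell contact adjacency, ``sister`` the involutive partial
    sister map, ``mirror`` the involutive left-right pairing.
    """

    cell_names: list[str]
    type_of: dict[str, str]
    contact: np.ndarray
    sister: dict[str, str]
    mirror: dict[str, str]

    def __post_init__(self) -> None:
        n = len(self.cell_names)
        if len(set(self.cell_names)) != n:
            raise ValueError("cell_names not unique")
        self.contact = np.asarray(self.contact, dtype=bool)
        if self.contact.shape != (n, n):
            raise ValueError("contact matrix shape mismatch")
        if not np.array_equal(self.contact, self.contact.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(self.contact)):
            raise ValueError("contact matrix must have zero diagonal")
        missing = set(self.cell_names) - set(self.type_of)
        if missing:
            raise ValueError(f"cells without type: {sorted(missing)[:5]}")
        for name, mapping in (("sister", self.sister), ("mirror", self.mirror)):
            for p, q in mapping.items():
                if p not in self.type_of or q not in self.type_of:
                    raise ValueError(f"{name} map references unknown cell: ({p}, {q})")
                back = mapping.get(q)
                if back != p:
                    raise ValueError(f"{name} map not involutive at ({p} -> {q} -> {back})")
        if set(self.mirror) != set(self.cell_names):
            raise ValueError("mirror map must cover every cell")

    @property
    def n_cells(self) -> int:
        return len(self.cell_names)

    @property
    def types(self) -> list[str]:
        """Type labels in order of first appearance along cell_names."""
        seen: list[str] = []
        for c in self.cell_names:
            t = self.type_of[c]
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def n_t(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.cell_names:
            counts[self.type_of[c]] = counts.get(self.type_of[c], 0) + 1
        return counts

    def index_of(self, cell: str) -> int:
        return self.cell_names.index(cell)

    def type_indices(self) -> dict[str, np.ndarray]:
        """Map type label -> array of 0-based cell indices."""
        out: dict[str, list[int]] = {t: [] for t in self.types}
        for i, c in enumerate(self.cell_names):
            out[self.type_of[c]].append(i)
        return {t: np.array(v, dtype=int) for t, v in out.items()}

    def sister_matrix(self) -> np.ndarray:
        """Symmetric 0/1 adjacency of sister pairs."""
        n = self.n_cells
        S = np.zeros((n, n), dtype=bool)
        idx = {c: i for i, c in enumerate(self.cell_names)}
        for p, q in self.sister.items():
            S[idx[p], idx[q]] = True
        return S

    def mirror_index(self) -> np.ndarray:
        """mirror_index[i] = index of the left-right partner of cell i."""
        idx = {c: i for i, c in enumerate(self.cell_names)}
        return np.array([idx[self.mirror[c]] for c in self.cell_names], dtype=int)


# ---------------------------------------------------------------------------
# RNG substreams
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, independent random substream from a root seed.

    Every stochastic operation in the pipeline takes its randomness from a
    named substream so that stages are independently reproducible: changing
    the number of draws in one stage does not perturb another.
    """
    ss = np.random.SeedSequence([seed, *(ord(ch) for ch in name)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# counts I/O (TSV with metadata sidecar)
# ---------------------------------------------------------------------------

_META_COLS = ["cell_id", "embryo_id", "stage", "mother_id"]


def _read_metadata(metadata_path: str | Path) -> list[CellRecord]:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("cell_id", "embryo_id", "stage"):
        if col not in meta.columns:
            raise ConsistencyError(f"metadata missing required column {col!r}")
    records = []
    for _, row in meta.iterrows():
        if pd.isna(row["embryo_id"]) or row["embryo_id"] == "":
            raise ConsistencyError(f"cell {row['cell_id']!r} has no embryo_id")
        mother = row.get("mother_id")
        ctype = row.get("cell_type")
        records.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                embryo_id=str(row["embryo_id"]),
                stage=int(row["stage"]),
                mother_id=None if mother is None or pd.isna(mother) else str(mother),
                cell_type=None if ctype is None or pd.isna(ctype) else str(ctype),
            )
        )
    return records


def _write_metadata(cells: Sequence[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "embryo_id": [c.embryo_id for c in cells],
            "stage": [c.stage for c in cells],
            "mother_id": [c.mother_id for c in cells],
            "cell_type": [c.cell_type for c in cells],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a counts TSV (rows = cells, columns = genes) plus metadata TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas names the line
        raise ValueError(f"malformed counts file {path}: {exc}") from exc
    records = _read_metadata(metadata_path)
    meta_ids = [c.cell_id for c in records]
    if list(table.index.astype(str)) != meta_ids:
        raise ConsistencyError(
            "cell ids in counts file do not match metadata "
            f"({list(table.index[:3])} vs {meta_ids[:3]} ...)"
        )
    values = table.to_numpy()
    if np.any(pd.isna(values)):
        bad = int(np.argwhere(pd.isna(values))[0][0]) + 2  # header + 1-based
        raise ValueError(f"malformed counts file {path}: missing value near line {bad}")
    return CountMatrix(values, [str(g) for g in table.columns], records)


def write_counts(cm: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=[c.cell_id for c in cm.cells], columns=cm.gene_ids)
    df.to_csv(path, sep="\t")
    _write_metadata(cm.cells, metadata_path)


# ---------------------------------------------------------------------------
# posterior I/O (mean/sd TSV pair)
# ---------------------------------------------------------------------------

def read_posterior(
    mean_path: str | Path, sd_path: str | Path, metadata_path: str | Path
) -> ExpressionPosterior:
    """Read an expression posterior stored as congruent mean and SD TSVs."""
    mean = pd.read_csv(mean_path, sep="\t", index_col=0)
    sd = pd.read_csv(sd_path, sep="\t", index_col=0)
    if mean.shape != sd.shape or list(mean.columns) != list(sd.columns):
        raise ConsistencyError("mean and sd matrices are not congruent")
    records = _read_metadata(metadata_path)
    if list(mean.index.astype(str)) != [c.cell_id for c in records]:
        raise ConsistencyError("cell ids in posterior files do not match metadata")
    return ExpressionPosterior(
        mean.to_numpy(float), sd.to_numpy(float), [str(g) for g in mean.columns], records
    )


def write_posterior(
    post: ExpressionPosterior,
    mean_path: str | Path,
    sd_path: str | Path,
    metadata_path: str | Path,
) -> None:
    ids = [c.cell_id for c in post.cells]
    pd.DataFrame(post.X, index=ids, columns=post.gene_ids).to_csv(mean_path, sep="\t")
    pd.DataFrame(post.eps, index=ids, columns=post.gene_ids).to_csv(sd_path, sep="\t")
    _write_metadata(post.cells, metadata_path)


# ---------------------------------------------------------------------------
# embryo-graph I/O (JSON)
# ---------------------------------------------------------------------------
# There is no community-standard format for cell-contact graphs with lineage
# annotation, so a small JSON document is used: sections `cells`, `types`,
# `contacts` (list of [a, b], both directions required), `sisters`,
# `mirrors` (lists of pairs).


def read_embryo_graph(path: str | Path) -> EmbryoGraph:
    with open(path) as fh:
        doc = json.load(fh)
    cells = list(doc["cells"])
    idx = {c: i for i, c in enumerate(cells)}
    n = len(cells)
    contact = np.zeros((n, n), dtype=bool)
    edges = {tuple(e) for e in doc.get("contacts", [])}
    for a, b in edges:
        if (b, a) not in edges:
            raise ValueError(f"contact list asymmetric: ({a}, {b}) present without ({b}, {a})")
        contact[idx[a], idx[b]] = True
    sister: dict[str, str] = {}
    for a, b in doc.get("sisters", []):
        sister[a] = b
        sister[b] = a
    mirror: dict[str, str] = {}
    for a, b in doc.get("mirrors", []):
        for p, q in ((a, b), (b, a)):
            if p in mirror and mirror[p] != q:
                raise ValueError(f"mirror map not involutive at {p}")
            mirror[p] = q
    return EmbryoGraph(cells, dict(doc["types"]), contact, sister, mirror)


def write_embryo_graph(graph: EmbryoGraph, path: str | Path) -> None:
    idx = graph.cell_names
    contacts = [
        [idx[i], idx[j]]
        for i in range(graph.n_cells)
        for j in range(graph.n_cells)
        if graph.contact[i, j]
    ]
    sisters = sorted({tuple(sorted((p, q))) for p, q in graph.sister.items()})
    mirrors = sorted({tuple(sorted((p, q))) for p, q in graph.mirror.items() if p != q})
    # self-mirror cells (on the midline) are recorded explicitly
    mirrors += sorted((p, p) for p, q in graph.mirror.items() if p == q)
    doc = {
        "cells": graph.cell_names,
        "types": graph.type_of,
        "contacts": [list(e) for e in contacts],
        "sisters": [list(e) for e in sisters],
        "mirrors": [list(e) for e in mirrors],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
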