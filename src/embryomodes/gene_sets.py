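"""Maternal/zygotic gene classification and differential expression.

Zygotic genes at the k-cell stage are genes silent at the 4-cell baseline
(fewer than 10 reads in every cell), strongly expressed later (more than 100
reads in some cell at stage k), and differentially expressed across cell
types; this excludes maternally deposited transcripts and genes that switch
on embryo-wide without spatial patterning.  Maternal genes are abundant at
the baseline (more than 500 reads in some cell) and never differentially
expressed afterwards.  Differential expression uses the two-sided Wilcoxon
rank-sum test per (gene, cell-type pair) with Benjamini-Hochberg adjustment
across all genes and pairs, significant at adjusted p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ExpressionPosterior

DE_ALPHA = 0.01

# count-filter thresholds (reads), strict inequalities
ZYGOTIC_BASELINE_MAX = 10     # baseline: fewer than 10 reads in every cell
ZYGOTIC_STAGE_MIN = 100       # stage k: more than 100 reads in some cell
MATERNAL_BASELINE_MIN = 500   # baseline: more than 500 reads in some cell


@dataclass
class GeneSetResult:
    """Maternal/zygotic partition plus the DE table that produced it."""

    zygotic: dict[int, list[str]]
    maternal: list[str]
    de_table: pd.DataFrame

    def __post_init__(self) -> None:
        zyg = {g for genes in self.zygotic.values() for g in genes}
        overlap = zyg & set(self.maternal)
        if overlap:
            raise ValueError(f"genes classified both zygotic and maternal: {sorted(overlap)[:5]}")
        if len(self.de_table) and not self.de_table["p_adj"].between(0, 1).all():
            raise ValueError("adjusted p-values must lie in [0, 1]")


def wilcoxon_de(
    expr: ExpressionPosterior, assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Two-sided rank-sum test per (gene, cell-type pair), BH-adjusted.

    Returns a long-format table with columns gene, type_a, type_b, p_raw,
    p_adj, significant.  Pairs where either type has fewer than two cells are
    skipped with a warning.
    """
    types = sorted({assignment[c.cell_id] for c in expr.cells if c.cell_id in assignment})
    if len(types) < 2:
        raise ValueError("need at least two cell types for differential expression")
    members = {
        t: np.array([i for i, c in enumerate(expr.cells) if assignment.get(c.cell_id) == t])
        for t in types
    }
    rows = []
    for ta, tb in combinations(types, 2):
        ia, ib = members[ta], members[tb]
        if len(ia) < 2 or len(ib) < 2:
            warnings.warn(f"type pair ({ta}, {tb}) skipped: fewer than 2 cells in a group")
            continue
        xa, xb = expr.X[ia], expr.X[ib]
        for gi, gene in enumerate(expr.gene_ids):
            a, b = xa[:, gi], xb[:, gi]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                p = 1.0  # identical values carry no rank information
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append((gene, ta, tb, p))
    table = pd.DataFrame(rows, columns=["gene", "type_a", "type_b", "p_raw"])
    if len(table):
        table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    table["significant"] = table["p_adj"] < DE_ALPHA
    return table


def _de_genes(de: pd.DataFrame) -> set[str]:
    if de is None or not len(de):
        return set()
    return set(de.loc[de["significant"], "gene"])


def classify_zygotic(
    counts_by_stage: Mapping[int, CountMatrix],
    de_by_stage: Mapping[int, pd.DataFrame],
    baseline_stage: int = 4,
) -> dict[int, list[str]]:
    """Purely zygotic genes per stage.

    A gene is zygotic at stage k iff its maximum baseline count is below
    ``ZYGOTIC_BASELINE_MAX``, its maximum stage-k count exceeds
    ``ZYGOTIC_STAGE_MIN``, and it is differentially expressed across cell
    types at stage k.
    """
    if baseline_stage not in counts_by_stage:
        raise ValueError(f"baseline ({baseline_stage}-cell) counts are required")
    base = counts_by_stage[baseline_stage]
    base_max = {g: m for g, m in zip(base.gene_ids, base.counts.max(axis=0))}
    out: dict[int, list[str]] = {}
    for stage, cm in counts_by_stage.items():
        if stage == baseline_stage:
            continue
        de_genes = _de_genes(de_by_stage.get(stage))
        stage_max = cm.counts.max(axis=0)
        kept = [
            g
            for g, m in zip(cm.gene_ids, stage_max)
            if base_max.get(g, 0) < ZYGOTIC_BASELINE_MAX
            and m > ZYGOTIC_STAGE_MIN
            and g in de_genes
        ]
        out[stage] = kept
    return out


def classify_maternal(
    counts_baseline: CountMatrix,
    de_by_stage: Mapping[int, pd.DataFrame],
    exclude: Iterable[str] = (),
) -> list[str]:
    """Purely maternal genes: abundant at baseline and never DE afterwards.

    ``exclude`` is a user-supplied list of genes to drop regardless (e.g.
    posterior-pole-localized germ-lineage transcripts, which are identified
    biologically rather than by a count criterion).
    """
    ever_de: set[str] = set()
    for de in de_by_stage.values():
        ever_de |= _de_genes(de)
    excluded = set(exclude)
    base_max = counts_baseline.counts.max(axis=0)
    return [
        g
        for g, m in zip(counts_baseline.gene_ids, base_max)
        if m > MATERNAL_BASELINE_MIN and g not in ever_de and g not in excluded
    ]
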