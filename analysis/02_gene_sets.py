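"""Classify genes as purely zygotic or purely maternal on the simulated counts.

Reads the cohorts from 01, normalizes the 16-cell counts to log-fraction
expression, runs Wilcoxon differential expression across the (known) cell
types, and applies the count filters: zygotic = silent at the 4-cell
baseline, strong later, and differentially expressed; maternal = abundant at
baseline and never differentially expressed.  Writes gene lists and the DE
table under results/gene_sets/.
"""

import sys
from pathlib import Path

from embryomodes.gene_sets import classify_maternal, classify_zygotic, wilcoxon_de
from embryomodes.io import read_counts
from embryomodes.normalization import normalize_log_fraction

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "gene_sets"
OUT.mkdir(parents=True, exist_ok=True)

baseline = read_counts(ROOT / "cohorts" / "counts_4cell.tsv",
                       ROOT / "cohorts" / "meta_4cell.tsv")
stage16 = read_counts(ROOT / "cohorts" / "counts_16cell.tsv",
                      ROOT / "cohorts" / "meta_16cell.tsv")

post = normalize_log_fraction(stage16)
assignment = {c.cell_id: c.cell_type for c in stage16.cells}
de = wilcoxon_de(post, assignment)
de.to_csv(OUT / "de_table_16cell.tsv", sep="\t", index=False)

zygotic = classify_zygotic({4: baseline, 16: stage16}, {16: de})
maternal = classify_maternal(baseline, {16: de})
(OUT / "zygotic_16cell.txt").write_text("\n".join(zygotic[16]) + "\n")
(OUT / "maternal.txt").write_text("\n".join(maternal) + "\n")

n_sig = int(de["significant"].sum())
print(f"DE tests: {len(de)} (significant at adjusted p<0.01: {n_sig})")
print(f"zygotic genes at 16-cell stage: {zygotic[16]}")
print(f"maternal genes: {maternal}")
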