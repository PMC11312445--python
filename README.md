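# embryomodes

Tools for detecting and modeling **collective gene-expression variation in
embryos with an invariant cell lineage** — organisms (the motivating system
is the early ascidian embryo) in which every individual has the same cells,
the same cell types, and the same cell–cell contact graph at a given stage.
Single-cell RNA sequencing of such embryos, with per-embryo barcoding, turns
each embryo into one observation of a high-dimensional *embryonic
transcriptome*: the joint expression state of all of its cells. Because
dissociation scrambles cell identities within a type, the pipeline works
entirely with type-level statistics.

The package takes per-cell expression posteriors (mean and SD of log
expression) and:

1. **identifies cell types robustly** — hierarchical clustering constrained
   by embryo structure (a true type has equal cell counts in every embryo),
   on informative genes, validated by resampling from the expression
   posterior against an embryo-shuffled null;
2. **strips known variance sources** — gene/type/mother/embryo means and a
   per-embryo developmental-time axis τ_e·α_tg — and keeps only the
   principal components that beat a permutation null;
3. **detects collective variation** with a shuffle test on the deviation
   statistic Δ = Σ((γ − γ̄)/σ)², where γ^tt′ are within-embryo inter-type
   covariances and γ̄, σ summarize the shuffle ensemble;
4. **fits maximum-entropy Gaussian models of cell–cell interaction**:
   constraining within-cell covariances per type and adjacency-averaged
   covariances between cells yields p(x) = N(0, J⁻¹) with

       J_(pi)(qj) = Σ_t M^t_ij I^t_pq + Σ_k S^k_ij Ψ^k_pq
                  + ½ Σ_k′ (U^k′_ij Ω^k′_pq + U^k′_ji Ω^k′_qp),

   fit by convex moment matching, scored by
   η = 1 − Σ(C−C̃)²/ΣC² against the full covariance set;
5. **infers sparse interaction networks** — L1-regularized fits across
   posterior/bootstrap covariance draws and a λ grid, stability ranking,
   Schulze aggregation, and forward selection to η > 0.9;
6. **extracts collective modes** — eigenvectors of Σ = J⁻¹ over the
   (cell, PC) state, with a random-rotation baseline for how special their
   alignment is.

A synthetic-embryo generator (`embryomodes.synthetic`) produces cohorts with
the exact statistical structure the analysis assumes — mirror-symmetric
contact graphs, conserved types, planted interaction matrices, scrambled
identities, planted mean structure — with complete ground truth, so every
stage can be scored. See `docs/methods.md` for models, assumptions, and
parameter choices.

## Worked example

Sample a 14-embryo cohort from a known neighbor-coupled model on the 16-cell
fixture graph, test for collective variation, and compare the three
interaction hypotheses:

```python
import numpy as np
from embryomodes.covariance import resample_covariances, shuffle_test
from embryomodes.maxent import embryo_wide_spec, fit_maxent, neighbor_spec, sister_spec
from embryomodes.synthetic import make_topology, neighbor_model, sample_embryos

graph = make_topology("mirror16")
ds = sample_embryos(neighbor_model(graph), n_embryos=14, eps_scale=0.1, seed=0)

res = shuffle_test(ds.posterior.X, ds.type_labels, ds.embryo_labels,
                   mode="across", n_shuffles=100, seed=1)
print(f"Delta = {res.delta_observed:.1f}, p = {res.p_value:.4f}")

def draw(rng):
    x = ds.posterior.X + ds.posterior.eps * rng.standard_normal(ds.posterior.X.shape)
    return x, ds.type_labels, ds.embryo_labels

cov = resample_covariances(draw, n_draws=5, n_boot=4, seed=2)
for name, spec in [("embryo-wide", embryo_wide_spec(graph)),
                   ("sister", sister_spec(graph)),
                   ("neighbor", neighbor_spec(graph))]:
    model, report = fit_maxent(cov, spec, graph)
    print(f"{name:12s} eta = {report.eta:.3f}")
```

prints (seeds as above):

```
Delta = 236.9, p = 0.0099
embryo-wide  eta = 0.885
sister       eta = 0.840
neighbor     eta = 0.926
```

The shuffle test rejects decisively (p = 1/101, the smallest attainable
value with 100 shuffles): cells of the same embryo covary. Fitting the three
single-hypothesis models, the neighbor model — the truth here — explains the
covariances best; the sister model does worst because couplings that act
only within sister pairs leave J block diagonal and cannot produce the
non-sister correlations present in the data.

The numbered drivers under `analysis/` run the full pipeline on synthetic
cohorts (simulation → gene sets → typing → variance decomposition → shuffle
tests → hypothesis models → sparse network → collective modes), each
printing what it found and writing tables under `results/`.

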