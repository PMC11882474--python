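# mglia

Single-nucleus RNA-seq analysis of striatal microglia under a 2×2 stress ×
exercise design: quality control, graph clustering with nonparametric
resolution selection, transcriptional-diversity maturity scoring,
negative-binomial mixed-model differential expression, activation-state
scores, composition statistics, and causal mediation between stress, gene
expression and wheel-running behavior.

The package is aimed at analysts working with pooled snRNA-seq designs —
multiple animals per treatment group, thousands of nuclei per animal — where
the animal, not the nucleus, is the unit of replication. Every inferential
step therefore carries a per-individual random effect, and a first-class
synthetic-data module generates full datasets with known ground truth so the
whole pipeline is testable without any sequencing data.

## Methods at a glance

**Resolution selection (K-MST).** Nuclei are embedded by PCA on Gamma–Poisson
Pearson residuals and connected by the union of k edge-disjoint minimum
spanning trees (K-MST). For labels from community detection at resolution r,
the within-cluster edge count R_W = #{(u,v) ∈ E : c(u) = c(v)} is standardized
against the uniform label-permutation null with exact moments

```
E[R_W]  = m · Σ_k (n_k)₂ / (n)₂
Var[R_W] = E[R_W²] − E[R_W]²,
E[R_W²] = E[R_W] + 2s·Σ_k (n_k)₃/(n)₃
          + 2(C(m,2) − s)·[Σ_k (n_k)₄ + Σ_{k≠l} (n_k)₂(n_l)₂]/(n)₄
```

where (x)_j is the falling factorial and s counts edge pairs sharing a
vertex. The resolution maximizing Z = (R_W − E)/√Var is selected.

**Differential expression.** Counts follow an NB mixed model per gene:
log μ = log L + x'β + b_individual, b ~ N(0, σ²), with gene dispersion θ
estimated once by Gamma–Poisson profile likelihood and held fixed. The model
is fit by a Laplace-approximation REML profile (joint Newton over β and the
donor intercepts; β integrated out through the Schur complement of the joint
information). Wald tests use a t reference with donor-level degrees of
freedom; FDR control uses Storey q-values.

**Mediation.** On per-individual mean corrected expression, the linear pair
M = a·T + ε, Y = c′·T + b·M + ε gives ACME = a·b and ADE = c′, with percentile
bootstrap confidence intervals over individuals, screened in both causal
directions (stress → gene → running and stress → running → gene).

## Worked example

```python
import numpy as np
from mglia import (SynthConfig, generate_dataset, apply_qc_filters,
                   normalize_residuals, pca_embed, build_snn_graph,
                   select_resolution)

cfg = SynthConfig(n_genes=2000, n_nuclei=3000, n_clusters=3,
                  marker_log2fc=1.5, seed=11)
adata, truth = generate_dataset(cfg)
adata, report = apply_qc_filters(adata)
print(report.n_kept, report.n_removed_by_rule)

resid = normalize_residuals(adata)
emb = pca_embed(resid, n_components=20, ids=list(adata.obs_names))
graph = build_snn_graph(emb, k=50)
scan = select_resolution(emb, graph,
                         grid=tuple(np.round(np.arange(0.1, 1.21, 0.1), 2)))
print(scan.selected_resolution, scan.selected.n_clusters)
```

This prints

```
2973 {'min_umi': 25, 'min_genes': 2, 'max_umi': 0, 'max_genes': 0, 'mito': 0}
1.0 3
```

— 2973 of 3000 synthetic nuclei pass the default QC thresholds (minimum 750
UMIs and 500 genes, maximum 20,000 UMIs and 5,000 genes, ≤5% mitochondrial
reads); 25 fall below the UMI floor and 2 below the gene floor, as expected
from the lognormal library-size tail. The resolution scan then selects the
resolution whose clustering maximizes the standardized within-cluster K-MST
edge count and recovers the three planted clusters (adjusted Rand index 0.94
against the ground truth in `adata.obs["true_cluster"]`).

A thin CLI mirrors the library: `mglia generate`, `mglia qc`, `mglia cluster`,
`mglia maturity`, `mglia de`, `mglia states`, `mglia mediation`
(see `mglia --help`).

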