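# Methods

This note documents the models implemented in `mglia`, the defaults and why
they were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that affect results.

## Study design being modeled

The pipeline targets a 2×2 rodent design: stress (acute inescapable stressor
vs. none) crossed with exercise (running-wheel access vs. none), six animals
per group, striatal nuclei pooled across animals and profiled by snRNA-seq.
Wheel animals carry running distances over five windows before sampling
(6 weeks, 24 h, 3 h, 30–90 min, 30 min). Stressed runners run a small
fraction (~15%) of control distances, and the scientific questions are (i)
which microglial genes and states respond to stress, exercise access, and
running levels, and (ii) which expression changes cause, versus follow, the
stress-induced running deficit.

Because nuclei from one animal are correlated, every test that compares
treatment groups treats the animal as the unit of replication: count models
and score models carry a per-individual random intercept, and the mediation
analysis operates on per-individual mean expression.

## Synthetic data (`syndata`)

`generate_dataset` draws counts as Gamma–Poisson (negative binomial):

    y_gi ~ NB(mean = L_i · exp(b_j) · p_g(k, j),  size = θ_g)

with softmax gene profiles p(k, j) per (cluster k, individual j), planted
marker genes (default +2 log2FC in their cluster), treatment log-fold effects
on designated genes, donor intercepts b_j ~ N(0, 0.15²) applied identically to
all genes of a nucleus (they scale the realized library), lognormal library
sizes (median ≈ 2000 UMIs, matching typical striatal snRNA-seq depth; log-SD
0.4), gene dispersions θ ~ log-uniform on [0.5, 10], and a ~1% mitochondrial
gene fraction with a mild abundance boost giving ~1.5% mitochondrial reads.
The 0.149 running-suppression factor, the 6-animals-per-group design, and the
QC thresholds reflect the study conditions; dispersion and library
distributions are calibration choices (the study reports only median UMI
ranges), not claims.

Specific structures:

- **Maturity gradient.** When enabled, each nucleus gets a uniform maturity
  rank u and expresses a Bernoulli-masked subset of genes with keep
  probability interpolating over [0.25, 1.0]; breadth of expression is the
  planted "immaturity". Counts are renormalized so library size stays
  independent of breadth.
- **QC violators.** Planted barcodes violate exactly one rule each (low UMI,
  low gene, high UMI, high gene, high mitochondrial fraction). When violators
  are requested, clean barcodes are clamped into a safe library band
  (1500–12,000 expected counts) so survivor counts are exact arithmetic; a
  low-UMI barcode may also have few genes, but first-violated-rule attribution
  (UMI floor first) keeps the report deterministic.
- **Mediation structure.** Mediator genes: the gene's individual-level
  expression shifts with stress plus donor noise, and log running distance
  responds to the gene's *donor-specific* (within-group) component.
  Consequence genes respond to the within-group standardized log running
  distance. The within-group coupling is deliberate: in a linear mediation
  screen the gene↔distance partial association (given treatment) is exactly
  symmetric between the two regression directions, so a gene whose entire
  treatment association flows through the planted arm is flagged in *both*
  directions — the true direction is unidentifiable. Coupling downstream
  responses to within-group variation nulls the reverse direction's treatment
  arm by construction and makes direction recovery a well-posed test. This is
  also the honest statement of a limitation: for real genes whose stress
  association is fully transmitted through running (or vice versa), this
  screen cannot distinguish cause from consequence.

The generator does **not** emulate: ambient RNA, doublets beyond the planted
QC violators, batch effects between pools, zero inflation (the downstream
model is NB, so none is added), per-gene donor×gene interaction variance
(donor intercepts are shared across genes and are therefore absorbed by the
library-size offset downstream). Passing tests on synthetic data demonstrate
that the machinery is correct under its stated model, not that the model
captures every artifact of real tissue. The separate `simulate_nb_gene`
simulator puts the donor intercept on a single gene's mean and defines the
conditions for the mixed-model calibration studies (12 donors × 200 nuclei,
donor SD 0.5 — a deliberately strong donor effect).

## Quality control (`qc`)

Thresholds default to 750 ≤ UMI ≤ 20,000, 500 ≤ genes ≤ 5,000, mitochondrial
fraction ≤ 5%. Exclusion semantics are strict inequalities (a barcode at
exactly 750 UMIs or exactly 5% mito is kept). "Mitochondrial fraction"
defaults to mitochondrial UMIs over total UMIs — the standard reading — with
a `gene_fraction` mode (detected mito genes over detected genes) available
because the phrase "% of all genes" is ambiguous. Removals are attributed to
the first violated rule in the fixed order (UMI floor, gene floor, UMI
ceiling, gene ceiling, mito) so reports are deterministic and additive.
Genotype-based doublet removal is replaced by trusting the generator's
individual labels; no expression-based doublet caller is included.

## Clustering and resolution selection (`cluster`)

- **Normalization.** Pearson residuals of a per-gene Gamma–Poisson fit with
  library offset: fitted means μ_ig = t_i·(Σy_g/Σt); per-gene overdispersion
  by a method-of-moments estimate (clipped to keep Poisson-like genes near
  Poisson); residuals clipped to ±√n. This is a deliberate re-specification of
  regression-based variance stabilization with the same intent (no parity with
  any particular published implementation is attempted). All-zero genes give
  all-zero residual columns.
- **PCA.** 50 components by default over the 3000 most variable residual
  genes; deterministic sign convention (largest-magnitude loading positive).
- **SNN graph.** k = 50 nearest neighbors (self included), Jaccard weights,
  prune = 0 (all positive overlaps kept) — the study's graph parameters.
- **Community detection.** Leiden refinement of modularity (RBConfiguration)
  at a given resolution, seeded; labels relabeled by decreasing size.
- **K-MST.** Union of k = 5 successive edge-disjoint MSTs on Euclidean
  distances in the embedding (Prim's algorithm on the dense distance matrix,
  ties broken toward the lowest index, duplicates allowed). k = 5 is a
  default, not a reported value; the union has exactly k(n−1) edges whenever
  the construction succeeds, and infeasible k (possible once k approaches
  n/2 — the complete graph holds at most ⌊n/2⌋ edge-disjoint spanning trees,
  and the greedy construction can fall short of that bound) raises a clear
  error. A variant on SNN dissimilarities exists for comparison but is not
  the default.
- **Selection statistic.** The within-cluster edge count is standardized with
  exact first and second moments under uniform permutation of the observed
  label multiset (cluster sizes fixed). The moments were derived analytically
  and are verified in the tests against exhaustive enumeration (n ≤ 8) and
  20,000-permutation Monte Carlo (n = 200). Degenerate labelings (one
  cluster, or all clusters singletons) have zero null variance and are
  excluded from the argmax; ties prefer fewer clusters, then lower
  resolution. The default grid is 0.05–2.0 in steps of 0.05; the recovery
  studies use a 0.1–1.2 step-0.1 grid with 20 PCs and 600 genes to keep the
  replicated studies fast — a scan-granularity choice, not a change to the
  statistic.
- **Identity calls.** Marker panels are scored as mean library-normalized
  expression relative to the gene's overall mean; the maximal panel names the
  cluster, exact ties are reported as ties, and empty panel intersections
  yield "unassigned".

UMAP and other 2-D layouts are visualization conveniences and no statistic
depends on them; none is required by the pipeline.

## Maturity (`maturity`)

The score follows the transcriptional-diversity principle: per-nucleus
detected-gene count; per-gene Pearson correlation of log-normalized expression
with that count; the top 200 correlated genes form the signature; the raw
score is mean signature expression, optionally kNN-smoothed in PCA space
(off by default — the analyses only use ordinal comparisons); the final score
is the empirical CDF (midranks), so any strictly monotone transform of the
raw signal gives identical scores. Higher score = broader expression = less
differentiated. The published description of such scores states at one point
that both ends of the scale are "mature"; this implementation resolves the
contradiction in favor of the core principle (diversity ⇒ immature ⇒ high
score). A constant matrix gives every nucleus 0.5 by the midrank convention.

Cluster comparisons use a Gaussian LMM (REML, statsmodels): score ~ cluster
fixed effect + individual random intercept, Wald tests per non-reference
cluster. A cluster confined to a single individual triggers a confounding
warning but still fits.

## Differential expression (`de`)

Two-step, mirroring the two-tool workflow it re-implements:

1. **Dispersion.** Per-gene Gamma–Poisson profile likelihood with
   fixed-effect means and log-library offset (random effect ignored at this
   stage); θ clamped to [1e−3, 1e6]; all-zero genes flagged untestable.
2. **Mixed fit.** NB log-link model with donor random intercept and the
   natural log of per-nucleus library size as offset. The joint (β, b) mode
   is found by full Newton with block elimination; σ² is profiled on a
   Laplace-REML criterion (the β block is integrated out through the Schur
   complement S of the joint information, adding ½log|S| to the Laplace
   objective — without this REML-type correction the variance component is
   biased low at 12 donors and Wald type-I error is inflated). SE(β) comes
   from S⁻¹, so random-effect uncertainty propagates. Wald tests use a t
   reference with df = (#individuals − rank of the individual-level design):
   with donor-level contrasts the effective information is the donor count,
   and a normal reference is anticonservative at n = 12. Boundary fits
   (σ² → 0) fall back to the fixed-effects NB GLM and are flagged
   `singular_refit`; non-convergent genes are flagged and excluded from the
   FDR denominator (auditable via the flag column).

Detection filter: genes in ≥1% of nuclei (a logged default; the source
workflow does not state one). Designs: stress, wheel, 2×2 with interaction,
per-window running-distance covariate (standardized, broadcast from
individuals to nuclei), and ANCOVA (stress + distance + interaction).

**Storey q-values** use the smoother π̂₀ estimate (cubic fit over
λ = 0.05…0.95 evaluated at λ_max, clipped to [0,1]); forcing π̂₀ = 1
reproduces Benjamini–Hochberg exactly, which the tests assert as a vector
identity. Enrichment p-values across gene sets use BH (the named method is
reserved for the DE genes, where it is named).

Marker tests between nucleus groups are Wilcoxon rank-sum with tie-corrected
normal approximation on log-normalized expression (all-tie genes get p = 1).
Over-representation is one-sided Fisher per GMT set with GeneRatio = hits /
input genes in the universe. Preranked GSEA uses the |stat|-weighted
running-sum ES with a seeded gene-label permutation null;
NES = ES / mean |null ES of matching sign|; positive NES = activated. The
deterministic ES is cross-checked against an independent implementation in
the tests.

## State scores and composition (`states`)

M1/M2/metabolism scores are raw transcript-count ratios (set counts / total
counts per nucleus), hence depth-invariant, in [0, 1], and exactly 1 for the
all-genes set. Curated gene lists are user-supplied GMT files; the shipped
`synthetic_state_sets` helper generates clearly-synthetic stand-ins for
testing only. Score comparisons reuse the Gaussian LMM. Composition tests:
Pearson χ² without continuity correction on the subcluster × group table
(the study's tables are large-sample, so Yates correction is immaterial) and
two-sided Fisher exact tests per (subcluster vs rest) × (group pair) at
α = 0.05, uncorrected by default with a BH option — matching the per-test
reporting style; sidedness was not stated and two-sided is the conservative
choice. The up/down goodness-of-fit statistic is the closed form
(n_up − n_down)²/(n_up + n_down) with a 1-df χ² tail.

## Mediation (`mediation`)

Linear structural pair M = a·T + ε, Y = c′·T + b·M + ε on per-individual mean
corrected expression and 6-week running distance; ACME = a·b, ADE = c′,
total = a·b + c′ (exact for the linear case). Confidence intervals are
percentile bootstrap over individuals (default 1000 resamples, 95%),
significance = CI excludes zero — chosen over quasi-Bayesian draws for its
weaker distributional assumptions; the resample count and seed are always
recorded. Degenerate bootstrap draws (a resample with constant treatment or
mediator) reuse the previous draw. The screen runs each candidate gene in
both directions with per-gene seeds spawned deterministically from the root
seed. Multiplicity across the screened genes is per-gene by default (matching
the reporting style of the analyses this reproduces), with BH available.

The direction-screen fixtures were fixed by a design-phase power analysis:
12 runner individuals per group, mediator gene (stress shift −1.0, running
slope 1.5 per donor-specific expression unit, donor noise 0.3), consequence
gene (slope 0.6 per within-group SD of log running, noise 0.35). These sizes
put the transmitted signal at roughly the noise level — large enough for
≥80% detection of the true direction at n = 24, small enough that the
(structurally null) reverse direction stays insignificant.

## Problem sizes used by the replicated studies

Cluster-number recovery runs 10 replicates each at K = 3 and K = 5 with 3000
nuclei, 600 genes and marker log2FC 1.5. Mixed-model calibration uses 1000
null genes and 60 effect genes at 12 donors × 200 nuclei with donor SD 0.5;
the recall/FDR study runs the full DE pipeline on 2000 genes × 2400 nuclei
with 40 planted ±1 log2FC genes. Maturity recovery uses 2000 nuclei × 1000
genes. Mediation coverage uses 100 replicates of the 24-individual linear
chain with 1000 bootstrap resamples. These are the package's own study sizes,
chosen to estimate each property with useful precision while keeping the full
suite fast on a laptop-class machine.

## Known limitations

- The donor intercept in the full generator is shared across genes and is
  absorbed by the library offset; gene-level donor variation is exercised only
  through `simulate_nb_gene`. Real data show gene-specific donor effects.
- The NB GLMM uses a single random intercept (no random slopes) and a
  Laplace/REML approximation; very low counts with few donors can leave the
  variance component at the boundary, where inference falls back to the GLM.
- Mediation direction is identifiable only when the reverse direction's
  treatment arm is null (see above); the screen inherits the usual
  sequential-ignorability assumptions and offers no sensitivity analysis.
- The resolution-selection statistic conditions on the observed cluster
  sizes; it compares resolutions on a fixed graph and is not a test of
  whether any clustering exists.
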