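# Methods

## Model and procedure

The pipeline treats a paired pre-/on-treatment expression cohort as a
single weighted network over the genes of interest and asks which groups of
genes change *together* under therapy.

**Expression changes.** For every patient with both timepoints, the
per-gene change is the difference of normalized (log-scale) values,
on-treatment minus pre-treatment. Each gene's row of changes is divided by
its cross-patient standard deviation (sample convention, n−1) but *not*
mean-centered: the sign of a change is biologically meaningful and module
scores must preserve it. Zero-variance genes are set to zero with a warning
rather than dropped, so the expression matrix stays aligned with the
network gene set; the network-construction step then excludes them
explicitly, since a correlation with a constant row is undefined.
Upstream, genes with fewer than 10 raw counts in strictly more than 90% of
samples are removed, and normalized columns are quantile-normalized onto
their common mean-rank reference (ties receive the mean of the reference
values across the tied rank span). Whether quantile normalization runs over
all loaded samples is a flag; the default normalizes everything that was
loaded, which matches how a cohort-level normalization is actually applied.

**Network.** The topology comes from a PPI edge list with confidence
scores. The filter chain is fixed: confidence cutoff (default 700, the
conventional "high confidence" level; the exact threshold used on the real
cohort is not recoverable, so it is config-exposed), optional
compartment-overlap sparsification (edges whose endpoints have disjoint
annotated compartment label sets are removed; unannotated genes are
permissive — our concretization of a procedure whose details live
elsewhere, off by default), a *single-pass* minimum-degree-5 filter
(degrees measured on the input topology, not iterated to a 5-core — the
intent is to discard initially unreliable low-degree vertices, not to find
a core decomposition), expansion of a core gene list to its full PPI
neighborhood, and finally the largest connected component (ties broken by
the lexicographically smallest vertex set for determinism). Edge weights:
ρ = Pearson correlation of scaled changes, ρ_shifted = (1+ρ)/2,
cost = 1/ρ_shifted with a similarity floor of 1e−6 so a perfectly
anti-correlated edge gets a large finite cost (1e6) instead of an infinite
one, preserving the cost ordering while keeping the metric finite.

**Diffusion.** L = I − K⁻¹C_N with C_N the shifted-correlation adjacency
(zero diagonal) and K its row sums. D(τ) = exp(−τL) is evaluated through
the eigendecomposition of the symmetric similar matrix K^(−1/2) C_N
K^(−1/2), computed once per network; each scale then costs two matrix
products. Negative entries from roundoff are clipped at zero and rows
renormalized, guarded by a 1e−8 row-mass error budget (violations raise).
A dense scaling-and-squaring fallback exists for the (never observed) case
that the eigensolver fails. The scale grid is 101 points with log10(τ)
uniform on [−2, 2].

**Curvature.** κ_ij(τ) = 1 − W₁(p_i, p_j)/d_ij. Two deliberate conventions:
the ground cost inside W₁ is the shortest-path metric, while the
denominator d_ij is the *direct* edge cost. Consequently κ(τ=0) can be
positive on an edge whose endpoints are connected more cheaply through a
multi-hop path; nothing is clamped. On fixtures where every direct edge is
itself a shortest path, κ(τ=0) = 0 exactly, and κ → 1 as the diffusion
reaches stationarity on a connected graph.

**Exact transport.** For a graph-metric ground cost, W₁ equals the optimal
value of the uncapacitated min-cost flow that routes the node imbalance
p − q through the graph's edges at their costs. The default solver
implements successive shortest paths with node potentials (reduced costs
stay nonnegative, so Dijkstra applies; numba-compiled). Each augmentation
zeroes a node imbalance or empties a cancelling arc, so iterations stay
near the number of imbalanced nodes. Termination tolerance is 1e−9 mass
per node during sweeps (worst-case κ error ≲ 1e−6, far below meaningful
curvature resolution) and 1e−12 for single solves. Two independent
backends exist for validation: a coupling-LP solve (HiGHS) restricted to
the two supports — the reference implementation, optionally with
cumulative-mass support truncation at δ = 1e−4 for large networks — and a
log-domain Sinkhorn solver (regularization 0.005 × max ground cost,
reporting the transport cost of its coupling), which agrees with the exact
solvers within 1% on the test fixtures and exists for networks too large
for exact solves.

**Critical scale and integral curvature.** τ_crit is the first *grid*
scale at which the 99th percentile (linear interpolation between order
statistics) of all edge curvatures reaches 0.75 — grid-point semantics,
not an interpolated crossing, because the curvature field is only ever
materialized on the grid. κ̄_crit integrates each edge's trajectory over
linear τ from 0 to τ_crit by the trapezoid rule, treating the log-spaced
grid as an uneven partition and prepending the exact point (τ=0, κ=0). An
optional flag divides by τ_crit (a mean rather than an integral); the
default is the literal integral. Because everything downstream uses only
scales up to τ_crit, the pipeline's sweep stops at the first crossing by
default (`stop_at_crit`), roughly halving the computation; a full sweep is
a flag away.

**Modules.** κ̄_crit values weight Louvain modularity (networkx
implementation, resolution 1, seeded and reproducible; optional
best-of-k restarts). Newman modularity assumes nonnegative weights while
κ̄_crit is negative on bridges; by default negative weights are clamped to
zero for the objective — zero weight is already the maximal penalty a
between-module edge can receive in the modularity sum, and clamping keeps
the objective well-defined. A passthrough mode feeds raw weights to the
reference implementation for comparison. Module labels are renumbered by
descending size. Module scores are per-patient means of the scaled changes
over module genes.

**Clinical statistics.** Multiple Cox regression of overall survival on
all module scores jointly (lifelines, Efron ties — the conventional choice
when the tie method is unspecified); Kaplan-Meier curves with a two-group
log-rank test on the median split of a score; Kruskal-Wallis (tie
corrected; defined as H=0, p=1 when every observation is tied) across
response groups after collapsing CR and PR into one responder group and
removing NE patients; per-gene two-sample Wilcoxon tests (exact
distribution when the pooled sample is ≤ 20 without ties, otherwise the
normal approximation with continuity and tie corrections) with
Benjamini-Hochberg adjustment *within* the tested module; hypergeometric
upper-tail over-representation of gene sets with BH-FDR across sets, the
universe defaulting to the analyzed network's gene set (config-overridable).

## Synthetic data: what it emulates, what it does not

The generator plants everything the pipeline is supposed to find.

- **Topology**: a planted-partition graph, defaults 120 genes in 6 blocks,
  within-block edge probability 0.4, between-block 0.01, confidence scores
  uniform in [700, 999]. Block density is chosen so that a block behaves
  like a tight functional module after the degree-5 filter (expected
  within-degree ≈ 7.6); bridge edges are added (and recorded) only if the
  graph is disconnected. Three core genes per block are the block's
  highest-degree vertices: therapy-relevant core genes are hubs in curated
  interactomes, which is what lets a small core's PPI neighborhood span
  most of the analysis network.
- **Expression**: per patient and module a latent loading λ ~ N(0,1); gene
  g in module m changes by a_g·λ_{p,m} + N(0, 0.5) with amplitudes
  a_g ~ U(0.5, 1.5). Pre-treatment values sit on a log2-like baseline
  (N(8, 1.5) plus per-sample noise), on = pre + change, raw counts are
  2^value rounded. 43 matched patients plus 8 pre-only and 15 on-only
  samples mirror the shape of a real paired cohort; 8 near-zero-count
  decoy genes exercise the expression filter; 400 unstructured background
  genes stand in for the rest of the transcriptome so that quantile
  normalization operates at a realistic scale — normalizing only ~120
  network genes would impose a strong per-sample distribution constraint
  that couples module scores, an artifact real transcriptome-wide
  normalization does not have.
- **Clinical**: survival is exponential with hazard h₀·exp(−β·λ_{p,m*})
  for the designated protective module m* (the last block), β = 1 by
  default, h₀ = ln 2/24 (median survival 24 time units at λ = 0), with
  independent exponential censoring calibrated to censor ≈ 30% of
  baseline patients. Response is ordinal on 1.5·λ + logistic noise with
  thresholds at the empirical latent quantiles fixing the group
  proportions (PD 50%, SD 29%, PR 14%, CR 7% of evaluable patients — CR
  and PR deliberately small, PD largest); one patient is relabeled NE to
  exercise the removal rule.

What passing tests on these data do **not** show: robustness to
library-size and composition effects (counts are synthesized from the
log-scale values, not from a read-level model), to hub-dominated scale-free
PPI topology, to correlated module loadings, to non-proportional hazards,
or to batch structure. The generator's rank-1-per-module signal is the
analysis model's best case; recovery rates on it are an upper bound.

## Numerical choices and degenerate inputs

- Sample (n−1) standard deviations throughout scaling.
- Quantile-normalization ties: mean of the reference values over the tied
  rank span.
- Duplicate symbols after ID mapping: the row with the highest mean raw
  count wins; discards are logged.
- "More than 90% of samples" is strict (>), so a gene low in exactly 90%
  survives.
- Component ties and module-label ties break lexicographically; Louvain is
  seeded (default 0).
- The curvature sweep is deterministic given config; the pipeline caches it
  keyed by a hash of the upstream configuration, stored at full precision
  (%.17g, round-trip parsing, C-ordered) so cached and fresh runs are
  bit-identical.
- Degenerate inputs raise early with the offending genes named: empty
  filters, absent core genes, disconnected networks, zero-variance genes,
  all-censored survival, single-group comparisons, degenerate median
  splits.

## Problem sizes used in the test suite

Unit tests run on graphs of 2–36 vertices against brute-force oracles
(exhaustive simple-path enumeration for shortest paths, integer-arithmetic
network simplex and closed-form path-graph CDF formulas for W₁, full
partition enumeration for modularity, combinatorial enumeration for rank
tests). End-to-end recovery runs the full pipeline on 20 seeded synthetic
studies at the default conditions (120 genes / 6 modules / 43 patients /
noise 0.5); survival calibration uses 200 replicates at n = 300. These
sizes were chosen so the entire suite exercises every stage at full
fidelity while remaining a desk-scale computation.

## Full-scale replay

Reproducing the real-cohort analysis requires the public paired
pre-/on-treatment melanoma expression data (raw counts plus
rlog-normalized values and RECIST/survival metadata), the STRING v11
protein-links export mapped to gene symbols, and the PD-1-blockade core
gene list. With those files, the documented configuration is the package
default: confidence ≥ 700 (the exact original cutoff is not published;
sweep 400–900 if matching edge counts matters), degree ≥ 5 single-pass,
core neighborhood, largest component, 101 scales in [10⁻², 10²],
percentile 99 / κ ≥ 0.75, Louvain resolution 1. When comparing a replay
against previously reported values for such a cohort, two sources of
legitimate variation must be held fixed: Louvain stochasticity (use the
same seed policy, or best-of-k restarts) and the κ̄_crit convention (raw
integral versus τ_crit-normalized mean — both are provided behind the
`normalize_integral` flag, and the within/between means scale accordingly).

## Known limitations

- Exact W₁ scales with edges × imbalanced nodes per scale; networks beyond
  a few thousand genes need the Sinkhorn backend or support truncation.
- The κ(τ=0) ≠ 0 effect on non-geodesic direct edges means trajectories on
  real correlation networks do not all start exactly at zero.
- Cox regression uses module scores only; no clinical covariate adjustment.
- Generic set-based over-representation only: no ontology-graph-aware
  enrichment semantics.
- Entrez-to-symbol mapping is a plain two-column table, not an annotation
  database.
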