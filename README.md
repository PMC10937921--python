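# dyncurv

Multi-scale geometric network analysis for treatment-response transcriptomics.

`dyncurv` discovers modules of genes whose expression changes move together
in response to a therapy, using the *dynamic Ollivier-Ricci curvature* of a
protein-interaction-constrained co-expression network, and then tests those
modules against clinical outcomes (overall survival and RECIST response).
It is aimed at computational biologists analyzing paired pre-/on-treatment
RNA-seq cohorts, and ships a fully synthetic data generator so every stage
of the pipeline can be exercised and validated without access to patient
data.

## The method

Given per-patient expression changes Δ (on-treatment minus pre-treatment,
each gene scaled by its cross-patient standard deviation without centering),
a weighted network is built on a PPI topology: each PPI edge carries the
Pearson correlation ρ of its endpoints' changes, shifted to a similarity
ρ_shifted = (1 + ρ)/2 ∈ [0, 1], with transport cost 1/ρ_shifted.

Information diffusion over the network is the heat semigroup of the
random-walk Laplacian

    L = I − K⁻¹ C_N,      D(τ) = e^(−τL),

where C_N is the shifted-correlation adjacency and K its row sums. Row i of
D(τ) is a Dirac delta at gene i diffused to scale τ. For every edge (i, j)
and scale τ, the Ollivier-Ricci curvature is

    κ_ij(τ) = 1 − W₁(p_i, p_j) / d_ij,

with W₁ the Wasserstein-1 distance under the shortest-path ground metric
and d_ij the direct edge cost. κ starts at 0 (deltas one edge apart), ends
at 1 (identical stationary distributions), and at intermediate scales
separates within-community edges (high κ) from bridges (low or negative κ).

Sweeping τ over 101 log-spaced scales in [10⁻², 10²], the *critical scale*
τ_crit is the first grid scale at which the 99th percentile of edge
curvatures reaches 0.75. Each edge's κ̄_crit = ∫₀^τcrit κ dτ is then used as
the modularity weight in Louvain clustering (resolution 1), partitioning
the genes into modules. Per-patient module scores (mean scaled change over
module genes) are tested with multiple Cox regression, Kaplan-Meier/log-rank
on a median split, Kruskal-Wallis across response groups, per-gene Wilcoxon
tests with Benjamini-Hochberg FDR, and hypergeometric over-representation
against gene-set collections.

W₁ is computed exactly: by default through an uncapacitated min-cost-flow
formulation on the network itself (numba-compiled successive shortest
paths), with a coupling-LP reference backend and an optional
entropy-regularized Sinkhorn backend.

## Worked example

```python
import dyncurv as dc

bundle = dc.simulate_study(seed=1)          # synthetic 43-patient study
config = dc.PipelineConfig()
result = dc.run_stages(
    bundle.study, bundle.topology, bundle.truth.core_genes, config,
    clinical=bundle.clinical, gene_sets=bundle.gene_sets,
)
print(round(result.tau_crit, 3), result.assignment.sizes())
print(round(result.edge_summary["mean_within"], 3),
      round(result.edge_summary["mean_between"], 3))
```

prints

```
2.291 {1: 19, 2: 19, 3: 18, 4: 18, 5: 17, 6: 15}
0.668 -0.58
```

i.e. the critical scale was reached at τ ≈ 2.29, six modules were found
(sizes 19…15), and the mean integrated curvature is strongly positive
within modules (0.67) and negative between them (−0.58) — the geometric
signature that the partition follows real community structure. The planted
protective module is recovered as module 4 and ranks first in the Cox
regression (`result.cox.summary`: HR 0.36, p = 0.003; all other modules
p > 0.4).

The same pipeline runs file-in/file-out from the command line:

```sh
dyncurv simulate --seed 1 --out-dir inputs/
dyncurv run-all --config config.yaml
```

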