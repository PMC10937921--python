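"""End-to-end orchestration: expression -> network -> curvature -> modules -> clinic.

``run_stages`` composes the library stages on in-memory objects and is what
tests exercise; ``run_pipeline`` adds file I/O, artifact writing, a JSON run
manifest, and a cache for the curvature sweep (keyed by a hash of the
configuration fields the sweep depends on, so downstream-only parameter
changes do not recompute it).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import (
    cox_multiple,
    km_logrank,
    kruskal_wallis,
    per_gene_response_test,
    response_groups,
)
from .curvature import (
    CurvatureField,
    curvature_sweep,
    default_tau_grid,
    find_tau_crit,
    integral_curvature,
)
from .enrichment import GeneSetCollection, hypergeometric_ora, read_gmt
from .expression import (
    DifferenceMatrix,
    ExpressionStudy,
    filter_low_expression,
    paired_difference,
    quantile_normalize,
    read_clinical,
    read_expression,
    scale_differences,
)
from .modules import (
    ModuleAssignment,
    louvain_modules,
    module_scores,
    within_between_summary,
)
from .network import (
    WeightedGeneNetwork,
    build_correlation_network,
    compartment_sparsify,
    filter_confidence,
    filter_min_degree,
    largest_component,
    read_ppi,
    select_core_neighborhood,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    The curvature-scale constants default to the method's canonical values:
    101 pseudotime points with log10(tau) in [-2, 2], critical-scale rule
    "99th percentile of edge curvature >= 0.75", Louvain resolution 1 and a
    single-pass minimum-degree threshold of 5.
    """

    # input paths (unused when stages are driven with in-memory objects)
    counts: str | None = None
    norm: str | None = None
    samples: str | None = None
    clinical: str | None = None
    ppi: str | None = None
    core_genes: str | None = None
    gene_sets: str | None = None
    compartments: str | None = None
    out_dir: str = "dyncurv_out"

    # expression handling
    apply_low_expression_filter: bool = True
    min_count: int = 10
    frac_threshold: float = 0.90
    apply_quantile_normalization: bool = True

    # network construction
    min_score: int = 700
    min_degree: int = 5
    similarity_floor: float = 1e-6

    # curvature sweep
    tau_points: int = 101
    tau_log10_min: float = -2.0
    tau_log10_max: float = 2.0
    percentile: float = 99.0
    kappa_threshold: float = 0.75
    ot_method: str = "flow"
    support_delta: float = 1e-4
    stop_at_crit: bool = True
    normalize_integral: bool = False

    # module detection
    resolution: float = 1.0
    louvain_seed: int = 0
    negative_weights: str = "clamp"
    louvain_restarts: int = 1

    def validate(self) -> None:
        if self.tau_points < 1:
            raise ValueError("tau grid needs at least one point")
        if self.tau_log10_min >= self.tau_log10_max and self.tau_points > 1:
            raise ValueError("tau grid range is empty")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.ot_method not in ("flow", "exact_lp", "sinkhorn"):
            raise ValueError(f"unknown OT method {self.ot_method!r}")
        if self.negative_weights not in ("clamp", "passthrough"):
            raise ValueError("negative_weights must be 'clamp' or 'passthrough'")

    def tau_grid(self) -> np.ndarray:
        return default_tau_grid(self.tau_points, (self.tau_log10_min, self.tau_log10_max))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def curvature_cache_key(self) -> str:
        relevant = {
            k: getattr(self, k)
            for k in (
                "counts", "norm", "samples", "ppi", "core_genes", "compartments",
                "apply_low_expression_filter", "min_count", "frac_threshold",
                "apply_quantile_normalization", "min_score", "min_degree",
                "similarity_floor", "tau_points", "tau_log10_min", "tau_log10_max",
                "percentile", "kappa_threshold", "ot_method", "support_delta",
                "stop_at_crit",
            )
        }
        blob = json.dumps(relevant, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    network: WeightedGeneNetwork
    field: CurvatureField
    tau_crit: float
    tau_crit_index: int
    kappa_crit: pd.Series
    kappa_bar: pd.Series
    assignment: ModuleAssignment
    edge_summary: dict
    scores: pd.DataFrame
    scaled_diff: DifferenceMatrix
    cox: object | None = None
    km: object | None = None
    kruskal: dict | None = None
    gene_response: pd.DataFrame | None = None
    enrichment: dict | None = None
    manifest: dict = field(default_factory=dict)


def prepare_differences(study: ExpressionStudy, config: PipelineConfig) -> DifferenceMatrix:
    if config.apply_low_expression_filter:
        study = filter_low_expression(study, config.min_count, config.frac_threshold)
    if config.apply_quantile_normalization:
        study = quantile_normalize(study)
    return scale_differences(paired_difference(study))


def build_network(
    topology: nx.Graph,
    scaled: DifferenceMatrix,
    core_genes,
    config: PipelineConfig,
    compartments: dict | None = None,
) -> WeightedGeneNetwork:
    """Apply the filter chain and attach correlation weights.

    Order: confidence cutoff, optional compartment sparsification, single-
    pass degree filter, core neighborhood, largest component. The topology
    is first restricted to genes present with nonzero variance in the
    scaled differences (correlation is undefined otherwise).
    """
    informative = scaled.values.index[scaled.values.std(axis=1) > 0]
    topo = topology.subgraph(set(informative) & set(topology.nodes())).copy()
    topo = filter_confidence(topo, config.min_score)
    if compartments:
        topo = compartment_sparsify(topo, compartments)
    topo = filter_min_degree(topo, config.min_degree)
    subset = select_core_neighborhood(topo, core_genes)
    topo = largest_component(topo, subset)
    return build_correlation_network(topo, scaled, config.similarity_floor)


def run_stages(
    study: ExpressionStudy,
    topology: nx.Graph,
    core_genes,
    config: PipelineConfig,
    clinical: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    compartments: dict | None = None,
    cached_field: CurvatureField | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    config.validate()
    scaled = prepare_differences(study, config)
    network = build_network(topology, scaled, core_genes, config, compartments)
    logger.info("network: %d genes, %d edges", network.n_nodes, network.n_edges)

    if cached_field is not None:
        fld = cached_field
    else:
        stop_kwargs = (
            {"stop_percentile": config.percentile, "stop_threshold": config.kappa_threshold}
            if config.stop_at_crit
            else {}
        )
        fld = curvature_sweep(
            network,
            tau_grid=config.tau_grid(),
            method=config.ot_method,
            support_delta=config.support_delta,
            **stop_kwargs,
        )
    tau_crit, idx = find_tau_crit(fld, config.percentile, config.kappa_threshold)
    kappa_crit = pd.Series(
        fld.kappa[:, idx],
        index=pd.MultiIndex.from_tuples(fld.edges, names=["gene_a", "gene_b"]),
        name="kappa_crit",
    )
    kappa_bar = integral_curvature(fld, idx, normalize=config.normalize_integral)
    kb_edges = pd.Series({e: kappa_bar[e] for e in fld.edges})

    assignment = louvain_modules(
        network,
        kb_edges,
        resolution=config.resolution,
        seed=config.louvain_seed,
        negative_weights=config.negative_weights,
        n_restarts=config.louvain_restarts,
    )
    edge_summary = within_between_summary(assignment, kb_edges)
    scores = module_scores(assignment, scaled)

    cox = km = kruskal = gene_response = None
    if clinical is not None:
        cox = cox_multiple(scores, clinical)
        # follow up on the module with the strongest survival association
        focus = int(cox.summary["p"].idxmin().removeprefix("module_"))
        km = km_logrank(scores[focus], clinical)
        groups = response_groups(clinical)
        kruskal = {}
        for m in assignment.module_ids:
            h, p = kruskal_wallis(scores[m], groups)
            kruskal[m] = {"H": h, "p": p}
        gene_response = per_gene_response_test(scaled, assignment.genes_in(focus), groups)

    enrich = None
    if gene_sets is not None:
        universe = set(network.nodes)
        restricted = gene_sets.restricted_to(universe)
        enrich = {
            m: hypergeometric_ora(assignment.genes_in(m), restricted, universe)
            for m in assignment.module_ids
        }

    manifest = {
        "dyncurv_version": __version__,
        "versions": _versions(),
        "config": asdict(config),
        "n_genes": network.n_nodes,
        "n_edges": network.n_edges,
        "tau_crit": tau_crit,
        "tau_crit_index": idx,
        "n_modules": assignment.n_modules,
        "module_sizes": assignment.sizes(),
        "edge_summary": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in edge_summary.items()
        },
    }
    return PipelineResult(
        network=network,
        field=fld,
        tau_crit=tau_crit,
        tau_crit_index=idx,
        kappa_crit=kappa_crit,
        kappa_bar=kappa_bar,
        assignment=assignment,
        edge_summary=edge_summary,
        scores=scores,
        scaled_diff=scaled,
        cox=cox,
        km=km,
        kruskal=kruskal,
        gene_response=gene_response,
        enrichment=enrich,
        manifest=manifest,
    )


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import scipy

    return {"numpy": numpy.__version__, "scipy": scipy.__version__, "networkx": networkx.__version__}


def _read_compartments(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for gene, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, set()).add(label)
    return out


def _load_field_cache(path: Path) -> CurvatureField:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1], float_precision="round_trip")
    tau = np.array([float(c) for c in df.columns])
    meta = json.loads(path.with_suffix(".json").read_text())
    full = np.asarray(meta["tau_grid"], dtype=float)
    return CurvatureField(
        edges=[tuple(e) for e in df.index],
        tau_grid=full,
        # C-layout so downstream reductions sum in the same order as a fresh run
        kappa=np.ascontiguousarray(df.to_numpy(dtype=float)),
        complete=len(tau) == len(full),
    )


def _save_field_cache(fld: CurvatureField, path: Path) -> None:
    # %.17g + round_trip parsing keeps the cache bit-exact across runs
    fld.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    path.with_suffix(".json").write_text(json.dumps({"tau_grid": list(fld.tau_grid)}))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven run: read inputs, execute all stages, write artifacts."""
    config.validate()
    for name in ("counts", "norm", "samples", "ppi", "core_genes"):
        if getattr(config, name) is None:
            raise ValueError(f"config is missing required input path: {name}")
    study = read_expression(config.counts, config.norm, config.samples)
    topology = read_ppi(config.ppi)
    core = [l.strip() for l in open(config.core_genes) if l.strip()]
    clinical = read_clinical(config.clinical) if config.clinical else None
    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
    compartments = _read_compartments(config.compartments) if config.compartments else None

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = out / f"curvature_{config.curvature_cache_key()}.tsv"
    cached = _load_field_cache(cache) if cache.exists() else None
    if cached is not None:
        logger.info("reusing cached curvature sweep %s", cache.name)

    result = run_stages(
        study,
        topology,
        core,
        config,
        clinical=clinical,
        gene_sets=gene_sets,
        compartments=compartments,
        cached_field=cached,
    )
    if cached is None:
        _save_field_cache(result.field, cache)
    write_artifacts(result, out)
    return result


def write_artifacts(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.network.write_graphml(out / "network.graphml")
    result.network.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        {"kappa_crit": result.kappa_crit, "kappa_bar_crit": result.kappa_bar}
    )
    summary.to_csv(out / "edge_curvature_summary.tsv", sep="\t")
    result.assignment.to_frame().to_csv(out / "module_assignment.tsv", sep="\t", index=False)
    result.scores.to_csv(out / "module_scores.tsv", sep="\t")
    if result.cox is not None:
        result.cox.summary.to_csv(out / "cox_summary.tsv", sep="\t")
    if result.gene_response is not None:
        result.gene_response.to_csv(out / "gene_response_tests.tsv", sep="\t")
    if result.kruskal is not None:
        pd.DataFrame(result.kruskal).T.rename_axis("module").to_csv(
            out / "kruskal_wallis.tsv", sep="\t"
        )
    if result.enrichment is not None:
        frames = []
        for m, tab in result.enrichment.items():
            t = tab.reset_index()
            t.insert(0, "module", m)
            frames.append(t)
        pd.concat(frames).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    manifest = dict(result.manifest)
    if result.km is not None:
        manifest["km_logrank_p"] = result.km.p_value
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
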