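"""Synthetic study generator with planted module structure.

Emulates the statistical shape of a paired pre-/on-treatment immunotherapy
expression study constrained by a PPI network: a planted-partition
interaction topology, per-module latent expression-change signals with
per-patient loadings and gene-level noise, paired samples (plus unmatched
extras), proportional-hazards survival driven by one designated protective
module, and 4-level RECIST-like response labels correlated with that
module's latent loading. All generators are pure functions of their seeds,
and every latent quantity is recorded so downstream recovery can be scored
against ground truth.

Defaults mirror the real study's shape at reduced scale: 43 matched
patients (plus 8 pre-only and 15 on-only), 6 modules over 120 genes, a
response distribution with CR and PR as small groups (3 and 6 of 42), PD
the largest, and one NE patient to exercise the removal rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, write_gmt
from .expression import ExpressionStudy
from .network import write_ppi

#: response categories ordered worst to best, with target fractions of the
#: evaluable patients (PD largest; CR/PR small, as in the study's cohort)
RESPONSE_LEVELS = ("PD", "SD", "PR", "CR")
RESPONSE_TARGET_FRACTIONS = (0.5, 0.2857, 0.1429, 0.0714)

#: strength of the latent-loading effect on the ordinal response scale
RESPONSE_SLOPE = 1.5


@dataclass
class SyntheticTruth:
    """Ground truth latents behind a synthetic study."""

    seed: int
    module_labels: dict[str, int]
    core_genes: list[str]
    bridges: list[tuple[str, str]]
    n_modules: int
    protective_module: int
    loadings: pd.DataFrame | None = None  # patient x module
    amplitudes: pd.Series | None = None  # per-gene signal amplitude
    noise_sd: float | None = None
    low_expressed: list[str] = field(default_factory=list)
    beta: float | None = None  # log-hazard coefficient of the protective loading
    censor_rate: float | None = None

    def labels_for(self, genes) -> list[int]:
        return [self.module_labels[g] for g in genes]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def generate_topology(
    n_genes: int = 120,
    n_modules: int = 6,
    p_in: float = 0.4,
    p_out: float = 0.01,
    confidence_range: tuple[int, int] = (700, 999),
    seed: int = 0,
    core_per_module: int = 3,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition PPI topology with block-structured connectivity.

    Within-block edges appear with probability ``p_in``, between-block with
    ``p_out``; confidence scores are drawn uniformly from
    ``confidence_range``. The graph is made connected by adding recorded
    bridge edges between components if necessary. ``core_per_module`` genes
    per block are designated core genes, so the core-neighborhood expansion
    of the real pipeline reaches every planted module.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_modules < 1:
        raise ValueError("need at least one module")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    sizes = [n_genes // n_modules + (1 if i < n_genes % n_modules else 0) for i in range(n_modules)]
    labels: dict[str, int] = {}
    start = 0
    for m, size in enumerate(sizes, start=1):
        for g in genes[start : start + size]:
            labels[g] = m
        start += size

    expected_degree = p_in * (max(sizes) - 1) + p_out * (n_genes - max(sizes))
    if expected_degree < 1:
        warnings.warn(f"expected degree {expected_degree:.2f} < 1; graph will be sparse")

    g = nx.Graph()
    g.add_nodes_from(genes)
    lo, hi = confidence_range
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            p = p_in if labels[genes[i]] == labels[genes[j]] else p_out
            if rng.random() < p:
                g.add_edge(genes[i], genes[j], confidence=int(rng.integers(lo, hi + 1)))

    bridges: list[tuple[str, str]] = []
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=len, reverse=True)
    while len(comps) > 1:
        a = comps[0][int(rng.integers(len(comps[0])))]
        b = comps[1][int(rng.integers(len(comps[1])))]
        g.add_edge(a, b, confidence=int(rng.integers(lo, hi + 1)))
        bridges.append(tuple(sorted((a, b))))
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=len, reverse=True)

    # core genes are the best-connected vertices of each block: therapy-core
    # genes are hubs in curated PPI databases, which is what lets a small core
    # neighborhood span most of the analysis network
    core: list[str] = []
    start = 0
    for size in sizes:
        block = genes[start : start + size]
        by_degree = sorted(block, key=lambda v: (-g.degree(v), v))
        core.extend(sorted(by_degree[: min(core_per_module, len(block))]))
        start += size

    truth = SyntheticTruth(
        seed=seed,
        module_labels=labels,
        core_genes=core,
        bridges=bridges,
        n_modules=n_modules,
        protective_module=n_modules,
    )
    return g, truth


def generate_expression(
    topology: nx.Graph,
    truth: SyntheticTruth,
    n_patients: int = 43,
    noise_sd: float = 0.5,
    n_unmatched_pre: int = 8,
    n_unmatched_on: int = 15,
    n_low_expressed: int = 8,
    n_background: int = 400,
    seed: int = 0,
) -> ExpressionStudy:
    """Paired expression study with rank-1 per-module change signals.

    For matched patient p and module m the latent loading lambda_{p,m} is
    standard normal; gene g in module m changes by
    ``a_g * lambda_{p,m} + Normal(0, noise_sd)`` with amplitude
    ``a_g ~ Uniform(0.5, 1.5)``. Pre-treatment values sit on a log2-like
    baseline; on = pre + change, and raw counts are ``round(2**value)`` so
    the low-expression filter is exercisable. ``n_low_expressed`` decoy
    genes outside the topology carry near-zero counts and should be removed
    by that filter. ``n_background`` unstructured well-expressed genes
    emulate the remainder of the transcriptome: cross-sample quantile
    normalization acts on the whole measured gene set, and at transcriptome
    scale it barely constrains any one gene, which a network-genes-only
    matrix would not reproduce. Unmatched pre-only/on-only patients
    contribute columns that the pairing step must drop.
    """
    if n_patients < 4:
        raise ValueError("need at least 4 matched patients")
    rng = np.random.default_rng(seed)
    genes = sorted(topology.nodes())
    width = len(str(n_low_expressed)) if n_low_expressed else 1
    decoys = [f"LOW{i + 1:0{width}d}" for i in range(n_low_expressed)]
    background = [f"BG{i + 1:04d}" for i in range(n_background)]
    all_genes = genes + decoys + background

    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    pre_only = [f"UPRE{i + 1:02d}" for i in range(n_unmatched_pre)]
    on_only = [f"UON{i + 1:02d}" for i in range(n_unmatched_on)]

    modules = sorted(set(truth.module_labels.values()))
    load = rng.standard_normal((n_patients + n_unmatched_on, len(modules)))
    loadings = pd.DataFrame(load, index=patients + on_only, columns=modules)
    amplitudes = pd.Series(rng.uniform(0.5, 1.5, size=len(genes)), index=genes)

    baseline = pd.Series(rng.normal(8.0, 1.5, size=len(genes)), index=genes)
    if decoys:
        baseline = pd.concat(
            [baseline, pd.Series(rng.normal(1.5, 0.5, size=len(decoys)), index=decoys)]
        )
    if background:
        baseline = pd.concat(
            [baseline, pd.Series(rng.normal(8.0, 1.5, size=len(background)), index=background)]
        )

    sample_ids, meta_rows = [], []
    columns: dict[str, np.ndarray] = {}

    def pre_profile() -> np.ndarray:
        return baseline[all_genes].to_numpy() + rng.normal(0.0, 0.3, size=len(all_genes))

    def change_profile(patient: str) -> np.ndarray:
        lam = loadings.loc[patient]
        sig = np.array(
            [amplitudes[g] * lam[truth.module_labels[g]] for g in genes]
        )
        delta = np.concatenate([sig, np.zeros(len(decoys) + len(background))])
        return delta + rng.normal(0.0, noise_sd, size=len(all_genes))

    for p in patients:
        pre = pre_profile()
        on = pre + change_profile(p)
        for tp, vals in (("pre", pre), ("on", on)):
            sid = f"{p}_{tp}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "patient_id": p, "timepoint": tp})
            columns[sid] = vals
    for p in pre_only:
        sid = f"{p}_pre"
        sample_ids.append(sid)
        meta_rows.append({"sample_id": sid, "patient_id": p, "timepoint": "pre"})
        columns[sid] = pre_profile()
    for p in on_only:
        sid = f"{p}_on"
        sample_ids.append(sid)
        meta_rows.append({"sample_id": sid, "patient_id": p, "timepoint": "on"})
        columns[sid] = pre_profile() + change_profile(p)

    norm = pd.DataFrame(columns, index=all_genes)[sample_ids]
    counts = np.rint(np.power(2.0, norm.to_numpy())).astype(np.int64)
    raw = pd.DataFrame(counts, index=all_genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    truth.loadings = loadings.loc[patients]
    truth.amplitudes = amplitudes
    truth.noise_sd = noise_sd
    truth.low_expressed = decoys
    return ExpressionStudy(raw_counts=raw, norm_values=norm, samples=meta)


def generate_clinical(
    truth: SyntheticTruth,
    loadings: pd.DataFrame | None = None,
    beta: float = 1.0,
    censor_rate: float = 0.3,
    baseline_hazard: float = np.log(2) / 24.0,
    seed: int = 0,
    n_ne: int = 1,
) -> pd.DataFrame:
    """Survival and RECIST-like response driven by the protective module.

    Event times are exponential with hazard
    ``h0 * exp(-beta * lambda_{p, m*})`` for the designated module m*
    (positive beta makes a higher loading protective). Censoring is an
    independent exponential calibrated so roughly ``censor_rate`` of
    baseline patients are censored. Response is ordinal on the latent score
    ``RESPONSE_SLOPE * lambda + logistic noise`` with thresholds at the
    empirical quantiles fixing the group proportions (PD largest); ``n_ne``
    patients are then relabeled NE.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if loadings is None:
        loadings = truth.loadings
    if loadings is None:
        raise ValueError("no loadings available; generate expression first")
    rng = np.random.default_rng(seed)
    lam = loadings[truth.protective_module].to_numpy(dtype=float)
    n = len(lam)

    hazard = baseline_hazard * np.exp(-beta * lam)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_hazard = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    eta = RESPONSE_SLOPE * lam + rng.logistic(0.0, 1.0, size=n)
    cuts = np.quantile(eta, np.cumsum(RESPONSE_TARGET_FRACTIONS)[:-1])
    response = np.array(RESPONSE_LEVELS)[np.searchsorted(cuts, eta, side="right")]
    response = response.astype(object)
    if n_ne > 0:
        ne_idx = rng.choice(n, size=min(n_ne, n), replace=False)
        response[ne_idx] = "NE"

    truth.beta = beta
    truth.censor_rate = censor_rate
    return pd.DataFrame(
        {
            "response": response,
            "os_time": os_time,
            "os_event": os_event,
        },
        index=pd.Index(loadings.index, name="patient_id"),
    )


def generate_gene_sets(
    truth: SyntheticTruth, n_decoy_sets: int = 10, seed: int = 0
) -> GeneSetCollection:
    """One exact set per planted module plus size-matched random decoys."""
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_labels)
    sets: dict[str, set[str]] = {}
    sizes = []
    for m in sorted(set(truth.module_labels.values())):
        members = {g for g, lbl in truth.module_labels.items() if lbl == m}
        sets[f"planted_module_{m}"] = members
        sizes.append(len(members))
    for d in range(n_decoy_sets):
        size = sizes[d % len(sizes)]
        picks = rng.choice(len(genes), size=size, replace=False)
        sets[f"decoy_{d + 1:02d}"] = {genes[k] for k in sorted(picks)}
    return GeneSetCollection(sets=sets, universe=set(genes))


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, generated from a single seed."""

    topology: nx.Graph
    truth: SyntheticTruth
    study: ExpressionStudy
    clinical: pd.DataFrame
    gene_sets: GeneSetCollection


def simulate_study(
    seed: int = 0,
    n_genes: int = 120,
    n_modules: int = 6,
    n_patients: int = 43,
    noise_sd: float = 0.5,
    beta: float = 1.0,
    censor_rate: float = 0.3,
    **topology_kwargs,
) -> SyntheticBundle:
    """Generate a complete synthetic study from one master seed."""
    s_top, s_expr, s_clin, s_sets = _child_seeds(seed, 4)
    topology, truth = generate_topology(
        n_genes=n_genes, n_modules=n_modules, seed=s_top, **topology_kwargs
    )
    study = generate_expression(
        topology, truth, n_patients=n_patients, noise_sd=noise_sd, seed=s_expr
    )
    clin = generate_clinical(truth, beta=beta, censor_rate=censor_rate, seed=s_clin)
    sets = generate_gene_sets(truth, seed=s_sets)
    return SyntheticBundle(
        topology=topology, truth=truth, study=study, clinical=clin, gene_sets=sets
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write a bundle as the pipeline's standard input files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "norm": out / "norm_values.tsv",
        "samples": out / "samples.tsv",
        "clinical": out / "clinical.tsv",
        "ppi": out / "ppi_links.txt",
        "core_genes": out / "core_genes.txt",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    bundle.study.raw_counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    bundle.study.norm_values.to_csv(paths["norm"], sep="\t", index_label="gene")
    bundle.study.samples.to_csv(paths["samples"], sep="\t")
    bundle.clinical.to_csv(paths["clinical"], sep="\t")
    write_ppi(bundle.topology, paths["ppi"])
    with open(paths["core_genes"], "w") as fh:
        fh.write("\n".join(bundle.truth.core_genes) + "\n")
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    truth = bundle.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "module_labels": truth.module_labels,
                "core_genes": truth.core_genes,
                "bridges": [list(b) for b in truth.bridges],
                "protective_module": truth.protective_module,
                "beta": truth.beta,
                "censor_rate": truth.censor_rate,
                "noise_sd": truth.noise_sd,
                "low_expressed": truth.low_expressed,
            },
            fh,
            indent=1,
        )
    return {k: str(v) for k, v in paths.items()}
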