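import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dyncurv.expression import DifferenceMatrix, ExpressionStudy
from dyncurv.network import WeightedGeneNetwork, all_pairs_shortest_paths

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_study(norm: pd.DataFrame, counts: pd.DataFrame | None = None) -> ExpressionStudy:
    """Study from a normalized matrix whose columns are '<patient>_<tp>' ids."""
    if counts is None:
        counts = pd.DataFrame(
            np.full(norm.shape, 100, dtype=int), index=norm.index, columns=norm.columns
        )
    meta = pd.DataFrame(
        [
            {"sample_id": s, "patient_id": s.rsplit("_", 1)[0], "timepoint": s.rsplit("_", 1)[1]}
            for s in norm.columns
        ]
    ).set_index("sample_id")
    return ExpressionStudy(raw_counts=counts, norm_values=norm, samples=meta)


def make_network(edge_rho: dict[tuple[str, str], float]) -> WeightedGeneNetwork:
    """Network straight from per-edge correlations (skipping expression data)."""
    g = nx.Graph()
    for (u, v), rho in edge_rho.items():
        shifted = (1.0 + rho) / 2.0
        g.add_edge(u, v, rho=rho, rho_shifted=shifted, cost=1.0 / max(shifted, 1e-6))
    nodes = sorted(g.nodes())
    dist = all_pairs_shortest_paths(g, nodes)
    return WeightedGeneNetwork(graph=g, nodes=nodes, dist=dist)


def uniform_network(edges, rho: float = 0.6) -> WeightedGeneNetwork:
    return make_network({tuple(sorted(e)): rho for e in edges})


@pytest.fixture
def clique_bridge_network() -> WeightedGeneNetwork:
    """Two tight triangles joined by one bridge edge (7th vertex unused)."""
    edges = {}
    for tri in (("A", "B", "C"), ("D", "E", "F")):
        for i in range(3):
            for j in range(i + 1, 3):
                edges[tuple(sorted((tri[i], tri[j])))] = 0.8
    edges[("C", "D")] = 0.8
    edges[("A", "G")] = 0.8
    return make_network(edges)


@pytest.fixture
def scaled_diff_small() -> DifferenceMatrix:
    rng = np.random.default_rng(7)
    genes = ["A", "B", "C", "D"]
    vals = pd.DataFrame(
        rng.normal(size=(4, 6)), index=genes, columns=[f"P{i}" for i in range(6)]
    )
    vals = vals.div(vals.std(axis=1, ddof=1), axis=0)
    return DifferenceMatrix(values=vals, scaled=True)
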