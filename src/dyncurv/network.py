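"""PPI-constrained weighted correlation network and its shortest-path geometry.

Construction follows a fixed filter order: confidence cutoff, optional
compartment sparsification, single-pass minimum-degree filter, core-gene
neighborhood expansion, largest connected component. Edge weights are then
derived from Pearson correlations of per-patient expression changes:
``rho_shifted = (1 + rho) / 2`` maps correlation to a [0, 1] similarity, and
the transport cost of an edge is its inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .expression import DifferenceMatrix

logger = logging.getLogger(__name__)

#: floor on the shifted correlation when inverting to an edge cost; keeps the
#: graph metric finite at rho = -1 while preserving the cost ordering
SIMILARITY_FLOOR = 1e-6


@dataclass
class WeightedGeneNetwork:
    """Correlation-weighted gene network with all-pairs shortest-path geometry.

    ``graph`` carries per-edge attributes ``rho`` (Pearson correlation of
    expression changes), ``rho_shifted`` ((1+rho)/2) and ``cost``
    (1/rho_shifted, floored). ``dist[i, j]`` is the shortest-path distance
    between ``nodes[i]`` and ``nodes[j]`` under the edge costs.
    """

    graph: nx.Graph
    nodes: list[str]
    dist: np.ndarray

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": a,
                "gene_b": b,
                "rho": d["rho"],
                "rho_shifted": d["rho_shifted"],
                "cost": d["cost"],
            }
            for (a, b), d in ((tuple(sorted((u, v))), d) for u, v, d in self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def read_ppi(path) -> nx.Graph:
    """Read a STRING protein-links style edge list.

    Whitespace-separated ``protein1 protein2 combined_score`` lines; a header
    line is tolerated. Duplicate pairs are collapsed (highest score kept) and
    self-loops dropped with a warning.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if lineno == 1 and (len(parts) < 3 or not _is_int(parts[2])):
                continue  # header
            if len(parts) < 3 or not _is_int(parts[2]):
                raise ValueError(f"{path}: malformed line {lineno}: {line.rstrip()!r}")
            a, b, score = parts[0], parts[1], int(parts[2])
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                score = max(score, g[a][b]["confidence"])
            g.add_edge(a, b, confidence=score)
    if n_loops:
        logger.warning("read_ppi: dropped %d self-loop lines", n_loops)
    return g


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_ppi(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, d in sorted(g.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{d['confidence']}\n")


def filter_confidence(g: nx.Graph, min_score: int) -> nx.Graph:
    """Keep edges with confidence >= min_score; drop resulting isolates."""
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(
        (u, v, d) for u, v, d in g.edges(data=True) if d.get("confidence", 0) >= min_score
    )
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def compartment_sparsify(g: nx.Graph, compartments: dict[str, set[str]]) -> nx.Graph:
    """Remove edges whose endpoints have disjoint cellular-compartment labels.

    Genes absent from the annotation table are treated as compatible with
    everything (permissive). An empty table is the identity.
    """
    out = g.copy()
    drop = [
        (u, v)
        for u, v in g.edges()
        if u in compartments
        and v in compartments
        and not (compartments[u] & compartments[v])
    ]
    out.remove_edges_from(drop)
    if drop:
        logger.info("compartment_sparsify: removed %d edges", len(drop))
    return out


def filter_min_degree(g: nx.Graph, min_degree: int = 5) -> nx.Graph:
    """Single-pass removal of vertices whose *initial* degree is < min_degree.

    Degrees are computed once on the input; the filter is intentionally not
    iterated to a k-core, so applying it twice may remove further vertices.
    """
    low = [v for v, d in g.degree() if d < min_degree]
    out = g.copy()
    out.remove_nodes_from(low)
    return out


def select_core_neighborhood(g: nx.Graph, core_genes) -> set[str]:
    """Core genes present in the graph plus all of their PPI neighbors."""
    present = set(core_genes) & set(g.nodes())
    if not present:
        raise ValueError("no core gene present in the network topology")
    selected = set(present)
    for c in present:
        selected.update(g.neighbors(c))
    return selected


def largest_component(g: nx.Graph, subset=None) -> nx.Graph:
    """Induced subgraph on ``subset`` restricted to its largest connected component.

    Size ties are broken by the lexicographically smallest vertex set, so the
    result is deterministic.
    """
    if subset is None:
        subset = set(g.nodes())
    subset = set(subset)
    if not subset:
        raise ValueError("empty vertex subset")
    sub = g.subgraph(subset)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    if not comps:
        raise ValueError("subset induces an empty graph")
    comps.sort(key=lambda c: (-len(c), c))
    return g.subgraph(comps[0]).copy()


def build_correlation_network(
    topology: nx.Graph,
    scaled_diff: DifferenceMatrix,
    similarity_floor: float = SIMILARITY_FLOOR,
) -> WeightedGeneNetwork:
    """Attach correlation-derived weights to the PPI topology edges.

    For each PPI edge, ``rho`` is the Pearson correlation of the two genes'
    scaled expression changes across patients; ``rho_shifted = (1+rho)/2``;
    ``cost = 1/max(rho_shifted, similarity_floor)``. No edges are created
    beyond the topology. All-pairs shortest-path distances are computed with
    Dijkstra's algorithm on the edge costs.
    """
    nodes = sorted(topology.nodes())
    missing = [v for v in nodes if v not in scaled_diff.values.index]
    if missing:
        raise ValueError(f"topology genes absent from difference matrix: {missing[:10]}")
    X = scaled_diff.values.loc[nodes].to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 patients to estimate correlations")
    sd = X.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance genes, correlation undefined: {[nodes[i] for i in zero[:10]]}"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    index = {v: i for i, v in enumerate(nodes)}

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in topology.edges():
        rho = float(np.clip(Xc[index[u]] @ Xc[index[v]], -1.0, 1.0))
        shifted = (1.0 + rho) / 2.0
        cost = 1.0 / max(shifted, similarity_floor)
        g.add_edge(u, v, rho=rho, rho_shifted=shifted, cost=cost)

    dist = all_pairs_shortest_paths(g, nodes)
    return WeightedGeneNetwork(graph=g, nodes=nodes, dist=dist)


def all_pairs_shortest_paths(g: nx.Graph, nodes: list[str] | None = None) -> np.ndarray:
    """Dense all-pairs shortest-path matrix under the ``cost`` edge attribute."""
    if nodes is None:
        nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, d in g.edges(data=True):
        i, j = index[u], index[v]
        w = float(d["cost"])
        if w <= 0:
            raise ValueError(f"nonpositive edge cost on ({u}, {v})")
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    adj = csr_matrix((vals, (rows, cols)), shape=(n, n))
    dist = dijkstra(adj, directed=False)
    if np.isinf(dist).any():
        raise ValueError("network is disconnected; take the largest component first")
    return dist
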