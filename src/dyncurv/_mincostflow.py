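"""Exact Wasserstein-1 on a weighted graph via uncapacitated min-cost flow.

For a ground metric given by shortest-path distances on a graph, the optimal
transport cost between two distributions equals the minimum-cost flow that
routes the imbalance ``b = p - q`` through the graph's edges at their edge
costs. This is solved with successive shortest paths under node potentials
(reduced costs stay nonnegative, so Dijkstra applies); each augmentation
zeroes at least one node's imbalance or empties a cancelling arc, so the
number of iterations is small. The kernel is numba-compiled; a pure-LP
reference backend lives in :mod:`dyncurv.curvature`.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from numba import njit


class GraphArcs:
    """Paired directed-arc representation of an undirected weighted graph.

    Arc ``a`` and ``a ^ 1`` are the two directions of one edge. ``adj`` holds
    arc ids grouped by tail vertex via ``indptr``.
    """

    def __init__(self, graph: nx.Graph, nodes: list, weight: str = "cost"):
        self.nodes = list(nodes)
        index = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        arc_to, arc_cost = [], []
        for u, v, d in graph.edges(data=True):
            w = float(d[weight])
            arc_to += [index[v], index[u]]
            arc_cost += [w, w]
        self.arc_to = np.asarray(arc_to, dtype=np.int64)
        self.arc_cost = np.asarray(arc_cost, dtype=np.float64)
        tails = self.arc_to[np.arange(len(self.arc_to)) ^ 1]
        self.adj = np.argsort(tails, kind="stable").astype(np.int64)
        counts = np.bincount(tails, minlength=n)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    def wasserstein1(self, p: np.ndarray, q: np.ndarray, tol: float = 1e-12) -> float:
        """Exact W1 between distributions ``p`` and ``q`` over ``self.nodes``."""
        b = np.asarray(p, dtype=np.float64) - np.asarray(q, dtype=np.float64)
        val = _mcf_w1(self.indptr, self.adj, self.arc_to, self.arc_cost, b, tol)
        if val < 0:
            raise RuntimeError(f"min-cost flow failed (code {val}); is the graph connected?")
        return float(val)

    def wasserstein1_rows(
        self,
        distributions: np.ndarray,
        pairs: np.ndarray,
        tol: float = 1e-12,
    ) -> np.ndarray:
        """Exact W1 between rows ``pairs[k] = (i, j)`` of a distribution matrix."""
        pairs = np.ascontiguousarray(pairs, dtype=np.int64)
        vals = _mcf_w1_batch(
            self.indptr,
            self.adj,
            self.arc_to,
            self.arc_cost,
            np.ascontiguousarray(distributions, dtype=np.float64),
            pairs,
            tol,
        )
        if (vals < 0).any():
            raise RuntimeError("min-cost flow failed on a pair; is the graph connected?")
        return vals


@njit(cache=True)
def _mcf_w1(indptr, adj, arc_to, arc_cost, b, tol):  # pragma: no cover - jit
    n = b.shape[0]
    narc = arc_to.shape[0]
    flow = np.zeros(narc)
    pot = np.zeros(n)
    dist = np.empty(n)
    visited = np.empty(n, np.uint8)
    pred_arc = np.empty(n, np.int64)
    cap = 2 * narc + 16
    heap_d = np.empty(cap)
    heap_v = np.empty(cap, np.int64)
    excess = b.copy()
    total = 0.0
    while True:
        # most-imbalanced source; stop when either side is exhausted
        s = -1
        best = tol
        worst = -tol
        for i in range(n):
            if excess[i] > best:
                best = excess[i]
                s = i
            if excess[i] < worst:
                worst = excess[i]
        if s < 0 or worst >= -tol:
            break
        # Dijkstra on residual reduced costs, stopping at the nearest deficit
        for i in range(n):
            dist[i] = np.inf
            visited[i] = 0
            pred_arc[i] = -1
        dist[s] = 0.0
        heap_d[0] = 0.0
        heap_v[0] = s
        hn = 1
        t = -1
        while hn > 0:
            d0 = heap_d[0]
            u = heap_v[0]
            hn -= 1
            heap_d[0] = heap_d[hn]
            heap_v[0] = heap_v[hn]
            k = 0
            while True:
                c1 = 2 * k + 1
                if c1 >= hn:
                    break
                cm = c1
                c2 = c1 + 1
                if c2 < hn and heap_d[c2] < heap_d[c1]:
                    cm = c2
                if heap_d[cm] < heap_d[k]:
                    heap_d[k], heap_d[cm] = heap_d[cm], heap_d[k]
                    heap_v[k], heap_v[cm] = heap_v[cm], heap_v[k]
                    k = cm
                else:
                    break
            if visited[u]:
                continue
            visited[u] = 1
            if excess[u] < -tol:
                t = u
                break
            for ii in range(indptr[u], indptr[u + 1]):
                a = adj[ii]
                v = arc_to[a]
                if visited[v]:
                    continue
                if flow[a ^ 1] > tol:
                    c = -arc_cost[a]  # cancelling opposite flow
                else:
                    c = arc_cost[a]
                nd = d0 + c + pot[u] - pot[v]
                if nd < dist[v] - 1e-15:
                    dist[v] = nd
                    pred_arc[v] = a
                    if hn >= cap:
                        return -2.0
                    heap_d[hn] = nd
                    heap_v[hn] = v
                    k = hn
                    hn += 1
                    while k > 0:
                        pk = (k - 1) // 2
                        if heap_d[k] < heap_d[pk]:
                            heap_d[k], heap_d[pk] = heap_d[pk], heap_d[k]
                            heap_v[k], heap_v[pk] = heap_v[pk], heap_v[k]
                            k = pk
                        else:
                            break
        if t == -1:
            return -1.0
        dt = dist[t]
        for i in range(n):
            if visited[i] and dist[i] < dt:
                pot[i] += dist[i]
            else:
                pot[i] += dt
        # bottleneck: node imbalances and any cancelling arcs on the path
        delta = excess[s]
        if -excess[t] < delta:
            delta = -excess[t]
        u = t
        while u != s:
            a = pred_arc[u]
            if flow[a ^ 1] > tol and flow[a ^ 1] < delta:
                delta = flow[a ^ 1]
            u = arc_to[a ^ 1]
        u = t
        while u != s:
            a = pred_arc[u]
            ca = arc_cost[a]
            fr = flow[a ^ 1]
            if fr > tol:
                if fr >= delta:
                    flow[a ^ 1] = fr - delta
                    total -= ca * delta
                else:
                    flow[a ^ 1] = 0.0
                    flow[a] += delta - fr
                    total += ca * (delta - 2.0 * fr)
            else:
                flow[a] += delta
                total += ca * delta
            u = arc_to[a ^ 1]
        excess[s] -= delta
        excess[t] += delta
    return total


@njit(cache=True)
def _mcf_w1_batch(indptr, adj, arc_to, arc_cost, D, pairs, tol):  # pragma: no cover - jit
    out = np.empty(pairs.shape[0])
    for k in range(pairs.shape[0]):
        b = D[pairs[k, 0]] - D[pairs[k, 1]]
        out[k] = _mcf_w1(indptr, adj, arc_to, arc_cost, b, tol)
    return out
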