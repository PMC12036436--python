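"""Multipartite trajectory graph and Balanced Forman curvature.

Trajectory ensembles induce a layered (multipartite) graph: one node
per visited (token, layer) state, one undirected edge per consecutive
state pair, with integer multiplicity counting how many trajectories
traverse the pair.  Because every edge joins consecutive layers the
graph is bipartite by layer parity and therefore triangle-free.

The Balanced Forman curvature of an edge (i, j) with degrees d_i <= d_j
combines degrees, triangle counts T_ij, and diagonal-free 4-cycle
counts S_i (neighbors of i completing such a cycle through the edge)
with gamma_max, the maximal number of those 4-cycles traversing a
common node:

    Ric(i,j) = 2/d_i + 2/d_j - 2 + 2 T_ij / max(d_i, d_j)
               + T_ij / min(d_i, d_j)
               + (S_i + S_j) / (gamma_max * max(d_i, d_j))

with Ric(i,j) := 0 when min(d_i, d_j) = 1 and the last term defined as 0
when gamma_max = 0.  Negative values mark bridges (bottlenecks of
information flow, prone to oversquashing); positive values mark hubs
with redundant connectivity.  Two degree notions are supported: the
simple degree (distinct neighbors) and the multiplicity degree (total
trajectory traversals); the cycle combinatorics always live on the
simple graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import LookupError_, ValidationError
from .datatypes import TrajectoryEnsemble

__all__ = [
    "LayeredGraph",
    "build_multipartite_graph",
    "edge_curvature",
    "node_curvature",
    "curvature_report",
    "balanced_forman_oracle",
]


@dataclass
class LayeredGraph:
    """Undirected layered graph with edge multiplicities."""

    graph: nx.Graph
    node_layer: dict
    node_cell_type: dict = field(default_factory=dict)

    def degree(self, node, mode: str = "simple") -> int:
        if mode == "simple":
            return self.graph.degree(node)
        if mode == "multiplicity":
            return sum(
                d["multiplicity"] for _, _, d in self.graph.edges(node, data=True)
            )
        raise ValidationError(f"unknown degree mode {mode!r}")


def build_multipartite_graph(
    ensemble: TrajectoryEnsemble, token_cell_type=None
) -> LayeredGraph:
    """One node per visited token, one edge per consecutive pair.

    Token ids are assumed layer-specific (the tokenizer guarantees it),
    so the token id itself is the node key and its position the layer.
    """
    if ensemble.n_trajectories == 0:
        raise ValidationError("cannot build a graph from an empty ensemble")
    g = nx.Graph()
    node_layer: dict = {}
    for row in ensemble.tokens:
        for t, tok in enumerate(row):
            tok = int(tok)
            if tok in node_layer and node_layer[tok] != t:
                raise ValidationError(
                    f"token {tok} appears at layers {node_layer[tok]} and {t}"
                )
            node_layer[tok] = t
            g.add_node(tok)
        for t in range(len(row) - 1):
            u, v = int(row[t]), int(row[t + 1])
            if g.has_edge(u, v):
                g[u][v]["multiplicity"] += 1
            else:
                g.add_edge(u, v, multiplicity=1)
    types = {}
    if token_cell_type is not None:
        types = {tok: str(token_cell_type[tok]) for tok in node_layer}
    return LayeredGraph(graph=g, node_layer=node_layer, node_cell_type=types)


def _edge_combinatorics(g: nx.Graph, i, j):
    """(T_ij, S_i, S_j, gamma_max) on the simple graph.

    S_i counts neighbors k of i (k != j, k not adjacent to j) that reach
    some neighbor w of j (w != i, w not adjacent to i): each such k
    closes a 4-cycle i-k-w-j with no inside diagonal.  gamma_max is the
    maximum, over nodes on such cycles, of the number of these 4-cycles
    through that node.
    """
    Ni = set(g.neighbors(i))
    Nj = set(g.neighbors(j))
    triangles = Ni & Nj
    T = len(triangles)
    side_i = Ni - Nj - {j}
    side_j = Nj - Ni - {i}
    S_i_nodes = set()
    S_j_nodes = set()
    cycle_count: dict = {}
    for k in side_i:
        Nk = set(g.neighbors(k))
        for w in side_j & Nk:
            S_i_nodes.add(k)
            S_j_nodes.add(w)
            cycle_count[k] = cycle_count.get(k, 0) + 1
            cycle_count[w] = cycle_count.get(w, 0) + 1
    gamma_max = max(cycle_count.values()) if cycle_count else 0
    return T, len(S_i_nodes), len(S_j_nodes), gamma_max


def edge_curvature(
    graph: LayeredGraph, edge, degree_mode: str = "simple"
) -> float:
    """Balanced Forman curvature of one edge."""
    i, j = edge
    g = graph.graph
    if not g.has_edge(i, j):
        raise LookupError_(f"edge {edge} not in graph")
    d_i = graph.degree(i, degree_mode)
    d_j = graph.degree(j, degree_mode)
    if min(d_i, d_j) == 1:
        return 0.0
    T, S_i, S_j, gamma_max = _edge_combinatorics(g, i, j)
    d_max, d_min = max(d_i, d_j), min(d_i, d_j)
    ric = 2.0 / d_i + 2.0 / d_j - 2.0 + 2.0 * T / d_max + T / d_min
    if gamma_max > 0:
        ric += (S_i + S_j) / (gamma_max * d_max)
    return float(ric)


def node_curvature(
    graph: LayeredGraph, node, degree_mode: str = "simple"
) -> float:
    """Degree-normalized sum of incident edge curvatures.

    In multiplicity mode each incident edge's curvature is weighted by
    its traversal multiplicity, and the normalizer is the multiplicity
    degree.
    """
    g = graph.graph
    d = graph.degree(node, degree_mode)
    if d == 0:
        raise ValidationError(f"node {node} is isolated")
    total = 0.0
    for _, j, data in g.edges(node, data=True):
        w = data["multiplicity"] if degree_mode == "multiplicity" else 1
        total += w * edge_curvature(graph, (node, j), degree_mode)
    return total / d


def curvature_report(
    graph: LayeredGraph, degree_mode: str = "simple"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-edge and per-node curvature tables (TSV-ready)."""
    edge_rows = []
    for i, j in graph.graph.edges:
        u, v = (i, j) if graph.node_layer[i] <= graph.node_layer[j] else (j, i)
        T, S_i, S_j, gmax = _edge_combinatorics(graph.graph, u, v)
        edge_rows.append(
            {
                "i": u,
                "j": v,
                "layer": graph.node_layer[u],
                "d_i": graph.degree(u, degree_mode),
                "d_j": graph.degree(v, degree_mode),
                "T_ij": T,
                "S_i": S_i,
                "S_j": S_j,
                "gamma_max": gmax,
                "ric": edge_curvature(graph, (u, v), degree_mode),
            }
        )
    node_rows = [
        {
            "token": n,
            "layer": graph.node_layer[n],
            "cell_type": graph.node_cell_type.get(n, ""),
            "kappa": node_curvature(graph, n, degree_mode),
        }
        for n in graph.graph.nodes
        if graph.graph.degree(n) > 0
    ]
    return pd.DataFrame(edge_rows), pd.DataFrame(node_rows)


def balanced_forman_oracle(g: nx.Graph, i, j) -> float:
    """Brute-force reference: enumerate all triangles and 4-cycles.

    Independent of :func:`edge_curvature`: it walks every ordered node
    pair (k, w) of the graph and tests the 4-cycle conditions directly.
    Intended for small graphs in tests.
    """
    d_i, d_j = g.degree(i), g.degree(j)
    if min(d_i, d_j) == 1:
        return 0.0
    nodes = list(g.nodes)
    T = sum(1 for k in nodes if g.has_edge(i, k) and g.has_edge(j, k))
    cycles = []  # diagonal-free 4-cycles i-k-w-j
    for k in nodes:
        for w in nodes:
            if k == w or k in (i, j) or w in (i, j):
                continue
            if (
                g.has_edge(i, k)
                and g.has_edge(k, w)
                and g.has_edge(w, j)
                and not g.has_edge(j, k)
                and not g.has_edge(i, w)
            ):
                cycles.append((k, w))
    S_i = len({k for k, _ in cycles})
    S_j = len({w for _, w in cycles})
    per_node: dict = {}
    for k, w in cycles:
        per_node[k] = per_node.get(k, 0) + 1
        per_node[w] = per_node.get(w, 0) + 1
    gamma_max = max(per_node.values()) if per_node else 0
    d_max, d_min = max(d_i, d_j), min(d_i, d_j)
    ric = 2.0 / d_i + 2.0 / d_j - 2.0 + 2.0 * T / d_max + T / d_min
    if gamma_max > 0:
        ric += (S_i + S_j) / (gamma_max * d_max)
    return float(ric)
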