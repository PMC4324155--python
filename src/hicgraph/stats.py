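"""Descriptive graph statistics, graph comparison, and contact distance.

``summarize`` reports the standard unweighted, undirected descriptors
(including the diameter — the longest shortest path — of the largest
connected component).  ``compare`` converts two graphs to binary
adjacency matrices over the union of their node sets and returns the
Pearson correlation of the flattened strict upper triangles.
``contact_distance`` is the minimum number of significant Hi-C edges
separating two genes: a shortest path restricted to edges with
BH-adjusted score ``q < alpha`` (``alpha = 1`` uses every edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .graph import NeighborhoodGraph

__all__ = ["GraphSummary", "summarize", "compare", "contact_distance", "ConstantAdjacencyError"]


class ConstantAdjacencyError(ValueError):
    """Raised when a graph's adjacency vector is constant (empty/complete)."""


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    degree_distribution: dict[int, int]
    n_components: int
    component_sizes: list[int]
    diameter_largest: int
    mean_clustering: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "degree_distribution": dict(sorted(self.degree_distribution.items())),
            "n_components": self.n_components,
            "component_sizes": self.component_sizes,
            "diameter_largest": self.diameter_largest,
            "mean_clustering": self.mean_clustering,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v}\n")


def summarize(graph: NeighborhoodGraph) -> GraphSummary:
    """Unweighted descriptive statistics; errors on an empty graph."""
    g = graph.g
    if g.number_of_nodes() == 0:
        raise ValueError("cannot summarize an empty graph")
    degrees = [d for _, d in g.degree()]
    dist: dict[int, int] = {}
    for d in degrees:
        dist[d] = dist.get(d, 0) + 1
    comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    largest = max(nx.connected_components(g), key=len)
    diameter = nx.diameter(g.subgraph(largest)) if len(largest) > 1 else 0
    clustering = nx.average_clustering(g) if g.number_of_nodes() > 0 else 0.0
    return GraphSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree_distribution=dist,
        n_components=len(comps),
        component_sizes=comps,
        diameter_largest=diameter,
        mean_clustering=float(clustering),
    )


def _adjacency_vector(g: nx.Graph, nodes: list[str], weighted: bool) -> np.ndarray:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mat = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        if u in idx and v in idx:
            w = d.get("weight", 1) if weighted else 1.0
            mat[idx[u], idx[v]] = w
            mat[idx[v], idx[u]] = w
    iu = np.triu_indices(n, k=1)
    return mat[iu]


def compare(
    a: NeighborhoodGraph, b: NeighborhoodGraph, weighted: bool = False
) -> float:
    """Pearson correlation of the two adjacency vectors on the node union."""
    nodes = sorted(set(a.g.nodes) | set(b.g.nodes))
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes (one dyad) to compare graphs")
    va = _adjacency_vector(a.g, nodes, weighted)
    vb = _adjacency_vector(b.g, nodes, weighted)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ConstantAdjacencyError(
            "adjacency vector is constant (empty or complete graph); "
            "Pearson correlation undefined"
        )
    if np.array_equal(va, vb):
        return 1.0  # exact on identical graphs (no float round-off)
    return float(np.corrcoef(va, vb)[0, 1])


def contact_distance(
    graph: NeighborhoodGraph, gene_x: str, gene_y: str, alpha: float = 0.05
) -> float:
    """Hop count between two genes over significant edges.

    Returns ``math.inf`` when unreachable through edges with
    ``q < alpha``.  With ``alpha = 1`` all edges qualify regardless of
    scoring.
    """
    for sym in (gene_x, gene_y):
        if sym not in graph.g:
            raise KeyError(f"gene {sym!r} not in graph")
    if alpha < 1:
        for u, v, d in graph.g.edges(data=True):
            if "q" not in d:
                raise ValueError(
                    f"edge {u}-{v} has no q score; score the graph first or use alpha=1"
                )
        keep = [
            (u, v) for u, v, d in graph.g.edges(data=True) if d["q"] < alpha
        ]
    else:
        keep = list(graph.g.edges())
    sub = nx.Graph()
    sub.add_nodes_from(graph.g.nodes)
    sub.add_edges_from(keep)
    try:
        return float(nx.shortest_path_length(sub, gene_x, gene_y))
    except nx.NetworkXNoPath:
        return math.inf


def compare_matrix(graphs: dict[str, NeighborhoodGraph], weighted: bool = False):
    """Pairwise comparison matrix for more than two graphs."""
    import pandas as pd

    names = list(graphs)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, x in enumerate(names):
        for j in range(i + 1, len(names)):
            y = names[j]
            r = compare(graphs[x], graphs[y], weighted)
            mat.loc[x, y] = mat.loc[y, x] = r
    return mat
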