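"""Gene-centric neighborhood graph construction.

The core procedure: starting from one or more seed genes, find the
restriction fragments belonging to each frontier gene, follow Hi-C
contacts to mate fragments, and map those onto genes; every supported
gene pair becomes an edge, newly reached genes take the next discovery
level, and the expansion repeats up to the configured level ``L``
(default 1, i.e. only genes directly in contact with the seeds).

Node levels equal the hop distance from the seed set in the induced
gene-gene support graph, so the iterative expansion is implemented as a
breadth-first search over a precomputed gene-pair support table; edges
between two already-discovered genes (including same-level lateral
edges) are retained whenever an expanded endpoint reaches them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .genome import FragmentGeneMap, GeneTable
from .hic import ContactTable

__all__ = ["BuildConfig", "NeighborhoodGraph", "build_neighborhood", "merge_graphs"]

NODE_COLUMNS = ["symbol", "chrom", "start", "end", "level"]
EDGE_COLUMNS = ["gene_a", "gene_b", "weight", "frag_pairs", "expected", "p", "q"]


@dataclass(frozen=True)
class BuildConfig:
    """Expansion parameters: max level ``L`` and minimum edge support."""

    level: int = 1
    min_edge_weight: int = 1

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.min_edge_weight < 1:
            raise ValueError("min edge weight must be >= 1")


class NeighborhoodGraph:
    """A gene-node graph with discovery levels and annotated edges.

    Thin wrapper around an undirected :class:`networkx.Graph`; node
    attributes hold coordinates, discovery level and mapped features,
    edge attributes hold contact weight, supporting fragment pairs and
    (after scoring) expected count, p and q.
    """

    def __init__(self, graph: nx.Graph | None = None, seeds: Iterable[str] = ()):
        self.g = graph if graph is not None else nx.Graph()
        self.seeds = frozenset(seeds)

    # -- inspection ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.g.edges)

    def level(self, symbol: str) -> int:
        return self.g.nodes[symbol]["level"]

    def copy(self) -> "NeighborhoodGraph":
        return NeighborhoodGraph(self.g.copy(), self.seeds)

    # -- serialization ---------------------------------------------------
    def node_table(self) -> pd.DataFrame:
        rows = []
        extra_keys: set[str] = set()
        for n, d in self.g.nodes(data=True):
            extra_keys |= set(d) - {"chrom", "start", "end", "level"}
        extras = sorted(extra_keys)
        for n in self.nodes():
            d = self.g.nodes[n]
            rows.append(
                [n, d["chrom"], d["start"], d["end"], d["level"]]
                + [d.get(k, np.nan) for k in extras]
            )
        return pd.DataFrame(rows, columns=NODE_COLUMNS + extras)

    def edge_table(self) -> pd.DataFrame:
        extra_keys: set[str] = set()
        base = {"weight", "frag_pairs", "expected", "p", "q"}
        for _, _, d in self.g.edges(data=True):
            extra_keys |= set(d) - base
        extras = sorted(extra_keys)
        rows = []
        for a, b in self.edges():
            d = self.g.edges[a, b]
            fp = ";".join(f"{x}-{y}" for x, y in d.get("frag_pairs", ()))
            rows.append(
                [a, b, d.get("weight", np.nan), fp,
                 d.get("expected", np.nan), d.get("p", np.nan), d.get("q", np.nan)]
                + [d.get(k, np.nan) for k in extras]
            )
        return pd.DataFrame(rows, columns=EDGE_COLUMNS + extras)

    def write_tsv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.node_table().to_csv(nodes_path, sep="\t", index=False, float_format="%.10g")
        edges = self.edge_table()
        edges.to_csv(edges_path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, nodes_path: str | Path, edges_path: str | Path
    ) -> "NeighborhoodGraph":
        nodes = pd.read_csv(nodes_path, sep="\t")
        edges = pd.read_csv(edges_path, sep="\t")
        g = nx.Graph()
        node_extras = [c for c in nodes.columns if c not in NODE_COLUMNS]
        for row in nodes.itertuples(index=False):
            d = row._asdict()
            attrs = {k: d[k] for k in ("chrom", "start", "end", "level")}
            for k in node_extras:
                if pd.notna(d[k]):
                    attrs[k] = d[k]
            g.add_node(d["symbol"], **attrs)
        edge_extras = [c for c in edges.columns if c not in EDGE_COLUMNS]
        for row in edges.itertuples(index=False):
            d = row._asdict()
            fp = ()
            if isinstance(d["frag_pairs"], str) and d["frag_pairs"]:
                fp = tuple(
                    tuple(int(x) for x in part.split("-"))
                    for part in d["frag_pairs"].split(";")
                )
            attrs = {"weight": int(d["weight"]), "frag_pairs": fp}
            for k in ("expected", "p", "q"):
                if pd.notna(d[k]):
                    attrs[k] = float(d[k])
            for k in edge_extras:
                if pd.notna(d[k]):
                    attrs[k] = d[k]
            g.add_edge(d["gene_a"], d["gene_b"], **attrs)
        seeds = [n for n, d in g.nodes(data=True) if d["level"] == 0]
        return cls(g, seeds)

    def to_graphml(self, path: str | Path) -> None:
        g = self.g.copy()
        for _, _, d in g.edges(data=True):
            if "frag_pairs" in d:
                d["frag_pairs"] = ";".join(f"{a}-{b}" for a, b in d["frag_pairs"])
        for n, d in g.nodes(data=True):
            d["seed"] = n in self.seeds
        nx.write_graphml(g, str(path))


def gene_pair_support(
    contacts: ContactTable, frag_gene_map: FragmentGeneMap
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], tuple], int]:
    """Aggregate contact rows into gene-pair support.

    Each contact row contributes its count once to every distinct
    unordered gene pair its two fragments connect.  Returns (weights,
    supporting fragment pairs, count of rows with a non-genic mate).
    """
    weights: dict[tuple[str, str], int] = {}
    frag_pairs: dict[tuple[str, str], list] = {}
    non_genic = 0
    for fa, fb, cnt in contacts.rows():
        genes_a = frag_gene_map.genes_of(fa)
        genes_b = frag_gene_map.genes_of(fb)
        if not genes_a or not genes_b:
            non_genic += 1
            continue
        pairs = {
            (ga, gb) if ga < gb else (gb, ga)
            for ga in genes_a
            for gb in genes_b
            if ga != gb
        }
        for key in pairs:
            weights[key] = weights.get(key, 0) + cnt
            frag_pairs.setdefault(key, []).append((fa, fb))
    return (
        weights,
        {k: tuple(sorted(v)) for k, v in frag_pairs.items()},
        non_genic,
    )


def build_neighborhood(
    seeds: Iterable[str],
    contacts: ContactTable,
    frag_gene_map: FragmentGeneMap,
    genes: GeneTable,
    config: BuildConfig = BuildConfig(),
) -> NeighborhoodGraph:
    """Build the seeded gene neighborhood graph (see module docstring).

    Deterministic for fixed input: expansion iterates genes in
    lexicographic order and the result is independent of contact-row
    order.  Raises ``KeyError`` for unknown seed symbols; a seed
    overlapping no fragment yields a warning and an isolated node.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("at least one seed gene required")
    for s in seeds:
        if s not in genes:
            raise KeyError(f"unknown seed gene {s!r}")
        if not frag_gene_map.fragments_of(s):
            warnings.warn(f"seed gene {s!r} overlaps no restriction fragment")

    weights, frag_pairs, non_genic = gene_pair_support(contacts, frag_gene_map)
    # adjacency restricted to sufficiently supported pairs
    adj: dict[str, set[str]] = {}
    for (ga, gb), w in weights.items():
        if w >= config.min_edge_weight:
            adj.setdefault(ga, set()).add(gb)
            adj.setdefault(gb, set()).add(ga)

    level: dict[str, int] = {s: 0 for s in seeds}
    frontier = list(seeds)
    for depth in range(1, config.level + 1):
        nxt = []
        for g in sorted(frontier):
            for mate in sorted(adj.get(g, ())):
                if mate not in level:
                    level[mate] = depth
                    nxt.append(mate)
        frontier = nxt

    graph = nx.Graph()
    graph.graph["non_genic_contact_rows"] = non_genic
    for sym in sorted(level):
        gene = genes[sym]
        graph.add_node(
            sym, chrom=gene.chrom, start=gene.start, end=gene.end, level=level[sym]
        )
    max_expanded = config.level - 1
    for (ga, gb), w in sorted(weights.items()):
        if w < config.min_edge_weight:
            continue
        if ga in level and gb in level and min(level[ga], level[gb]) <= max_expanded:
            graph.add_edge(ga, gb, weight=w, frag_pairs=frag_pairs[(ga, gb)])
    return NeighborhoodGraph(graph, seeds)


def merge_graphs(
    a: NeighborhoodGraph,
    b: NeighborhoodGraph,
    weight_policy: str = "max",
) -> NeighborhoodGraph:
    """Merge two neighborhood graphs over the same gene annotation space.

    Node union takes the minimum level; edge union combines weights by
    ``max`` (default; correct when the graphs were built from the same
    contact set) or ``sum`` (for disjoint contact sets).  Edge scores
    are dropped wherever the two inputs disagree (a merged edge needs
    re-scoring).
    """
    if weight_policy not in ("max", "sum"):
        raise ValueError("weight_policy must be 'max' or 'sum'")
    g = nx.Graph()
    for src in (a.g, b.g):
        for n, d in src.nodes(data=True):
            if n in g:
                prev = g.nodes[n]
                for k in ("chrom", "start", "end"):
                    if prev[k] != d[k]:
                        raise ValueError(f"conflicting coordinates for gene {n!r}")
                prev["level"] = min(prev["level"], d["level"])
            else:
                g.add_node(n, **dict(d))
    for src in (a.g, b.g):
        for u, v, d in src.edges(data=True):
            if g.has_edge(u, v):
                prev = g.edges[u, v]
                combine = max if weight_policy == "max" else (lambda x, y: x + y)
                prev["weight"] = combine(prev["weight"], d["weight"])
                prev["frag_pairs"] = tuple(
                    sorted(set(prev.get("frag_pairs", ())) | set(d.get("frag_pairs", ())))
                )
                for k in ("expected", "p", "q"):
                    if prev.get(k) != d.get(k):
                        prev.pop(k, None)
            else:
                g.add_edge(u, v, **dict(d))
    return NeighborhoodGraph(g, a.seeds | b.seeds)
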