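"""Mapping BED feature tracks and expression values onto the graph.

Node features count track intervals overlapping the gene body (plus an
optional flanking window); edge features count track intervals
overlapping any restriction fragment supporting the edge, reflecting
that looping elements such as CTCF sites act at the contact loci rather
than inside the gene bodies.  Expression values join nodes by exact
gene symbol.  None of these operations alter graph topology, and
re-mapping the same track is idempotent (the attribute is overwritten).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import FeatureTrack, FragmentMap
from .graph import NeighborhoodGraph

__all__ = [
    "map_node_features",
    "map_edge_features",
    "map_expression",
    "read_expression_tsv",
]


def _overlap_count(track: pd.DataFrame, chrom: str, start: int, end: int) -> int:
    sub = track[track["chrom"] == chrom]
    if sub.empty:
        return 0
    return int(((sub["start"] < end) & (sub["end"] > start)).sum())


def map_node_features(
    graph: NeighborhoodGraph, track: FeatureTrack, window: int = 0
) -> NeighborhoodGraph:
    """Count track intervals overlapping ``[start - window, end + window)``.

    The count is stored as node attribute ``track.name``.
    """
    for n, d in graph.g.nodes(data=True):
        d[track.name] = _overlap_count(
            track.df, d["chrom"], d["start"] - window, d["end"] + window
        )
    return graph


def map_edge_features(
    graph: NeighborhoodGraph, track: FeatureTrack, fragments: FragmentMap
) -> NeighborhoodGraph:
    """Count track intervals overlapping any supporting fragment of each edge.

    Each track interval is counted once per edge even when it touches
    several supporting fragments.  Requires edges to carry fragment
    provenance (``frag_pairs``).
    """
    fdf = fragments.df
    for a, b, d in graph.g.edges(data=True):
        if "frag_pairs" not in d or d["frag_pairs"] is None:
            raise ValueError(f"edge {a}-{b} lacks supporting fragment provenance")
        frag_ids = sorted({f for pair in d["frag_pairs"] for f in pair})
        hit = np.zeros(len(track.df), dtype=bool)
        tdf = track.df
        for fid in frag_ids:
            frag = fdf.iloc[fid]
            hit |= (
                (tdf["chrom"] == frag["chrom"])
                & (tdf["start"] < frag["end"])
                & (tdf["end"] > frag["start"])
            ).to_numpy()
        d[track.name] = int(hit.sum())
    return graph


def read_expression_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (symbol, value) expression table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["symbol", "value"], comment="#")
    if df["symbol"].duplicated().any():
        dups = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate symbols in expression table: {dups}")
    return pd.Series(
        pd.to_numeric(df["value"]).to_numpy(), index=df["symbol"], name="expr"
    )


def map_expression(
    graph: NeighborhoodGraph, expression: "pd.Series | Mapping[str, float]"
) -> tuple[NeighborhoodGraph, int]:
    """Attach expression values to nodes by exact symbol match.

    Unmatched nodes get ``NaN`` as the missing marker; their number is
    returned alongside the graph.  Duplicate symbols raise.
    """
    if not isinstance(expression, pd.Series):
        expression = pd.Series(dict(expression), name="expr")
    if expression.index.duplicated().any():
        raise ValueError("duplicate symbols in expression table")
    missing = 0
    for n, d in graph.g.nodes(data=True):
        if n in expression.index:
            d["expr"] = float(expression[n])
        else:
            d["expr"] = float("nan")
            missing += 1
    return graph, missing
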