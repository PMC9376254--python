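"""Centrality indices on the weighted signed network.

Strength is the sum of absolute edge weights at a node (the convention for
signed psychometric networks; a signed variant, expected influence, is
exposed separately). Closeness and betweenness are shortest-path indices
under edge lengths ``1 / |w|`` (stronger association = shorter path); the
alternative ``-log |w|`` transform is available. Betweenness uses
Brandes-style fractional counting of shortest-path ties, so results are
deterministic under exact ties.

Disconnected convention: an unreachable pair contributes nothing to
betweenness, and any infinite distance makes a node's closeness 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse.csgraph import dijkstra

from .network import WeightedNetwork


def strength(net: WeightedNetwork, signed: bool = False) -> pd.Series:
    """Node strength: sum of |w_ij| over neighbors (signed sum if
    ``signed=True``, i.e. one-step expected influence)."""
    w = net.weights if signed else np.abs(net.weights)
    return pd.Series(w.sum(axis=1), index=net.labels, name="strength")


def _edge_lengths(net: WeightedNetwork, transform: str) -> np.ndarray:
    a = np.abs(net.weights)
    with np.errstate(divide="ignore"):
        if transform == "inverse_abs":
            lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), np.inf)
        elif transform == "neg_log":
            lengths = np.where(a > 0, -np.log(np.where(a > 0, a, 1.0)),
                               np.inf)
        else:
            raise ValueError(f"unknown distance transform: {transform!r}")
    np.fill_diagonal(lengths, 0.0)
    return lengths


def graph_distances(net: WeightedNetwork, transform: str = "inverse_abs",
                    ) -> np.ndarray:
    """All-pairs shortest-path length matrix under the edge-length
    transform; ``inf`` for disconnected pairs, zero diagonal."""
    lengths = _edge_lengths(net, transform)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    mask = np.isfinite(lengths) & (lengths > 0)
    graph = np.where(mask, finite, 0.0)
    d = dijkstra(graph, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def closeness(net: WeightedNetwork, transform: str = "inverse_abs",
              ) -> pd.Series:
    """Reciprocal of the mean shortest-path length to the other nodes:
    ``(p - 1) / sum_j d_ij``; 0 when any other node is unreachable."""
    d = graph_distances(net, transform)
    p = net.p
    out = np.zeros(p)
    for i in range(p):
        others = np.delete(d[i], i)
        if np.all(np.isfinite(others)) and others.sum() > 0:
            out[i] = (p - 1) / others.sum()
    return pd.Series(out, index=net.labels, name="closeness")


def _length_graph(net: WeightedNetwork, transform: str) -> nx.Graph:
    lengths = _edge_lengths(net, transform)
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            if np.isfinite(lengths[i, j]) and net.weights[i, j] != 0:
                g.add_edge(net.labels[i], net.labels[j],
                           length=lengths[i, j])
    return g


def betweenness(net: WeightedNetwork, transform: str = "inverse_abs",
                ) -> pd.Series:
    """Brandes betweenness: for each node v, the sum over unordered pairs
    (s, t) of the fraction of shortest s-t paths passing through v."""
    g = _length_graph(net, transform)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return pd.Series([bc[lab] for lab in net.labels], index=net.labels,
                     name="betweenness")


def centrality_table(net: WeightedNetwork, transform: str = "inverse_abs",
                     zscores: bool = True) -> pd.DataFrame:
    """Per-node strength, closeness, and betweenness (+ z-standardized
    columns for plotting when ``zscores=True``)."""
    table = pd.concat([strength(net), closeness(net, transform),
                       betweenness(net, transform)], axis=1)
    if zscores:
        for col in ("strength", "closeness", "betweenness"):
            sd = table[col].std(ddof=1)
            table[f"{col}_z"] = ((table[col] - table[col].mean()) / sd
                                 if sd > 0 else 0.0)
    table.index.name = "node"
    return table


def centrality_long(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format (node, index, value) view matching centrality-plot data."""
    cols = [c for c in ("strength", "closeness", "betweenness")
            if c in table.columns]
    long = table.reset_index().melt(id_vars="node", value_vars=cols,
                                    var_name="index", value_name="value")
    return long
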