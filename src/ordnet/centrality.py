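"""Node centrality for partial-correlation networks.

Three indices: strength (sum of absolute incident edge weights, the
headline index), closeness (reciprocal of the summed shortest-path
distances to all reachable nodes) and betweenness (share of shortest
paths between other node pairs passing through the node, with fractional
credit under ties).  Shortest paths use the convention distance = 1/|w|:
stronger edges are shorter.  For a node that cannot reach every other
node, closeness is computed within its component and the node is flagged.

Strength is the only index surfaced by default in study reports; closeness
and betweenness are computed and emitted but marked secondary because
case-dropping stability rarely supports interpreting them.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .ggm import EDGE_EPS, NetworkModel

INDICES = ("strength", "closeness", "betweenness")


def _weights_and_names(network, node_names=None):
    if isinstance(network, NetworkModel):
        return network.weights, list(network.node_names)
    w = np.asarray(network, dtype=float)
    names = list(node_names) if node_names is not None else \
        [f"V{i + 1}" for i in range(w.shape[0])]
    return w, names


def node_strength(network, node_names=None) -> pd.Series:
    """s_i = sum_j |w_ij|: how strongly a node is directly connected."""
    w, names = _weights_and_names(network, node_names)
    return pd.Series(np.abs(w).sum(axis=1), index=names, name="strength")


def _distance_graph(w: np.ndarray) -> nx.Graph:
    p = w.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if abs(w[i, j]) > EDGE_EPS:
                G.add_edge(i, j, length=1.0 / abs(w[i, j]))
    return G


def closeness_betweenness(network, node_names=None) -> pd.DataFrame:
    """Closeness and betweenness under the 1/|w| distance convention.

    closeness_i = 1 / sum_j d(i, j) over the nodes reachable from i (0 for
    an isolated node); betweenness_i counts node pairs whose shortest path
    runs through i, splitting credit equally among tied shortest paths.
    A ``disconnected`` flag marks nodes that cannot reach every other node.
    """
    w, names = _weights_and_names(network, node_names)
    p = w.shape[0]
    G = _distance_graph(w)
    closeness = np.zeros(p)
    disconnected = np.zeros(p, dtype=bool)
    for i in range(p):
        dist = nx.single_source_dijkstra_path_length(G, i, weight="length")
        total = sum(d for j, d in dist.items() if j != i)
        reachable = len(dist) - 1
        closeness[i] = 1.0 / total if total > 0 else 0.0
        disconnected[i] = reachable < p - 1
    btw = nx.betweenness_centrality(G, normalized=False, weight="length")
    return pd.DataFrame({
        "closeness": closeness,
        "betweenness": np.array([btw[i] for i in range(p)]),
        "disconnected": disconnected,
    }, index=names)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd <= 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def centrality_table(network, node_names=None) -> pd.DataFrame:
    """Full per-node centrality table, raw and z-standardized."""
    w, names = _weights_and_names(network, node_names)
    out = closeness_betweenness(w, names)
    out.insert(0, "strength", node_strength(w, names))
    for idx in INDICES:
        out[f"z_{idx}"] = _zscore(out[idx].to_numpy(dtype=float))
    out.index.name = "node"
    return out[["strength", "closeness", "betweenness",
                "z_strength", "z_closeness", "z_betweenness", "disconnected"]]
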