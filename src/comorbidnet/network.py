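"""Protein-interaction graph construction, centralities and hub selection.

Edges below the confidence threshold (strictly greater than 0.7 by default,
mirroring a high-confidence STRING cut) are dropped; betweenness is computed
on the unweighted graph, unnormalized, each unordered pair counted once,
with multiple shortest paths split fractionally; hubs are the top-k nodes by
mean centrality rank among nodes passing the degree floor.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_graph", "centralities", "select_hubs"]

logger = logging.getLogger(__name__)


def build_graph(edges: pd.DataFrame, confidence_min: float = 0.7,
                score_scale: str = "unit") -> nx.Graph:
    """Build an undirected simple graph from a (node1, node2, confidence) table.

    ``score_scale='string'`` divides integer scores 0-999 by 1000 first.
    The filter is strictly greater than ``confidence_min``; self-loops are
    dropped and duplicate edges keep the highest confidence.  Isolated nodes
    never enter (nodes exist only through surviving edges).  Nodes are added
    in lexicographic order for deterministic iteration.
    """
    required = {"node1", "node2", "confidence"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    conf = edges["confidence"].to_numpy(dtype=float)
    if score_scale == "string":
        conf = conf / 1000.0
    elif score_scale != "unit":
        raise ValueError("score_scale must be 'unit' or 'string'")
    bad = ~np.isfinite(conf) | (conf < 0) | (conf > 1)
    if bad.any():
        line = int(np.argmax(bad))
        raise ValueError(f"malformed confidence at row {line}: {conf[line]}")
    g = nx.Graph()
    keep = edges.loc[conf > confidence_min].assign(confidence=conf[conf > confidence_min])
    if keep.empty:
        logger.warning("no edges above confidence %.2f; graph is empty",
                       confidence_min)
        return g
    nodes = sorted(set(keep["node1"]).union(keep["node2"]))
    g.add_nodes_from(nodes)
    for u, v, c in keep[["node1", "node2", "confidence"]].itertuples(index=False):
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["confidence"] = max(g[u][v]["confidence"], float(c))
        else:
            g.add_edge(u, v, confidence=float(c))
    g.remove_nodes_from([n for n in nodes if g.degree(n) == 0])
    return g


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node.

    Betweenness: unweighted shortest paths, unnormalized, each unordered
    pair counted once (``normalized_betweenness`` is also reported, divided
    by (n-1)(n-2)/2).  Closeness: (component size - 1) / sum of distances
    within the node's component.
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "degree", "betweenness",
                                     "normalized_betweenness", "closeness"])
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.closeness_centrality(g, wf_improved=False)
    n = g.number_of_nodes()
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    rows = [{"node": v, "degree": g.degree(v), "betweenness": bc[v],
             "normalized_betweenness": bc[v] / norm, "closeness": cc[v]}
            for v in sorted(g.nodes)]
    return pd.DataFrame(rows)


def select_hubs(table: pd.DataFrame, k: int = 10,
                degree_min: int = 10) -> pd.DataFrame:
    """Select hub genes: degree floor, then mean centrality rank.

    Nodes with degree >= ``degree_min`` are ranked by the mean of their
    (descending) ranks across degree, betweenness and closeness; ties break
    lexicographically by node id; the list is truncated to ``k``.  A
    ``flagged`` column marks results with fewer than ``k`` qualifying nodes.
    """
    qual = table[table["degree"] >= degree_min].copy()
    flagged = len(qual) < k
    if flagged:
        logger.warning("only %d nodes pass degree >= %d (requested top %d)",
                       len(qual), degree_min, k)
    if qual.empty:
        out = qual.assign(mean_rank=pd.Series(dtype=float))
        out["flagged"] = flagged
        return out
    ranks = pd.concat(
        [qual[c].rank(ascending=False) for c in
         ("degree", "betweenness", "closeness")], axis=1)
    qual["mean_rank"] = ranks.mean(axis=1)
    qual = qual.sort_values(["mean_rank", "node"]).head(k)
    qual["flagged"] = flagged
    return qual.reset_index(drop=True)
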