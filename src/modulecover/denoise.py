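"""Clustering-coefficient edge de-noising.

High-throughput interaction data carry spurious edges.  Each edge is scored
by how much its removal would lower its endpoints' clustering coefficients:

    SCC(i, j) = CC_i + CC_j - CC'_i - CC'_j

where CC_i = 2 n_i / (k_i (k_i - 1)) (n_i = triangles through i) and CC' is
evaluated on the graph with edge (i, j) deleted.  An edge embedded in a
triangle-rich neighborhood loses the endpoints a lot of local clustering
when removed (large SCC); an edge whose removal changes nothing — or even
raises the coefficients, which happens when it contributes degree but no
triangles — scores <= 0 and is treated as noise.  De-noising removes every
edge with SCC <= alpha in a single simultaneous pass over weights computed
on the original network.

Degree-< 2 convention: CC is 0/0 for nodes with fewer than two neighbors;
we define it as 0 there, which makes SCC total.
"""

from __future__ import annotations

import logging

import networkx as nx

from .containers import EdgeWeightTable, edge_key

logger = logging.getLogger(__name__)


def clustering_coefficient(net: nx.Graph, i: str) -> float:
    """CC_i = 2 n_i / (k_i (k_i - 1)); 0 for degree < 2."""
    if i not in net:
        raise KeyError(f"node {i!r} not in network")
    return nx.clustering(net, i)


def _cc_terms(degree: int, triangles: int) -> float:
    if degree < 2:
        return 0.0
    return 2.0 * triangles / (degree * (degree - 1))


def edge_weight(net: nx.Graph, i: str, j: str) -> float:
    """SCC(i, j): clustering-coefficient drop caused by deleting edge (i, j).

    The deletion is conceptual only — the input graph is never mutated.
    Removing (i, j) lowers both endpoint degrees by one and removes the
    triangles they share, i.e. their common-neighbor count.
    """
    if not net.has_edge(i, j):
        raise ValueError(f"({i!r}, {j!r}) is not an edge of the network")
    tri = nx.triangles(net, [i, j])
    common = len(set(net.adj[i]) & set(net.adj[j]))
    ki, kj = net.degree(i), net.degree(j)
    cc_i = _cc_terms(ki, tri[i])
    cc_j = _cc_terms(kj, tri[j])
    cc_i_removed = _cc_terms(ki - 1, tri[i] - common)
    cc_j_removed = _cc_terms(kj - 1, tri[j] - common)
    return cc_i + cc_j - cc_i_removed - cc_j_removed


def compute_edge_weights(net: nx.Graph) -> EdgeWeightTable:
    """SCC for every edge of ``net`` (computed once, on the original graph)."""
    tri = nx.triangles(net)
    deg = dict(net.degree())
    weights: dict[tuple[str, str], float] = {}
    for u, v in net.edges():
        common = len(set(net.adj[u]) & set(net.adj[v]))
        w = (
            _cc_terms(deg[u], tri[u])
            + _cc_terms(deg[v], tri[v])
            - _cc_terms(deg[u] - 1, tri[u] - common)
            - _cc_terms(deg[v] - 1, tri[v] - common)
        )
        weights[edge_key(u, v)] = w
    return EdgeWeightTable(weights=weights)


def denoise(net: nx.Graph, alpha: float = 0.0) -> tuple[nx.Graph, EdgeWeightTable]:
    """Remove all edges with SCC <= alpha (single pass, no recomputation).

    Weights are computed on the original network first, then all removals
    applied simultaneously.  Nodes isolated by the removal are dropped from
    the returned graph (they are recoverable as ``set(net) - set(result)``
    and count as discarded in downstream bookkeeping).  Pass
    ``alpha=float("-inf")`` to disable de-noising.

    Returns the reduced graph and the full weight table of the *original*
    edges (with ``alpha`` recorded on it).
    """
    table = compute_edge_weights(net)
    table.alpha = alpha
    reduced = net.copy()
    to_remove = [e for e, w in table.weights.items() if w <= alpha]
    reduced.remove_edges_from(to_remove)
    isolated = [n for n, d in reduced.degree() if d == 0]
    reduced.remove_nodes_from(isolated)
    logger.info(
        "de-noising (alpha=%g): removed %d/%d edges, isolated %d nodes",
        alpha, len(to_remove), net.number_of_edges(), len(isolated),
    )
    if reduced.number_of_edges() == 0:
        logger.warning("de-noising removed every edge (alpha=%g)", alpha)
    return reduced, table
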