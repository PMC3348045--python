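"""Overlap expansion: from a disjoint partition to a module cover.

A node sitting at a module boundary may genuinely belong to several
modules.  Candidates are the nodes with at least one neighbor in a foreign
module.  For each candidate i and each neighboring foreign module B we ask
whether *copying* i into B raises B's own modularity contribution

    Q_B = e_BB - a_B^2

where e_BB counts edges with both endpoints in B (as a fraction of all m
edges) and a_B is the degree fraction of B's members.  Copies duplicate
membership, not edges: a copied node brings its full degree into a_B and
its edges into B into e_BB, while m stays global.  If Q_{B + i} > Q_B
strictly, i is added to B (always keeping its primary module).  The scan
repeats until a full pass adds nothing; processing order is deterministic
(sorted nodes, sorted module ids).

A consequence worth knowing: a node wired perfectly symmetrically between
two modules of a two-module network gains *exactly* zero (the inequality
degenerates to equality), so it is not copied.  Overlap emerges when the
rest of the network is large relative to the target module.
"""

from __future__ import annotations

import networkx as nx

from .containers import ModuleCover, cover_from_partition


def candidate_nodes(net: nx.Graph, partition: dict[str, set[str]]) -> set[str]:
    """Nodes with >= 1 neighbor whose module differs from their own."""
    home: dict[str, str] = {}
    for mid, members in partition.items():
        for node in members:
            home[node] = mid
    out: set[str] = set()
    for node in net.nodes():
        mine = home.get(node)
        if any(home.get(nb) != mine for nb in net.adj[node]):
            out.add(node)
    return out


def module_modularity(net: nx.Graph, cover: ModuleCover, module_id: str) -> float:
    """Per-module modularity Q_B = e_BB - a_B^2 under the copy semantics."""
    if module_id not in cover.modules:
        raise KeyError(f"unknown module {module_id!r}")
    members = cover.modules[module_id]
    m = net.number_of_edges()
    intra = sum(1 for u, v in net.edges(members) if u in members and v in members)
    a = sum(net.degree(n) for n in members) / (2 * m)
    return intra / m - a * a


def _gain(net: nx.Graph, members: set[str], node: str) -> tuple[float, float]:
    """(Q_B, Q_{B+node}) computed incrementally."""
    m = net.number_of_edges()
    intra = sum(1 for u, v in net.edges(members) if u in members and v in members)
    deg_sum = sum(net.degree(n) for n in members)
    a = deg_sum / (2 * m)
    q_before = intra / m - a * a
    edges_in = sum(1 for nb in net.adj[node] if nb in members)
    a_after = (deg_sum + net.degree(node)) / (2 * m)
    q_after = (intra + edges_in) / m - a_after * a_after
    return q_before, q_after


def expand_overlaps(net: nx.Graph, partition: dict[str, set[str]]) -> ModuleCover:
    """Copy candidate nodes into every foreign neighbor module they improve.

    Each accepted copy strictly increased the target module's modularity at
    acceptance time; the (node, module, Q_before, Q_after) tuples are kept
    on ``cover.expansion_log`` for re-checking.  Terminates because a node
    enters a given module at most once and the module set is fixed.
    """
    cover = cover_from_partition(partition)
    candidates = sorted(candidate_nodes(net, partition))
    changed = True
    while changed:
        changed = False
        for node in candidates:
            neighbor_modules: set[str] = set()
            for nb in net.adj[node]:
                neighbor_modules |= cover.membership(nb)
            foreign = sorted(neighbor_modules - cover.membership(node))
            for mid in foreign:
                q_before, q_after = _gain(net, cover.modules[mid], node)
                if q_after > q_before:
                    cover.modules[mid].add(node)
                    cover.expansion_log.append((node, mid, q_before, q_after))
                    changed = True
    return cover


def filter_min_size(cover: ModuleCover, min_size: int) -> ModuleCover:
    """Delete modules smaller than ``min_size``; nodes left in no module
    move to the discarded set.  Primary assignments pointing at a deleted
    module are remapped to the smallest surviving module of the node."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = {
        mid: set(members)
        for mid, members in cover.modules.items()
        if len(members) >= min_size
    }
    covered: set[str] = set()
    for members in kept.values():
        covered |= members
    discarded = set(cover.discarded) | (cover.covered_nodes() - covered)
    primary: dict[str, str] = {}
    for node in covered:
        home = cover.primary.get(node)
        if home in kept and node in kept[home]:
            primary[node] = home
        else:
            primary[node] = min(mid for mid, mem in kept.items() if node in mem)
    return ModuleCover(
        modules=kept,
        discarded=discarded,
        primary=primary,
        expansion_log=list(cover.expansion_log),
    )
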