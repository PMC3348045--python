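"""Party and date hub detection.

Party hubs interact with their partners simultaneously and sit inside
modules: the party hub of module r is its member with maximal nodal weight

    w_i = sum over neighbors j of SCC(i, j)

summed over the node's incident edges in the *original* (pre-de-noising)
network, so hub scores exist even for endpoints of removed edges.  Ties are
broken toward the lexicographically smallest name.  Note w_i carries no
sign guarantee — SCC can be negative — and is identically zero on
triangle-free networks, where the tie-break alone decides.

Date hubs organize the network across modules: a node bound to at least
``min_contacts`` (default 3) retained modules that it does not itself
belong to.  The contact count

    ACC_i = #{ modules r : i not in r, some neighbor of i is in r }

is evaluated for every node by default; restricting candidates to the
discarded set (``candidates="discarded"``) is available and coincides with
the default on that set.
"""

from __future__ import annotations

import math

import networkx as nx

from .containers import EdgeWeightTable, HubReport, ModuleCover


def nodal_weight(weights: EdgeWeightTable, net: nx.Graph, i: str) -> float:
    """w_i: sum of SCC over i's incident edges in ``net``."""
    if i not in net:
        raise KeyError(f"node {i!r} not in network")
    w = 0.0
    for j in net.adj[i]:
        w += weights.get(i, j)
    if not math.isfinite(w):
        raise ValueError(f"non-finite nodal weight for {i!r}")
    return w


def party_hubs(
    cover: ModuleCover, weights: EdgeWeightTable, net: nx.Graph
) -> dict[str, str]:
    """One party hub per module: argmax nodal weight, ties to smallest name."""
    if not cover.modules:
        raise ValueError("cover has no modules")
    out: dict[str, str] = {}
    for mid, members in cover.modules.items():
        best_node, best_w = None, -math.inf
        for node in sorted(members):
            w = nodal_weight(weights, net, node) if node in net else 0.0
            if w > best_w:
                best_node, best_w = node, w
        out[mid] = best_node
    return out


def module_contacts(cover: ModuleCover, net: nx.Graph, i: str) -> int:
    """ACC_i: number of retained modules not containing i that hold >= 1
    neighbor of i."""
    count = 0
    for mid, members in cover.modules.items():
        if i in members:
            continue
        if any(nb in members for nb in net.adj[i]):
            count += 1
    return count


def date_hubs(
    cover: ModuleCover,
    net: nx.Graph,
    min_contacts: int = 3,
    candidates: str = "all",
) -> set[str]:
    """Nodes bound to >= ``min_contacts`` foreign retained modules.

    ``candidates="all"`` (default) screens every node of ``net``;
    ``"discarded"`` restricts to the cover's discarded set.
    """
    if candidates == "all":
        pool = set(net.nodes())
    elif candidates == "discarded":
        pool = set(cover.discarded) & set(net.nodes())
    else:
        raise ValueError("candidates must be 'all' or 'discarded'")
    return {i for i in pool if module_contacts(cover, net, i) >= min_contacts}


def hub_report(
    cover: ModuleCover,
    weights: EdgeWeightTable,
    net: nx.Graph,
    contact_net: nx.Graph | None = None,
    min_contacts: int = 3,
    candidates: str = "all",
) -> HubReport:
    """Full hub detection.

    ``net`` is the original network (nodal weights); ``contact_net`` (the
    de-noised working graph, defaulting to ``net``) defines adjacency for
    the date-hub contact counts.
    """
    contact_net = contact_net if contact_net is not None else net
    party = party_hubs(cover, weights, net)
    contacts = {
        i: module_contacts(cover, contact_net, i) for i in contact_net.nodes()
    }
    date = date_hubs(cover, contact_net, min_contacts, candidates)
    w = {i: nodal_weight(weights, net, i) for i in net.nodes()}
    return HubReport(
        party=party,
        date=date,
        nodal_weight=w,
        contacts=contacts,
        date_hub_min=min_contacts,
    )
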