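"""Greedy agglomerative modularity clustering (Newman's fast algorithm).

Modularity of a partition into modules r:

    Q = sum_r (e_rr - a_r^2)

where e_rk is the fraction of edge ends running between modules r and k
(each edge contributes 1/2m to e_rk and 1/2m to e_kr; an intra-module edge
therefore adds 1/m to the diagonal) and a_r = sum_k e_rk = (total degree of
r) / 2m.  Starting from singletons, the algorithm repeatedly merges the
connected module pair with the largest modularity gain

    dQ = 2 (e_rk - a_r a_k)

recording every merge and its cumulative Q, and returns the partition at
the step where cumulative Q was maximal (earliest such step on ties).

Only pairs joined by at least one edge are considered: merging disconnected
modules has dQ = -2 a_r a_k <= 0 and can never help.  Ties in dQ are broken
toward the lexicographically smallest (id, id) pair; module ids are the
smallest member name, so runs are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .containers import MergeStep, MergeTrace


@dataclass
class ModuleFractionState:
    """The e-matrix / a-vector bookkeeping of the agglomeration.

    ``e`` is stored sparsely as a symmetric dict-of-dicts over live module
    ids (diagonal included); ``a[r]`` is the row sum; ``members`` maps each
    live module to its node set.  Invariant: sum of all e entries is 1.
    """

    e: dict[str, dict[str, float]]
    a: dict[str, float]
    m: int
    members: dict[str, set[str]] = field(default_factory=dict)

    def total(self) -> float:
        return sum(sum(row.values()) for row in self.e.values())


def init_state(net: nx.Graph) -> ModuleFractionState:
    """One singleton module per node; e and a from the edge fractions."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot initialize clustering state on an empty network")
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("network has no edges")
    half = 1.0 / (2 * m)
    e: dict[str, dict[str, float]] = {n: {} for n in net.nodes()}
    for u, v in net.edges():
        e[u][v] = e[u].get(v, 0.0) + half
        e[v][u] = e[v].get(u, 0.0) + half
    a = {n: net.degree(n) * half for n in net.nodes()}
    members = {n: {n} for n in net.nodes()}
    return ModuleFractionState(e=e, a=a, m=m, members=members)


def modularity(net: nx.Graph, partition: dict[str, set[str]]) -> float:
    """Q computed from scratch on ``net`` for a disjoint full partition."""
    home: dict[str, str] = {}
    for mid, members in partition.items():
        for node in members:
            if node in home:
                raise ValueError(f"node {node!r} appears in two modules")
            home[node] = mid
    missing = set(net.nodes()) - set(home)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]}...")
    m = net.number_of_edges()
    intra = {mid: 0 for mid in partition}
    for u, v in net.edges():
        if home[u] == home[v]:
            intra[home[u]] += 1
    q = 0.0
    for mid, members in partition.items():
        e_rr = intra[mid] / m
        a_r = sum(net.degree(n) for n in members) / (2 * m)
        q += e_rr - a_r * a_r
    return q


def greedy_cluster(net: nx.Graph) -> tuple[MergeTrace, dict[str, set[str]]]:
    """Run the full agglomeration and cut at maximum cumulative Q.

    Returns the merge trace (all steps down to one module per component)
    and the partition at the earliest maximal-Q step, keyed by canonical
    module ids (smallest member name).
    """
    state = init_state(net)
    e, a = state.e, state.a
    q = -sum(x * x for x in a.values())  # singletons: all e_rr = 0
    trace = MergeTrace(initial_q=q)
    step = 0
    merges: list[tuple[str, str]] = []
    while True:
        best_pair: tuple[str, str] | None = None
        best_dq = 0.0
        for u in sorted(e):
            row = e[u]
            for v in sorted(row):
                if v <= u:
                    continue
                dq = 2.0 * (row[v] - a[u] * a[v])
                if best_pair is None or dq > best_dq:
                    best_pair, best_dq = (u, v), dq
        if best_pair is None:
            break  # no connected module pairs left (one module per component)
        u, v = best_pair  # u < v, so u is the canonical merged id
        step += 1
        q += best_dq
        # Fold module v's row/column into u's.
        e[u][u] = e[u].get(u, 0.0) + e[v].get(v, 0.0) + 2.0 * e[u][v]
        for w, val in e[v].items():
            if w in (u, v):
                continue
            e[u][w] = e[u].get(w, 0.0) + val
            e[w][u] = e[u][w]
            del e[w][v]
        del e[u][v]
        del e[v]
        a[u] += a[v]
        del a[v]
        state.members[u] |= state.members.pop(v)
        merges.append((u, v))
        trace.steps.append(MergeStep(step, u, v, best_dq, q))
    # Replay merges up to the earliest maximal-Q state.
    best = trace.best_step
    partition: dict[str, set[str]] = {n: {n} for n in net.nodes()}
    for u, v in merges[:best]:
        partition[u] |= partition.pop(v)
    return trace, partition
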