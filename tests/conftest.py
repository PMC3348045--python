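"""Shared fixtures: small hand-checkable graphs and brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pytest

from modulecover import modularity


def graph_from_edges(edges) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


@pytest.fixture
def triangle() -> nx.Graph:
    return graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangle_bridge() -> nx.Graph:
    """Two triangles a-b-c and d-e-f joined by the bridge c-d (m = 7)."""
    return graph_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")]
    )


@pytest.fixture
def k4_minus_edge() -> nx.Graph:
    """K4 on a, b, c, d with edge (c, d) removed."""
    g = nx.complete_graph(["a", "b", "c", "d"])
    g.remove_edge("c", "d")
    return g


def small_graph_battery() -> list[tuple[str, nx.Graph]]:
    """Connected fixture graphs with <= 7 nodes for oracle comparisons."""
    battery = [
        ("triangle", graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])),
        ("path4", nx.path_graph(["a", "b", "c", "d"])),
        ("star5", nx.star_graph(["c", "a", "b", "d", "e"])),
        ("cycle5", nx.cycle_graph(["a", "b", "c", "d", "e"])),
        ("cycle7", nx.cycle_graph(list("abcdefg"))),
        ("k4", nx.complete_graph(["a", "b", "c", "d"])),
        ("k4_minus_edge", None),
        ("two_triangle_bridge", graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])),
        ("bowtie", graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("c", "d"), ("c", "e"), ("d", "e")])),
        ("lollipop", graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")])),
        ("k23", nx.complete_bipartite_graph(2, 3)),
        ("triangle_pendant", graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])),
    ]
    k4m = nx.complete_graph(["a", "b", "c", "d"])
    k4m.remove_edge("c", "d")
    out = []
    for name, g in battery:
        if g is None:
            g = k4m
        out.append((name, nx.relabel_nodes(g, {n: str(n) for n in g.nodes()})))
    return out


def set_partitions(items: list):
    """All set partitions of ``items`` (recursive; fine for n <= 7)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_q(net: nx.Graph) -> float:
    """Maximum modularity over every partition, by enumeration."""
    nodes = sorted(net.nodes())
    best = -float("inf")
    for blocks in set_partitions(nodes):
        partition = {min(b): set(b) for b in blocks}
        best = max(best, modularity(net, partition))
    return best


def replay_partitions(net: nx.Graph, trace):
    """Yield (step_index, partition) for every state of a merge trace."""
    partition = {n: {n} for n in net.nodes()}
    yield 0, {k: set(v) for k, v in partition.items()}
    for i, step in enumerate(trace.steps, start=1):
        partition[step.module_a] |= partition.pop(step.module_b)
        yield i, {k: set(v) for k, v in partition.items()}
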