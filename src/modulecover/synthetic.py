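"""Deterministic generators for benchmark networks.

Two families:

* :func:`make_word_network` — a double-layer word-association-style
  network: one central hub ("day") linked to the centers of eight
  sub-networks, each center heading a star of spoke words, a handful of
  shared words linking adjacent sub-network pairs, and one extra
  second-layer cycle.  The default arithmetic lands exactly on 151 nodes
  and 155 edges.  Ground-truth labels (sub-network membership; the central
  hub deliberately unlabeled) and the expected hub/overlap sets are emitted
  alongside.

  Note the totals force a cycle rank of 5: with four shared nodes each
  closing one independent cycle, only one extra cycle remains, so the
  network is necessarily triangle-free.  All SCC edge weights are then
  identically zero and party hubs are decided by the deterministic
  lexicographic tie-break; node naming (spokes prefixed by their center's
  name, shared nodes prefixed ``zz_``) makes the tie-break land on the
  centers, mirroring their role in the real word-association data.

* :func:`make_planted` — planted-partition (stochastic-block-model-style)
  graphs with optional planted overlap nodes wired into two blocks, plus
  their ground-truth labels.  Pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

_DEFAULT_CENTERS = (
    "camp", "enjoy", "long", "month", "sleep", "sunny", "sunshine", "work",
)
# Smallest count first: the weakest (lowest total-degree) sub-network
# attracts the central hub at the end of the agglomeration, and keeping it
# on the lexicographically smallest center makes the fixture's party-hub
# tie-breaks unambiguous.
_DEFAULT_SPOKES = (10, 18, 18, 18, 18, 18, 18, 19)


@dataclass(frozen=True)
class WordNetSpec:
    """Parameters of the double-layer word network."""

    centers: tuple[str, ...] = _DEFAULT_CENTERS
    spoke_counts: tuple[int, ...] = _DEFAULT_SPOKES
    n_shared: int = 4
    central_hub: str = "day"
    n_cycle_nodes: int = 1
    seed: int = 0

    @property
    def n_subnetworks(self) -> int:
        return len(self.centers)

    @property
    def n_nodes(self) -> int:
        return 1 + len(self.centers) + sum(self.spoke_counts) \
            + self.n_cycle_nodes + self.n_shared

    @property
    def n_edges(self) -> int:
        return len(self.centers) + sum(self.spoke_counts) \
            + 2 * self.n_cycle_nodes + 2 * self.n_shared


def _validate_word_spec(spec: WordNetSpec) -> None:
    if len(spec.centers) != len(spec.spoke_counts):
        raise ValueError("one spoke count per center required")
    if len(spec.centers) < 2:
        raise ValueError("need at least two sub-networks")
    if len(set(spec.centers)) != len(spec.centers):
        raise ValueError("center names must be distinct")
    if spec.central_hub in spec.centers:
        raise ValueError("central hub cannot also be a center")
    if any(c < 1 for c in spec.spoke_counts):
        raise ValueError("every sub-network needs at least one spoke")
    if spec.n_shared > len(spec.centers) // 2:
        raise ValueError(
            "shared nodes join disjoint adjacent center pairs: "
            f"n_shared <= {len(spec.centers) // 2}"
        )
    if spec.n_cycle_nodes not in (0, 1):
        raise ValueError("n_cycle_nodes must be 0 or 1")
    if spec.n_cycle_nodes and spec.spoke_counts[-1] < 2:
        raise ValueError("cycle node needs >= 2 spokes in the last sub-network")


def make_word_network(
    spec: WordNetSpec = WordNetSpec(),
) -> tuple[nx.Graph, dict[str, str], dict[str, object]]:
    """Build the word network, its ground-truth labels, and the expected
    hub/overlap manifest.

    Returns ``(graph, truth, expected)`` where ``truth`` maps every node
    except the central hub to its sub-network (shared nodes carry the label
    of their first host) and ``expected`` holds ``party_hubs`` (the
    centers), ``date_hub`` (the central hub) and ``overlap_nodes`` (the
    shared nodes).
    """
    _validate_word_spec(spec)
    g = nx.Graph()
    truth: dict[str, str] = {}
    hub = spec.central_hub
    for center, count in zip(spec.centers, spec.spoke_counts):
        g.add_edge(hub, center)
        truth[center] = center
        for i in range(1, count + 1):
            spoke = f"{center}_w{i:02d}"
            g.add_edge(center, spoke)
            truth[spoke] = center
    if spec.n_cycle_nodes:
        host = spec.centers[-1]
        cycle = f"{host}_x01"
        g.add_edge(cycle, f"{host}_w01")
        g.add_edge(cycle, f"{host}_w02")
        truth[cycle] = host
    shared: list[str] = []
    for j in range(spec.n_shared):
        c1, c2 = spec.centers[2 * j], spec.centers[2 * j + 1]
        node = f"zz_{c1}_{c2}"
        g.add_edge(node, c1)
        g.add_edge(node, c2)
        truth[node] = c1
        shared.append(node)
    assert g.number_of_nodes() == spec.n_nodes
    assert g.number_of_edges() == spec.n_edges
    expected = {
        "party_hubs": set(spec.centers),
        "date_hub": hub,
        "overlap_nodes": set(shared),
    }
    return g, truth, expected


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-partition graph with optional planted
    overlap nodes (each wired into two adjacent blocks)."""

    n_blocks: int = 4
    block_size: int = 8
    p_in: float = 0.9
    p_out: float = 0.05
    n_overlap: int = 0
    overlap_edges_per_block: int = 3
    seed: int = 0


def make_planted(spec: PlantedSpec) -> tuple[nx.Graph, dict[str, str]]:
    """Stochastic-block-model-style graph plus ground-truth labels.

    Planted overlap nodes are extra nodes named ``ovNN`` connected to
    ``overlap_edges_per_block`` distinct members of each of two adjacent
    blocks; their reference label is the first host block (the reference
    is a partition, not a cover).
    """
    if spec.n_blocks < 2 or spec.block_size < 2:
        raise ValueError("need >= 2 blocks of >= 2 nodes")
    if not (0 <= spec.p_in <= 1 and 0 <= spec.p_out <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if spec.overlap_edges_per_block > spec.block_size:
        raise ValueError("more overlap edges than block members")
    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    blocks: list[list[str]] = []
    truth: dict[str, str] = {}
    for b in range(spec.n_blocks):
        label = f"b{b:02d}"
        members = [f"{label}_n{i:02d}" for i in range(spec.block_size)]
        g.add_nodes_from(members)
        blocks.append(members)
        truth.update({m: label for m in members})
    nodes = [m for block in blocks for m in block]
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = spec.p_in if truth[u] == truth[v] else spec.p_out
            if rng.random() < p:
                g.add_edge(u, v)
    for j in range(spec.n_overlap):
        node = f"ov{j:02d}"
        first, second = j % spec.n_blocks, (j + 1) % spec.n_blocks
        for b in (first, second):
            picks = rng.choice(
                spec.block_size, size=spec.overlap_edges_per_block,
                replace=False,
            )
            for i in sorted(int(x) for x in picks):
                g.add_edge(node, blocks[b][i])
        truth[node] = f"b{first:02d}"
    return g, truth
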