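"""Shared result containers used across the pipeline stages.

These are deliberately thin, serialization-friendly dataclasses: the graph
itself is a :class:`networkx.Graph`, and everything derived from it (edge
weights, the agglomerative merge trace, the possibly-overlapping module
cover, hub and evaluation reports) lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered key for an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class EdgeWeightTable:
    """Per-edge SCC reliability scores.

    SCC(i, j) is the drop in the endpoints' clustering coefficients caused
    by deleting edge (i, j); symmetric by construction, defined exactly for
    the edges of the network it was computed on.
    """

    weights: dict[tuple[str, str], float]
    alpha: float | None = None

    def get(self, u: str, v: str) -> float:
        return self.weights[edge_key(u, v)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return edge_key(*pair) in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self.weights.items()))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for (u, v), w in self.items():
                fh.write(f"{u}\t{v}\t{w:.12g}\n")


class MergeStep(NamedTuple):
    step: int
    module_a: str
    module_b: str
    delta_q: float
    q: float


@dataclass
class MergeTrace:
    """Ordered record of agglomerative merges (the dendrogram).

    ``initial_q`` is the modularity of the all-singletons state; ``steps``
    hold one entry per merge with the cumulative modularity after it.
    """

    initial_q: float
    steps: list[MergeStep] = field(default_factory=list)

    @property
    def q_values(self) -> list[float]:
        return [self.initial_q] + [s.q for s in self.steps]

    @property
    def best_step(self) -> int:
        """Earliest state index (0 = singletons) attaining max cumulative Q."""
        qs = self.q_values
        best = 0
        for i, q in enumerate(qs):
            if q > qs[best]:
                best = i
        return best

    @property
    def q_max(self) -> float:
        return self.q_values[self.best_step]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("step\tmodule_a\tmodule_b\tdelta_q\tq\n")
            for s in self.steps:
                fh.write(
                    f"{s.step}\t{s.module_a}\t{s.module_b}\t"
                    f"{s.delta_q:.12g}\t{s.q:.12g}\n"
                )


@dataclass
class ModuleCover:
    """A possibly overlapping assignment of nodes to modules.

    ``modules`` maps module id -> member set (sets may intersect);
    ``discarded`` holds nodes retained in no module; ``primary`` records the
    disjoint-partition home of each covered node.
    """

    modules: dict[str, set[str]]
    discarded: set[str] = field(default_factory=set)
    primary: dict[str, str] = field(default_factory=dict)
    expansion_log: list[tuple[str, str, float, float]] = field(
        default_factory=list, compare=False, repr=False
    )

    def covered_nodes(self) -> set[str]:
        out: set[str] = set()
        for members in self.modules.values():
            out |= members
        return out

    def all_nodes(self) -> set[str]:
        return self.covered_nodes() | self.discarded

    def membership(self, node: str) -> set[str]:
        return {mid for mid, members in self.modules.items() if node in members}

    def overlap_nodes(self) -> set[str]:
        seen: set[str] = set()
        overlap: set[str] = set()
        for members in self.modules.values():
            overlap |= members & seen
            seen |= members
        return overlap

    def sizes(self) -> dict[str, int]:
        return {mid: len(members) for mid, members in self.modules.items()}

    def copy(self) -> "ModuleCover":
        return ModuleCover(
            modules={mid: set(m) for mid, m in self.modules.items()},
            discarded=set(self.discarded),
            primary=dict(self.primary),
            expansion_log=list(self.expansion_log),
        )


def cover_from_partition(partition: dict[str, set[str]]) -> ModuleCover:
    """Wrap a disjoint partition as a (trivial) module cover."""
    primary = {}
    for mid, members in partition.items():
        for node in members:
            primary[node] = mid
    return ModuleCover(
        modules={mid: set(m) for mid, m in partition.items()},
        discarded=set(),
        primary=primary,
    )


@dataclass
class HubReport:
    """Party hubs (one per module, maximal nodal weight) and date hubs
    (nodes touching >= ``date_hub_min`` modules they do not belong to)."""

    party: dict[str, str]
    date: set[str]
    nodal_weight: dict[str, float]
    contacts: dict[str, int]
    date_hub_min: int = 3

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#PARTY\nmodule\thub\tnodal_weight\n")
            for mid in sorted(self.party):
                hub = self.party[mid]
                fh.write(f"{mid}\t{hub}\t{self.nodal_weight.get(hub, 0.0):.12g}\n")
            fh.write("#DATE\nnode\tcontacts\n")
            for node in sorted(self.date):
                fh.write(f"{node}\t{self.contacts.get(node, 0)}\n")


@dataclass
class EvalReport:
    """Cover-quality metrics: accuracy (AC), overlapping rate (OL), average
    degree (AVD), module count and discard rate, plus per-module sizes."""

    ac: float | None
    ol: float
    avd: float
    n_modules: int
    discard_rate: float
    sizes: dict[str, int]
    degree_hist: dict[int, float]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("metric\tvalue\n")
            if self.ac is not None:
                fh.write(f"AC\t{self.ac:.6g}\n")
            fh.write(f"OL\t{self.ol:.6g}\n")
            fh.write(f"AVD\t{self.avd:.6g}\n")
            fh.write(f"n_modules\t{self.n_modules}\n")
            fh.write(f"discard_rate\t{self.discard_rate:.6g}\n")
            fh.write("#module_sizes\n")
            for mid in sorted(self.sizes):
                fh.write(f"{mid}\t{self.sizes[mid]}\n")
            fh.write("#degree_histogram\n")
            for k in sorted(self.degree_hist):
                fh.write(f"{k}\t{self.degree_hist[k]:.6g}\n")
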