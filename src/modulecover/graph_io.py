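"""Reading and sanitizing networks and auxiliary tables.

Input networks are plain two-column edge lists (whitespace- or
tab-separated) or simple interaction format (SIF).  Loading enforces the
simple-graph invariants: self-loops are dropped, duplicate and reversed
edges collapsed, and nodes left without any edge removed.  Node names are
case-sensitive opaque strings; no identifier normalization is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .containers import ModuleCover

logger = logging.getLogger(__name__)

_FORMATS = ("edgelist", "sif")


def read_network(path, format: str = "edgelist") -> nx.Graph:
    """Read and sanitize an undirected network.

    Parameters
    ----------
    path
        Edge-list file: one edge per line, first two whitespace-separated
        tokens are the endpoints; a single-token line declares a (dropped)
        isolated node; ``#`` starts a comment.  SIF lines are
        ``source relation target [target ...]``.
    format
        ``"edgelist"`` (default) or ``"sif"``.

    Returns
    -------
    networkx.Graph
        Simple graph with no self-loops and no isolated nodes.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    g = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if format == "sif":
                if len(tokens) < 3:
                    raise ValueError(
                        f"{path}:{ln}: malformed SIF line (need source, "
                        f"relation, >=1 target): {line!r}"
                    )
                pairs = [(tokens[0], t) for t in tokens[2:]]
            else:
                if len(tokens) == 1:
                    # Lone node declaration: isolated, dropped at load time.
                    g.add_node(tokens[0])
                    continue
                pairs = [(tokens[0], tokens[1])]
            for u, v in pairs:
                if u == v:
                    n_self += 1
                    continue
                if g.has_edge(u, v):
                    n_dup += 1
                    continue
                g.add_edge(u, v)
    isolated = [n for n, d in g.degree() if d == 0]
    g.remove_nodes_from(isolated)
    logger.info(
        "read %s: %d nodes, %d edges (dropped %d self-loops, %d duplicate "
        "edges, %d isolated nodes)",
        path, g.number_of_nodes(), g.number_of_edges(), n_self, n_dup,
        len(isolated),
    )
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: network is empty after sanitizing")
    return g


def write_network(net: nx.Graph, path) -> None:
    """Write a sorted two-column edge list (stable across runs)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


_DISCARDED_MARK = "__discarded__"


def write_module_cover(cover: ModuleCover, path) -> None:
    """Write a cover as ``module_id<TAB>size<TAB>member...`` lines followed
    by a trailing section listing discarded nodes."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for mid in sorted(cover.modules):
            members = sorted(cover.modules[mid])
            fh.write("\t".join([mid, str(len(members))] + members) + "\n")
        fh.write(
            "\t".join([_DISCARDED_MARK, str(len(cover.discarded))]
                      + sorted(cover.discarded)) + "\n"
        )


def read_module_cover(path) -> ModuleCover:
    """Inverse of :func:`write_module_cover`.

    The primary-module provenance is not serialized; on read, each node's
    primary is set to the lexicographically smallest module containing it.
    """
    modules: dict[str, set[str]] = {}
    discarded: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            tokens = line.split("\t")
            if len(tokens) < 2:
                raise ValueError(f"{path}:{ln}: malformed cover line: {line!r}")
            name, count, members = tokens[0], tokens[1], tokens[2:]
            if int(count) != len(members):
                raise ValueError(
                    f"{path}:{ln}: declared size {count} != {len(members)} members"
                )
            if name == _DISCARDED_MARK:
                discarded = set(members)
            else:
                modules[name] = set(members)
    primary: dict[str, str] = {}
    for mid in sorted(modules):
        for node in modules[mid]:
            primary.setdefault(node, mid)
    return ModuleCover(modules=modules, discarded=discarded, primary=primary)


def read_label_table(path) -> dict[str, str]:
    """Read a node -> reference-label TSV (a partition: one label per node)."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) < 2:
                raise ValueError(f"{path}:{ln}: expected node<TAB>label: {line!r}")
            node, label = tokens[0], tokens[1]
            if node in labels and labels[node] != label:
                raise ValueError(
                    f"{path}:{ln}: node {node!r} has conflicting labels "
                    f"{labels[node]!r} and {label!r}"
                )
            labels[node] = label
    return labels


def write_label_table(labels: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for node in sorted(labels):
            fh.write(f"{node}\t{labels[node]}\n")


def read_annotations(path) -> dict[str, set[str]]:
    """Read a GMT-like annotation file: ``term<TAB>description<TAB>gene...``.

    Returns term id -> gene set.  Duplicate term lines are unioned.
    """
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise ValueError(
                    f"{path}:{ln}: expected term<TAB>description<TAB>gene...: "
                    f"{line!r}"
                )
            term, genes = tokens[0], {t for t in tokens[2:] if t}
            if not genes:
                raise ValueError(f"{path}:{ln}: term {term!r} has an empty gene set")
            annotations.setdefault(term, set()).update(genes)
    return annotations
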