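"""Evaluation metrics and local enrichment.

Cover-quality metrics against a reference partition and on their own:

* AC (accuracy): each predicted module is mapped to the reference label it
  overlaps most; a node j counts as correctly classified when its predicted
  label set contains its reference label; AC averages, over nodes i, the
  fraction of i's neighbors classified correctly.  Nodes absent from the
  label table are excluded from the metric entirely (both as centers and as
  neighbors) — reference tables may deliberately leave connector nodes
  unlabeled.
* OL (overlapping rate): sum of module sizes over the number of distinct
  nodes; exactly 1 for a disjoint full cover, > 1 in the presence of
  overlap.
* AVD (average degree): 2 * sum of intra-module edges / sum of module sizes.
* discard rate: fraction of input nodes assigned to no retained module.

Enrichment of a module against a flat term -> gene-set table uses the
upper-tail cumulative hypergeometric probability of drawing at least ol
annotated members in a size-n1 module from a background of n genes with n2
annotated (the convention of the standard GO term-finder tools), reported
with its negative natural logarithm and the cluster frequency ol / n2.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .containers import EvalReport, ModuleCover


def map_modules_to_labels(
    cover: ModuleCover, truth: dict[str, str]
) -> dict[str, str | None]:
    """Best-overlap module -> reference-label mapping (ties to the
    lexicographically smaller label; None for modules with no labeled
    member)."""
    mapping: dict[str, str | None] = {}
    for mid, members in cover.modules.items():
        counts: dict[str, int] = {}
        for node in members:
            label = truth.get(node)
            if label is not None:
                counts[label] = counts.get(label, 0) + 1
        if not counts:
            mapping[mid] = None
            continue
        mapping[mid] = min(
            counts, key=lambda lab: (-counts[lab], lab)
        )
    return mapping


def accuracy(cover: ModuleCover, truth: dict[str, str], net: nx.Graph) -> float:
    """AC: mean over labeled nodes of the fraction of their labeled
    neighbors whose predicted label set contains the reference label."""
    mapping = map_modules_to_labels(cover, truth)
    predicted: dict[str, set[str]] = {}
    for mid, members in cover.modules.items():
        label = mapping[mid]
        if label is None:
            continue
        for node in members:
            predicted.setdefault(node, set()).add(label)
    total, count = 0.0, 0
    for i in sorted(net.nodes()):
        if i not in truth:
            continue
        neighbors = [j for j in net.adj[i] if j in truth]
        if not neighbors:
            continue
        correct = sum(
            1 for j in neighbors if truth[j] in predicted.get(j, set())
        )
        total += correct / len(neighbors)
        count += 1
    if count == 0:
        raise ValueError("no labeled node with labeled neighbors; AC undefined")
    return total / count


def overlap_rate(cover: ModuleCover) -> float:
    """OL: sum of module sizes / number of distinct nodes (covered or
    discarded)."""
    if not cover.modules:
        raise ValueError("cover has no modules")
    n = len(cover.all_nodes())
    return sum(len(m) for m in cover.modules.values()) / n


def average_degree(cover: ModuleCover, net: nx.Graph) -> float:
    """AVD: 2 * sum of intra-module edge counts / sum of module sizes."""
    if not cover.modules:
        raise ValueError("cover has no modules")
    total_edges = 0
    total_nodes = 0
    for members in cover.modules.values():
        total_edges += sum(
            1 for u, v in net.edges(members) if u in members and v in members
        )
        total_nodes += len(members)
    return 2.0 * total_edges / total_nodes


def discard_rate(n_in: int, cover: ModuleCover) -> float:
    """1 - (distinct retained nodes) / (input node count)."""
    covered = len(cover.covered_nodes())
    if n_in < covered:
        raise ValueError(f"n_in={n_in} smaller than covered node count {covered}")
    return 1.0 - covered / n_in


def enrichment_p(n: int, n1: int, n2: int, ol: int) -> float:
    """Upper-tail cumulative hypergeometric P(X >= ol) for a size-n1 module
    drawn from a background of n genes of which n2 carry the term."""
    if not (0 <= ol <= min(n1, n2) <= n) or n1 > n:
        raise ValueError(
            f"infeasible counts: n={n}, n1={n1}, n2={n2}, ol={ol}"
        )
    p = float(hypergeom.sf(ol - 1, n, n2, n1))
    return min(1.0, max(p, 5e-324))


def cluster_frequency(ol: int, n2: int) -> float:
    """Fraction of a term's annotated genes captured by the module."""
    if n2 <= 0 or not 0 <= ol <= n2:
        raise ValueError(f"infeasible counts: ol={ol}, n2={n2}")
    return ol / n2


def enrich_modules(
    cover: ModuleCover,
    annotations: dict[str, set[str]],
    background_size: int | None = None,
    p_max: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(module, term) enrichment table.

    Keeps, per module, its best term plus every row with p <= ``p_max``.
    ``background_size`` defaults to the size of the union of all annotation
    sets and covered nodes.  The optional Bonferroni correction multiplies
    p by the number of terms before the cut (off by default; the raw cut is
    the convention followed here).
    """
    if not annotations:
        raise ValueError("annotation table is empty")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    universe: set[str] = set()
    for genes in annotations.values():
        universe |= genes
    universe |= cover.covered_nodes()
    n = background_size if background_size is not None else len(universe)
    n_terms = len(annotations)
    rows = []
    for mid in sorted(cover.modules):
        members = cover.modules[mid]
        n1 = len(members)
        best_idx, best_p = None, math.inf
        module_rows = []
        for term in sorted(annotations):
            genes = annotations[term]
            n2 = len(genes)
            ol = len(members & genes)
            if min(n1, n2) > n:
                raise ValueError(
                    f"background n={n} smaller than module/term sizes"
                )
            p = enrichment_p(n, n1, n2, ol)
            if bonferroni:
                p = min(1.0, p * n_terms)
            module_rows.append(
                {
                    "module": mid,
                    "term": term,
                    "ol": ol,
                    "n1": n1,
                    "n2": n2,
                    "n": n,
                    "p_value": p,
                    "minus_log_p": -math.log(p),
                    "cluster_frequency": cluster_frequency(ol, n2),
                    "best": False,
                }
            )
            if p < best_p:
                best_idx, best_p = len(module_rows) - 1, p
        module_rows[best_idx]["best"] = True
        rows.extend(
            r for r in module_rows if r["best"] or r["p_value"] <= p_max
        )
    return pd.DataFrame(
        rows,
        columns=[
            "module", "term", "ol", "n1", "n2", "n",
            "p_value", "minus_log_p", "cluster_frequency", "best",
        ],
    )


def degree_histogram(net: nx.Graph) -> dict[int, float]:
    """Degree -> fraction of nodes; fractions sum to 1."""
    n = net.number_of_nodes()
    hist: dict[int, float] = {}
    for _, d in net.degree():
        hist[d] = hist.get(d, 0) + 1
    return {k: c / n for k, c in sorted(hist.items())}


def evaluate(
    cover: ModuleCover,
    net: nx.Graph,
    n_in: int | None = None,
    truth: dict[str, str] | None = None,
) -> EvalReport:
    """Bundle the cover-level metrics into an :class:`EvalReport`."""
    n_in = n_in if n_in is not None else net.number_of_nodes()
    return EvalReport(
        ac=accuracy(cover, truth, net) if truth is not None else None,
        ol=overlap_rate(cover),
        avd=average_degree(cover, net),
        n_modules=len(cover.modules),
        discard_rate=discard_rate(n_in, cover),
        sizes=cover.sizes(),
        degree_hist=degree_histogram(net),
    )
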