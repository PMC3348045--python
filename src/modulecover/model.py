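"""Model/Results interface over the full identification pipeline.

:class:`OverlappingModuleModel` is built from a network plus the pipeline
settings; :meth:`~OverlappingModuleModel.fit` runs de-noising, greedy
modularity agglomeration, overlap expansion, minimum-size filtering and
hub detection, and returns an :class:`ModuleIdentificationResults` carrying
the cover, the merge trace, the hub report and diagnostics, with
``summary()``, ``evaluate()``, ``enrich()`` and ``save()`` methods.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from . import evaluation, graph_io
from .containers import (
    EdgeWeightTable,
    EvalReport,
    HubReport,
    MergeTrace,
    ModuleCover,
    cover_from_partition,
)
from .denoise import compute_edge_weights, denoise
from .hubs import hub_report
from .newman import greedy_cluster
from .overlap import expand_overlaps, filter_min_size


class OverlappingModuleModel:
    """Overlapping-module identification on an undirected simple network.

    Parameters
    ----------
    network
        Undirected simple graph (node names are opaque strings).
    denoise
        Whether to remove low-reliability edges before clustering.
    alpha
        De-noising threshold: edges with SCC <= alpha are removed.
    min_size
        Minimum retained module size (applied after overlap expansion).
    date_hub_min
        Minimum number of foreign-module contacts for a date hub.
    date_hub_candidates
        ``"all"`` (every node) or ``"discarded"`` (only nodes left in no
        retained module).
    """

    def __init__(
        self,
        network: nx.Graph,
        *,
        denoise: bool = True,
        alpha: float = 0.0,
        min_size: int = 4,
        date_hub_min: int = 3,
        date_hub_candidates: str = "all",
    ):
        if network.number_of_nodes() == 0:
            raise ValueError("network is empty")
        if any(u == v for u, v in nx.selfloop_edges(network)):
            raise ValueError("network must be simple (self-loops present)")
        if network.is_directed():
            raise ValueError("network must be undirected")
        if min_size < 1:
            raise ValueError("min_size must be >= 1")
        self.network = network.copy()
        self.denoise = denoise
        self.alpha = alpha
        self.min_size = min_size
        self.date_hub_min = date_hub_min
        self.date_hub_candidates = date_hub_candidates

    @classmethod
    def from_edgelist(cls, path, format: str = "edgelist", **kwargs):
        """Build the model straight from an edge-list or SIF file."""
        return cls(graph_io.read_network(path, format=format), **kwargs)

    def fit(self) -> "ModuleIdentificationResults":
        """Run the pipeline: de-noise, cluster, expand overlaps, filter,
        detect hubs."""
        if self.denoise:
            working, weights = denoise(self.network, self.alpha)
            if working.number_of_edges() == 0:
                raise ValueError(
                    f"de-noising with alpha={self.alpha} removed every edge"
                )
        else:
            working = self.network.copy()
            weights = compute_edge_weights(self.network)
        denoise_discarded = set(self.network.nodes()) - set(working.nodes())
        trace, partition = greedy_cluster(working)
        cover = expand_overlaps(working, partition)
        cover = filter_min_size(cover, self.min_size)
        cover.discarded |= denoise_discarded
        if not cover.modules:
            raise ValueError(
                f"no module reaches min_size={self.min_size}; "
                "lower it or relax de-noising"
            )
        report = hub_report(
            cover,
            weights,
            self.network,
            contact_net=working,
            min_contacts=self.date_hub_min,
            candidates=self.date_hub_candidates,
        )
        return ModuleIdentificationResults(
            model=self,
            working_network=working,
            edge_weights=weights,
            merge_trace=trace,
            partition=partition,
            cover=cover,
            hubs=report,
        )


class ModuleIdentificationResults:
    """Fitted pipeline outputs.

    Attributes
    ----------
    partition
        Disjoint max-modularity partition (module id -> node set).
    cover
        Final overlapping, size-filtered module cover.
    merge_trace
        Full agglomeration record; ``merge_trace.q_max`` is the cut Q.
    hubs
        Party/date hub report with nodal weights and contact counts.
    edge_weights
        SCC table of the original network's edges.
    """

    def __init__(
        self,
        model: OverlappingModuleModel,
        working_network: nx.Graph,
        edge_weights: EdgeWeightTable,
        merge_trace: MergeTrace,
        partition: dict[str, set[str]],
        cover: ModuleCover,
        hubs: HubReport,
    ):
        self.model = model
        self.network = model.network
        self.working_network = working_network
        self.edge_weights = edge_weights
        self.merge_trace = merge_trace
        self.partition = partition
        self.cover = cover
        self.hubs = hubs

    @property
    def q_max(self) -> float:
        return self.merge_trace.q_max

    @property
    def n_modules(self) -> int:
        return len(self.cover.modules)

    @property
    def overlap_nodes(self) -> set[str]:
        return self.cover.overlap_nodes()

    @property
    def party_hubs(self) -> dict[str, str]:
        return self.hubs.party

    @property
    def date_hubs(self) -> set[str]:
        return self.hubs.date

    def baseline_cover(self) -> ModuleCover:
        """The disjoint partition wrapped as a cover (no overlap stage)."""
        return cover_from_partition(self.partition)

    def evaluate(self, truth: dict[str, str] | None = None) -> EvalReport:
        """AC/OL/AVD/discard-rate report against optional reference labels."""
        return evaluation.evaluate(
            self.cover,
            self.working_network,
            n_in=self.network.number_of_nodes(),
            truth=truth,
        )

    def enrich(self, annotations, background_size=None, p_max=0.01,
               bonferroni=False):
        """Hypergeometric enrichment of every module against a flat
        term -> gene-set table; returns a DataFrame."""
        return evaluation.enrich_modules(
            self.cover, annotations,
            background_size=background_size, p_max=p_max,
            bonferroni=bonferroni,
        )

    def summary(self) -> str:
        """Human-readable run summary."""
        sizes = sorted(self.cover.sizes().values())
        mean_size = sum(sizes) / len(sizes) if sizes else 0.0
        ol = evaluation.overlap_rate(self.cover) if sizes else float("nan")
        lines = [
            "Overlapping module identification",
            "=" * 49,
            f"{'Input nodes:':<28}{self.network.number_of_nodes():>8}",
            f"{'Input edges:':<28}{self.network.number_of_edges():>8}",
            f"{'De-noising:':<28}"
            f"{('alpha=%g' % self.model.alpha) if self.model.denoise else 'off':>8}",
            f"{'Working nodes:':<28}{self.working_network.number_of_nodes():>8}",
            f"{'Working edges:':<28}{self.working_network.number_of_edges():>8}",
            f"{'Max modularity Q:':<28}{self.q_max:>8.4f}",
            f"{'Modules (>= size %d):' % self.model.min_size:<28}"
            f"{self.n_modules:>8}",
            f"{'Mean module size:':<28}{mean_size:>8.2f}",
            f"{'Overlapping rate OL:':<28}{ol:>8.4f}",
            f"{'Overlap nodes:':<28}{len(self.overlap_nodes):>8}",
            f"{'Discarded nodes:':<28}{len(self.cover.discarded):>8}",
            f"{'Party hubs:':<28}{len(self.party_hubs):>8}",
            f"{'Date hubs (>= %d contacts):' % self.hubs.date_hub_min:<28}"
            f"{len(self.date_hubs):>8}",
            "=" * 49,
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write cover, merge trace, edge weights and hub report as TSV.

        Returns the mapping of artifact name -> path.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cover": outdir / "module_cover.tsv",
            "trace": outdir / "merge_trace.tsv",
            "weights": outdir / "edge_weights.tsv",
            "hubs": outdir / "hub_report.tsv",
        }
        graph_io.write_module_cover(self.cover, paths["cover"])
        self.merge_trace.to_tsv(paths["trace"])
        self.edge_weights.to_tsv(paths["weights"])
        self.hubs.to_tsv(paths["hubs"])
        return paths
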