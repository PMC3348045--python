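"""Evaluation metrics: AC / OL / AVD / discard rate, enrichment, histogram."""

from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modulecover import (
    ModuleCover,
    accuracy,
    average_degree,
    cover_from_partition,
    degree_histogram,
    discard_rate,
    enrich_modules,
    enrichment_p,
    overlap_rate,
)
from modulecover.evaluation import cluster_frequency
from .conftest import graph_from_edges


def hypergeom_tail_oracle(n: int, n1: int, n2: int, ol: int) -> Fraction:
    """Exact upper-tail hypergeometric by combinatorial enumeration."""
    total = comb(n, n1)
    return sum(
        (Fraction(comb(n2, k) * comb(n - n2, n1 - k), total)
         for k in range(ol, min(n1, n2) + 1)),
        Fraction(0),
    )


class TestAccuracy:
    def test_perfect_prediction(self, two_triangle_bridge):
        truth = {n: "A" for n in "abc"} | {n: "B" for n in "def"}
        cover = cover_from_partition(
            {"M1": {"a", "b", "c"}, "M2": {"d", "e", "f"}})
        assert accuracy(cover, truth, two_triangle_bridge) == 1.0

    def test_all_labeled_nodes_uncovered_gives_zero(self):
        g = graph_from_edges([("a", "b"), ("e", "f")])
        truth = {"a": "X", "b": "Y"}
        cover = ModuleCover(modules={"M1": {"e", "f"}}, discarded={"a", "b"})
        assert accuracy(cover, truth, g) == 0.0

    def test_half_of_each_neighborhood_correct(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        truth = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        cover = ModuleCover(modules={"M1": {"a", "b"}}, discarded={"c", "d"})
        assert accuracy(cover, truth, g) == pytest.approx(0.5)

    def test_unlabeled_nodes_excluded_from_metric(self):
        # Connector node u carries no reference label: it neither counts as
        # a neighbor nor as a center, so the rest can still score 1.
        g = graph_from_edges(
            [("a", "b"), ("u", "a"), ("u", "c"), ("c", "d")])
        truth = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        cover = cover_from_partition(
            {"M1": {"a", "b", "u"}, "M2": {"c", "d"}})
        assert accuracy(cover, truth, g) == 1.0

    def test_overlap_node_correct_via_either_module(self):
        g = graph_from_edges([("a", "x"), ("x", "b"), ("a", "b")])
        truth = {"a": "X", "b": "Y", "x": "Y"}
        cover = ModuleCover(modules={"M1": {"a", "x"}, "M2": {"b", "x"}})
        assert accuracy(cover, truth, g) == 1.0

    def test_no_labeled_neighbors_errors(self, triangle):
        cover = cover_from_partition({"M": {"a", "b", "c"}})
        with pytest.raises(ValueError):
            accuracy(cover, {}, triangle)


class TestCoverMetrics:
    def test_disjoint_full_cover_rate_is_one(self):
        cover = cover_from_partition({"M1": {"a", "b"}, "M2": {"c"}})
        assert overlap_rate(cover) == 1.0

    def test_one_duplicated_node(self):
        modules = {"M1": set("abcde"), "M2": set("fghij") | {"a"}}
        cover = ModuleCover(modules=modules)
        assert overlap_rate(cover) == pytest.approx(1.1)

    def test_empty_cover_errors(self):
        with pytest.raises(ValueError):
            overlap_rate(ModuleCover(modules={}))

    def test_average_degree_triangle(self, triangle):
        cover = cover_from_partition({"M": {"a", "b", "c"}})
        assert average_degree(cover, triangle) == pytest.approx(2.0)

    def test_average_degree_path(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        cover = cover_from_partition({"M": {"a", "b", "c"}})
        assert average_degree(cover, g) == pytest.approx(4 / 3)

    def test_average_degree_mixed_modules(self):
        g = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e")])
        cover = cover_from_partition({"M1": {"a", "b", "c"}, "M2": {"d", "e"}})
        assert average_degree(cover, g) == pytest.approx(1.6)

    def test_discard_rate(self):
        cover = ModuleCover(modules={"M": set(map(str, range(60)))})
        assert discard_rate(100, cover) == pytest.approx(0.4)
        assert discard_rate(60, cover) == 0.0
        with pytest.raises(ValueError):
            discard_rate(10, cover)


class TestEnrichment:
    def test_fully_enriched_small_case(self):
        # All 5 annotated genes drawn into a 5-member module from n = 10.
        assert enrichment_p(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_tail_is_one(self):
        assert enrichment_p(100, 10, 10, 0) == 1.0

    def test_module_equal_to_background(self):
        assert enrichment_p(10, 10, 4, 4) == pytest.approx(1.0)

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError):
            enrichment_p(10, 5, 5, 6)
        with pytest.raises(ValueError):
            enrichment_p(10, 12, 5, 3)

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.integers(2, 20),
        data=st.data(),
    )
    def test_matches_exact_enumeration(self, n, data):
        n1 = data.draw(st.integers(0, n))
        n2 = data.draw(st.integers(0, n))
        ol = data.draw(st.integers(0, min(n1, n2)))
        expected = float(hypergeom_tail_oracle(n, n1, n2, ol))
        assert enrichment_p(n, n1, n2, ol) == pytest.approx(
            max(expected, 5e-324), abs=1e-12)

    def test_monotone_nonincreasing_in_overlap(self):
        values = [enrichment_p(50, 12, 9, ol) for ol in range(10)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_cluster_frequency(self):
        assert cluster_frequency(3, 6) == pytest.approx(0.5)

    def test_enrich_modules_filters_and_keeps_best(self):
        cover = ModuleCover(modules={"M1": {"g1", "g2", "g3", "g4", "g5"}})
        annotations = {
            "T_hit": {"g1", "g2", "g3", "g4", "g5"},
            "T_miss": {f"x{i}" for i in range(20)},
        }
        table = enrich_modules(cover, annotations, background_size=1000)
        hit = table[table.term == "T_hit"].iloc[0]
        assert hit.p_value < 1e-10 and bool(hit.best)
        assert hit.cluster_frequency == 1.0
        assert "T_miss" not in set(table[~table.best].term)

    def test_empty_annotations_error(self):
        cover = ModuleCover(modules={"M1": {"a"}})
        with pytest.raises(ValueError):
            enrich_modules(cover, {})


class TestDegreeHistogram:
    def test_triangle(self, triangle):
        assert degree_histogram(triangle) == {2: 1.0}

    def test_star(self):
        g = graph_from_edges([("c", "a"), ("c", "b"), ("c", "d")])
        assert degree_histogram(g) == {1: 0.75, 3: 0.25}

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_fractions_sum_to_one(self, seed):
        import networkx as nx
        g = nx.gnp_random_graph(15, 0.3, seed=seed)
        assert sum(degree_histogram(g).values()) == pytest.approx(1.0)
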