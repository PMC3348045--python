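"""Overlap expansion and size filtering."""

import pytest

from modulecover import (
    ModuleCover,
    candidate_nodes,
    cover_from_partition,
    expand_overlaps,
    filter_min_size,
    module_modularity,
)
from .conftest import graph_from_edges


@pytest.fixture
def four_triangles_with_straddler():
    """Four triangles plus node x wired 2-and-2 into the first two.

    m = 16.  Copying x into B = {b1,b2,b3}: Q_B = 3/16 - (8/32)^2 = 1/8,
    Q_{B+x} = 5/16 - (12/32)^2 = 11/64 > 1/8, so x overlaps A and B.
    """
    edges = []
    for p in "abcd":
        edges += [(f"{p}1", f"{p}2"), (f"{p}2", f"{p}3"), (f"{p}1", f"{p}3")]
    edges += [("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2")]
    g = graph_from_edges(edges)
    partition = {
        "A": {"a1", "a2", "a3", "x"},
        "B": {"b1", "b2", "b3"},
        "C": {"c1", "c2", "c3"},
        "D": {"d1", "d2", "d3"},
    }
    return g, partition


class TestCandidateNodes:
    def test_disjoint_triangles_have_no_candidates(self):
        g = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("x", "y"), ("y", "z"), ("x", "z")])
        p = {"A": {"a", "b", "c"}, "B": {"x", "y", "z"}}
        assert candidate_nodes(g, p) == set()

    def test_bridge_endpoints_are_candidates(self, two_triangle_bridge):
        p = {"A": {"a", "b", "c"}, "B": {"d", "e", "f"}}
        assert candidate_nodes(two_triangle_bridge, p) == {"c", "d"}

    def test_single_module_has_no_candidates(self, triangle):
        assert candidate_nodes(triangle, {"A": {"a", "b", "c"}}) == set()


class TestModuleModularity:
    def test_triangle_module_of_bridge_graph(self, two_triangle_bridge):
        cover = cover_from_partition(
            {"A": {"a", "b", "c"}, "B": {"d", "e", "f"}})
        assert module_modularity(two_triangle_bridge, cover, "A") == \
            pytest.approx(5 / 28)

    def test_whole_network_as_single_module_is_zero(self, two_triangle_bridge):
        cover = cover_from_partition({"A": set(two_triangle_bridge.nodes())})
        assert module_modularity(two_triangle_bridge, cover, "A") == \
            pytest.approx(0.0)

    def test_adding_unconnected_node_decreases_q(self, two_triangle_bridge):
        cover = cover_from_partition(
            {"A": {"a", "b", "c"}, "B": {"d", "e", "f"}})
        before = module_modularity(two_triangle_bridge, cover, "A")
        cover.modules["A"].add("f")  # f has no edge into {a,b,c}
        assert module_modularity(two_triangle_bridge, cover, "A") < before

    def test_unknown_module_errors(self, triangle):
        cover = cover_from_partition({"A": {"a", "b", "c"}})
        with pytest.raises(KeyError):
            module_modularity(triangle, cover, "Z")


class TestExpandOverlaps:
    def test_disjoint_cliques_unchanged(self):
        g = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("x", "y"), ("y", "z"), ("x", "z")])
        p = {"A": {"a", "b", "c"}, "B": {"x", "y", "z"}}
        cover = expand_overlaps(g, p)
        assert cover.modules == p
        assert cover.overlap_nodes() == set()

    def test_bridge_endpoints_not_copied(self, two_triangle_bridge):
        # Copying c into {d,e,f}: Q drops from 5/28 to 4/7 - (10/14)^2 =
        # 3/49, so the strict inequality rejects the copy.
        p = {"A": {"a", "b", "c"}, "B": {"d", "e", "f"}}
        cover = expand_overlaps(two_triangle_bridge, p)
        assert cover.overlap_nodes() == set()

    def test_straddler_copied_into_second_module(self, four_triangles_with_straddler):
        g, partition = four_triangles_with_straddler
        cover = expand_overlaps(g, partition)
        assert cover.membership("x") == {"A", "B"}
        assert cover.overlap_nodes() == {"x"}
        # Each accepted copy strictly increased its target's modularity.
        for node, mid, q_before, q_after in cover.expansion_log:
            assert q_after > q_before
        (node, mid, q_before, q_after), = cover.expansion_log
        assert (node, mid) == ("x", "B")
        assert q_before == pytest.approx(1 / 8)
        assert q_after == pytest.approx(11 / 64)

    def test_primary_assignment_preserved(self, four_triangles_with_straddler):
        g, partition = four_triangles_with_straddler
        cover = expand_overlaps(g, partition)
        for mid, members in partition.items():
            assert members <= cover.modules[mid]
            for node in members:
                assert cover.primary[node] == mid

    def test_deterministic(self, four_triangles_with_straddler):
        g, partition = four_triangles_with_straddler
        c1 = expand_overlaps(g, partition)
        c2 = expand_overlaps(g, partition)
        assert c1.modules == c2.modules
        assert c1.expansion_log == c2.expansion_log


class TestFilterMinSize:
    def test_small_module_discarded(self):
        cover = ModuleCover(
            modules={"M1": {"a", "b", "c", "d", "e"}, "M2": {"x", "y"}},
            primary={n: "M1" for n in "abcde"} | {"x": "M2", "y": "M2"},
        )
        out = filter_min_size(cover, 4)
        assert set(out.modules) == {"M1"}
        assert out.discarded == {"x", "y"}

    def test_min_size_one_is_identity(self):
        cover = ModuleCover(modules={"M1": {"a"}, "M2": {"b", "c"}})
        out = filter_min_size(cover, 1)
        assert out.modules == cover.modules

    def test_overlap_node_survives_via_larger_module(self):
        cover = ModuleCover(
            modules={"M1": {"a", "b", "c", "d", "x"}, "M2": {"x", "y"}},
            primary={"x": "M2", "y": "M2"}
            | {n: "M1" for n in "abcd"},
        )
        out = filter_min_size(cover, 4)
        assert "x" in out.modules["M1"]
        assert "x" not in out.discarded
        assert out.primary["x"] == "M1"  # remapped off the deleted module
        assert out.discarded == {"y"}

    def test_invalid_min_size(self):
        with pytest.raises(ValueError):
            filter_min_size(ModuleCover(modules={}), 0)
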