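import math
import random
from fractions import Fraction
from itertools import combinations

import networkx as nx
import pytest

import netdyad as nd
from netdyad.core import DegenerateMetricError

from conftest import annotate


def brute_force_counts(graph, flagged):
    """Independent dyad recount straight off the edge list."""
    flagged = set(flagged)
    m11 = sum(1 for u, v in graph.edges if u in flagged and v in flagged)
    m00 = sum(1 for u, v in graph.edges if u not in flagged and v not in flagged)
    return m11, graph.number_of_edges() - m11 - m00, m00


class TestCountDyads:
    def test_all_flagged_triangle(self, triangle):
        counts = nd.count_dyads(triangle, annotate(triangle, "abc"))
        assert (counts.m11, counts.m10, counts.m00) == (3, 0, 0)

    def test_path_center_flagged(self):
        g = nx.path_graph(["a", "b", "c"])
        counts = nd.count_dyads(g, annotate(g, {"b"}))
        assert (counts.m11, counts.m10, counts.m00) == (0, 2, 0)

    def test_toy_fixture_counts(self, toy):
        g, ann = toy
        counts = nd.count_dyads(g, ann)
        assert (counts.m11, counts.m10, counts.m00) == (6, 37, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_recount_and_sums_to_m(self, seed):
        rng = random.Random(seed)
        g = nx.gnm_random_graph(12, 20, seed=rng)
        flagged = rng.sample(sorted(g.nodes), rng.randint(0, 12))
        counts = nd.count_dyads(g, annotate(g, flagged))
        assert (counts.m11, counts.m10, counts.m00) == brute_force_counts(g, flagged)
        assert counts.m == g.number_of_edges()

    def test_complement_swaps_m11_m00(self, toy):
        g, ann = toy
        counts = nd.count_dyads(g, ann)
        flipped = nd.BinaryAnnotation("flip", {v: 1 - c for v, c in ann.labels.items()})
        assert nd.count_dyads(g, flipped) == counts.complement()


class TestExpectedCounts:
    def test_density_and_expectations_n25_m32(self):
        exp = nd.expected_counts(25, 32, 5)
        assert exp.delta == Fraction(64, 600)
        assert exp.m11_bar == 10 * Fraction(64, 600)
        assert exp.m10_bar == 100 * Fraction(64, 600)
        assert float(exp.m11_bar) == pytest.approx(1.0667, abs=1e-4)
        assert float(exp.m10_bar) == pytest.approx(10.667, abs=1e-3)

    def test_no_flagged_nodes(self):
        exp = nd.expected_counts(10, 12, 0)
        assert exp.m11_bar == 0 and exp.m10_bar == 0

    def test_triangle_expectation_equals_enumeration_mean(self, triangle):
        exp = nd.expected_counts(3, 3, 2)
        dmap = nd.enumerate_configurations(triangle, 2)
        assert dmap.mean_m11() == exp.m11_bar == 1
        assert dmap.mean_m10() == exp.m10_bar == 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nd.expected_counts(1, 0, 0)
        with pytest.raises(ValueError):
            nd.expected_counts(5, 11, 2)
        with pytest.raises(ValueError):
            nd.expected_counts(5, 3, 6)


class TestDyadBounds:
    def test_complete_triangle_tight(self):
        b = nd.dyad_bounds([2, 2, 2], 2)
        assert (b.m11_lower, b.m11_upper) == (1, 1)
        assert (b.m10_lower, b.m10_upper) == (2, 2)

    def test_star_bounds_contain_realizable_values(self, star):
        b = nd.dyad_bounds([4, 1, 1, 1, 1], 2)
        assert (b.m11_lower, b.m11_upper) == (0, 1)
        assert (b.m10_lower, b.m10_upper) == (1, 4)
        realized = {
            brute_force_counts(star, pair)[:2]
            for pair in combinations(star.nodes, 2)
        }
        assert {m11 for m11, _ in realized} == {0, 1}
        assert {m10 for _, m10 in realized} == {2, 3}

    def test_n1_zero_gives_zero_m10_lower(self):
        b = nd.dyad_bounds([2, 2, 1, 1], 0)
        assert b.m10_lower == 0 and b.m10_upper == 0

    def test_disconnected_graph_relaxes_m10_floor(self):
        # two disjoint edges: both flags can sit on one component
        b = nd.dyad_bounds([1, 1, 1, 1], 2, connected=False)
        assert b.m10_lower == 0
        assert nd.dyad_bounds([1, 1, 1, 1], 2, connected=True).m10_lower == 1

    def test_odd_degree_sum_rejected(self):
        with pytest.raises(ValueError, match="even"):
            nd.dyad_bounds([3, 1, 1], 2)

    def test_m_inconsistent_with_degrees_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            nd.dyad_bounds([2, 2, 2], 2, m=5)

    @pytest.mark.parametrize("seed", range(8))
    def test_enumeration_extremes_within_bounds(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 9)
        m = rng.randint(n - 1, math.comb(n, 2))
        g = nx.gnm_random_graph(n, m, seed=rng)
        connected = nx.is_connected(g)
        degs = [d for _, d in g.degree()]
        for n1 in range(n + 1):
            b = nd.dyad_bounds(degs, n1, m, connected=connected)
            for subset in combinations(g.nodes, n1):
                m11, m10, _ = brute_force_counts(g, subset)
                assert b.m11_lower <= m11 <= b.m11_upper
                assert b.m10_lower <= m10 <= b.m10_upper


class TestM00Bounds:
    def test_triangle_unflagged_pair_always_adjacent(self):
        assert nd.m00_bounds([2, 2, 2], 1) == (1, 1)

    def test_all_flagged_leaves_no_m00(self):
        assert nd.m00_bounds([2, 2, 2], 3) == (0, 0)

    def test_role_swap_identity_on_star(self):
        swapped = nd.dyad_bounds([4, 1, 1, 1, 1], 3)
        assert nd.m00_bounds([4, 1, 1, 1, 1], 2) == (
            swapped.m11_lower, swapped.m11_upper,
        )


class TestDyadicityHeterophilicity:
    def test_toy_values(self):
        metrics = nd.dyadicity_heterophilicity(
            nd.DyadCounts(6, 37, 2), nd.expected_counts(43, 45, 4)
        )
        assert metrics.D == pytest.approx(20.07, abs=0.005)
        assert metrics.H == pytest.approx(4.76, abs=0.005)

    def test_observed_equal_expected_is_one(self):
        metrics = nd.dyadicity_heterophilicity(
            nd.DyadCounts(1, 2, 0), nd.expected_counts(3, 3, 2)
        )
        assert metrics.D == 1.0 and metrics.H == 1.0

    def test_identity_with_expectations(self):
        counts = nd.DyadCounts(4, 11, 9)
        exp = nd.expected_counts(12, 24, 5)
        metrics = nd.dyadicity_heterophilicity(counts, exp)
        assert metrics.D * float(exp.m11_bar) == pytest.approx(counts.m11)
        assert metrics.H * float(exp.m10_bar) == pytest.approx(counts.m10)

    @pytest.mark.parametrize("n1", [0, 1])
    def test_degenerate_expectation_raises(self, n1):
        with pytest.raises(DegenerateMetricError):
            nd.dyadicity_heterophilicity(
                nd.DyadCounts(0, 0, 3), nd.expected_counts(3, 3, n1)
            )


class TestBinaryAssortativity:
    def test_perfectly_assortative(self):
        assert nd.binary_assortativity(nd.DyadCounts(3, 0, 3)) == 1.0

    def test_perfectly_disassortative(self):
        assert nd.binary_assortativity(nd.DyadCounts(0, 4, 0)) == -1.0

    def test_toy_counts(self):
        r = nd.binary_assortativity(nd.DyadCounts(6, 37, 2), m=45)
        assert r == pytest.approx(-0.658, abs=0.001)

    def test_matches_networkx_on_random_graph(self):
        rng = random.Random(3)
        g = nx.gnm_random_graph(15, 30, seed=rng)
        flagged = set(rng.sample(sorted(g.nodes), 6))
        nx.set_node_attributes(g, {v: int(v in flagged) for v in g.nodes}, "c")
        ours = nd.binary_assortativity(nd.count_dyads(g, annotate(g, flagged)))
        assert ours == pytest.approx(nx.attribute_assortativity_coefficient(g, "c"))

    def test_concentrated_mixing_undefined(self):
        with pytest.raises(DegenerateMetricError):
            nd.binary_assortativity(nd.DyadCounts(5, 0, 0))
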