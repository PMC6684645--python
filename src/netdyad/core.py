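"""Dyad counting, random-assignment expectations, degree-sequence bounds,
dyadicity/heterophilicity and binary assortativity.

A *dyad* is an edge typed by its endpoints' binary labels: (1-1), (1-0) or
(0-0), with counts ``m11 + m10 + m00 = m``. Under uniformly random placement
of the ``n1`` flagged labels the expected counts are

    m11_bar = C(n1, 2) * delta        m10_bar = n1 * (n - n1) * delta

with density ``delta = 2m / (n (n-1))``. Dyadicity ``D = m11 / m11_bar`` and
heterophilicity ``H = m10 / m10_bar`` measure the departure of the observed
configuration from random. Independently of any enumeration, ``m11`` and
``m10`` are confined to ranges computable from the degree sequence alone;
those extremal bounds are what makes the relevance geometry tractable on
large networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import networkx as nx

from .io import BinaryAnnotation, validate_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "DyadCounts",
    "ExpectedCounts",
    "DyadBounds",
    "HDMetrics",
    "DegenerateMetricError",
    "count_dyads",
    "expected_counts",
    "dyad_bounds",
    "m00_bounds",
    "bounds_for",
    "dyadicity_heterophilicity",
    "binary_assortativity",
]


class DegenerateMetricError(ValueError):
    """A metric whose defining expectation (or denominator) is zero."""


@dataclass(frozen=True)
class DyadCounts:
    """Observed dyad counts; ``m`` is their total (the edge count)."""

    m11: int
    m10: int
    m00: int

    def __post_init__(self) -> None:
        if min(self.m11, self.m10, self.m00) < 0:
            raise ValueError("dyad counts must be non-negative")

    @property
    def m(self) -> int:
        return self.m11 + self.m10 + self.m00

    def complement(self) -> "DyadCounts":
        """Counts after relabeling 1 <-> 0 (swaps m11 and m00)."""
        return DyadCounts(self.m00, self.m10, self.m11)


@dataclass(frozen=True)
class ExpectedCounts:
    """Exact rational density and expected dyad counts under random labels."""

    delta: Fraction
    m11_bar: Fraction
    m10_bar: Fraction


@dataclass(frozen=True)
class DyadBounds:
    """Degree-sequence bounds on m11 and m10 (inclusive integer ranges)."""

    m11_lower: int
    m11_upper: int
    m10_lower: int
    m10_upper: int

    def __post_init__(self) -> None:
        if not (0 <= self.m11_lower <= self.m11_upper):
            raise ValueError("inconsistent m11 bounds")
        if not (0 <= self.m10_lower <= self.m10_upper):
            raise ValueError("inconsistent m10 bounds")


@dataclass(frozen=True)
class HDMetrics:
    D: float
    H: float


def count_dyads(graph: nx.Graph, annotation: BinaryAnnotation) -> DyadCounts:
    """Count (1-1), (1-0) and (0-0) edges with one pass over the edge set."""
    annotation = validate_annotation(graph, annotation)
    labels = annotation.labels
    m11 = m10 = m00 = 0
    for u, v in graph.edges():
        s = labels[u] + labels[v]
        if s == 2:
            m11 += 1
        elif s == 1:
            m10 += 1
        else:
            m00 += 1
    return DyadCounts(m11, m10, m00)


def expected_counts(n: int, m: int, n1: int) -> ExpectedCounts:
    """Expected dyad counts under uniformly random placement of n1 flags.

    Exact rationals: ``delta = 2m/(n(n-1))``, ``m11_bar = C(n1,2) delta``,
    ``m10_bar = n1 (n-n1) delta``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 <= n1 <= n:
        raise ValueError("n1 must lie in [0, n]")
    if not 0 <= m <= math.comb(n, 2):
        raise ValueError("m must lie in [0, C(n,2)]")
    delta = Fraction(2 * m, n * (n - 1))
    return ExpectedCounts(
        delta=delta,
        m11_bar=math.comb(n1, 2) * delta,
        m10_bar=n1 * (n - n1) * delta,
    )


def _check_degree_sequence(degree_sequence: Sequence[int], m: int | None) -> tuple[list[int], int]:
    degs = sorted(degree_sequence, reverse=True)
    if not degs:
        raise ValueError("empty degree sequence")
    if any(d < 0 for d in degs):
        raise ValueError("degrees must be non-negative")
    total = sum(degs)
    if total % 2:
        raise ValueError("degree sum must be even")
    if m is None:
        m = total // 2
    elif 2 * m != total:
        raise ValueError(f"degree sum {total} inconsistent with m={m}")
    return degs, m


def dyad_bounds(
    degree_sequence: Sequence[int],
    n1: int,
    m: int | None = None,
    connected: bool = True,
) -> DyadBounds:
    """Extremal bounds on m11 and m10 from the degree sequence.

    With the degree sequence sorted non-increasing, head(k) denotes its k
    largest entries and tail(k) its k smallest (head(k) and tail(n-k)
    partition the sequence). The bounds:

    * m11 upper: min of m, the n1-clique size C(n1,2), and the edge capacity
      of the n1 highest-degree nodes, ceil(sum over head(n1) of
      min(d_i, n1-1) / 2).
    * m10 upper: min of m, the complete-bipartite count n1*n0, and the lesser
      of the two cross-capacity sums (head(n1) capped at n0, head(n0) capped
      at n1).
    * m11 lower: max(0, floor((sum tail(n1) - sum head(n0)) / 2)) — edges the
      n1 lowest-degree nodes cannot avoid spending on each other.
    * m10 lower: 0 when n1 is 0 or n; otherwise max(1, sum tail(n1) -
      n1(n1-1)) for a connected graph, which always has at least one
      cross edge. For disconnected input the floor of 1 does not apply and
      0 is substituted.
    """
    degs, m = _check_degree_sequence(degree_sequence, m)
    n = len(degs)
    if not 0 <= n1 <= n:
        raise ValueError("n1 must lie in [0, n]")
    n0 = n - n1

    def head(k: int) -> list[int]:
        return degs[:k]

    def tail(k: int) -> list[int]:
        return degs[n - k:] if k else []

    m11_upper = min(
        m,
        math.comb(n1, 2),
        math.ceil(sum(min(d, n1 - 1) for d in head(n1)) / 2) if n1 else 0,
    )
    m10_upper = min(
        m,
        n1 * n0,
        min(
            sum(min(d, n0) for d in head(n1)),
            sum(min(d, n1) for d in head(n0)),
        ),
    )
    m11_lower = max(0, (sum(tail(n1)) - sum(head(n0))) // 2)
    if n1 in (0, n):
        m10_lower = 0
    else:
        floor = 1 if connected else 0
        m10_lower = max(floor, sum(tail(n1)) - n1 * (n1 - 1))
        if not connected and m10_lower == 0:
            logger.debug("disconnected graph: m10 lower bound relaxed to 0")
    return DyadBounds(m11_lower, m11_upper, m10_lower, m10_upper)


def m00_bounds(
    degree_sequence: Sequence[int],
    n1: int,
    m: int | None = None,
    connected: bool = True,
) -> tuple[int, int]:
    """Bounds on m00, by the 1 <-> 0 role swap: the m11 bounds at n1 -> n0."""
    n = len(degree_sequence)
    swapped = dyad_bounds(degree_sequence, n - n1, m, connected)
    return swapped.m11_lower, swapped.m11_upper


def bounds_for(graph: nx.Graph, n1: int) -> DyadBounds:
    """Convenience: dyad bounds of a graph, detecting connectivity."""
    degs = [d for _, d in graph.degree()]
    connected = graph.number_of_nodes() > 0 and nx.is_connected(graph)
    return dyad_bounds(degs, n1, graph.number_of_edges(), connected=connected)


def dyadicity_heterophilicity(counts: DyadCounts, expected: ExpectedCounts) -> HDMetrics:
    """D = m11 / m11_bar and H = m10 / m10_bar.

    Undefined when the corresponding expectation vanishes (n1 <= 1 for D,
    n1 in {0, n} for H).
    """
    if expected.m11_bar == 0:
        raise DegenerateMetricError("dyadicity undefined: expected m11 is zero (n1 <= 1)")
    if expected.m10_bar == 0:
        raise DegenerateMetricError("heterophilicity undefined: expected m10 is zero (n1 in {0, n})")
    return HDMetrics(
        D=float(Fraction(counts.m11) / expected.m11_bar),
        H=float(Fraction(counts.m10) / expected.m10_bar),
    )


def binary_assortativity(counts: DyadCounts, m: int | None = None) -> float:
    """Newman's categorical assortativity of the binary labels across edges.

    Built from the 2x2 edge-mixing matrix e with e11 = m11/m, e00 = m00/m and
    e10 = e01 = m10/(2m); with marginals a_i the coefficient is
    ``r = (sum_i e_ii - sum_i a_i^2) / (1 - sum_i a_i^2)``, in [-1, 1].
    """
    if m is None:
        m = counts.m
    elif m != counts.m:
        raise ValueError(f"m={m} inconsistent with counts totalling {counts.m}")
    if m == 0:
        raise DegenerateMetricError("assortativity undefined on an empty edge set")
    e11 = Fraction(counts.m11, m)
    e00 = Fraction(counts.m00, m)
    e10 = Fraction(counts.m10, 2 * m)
    a1 = e11 + e10
    a0 = e00 + e10
    trace = e11 + e00
    sq = a1 * a1 + a0 * a0
    if sq == 1:
        raise DegenerateMetricError(
            "assortativity undefined: mixing matrix fully concentrated"
        )
    return float((trace - sq) / (1 - sq))
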