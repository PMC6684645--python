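"""Exact enumeration of label assignments: the (m10, m11) degeneracy map.

For a fixed graph and n1, every one of the C(n, n1) placements of the
flagged labels yields a dyad-count pair (m10, m11); the *degeneracy* of a
pair is the number of placements producing it. The resulting map is the
phase diagram of the configuration space: highly degenerate cells sit near
the expected counts and are the "typical" configurations, while the sparse
boundary cells are the atypical — hence significant — ones.

Enumeration is exponential in n (C(n, n/2) ~ 2^n), so it is only feasible
for small networks; here it serves as the exact oracle against which the
closed-form bounds, expectations and Monte-Carlo p-values are verified.
A hard cap refuses oversized requests rather than silently truncating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import networkx as nx

from . import core

__all__ = [
    "DegeneracyMap",
    "EnumerationCapError",
    "VerificationReport",
    "enumeration_size",
    "enumerate_configurations",
    "verify_against_bounds",
    "write_degeneracy",
]

DEFAULT_CAP = 2_000_000


class EnumerationCapError(ValueError):
    """Requested enumeration exceeds the configured subset cap."""


@dataclass(frozen=True)
class DegeneracyMap:
    """Multiplicity of every realizable (m10, m11) pair for a fixed n1."""

    entries: dict[tuple[int, int], int]
    n1: int

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def mean_m11(self) -> Fraction:
        return Fraction(
            sum(m11 * k for (_, m11), k in self.entries.items()), self.total
        )

    def mean_m10(self) -> Fraction:
        return Fraction(
            sum(m10 * k for (m10, _), k in self.entries.items()), self.total
        )


@dataclass
class VerificationReport:
    """Outcome of checking a degeneracy map against bounds and expectations."""

    ok: bool
    failures: list[str] = field(default_factory=list)


def enumeration_size(n: int, n1: int) -> int:
    """Number of assignments to enumerate: the binomial coefficient C(n, n1)."""
    if not 0 <= n1 <= n:
        raise ValueError("n1 must lie in [0, n]")
    return math.comb(n, n1)


def enumerate_configurations(
    graph: nx.Graph, n1: int, cap: int = DEFAULT_CAP
) -> DegeneracyMap:
    """Count dyads for every n1-subset of the nodes, in lexicographic order.

    Refuses (reporting the exact count and the cap) when C(n, n1) exceeds
    *cap*. For each subset S, m11 is the number of edges inside S and
    m10 = (degree sum over S) - 2 m11.
    """
    n = graph.number_of_nodes()
    size = enumeration_size(n, n1)
    if size > cap:
        raise EnumerationCapError(
            f"C({n}, {n1}) = {size} assignments exceed the cap of {cap}"
        )
    nodes = sorted(graph.nodes, key=str)
    adj = {v: set(graph.neighbors(v)) for v in nodes}
    deg = dict(graph.degree())
    entries: dict[tuple[int, int], int] = {}
    for subset in combinations(nodes, n1):
        m11 = sum(1 for u, v in combinations(subset, 2) if v in adj[u])
        m10 = sum(deg[v] for v in subset) - 2 * m11
        key = (m10, m11)
        entries[key] = entries.get(key, 0) + 1
    return DegeneracyMap(entries=entries, n1=n1)


def verify_against_bounds(
    dmap: DegeneracyMap,
    bounds: core.DyadBounds,
    expected: core.ExpectedCounts,
) -> VerificationReport:
    """Check the enumerated map against the closed-form bounds/expectations.

    Asserts that every realizable (m10, m11) lies inside the bounds
    rectangle and that the multiplicity-weighted means equal the expected
    counts exactly (rational arithmetic).
    """
    failures: list[str] = []
    for (m10, m11) in dmap.entries:
        if not bounds.m11_lower <= m11 <= bounds.m11_upper:
            failures.append(
                f"m11={m11} outside [{bounds.m11_lower}, {bounds.m11_upper}] at (m10={m10}, m11={m11})"
            )
        if not bounds.m10_lower <= m10 <= bounds.m10_upper:
            failures.append(
                f"m10={m10} outside [{bounds.m10_lower}, {bounds.m10_upper}] at (m10={m10}, m11={m11})"
            )
    if dmap.mean_m11() != expected.m11_bar:
        failures.append(
            f"mean m11 {dmap.mean_m11()} != expected {expected.m11_bar}"
        )
    if dmap.mean_m10() != expected.m10_bar:
        failures.append(
            f"mean m10 {dmap.mean_m10()} != expected {expected.m10_bar}"
        )
    return VerificationReport(ok=not failures, failures=failures)


def write_degeneracy(
    dmap: DegeneracyMap,
    path,
    bounds: core.DyadBounds | None = None,
    expected: core.ExpectedCounts | None = None,
    delimiter: str = "\t",
) -> None:
    """Export the map as (m10, m11, count) rows for external heatmap plotting.

    Optional header comments carry the bounds rectangle and expected point.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# n1={dmap.n1} total={dmap.total}\n")
        if bounds is not None:
            fh.write(
                f"# bounds m10=[{bounds.m10_lower},{bounds.m10_upper}] "
                f"m11=[{bounds.m11_lower},{bounds.m11_upper}]\n"
            )
        if expected is not None:
            fh.write(
                f"# expected m10={float(expected.m10_bar):.6g} "
                f"m11={float(expected.m11_bar):.6g}\n"
            )
        fh.write(delimiter.join(["m10", "m11", "count"]) + "\n")
        for (m10, m11), k in sorted(dmap.entries.items()):
            fh.write(delimiter.join(map(str, (m10, m11, k))) + "\n")
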