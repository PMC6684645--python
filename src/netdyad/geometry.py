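"""Geometry of the H-D space: bounded rectangle, quadrant regions around the
pivot (1, 1), and the normalized-projection relevance score.

Dividing the combinatorial bounds on (m10, m11) by the random-assignment
expectations maps them into heterophilicity/dyadicity coordinates, giving a
rectangle [Hmin, Hmax] x [Dmin, Dmax] that always contains the pivot
H = D = 1. The four quadrants around the pivot are

    I   heterophobic-dyadic      (H < 1, D > 1)
    II  heterophilic-dyadic      (H > 1, D > 1)
    III heterophilic-antidyadic  (H > 1, D < 1)
    IV  heterophobic-antidyadic  (H < 1, D < 1)

An observed configuration v = (H - 1, D - 1) is scored against the diagonal
u of its own region — the vector from the pivot to the region's corner, the
longest realizable displacement there — by projecting v onto u and dividing
by the diagonal's length: r = (v . u) / (u . u), in [0, 1]. Because every
attribute is normalized within its own feasible region, scores for metadata
with different n1 (hence different rectangles) are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable

import networkx as nx
import numpy as np

from . import core
from .io import BinaryAnnotation, validate_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "HDSpace",
    "RelevanceResult",
    "DegenerateSpaceError",
    "hd_space",
    "classify_region",
    "region_diagonal",
    "relevance",
    "annotation_eligible",
    "score_annotation",
    "rank_metadata",
]

_TOL = 1e-9


class DegenerateSpaceError(ValueError):
    """An H-D space that cannot be built (zero expectation)."""


class Region(Enum):
    I = "heterophobic-dyadic"
    II = "heterophilic-dyadic"
    III = "heterophilic-antidyadic"
    IV = "heterophobic-antidyadic"
    PIVOT = "pivot"


@dataclass(frozen=True)
class HDSpace:
    """The rectangle [h_min, h_max] x [d_min, d_max] with pivot (1, 1)."""

    h_min: float
    h_max: float
    d_min: float
    d_max: float

    def contains(self, H: float, D: float, tol: float = 1e-6) -> bool:
        return (
            self.h_min - tol <= H <= self.h_max + tol
            and self.d_min - tol <= D <= self.d_max + tol
        )

    def corner(self, region: Region) -> tuple[float, float]:
        """(H, D) corner of a quadrant: the region's extremal configuration."""
        if region is Region.I:
            return self.h_min, self.d_max
        if region is Region.II:
            return self.h_max, self.d_max
        if region is Region.III:
            return self.h_max, self.d_min
        if region is Region.IV:
            return self.h_min, self.d_min
        raise ValueError("the pivot has no corner")


@dataclass(frozen=True)
class RelevanceResult:
    """Relevance of one binary attribute on one graph."""

    name: str
    n1: int
    D: float
    H: float
    region: Region
    r: float


def hd_space(bounds: core.DyadBounds, expected: core.ExpectedCounts) -> HDSpace:
    """Map dyad-count bounds into H-D coordinates by dividing by expectations."""
    if expected.m11_bar == 0 or expected.m10_bar == 0:
        raise DegenerateSpaceError(
            "H-D space undefined: an expected dyad count is zero"
        )
    return HDSpace(
        h_min=float(Fraction(bounds.m10_lower) / expected.m10_bar),
        h_max=float(Fraction(bounds.m10_upper) / expected.m10_bar),
        d_min=float(Fraction(bounds.m11_lower) / expected.m11_bar),
        d_max=float(Fraction(bounds.m11_upper) / expected.m11_bar),
    )


def classify_region(H: float, D: float) -> Region:
    """Quadrant of (H, D) around the pivot.

    Boundary convention: H = 1 joins the heterophilic side (II/III), D = 1
    joins the dyadic side (I/II); exactly (1, 1) is the pivot.
    """
    if H < 0 or D < 0:
        raise ValueError("H and D must be non-negative")
    if H == 1 and D == 1:
        return Region.PIVOT
    dyadic = D >= 1
    heterophilic = H >= 1
    if dyadic and not heterophilic:
        return Region.I
    if dyadic and heterophilic:
        return Region.II
    if heterophilic:
        return Region.III
    return Region.IV


def region_diagonal(space: HDSpace, region: Region) -> np.ndarray:
    """Vector from the pivot (1, 1) to the region's corner.

    A zero vector signals a collapsed (degenerate) region.
    """
    if region is Region.PIVOT:
        raise ValueError("the pivot has no diagonal")
    h, d = space.corner(region)
    return np.array([h - 1.0, d - 1.0])


def relevance(H: float, D: float, space: HDSpace) -> float:
    """Normalized projection of (H, D) onto its region's diagonal, in [0, 1].

    With v = (H-1, D-1) and u the region diagonal, r = (v . u) / (u . u);
    the pivot and collapsed regions score 0. Raises if the point lies
    outside the rectangle (inconsistent inputs).
    """
    if not space.contains(H, D):
        raise ValueError(
            f"point (H={H}, D={D}) outside the H-D rectangle "
            f"[{space.h_min}, {space.h_max}] x [{space.d_min}, {space.d_max}]"
        )
    region = classify_region(H, D)
    if region is Region.PIVOT:
        return 0.0
    u = region_diagonal(space, region)
    uu = float(u @ u)
    if uu <= _TOL**2:
        return 0.0
    v = np.array([H - 1.0, D - 1.0])
    r = float(v @ u) / uu
    return min(1.0, max(0.0, r))


def annotation_eligible(n1: int, n: int) -> bool:
    """True when both metrics and all four bounds are non-degenerate.

    Requires 2 <= n1 <= n - 2: below 2 the expected m11 vanishes (D
    undefined); above n - 2 the complementary class degenerates the space.
    """
    return 2 <= n1 <= n - 2


def score_annotation(
    graph: nx.Graph, annotation: BinaryAnnotation, connected: bool | None = None
) -> RelevanceResult:
    """Full per-attribute pipeline: counts -> expectations -> bounds -> r."""
    annotation = validate_annotation(graph, annotation)
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    n1 = annotation.n1
    counts = core.count_dyads(graph, annotation)
    expected = core.expected_counts(n, m, n1)
    if connected is None:
        connected = nx.is_connected(graph)
    bounds = core.dyad_bounds(
        [d for _, d in graph.degree()], n1, m, connected=connected
    )
    metrics = core.dyadicity_heterophilicity(counts, expected)
    space = hd_space(bounds, expected)
    r = relevance(metrics.H, metrics.D, space)
    return RelevanceResult(
        name=annotation.name,
        n1=n1,
        D=metrics.D,
        H=metrics.H,
        region=classify_region(metrics.H, metrics.D),
        r=r,
    )


def rank_metadata(
    graph: nx.Graph, annotations: Iterable[BinaryAnnotation]
) -> list[RelevanceResult]:
    """Score every eligible annotation and sort by relevance.

    Attributes with degenerate n1 (outside [2, n-2]) are skipped with a
    logged reason. Ties in r are broken by attribute name.
    """
    n = graph.number_of_nodes()
    connected = nx.is_connected(graph)
    results = []
    for annotation in annotations:
        annotation = validate_annotation(graph, annotation)
        if not annotation_eligible(annotation.n1, n):
            logger.info(
                "skipping attribute %r: n1=%d of n=%d degenerates the H-D space",
                annotation.name, annotation.n1, n,
            )
            continue
        results.append(score_annotation(graph, annotation, connected=connected))
    return sorted(results, key=lambda res: (-res.r, res.name))
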