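"""Permutation (label-reshuffling) significance for D, H and the relevance r.

The null model reshuffles the metadata vector over the nodes while keeping
the graph and n1 fixed: each of the K draws is a uniformly random n1-subset
of the nodes. The graph-side quantities (expectations, bounds, the H-D
rectangle) depend only on (n, m, n1, degree sequence) and are therefore
computed once and shared by all draws.

p-values are plain proportions of qualifying draws (no smoothing), with
non-strict inequalities so ties count as qualifying. p_r is the probability
of a reshuffled vector scoring at least the observed relevance. p_D and p_H
are one-sided in the direction of the observed departure from the pivot:
for a dyadic configuration (D >= 1) p_D counts draws with a higher D, for an
antidyadic one draws with a lower D, and symmetrically for H.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx

from . import core, geometry
from .io import BinaryAnnotation, validate_annotation

__all__ = ["PermutationResult", "permutation_test"]


@dataclass(frozen=True)
class PermutationResult:
    """Monte-Carlo permutation p-values for one annotation on one graph."""

    p_D: float
    p_H: float
    p_r: float
    K: int
    seed: int
    D: float
    H: float
    r: float


def permutation_test(
    graph: nx.Graph,
    annotation: BinaryAnnotation,
    K: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-reshuffling significance of an annotation's (D, H, r).

    Draws K uniform random relabelings preserving n1 and recomputes the
    three statistics for each. The seed is required: the null is Monte
    Carlo and results must be reproducible.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    annotation = validate_annotation(graph, annotation)
    n = graph.number_of_nodes()
    n1 = annotation.n1
    # D and H both defined requires 2 <= n1 <= n-1 (a collapsed H-D space is
    # fine: every draw then scores r = 0 and all p-values are 1)
    if not 2 <= n1 <= n - 1:
        raise core.DegenerateMetricError(
            f"annotation {annotation.name!r}: n1={n1} of n={n} degenerates the test"
        )

    m = graph.number_of_edges()
    expected = core.expected_counts(n, m, n1)
    bounds = core.dyad_bounds(
        [d for _, d in graph.degree()], n1, m, connected=nx.is_connected(graph)
    )
    space = geometry.hd_space(bounds, expected)
    m11_bar = float(expected.m11_bar)
    m10_bar = float(expected.m10_bar)

    def statistics(flagged: frozenset | set) -> tuple[float, float, float]:
        m11 = m10 = 0
        for u, v in graph.edges():
            fu = u in flagged
            fv = v in flagged
            if fu and fv:
                m11 += 1
            elif fu or fv:
                m10 += 1
        D = m11 / m11_bar
        H = m10 / m10_bar
        return D, H, geometry.relevance(H, D, space)

    D_obs, H_obs, r_obs = statistics(annotation.flagged)

    rng = random.Random(seed)
    nodes = sorted(graph.nodes, key=str)
    hits_D = hits_H = hits_r = 0
    dyadic = D_obs >= 1
    heterophilic = H_obs > 1
    for _ in range(K):
        flagged = set(rng.sample(nodes, n1))
        D_k, H_k, r_k = statistics(flagged)
        if (D_k >= D_obs) if dyadic else (D_k <= D_obs):
            hits_D += 1
        if (H_k >= H_obs) if heterophilic else (H_k <= H_obs):
            hits_H += 1
        if r_k >= r_obs:
            hits_r += 1
    return PermutationResult(
        p_D=hits_D / K,
        p_H=hits_H / K,
        p_r=hits_r / K,
        K=K,
        seed=seed,
        D=D_obs,
        H=H_obs,
        r=r_obs,
    )
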