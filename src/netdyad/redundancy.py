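"""Redundancy of binary metadata via cosine similarity, and the
Redundancy-Relevance (R-R) pair table.

Two metadata vectors are redundant when they flag largely the same nodes;
the cosine of the angle between the binary vectors measures that overlap
(1 for identical assignments, 0 for disjoint supports). Crossing redundancy
with the structural relevance of each member of a pair separates the
informative situations — e.g. near-identical assignments with very different
relevance point to a handful of structurally decisive nodes. Redundant
metadata are kept and displayed, not trimmed: interpretation, not model
fitting, is the goal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from . import geometry
from .io import BinaryAnnotation

logger = logging.getLogger(__name__)

__all__ = ["RedundancyPair", "cosine_similarity", "rr_table", "write_rr_table", "plot_rr"]


@dataclass(frozen=True)
class RedundancyPair:
    """Cosine redundancy of an unordered attribute pair plus member relevances."""

    attribute_a: str
    attribute_b: str
    cosine: float
    relevance_a: float
    relevance_b: float


def cosine_similarity(vec_a: Sequence[int], vec_b: Sequence[int]) -> float:
    """Cosine of the angle between two binary vectors over the same node order.

    dot(a, b) / (||a|| ||b||): 1 for identical vectors, 0 for disjoint
    supports. Undefined (raises) when either vector is all-zero.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the same node order and length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(a @ b / (na * nb))


def rr_table(
    graph: nx.Graph, annotations: Iterable[BinaryAnnotation]
) -> list[RedundancyPair]:
    """One row per unordered pair of rankable annotations, sorted by cosine.

    Relevances come from the same per-attribute pipeline used for ranking;
    annotations excluded from ranking (degenerate n1) are omitted from the
    table rather than shown with missing relevance.
    """
    annotations = list(annotations)
    ranked = {res.name: res.r for res in geometry.rank_metadata(graph, annotations)}
    kept = [a for a in annotations if a.name in ranked]
    dropped = [a.name for a in annotations if a.name not in ranked]
    if dropped:
        logger.info("R-R table omits unrankable attribute(s): %s", dropped)
    order = sorted(graph.nodes, key=str)
    vectors = {a.name: a.vector(order) for a in kept}
    pairs = [
        RedundancyPair(
            attribute_a=a.name,
            attribute_b=b.name,
            cosine=cosine_similarity(vectors[a.name], vectors[b.name]),
            relevance_a=ranked[a.name],
            relevance_b=ranked[b.name],
        )
        for a, b in itertools.combinations(kept, 2)
    ]
    return sorted(pairs, key=lambda p: (-p.cosine, p.attribute_a, p.attribute_b))


def write_rr_table(pairs: Iterable[RedundancyPair], path, delimiter: str = "\t") -> None:
    """Export the R-R table as delimited text."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(delimiter.join(
            ["attribute_a", "attribute_b", "cosine", "relevance_a", "relevance_b"]
        ) + "\n")
        for p in pairs:
            fh.write(delimiter.join([
                p.attribute_a, p.attribute_b,
                f"{p.cosine:.3f}", f"{p.relevance_a:.2f}", f"{p.relevance_b:.2f}",
            ]) + "\n")


def plot_rr(pairs: Sequence[RedundancyPair], path) -> None:
    """R-R scatter: x = redundancy, y = relevance, dashed segment per couple."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for p in pairs:
        ax.plot([p.cosine, p.cosine], [p.relevance_a, p.relevance_b],
                linestyle="--", color="0.6", linewidth=0.8, zorder=1)
        ax.scatter([p.cosine], [p.relevance_a], s=25, zorder=2)
        ax.scatter([p.cosine], [p.relevance_b], s=25, zorder=2)
    ax.set_xlabel("redundancy (cosine similarity)")
    ax.set_ylabel("relevance r")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
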