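"""Readers, writers and validators for graphs and node-metadata tables.

Graphs are plain-text edge lists (one edge per line, ``#`` comments) held in
:class:`networkx.Graph`; metadata tables are delimited text with a header row
and the node id in the first column, held in :class:`pandas.DataFrame`.
Numeric attributes are dichotomized at their arithmetic mean: a node is
flagged (label 1) when its value is strictly greater than the average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from io import IOBase
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryAnnotation",
    "GraphInputError",
    "MetadataError",
    "AnnotationError",
    "read_edge_list",
    "write_edge_list",
    "read_metadata_table",
    "write_metadata_table",
    "binarize_mean",
    "annotations_from_table",
    "validate_annotation",
    "validate_graph",
]


class GraphInputError(ValueError):
    """Malformed or inconsistent edge-list input."""


class MetadataError(ValueError):
    """Malformed node-metadata table."""


class AnnotationError(ValueError):
    """A binary annotation inconsistent with the graph it describes."""


@dataclass(frozen=True)
class BinaryAnnotation:
    """One named binary attribute over a node set.

    ``labels`` maps every node id to 0 or 1; ``n1`` is the number of flagged
    (label-1) nodes and ``n0`` the complement.
    """

    name: str
    labels: Mapping[object, int] = field(repr=False)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if v not in (0, 1)}
        if bad:
            raise AnnotationError(
                f"annotation {self.name!r} has labels outside {{0,1}}: {sorted(map(repr, bad))}"
            )

    @property
    def n1(self) -> int:
        return sum(self.labels.values())

    @property
    def n0(self) -> int:
        return len(self.labels) - self.n1

    @property
    def flagged(self) -> frozenset:
        return frozenset(v for v, c in self.labels.items() if c == 1)

    def vector(self, ordered_nodes: Iterable) -> np.ndarray:
        """Binary vector of the labels in the given node order."""
        return np.array([self.labels[v] for v in ordered_nodes], dtype=int)


def _as_lines(stream) -> Iterable[str]:
    if isinstance(stream, (str, Path)):
        with open(stream, "rt", encoding="utf-8") as fh:
            yield from fh
    elif isinstance(stream, IOBase) or hasattr(stream, "read"):
        yield from stream
    else:
        yield from stream


def read_edge_list(stream, delimiter: str | None = None) -> nx.Graph:
    """Read a simple undirected graph from an edge list.

    One edge per line, two node ids separated by *delimiter* (any run of
    whitespace by default). Lines starting with ``#`` and blank lines are
    skipped. Duplicate edges (in either orientation) are collapsed with a
    logged count; self-loops are rejected.
    """
    graph: nx.Graph = nx.Graph()
    duplicates = 0
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise GraphInputError(
                f"line {lineno}: expected at least two fields, got {line!r}"
            )
        u, v = fields[0], fields[1]
        if u == v:
            raise GraphInputError(f"line {lineno}: self-loop on node {u!r}")
        if graph.has_edge(u, v):
            duplicates += 1
        graph.add_edge(u, v)
    if duplicates:
        logger.warning("collapsed %d duplicate edge line(s)", duplicates)
    validate_graph(graph)
    return graph


def validate_graph(graph: nx.Graph) -> nx.Graph:
    """Check simple-graph invariants: n >= 2, no self-loops, degree sum 2m."""
    if graph.number_of_nodes() < 2:
        raise GraphInputError("graph must have at least 2 nodes")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise GraphInputError(f"graph has self-loops: {loops[:5]}")
    assert sum(d for _, d in graph.degree()) == 2 * graph.number_of_edges()
    return graph


def write_edge_list(graph: nx.Graph, path, delimiter: str = " ") -> None:
    """Write the graph as a plain-text edge list (isolated nodes as comments)."""
    with open(path, "wt", encoding="utf-8") as fh:
        isolated = [v for v, d in graph.degree() if d == 0]
        if isolated:
            fh.write("# isolated: " + " ".join(str(v) for v in isolated) + "\n")
        for u, v in sorted((sorted((str(a), str(b))) for a, b in graph.edges())):
            fh.write(f"{u}{delimiter}{v}\n")


def read_metadata_table(stream, delimiter: str = ",") -> pd.DataFrame:
    """Read a node-metadata table: header row, node id in the first column.

    Returns a DataFrame indexed by node id with numeric columns. Duplicate
    node ids and non-numeric cells raise :class:`MetadataError` naming the
    offending row/column.
    """
    table = pd.read_csv(stream, sep=delimiter, index_col=0, dtype={0: str})
    table.index = table.index.astype(str)
    dup = table.index[table.index.duplicated()].unique()
    if len(dup):
        raise MetadataError(f"duplicate node id(s) in metadata table: {list(dup)}")
    if len(set(table.columns)) != len(table.columns):
        raise MetadataError("attribute names must be unique")
    for col in table.columns:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            raise MetadataError(
                f"non-numeric value in column {col!r} at row id {bad[0]!r}"
            )
        table[col] = coerced
    return table


def write_metadata_table(
    annotations: Iterable[BinaryAnnotation], path, delimiter: str = ","
) -> None:
    """Write binary annotations as a metadata CSV (one column per attribute)."""
    annotations = list(annotations)
    nodes = sorted({v for a in annotations for v in a.labels}, key=str)
    frame = pd.DataFrame(
        {a.name: [a.labels[v] for v in nodes] for a in annotations},
        index=pd.Index(nodes, name="id"),
    )
    frame.to_csv(path, sep=delimiter)


def binarize_mean(values: Mapping[object, float], name: str) -> BinaryAnnotation:
    """Dichotomize a numeric node attribute at its arithmetic mean.

    Label 1 is assigned when the value is strictly greater than the mean
    (over-performers); values equal to or below the mean get label 0. With
    all values equal no node exceeds the mean, so ``n1 = 0``.
    """
    if not values:
        raise MetadataError(f"attribute {name!r}: no values to binarize")
    for node, x in values.items():
        if x is None or not math.isfinite(x):
            raise MetadataError(f"attribute {name!r}: non-finite value for node {node!r}")
    mean = sum(values.values()) / len(values)
    return BinaryAnnotation(name, {v: int(x > mean) for v, x in values.items()})


def annotations_from_table(
    table: pd.DataFrame, binarize: bool = False
) -> list[BinaryAnnotation]:
    """One annotation per table column; numeric columns mean-binarized on request."""
    out = []
    for col in table.columns:
        values = table[col].to_dict()
        if binarize:
            out.append(binarize_mean(values, col))
        else:
            labels = {}
            for node, x in values.items():
                if x not in (0, 1):
                    raise MetadataError(
                        f"attribute {col!r} is not binary at node {node!r} "
                        f"(value {x!r}); pass binarize=True to dichotomize"
                    )
                labels[node] = int(x)
            out.append(BinaryAnnotation(col, labels))
    return out


def validate_annotation(graph: nx.Graph, annotation: BinaryAnnotation) -> BinaryAnnotation:
    """Verify an annotation against a graph and restrict it to the graph's nodes.

    Every graph node must carry a label in {0,1}; labels for nodes absent
    from the graph are dropped (with ``n1`` recomputed on the restriction).
    """
    missing = [v for v in graph.nodes if v not in annotation.labels]
    if missing:
        raise AnnotationError(
            f"annotation {annotation.name!r} lacks labels for {len(missing)} node(s), "
            f"e.g. {missing[:5]}"
        )
    restricted = {v: annotation.labels[v] for v in graph.nodes}
    return BinaryAnnotation(annotation.name, restricted)
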