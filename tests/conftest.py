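import networkx as nx
import pytest

from netdyad import BinaryAnnotation
from netdyad.fixtures import rich_club_toy


@pytest.fixture(scope="session")
def toy():
    """The rich-club toy: 43 nodes, 45 edges, flagged 4-clique."""
    return rich_club_toy()


@pytest.fixture
def triangle():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def star():
    """Star K1,4 with center 'hub'."""
    return nx.star_graph(["hub", "l1", "l2", "l3", "l4"])


def annotate(graph, flagged, name="x"):
    """Helper: annotation flagging the given nodes of a graph."""
    flagged = set(flagged)
    return BinaryAnnotation(name, {v: int(v in flagged) for v in graph.nodes})
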