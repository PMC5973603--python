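import pytest

from compoundnet import Options, worked_example_graph


@pytest.fixture
def example():
    return worked_example_graph()


@pytest.fixture
def quiet():
    """Options with all layout hooks off, for pure-topology assertions."""
    return Options(layout_after_op="none", fisheye=False)


def topology_signature(graph):
    """Order-insensitive summary of the active topology and archive state."""
    return (
        frozenset(graph.nodes),
        frozenset((n.id, n.parent, n.collapsed) for n in graph.nodes.values()),
        frozenset(
            (e.id, frozenset((e.source, e.target)), e.kind, e.original_ref)
            for e in graph.edges.values()
        ),
        frozenset(graph.archived_originals),
    )
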