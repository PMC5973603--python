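import random

import numpy as np
import pytest

from compoundnet import (
    GeneratorParams,
    GraphError,
    Options,
    build_graph,
    collapse_all,
    collapse_node,
    collapse_set,
    collapsed_children,
    collapsible_nodes,
    expand_all,
    expand_node,
    expand_set,
    expandable_nodes,
    generate_compound_graph,
    node_op_state,
    validate,
)
from conftest import topology_signature


def three_level_fixture():
    """c contains c_s contains s; y outside; single edge {s, y}."""
    return build_graph(
        [
            {"id": "c"},
            {"id": "c_s", "parent": "c"},
            {"id": "s", "parent": "c_s", "x": 10, "y": 10},
            {"id": "y", "x": 200, "y": 0},
        ],
        [{"id": "s--y", "source": "s", "target": "y"}],
    )


class TestCollapseNode:
    def test_example_collapse_c2(self, example, quiet):
        report = collapse_node(example, "c2", quiet)
        assert report.created_meta_edges == ["meta:d--e"]
        m = example.edges["meta:d--e"]
        assert {m.source, m.target} == {"d", "c2"}
        assert m.original_ref == "d--e"
        assert "d--e" in example.archived_originals
        assert "e" not in example.nodes
        assert report.archived_nodes == ["e"]
        assert validate(example) == []

    def test_example_collapse_c1_no_meta(self, example, quiet):
        report = collapse_node(example, "c1", quiet)
        assert report.created_meta_edges == []
        assert set(report.archived_nodes) == {"a", "b", "c2", "d", "e"}
        assert set(report.archived_edges) == {"a--b", "b--d", "d--e"}
        assert len(example.edges) == 0
        assert list(example.nodes) == ["c1"]
        assert validate(example) == []

    def test_collapsed_proxy_geometry(self, example, quiet):
        center = example.nodes["c2"].center
        collapse_node(example, "c2", quiet)
        c2 = example.nodes["c2"]
        assert c2.collapsed and c2.store is not None
        assert c2.center == center
        assert (c2.width, c2.height) == (30.0, 30.0)

    def test_nested_meta_reconnected_not_duplicated(self, quiet):
        g = three_level_fixture()
        collapse_node(g, "c_s", quiet)
        report = collapse_node(g, "c", quiet)
        assert report.created_meta_edges == []
        assert len(report.reconnected_meta_edges) == 1
        m = g.edges["meta:s--y"]
        assert {m.source, m.target} == {"c", "y"}
        assert m.original_ref == "s--y"
        assert len(g.archived_originals) == 1
        assert validate(g) == []

    def test_errors(self, example, quiet):
        with pytest.raises(GraphError):
            collapse_node(example, "zzz", quiet)
        with pytest.raises(GraphError):
            collapse_node(example, "a", quiet)  # leaf
        collapse_node(example, "c2", quiet)
        with pytest.raises(GraphError):
            collapse_node(example, "c2", quiet)  # already collapsed

    def test_hidden_descendants_archived_with_flags(self, example, quiet):
        example.nodes["e"].hidden = True
        collapse_node(example, "c2", quiet)
        expand_node(example, "c2", quiet)
        assert example.nodes["e"].hidden is True

    def test_callbacks_fire_around_mutation(self, example):
        events = []
        opts = Options(
            layout_after_op="none",
            fisheye=False,
            before_collapse=lambda c: events.append(("before", c, "e" in example.nodes)),
            after_collapse=lambda c: events.append(("after", c, "e" in example.nodes)),
        )
        collapse_node(example, "c2", opts)
        assert events == [("before", "c2", True), ("after", "c2", False)]


class TestExpandNode:
    def test_example_roundtrip_restores_topology(self, example, quiet):
        before = topology_signature(example)
        collapse_node(example, "c2", quiet)
        report = expand_node(example, "c2", quiet)
        assert report.discarded_meta_edges == ["meta:d--e"]
        assert "d--e" in example.edges
        assert example.edges["d--e"].kind == "original"
        assert example.archived_originals == {}
        assert topology_signature(example) == before
        assert validate(example) == []

    def test_three_level_partial_expand_retargets(self, quiet):
        g = three_level_fixture()
        collapse_node(g, "c_s", quiet)
        collapse_node(g, "c", quiet)
        report = expand_node(g, "c", quiet)
        # s is still archived inside collapsed c_s: the meta edge must hop
        # to c_s and the original stays archived
        assert report.discarded_meta_edges == []
        m = g.edges["meta:s--y"]
        assert {m.source, m.target} == {"c_s", "y"}
        assert "s--y" in g.archived_originals
        assert validate(g) == []
        expand_node(g, "c_s", quiet)
        assert "s--y" in g.edges and g.archived_originals == {}

    def test_expand_leaf_errors(self, example, quiet):
        with pytest.raises(GraphError):
            expand_node(example, "a", quiet)

    def test_children_restored_relative_to_moved_center(self, example, quiet):
        collapse_node(example, "c2", quiet)
        c2 = example.nodes["c2"]
        rel = example.nodes["c2"].store.nodes[0].center
        c2.center = (c2.x + 100.0, c2.y - 50.0)
        expand_node(example, "c2", quiet)
        e = example.nodes["e"]
        assert e.center == pytest.approx((c2.x + rel[0], c2.y + rel[1]))


class TestBulkVariants:
    def test_collapse_set_recursive_bottom_up(self, example, quiet):
        collapse_set(example, ["c1", "c2"], recursive=True, options=quiet)
        assert list(example.nodes) == ["c1"]
        assert example.nodes["c1"].collapsed
        assert not any(e.kind == "meta" for e in example.edges.values())
        # c2 is collapsed inside c1's store
        stored = {n.id: n for n in example.nodes["c1"].store.nodes}
        assert stored["c2"].collapsed and stored["c2"].store is not None
        assert validate(example) == []

    def test_collapse_set_empty(self, example, quiet):
        before = topology_signature(example)
        report = collapse_set(example, [], options=quiet)
        assert topology_signature(example) == before
        assert report.subjects == [] and report.edge_touch_count == 0

    def test_sibling_compounds_one_meta_either_order(self, quiet):
        def make():
            return build_graph(
                [
                    {"id": "p"},
                    {"id": "q"},
                    {"id": "u", "parent": "p"},
                    {"id": "v", "parent": "q", "x": 100},
                ],
                [{"id": "u--v", "source": "u", "target": "v"}],
            )

        sigs = []
        for order in (["p", "q"], ["q", "p"]):
            g = make()
            for c in order:
                collapse_node(g, c, quiet)
            metas = [e for e in g.edges.values() if e.kind == "meta"]
            assert len(metas) == 1
            assert {metas[0].source, metas[0].target} == {"p", "q"}
            sigs.append(topology_signature(g))
        assert sigs[0] == sigs[1]

    def test_expand_all_restores_pristine(self, example, quiet):
        before = topology_signature(example)
        collapse_all(example, quiet)
        expand_all(example, quiet)
        assert topology_signature(example) == before

    def test_expand_set_skips_expanded(self, example, quiet):
        report = expand_set(example, ["c2"], options=quiet)
        assert report.skipped == ["c2"]

    def test_non_compounds_skipped(self, example, quiet):
        report = collapse_set(example, ["a", "c2"], options=quiet)
        assert report.skipped == ["a"]
        assert example.nodes["c2"].collapsed


class TestNodeOpState:
    def test_pristine_c2(self, example):
        assert node_op_state(example, "c2") == {"collapsible": True, "expandable": False}

    def test_collapsed_c2(self, example, quiet):
        collapse_node(example, "c2", quiet)
        assert node_op_state(example, "c2") == {"collapsible": False, "expandable": True}

    def test_leaf(self, example):
        assert node_op_state(example, "a") == {"collapsible": False, "expandable": False}

    def test_set_queries(self, example, quiet):
        collapse_node(example, "c2", quiet)
        assert collapsible_nodes(example) == ["c1"]
        assert expandable_nodes(example) == ["c2"]


class TestCollapsedChildren:
    def test_direct_excludes_intergraph_original(self, example, quiet):
        collapse_node(example, "c2", quiet)
        got = collapsed_children(example, "c2", "direct")
        assert got == {"nodes": ["e"], "edges": []}

    def test_recursive_after_collapse_all(self, example, quiet):
        collapse_all(example, quiet)
        got = collapsed_children(example, "c1", "recursive")
        assert sorted(got["nodes"]) == ["a", "b", "c2", "d", "e"]
        assert sorted(got["edges"]) == ["a--b", "b--d"]

    def test_all_graph_nothing_collapsed(self, example):
        assert collapsed_children(example, mode="all_graph") == {"nodes": [], "edges": []}

    def test_not_collapsed_errors(self, example):
        with pytest.raises(GraphError):
            collapsed_children(example, "c2", "direct")


# -- randomized properties ------------------------------------------------


def random_graph(seed, n=25):
    return generate_compound_graph(
        GeneratorParams(
            n_leaf_nodes=n, n_compounds=6, max_depth=4, edge_density=1.5,
            p_intergraph=0.3, seed=seed,
        )
    )


def original_edge_ids(graph):
    out = set(graph.archived_originals)
    out |= {e.id for e in graph.edges.values() if e.kind == "original"}
    stack = [n.store for n in graph.nodes.values() if n.store is not None]
    while stack:
        store = stack.pop()
        out |= {e.id for e in store.edges if e.kind == "original"}
        for n in store.nodes:
            if n.store is not None:
                stack.append(n.store)
    return out


@pytest.mark.parametrize("seed", range(12))
def test_random_sequences_preserve_invariants(seed, quiet):
    rng = random.Random(seed)
    g = random_graph(seed)
    pristine = topology_signature(g)
    originals = original_edge_ids(g)
    for _ in range(30):
        coll = collapsible_nodes(g)
        expa = expandable_nodes(g)
        candidates = [("c", c) for c in coll] + [("e", c) for c in expa]
        if not candidates:
            break
        kind, target = rng.choice(candidates)
        if kind == "c":
            collapse_node(g, target, quiet)
        else:
            expand_node(g, target, quiet)
        assert validate(g) == []  # includes one-meta-per-original
        assert original_edge_ids(g) == originals  # originals never lost
    expand_all(g, quiet)
    assert topology_signature(g) == pristine


def antichain(graph, compounds):
    """Drop compounds nested inside another member of the set."""
    keep = []
    for c in compounds:
        anc = set(graph.ancestors(c))
        if not any(o in anc or c in set(graph.ancestors(o)) for o in compounds if o != c):
            keep.append(c)
    return keep


@pytest.mark.parametrize("seed", range(8))
def test_collapse_order_independence_on_antichains(seed, quiet):
    rng = random.Random(seed)
    base = generate_compound_graph(
        GeneratorParams(n_leaf_nodes=25, n_compounds=6, max_depth=2,
                        edge_density=1.5, p_intergraph=0.4, seed=seed)
    )
    compounds = antichain(base, collapsible_nodes(base))
    if len(compounds) < 2:
        pytest.skip("no unnested compound pair in this draw")
    subset = rng.sample(compounds, min(3, len(compounds)))
    sigs = set()
    for _ in range(4):
        order = subset[:]
        rng.shuffle(order)
        g = base.clone()
        for c in order:
            collapse_node(g, c, quiet)
        sigs.add(topology_signature(g))
    assert len(sigs) == 1


@pytest.mark.parametrize("seed", range(8))
def test_collapse_set_permutation_invariance(seed, quiet):
    # collapse_set normalizes arbitrary (possibly nested) sets bottom-up,
    # so any permutation of the input yields the same topology
    rng = random.Random(seed)
    base = random_graph(seed)
    compounds = collapsible_nodes(base)
    if len(compounds) < 2:
        pytest.skip("no compound pair in this draw")
    subset = rng.sample(compounds, min(4, len(compounds)))
    sigs = set()
    for _ in range(4):
        order = subset[:]
        rng.shuffle(order)
        g = base.clone()
        collapse_set(g, order, options=quiet)
        sigs.add(topology_signature(g))
    assert len(sigs) == 1


def test_collapse_roundtrip_identity_on_random_graphs(quiet):
    for seed in range(6):
        g = random_graph(seed)
        before = topology_signature(g)
        for c in collapsible_nodes(g)[:2]:
            collapse_node(g, c, quiet)
            expand_node(g, c, quiet)
            assert topology_signature(g) == before


def test_touch_count_bounded_linearly(quiet):
    # edge_touch_count <= K * (descendants + incident edges) for fixed K
    K = 2
    for seed in range(5):
        g = random_graph(seed, n=40)
        for c in collapsible_nodes(g):
            if c not in g.nodes:
                continue  # archived by an earlier collapse in this loop
            desc = set(g.descendants(c))
            incident = {
                e.id
                for e in g.edges.values()
                if e.source in desc or e.target in desc
            }
            report = collapse_node(g, c, quiet)
            assert report.edge_touch_count <= K * (len(desc) + len(incident))
            assert report.edge_touch_count >= (
                len(report.created_meta_edges)
                + len(report.discarded_meta_edges)
                + len(report.reconnected_meta_edges)
            )


def test_incremental_layout_runs_after_collapse(example):
    opts = Options(layout_after_op="incremental", fisheye=False)
    report = collapse_node(example, "c2", opts)
    assert report.layout_iterations > 0
    assert validate(example) == []


def test_fisheye_opens_room_on_expand(quiet):
    g = build_graph(
        [
            {"id": "c"},
            {"id": "u", "parent": "c", "x": -60, "y": 0},
            {"id": "v", "parent": "c", "x": 60, "y": 0},
            {"id": "far", "x": 300, "y": 0},
        ],
        [],
    )
    collapse_node(g, "c", quiet)
    x_before = g.nodes["far"].x
    expand_node(g, "c", Options(layout_after_op="none", fisheye=True))
    # the neighbor to the right must be pushed further right
    assert g.nodes["far"].x > x_before
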