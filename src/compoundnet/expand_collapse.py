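"""Collapse and expand of compound nodes with meta-edge bookkeeping.

Collapsing a compound archives its content into a per-node store and
replaces every edge crossing the compound boundary with (or reconnects
an existing) *meta edge* attached to the collapsed proxy.  Exactly one
meta edge exists per archived original edge at all times, and the
resulting topology is independent of the order in which compounds are
collapsed.  Expanding reverses the bookkeeping; a full expand restores
the pristine topology exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from . import layout as _layout
from .core_model import (
    META,
    ORIGINAL,
    CompoundGraph,
    EdgeRecord,
    GraphError,
    _all_node_records,
    inclusion_level,
)


@dataclass
class Options:
    """Operation options, defaults mirroring the library surface."""

    layout_after_op: str = "incremental"  # one of {"none", "incremental"}
    fisheye: bool = True
    cue_size: float = 12.0
    cue_line_size: float = 8.0
    cue_position: str = "top-left"
    unhighlighted_opacity: float = 0.3
    set_visibility_on_hide: bool = False
    set_display_on_hide: bool = True
    before_collapse: Optional[Callable[[str], None]] = None
    after_collapse: Optional[Callable[[str], None]] = None
    before_expand: Optional[Callable[[str], None]] = None
    after_expand: Optional[Callable[[str], None]] = None
    layout_params: Optional[_layout.LayoutParams] = None

    def __post_init__(self) -> None:
        if self.layout_after_op not in ("none", "incremental"):
            raise ValueError("layout_after_op must be 'none' or 'incremental'")
        if not (0.0 <= self.unhighlighted_opacity <= 1.0):
            raise ValueError("unhighlighted_opacity must be in [0, 1]")
        if self.cue_size <= 0 or self.cue_line_size <= 0:
            raise ValueError("cue sizes must be positive")


@dataclass
class OpReport:
    operation: str
    subjects: list[str] = field(default_factory=list)
    created_meta_edges: list[str] = field(default_factory=list)
    discarded_meta_edges: list[str] = field(default_factory=list)
    reconnected_meta_edges: list[tuple] = field(default_factory=list)
    archived_nodes: list[str] = field(default_factory=list)
    archived_edges: list[str] = field(default_factory=list)
    restored_nodes: list[str] = field(default_factory=list)
    restored_edges: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    levels: list[list[str]] = field(default_factory=list)
    hidden_elements: list[str] = field(default_factory=list)
    shown_elements: list[str] = field(default_factory=list)
    layout_iterations: int = 0
    edge_touch_count: int = 0

    @property
    def archived_elements(self) -> list[str]:
        return self.archived_nodes + self.archived_edges

    @property
    def restored_elements(self) -> list[str]:
        return self.restored_nodes + self.restored_edges

    def merge(self, other: "OpReport") -> None:
        self.subjects += other.subjects
        self.created_meta_edges += other.created_meta_edges
        self.discarded_meta_edges += other.discarded_meta_edges
        self.reconnected_meta_edges += other.reconnected_meta_edges
        self.archived_nodes += other.archived_nodes
        self.archived_edges += other.archived_edges
        self.restored_nodes += other.restored_nodes
        self.restored_edges += other.restored_edges
        self.skipped += other.skipped
        self.hidden_elements += other.hidden_elements
        self.shown_elements += other.shown_elements
        self.layout_iterations += other.layout_iterations
        self.edge_touch_count += other.edge_touch_count


def _post_op_layout(graph: CompoundGraph, options: Options, report: OpReport) -> None:
    if options.layout_after_op != "incremental":
        return
    params = options.layout_params or _layout.LayoutParams()
    report.layout_iterations += _layout.apply_incremental(graph, params)


def node_op_state(graph: CompoundGraph, node_id: str) -> dict:
    """Whether a node can currently be collapsed or expanded."""
    n = graph.node(node_id)
    return {
        "collapsible": (not n.collapsed) and graph.has_children(node_id),
        "expandable": n.collapsed,
    }


def collapsible_nodes(graph: CompoundGraph, node_ids: Optional[Iterable[str]] = None) -> list[str]:
    ids = list(node_ids) if node_ids is not None else list(graph.nodes)
    return [i for i in ids if node_op_state(graph, i)["collapsible"]]


def expandable_nodes(graph: CompoundGraph, node_ids: Optional[Iterable[str]] = None) -> list[str]:
    ids = list(node_ids) if node_ids is not None else list(graph.nodes)
    return [i for i in ids if node_op_state(graph, i)["expandable"]]


# -- collapse ------------------------------------------------------------


def collapse_node(
    graph: CompoundGraph, c: str, options: Optional[Options] = None
) -> OpReport:
    """Collapse compound ``c``: archive its content, maintain meta edges.

    For every edge with exactly one endpoint strictly inside ``c``:
    an original edge is archived and replaced by a fresh meta edge
    ``{c, outside-end}`` pointing at it; a meta edge is reconnected to
    ``{c, outside-end}`` keeping its original pointer.  Edges fully
    inside ``c`` move to the store untouched.
    """
    options = options or Options()
    node = graph.node(c)
    if node.collapsed:
        raise GraphError(f"{c!r} is already collapsed")
    if not graph.has_children(c):
        raise GraphError(f"{c!r} is not a compound (no children to collapse)")
    if options.before_collapse:
        options.before_collapse(c)

    report = OpReport(operation="collapse", subjects=[c])
    inside = set(graph.descendants(c))

    ig_edges: list[EdgeRecord] = []
    inner_edges: list[EdgeRecord] = []
    for e in graph.edges.values():
        s_in = e.source in inside
        t_in = e.target in inside
        if s_in and t_in:
            inner_edges.append(e)
        elif s_in or t_in:
            ig_edges.append(e)

    for e in ig_edges:
        y = e.target if e.source in inside else e.source
        if e.kind == ORIGINAL:
            m = EdgeRecord(
                id=f"meta:{e.id}",
                source=c,
                target=y,
                kind=META,
                original_ref=e.id,
                hidden=e.hidden,
            )
            del graph.edges[e.id]
            graph.archived_originals[e.id] = e
            graph.edges[m.id] = m
            report.created_meta_edges.append(m.id)
        else:
            old = (e.source, e.target)
            if e.source in inside:
                e.source = c
            else:
                e.target = c
            report.reconnected_meta_edges.append((e.id, old, (e.source, e.target)))
        report.edge_touch_count += 1

    from .core_model import SubgraphStore

    store = SubgraphStore()
    for e in inner_edges:
        del graph.edges[e.id]
        store.edges.append(e)
        report.archived_edges.append(e.id)
        report.edge_touch_count += 1
    cx, cy = node.center
    for nid in graph.descendants(c):  # top-down order, restores cleanly
        rec = graph.nodes.pop(nid)
        rec.center = (rec.x - cx, rec.y - cy)
        store.nodes.append(rec)
        report.archived_nodes.append(nid)

    node.collapsed = True
    node.store = store
    node.center = (cx, cy)
    graph.refresh_compound_bounds()

    _post_op_layout(graph, options, report)
    if options.after_collapse:
        options.after_collapse(c)
    return report


# -- expand --------------------------------------------------------------


def _inside_endpoint(graph: CompoundGraph, edge: EdgeRecord, c: str) -> tuple[str, str]:
    """Endpoints of an archived original split into (inside-c, outside-c).

    Looks through nested stores, since the inside endpoint may still be
    archived deeper down.
    """
    records = _all_node_records(graph)
    for u in (edge.source, edge.target):
        cur = records.get(u)
        while cur is not None and cur.parent is not None:
            if cur.parent == c:
                return u, edge.other(u)
            cur = records.get(cur.parent)
    raise GraphError(f"no endpoint of {edge.id!r} lies inside {c!r}")


def _active_representative(graph: CompoundGraph, c: str, s: str) -> str:
    """Highest collapsed node on the inclusion path strictly below ``c``
    containing ``s``; ``s`` itself when the whole path is expanded."""
    records = _all_node_records(graph)
    path = [s]
    cur = records[s].parent
    while cur is not None and cur != c:
        path.append(cur)
        cur = records[cur].parent
    for nid in reversed(path):  # scan from just below c downwards
        if records[nid].collapsed:
            return nid
    return s


def expand_node(
    graph: CompoundGraph, c: str, options: Optional[Options] = None
) -> OpReport:
    """Expand collapsed compound ``c``, restoring content and originals.

    Each meta edge incident to ``c`` either reconnects to the topmost
    still-collapsed container of its inside endpoint, or — when both
    original endpoints are active again — is discarded and its original
    edge reactivated.
    """
    options = options or Options()
    node = graph.node(c)
    if not node.collapsed:
        raise GraphError(f"{c!r} is not collapsed")
    if options.before_expand:
        options.before_expand(c)

    report = OpReport(operation="expand", subjects=[c])

    if options.fisheye and node.store.nodes:
        new_w, new_h = _expanded_extents(node)
        _layout.fisheye_adjust(graph, c, new_w, new_h)

    cx, cy = node.center
    store = node.store
    node.collapsed = False
    node.store = None
    for rec in store.nodes:
        rec.center = (rec.x + cx, rec.y + cy)
        graph.nodes[rec.id] = rec
        report.restored_nodes.append(rec.id)
    for e in store.edges:
        graph.edges[e.id] = e
        report.restored_edges.append(e.id)
        report.edge_touch_count += 1

    metas = [
        e
        for e in list(graph.edges.values())
        if e.kind == META and c in (e.source, e.target)
    ]
    for m in metas:
        orig = graph.archived_originals[m.original_ref]
        s, t = _inside_endpoint(graph, orig, c)
        y = m.other(c)
        repr_s = _active_representative(graph, c, s)
        if repr_s == s and y == t:
            del graph.edges[m.id]
            del graph.archived_originals[orig.id]
            graph.edges[orig.id] = orig
            report.discarded_meta_edges.append(m.id)
            report.restored_edges.append(orig.id)
        else:
            old = (m.source, m.target)
            if m.source == c:
                m.source = repr_s
            else:
                m.target = repr_s
            report.reconnected_meta_edges.append((m.id, old, (m.source, m.target)))
        report.edge_touch_count += 1

    graph.refresh_compound_bounds()
    _post_op_layout(graph, options, report)
    if options.after_expand:
        options.after_expand(c)
    return report


def _expanded_extents(node) -> tuple[float, float]:
    """Extents the compound will need once its store is restored."""
    from .core_model import COMPOUND_MARGIN

    xs0 = [n.x - n.width / 2 for n in node.store.nodes]
    xs1 = [n.x + n.width / 2 for n in node.store.nodes]
    ys0 = [n.y - n.height / 2 for n in node.store.nodes]
    ys1 = [n.y + n.height / 2 for n in node.store.nodes]
    w = (max(xs1) - min(xs0)) + 2 * COMPOUND_MARGIN
    h = (max(ys1) - min(ys0)) + 2 * COMPOUND_MARGIN
    return w, h


# -- bulk variants -------------------------------------------------------


def collapse_set(
    graph: CompoundGraph,
    node_ids: Iterable[str],
    recursive: bool = False,
    options: Optional[Options] = None,
) -> OpReport:
    """Collapse the collapsible members of a set, inner compounds first."""
    options = options or Options()
    report = OpReport(operation="collapse_set")
    targets = set()
    for nid in node_ids:
        graph.node(nid)
        targets.add(nid)
        if recursive:
            targets.update(graph.descendants(nid))
    ordered = sorted(targets, key=lambda i: (-inclusion_level(graph, i), i))
    for nid in ordered:
        if node_op_state(graph, nid)["collapsible"]:
            report.merge(collapse_node(graph, nid, options))
        else:
            report.skipped.append(nid)
    return report


def collapse_all(graph: CompoundGraph, options: Optional[Options] = None) -> OpReport:
    return collapse_set(graph, list(graph.nodes), recursive=True, options=options)


def expand_set(
    graph: CompoundGraph,
    node_ids: Iterable[str],
    recursive: bool = False,
    options: Optional[Options] = None,
) -> OpReport:
    """Expand the expandable members of a set, outer compounds first."""
    options = options or Options()
    report = OpReport(operation="expand_set")
    queue = sorted(
        set(node_ids), key=lambda i: (inclusion_level(graph, i), i)
    )
    seen = set()
    while queue:
        nid = queue.pop(0)
        if nid in seen:
            continue
        seen.add(nid)
        if nid not in graph.nodes:
            report.skipped.append(nid)
            continue
        if node_op_state(graph, nid)["expandable"]:
            sub = expand_node(graph, nid, options)
            report.merge(sub)
            if recursive:
                for rid in sub.restored_nodes:
                    if rid in graph.nodes and graph.nodes[rid].collapsed:
                        queue.append(rid)
        else:
            report.skipped.append(nid)
    return report


def expand_all(graph: CompoundGraph, options: Optional[Options] = None) -> OpReport:
    return expand_set(graph, list(graph.nodes), recursive=True, options=options)


# -- queries -------------------------------------------------------------


def collapsed_children(
    graph: CompoundGraph, node_id: Optional[str] = None, mode: str = "direct"
) -> dict:
    """Archived content of collapsed compounds as ``{"nodes": [...], "edges": [...]}``.

    ``direct`` lists a store's immediate content, ``recursive`` descends
    nested stores, ``all_graph`` unions over every collapsed compound.
    Meta edges are bookkeeping, not user content, so only original-kind
    edges are listed; originals represented by active meta edges live in
    the graph-level registry and are excluded likewise.
    """
    if mode not in ("direct", "recursive", "all_graph"):
        raise GraphError(f"unknown mode {mode!r}")

    def collect(store, recurse: bool, nodes: list, edges: list) -> None:
        for n in store.nodes:
            nodes.append(n.id)
            if recurse and n.store is not None:
                collect(n.store, True, nodes, edges)
        for e in store.edges:
            if e.kind == ORIGINAL:
                edges.append(e.id)

    nodes: list[str] = []
    edges: list[str] = []
    if mode == "all_graph":
        for n in graph.nodes.values():
            if n.store is not None:
                collect(n.store, True, nodes, edges)
    else:
        n = graph.node(node_id)
        if n.store is None:
            raise GraphError(f"{node_id!r} is not collapsed")
        collect(n.store, mode == "recursive", nodes, edges)
    return {"nodes": nodes, "edges": edges}
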