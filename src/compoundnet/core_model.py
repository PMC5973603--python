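"""In-memory model of compound (nested) graphs.

A compound graph couples an ordinary undirected graph with an inclusion
tree: every node may name a *parent* compound node, and the parent
relation must form a rooted forest hanging off an implied virtual root.
Adjacency edges are forbidden between a node and its ancestors or
descendants.  Edges are either *original* or *meta*; a meta edge stands
in for exactly one archived original edge and carries a pointer to it.

All structural queries used by the complexity-management operations
(expand/collapse, hide/show, layout) live here.
"""

from __future__ import annotations

import copy
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

DEFAULT_NODE_SIZE = 30.0
COMPOUND_MARGIN = 10.0
COLLAPSED_SIZE = 30.0

ORIGINAL = "original"
META = "meta"


class GraphError(ValueError):
    """Raised on malformed input or an operation precondition failure."""


@dataclass
class SubgraphStore:
    """Archived content of a collapsed compound.

    Node positions are stored *relative* to the owning compound's center
    so the inner layout survives movement of the collapsed proxy.
    """

    nodes: list["NodeRecord"] = field(default_factory=list)
    edges: list["EdgeRecord"] = field(default_factory=list)


@dataclass
class NodeRecord:
    id: str
    parent: Optional[str] = None
    center: tuple[float, float] = (0.0, 0.0)
    width: float = DEFAULT_NODE_SIZE
    height: float = DEFAULT_NODE_SIZE
    hidden: bool = False
    highlighted: bool = False
    collapsed: bool = False
    store: Optional[SubgraphStore] = None
    label: Optional[str] = None
    extra: dict = field(default_factory=dict)

    @property
    def x(self) -> float:
        return self.center[0]

    @property
    def y(self) -> float:
        return self.center[1]


@dataclass
class EdgeRecord:
    id: str
    source: str
    target: str
    kind: str = ORIGINAL
    original_ref: Optional[str] = None
    hidden: bool = False
    highlighted: bool = False
    extra: dict = field(default_factory=dict)

    def endpoints(self) -> frozenset[str]:
        return frozenset((self.source, self.target))

    def other(self, node_id: str) -> str:
        if node_id == self.source:
            return self.target
        if node_id == self.target:
            return self.source
        raise GraphError(f"node {node_id!r} is not an endpoint of edge {self.id!r}")


@dataclass
class Violation:
    code: str
    subject: str
    message: str


VIOLATION_CODES = (
    "not_a_tree",
    "ancestor_edge",
    "dangling_ref",
    "bad_geometry",
    "meta_without_original",
)


class CompoundGraph:
    """Active nodes/edges plus the registry of archived original edges.

    ``nodes`` and ``edges`` hold only *active* elements; content removed
    by a collapse lives in the collapsed compound's :class:`SubgraphStore`,
    and originals currently represented by a meta edge live in
    ``archived_originals`` (a graph-level registry, so nested collapses
    never duplicate them).
    """

    def __init__(self) -> None:
        self.nodes: dict[str, NodeRecord] = {}
        self.edges: dict[str, EdgeRecord] = {}
        self.archived_originals: dict[str, EdgeRecord] = {}
        self.highlight_active: bool = False

    # -- basic accessors -------------------------------------------------

    def node(self, node_id: str) -> NodeRecord:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node {node_id!r}") from None

    def edge(self, edge_id: str) -> EdgeRecord:
        try:
            return self.edges[edge_id]
        except KeyError:
            raise GraphError(f"unknown edge {edge_id!r}") from None

    def children(self, node_id: Optional[str]) -> list[NodeRecord]:
        """Active children of a compound (``None`` means the virtual root)."""
        return [n for n in self.nodes.values() if n.parent == node_id]

    def has_children(self, node_id: str) -> bool:
        return any(n.parent == node_id for n in self.nodes.values())

    def is_compound(self, node_id: str) -> bool:
        n = self.node(node_id)
        return n.collapsed or self.has_children(node_id)

    def ancestors(self, node_id: str) -> list[str]:
        """Parent chain from the node's parent up to (not including) the root."""
        chain: list[str] = []
        seen = {node_id}
        cur = self.node(node_id).parent
        while cur is not None:
            if cur in seen:
                raise GraphError(f"parent cycle through {cur!r}")
            seen.add(cur)
            chain.append(cur)
            cur = self.node(cur).parent
        return chain

    def is_ancestor(self, anc: str, node_id: str) -> bool:
        return anc in self.ancestors(node_id)

    def descendants(self, node_id: str) -> list[str]:
        """Active descendants in top-down order."""
        out: list[str] = []
        frontier = [node_id]
        while frontier:
            nxt: list[str] = []
            for n in self.nodes.values():
                if n.parent in frontier:
                    out.append(n.id)
                    nxt.append(n.id)
            frontier = nxt
        return out

    def incident_edges(self, node_id: str) -> list[EdgeRecord]:
        return [e for e in self.edges.values() if node_id in (e.source, e.target)]

    def visible_nodes(self) -> list[NodeRecord]:
        return [n for n in self.nodes.values() if not n.hidden]

    def visible_edges(self) -> list[EdgeRecord]:
        out = []
        for e in self.edges.values():
            if e.hidden:
                continue
            if self.nodes[e.source].hidden or self.nodes[e.target].hidden:
                continue
            out.append(e)
        return out

    def clone(self) -> "CompoundGraph":
        return copy.deepcopy(self)

    # -- geometry --------------------------------------------------------

    def refresh_compound_bounds(self) -> None:
        """Recompute derived geometry of expanded compounds, bottom-up.

        An expanded compound takes the bounding box of its visible
        children plus a fixed margin on each side; a collapsed compound
        keeps fixed proxy dimensions at its own center.  Compounds whose
        children are all hidden keep their current geometry.
        """
        order = sorted(
            (n for n in self.nodes.values() if self.has_children(n.id)),
            key=lambda n: -len(self.ancestors(n.id)),
        )
        for n in order:
            if n.collapsed:
                n.width = n.height = COLLAPSED_SIZE
                continue
            kids = [c for c in self.children(n.id) if not c.hidden]
            if not kids:
                continue
            x0 = min(c.x - c.width / 2 for c in kids) - COMPOUND_MARGIN
            x1 = max(c.x + c.width / 2 for c in kids) + COMPOUND_MARGIN
            y0 = min(c.y - c.height / 2 for c in kids) - COMPOUND_MARGIN
            y1 = max(c.y + c.height / 2 for c in kids) + COMPOUND_MARGIN
            n.center = ((x0 + x1) / 2, (y0 + y1) / 2)
            n.width = x1 - x0
            n.height = y1 - y0
        for n in self.nodes.values():
            if n.collapsed:
                n.width = n.height = COLLAPSED_SIZE


# -- construction --------------------------------------------------------


def build_graph(node_specs: Iterable[dict], edge_specs: Iterable[dict]) -> CompoundGraph:
    """Build and validate a compound graph from plain descriptors.

    Node descriptors carry ``id`` and optionally ``parent``, ``x``, ``y``,
    ``width``, ``height``, ``label``; edge descriptors carry ``id``
    (defaulted from the endpoints), ``source`` and ``target``.  Defaulted
    geometry is deterministic (a fixed-size box at the origin).
    """
    g = CompoundGraph()
    for spec in node_specs:
        nid = str(spec["id"])
        if nid in g.nodes:
            raise GraphError(f"duplicate node id {nid!r}")
        g.nodes[nid] = NodeRecord(
            id=nid,
            parent=spec.get("parent"),
            center=(float(spec.get("x", 0.0)), float(spec.get("y", 0.0))),
            width=float(spec.get("width", DEFAULT_NODE_SIZE)),
            height=float(spec.get("height", DEFAULT_NODE_SIZE)),
            label=spec.get("label"),
        )
    for n in g.nodes.values():
        if n.parent is not None and n.parent not in g.nodes:
            raise GraphError(f"unknown parent {n.parent!r} of node {n.id!r}")
    for n in g.nodes.values():
        g.ancestors(n.id)  # raises on parent cycles
    for spec in edge_specs:
        s, t = str(spec["source"]), str(spec["target"])
        eid = str(spec.get("id", f"{s}--{t}"))
        if eid in g.edges:
            raise GraphError(f"duplicate edge id {eid!r}")
        if s not in g.nodes or t not in g.nodes:
            raise GraphError(f"edge {eid!r} has unknown endpoint")
        if s == t or g.is_ancestor(s, t) or g.is_ancestor(t, s):
            raise GraphError(
                f"edge {eid!r} connects {s!r} to an ancestor/descendant {t!r}"
            )
        g.edges[eid] = EdgeRecord(id=eid, source=s, target=t)
    g.refresh_compound_bounds()
    return g


# -- structural queries --------------------------------------------------


def is_inter_graph_edge(graph: CompoundGraph, edge) -> bool:
    """True iff the edge's endpoints live in different owner graphs."""
    e = graph.edge(edge) if isinstance(edge, str) else graph.edge(edge.id)
    return graph.node(e.source).parent != graph.node(e.target).parent


def inclusion_level(graph: CompoundGraph, node_id: str) -> int:
    """Nesting depth: number of ancestors between the node and the root."""
    return len(graph.ancestors(node_id))


def top_container_within(graph: CompoundGraph, c: str, s: str) -> str:
    """The child of compound ``c`` on the inclusion path down to ``s``.

    Returns ``s`` itself when ``s`` is immediately inside ``c``.
    """
    graph.node(c)
    prev = s
    for anc in graph.ancestors(s):
        if anc == c:
            return prev
        prev = anc
    raise GraphError(f"{s!r} is not a descendant of {c!r}")


def neighbors_within_distance(
    graph: CompoundGraph, node_id: str, k: int
) -> dict[str, int]:
    """Visible nodes within shortest-path distance ``k``, mapped to distance.

    Distances are measured over visible active edges (meta edges count);
    the start node itself is excluded.
    """
    start = graph.node(node_id)
    if start.hidden:
        raise GraphError(f"node {node_id!r} is hidden")
    adj: dict[str, set[str]] = {}
    for e in graph.visible_edges():
        adj.setdefault(e.source, set()).add(e.target)
        adj.setdefault(e.target, set()).add(e.source)
    dist = {node_id: 0}
    q = deque([node_id])
    while q:
        cur = q.popleft()
        if dist[cur] >= k:
            continue
        for nb in adj.get(cur, ()):
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                q.append(nb)
    dist.pop(node_id)
    return dist


# -- validation ----------------------------------------------------------


def _all_node_records(graph: CompoundGraph):
    """Active node records plus every record archived in a nested store."""
    out = dict(graph.nodes)
    stack = [n.store for n in graph.nodes.values() if n.store is not None]
    while stack:
        store = stack.pop()
        for n in store.nodes:
            out[n.id] = n
            if n.store is not None:
                stack.append(n.store)
    return out


def _all_meta_edges(graph: CompoundGraph) -> list[EdgeRecord]:
    out = [e for e in graph.edges.values() if e.kind == META]
    stack = [n.store for n in graph.nodes.values() if n.store is not None]
    while stack:
        store = stack.pop()
        out.extend(e for e in store.edges if e.kind == META)
        for n in store.nodes:
            if n.store is not None:
                stack.append(n.store)
    return out


def validate(graph: CompoundGraph) -> list[Violation]:
    """Check every structural invariant; return violations, never raise."""
    out: list[Violation] = []

    for n in graph.nodes.values():
        if n.parent is not None and n.parent not in graph.nodes:
            out.append(Violation("dangling_ref", n.id, f"parent {n.parent!r} unknown"))
    # parent cycles: follow chains with a visited set
    for n in graph.nodes.values():
        seen = set()
        cur: Optional[str] = n.id
        while cur is not None:
            if cur in seen:
                out.append(Violation("not_a_tree", n.id, "parent chain has a cycle"))
                break
            seen.add(cur)
            nxt = graph.nodes.get(cur)
            cur = nxt.parent if nxt is not None else None

    cyclic = {v.subject for v in out if v.code == "not_a_tree"}

    def safe_ancestors(nid: str) -> list[str]:
        chain, seen, cur = [], {nid}, graph.nodes[nid].parent
        while cur is not None and cur not in seen and cur in graph.nodes:
            seen.add(cur)
            chain.append(cur)
            cur = graph.nodes[cur].parent
        return chain

    for n in graph.nodes.values():
        if not (n.width > 0 and n.height > 0) or not all(
            math.isfinite(v) for v in (*n.center, n.width, n.height)
        ):
            out.append(Violation("bad_geometry", n.id, "non-positive or non-finite geometry"))
        if n.collapsed != (n.store is not None):
            out.append(
                Violation(
                    "dangling_ref",
                    n.id,
                    "collapsed flag and store presence disagree",
                )
            )
        if n.store is not None:
            for a in n.store.nodes:
                if not all(math.isfinite(v) for v in a.center):
                    out.append(Violation("bad_geometry", a.id, "non-finite stored position"))
                if a.id in graph.nodes:
                    out.append(
                        Violation("dangling_ref", a.id, "archived node also active")
                    )

    for e in graph.edges.values():
        if e.source not in graph.nodes or e.target not in graph.nodes:
            out.append(Violation("dangling_ref", e.id, "endpoint unknown"))
            continue
        if e.source == e.target:
            out.append(Violation("ancestor_edge", e.id, "self loop"))
            continue
        if e.source not in cyclic and e.target not in cyclic:
            if e.source in safe_ancestors(e.target) or e.target in safe_ancestors(e.source):
                out.append(
                    Violation("ancestor_edge", e.id, "connects a node to an ancestor")
                )

    metas = _all_meta_edges(graph)
    ref_counts: dict[str, int] = {}
    for m in metas:
        if m.original_ref is None or m.original_ref not in graph.archived_originals:
            out.append(
                Violation("meta_without_original", m.id, "original_ref does not resolve")
            )
        else:
            ref_counts[m.original_ref] = ref_counts.get(m.original_ref, 0) + 1
    for oid in graph.archived_originals:
        if ref_counts.get(oid, 0) != 1:
            out.append(
                Violation(
                    "dangling_ref",
                    oid,
                    f"archived original referenced by {ref_counts.get(oid, 0)} meta edges",
                )
            )
    for e in graph.edges.values():
        if e.kind == ORIGINAL and e.original_ref is not None:
            out.append(
                Violation("meta_without_original", e.id, "original edge carries original_ref")
            )

    out.sort(key=lambda v: (v.code, v.subject))
    return out
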