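"""Hide/show of arbitrary element sets and highlight management.

Hiding keeps coordinates and simply flags elements invisible; showing
brings nodes back *level by level*, placing each revealed node in the
least crowded quadrant around an already-visible anchor (+3 per
first-degree neighbor, +1 per second-degree neighbor, lowest total
wins), roughly one ideal edge length away, with a few incremental
layout iterations interleaved between levels.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import layout as _layout
from .core_model import CompoundGraph, GraphError, neighbors_within_distance
from .expand_collapse import Options, OpReport

QUADRANTS = ("I", "II", "III", "IV")
_BISECTORS = {"I": 45.0, "II": 135.0, "III": 225.0, "IV": 315.0}

SCORE_FIRST_DEGREE = 3
SCORE_SECOND_DEGREE = 1


@dataclass
class PlacementParams:
    ideal_edge_length: float = 50.0
    radial_jitter: float = 0.1  # fraction of ideal_edge_length
    angular_jitter: float = 30.0  # degrees around the quadrant bisector
    iterations_per_level: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ideal_edge_length <= 0:
            raise ValueError("ideal_edge_length must be positive")
        if self.iterations_per_level < 1:
            raise ValueError("iterations_per_level must be >= 1")


@dataclass
class QuadrantScoreTable:
    scores: dict[str, int] = field(default_factory=lambda: dict.fromkeys(QUADRANTS, 0))
    score_first_degree: int = SCORE_FIRST_DEGREE
    score_second_degree: int = SCORE_SECOND_DEGREE
    chosen: str = "I"


def _classify_quadrant(dx: float, dy: float) -> str:
    """Axis-aligned quadrant of (dx, dy), y-up; boundary points count
    toward the lower-numbered adjacent quadrant."""
    if dx == 0.0 and dy == 0.0:
        return "I"
    if dx == 0.0:
        return "I" if dy > 0 else "III"
    if dy == 0.0:
        return "I" if dx > 0 else "II"
    if dx > 0:
        return "I" if dy > 0 else "IV"
    return "II" if dy > 0 else "III"


def quadrant_scores(graph: CompoundGraph, anchor: str) -> QuadrantScoreTable:
    """Crowding of each quadrant around a visible anchor node."""
    a = graph.node(anchor)
    if a.hidden:
        raise GraphError(f"anchor {anchor!r} is hidden")
    table = QuadrantScoreTable()
    for nid, dist in neighbors_within_distance(graph, anchor, 2).items():
        n = graph.nodes[nid]
        if n.hidden:
            continue
        q = _classify_quadrant(n.x - a.x, n.y - a.y)
        table.scores[q] += SCORE_FIRST_DEGREE if dist == 1 else SCORE_SECOND_DEGREE
    table.chosen = min(QUADRANTS, key=lambda q: (table.scores[q], QUADRANTS.index(q)))
    return table


def _place(graph, anchor, new_nodes, params, rng) -> dict[str, tuple[float, float]]:
    a = graph.node(anchor)
    chosen = quadrant_scores(graph, anchor).chosen
    bisector = _BISECTORS[chosen]
    out: dict[str, tuple[float, float]] = {}
    for nid in sorted(new_nodes):
        r = params.ideal_edge_length * (
            1.0 + rng.uniform(-params.radial_jitter, params.radial_jitter)
        )
        ang = math.radians(
            bisector + rng.uniform(-params.angular_jitter, params.angular_jitter)
        )
        out[nid] = (a.x + r * math.cos(ang), a.y + r * math.sin(ang))
    return out


def place_unhidden_level(
    graph: CompoundGraph,
    anchor: str,
    new_nodes: Iterable[str],
    params: Optional[PlacementParams] = None,
) -> dict[str, tuple[float, float]]:
    """Positions for nodes being revealed around an anchor.

    Each node lands roughly one ideal edge length from the anchor, at a
    jittered angle around the bisector of the anchor's least crowded
    quadrant.  Draws consume a seeded generator in sorted-id order.
    """
    params = params or PlacementParams()
    new_nodes = list(new_nodes)
    for nid in new_nodes:
        n = graph.node(nid)
        if not any(
            nid in (e.source, e.target) and e.other(nid) == anchor
            for e in graph.edges.values()
        ):
            raise GraphError(f"{nid!r} is not adjacent to anchor {anchor!r}")
    rng = np.random.default_rng(params.seed)
    placed = _place(graph, anchor, new_nodes, params, rng)
    for nid, center in placed.items():
        graph.nodes[nid].center = center
    return placed


# -- hide / show ---------------------------------------------------------


def _resolve(graph: CompoundGraph, element_id: str):
    if element_id in graph.nodes:
        return graph.nodes[element_id]
    if element_id in graph.edges:
        return graph.edges[element_id]
    raise GraphError(f"unknown element {element_id!r}")


def hide(
    graph: CompoundGraph, elements: Iterable[str], options: Optional[Options] = None
) -> OpReport:
    """Flag the listed elements (and edges incident to listed nodes) hidden."""
    options = options or Options()
    report = OpReport(operation="hide", subjects=sorted(set(elements)))
    for eid in report.subjects:
        _resolve(graph, eid)
    newly: list[str] = []
    for eid in report.subjects:
        el = _resolve(graph, eid)
        if not el.hidden:
            el.hidden = True
            newly.append(eid)
        if eid in graph.nodes:
            for e in graph.incident_edges(eid):
                if not e.hidden:
                    e.hidden = True
                    newly.append(e.id)
    report.hidden_elements = newly
    graph.refresh_compound_bounds()
    if newly and options.layout_after_op == "incremental":
        params = options.layout_params or _layout.LayoutParams()
        report.layout_iterations += _layout.apply_incremental(graph, params)
    return report


def _bfs_levels(
    graph: CompoundGraph, to_show_nodes: set[str], reveal_edges: set[str]
) -> dict[str, Optional[int]]:
    """Distance of each node-to-show from the visible frontier, measured
    over edges being revealed plus currently visible edges."""
    adj: dict[str, set[str]] = {}
    usable = {e.id for e in graph.visible_edges()} | reveal_edges
    for eid in usable:
        e = graph.edges[eid]
        adj.setdefault(e.source, set()).add(e.target)
        adj.setdefault(e.target, set()).add(e.source)
    dist: dict[str, int] = {}
    q: deque[str] = deque()
    for n in graph.visible_nodes():
        dist[n.id] = 0
        q.append(n.id)
    while q:
        cur = q.popleft()
        for nb in adj.get(cur, ()):
            if nb not in dist and (nb in to_show_nodes or not graph.nodes[nb].hidden):
                dist[nb] = dist[cur] + 1
                q.append(nb)
    return {nid: dist.get(nid) for nid in to_show_nodes}


def show(
    graph: CompoundGraph,
    elements: Iterable[str],
    options: Optional[Options] = None,
    params: Optional[PlacementParams] = None,
) -> OpReport:
    """Reveal hidden elements level by level, interleaved with layout.

    Nodes reachable from the visible part are placed around their
    visible anchors via the quadrant heuristic, one BFS level at a time,
    with ``iterations_per_level`` incremental layout iterations between
    levels; unreachable nodes are restored at their stored coordinates.
    """
    options = options or Options()
    params = params or PlacementParams()
    report = OpReport(operation="show", subjects=sorted(set(elements)))
    for eid in report.subjects:
        _resolve(graph, eid)

    node_set = {i for i in report.subjects if i in graph.nodes and graph.nodes[i].hidden}
    edge_set = {i for i in report.subjects if i in graph.edges and graph.edges[i].hidden}
    for nid in node_set:
        for e in graph.incident_edges(nid):
            if e.hidden:
                edge_set.add(e.id)

    levels = _bfs_levels(graph, node_set, edge_set)
    rng = np.random.default_rng(params.seed)
    lay = _layout.LayoutParams(
        ideal_edge_length=params.ideal_edge_length,
        max_iterations=params.iterations_per_level,
        convergence_threshold_factor=0.0,  # run the full per-level budget
        incremental=True,
    )

    def reveal_ready_edges() -> None:
        for eid in sorted(edge_set):
            e = graph.edges[eid]
            if e.hidden and not graph.nodes[e.source].hidden and not graph.nodes[e.target].hidden:
                e.hidden = False
                report.shown_elements.append(eid)

    depth = 1
    remaining = {nid for nid, lv in levels.items() if lv is not None}
    while any(levels[nid] == depth for nid in remaining):
        level_nodes = sorted(nid for nid in remaining if levels[nid] == depth)
        # group by anchor: the smallest-id visible neighbor over edges being revealed
        groups: dict[str, list[str]] = {}
        for nid in level_nodes:
            anchors = sorted(
                e.other(nid)
                for e in graph.incident_edges(nid)
                if e.id in edge_set or not e.hidden
                if not graph.nodes[e.other(nid)].hidden
            )
            if not anchors:  # anchor itself unreachable this level; defer
                levels[nid] = depth + 1
                continue
            groups.setdefault(anchors[0], []).append(nid)
        for anchor in sorted(groups):
            placed = _place(graph, anchor, groups[anchor], params, rng)
            for nid, center in placed.items():
                n = graph.nodes[nid]
                n.center = center
                n.hidden = False
                report.shown_elements.append(nid)
                remaining.discard(nid)
        reveal_ready_edges()
        graph.refresh_compound_bounds()
        if groups:
            report.levels.append(sorted(x for g in groups.values() for x in g))
            if options.layout_after_op == "incremental":
                report.layout_iterations += _layout.apply_incremental(graph, lay)
        elif level_nodes:
            break  # nothing placeable; remaining nodes fall back to stored coords
        depth += 1

    # nodes with no path to the visible part: restore at stored coordinates
    stranded = sorted(nid for nid in node_set if graph.nodes[nid].hidden)
    for nid in stranded:
        graph.nodes[nid].hidden = False
        report.shown_elements.append(nid)
    if stranded:
        report.levels.append(stranded)
    reveal_ready_edges()
    graph.refresh_compound_bounds()
    return report


# -- highlight -----------------------------------------------------------


def _with_neighbors(graph: CompoundGraph, elements: set[str]) -> set[str]:
    out = set(elements)
    for eid in elements:
        if eid in graph.nodes:
            for e in graph.visible_edges():
                if eid in (e.source, e.target):
                    out.add(e.id)
                    out.add(e.other(eid))
    return out


def set_highlight(
    graph: CompoundGraph, elements: Iterable[str], mode: str = "highlight"
) -> OpReport:
    """Update highlight flags; the first highlight dims everything else."""
    modes = (
        "highlight",
        "unhighlight",
        "highlight_neighbors",
        "unhighlight_neighbors",
        "remove_all",
    )
    if mode not in modes:
        raise GraphError(f"unknown highlight mode {mode!r}")
    ids = set(elements)
    for eid in ids:
        _resolve(graph, eid)
    report = OpReport(operation=f"highlight:{mode}", subjects=sorted(ids))

    if mode == "remove_all":
        targets = ids or ({n.id for n in graph.nodes.values()} | set(graph.edges))
        for eid in targets:
            _resolve(graph, eid).highlighted = False
        if not ids:
            graph.highlight_active = False
        return report

    if mode in ("highlight_neighbors", "unhighlight_neighbors"):
        ids = _with_neighbors(graph, ids)
    flag = mode.startswith("highlight")
    if flag:
        graph.highlight_active = True
    for eid in sorted(ids):
        _resolve(graph, eid).highlighted = flag
    return report
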