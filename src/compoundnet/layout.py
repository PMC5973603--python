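"""Force-directed layout for compound graphs, plus fisheye adjustment.

The force model is a spring embedder: edges pull their endpoints toward
an ideal length, nodes repel with an inverse-square force on the gap
between their boxes, and members of a compound feel a constant gravity
toward the compound's center.  Per-iteration displacement is capped by a
geometrically cooled *temperature*; an incremental run starts from the
current coordinates with a low initial temperature so the drawing (and
the user's mental map) changes gently, while a static run starts hot
from seeded random positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import CompoundGraph, GraphError, inclusion_level


@dataclass
class LayoutParams:
    ideal_edge_length: float = 50.0
    spring_constant: float = 0.45
    repulsion_constant: float = 4500.0
    gravity_constant: float = 0.25
    nesting_length_factor: float = 0.2
    initial_temperature_static_factor: float = 3.0  # times ideal_edge_length
    initial_temperature_incremental_factor: float = 0.3
    cooling_factor: float = 0.95
    max_iterations: int = 500
    convergence_threshold_factor: float = 0.01  # times ideal_edge_length
    incremental: bool = False
    seed: int = 0

    @property
    def initial_temperature_static(self) -> float:
        return self.initial_temperature_static_factor * self.ideal_edge_length

    @property
    def initial_temperature_incremental(self) -> float:
        return self.initial_temperature_incremental_factor * self.ideal_edge_length

    @property
    def convergence_threshold(self) -> float:
        return self.convergence_threshold_factor * self.ideal_edge_length

    def __post_init__(self) -> None:
        if self.ideal_edge_length <= 0:
            raise ValueError("ideal_edge_length must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must be in (0, 1)")


def _particles(graph: CompoundGraph) -> list[str]:
    """Visible nodes with no visible children: the movable point masses."""
    vis = {n.id for n in graph.visible_nodes()}
    has_vis_child = {n.parent for n in graph.visible_nodes() if n.parent is not None}
    return sorted(i for i in vis if i not in has_vis_child)


def _leaf_set(graph: CompoundGraph, node_id: str, particles: set[str]) -> list[str]:
    """Particles an edge endpoint resolves to (itself, or its visible leaves)."""
    if node_id in particles:
        return [node_id]
    out = [d for d in graph.descendants(node_id) if d in particles]
    return out or []


def _pair_gap(pos: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Pairwise distance between box boundaries, clamped below at 1."""
    dx = np.abs(pos[:, 0, None] - pos[None, :, 0]) - (half[:, 0, None] + half[None, :, 0])
    dy = np.abs(pos[:, 1, None] - pos[None, :, 1]) - (half[:, 1, None] + half[None, :, 1])
    gap = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
    return np.maximum(gap, 1.0)


def _excluded_pairs(graph: CompoundGraph, ids: list[str]) -> np.ndarray:
    n = len(ids)
    excl = np.zeros((n, n), dtype=bool)
    anc = {i: set(graph.ancestors(i)) for i in ids}
    for a, ia in enumerate(ids):
        for b in range(a + 1, n):
            ib = ids[b]
            if ib in anc[ia] or ia in anc[ib]:
                excl[a, b] = excl[b, a] = True
    np.fill_diagonal(excl, True)
    return excl


def force_layout(
    graph: CompoundGraph, params: Optional[LayoutParams] = None
) -> dict[str, tuple[float, float]]:
    """Run the spring embedder; mutates node centers, returns final centers.

    Static mode seeds random initial positions; incremental mode starts
    from the current (finite) coordinates and a low temperature.
    """
    params = params or LayoutParams()
    ids = _particles(graph)
    if len(ids) <= 1:
        graph.refresh_compound_bounds()
        return {n.id: n.center for n in graph.nodes.values()}

    if params.incremental:
        for i in ids:
            n = graph.nodes[i]
            if not all(math.isfinite(v) for v in n.center):
                raise GraphError(f"non-finite coordinates on {i!r} in incremental mode")
        t0 = params.initial_temperature_incremental
    else:
        rng = np.random.default_rng(params.seed)
        side = params.ideal_edge_length * math.sqrt(len(ids))
        for i in ids:
            graph.nodes[i].center = tuple(rng.uniform(0.0, side, size=2))
        t0 = params.initial_temperature_static
    graph.refresh_compound_bounds()

    idx = {i: k for k, i in enumerate(ids)}
    pset = set(ids)
    half = np.array(
        [[graph.nodes[i].width / 2, graph.nodes[i].height / 2] for i in ids]
    )
    excl = _excluded_pairs(graph, ids)
    levels = {n.id: inclusion_level(graph, n.id) for n in graph.nodes.values()}

    # endpoint -> (particle indices, weight) for spring distribution
    edge_terms = []
    for e in graph.visible_edges():
        le = params.ideal_edge_length * (
            1.0 + params.nesting_length_factor * abs(levels[e.source] - levels[e.target])
        )
        s_leaves = [idx[i] for i in _leaf_set(graph, e.source, pset)]
        t_leaves = [idx[i] for i in _leaf_set(graph, e.target, pset)]
        if s_leaves and t_leaves:
            edge_terms.append((e.source, e.target, le, s_leaves, t_leaves))

    k_s = params.spring_constant
    k_r = params.repulsion_constant
    k_g = params.gravity_constant

    temp = t0
    iterations = 0
    for it in range(params.max_iterations):
        iterations = it + 1
        pos = np.array([graph.nodes[i].center for i in ids])
        forces = np.zeros_like(pos)

        # springs (computed on endpoint node centers, applied to leaf particles)
        centers = {n.id: np.array(n.center) for n in graph.nodes.values()}
        for s, t, le, s_leaves, t_leaves in edge_terms:
            delta = centers[t] - centers[s]
            d = float(np.hypot(*delta))
            if d < 1e-12:
                continue
            f = k_s * (d - le) * delta / d
            forces[s_leaves] += f / len(s_leaves)
            forces[t_leaves] -= f / len(t_leaves)

        # inverse-square repulsion on box gaps
        gap = _pair_gap(pos, half)
        mag = k_r / gap**2
        mag[excl] = 0.0
        dvec = pos[:, None, :] - pos[None, :, :]
        dist = np.maximum(np.hypot(dvec[..., 0], dvec[..., 1]), 1e-9)
        forces += np.einsum("ij,ijk->ik", mag / dist, dvec)

        # gravity toward the owning compound's center
        for i in ids:
            p = graph.nodes[i].parent
            if p is not None:
                delta = np.array(graph.nodes[p].center) - np.array(graph.nodes[i].center)
                d = float(np.hypot(*delta))
                if d > 1e-12:
                    forces[idx[i]] += k_g * delta / d

        norms = np.maximum(np.hypot(forces[:, 0], forces[:, 1]), 1e-12)
        step = np.minimum(norms, temp)
        disp = forces / norms[:, None] * step[:, None]
        for i in ids:
            n = graph.nodes[i]
            d = disp[idx[i]]
            n.center = (n.x + float(d[0]), n.y + float(d[1]))
        graph.refresh_compound_bounds()

        temp *= params.cooling_factor
        if float(np.mean(step)) < params.convergence_threshold:
            break

    graph._last_layout_iterations = iterations
    return {n.id: n.center for n in graph.nodes.values()}


def apply_incremental(graph: CompoundGraph, params: Optional[LayoutParams] = None) -> int:
    """Low-temperature polish from current coordinates; returns iterations."""
    params = params or LayoutParams()
    if len(_particles(graph)) <= 1:
        return 0
    p = LayoutParams(**{**params.__dict__, "incremental": True})
    force_layout(graph, p)
    return getattr(graph, "_last_layout_iterations", 0)


def drawing_energy(graph: CompoundGraph, params: Optional[LayoutParams] = None) -> float:
    """Spring potential plus repulsion potential of the visible drawing."""
    params = params or LayoutParams()
    ids = _particles(graph)
    levels = {n.id: inclusion_level(graph, n.id) for n in graph.nodes.values()}
    energy = 0.0
    for e in graph.visible_edges():
        le = params.ideal_edge_length * (
            1.0 + params.nesting_length_factor * abs(levels[e.source] - levels[e.target])
        )
        s, t = graph.nodes[e.source], graph.nodes[e.target]
        d = math.hypot(t.x - s.x, t.y - s.y)
        energy += 0.5 * params.spring_constant * (d - le) ** 2
    if len(ids) > 1:
        pos = np.array([graph.nodes[i].center for i in ids])
        half = np.array(
            [[graph.nodes[i].width / 2, graph.nodes[i].height / 2] for i in ids]
        )
        gap = _pair_gap(pos, half)
        mask = ~_excluded_pairs(graph, ids)
        energy += float(np.sum(np.triu(mask, 1) * (params.repulsion_constant / gap)))
    return energy


def fisheye_adjust(
    graph: CompoundGraph, anchor: str, new_width: float, new_height: float
) -> dict[str, tuple[float, float]]:
    """Push surrounding nodes outward for an anchor growing to a new size.

    The translation budget is half the change in each extent; a node at
    angle theta from the anchor's center moves by (T_x*cos(theta),
    T_y*sin(theta)), so purely horizontal neighbors move by exactly T_x
    and purely vertical ones by exactly T_y.  Signs of the relative
    coordinates are preserved, so the drawing's topology survives.
    Shrinking (negative budget) pulls nodes back in.
    """
    a = graph.node(anchor)
    if a.hidden:
        raise GraphError(f"anchor {anchor!r} is hidden")
    if new_width <= 0 or new_height <= 0:
        raise GraphError("new extents must be positive")
    t_x = (new_width - a.width) / 2.0
    t_y = (new_height - a.height) / 2.0
    ax, ay = a.center
    anc = set(graph.ancestors(anchor))
    desc = set(graph.descendants(anchor))
    for n in graph.nodes.values():
        if n.id == anchor or n.hidden or n.id in anc or n.id in desc:
            continue
        dx, dy = n.x - ax, n.y - ay
        if dx == 0.0 and dy == 0.0:
            continue
        theta = math.atan2(dy, dx)
        n.center = (n.x + t_x * math.cos(theta), n.y + t_y * math.sin(theta))
    a.width, a.height = new_width, new_height
    a.center = (ax, ay)
    graph.refresh_compound_bounds()
    return {n.id: n.center for n in graph.nodes.values()}
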