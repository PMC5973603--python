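"""Deterministic fixtures and seeded random compound-graph generators.

Everything any test or demo needs is generated here: the small worked
example with two nested compounds, seeded random nested graphs with
controllable size/depth/density, and plain node grids for the fisheye
tests.  No external data is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import CompoundGraph, GraphError, build_graph


def worked_example_graph() -> CompoundGraph:
    """The worked two-compound example.

    Six nodes: compound ``c1`` at the root containing ``a``, ``b``,
    ``d`` and compound ``c2``, which contains ``e``.  Three edges:
    ``{a,b}``, ``{b,d}`` and the single inter-graph edge ``{d,e}``.
    Geometry is a fixed, deterministic layout.
    """
    nodes = [
        {"id": "c1"},
        {"id": "c2", "parent": "c1"},
        {"id": "a", "parent": "c1", "x": -80.0, "y": 40.0},
        {"id": "b", "parent": "c1", "x": 0.0, "y": 40.0},
        {"id": "d", "parent": "c1", "x": 80.0, "y": 40.0},
        {"id": "e", "parent": "c2", "x": 80.0, "y": -60.0},
    ]
    edges = [
        {"id": "a--b", "source": "a", "target": "b"},
        {"id": "b--d", "source": "b", "target": "d"},
        {"id": "d--e", "source": "d", "target": "e"},
    ]
    return build_graph(nodes, edges)


@dataclass
class GeneratorParams:
    n_leaf_nodes: int = 20
    n_compounds: int = 3
    max_depth: int = 3
    edge_density: float = 1.2  # expected edges per node
    p_intergraph: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaf_nodes < 0 or self.n_compounds < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.p_intergraph <= 1.0):
            raise ValueError("p_intergraph must be a probability")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def generate_compound_graph(params: GeneratorParams) -> CompoundGraph:
    """Seeded random nested graph.

    The inclusion tree is built first (random recursive attachment
    bounded by ``max_depth``), then edges are sampled between leaf
    pairs: with probability ``p_intergraph`` the endpoints are drawn
    from different owners, otherwise from the same owner.  Pure
    function of the seed.
    """
    if params.p_intergraph > 0 and params.n_compounds == 0 and params.n_leaf_nodes > 0:
        raise GraphError("p_intergraph > 0 requires at least one compound")
    rng = np.random.default_rng(params.seed)

    node_specs: list[dict] = []
    compound_ids: list[str] = []
    depth: dict[str | None, int] = {None: 0}
    for i in range(params.n_compounds):
        cid = f"c{i}"
        shallow = [p for p in [None, *compound_ids] if depth[p] < params.max_depth - 1]
        parent = shallow[int(rng.integers(len(shallow)))] if shallow else None
        depth[cid] = depth[parent] + 1
        node_specs.append({"id": cid, "parent": parent})
        compound_ids.append(cid)

    leaf_ids: list[str] = []
    owners = [None, *compound_ids]
    side = 60.0 * max(1.0, np.sqrt(params.n_leaf_nodes))
    for i in range(params.n_leaf_nodes):
        nid = f"n{i}"
        parent = owners[int(rng.integers(len(owners)))]
        x, y = rng.uniform(0.0, side, size=2)
        node_specs.append({"id": nid, "parent": parent, "x": float(x), "y": float(y)})
        leaf_ids.append(nid)

    owner_of = {s["id"]: s.get("parent") for s in node_specs}
    edge_specs: list[dict] = []
    seen: set[frozenset] = set()
    n_edges = int(round(params.edge_density * params.n_leaf_nodes))
    if len(leaf_ids) >= 2:
        for _ in range(n_edges):
            # decide inter vs intra first, then rejection-sample a matching
            # pair, so the realized fraction tracks p_intergraph
            want_inter = rng.random() < params.p_intergraph
            for _ in range(200):
                u, v = (leaf_ids[int(k)] for k in rng.integers(len(leaf_ids), size=2))
                if u == v or frozenset((u, v)) in seen:
                    continue
                if (owner_of[u] != owner_of[v]) != want_inter:
                    continue
                seen.add(frozenset((u, v)))
                edge_specs.append({"id": f"{u}--{v}", "source": u, "target": v})
                break

    return build_graph(node_specs, edge_specs)


def generate_grid_graph(rows: int, cols: int, spacing: float = 50.0) -> CompoundGraph:
    """Edge-free lattice of parentless nodes, for fisheye tests."""
    if rows < 1 or cols < 1:
        raise GraphError("grid dimensions must be positive")
    nodes = [
        {"id": f"g{r}_{c}", "x": c * spacing, "y": r * spacing}
        for r in range(rows)
        for c in range(cols)
    ]
    return build_graph(nodes, [])
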