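"""Readers/writers for nested GraphML and a JSON elements dialect, plus
an SVG renderer with expand/collapse cues.

GraphML encodes the inclusion tree with the standard nested ``<graph>``
element under each compound ``<node>``; geometry and state flags are
data keys.  Meta edges carry their original-edge pointer, and archived
content (collapsed stores, originals represented by meta edges) is
serialized as JSON blobs in dedicated data sections so collapse state
survives a round trip exactly.  Output is deterministic: a
write-read-write cycle is byte identical.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from typing import Optional

from .core_model import (
    META,
    CompoundGraph,
    EdgeRecord,
    GraphError,
    NodeRecord,
    SubgraphStore,
    inclusion_level,
    validate,
)
from .expand_collapse import Options, node_op_state

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

_NODE_KEYS = [
    ("x", "double"),
    ("y", "double"),
    ("w", "double"),
    ("h", "double"),
    ("hidden", "boolean"),
    ("highlighted", "boolean"),
    ("collapsed", "boolean"),
    ("label", "string"),
    ("store", "string"),
    ("extra", "string"),
]
_EDGE_KEYS = [
    ("kind", "string"),
    ("original_ref", "string"),
    ("hidden", "boolean"),
    ("highlighted", "boolean"),
    ("extra", "string"),
]
_GRAPH_KEYS = [("archived_originals", "string"), ("highlight_active", "boolean")]


# -- JSON encoding of records (shared by both formats) --------------------


def _edge_to_obj(e: EdgeRecord) -> dict:
    obj: dict = {"id": e.id, "source": e.source, "target": e.target, "kind": e.kind}
    if e.original_ref is not None:
        obj["original_ref"] = e.original_ref
    if e.hidden:
        obj["hidden"] = True
    if e.highlighted:
        obj["highlighted"] = True
    if e.extra:
        obj["extra"] = e.extra
    return obj


def _edge_from_obj(obj: dict) -> EdgeRecord:
    return EdgeRecord(
        id=obj["id"],
        source=obj["source"],
        target=obj["target"],
        kind=obj.get("kind", "original"),
        original_ref=obj.get("original_ref"),
        hidden=bool(obj.get("hidden", False)),
        highlighted=bool(obj.get("highlighted", False)),
        extra=obj.get("extra", {}),
    )


def _node_to_obj(n: NodeRecord) -> dict:
    obj: dict = {
        "id": n.id,
        "parent": n.parent,
        "x": n.x,
        "y": n.y,
        "width": n.width,
        "height": n.height,
    }
    if n.hidden:
        obj["hidden"] = True
    if n.highlighted:
        obj["highlighted"] = True
    if n.collapsed:
        obj["collapsed"] = True
    if n.label is not None:
        obj["label"] = n.label
    if n.store is not None:
        obj["store"] = _store_to_obj(n.store)
    if n.extra:
        obj["extra"] = n.extra
    return obj


def _node_from_obj(obj: dict) -> NodeRecord:
    store = obj.get("store")
    return NodeRecord(
        id=obj["id"],
        parent=obj.get("parent"),
        center=(float(obj.get("x", 0.0)), float(obj.get("y", 0.0))),
        width=float(obj.get("width", 30.0)),
        height=float(obj.get("height", 30.0)),
        hidden=bool(obj.get("hidden", False)),
        highlighted=bool(obj.get("highlighted", False)),
        collapsed=bool(obj.get("collapsed", False)),
        store=_store_from_obj(store) if store is not None else None,
        label=obj.get("label"),
        extra=obj.get("extra", {}),
    )


def _store_to_obj(store: SubgraphStore) -> dict:
    return {
        "nodes": [_node_to_obj(n) for n in store.nodes],
        "edges": [_edge_to_obj(e) for e in store.edges],
    }


def _store_from_obj(obj: dict) -> SubgraphStore:
    return SubgraphStore(
        nodes=[_node_from_obj(o) for o in obj.get("nodes", [])],
        edges=[_edge_from_obj(o) for o in obj.get("edges", [])],
    )


def _check(graph: CompoundGraph) -> CompoundGraph:
    violations = validate(graph)
    if violations:
        detail = "; ".join(f"{v.code}({v.subject}): {v.message}" for v in violations)
        raise GraphError(f"invalid graph: {detail}")
    return graph


# -- GraphML --------------------------------------------------------------


def write_graphml(graph: CompoundGraph, path: str) -> None:
    ET.register_namespace("", GRAPHML_NS)
    root = ET.Element(f"{{{GRAPHML_NS}}}graphml")
    for domain, keys in (("node", _NODE_KEYS), ("edge", _EDGE_KEYS), ("graph", _GRAPH_KEYS)):
        for name, typ in keys:
            ET.SubElement(
                root,
                f"{{{GRAPHML_NS}}}key",
                {"id": f"{domain[0]}_{name}", "for": domain, "attr.name": name, "attr.type": typ},
            )
    g_el = ET.SubElement(
        root, f"{{{GRAPHML_NS}}}graph", {"id": "G", "edgedefault": "undirected"}
    )
    archived = [
        _edge_to_obj(graph.archived_originals[k]) for k in sorted(graph.archived_originals)
    ]
    _data(g_el, "g_archived_originals", json.dumps(archived, sort_keys=True))
    _data(g_el, "g_highlight_active", "true" if graph.highlight_active else "false")

    def emit(parent_el: ET.Element, owner: Optional[str]) -> None:
        for n in sorted(graph.children(owner), key=lambda r: r.id):
            n_el = ET.SubElement(parent_el, f"{{{GRAPHML_NS}}}node", {"id": n.id})
            _data(n_el, "n_x", repr(n.x))
            _data(n_el, "n_y", repr(n.y))
            _data(n_el, "n_w", repr(n.width))
            _data(n_el, "n_h", repr(n.height))
            if n.hidden:
                _data(n_el, "n_hidden", "true")
            if n.highlighted:
                _data(n_el, "n_highlighted", "true")
            if n.collapsed:
                _data(n_el, "n_collapsed", "true")
            if n.label is not None:
                _data(n_el, "n_label", n.label)
            if n.store is not None:
                _data(n_el, "n_store", json.dumps(_store_to_obj(n.store), sort_keys=True))
            if n.extra:
                _data(n_el, "n_extra", json.dumps(n.extra, sort_keys=True))
            if graph.has_children(n.id):
                sub = ET.SubElement(
                    n_el,
                    f"{{{GRAPHML_NS}}}graph",
                    {"id": f"{n.id}:sub", "edgedefault": "undirected"},
                )
                emit(sub, n.id)

    emit(g_el, None)
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        e_el = ET.SubElement(
            g_el,
            f"{{{GRAPHML_NS}}}edge",
            {"id": e.id, "source": e.source, "target": e.target},
        )
        _data(e_el, "e_kind", e.kind)
        if e.original_ref is not None:
            _data(e_el, "e_original_ref", e.original_ref)
        if e.hidden:
            _data(e_el, "e_hidden", "true")
        if e.highlighted:
            _data(e_el, "e_highlighted", "true")
        if e.extra:
            _data(e_el, "e_extra", json.dumps(e.extra, sort_keys=True))

    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    tree.write(path, encoding="unicode", xml_declaration=True)


def _data(parent: ET.Element, key: str, value: str) -> None:
    el = ET.SubElement(parent, f"{{{GRAPHML_NS}}}data", {"key": key})
    el.text = value


def read_graphml(path: str) -> CompoundGraph:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise GraphError(f"malformed GraphML: {exc}") from None
    root = tree.getroot()
    ns = {"g": GRAPHML_NS}
    g_el = root.find("g:graph", ns)
    if g_el is None:
        raise GraphError("no <graph> element found")
    graph = CompoundGraph()

    def datum(el: ET.Element, key: str) -> Optional[str]:
        for d in el.findall("g:data", ns):
            if d.get("key") == key:
                return d.text or ""
        return None

    def parse_nodes(container: ET.Element, owner: Optional[str]) -> None:
        for n_el in container.findall("g:node", ns):
            nid = n_el.get("id")
            if nid is None or nid in graph.nodes:
                raise GraphError(f"missing or duplicate node id {nid!r}")
            store_txt = datum(n_el, "n_store")
            extra_txt = datum(n_el, "n_extra")
            graph.nodes[nid] = NodeRecord(
                id=nid,
                parent=owner,
                center=(
                    float(datum(n_el, "n_x") or 0.0),
                    float(datum(n_el, "n_y") or 0.0),
                ),
                width=float(datum(n_el, "n_w") or 30.0),
                height=float(datum(n_el, "n_h") or 30.0),
                hidden=datum(n_el, "n_hidden") == "true",
                highlighted=datum(n_el, "n_highlighted") == "true",
                collapsed=datum(n_el, "n_collapsed") == "true",
                store=_store_from_obj(json.loads(store_txt)) if store_txt else None,
                label=datum(n_el, "n_label"),
                extra=json.loads(extra_txt) if extra_txt else {},
            )
            sub = n_el.find("g:graph", ns)
            if sub is not None:
                parse_nodes(sub, nid)

    parse_nodes(g_el, None)
    for e_el in g_el.findall("g:edge", ns):
        eid = e_el.get("id") or f"{e_el.get('source')}--{e_el.get('target')}"
        extra_txt = datum(e_el, "e_extra")
        graph.edges[eid] = EdgeRecord(
            id=eid,
            source=e_el.get("source"),
            target=e_el.get("target"),
            kind=datum(e_el, "e_kind") or "original",
            original_ref=datum(e_el, "e_original_ref"),
            hidden=datum(e_el, "e_hidden") == "true",
            highlighted=datum(e_el, "e_highlighted") == "true",
            extra=json.loads(extra_txt) if extra_txt else {},
        )
    arch_txt = datum(g_el, "g_archived_originals")
    if arch_txt:
        for obj in json.loads(arch_txt):
            e = _edge_from_obj(obj)
            graph.archived_originals[e.id] = e
    graph.highlight_active = datum(g_el, "g_highlight_active") == "true"
    return _check(graph)


# -- JSON elements dialect ------------------------------------------------


def write_json(graph: CompoundGraph, path: str, options: Optional[Options] = None) -> None:
    options = options or Options()
    elements: list[dict] = []
    for nid in sorted(graph.nodes):
        n = graph.nodes[nid]
        obj = _node_to_obj(n)
        data = {"id": obj.pop("id")}
        if obj.pop("parent", None) is not None:
            data["parent"] = n.parent
        if n.label is not None:
            data["label"] = obj.pop("label")
        el = {
            "group": "nodes",
            "data": data,
            "position": {"x": obj.pop("x"), "y": obj.pop("y")},
            "dimensions": {"w": obj.pop("width"), "h": obj.pop("height")},
        }
        extra = obj.pop("extra", None)
        el.update(obj)  # hidden/highlighted/collapsed/store if set
        if n.hidden:
            if options.set_display_on_hide:
                el["display"] = "none"
            if options.set_visibility_on_hide:
                el["visibility"] = "hidden"
        if extra:
            el.update(extra)
        elements.append(el)
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        obj = _edge_to_obj(e)
        data = {
            "id": obj.pop("id"),
            "source": obj.pop("source"),
            "target": obj.pop("target"),
        }
        if e.kind != "original":
            data["kind"] = e.kind
            data["original_ref"] = obj.pop("original_ref", None)
        obj.pop("kind", None)
        extra = obj.pop("extra", None)
        el = {"group": "edges", "data": data}
        el.update(obj)
        if e.hidden:
            if options.set_display_on_hide:
                el["display"] = "none"
            if options.set_visibility_on_hide:
                el["visibility"] = "hidden"
        if extra:
            el.update(extra)
        elements.append(el)
    doc = {
        "elements": elements,
        "archived_originals": [
            _edge_to_obj(graph.archived_originals[k])
            for k in sorted(graph.archived_originals)
        ],
        "highlight_active": graph.highlight_active,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


_KNOWN_ELEMENT_KEYS = {
    "group",
    "data",
    "position",
    "dimensions",
    "hidden",
    "highlighted",
    "collapsed",
    "store",
    "display",
    "visibility",
}


def read_json(path: str) -> CompoundGraph:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphError(f"malformed JSON: {exc}") from None
    elements = doc.get("elements", doc if isinstance(doc, list) else [])
    graph = CompoundGraph()
    for el in elements:
        data = el.get("data", {})
        if "id" not in data:
            raise GraphError("element without data.id")
        extra = {k: v for k, v in el.items() if k not in _KNOWN_ELEMENT_KEYS}
        group = el.get("group", "edges" if "source" in data else "nodes")
        hidden = bool(el.get("hidden", False)) or el.get("display") == "none"
        if group == "nodes":
            pos = el.get("position", {})
            dim = el.get("dimensions", {})
            store = el.get("store")
            graph.nodes[data["id"]] = NodeRecord(
                id=data["id"],
                parent=data.get("parent"),
                center=(float(pos.get("x", 0.0)), float(pos.get("y", 0.0))),
                width=float(dim.get("w", 30.0)),
                height=float(dim.get("h", 30.0)),
                hidden=hidden,
                highlighted=bool(el.get("highlighted", False)),
                collapsed=bool(el.get("collapsed", False)),
                store=_store_from_obj(store) if store is not None else None,
                label=data.get("label"),
                extra=extra,
            )
        else:
            graph.edges[data["id"]] = EdgeRecord(
                id=data["id"],
                source=data["source"],
                target=data["target"],
                kind=data.get("kind", "original"),
                original_ref=data.get("original_ref"),
                hidden=hidden,
                highlighted=bool(el.get("highlighted", False)),
                extra=extra,
            )
    for obj in doc.get("archived_originals", []) if isinstance(doc, dict) else []:
        e = _edge_from_obj(obj)
        graph.archived_originals[e.id] = e
    if isinstance(doc, dict):
        graph.highlight_active = bool(doc.get("highlight_active", False))
    for n in graph.nodes.values():
        if n.parent is not None and n.parent not in graph.nodes:
            raise GraphError(f"unknown parent {n.parent!r} of node {n.id!r}")
    return _check(graph)


def read_graph(path: str) -> CompoundGraph:
    if str(path).endswith(".graphml"):
        return read_graphml(path)
    return read_json(path)


def write_graph(graph: CompoundGraph, path: str, options: Optional[Options] = None) -> None:
    if str(path).endswith(".graphml"):
        write_graphml(graph, path)
    else:
        write_json(graph, path, options)


# -- SVG rendering --------------------------------------------------------


class RenderStyle:
    """Visual defaults for the SVG renderer."""

    def __init__(
        self,
        cue_size: float = 12.0,
        cue_line_size: float = 8.0,
        cue_position: str = "top-left",
        unhighlighted_opacity: float = 0.3,
        meta_dash: str = "6,4",
        compound_fill: str = "#f0f0f5",
    ) -> None:
        if cue_size <= 0 or cue_line_size <= 0:
            raise ValueError("cue sizes must be positive")
        if not (0.0 <= unhighlighted_opacity <= 1.0):
            raise ValueError("opacity must be in [0, 1]")
        self.cue_size = cue_size
        self.cue_line_size = cue_line_size
        self.cue_position = cue_position
        self.unhighlighted_opacity = unhighlighted_opacity
        self.meta_dash = meta_dash
        self.compound_fill = compound_fill


def render_svg(graph: CompoundGraph, path: str, style: Optional[RenderStyle] = None) -> dict:
    """Draw the visible graph; returns a summary of what was drawn.

    Model space is y-up, SVG is y-down, so the renderer flips.  Every
    collapsed compound gets a plus cue, every expanded compound a minus
    cue, at its top-left corner; when any highlight is active,
    unhighlighted elements are drawn at the configured opacity.
    """
    style = style or RenderStyle()
    visible = graph.visible_nodes()
    pad = 20.0
    if visible:
        x0 = min(n.x - n.width / 2 for n in visible) - pad
        x1 = max(n.x + n.width / 2 for n in visible) + pad
        y0 = min(n.y - n.height / 2 for n in visible) - pad
        y1 = max(n.y + n.height / 2 for n in visible) + pad
    else:
        x0, y0, x1, y1 = 0.0, 0.0, 100.0, 100.0

    def sx(x: float) -> float:
        return x - x0

    def sy(y: float) -> float:
        return y1 - y  # flip to screen coordinates

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": f"{x1 - x0:.1f}",
            "height": f"{y1 - y0:.1f}",
            "viewBox": f"0 0 {x1 - x0:.1f} {y1 - y0:.1f}",
        },
    )

    def opacity_of(el) -> Optional[float]:
        if graph.highlight_active and not el.highlighted:
            return style.unhighlighted_opacity
        return None

    summary = {
        "nodes": 0,
        "compounds": 0,
        "edges": 0,
        "meta_edges": 0,
        "cues": [],
        "unhighlighted_opacity": None,
    }

    compounds = [n for n in visible if graph.has_children(n.id) or n.collapsed]
    leaves = [n for n in visible if n not in compounds]
    for n in sorted(compounds, key=lambda r: inclusion_level(graph, r.id)):
        attrs = {
            "x": f"{sx(n.x - n.width / 2):.2f}",
            "y": f"{sy(n.y + n.height / 2):.2f}",
            "width": f"{n.width:.2f}",
            "height": f"{n.height:.2f}",
            "fill": style.compound_fill,
            "stroke": "#888",
            "data-id": n.id,
        }
        op = opacity_of(n)
        if op is not None:
            attrs["opacity"] = repr(op)
            summary["unhighlighted_opacity"] = op
        ET.SubElement(svg, "rect", attrs)
        summary["compounds"] += 1

    for e in graph.visible_edges():
        s, t = graph.nodes[e.source], graph.nodes[e.target]
        attrs = {
            "x1": f"{sx(s.x):.2f}",
            "y1": f"{sy(s.y):.2f}",
            "x2": f"{sx(t.x):.2f}",
            "y2": f"{sy(t.y):.2f}",
            "stroke": "#555",
            "data-id": e.id,
        }
        if e.kind == META:
            attrs["stroke-dasharray"] = style.meta_dash
            summary["meta_edges"] += 1
        op = opacity_of(e)
        if op is not None:
            attrs["opacity"] = repr(op)
            summary["unhighlighted_opacity"] = op
        ET.SubElement(svg, "line", attrs)
        summary["edges"] += 1

    for n in sorted(leaves, key=lambda r: r.id):
        attrs = {
            "x": f"{sx(n.x - n.width / 2):.2f}",
            "y": f"{sy(n.y + n.height / 2):.2f}",
            "width": f"{n.width:.2f}",
            "height": f"{n.height:.2f}",
            "fill": "#cfe2ff",
            "stroke": "#345",
            "data-id": n.id,
        }
        op = opacity_of(n)
        if op is not None:
            attrs["opacity"] = repr(op)
            summary["unhighlighted_opacity"] = op
        ET.SubElement(svg, "rect", attrs)
        summary["nodes"] += 1

    for n in sorted(compounds, key=lambda r: r.id):
        state = node_op_state(graph, n.id)
        kind = "plus" if state["expandable"] else "minus"
        cx = sx(n.x - n.width / 2) + style.cue_size / 2  # top-left corner
        cy = sy(n.y + n.height / 2) + style.cue_size / 2
        half = style.cue_size / 2
        stroke = {"stroke": "#222", "stroke-width": repr(style.cue_line_size)}
        ET.SubElement(
            svg,
            "line",
            {
                "x1": f"{cx - half:.2f}",
                "y1": f"{cy:.2f}",
                "x2": f"{cx + half:.2f}",
                "y2": f"{cy:.2f}",
                "data-cue": n.id,
                **stroke,
            },
        )
        if kind == "plus":
            ET.SubElement(
                svg,
                "line",
                {
                    "x1": f"{cx:.2f}",
                    "y1": f"{cy - half:.2f}",
                    "x2": f"{cx:.2f}",
                    "y2": f"{cy + half:.2f}",
                    "data-cue": n.id,
                    **stroke,
                },
            )
        summary["cues"].append(
            {
                "node": n.id,
                "type": kind,
                "size": style.cue_size,
                "line_size": style.cue_line_size,
                "x": cx,
                "y": cy,
            }
        )

    tree = ET.ElementTree(svg)
    ET.indent(tree, space="  ")
    tree.write(path, encoding="unicode", xml_declaration=True)
    return summary
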