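# compoundnet

Headless library + CLI for managing the complexity of large nested
(*compound*) networks — the kind of deeply nested structure found in
biological pathway maps. It provides:

- **Expand/collapse** of compound nodes with consistent *meta-edge*
  bookkeeping: every edge crossing a collapsed boundary is represented by
  exactly one meta edge carrying a pointer to its archived original; the
  resulting topology is independent of the order of operations, and a full
  expand restores the pristine graph exactly. The cost of each operation is
  linear in the content collapsed/expanded plus its incident edges.
- **Hide/show** of arbitrary element sets. Revealed nodes are re-placed
  level by level using a quadrant-crowding heuristic (+3 per first-degree
  neighbor, +1 per second-degree neighbor; least crowded quadrant wins) at
  roughly one ideal edge length from their visible anchor, interleaved with
  incremental layout; plus highlight/unhighlight state management.
- **Incremental force-directed layout** with compound support and a
  geometrically cooled temperature cap on per-iteration movement — a low
  initial temperature preserves the user's mental map after collapse/hide —
  and a **fisheye adjustment** that pushes surrounding nodes outward by the
  change in a growing node's required space before an expand.
- **I/O**: nested GraphML and a JSON elements dialect (both round-trip the
  full state, including collapsed stores, byte-identically), SVG rendering
  with plus/minus expand-collapse cues, and a seeded synthetic-graph
  generator so nothing external is ever needed.

## Library quick start

```python
import compoundnet as cn

g = cn.worked_example_graph()                      # two nested compounds, 3 edges
cn.collapse_node(g, "c2")                # archives e, creates meta edge {d, c2}
cn.expand_node(g, "c2")                  # restores the original {d, e}

g = cn.generate_compound_graph(cn.GeneratorParams(n_leaf_nodes=50, seed=1))
cn.hide(g, ["n0", "n1"])
cn.show(g, ["n0", "n1"])                 # quadrant-heuristic re-placement
cn.force_layout(g, cn.LayoutParams(incremental=True))
```

## CLI

Format (GraphML vs JSON) is inferred from file extensions.

```sh
compoundnet generate --out g.json --leaf-nodes 40 --compounds 6 --seed 7
compoundnet stats    --in g.json
compoundnet collapse --in g.json --out c.json --nodes c2 --recursive
compoundnet expand   --in c.json --out e.json --all
compoundnet hide     --in g.json --out h.json --elements n0,n1
compoundnet show     --in h.json --out s.json --elements n0,n1
compoundnet layout   --in g.json --out l.json --incremental
compoundnet render   --in g.json --out g.svg
compoundnet validate --in g.json
```

A JSON `--config` file can override any option or parameter by field name
(e.g. `{"cue_size": 16, "ideal_edge_length": 80}`).

## GraphML dialect

Compound nesting uses the standard nested `<graph>` element under each
compound `<node>`. Custom data keys: nodes carry `x`, `y`, `w`, `h`,
`hidden`, `highlighted`, `collapsed`, `label`, `store` (JSON blob of the
archived subgraph of a collapsed compound) and `extra`; edges carry
`kind` (`original`/`meta`), `original_ref`, `hidden`, `highlighted`,
`extra`; the graph carries `archived_originals` (JSON list of original
edges currently represented by meta edges) and `highlight_active`. The
JSON dialect is an elements list with `data.id`/`data.parent`, plus the
same state fields; hidden elements are written with `display: "none"`
and/or `visibility: "hidden"` according to the
`set_display_on_hide`/`set_visibility_on_hide` options.

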