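"""Graph documents: lossless JSON serialization and DOT rendering.

The JSON document is a flat, versioned record of variables, factors, the
context tree, plugin payloads and (optionally) discrete factor tables.
``from_json(to_json(g))`` reproduces the graph with identical node ids, so
documents can be built on one machine and constrained or executed on
another.
"""

from __future__ import annotations

import json
from typing import Any, Optional

import numpy as np

from .engine.discrete import TableSet
from .errors import SchemaViolation, VersionMismatch
from .graph import Context, FactorGraph, FactorNode, VariableNode

FORMAT_VERSION = "1.0"


def _plain(value: Any):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    return value


def to_json(graph: FactorGraph, tables: Optional[TableSet] = None) -> dict:
    """Serialize a graph (and optional discrete tables) to a document."""
    ctx_ids: dict[int, str] = {}
    contexts = []
    for k, ctx in enumerate(graph.context_root.walk()):
        ctx_ids[id(ctx)] = f"c{k}"
    for ctx in graph.context_root.walk():
        contexts.append({
            "id": ctx_ids[id(ctx)],
            "model_name": ctx.model_name,
            "invocation": ctx.invocation,
            "parent": ctx_ids[id(ctx.parent)] if ctx.parent else None,
            "local_bindings": [[n, i, v] for (n, i), v in ctx.local_bindings.items()],
            "local_values": [[n, i, _plain(v)] for (n, i), v in ctx.local_values.items()],
            "interface_bindings": dict(ctx.interface_bindings),
            "vector_bindings": [[iface, ctx_ids[id(owner)], base, length]
                                for iface, (owner, base, length)
                                in ctx.vector_bindings.items()],
            "vector_lengths": dict(ctx.vector_lengths),
            "child_counters": dict(ctx._child_counters),
            "anon_counters": dict(ctx._anon_counters),
        })
    doc = {
        "format_version": FORMAT_VERSION,
        "variables": [{
            "id": v.id, "name": v.name, "index": v.index,
            "path": list(v.path), "kind": v.kind, "value": _plain(v.value),
        } for v in graph.variables.values()],
        "factors": [{
            "id": f.id, "label": f.label, "deterministic": f.deterministic,
            "interfaces": [[i, v] for i, v in f.interfaces.items()],
            "path": list(f.path),
        } for f in graph.factors.values()],
        "contexts": contexts,
        "plugins": {p: {t: _plain(payload) for t, payload in store.items()}
                    for p, store in graph.plugins.items()},
    }
    if tables is not None:
        doc["tables"] = {
            "domains": {v: [_plain(x) for x in dom]
                        for v, dom in tables.domains.items()},
            "values": {f: np.asarray(t).tolist()
                       for f, t in tables.tables.items()},
        }
    return doc


def from_json(document: dict) -> tuple[FactorGraph, Optional[TableSet]]:
    """Rebuild a graph (and tables, if present) from a document."""
    if not isinstance(document, dict) or "format_version" not in document:
        raise SchemaViolation("document lacks a format_version field")
    version = str(document["format_version"])
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise VersionMismatch(f"unsupported format version {version!r}")
    for key in ("variables", "factors", "contexts"):
        if key not in document:
            raise SchemaViolation(f"document lacks the {key!r} section")

    ctx_docs = document["contexts"]
    if not ctx_docs or ctx_docs[0]["parent"] is not None:
        raise SchemaViolation("first context must be the parentless root")
    graph = FactorGraph(root_model_name=ctx_docs[0]["model_name"])
    by_id: dict[str, Context] = {ctx_docs[0]["id"]: graph.context_root}
    graph.context_root.invocation = ctx_docs[0].get("invocation", 0)
    for cd in ctx_docs[1:]:
        parent = by_id.get(cd["parent"])
        if parent is None:
            raise SchemaViolation(f"context {cd['id']!r} appears before its parent")
        by_id[cd["id"]] = Context(cd["model_name"], cd.get("invocation", 0),
                                  parent=parent)

    max_id = -1
    ctx_by_path = {ctx.path: ctx for ctx in graph.context_root.walk()}
    for vd in document["variables"]:
        try:
            node = VariableNode(id=vd["id"], name=vd["name"],
                                index=vd["index"], path=tuple(vd["path"]),
                                kind=vd["kind"], value=vd["value"])
        except KeyError as e:
            raise SchemaViolation(f"variable record missing field {e}") from None
        graph.variables[node.id] = node
        graph._var_key_index[(node.name, node.index, node.path)] = node.id
        max_id = max(max_id, _numeric_suffix(node.id))
    for fd in document["factors"]:
        try:
            node = FactorNode(id=fd["id"], label=fd["label"],
                              deterministic=fd["deterministic"],
                              interfaces={i: v for i, v in fd["interfaces"]},
                              path=tuple(fd["path"]))
        except KeyError as e:
            raise SchemaViolation(f"factor record missing field {e}") from None
        graph.factors[node.id] = node
        max_id = max(max_id, _numeric_suffix(node.id))
    graph._next_id = max_id + 1

    for cd in ctx_docs:
        ctx = by_id[cd["id"]]
        ctx.local_bindings = {(n, i): v for n, i, v in cd.get("local_bindings", [])}
        ctx.local_values = {(n, i): v for n, i, v in cd.get("local_values", [])}
        ctx.interface_bindings = dict(cd.get("interface_bindings", {}))
        ctx.vector_bindings = {iface: (by_id[oid], base, length)
                               for iface, oid, base, length
                               in cd.get("vector_bindings", [])}
        ctx.vector_lengths = dict(cd.get("vector_lengths", {}))
        ctx._child_counters = dict(cd.get("child_counters", {}))
        ctx._anon_counters = dict(cd.get("anon_counters", {}))
        if ctx.path not in ctx_by_path:  # pragma: no cover - defensive
            raise SchemaViolation(f"context {cd['id']!r} has an inconsistent path")

    graph.plugins = {p: dict(store)
                     for p, store in document.get("plugins", {}).items()}

    tables = None
    if "tables" in document:
        td = document["tables"]
        tables = TableSet(
            domains={v: list(dom) for v, dom in td["domains"].items()},
            tables={f: np.asarray(t, dtype=float)
                    for f, t in td["values"].items()})

    diagnostics = [d for d in graph.validate() if d.level == "error"]
    if diagnostics:
        raise SchemaViolation("document violates graph invariants: "
                              + "; ".join(map(str, diagnostics)))
    return graph, tables


def _numeric_suffix(node_id: str) -> int:
    digits = "".join(c for c in node_id if c.isdigit())
    return int(digits) if digits else -1


def save_json(graph: FactorGraph, path, tables: Optional[TableSet] = None) -> None:
    with open(path, "w") as fh:
        json.dump(to_json(graph, tables=tables), fh, indent=1)


def load_json(path) -> tuple[FactorGraph, Optional[TableSet]]:
    with open(path) as fh:
        return from_json(json.load(fh))


# -- DOT rendering -------------------------------------------------------------

def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(graph: FactorGraph, cluster_contexts: bool = True,
           strict_ffg: bool = False) -> str:
    """Render the graph as DOT text: factors as boxes, variables as circles,
    one cluster per submodel context ("closing the box" drawn literally).

    With ``strict_ffg`` every variable shared by more than two factors is
    expanded through an explicit equality node, recovering the classic
    degree-two edge discipline of Forney-style drawings.
    """
    adj = graph.variable_adjacency()
    lines = ["graph G {", '  node [fontsize=10];']
    emitted_edges: list[str] = []

    def var_decl(vid: str, label: str) -> str:
        return f'  "{vid}" [shape=circle, label="{_dot_escape(label)}"];'

    def fac_decl(fid: str, label: str) -> str:
        return f'  "{fid}" [shape=box, style=filled, fillcolor=lightgray, ' \
               f'label="{_dot_escape(label)}"];'

    decls: dict[tuple[str, ...], list[str]] = {}

    def add_decl(path, text):
        decls.setdefault(tuple(path), []).append(text)

    expanded: set[str] = set()
    for vid, var in graph.variables.items():
        base = var.name if var.index is None else f"{var.name}[{var.index}]"
        if strict_ffg and len(adj[vid]) > 2:
            expanded.add(vid)
            add_decl(var.path, fac_decl(f"{vid}__eq", "="))
            for k, (fid, iface) in enumerate(adj[vid]):
                alias = f"{vid}__{k}"
                add_decl(var.path, var_decl(alias, base))
                emitted_edges.append(f'  "{alias}" -- "{vid}__eq";')
                emitted_edges.append(
                    f'  "{fid}" -- "{alias}" [label="{_dot_escape(iface)}"];')
        else:
            add_decl(var.path, var_decl(vid, base))
    for fid, fac in graph.factors.items():
        add_decl(fac.path, fac_decl(fid, fac.label))
        for iface, vid in fac.interfaces.items():
            if vid in expanded:
                continue
            emitted_edges.append(
                f'  "{fid}" -- "{vid}" [label="{_dot_escape(iface)}", '
                'fontsize=8];')

    if cluster_contexts:
        counter = [0]

        def emit_context(ctx: Context, indent: str):
            for text in decls.pop(ctx.path, []):
                lines.append(indent + text.strip())
            for child in ctx.children:
                counter[0] += 1
                lines.append(f"{indent}subgraph cluster_{counter[0]} {{")
                label = f"{child.model_name}:{child.invocation}"
                lines.append(f'{indent}  label="{_dot_escape(label)}";')
                lines.append(f"{indent}  style=dashed;")
                emit_context(child, indent + "  ")
                lines.append(indent + "}")

        emit_context(graph.context_root, "  ")
        # nodes whose path has no surviving context (defensive)
        for remaining in decls.values():
            lines.extend(remaining)
    else:
        for block in decls.values():
            lines.extend(block)
    lines.extend(emitted_edges)
    lines.append("}")
    return "\n".join(lines) + "\n"
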