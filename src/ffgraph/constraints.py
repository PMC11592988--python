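"""Variational-constraints plugin: factorization and functional-form
constraints, scoped resolution over the context tree, and translation to
per-factor local factorizations.

The default variational family assigns each factor node a joint belief over
all of its interfaces (the Bethe family).  A factorization constraint (FC)
such as ``q(x, y, z) = q(x, y) q(z)`` refines that default: for every factor
in the constraint's scope whose interfaces are bound to the named variables,
the interface set is split so that variables placed in different FC blocks
never share a belief block.  The resolved per-factor partition is the
coarsest partition consistent with all applicable FCs (a lattice meet).
Functional-form constraints (FFCs) such as ``q(x) :: Beta`` tag a variable's
marginal belief with a distribution family.  Together with the normalization
and marginalization constraints enforced by the engine, a constraint set
defines a Constrained Bethe Free Energy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional, Union

from .builder import _resolve_ref
from .errors import (
    ConflictingConstraints,
    MalformedPartition,
    UnknownConstraintVariable,
    UnknownFamily,
)
from .graph import CONSTANT, Context, Diagnostic, FactorGraph
from .plugins import attach_payload
from .registry import NodeTypeRegistry
from .statements import Ref

PLUGIN_NAME = "variational_constraints"

#: distribution families an FFC may name when no registry is supplied
DEFAULT_FAMILIES = frozenset({
    "Beta", "Bernoulli", "Gamma", "Categorical", "Normal",
    "NormalMeanVariance", "NormalMeanPrecision",
    "NormalWeightedMeanVariance", "NormalWeightedMeanPrecision",
})


@dataclass(frozen=True)
class FactorizationConstraint:
    variables: tuple[str, ...]
    partition: tuple[tuple[str, ...], ...]
    scope: tuple[str, ...] = ()

    def __post_init__(self):
        flat = [v for block in self.partition for v in block]
        if len(flat) != len(set(flat)) or set(flat) != set(self.variables) \
                or any(not block for block in self.partition):
            raise MalformedPartition(
                f"partition {self.partition!r} is not a partition of "
                f"{self.variables!r}")

    def block_of(self, name: str) -> Optional[int]:
        for b, block in enumerate(self.partition):
            if name in block:
                return b
        return None


@dataclass(frozen=True)
class FunctionalFormConstraint:
    variable: str
    family: str
    scope: tuple[str, ...] = ()


ConstraintEntry = Union[FactorizationConstraint, FunctionalFormConstraint]


class ConstraintSet:
    """Ordered, validated collection of constraint entries."""

    def __init__(self, entries: list[ConstraintEntry]):
        self.entries = list(entries)
        self._validate()

    def _validate(self) -> None:
        seen: dict[tuple, tuple] = {}
        for e in self.entries:
            if not isinstance(e, FactorizationConstraint):
                continue
            key = (e.scope, frozenset(e.variables))
            canon = tuple(sorted(tuple(sorted(b)) for b in e.partition))
            if key in seen and seen[key] != canon:
                raise ConflictingConstraints(
                    f"two factorization constraints over {sorted(key[1])} in "
                    f"scope {list(e.scope) or '<root>'} disagree")
            seen[key] = canon

    def factorizations(self) -> list[FactorizationConstraint]:
        return [e for e in self.entries if isinstance(e, FactorizationConstraint)]

    def functional_forms(self) -> list[FunctionalFormConstraint]:
        return [e for e in self.entries if isinstance(e, FunctionalFormConstraint)]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# -- the q(...) surface syntax -------------------------------------------------

_FC_RE = re.compile(r"^\s*q\(([^()]*)\)\s*=\s*((?:\s*q\([^()]*\)\s*)+)$")
_FFC_RE = re.compile(r"^\s*q\(([^(),]+)\)\s*::\s*(\S+)\s*$")
_BLOCK_RE = re.compile(r"q\(([^()]*)\)")


def _names(csv: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in csv.split(",") if s.strip())


def parse_constraint(text: str, scope: tuple[str, ...] = ()) -> ConstraintEntry:
    """Parse ``q(x, y, z) = q(x, y)q(z)`` or ``q(x) :: Beta``."""
    m = _FFC_RE.match(text)
    if m:
        return FunctionalFormConstraint(variable=m.group(1).strip(),
                                        family=m.group(2), scope=scope)
    m = _FC_RE.match(text)
    if m:
        variables = _names(m.group(1))
        partition = tuple(_names(b) for b in _BLOCK_RE.findall(m.group(2)))
        return FactorizationConstraint(variables=variables,
                                       partition=partition, scope=scope)
    raise MalformedPartition(f"cannot parse constraint {text!r}")


def build_constraint_set(spec: Any) -> ConstraintSet:
    """Build a validated constraint set from a nested specification.

    Accepts a list of entries (strings in the ``q(...)`` syntax, constraint
    objects, or ``{"scope": ..., "entries": [...]}`` blocks, recursively
    path-prefixed) or a mapping with an ``entries`` key, as loaded from a
    YAML/JSON document.
    """
    if isinstance(spec, ConstraintSet):
        return spec

    entries: list[ConstraintEntry] = []

    def walk(node: Any, scope: tuple[str, ...]) -> None:
        if isinstance(node, str):
            entries.append(parse_constraint(node, scope))
        elif isinstance(node, (FactorizationConstraint, FunctionalFormConstraint)):
            merged = scope + node.scope
            if isinstance(node, FactorizationConstraint):
                entries.append(FactorizationConstraint(node.variables,
                                                       node.partition, merged))
            else:
                entries.append(FunctionalFormConstraint(node.variable,
                                                        node.family, merged))
        elif isinstance(node, dict) and "entries" in node:
            raw = node.get("scope", ())
            inner = (raw,) if isinstance(raw, str) else tuple(raw)
            for sub in node["entries"]:
                walk(sub, scope + inner)
        elif isinstance(node, dict) and "partition" in node:
            entries.append(FactorizationConstraint(
                variables=tuple(node["variables"]),
                partition=tuple(tuple(b) for b in node["partition"]),
                scope=scope + tuple(node.get("scope", ()))))
        elif isinstance(node, dict) and "family" in node:
            entries.append(FunctionalFormConstraint(
                variable=node["variable"], family=node["family"],
                scope=scope + tuple(node.get("scope", ()))))
        elif isinstance(node, (list, tuple)):
            for sub in node:
                walk(sub, scope)
        else:
            raise MalformedPartition(f"cannot interpret constraint spec {node!r}")

    top = spec.get("entries", []) if isinstance(spec, dict) else spec
    walk(top, ())
    return ConstraintSet(entries)


# -- scope resolution ----------------------------------------------------------

def _scope_matches(pattern: tuple[str, ...], ctx: Context) -> bool:
    """A pattern applies to every context whose model-name path ends with it,
    regardless of invocation counters; the empty pattern means the root."""
    if not pattern:
        return ctx.parent is None
    path = ctx.model_path
    return len(path) >= len(pattern) and path[-len(pattern):] == tuple(pattern)


def resolve_scopes(constraint_set: ConstraintSet, graph: FactorGraph
                   ) -> tuple[dict[Context, list[ConstraintEntry]], list[Diagnostic]]:
    """Map each context of the graph to the constraint entries applying to it.

    A pattern that matches no context yields a warning-level diagnostic, not
    an error."""
    mapping: dict[Context, list[ConstraintEntry]] = {}
    diagnostics: list[Diagnostic] = []
    contexts = list(graph.context_root.walk())
    for entry in constraint_set:
        matched = False
        for ctx in contexts:
            if _scope_matches(entry.scope, ctx):
                mapping.setdefault(ctx, []).append(entry)
                matched = True
        if not matched:
            diagnostics.append(Diagnostic(
                "warning",
                f"constraint scope {list(entry.scope)} matches no context"))
    return mapping, diagnostics


# -- local factorization -------------------------------------------------------

Partition = tuple[tuple[str, ...], ...]


class LocalFactorization:
    """Per-factor partition of the interface set into belief blocks."""

    def __init__(self, blocks: dict[str, Partition]):
        self.blocks = dict(blocks)

    def __getitem__(self, factor_id: str) -> Partition:
        return self.blocks[factor_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, LocalFactorization) and self.blocks == other.blocks

    def validate(self, graph: FactorGraph) -> list[Diagnostic]:
        out = []
        for fid, partition in self.blocks.items():
            fac = graph.factors[fid]
            flat = [i for block in partition for i in block]
            if sorted(flat) != sorted(fac.interfaces) or \
                    len(flat) != len(set(flat)) or any(not b for b in partition):
                out.append(Diagnostic(
                    "error", f"blocks {partition!r} do not partition the "
                             f"interfaces of {fac.label}", (fid,)))
        return out

    def to_payload(self) -> dict[str, list[list[str]]]:
        return {fid: [list(b) for b in p] for fid, p in self.blocks.items()}

    @classmethod
    def from_payload(cls, payload: dict) -> "LocalFactorization":
        return cls({fid: tuple(tuple(b) for b in p) for fid, p in payload.items()})


def _canonical(partition: list[set[str]], order: list[str]) -> Partition:
    ordered = [tuple(i for i in order if i in block) for block in partition]
    ordered.sort(key=lambda b: order.index(b[0]))
    return tuple(ordered)


def _meet(current: Partition, induced: list[set[str]], order: list[str]) -> Partition:
    """Coarsest partition refined by both: group interfaces by their pair of
    block memberships."""
    label: dict[str, tuple[int, int]] = {}
    for a, block in enumerate(current):
        for i in block:
            label[i] = (a, -1)
    for b, block in enumerate(induced):
        for i in block:
            label[i] = (label[i][0], b)
    groups: dict[tuple[int, int], set[str]] = {}
    for i, lab in label.items():
        groups.setdefault(lab, set()).add(i)
    return _canonical(list(groups.values()), order)


def _resolve_constraint_names(graph: FactorGraph, ctx: Context,
                              names: tuple[str, ...],
                              reject_constants: bool = True
                              ) -> dict[str, set[str]]:
    """Map each constrained name to the variable ids it denotes in ``ctx``
    (one id for a scalar, all touched elements for a vector)."""
    out: dict[str, set[str]] = {}
    for name in names:
        ids: set[str] = set()
        vec = None
        if name in ctx.vector_bindings:
            owner, base, length = ctx.vector_bindings[name]
            vec = (owner, base, length)
        elif name in ctx.vector_lengths:
            vec = (ctx, name, ctx.vector_lengths[name])
        if vec is not None:
            owner, base, length = vec
            for i in range(length):
                vid = graph.find_variable(owner, base, i)
                if vid is not None:
                    ids.add(vid)
        else:
            hit = _resolve_ref(graph, ctx, Ref(name))
            if hit is not None and hit[0] == "var":
                ids.add(hit[1])
        if not ids:
            raise UnknownConstraintVariable(
                f"constraint names {name!r}, which does not resolve to a "
                f"variable in scope {'/'.join(ctx.path) or ctx.model_name}")
        if reject_constants:
            for vid in ids:
                if graph.variables[vid].kind == CONSTANT:
                    raise UnknownConstraintVariable(
                        f"constraint names {name!r}, which is a constant; "
                        "beliefs are defined over latent and data variables only")
        out[name] = ids
    return out


def apply_factorization(graph: FactorGraph,
                        constraint_set: ConstraintSet) -> LocalFactorization:
    """Resolve all factorization constraints to per-factor belief blocks.

    Starts from the Bethe default (one block spanning each factor's
    interfaces) and takes, per factor, the coarsest partition consistent
    with every FC whose scope covers the factor's context.  Idempotent under
    re-application."""
    result: dict[str, Partition] = {
        fid: (tuple(fac.interfaces.keys()),) for fid, fac in graph.factors.items()
    }
    mapping, _ = resolve_scopes(constraint_set, graph)
    for ctx, entries in mapping.items():
        fcs = [e for e in entries if isinstance(e, FactorizationConstraint)]
        if not fcs:
            continue
        local_factors = [f for f in graph.factors.values() if f.path == ctx.path]
        for fc in fcs:
            name_ids = _resolve_constraint_names(graph, ctx, fc.variables)
            id_block = {vid: fc.block_of(name)
                        for name, ids in name_ids.items() for vid in ids}
            for fac in local_factors:
                order = list(fac.interfaces.keys())
                mentioned = {i: id_block[v] for i, v in fac.interfaces.items()
                             if v in id_block}
                if not mentioned:
                    continue
                induced: dict[int, set[str]] = {}
                for iface, b in mentioned.items():
                    induced.setdefault(b, set()).add(iface)
                rest = {i for i in order if i not in mentioned}
                blocks = list(induced.values()) + ([rest] if rest else [])
                result[fac.id] = _meet(result[fac.id], blocks, order)
    return LocalFactorization(result)


def apply_functional_form(graph: FactorGraph, constraint_set: ConstraintSet,
                          registry: Optional[NodeTypeRegistry] = None
                          ) -> dict[str, str]:
    """Tag constrained variables with their marginal's distribution family.

    Tags are attached as plugin payloads under the variational-constraints
    namespace; unconstrained variables stay untagged (free-form)."""
    families = set(DEFAULT_FAMILIES)
    if registry is not None:
        families.update(registry.labels())
    mapping, _ = resolve_scopes(constraint_set, graph)
    tags: dict[str, str] = {}
    for ctx, entries in mapping.items():
        for e in entries:
            if not isinstance(e, FunctionalFormConstraint):
                continue
            if e.family not in families:
                raise UnknownFamily(f"family {e.family!r} is not registered")
            name_ids = _resolve_constraint_names(graph, ctx, (e.variable,))
            for vid in name_ids[e.variable]:
                if graph.variables[vid].kind != "random":
                    raise UnknownConstraintVariable(
                        f"functional form on {e.variable!r}: only latent "
                        "variables can carry a family tag")
                tags[vid] = e.family
                existing = graph.plugins.get(PLUGIN_NAME, {}).get(vid, {})
                payload = dict(existing) if isinstance(existing, dict) else {}
                payload["functional_form"] = e.family
                attach_payload(graph, PLUGIN_NAME, vid, payload)
    return tags


def attach_local_factorization(graph: FactorGraph,
                               lf: LocalFactorization) -> None:
    """Record a resolved local factorization on the graph so serialization
    round-trips it."""
    for fid, partition in lf.blocks.items():
        existing = graph.plugins.get(PLUGIN_NAME, {}).get(fid, {})
        payload = dict(existing) if isinstance(existing, dict) else {}
        payload["factorization"] = [list(b) for b in partition]
        attach_payload(graph, PLUGIN_NAME, fid, payload)


def local_factorization_from_graph(graph: FactorGraph) -> Optional[LocalFactorization]:
    store = graph.plugins.get(PLUGIN_NAME, {})
    blocks = {fid: tuple(tuple(b) for b in payload["factorization"])
              for fid, payload in store.items()
              if isinstance(payload, dict) and "factorization" in payload}
    return LocalFactorization(blocks) if blocks else None
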