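"""Bipartite Forney-style factor graph with hierarchical naming contexts.

A Forney-style factor graph (FFG) represents a factorized distribution
``p(s) = prod_a f_a(s_a)``: factor nodes stand for the factor functions and
variable nodes for the variables they share.  Classic FFGs draw variables as
edges of degree at most two; here a variable shared by more than two factors
is kept as a single hyper-edge node (the equality-node expansion is available
as a rendering option only).

Submodel nesting is recorded in a tree of :class:`Context` objects.  Every
node carries the path of the context that created it, so "closing the box"
around any submodel invocation is a pure bookkeeping operation and the Markov
blanket of any factor group can be read off the bipartite adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .errors import (
    DuplicateName,
    EmptyInterfaces,
    MissingValue,
    UnknownFactor,
    UnknownVariable,
)

RANDOM = "random"
CONSTANT = "constant"
DATA = "data"
_KINDS = (RANDOM, CONSTANT, DATA)


@dataclass
class VariableNode:
    id: str
    name: str
    index: Optional[int]
    path: tuple[str, ...]
    kind: str
    value: Any = None

    @property
    def qualified_name(self) -> str:
        base = self.name if self.index is None else f"{self.name}[{self.index}]"
        return "/".join(self.path + (base,))


@dataclass
class FactorNode:
    id: str
    label: str
    deterministic: bool
    interfaces: dict[str, str]  # interface name -> variable id, insertion-ordered
    path: tuple[str, ...]

    @property
    def degree(self) -> int:
        return len(self.interfaces)


@dataclass
class Diagnostic:
    level: str  # "error" | "warning"
    message: str
    node_ids: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ids = f" [{', '.join(self.node_ids)}]" if self.node_ids else ""
        return f"{self.level}: {self.message}{ids}"


class Context:
    """One invocation of a model definition; the root context is the model itself.

    ``local_bindings`` maps ``(name, index)`` to variable ids created inside
    this context; ``interface_bindings`` maps interface names to variables in
    the *parent* scope (for the root, to the root's own nodes).  Folded
    deterministic results live in ``local_values`` as plain numbers, not nodes.
    """

    def __init__(self, model_name: str, invocation: int = 0,
                 parent: Optional["Context"] = None):
        self.model_name = model_name
        self.invocation = invocation
        self.parent = parent
        self.children: list[Context] = []
        self.local_bindings: dict[tuple[str, Optional[int]], str] = {}
        self.local_values: dict[tuple[str, Optional[int]], Any] = {}
        self.interface_bindings: dict[str, str] = {}
        # interface bound to a whole vector living in the parent scope:
        # name -> (owner context, parent-side base name, length)
        self.vector_bindings: dict[str, tuple["Context", str, int]] = {}
        self.vector_lengths: dict[str, int] = {}
        self._child_counters: dict[str, int] = {}
        self._anon_counters: dict[str, int] = {}
        if parent is not None:
            parent.children.append(self)

    # -- paths ---------------------------------------------------------------

    @property
    def path(self) -> tuple[str, ...]:
        if self.parent is None:
            return ()
        return self.parent.path + (f"{self.model_name}:{self.invocation}",)

    @property
    def model_path(self) -> tuple[str, ...]:
        """Model-name sequence from the root to this context, counters dropped."""
        if self.parent is None:
            return (self.model_name,)
        return self.parent.model_path + (self.model_name,)

    def walk(self) -> Iterable["Context"]:
        yield self
        for child in self.children:
            yield from child.walk()

    # -- naming helpers --------------------------------------------------------

    def next_invocation(self, model_name: str) -> int:
        k = self._child_counters.get(model_name, 0)
        self._child_counters[model_name] = k + 1
        return k

    def fresh_anonymous(self, stem: str) -> str:
        """Deterministic per-context counter, e.g. ``y_tmp_0``, ``const_2``."""
        k = self._anon_counters.get(stem, 0)
        self._anon_counters[stem] = k + 1
        return f"{stem}_{k}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Context({'/'.join(self.path) or self.model_name})"


class FactorGraph:
    """Mutable bipartite graph of factor and variable nodes plus a context tree."""

    def __init__(self, root_model_name: str = "model"):
        self.variables: dict[str, VariableNode] = {}
        self.factors: dict[str, FactorNode] = {}
        self.context_root = Context(root_model_name)
        self.plugins: dict[str, dict[str, Any]] = {}
        self._var_key_index: dict[tuple[str, Optional[int], tuple[str, ...]], str] = {}
        self._next_id = 0

    # -- construction ----------------------------------------------------------

    def _fresh_id(self, prefix: str) -> str:
        i = self._next_id
        self._next_id += 1
        return f"{prefix}{i}"

    def add_variable(self, context: Context, name: str, kind: str = RANDOM,
                     value: Any = None, index: Optional[int] = None) -> str:
        if not name:
            raise DuplicateName("variable name must be nonempty")
        if kind not in _KINDS:
            raise ValueError(f"unknown variable kind {kind!r}")
        if kind == RANDOM and value is not None:
            raise ValueError("random variables cannot carry a value")
        if kind in (CONSTANT, DATA) and value is None:
            raise MissingValue(f"{kind} variable {name!r} requires a value")
        key = (name, index, context.path)
        if key in self._var_key_index:
            raise DuplicateName(
                f"variable {name!r} (index={index}) already exists in context "
                f"{'/'.join(context.path) or '<root>'}")
        vid = self._fresh_id("v")
        node = VariableNode(id=vid, name=name, index=index,
                            path=context.path, kind=kind, value=value)
        self.variables[vid] = node
        self._var_key_index[key] = vid
        context.local_bindings[(name, index)] = vid
        return vid

    def add_factor(self, context: Context, label: str,
                   interface_map: dict[str, str],
                   deterministic: bool = False) -> str:
        if not interface_map:
            raise EmptyInterfaces(f"factor {label!r} declared with no interfaces")
        for iface, vid in interface_map.items():
            if vid not in self.variables:
                raise UnknownVariable(
                    f"factor {label!r} interface {iface!r} references unknown "
                    f"variable id {vid!r}")
        fid = self._fresh_id("f")
        self.factors[fid] = FactorNode(id=fid, label=label,
                                       deterministic=deterministic,
                                       interfaces=dict(interface_map),
                                       path=context.path)
        return fid

    def find_variable(self, context: Context, name: str,
                      index: Optional[int] = None) -> Optional[str]:
        return self._var_key_index.get((name, index, context.path))

    def get_or_create_indexed(self, context: Context, name: str, index: int) -> str:
        """Sparse-vector semantics: return the node at (name, index) or create
        a fresh random one.  Idempotent."""
        if index < 0:
            raise ValueError("vector indices are 0-based and nonnegative")
        vid = self.find_variable(context, name, index)
        if vid is not None:
            return vid
        return self.add_variable(context, name, RANDOM, index=index)

    # -- adjacency -------------------------------------------------------------

    def variable_adjacency(self) -> dict[str, list[tuple[str, str]]]:
        """Map variable id -> list of (factor id, interface name) touching it."""
        adj: dict[str, list[tuple[str, str]]] = {v: [] for v in self.variables}
        for fid, fac in self.factors.items():
            for iface, vid in fac.interfaces.items():
                adj.setdefault(vid, []).append((fid, iface))
        return adj

    def degree(self, variable_id: str) -> int:
        return len(self.variable_adjacency()[variable_id])

    # -- queries ---------------------------------------------------------------

    def markov_blanket(self, factor_subset: Iterable[str]) -> set[str]:
        """Variables adjacent to at least one factor inside the subset and at
        least one factor outside it (the boundary-crossing edges)."""
        subset = set(factor_subset)
        for fid in subset:
            if fid not in self.factors:
                raise UnknownFactor(f"unknown factor id {fid!r}")
        inside: set[str] = set()
        outside: set[str] = set()
        for fid, fac in self.factors.items():
            bucket = inside if fid in subset else outside
            bucket.update(fac.interfaces.values())
        return inside & outside

    def validate(self) -> list[Diagnostic]:
        """Check every structural invariant; one diagnostic per violation."""
        out: list[Diagnostic] = []
        seen: dict[tuple[str, Optional[int], tuple[str, ...]], str] = {}
        for vid, var in self.variables.items():
            if var.kind not in _KINDS:
                out.append(Diagnostic("error", f"unknown kind {var.kind!r}", (vid,)))
            if var.kind == RANDOM and var.value is not None:
                out.append(Diagnostic("error", "random variable carries a value", (vid,)))
            if var.kind in (CONSTANT, DATA) and var.value is None:
                out.append(Diagnostic("error", f"{var.kind} variable has no value", (vid,)))
            key = (var.name, var.index, var.path)
            if key in seen:
                out.append(Diagnostic("error",
                                      f"duplicate (name, index, path) {key!r}",
                                      (seen[key], vid)))
            seen[key] = vid
        for fid, fac in self.factors.items():
            if not fac.interfaces:
                out.append(Diagnostic("error", "factor has no interfaces", (fid,)))
            for iface, vid in fac.interfaces.items():
                if vid not in self.variables:
                    out.append(Diagnostic(
                        "error",
                        f"interface {iface!r} references missing variable {vid!r}",
                        (fid,)))
                elif vid in self.factors:  # pragma: no cover - id spaces disjoint
                    out.append(Diagnostic("error", "factor-factor adjacency", (fid, vid)))
        # bipartiteness: ids must not be shared between the two node sets
        overlap = set(self.variables) & set(self.factors)
        for nid in sorted(overlap):
            out.append(Diagnostic("error",
                                  "node registered as both variable and factor",
                                  (nid,)))
        return out

    # -- summaries -------------------------------------------------------------

    def factors_by_label(self, label: str) -> list[FactorNode]:
        return [f for f in self.factors.values() if f.label == label]

    def label_degree_multiset(self) -> list[tuple[str, int]]:
        """Sorted multiset of (factor label, degree); the nesting-invariant
        fingerprint of a graph up to anonymous renaming."""
        return sorted((f.label, f.degree) for f in self.factors.values())

    def latent_variables(self) -> list[str]:
        return [vid for vid, v in self.variables.items() if v.kind == RANDOM]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FactorGraph({self.context_root.model_name}: "
                f"{len(self.variables)} variables, {len(self.factors)} factors)")
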