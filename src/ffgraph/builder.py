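"""Recording builder: statement materialization, submodel invocation,
model definitions and whole-model materialization.

The host-language surface is a :class:`ModelBuilder` handed to a model body.
A body is an ordinary Python callable that *records* statements::

    def body(m, y):
        m.tilde("theta", call("Beta", 1, 1))
        for i in range(len(y)):
            m.tilde(y[i], call("Bernoulli", m["theta"]))

``tilde`` implements the stochastic relation; ``assign`` is the deterministic
alias (recorded only for rendering — materialization is identical).  When a
deterministic node type is applied to arguments that are all known at
construction time, no factor node is created: the evaluator runs and the
result is folded into the context as a plain value.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from typing import Any, Callable, Optional, Sequence, Union

import numpy as np

from .errors import (
    DuplicateInterface,
    MultipleMissingInterfaces,
    NoMissingInterface,
    UnknownInterface,
    UnresolvableReference,
)
from .graph import CONSTANT, DATA, RANDOM, Context, FactorGraph
from .registry import NodeTypeRegistry, default_registry
from .statements import ASSIGN, TILDE, Call, Lit, Ref, Statement, call, unroll_compound

__all__ = [
    "Var", "Data", "UnboundVector", "ModelDefinition", "define_model",
    "ModelBuilder", "materialize_statement", "invoke_submodel",
    "materialize_model", "call",
]


class Var:
    """Lightweight handle to a (possibly indexed) variable name in scope."""

    def __init__(self, name: str, index: Optional[int] = None,
                 length: Optional[int] = None):
        self.name = name
        self.index = index
        self.length = length

    def __getitem__(self, i: int) -> "Var":
        if self.index is not None:
            raise TypeError(f"{self} is already indexed")
        return Var(self.name, index=int(i))

    def __len__(self) -> int:
        if self.length is None:
            raise TypeError(f"{self.name} is not a vector interface")
        return self.length

    def to_ref(self) -> Ref:
        return Ref(self.name, self.index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Var({self.to_ref()})"


@dataclass(frozen=True)
class Data:
    """Marks a scalar interface binding as observed data (array bindings are
    always data)."""
    value: Any


@dataclass(frozen=True)
class UnboundVector:
    """Interface bound to a vector of n latent (random) variables."""
    n: int


@dataclass(frozen=True)
class ModelDefinition:
    """A named, reusable model: an ordered interface list plus a body callable
    with signature ``body(m, **interface_handles)``.  Definition has no graph
    side effects; only materialization or invocation builds nodes."""
    name: str
    interface_names: tuple[str, ...]
    body: Callable

    def __post_init__(self):
        if len(set(self.interface_names)) != len(self.interface_names):
            raise DuplicateInterface(
                f"model {self.name!r} declares duplicate interfaces "
                f"{list(self.interface_names)}")


def define_model(name: str, interface_names: Sequence[str],
                 body: Callable) -> ModelDefinition:
    return ModelDefinition(name=name, interface_names=tuple(interface_names),
                           body=body)


@dataclass
class MaterializeResult:
    """Outcome of materializing one primitive statement."""
    factor_id: Optional[str]
    lhs_variable: Optional[str]
    folded_value: Any = None
    created_variables: tuple[str, ...] = ()

    @property
    def folded(self) -> bool:
        return self.factor_id is None


# -- scope resolution ---------------------------------------------------------

def _resolve_ref(graph: FactorGraph, ctx: Context, ref: Ref,
                 create_indexed: bool = False):
    """Resolve a reference in a context's scope.

    Returns ("value", v) for folded constants, ("var", id) for variable
    nodes, or None.  Submodel scopes see only their interfaces and their own
    locals — never the parent's locals directly.
    """
    key = (ref.name, ref.index)
    if key in ctx.local_values:
        return ("value", ctx.local_values[key])
    if ref.index is None and ref.name in ctx.interface_bindings:
        return ("var", ctx.interface_bindings[ref.name])
    if ref.index is not None and ref.name in ctx.vector_bindings:
        owner, base, length = ctx.vector_bindings[ref.name]
        if not 0 <= ref.index < length:
            raise UnresolvableReference(
                f"index {ref.index} out of range for vector interface "
                f"{ref.name!r} of length {length}")
        vid = graph.find_variable(owner, base, ref.index)
        if vid is None:
            vid = graph.get_or_create_indexed(owner, base, ref.index)
        return ("var", vid)
    if key in ctx.local_bindings:
        return ("var", ctx.local_bindings[key])
    if ref.index is not None and create_indexed:
        return ("var", graph.get_or_create_indexed(ctx, ref.name, ref.index))
    return None


def _is_literal_value(x: Any) -> bool:
    return isinstance(x, numbers.Number) or isinstance(x, (list, tuple, np.ndarray))


# -- statement materialization ------------------------------------------------

def materialize_statement(graph: FactorGraph, ctx: Context,
                          registry: NodeTypeRegistry,
                          stmt: Statement) -> MaterializeResult:
    """Materialize one primitive statement into the graph.

    Stochastic label: one factor node, the lhs variable (created if absent)
    and one fresh constant variable node per literal argument.  Deterministic
    label with all-known arguments: no nodes; the lhs is bound in the context
    to the evaluator's result.  Deterministic with at least one variable
    argument: a deterministic factor node.
    """
    if not stmt.is_primitive():
        raise ValueError("statement is compound; call unroll_compound first")

    kwargs = stmt.rhs.kwargs_dict()
    if kwargs and stmt.rhs.args:
        raise ValueError(
            f"{stmt.rhs.label!r}: mixing positional and keyword arguments "
            "is not supported")
    if kwargs:
        label, args = registry.resolve_alias(stmt.rhs.label, kwargs)
    else:
        label, args = stmt.rhs.label, list(stmt.rhs.args)
    entry = registry.get(label)

    # resolve arguments to literals or variable ids
    resolved: list[tuple[str, Any]] = []
    for a in args:
        if isinstance(a, Lit):
            resolved.append(("value", a.value))
        elif isinstance(a, Ref):
            hit = _resolve_ref(graph, ctx, a)
            if hit is None:
                raise UnresolvableReference(
                    f"{a} is not defined in scope of "
                    f"{'/'.join(ctx.path) or ctx.model_name}")
            resolved.append(hit)
        elif _is_literal_value(a):
            resolved.append(("value", a))
        else:
            raise TypeError(f"unsupported argument {a!r}")

    created: list[str] = []

    if entry.deterministic and all(tag == "value" for tag, _ in resolved):
        value = entry.evaluator(*[v for _, v in resolved])
        ctx.local_values[(stmt.lhs.name, stmt.lhs.index)] = value
        return MaterializeResult(factor_id=None, lhs_variable=None,
                                 folded_value=value)

    # lhs variable (created if absent)
    hit = _resolve_ref(graph, ctx, stmt.lhs)
    if hit is not None and hit[0] == "value":
        raise UnresolvableReference(
            f"{stmt.lhs} is already bound to a folded constant")
    if hit is None:
        if stmt.lhs.index is not None:
            lhs_id = graph.get_or_create_indexed(ctx, stmt.lhs.name, stmt.lhs.index)
        else:
            lhs_id = graph.add_variable(ctx, stmt.lhs.name, RANDOM)
        created.append(lhs_id)
    else:
        lhs_id = hit[1]

    # literal arguments materialize fresh constant nodes, never deduplicated
    interface_map: dict[str, str] = {"out": lhs_id}
    arg_names = entry.arg_names or ()
    for k, (tag, val) in enumerate(resolved):
        iface = arg_names[k] if k < len(arg_names) else f"in{k + 1}"
        if tag == "value":
            cname = ctx.fresh_anonymous("const")
            vid = graph.add_variable(ctx, cname, CONSTANT, value=val)
            created.append(vid)
            interface_map[iface] = vid
        else:
            interface_map[iface] = val

    fid = graph.add_factor(ctx, label, interface_map,
                           deterministic=entry.deterministic)
    return MaterializeResult(factor_id=fid, lhs_variable=lhs_id,
                             created_variables=tuple(created))


# -- submodel invocation -------------------------------------------------------

def _vector_info(ctx: Context, name: str):
    """(owner context, base name, length) if ``name`` is a vector in scope."""
    if name in ctx.vector_bindings:
        return ctx.vector_bindings[name]
    if name in ctx.vector_lengths:
        return (ctx, name, ctx.vector_lengths[name])
    return None


def invoke_submodel(graph: FactorGraph, parent: Context,
                    registry: NodeTypeRegistry, modeldef: ModelDefinition,
                    kwargs: dict[str, Any], lhs: Any = None) -> Context:
    """Run a model definition as a submodel of ``parent``.

    All but at most one interface are supplied by keyword; the missing one is
    bound to the statement's left-hand side (created in the parent scope if
    absent).  Indexed references among the keywords use get-or-create
    semantics, so a state chain can create ``x[t+1]`` on the line that uses
    it.  Interface detection is by name only — there is no positional
    fallback.
    """
    for k in kwargs:
        if k not in modeldef.interface_names:
            raise UnknownInterface(
                f"{modeldef.name!r} has no interface {k!r}; interfaces are "
                f"{list(modeldef.interface_names)}")
    missing = [i for i in modeldef.interface_names if i not in kwargs]
    if lhs is not None:
        if not missing:
            raise NoMissingInterface(
                f"all interfaces of {modeldef.name!r} were supplied but a "
                "left-hand side was given")
        if len(missing) > 1:
            raise MultipleMissingInterfaces(
                f"interfaces {missing} of {modeldef.name!r} are unbound; "
                "exactly one may be left for the left-hand side")
    elif missing:
        raise MultipleMissingInterfaces(
            f"interfaces {missing} of {modeldef.name!r} are unbound and no "
            "left-hand side was given")

    child = Context(modeldef.name, parent.next_invocation(modeldef.name),
                    parent=parent)

    for iface, value in kwargs.items():
        if isinstance(value, Var) and value.index is None:
            vec = _vector_info(parent, value.name)
            if vec is not None:
                child.vector_bindings[iface] = vec
                continue
            value = value.to_ref()
        elif isinstance(value, Var):
            value = value.to_ref()
        if isinstance(value, Ref):
            hit = _resolve_ref(graph, parent, value, create_indexed=True)
            if hit is None:
                raise UnresolvableReference(
                    f"interface {iface!r} of {modeldef.name!r}: {value} is "
                    "not defined in the parent scope")
            if hit[0] == "value":
                child.local_values[(iface, None)] = hit[1]
            else:
                child.interface_bindings[iface] = hit[1]
        elif _is_literal_value(value):
            # literals bound to interfaces stay foldable inside the child
            child.local_values[(iface, None)] = value
        else:
            raise TypeError(f"unsupported interface binding {value!r}")

    if lhs is not None:
        ref = lhs.to_ref() if isinstance(lhs, Var) else (
            lhs if isinstance(lhs, Ref) else Ref(str(lhs)))
        hit = _resolve_ref(graph, parent, ref, create_indexed=True)
        if hit is None:
            vid = graph.add_variable(parent, ref.name, RANDOM, index=ref.index)
        elif hit[0] == "value":
            raise UnresolvableReference(
                f"{ref} is bound to a constant and cannot receive the "
                f"missing interface {missing[0]!r}")
        else:
            vid = hit[1]
        child.interface_bindings[missing[0]] = vid

    m = ModelBuilder(graph, child, registry)
    modeldef.body(m, **{i: m.interface_handle(i) for i in modeldef.interface_names})
    return child


# -- whole-model materialization -----------------------------------------------

def materialize_model(modeldef: ModelDefinition,
                      bindings: Optional[dict[str, Any]] = None,
                      registry: Optional[NodeTypeRegistry] = None,
                      check: bool = True) -> FactorGraph:
    """Materialize a model definition into a fresh, validated factor graph.

    Interface bindings: a numeric array becomes one data node per element; a
    :class:`Data` scalar becomes a single data node; a plain number is a
    foldable constant; :class:`UnboundVector` creates latent elements; an
    absent binding creates a single latent scalar node.
    """
    bindings = dict(bindings or {})
    registry = registry or default_registry()
    for k in bindings:
        if k not in modeldef.interface_names:
            raise UnknownInterface(
                f"{modeldef.name!r} has no interface {k!r}")

    graph = FactorGraph(root_model_name=modeldef.name)
    root = graph.context_root
    for iface in modeldef.interface_names:
        value = bindings.get(iface)
        if value is None:
            vid = graph.add_variable(root, iface, RANDOM)
            root.interface_bindings[iface] = vid
        elif isinstance(value, UnboundVector):
            for i in range(value.n):
                graph.add_variable(root, iface, RANDOM, index=i)
            root.vector_lengths[iface] = value.n
        elif isinstance(value, Data) :
            vid = graph.add_variable(root, iface, DATA, value=value.value)
            root.interface_bindings[iface] = vid
        elif isinstance(value, (list, tuple, np.ndarray)):
            arr = np.asarray(value)
            for i, x in enumerate(arr):
                graph.add_variable(root, iface, DATA, value=float(x), index=i)
            root.vector_lengths[iface] = len(arr)
        elif isinstance(value, numbers.Number):
            root.local_values[(iface, None)] = value
        else:
            raise TypeError(f"unsupported binding for {iface!r}: {value!r}")

    m = ModelBuilder(graph, root, registry)
    modeldef.body(m, **{i: m.interface_handle(i) for i in modeldef.interface_names})
    if check:
        diagnostics = graph.validate()
        if diagnostics:  # pragma: no cover - defensive; builders keep invariants
            raise AssertionError(
                "materialized graph failed validation: "
                + "; ".join(map(str, diagnostics)))
    return graph


class ModelBuilder:
    """The recording surface a model body writes statements against."""

    def __init__(self, graph: FactorGraph, context: Context,
                 registry: NodeTypeRegistry):
        self.graph = graph
        self.context = context
        self.registry = registry

    # handles ------------------------------------------------------------------

    def interface_handle(self, name: str) -> Var:
        vec = _vector_info(self.context, name)
        return Var(name, length=vec[2] if vec else None)

    def var(self, name: str) -> Var:
        vec = _vector_info(self.context, name)
        return Var(name, length=vec[2] if vec else None)

    def vector(self, name: str, n: int) -> Var:
        """Declare a local vector of (lazily created) random variables."""
        self.context.vector_lengths.setdefault(name, n)
        return Var(name, length=n)

    def constant_vector(self, name: str, values) -> Var:
        """Declare a local vector of constant nodes, one per value."""
        arr = np.asarray(values)
        for i, x in enumerate(arr):
            self.graph.add_variable(self.context, name, CONSTANT,
                                    value=float(x), index=i)
        self.context.vector_lengths[name] = len(arr)
        return Var(name, length=len(arr))

    def __getitem__(self, name: str) -> Var:
        return Var(name)

    # statements ---------------------------------------------------------------

    def tilde(self, lhs: Union[str, Var, Ref], rhs: Call,
              relation: str = TILDE):
        """Record ``lhs ~ rhs``: unroll, then materialize each primitive."""
        if isinstance(lhs, Var):
            lhs_ref = lhs.to_ref()
        elif isinstance(lhs, Ref):
            lhs_ref = lhs
        else:
            lhs_ref = Ref(str(lhs))
        if not isinstance(rhs, Call):
            raise TypeError("right-hand side must be a call expression")
        stmt = Statement(lhs_ref, rhs, relation)

        def fresh() -> str:
            return self.context.fresh_anonymous(f"{lhs_ref.name}_tmp")

        result = None
        for prim in unroll_compound(stmt, self.registry, fresh_name=fresh):
            result = materialize_statement(self.graph, self.context,
                                           self.registry, prim)
        return result

    def assign(self, lhs: Union[str, Var, Ref], rhs: Call):
        """``lhs := rhs`` — the deterministic alias of ``~``."""
        return self.tilde(lhs, rhs, relation=ASSIGN)

    def invoke(self, modeldef: ModelDefinition, lhs: Any = None,
               **kwargs: Any) -> Context:
        return invoke_submodel(self.graph, self.context, self.registry,
                               modeldef, kwargs, lhs=lhs)
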