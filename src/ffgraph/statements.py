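"""Statement and expression trees for the model-specification language.

A statement is ``lhs ~ rhs`` (stochastic) or ``lhs := rhs`` (deterministic,
an alias of ``~`` recorded only for rendering).  The right-hand side is a
finite call tree whose leaves are literals or variable references.  Compound
right-hand sides are unrolled innermost-first, left-to-right, into primitive
statements whose arguments are all flat, binding intermediate results to
deterministically named anonymous variables (``<lhs>_tmp_<k>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Union

from .errors import UnknownLabel
from .registry import NodeTypeRegistry

TILDE = "~"
ASSIGN = ":="


@dataclass(frozen=True)
class Lit:
    """A literal argument (number or numeric array)."""
    value: Any


@dataclass(frozen=True)
class Ref:
    """A reference to a (possibly indexed) variable name in the current scope."""
    name: str
    index: Optional[int] = None

    def __str__(self) -> str:
        return self.name if self.index is None else f"{self.name}[{self.index}]"


@dataclass(frozen=True)
class Call:
    label: str
    args: tuple = ()
    kwargs: tuple = ()  # tuple of (key, expression) pairs, order-preserving

    def kwargs_dict(self) -> dict:
        return dict(self.kwargs)


Expression = Union[Lit, Ref, Call]


@dataclass(frozen=True)
class Statement:
    lhs: Ref
    rhs: Call
    relation: str = TILDE

    def is_primitive(self) -> bool:
        flat = all(not isinstance(a, Call) for a in self.rhs.args)
        flat_kw = all(not isinstance(v, Call) for _, v in self.rhs.kwargs)
        return flat and flat_kw


def as_expression(obj: Any) -> Expression:
    """Coerce builder-level arguments (numbers, handles, expressions) to the
    expression algebra."""
    if isinstance(obj, (Lit, Ref, Call)):
        return obj
    # late import to avoid a cycle with builder handles
    from .builder import Var
    if isinstance(obj, Var):
        return obj.to_ref()
    return Lit(obj)


def call(label: str, *args: Any, **kwargs: Any) -> Call:
    """Build a call expression; plain numbers become literals, variable
    handles become references."""
    return Call(label,
                tuple(as_expression(a) for a in args),
                tuple((k, as_expression(v)) for k, v in kwargs.items()))


def _check_labels(expr: Expression, registry: NodeTypeRegistry) -> None:
    if isinstance(expr, Call):
        if expr.label not in registry and not registry._alias_rules(expr.label):
            raise UnknownLabel(f"label {expr.label!r} is not registered")
        for a in expr.args:
            _check_labels(a, registry)
        for _, v in expr.kwargs:
            _check_labels(v, registry)


def unroll_compound(statement: Statement,
                    registry: Optional[NodeTypeRegistry] = None,
                    fresh_name: Optional[Callable[[], str]] = None,
                    ) -> list[Statement]:
    """Flatten a compound statement into primitive statements.

    Evaluation order is innermost-first, left-to-right; the final statement
    binds the original left-hand side.  ``fresh_name`` supplies anonymous
    names; by default ``<lhs>_tmp_<k>`` with k counting from 0.
    """
    if registry is not None:
        _check_labels(statement.rhs, registry)
    counter = [0]

    def default_fresh() -> str:
        name = f"{statement.lhs.name}_tmp_{counter[0]}"
        counter[0] += 1
        return name

    fresh = fresh_name or default_fresh
    out: list[Statement] = []

    def flatten(expr: Expression) -> Expression:
        """Return a flat (non-Call) expression, emitting statements for any
        nested calls in post-order."""
        if not isinstance(expr, Call):
            return expr
        flat_args = tuple(flatten(a) for a in expr.args)
        flat_kwargs = tuple((k, flatten(v)) for k, v in expr.kwargs)
        tmp = Ref(fresh())
        out.append(Statement(tmp, Call(expr.label, flat_args, flat_kwargs), TILDE))
        return tmp

    rhs = statement.rhs
    flat_args = tuple(flatten(a) for a in rhs.args)
    flat_kwargs = tuple((k, flatten(v)) for k, v in rhs.kwargs)
    out.append(Statement(statement.lhs,
                         Call(rhs.label, flat_args, flat_kwargs),
                         statement.relation))
    return out
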