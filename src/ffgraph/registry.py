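"""Node-type registry: stochastic/deterministic labels and keyword aliasing.

A statement's right-hand side names a node type.  Stochastic labels always
materialize factor nodes; deterministic labels fold to a plain value when all
arguments are known at construction time and materialize a deterministic
factor otherwise.  Keyword arguments are resolved through alias rules so a
generic ``Normal(mean=m, var=v)`` maps to the concrete parameterization
``NormalMeanVariance(m, v)`` without exposing that choice to the modeler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    AmbiguousAlias,
    DuplicateLabel,
    EvaluatorMissing,
    UnknownKeywordSet,
    UnknownLabel,
)

STOCHASTIC = "stochastic"
DETERMINISTIC = "deterministic"


@dataclass(frozen=True)
class AliasRule:
    source_label: str
    keyword_set: frozenset[str]
    target_label: str
    positional_order: tuple[str, ...]

    def __post_init__(self):
        if self.keyword_set != frozenset(self.positional_order):
            raise ValueError("keyword_set must equal set(positional_order)")


@dataclass
class NodeTypeEntry:
    label: str
    kind: str
    evaluator: Optional[Callable] = None
    arg_names: Optional[tuple[str, ...]] = None  # interface names for positional args
    alias_rules: list[AliasRule] = field(default_factory=list)

    @property
    def deterministic(self) -> bool:
        return self.kind == DETERMINISTIC


class NodeTypeRegistry:
    """Mutable mapping label -> NodeTypeEntry with keyword-alias resolution."""

    def __init__(self):
        self._entries: dict[str, NodeTypeEntry] = {}
        # alias rules whose source label is itself never registered as a node
        self._orphan_rules: dict[str, list[AliasRule]] = {}

    def register(self, label: str, kind: str,
                 evaluator: Optional[Callable] = None,
                 arg_names: Optional[Sequence[str]] = None,
                 overwrite: bool = False) -> NodeTypeEntry:
        if kind not in (STOCHASTIC, DETERMINISTIC):
            raise ValueError(f"kind must be stochastic or deterministic, got {kind!r}")
        if kind == DETERMINISTIC and evaluator is None:
            raise EvaluatorMissing(f"deterministic label {label!r} needs an evaluator")
        if label in self._entries and not overwrite:
            raise DuplicateLabel(f"label {label!r} already registered")
        entry = NodeTypeEntry(label=label, kind=kind, evaluator=evaluator,
                              arg_names=tuple(arg_names) if arg_names else None)
        self._entries[label] = entry
        return entry

    def add_alias(self, source_label: str, keywords: Sequence[str],
                  target_label: str) -> AliasRule:
        rule = AliasRule(source_label=source_label,
                         keyword_set=frozenset(keywords),
                         target_label=target_label,
                         positional_order=tuple(keywords))
        for other in self._alias_rules(source_label):
            if other.keyword_set == rule.keyword_set:
                raise DuplicateLabel(
                    f"alias for {source_label!r} with keywords "
                    f"{sorted(rule.keyword_set)} already exists")
        if source_label in self._entries:
            self._entries[source_label].alias_rules.append(rule)
        else:
            self._orphan_rules.setdefault(source_label, []).append(rule)
        return rule

    def _alias_rules(self, label: str) -> list[AliasRule]:
        rules: list[AliasRule] = []
        if label in self._entries:
            rules.extend(self._entries[label].alias_rules)
        rules.extend(self._orphan_rules.get(label, []))
        return rules

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def get(self, label: str) -> NodeTypeEntry:
        try:
            return self._entries[label]
        except KeyError:
            raise UnknownLabel(f"label {label!r} is not registered") from None

    def labels(self) -> list[str]:
        return sorted(self._entries)

    def resolve_alias(self, label: str, kwargs: dict) -> tuple[str, list]:
        """Map (label, keyword args) to a concrete label plus ordered
        positional args.  Identity when no keywords are supplied and the
        label itself is registered."""
        if not kwargs:
            if label not in self._entries:
                raise UnknownLabel(f"label {label!r} is not registered")
            return label, []
        keyset = frozenset(kwargs)
        matches = [r for r in self._alias_rules(label) if r.keyword_set == keyset]
        if len(matches) > 1:
            raise AmbiguousAlias(
                f"{len(matches)} alias rules for {label!r} match keywords "
                f"{sorted(keyset)}")
        if not matches:
            raise UnknownKeywordSet(
                f"no alias rule for {label!r} matches keywords {sorted(keyset)}")
        rule = matches[0]
        return rule.target_label, [kwargs[k] for k in rule.positional_order]


def _norm(x) -> float:
    return float(np.linalg.norm(np.asarray(x, dtype=float)))


def _dot(*args) -> float:
    # flat argument list: first half inputs, second half weights
    half = len(args) // 2
    a = np.asarray(args[:half], dtype=float)
    b = np.asarray(args[half:], dtype=float)
    return float(a @ b)


def default_registry() -> NodeTypeRegistry:
    """Registry with the standard distribution and operator node types.

    The four Normal parameterizations mirror the concrete node types a
    message-passing backend distinguishes; the generic ``Normal`` label keeps
    the mean-variance convention for positional use.
    """
    reg = NodeTypeRegistry()
    # stochastic node types
    reg.register("Beta", STOCHASTIC, arg_names=("a", "b"))
    reg.register("Bernoulli", STOCHASTIC, arg_names=("p",))
    reg.register("Gamma", STOCHASTIC, arg_names=("shape", "rate"))
    reg.register("Categorical", STOCHASTIC, arg_names=("p",))
    reg.register("Normal", STOCHASTIC, arg_names=("mean", "var"))
    reg.register("NormalMeanVariance", STOCHASTIC, arg_names=("mean", "var"))
    reg.register("NormalMeanPrecision", STOCHASTIC, arg_names=("mean", "precision"))
    reg.register("NormalWeightedMeanVariance", STOCHASTIC, arg_names=("w", "var"))
    reg.register("NormalWeightedMeanPrecision", STOCHASTIC, arg_names=("w", "precision"))
    # Normal keyword aliases (ASCII and the Greek spellings used in the field)
    reg.add_alias("Normal", ("mean", "var"), "NormalMeanVariance")
    reg.add_alias("Normal", ("mean", "variance"), "NormalMeanVariance")
    reg.add_alias("Normal", ("mean", "precision"), "NormalMeanPrecision")
    reg.add_alias("Normal", ("mean", "τ"), "NormalMeanPrecision")
    reg.add_alias("Normal", ("w", "precision"), "NormalWeightedMeanPrecision")
    reg.add_alias("Normal", ("ν", "τ"), "NormalWeightedMeanPrecision")
    reg.add_alias("Normal", ("ν", "var"), "NormalWeightedMeanVariance")
    # deterministic node types
    reg.register("exp", DETERMINISTIC, evaluator=math.exp, arg_names=("in",))
    reg.register("log", DETERMINISTIC, evaluator=math.log, arg_names=("in",))
    reg.register("tanh", DETERMINISTIC, evaluator=math.tanh, arg_names=("in",))
    reg.register("+", DETERMINISTIC, evaluator=lambda a, b: a + b,
                 arg_names=("in1", "in2"))
    reg.register("-", DETERMINISTIC, evaluator=lambda a, b: a - b,
                 arg_names=("in1", "in2"))
    reg.register("*", DETERMINISTIC, evaluator=lambda a, b: a * b,
                 arg_names=("in1", "in2"))
    reg.register("norm", DETERMINISTIC, evaluator=_norm, arg_names=("in",))
    reg.register("dot", DETERMINISTIC, evaluator=_dot)
    return reg
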