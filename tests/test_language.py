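"""Model-language semantics: registry and aliasing, compound unrolling,
statement materialization, deterministic folding, submodel invocation."""

import math

import pytest

import ffgraph as fg
from ffgraph import zoo
from ffgraph.errors import (
    AmbiguousAlias,
    DuplicateInterface,
    DuplicateLabel,
    EvaluatorMissing,
    MultipleMissingInterfaces,
    NoMissingInterface,
    UnknownInterface,
    UnknownKeywordSet,
    UnknownLabel,
    UnresolvableReference,
)
from ffgraph.registry import DETERMINISTIC, STOCHASTIC


class TestRegistry:
    def test_register_and_lookup(self):
        reg = fg.NodeTypeRegistry()
        reg.register("Bernoulli", STOCHASTIC)
        reg.register("exp", DETERMINISTIC, evaluator=math.exp)
        assert "Bernoulli" in reg
        assert reg.get("exp").evaluator(0) == 1.0

    def test_duplicate_label_rejected_unless_overwrite(self):
        reg = fg.NodeTypeRegistry()
        reg.register("exp", DETERMINISTIC, evaluator=math.exp)
        with pytest.raises(DuplicateLabel):
            reg.register("exp", DETERMINISTIC, evaluator=math.exp)
        reg.register("exp", DETERMINISTIC, evaluator=lambda x: x,
                     overwrite=True)
        assert reg.get("exp").evaluator(5) == 5

    def test_deterministic_requires_evaluator(self):
        reg = fg.NodeTypeRegistry()
        with pytest.raises(EvaluatorMissing):
            reg.register("f", DETERMINISTIC)

    @pytest.mark.parametrize("kwargs, expected", [
        ({"ν": 1, "τ": 1}, ("NormalWeightedMeanPrecision", [1, 1])),
        ({"mean": "m", "var": "v"}, ("NormalMeanVariance", ["m", "v"])),
        ({"mean": "m", "precision": "p"}, ("NormalMeanPrecision", ["m", "p"])),
    ])
    def test_normal_aliases(self, registry, kwargs, expected):
        assert registry.resolve_alias("Normal", kwargs) == expected

    def test_unknown_keyword_set(self, registry):
        with pytest.raises(UnknownKeywordSet):
            registry.resolve_alias("Normal", {"mean": 1, "flavor": 2})

    def test_identity_mapping_without_keywords(self, registry):
        assert registry.resolve_alias("Beta", {}) == ("Beta", [])
        with pytest.raises(UnknownLabel):
            registry.resolve_alias("Frobnitz", {})

    def test_ambiguous_alias_detected(self):
        reg = fg.NodeTypeRegistry()
        reg.register("N", STOCHASTIC)
        reg.add_alias("N", ("a", "b"), "N1")
        with pytest.raises(DuplicateLabel):
            reg.add_alias("N", ("b", "a"), "N2")  # same keyword set
        # distinct rule objects matching the same keyword set via orphan store
        reg._orphan_rules.setdefault("N", []).append(
            fg.registry.AliasRule("N", frozenset({"a", "b"}), "N2", ("a", "b")))
        with pytest.raises(AmbiguousAlias):
            reg.resolve_alias("N", {"a": 1, "b": 2})


class TestUnrollCompound:
    def test_primitive_statement_is_unchanged(self, registry):
        stmt = fg.Statement(fg.Ref("theta"), fg.call("Beta", 1, 1))
        assert fg.unroll_compound(stmt, registry) == [stmt]

    def test_gcv_compound_creates_four_statements(self, registry):
        stmt = fg.Statement(fg.Ref("y"), fg.call(
            "Normal", fg.Ref("x"),
            fg.call("exp", fg.call("+", fg.call("*", fg.Ref("k"), fg.Ref("z")),
                                   fg.Ref("w")))))
        prims = fg.unroll_compound(stmt, registry)
        assert [p.rhs.label for p in prims] == ["*", "+", "exp", "Normal"]
        assert prims[-1].lhs == fg.Ref("y")
        temps = {str(p.lhs) for p in prims[:-1]}
        assert temps == {"y_tmp_0", "y_tmp_1", "y_tmp_2"}

    def test_innermost_first_left_to_right_order(self, registry):
        stmt = fg.Statement(fg.Ref("y"), fg.call(
            "Normal", fg.call("exp", fg.Ref("a")), fg.call("exp", fg.Ref("b"))))
        prims = fg.unroll_compound(stmt, registry)
        assert [str(p.rhs.args[0]) for p in prims[:2]] == ["a", "b"]
        assert [str(a) for a in prims[2].rhs.args] == ["y_tmp_0", "y_tmp_1"]

    def test_unknown_label_rejected(self, registry):
        stmt = fg.Statement(fg.Ref("y"), fg.call("Mystery", 1))
        with pytest.raises(UnknownLabel):
            fg.unroll_compound(stmt, registry)


class TestMaterializeStatement:
    def test_deterministic_folding_creates_no_nodes(self, registry):
        g = fg.FactorGraph()
        m = fg.ModelBuilder(g, g.context_root, registry)
        r = m.tilde("a", fg.call("norm", [1, 2, 3]))
        assert r.folded
        assert r.folded_value == pytest.approx(math.sqrt(14))
        assert len(g.variables) == 0 and len(g.factors) == 0

    def test_assign_with_random_argument_materializes_factor(self, registry):
        g = fg.FactorGraph()
        m = fg.ModelBuilder(g, g.context_root, registry)
        g.add_variable(g.context_root, "x")
        r = m.assign("w", fg.call("exp", fg.Ref("x")))
        fac = g.factors[r.factor_id]
        assert fac.deterministic and fac.label == "exp"
        assert set(fac.interfaces) == {"out", "in"}

    def test_folding_soundness_no_all_constant_deterministic_factor(self):
        # after materializing a mixed model, every deterministic factor has
        # at least one non-constant input
        g = fg.materialize_model(zoo.gcv_lm())
        for fac in g.factors.values():
            if fac.deterministic:
                kinds = [g.variables[v].kind
                         for i, v in fac.interfaces.items() if i != "out"]
                assert any(k != "constant" for k in kinds)

    def test_unresolvable_reference(self, registry):
        g = fg.FactorGraph()
        m = fg.ModelBuilder(g, g.context_root, registry)
        with pytest.raises(UnresolvableReference):
            m.tilde("y", fg.call("Bernoulli", fg.Ref("ghost")))

    def test_unrolling_matches_hand_unrolled_build(self, registry):
        compound = fg.materialize_model(zoo.gcv("compound"))
        by_hand = fg.materialize_model(zoo.gcv("assign"))
        assert compound.label_degree_multiset() == by_hand.label_degree_multiset()
        assert len(compound.variables) == len(by_hand.variables)


class TestModelDefinition:
    def test_duplicate_interface_rejected(self):
        with pytest.raises(DuplicateInterface):
            fg.define_model("m", ["a", "a"], lambda m, a: None)

    def test_definition_has_no_side_effects(self):
        calls = []
        fg.define_model("m", ["a"], lambda m, a: calls.append(1))
        assert calls == []

    def test_empty_body_one_interface(self):
        g = fg.materialize_model(fg.define_model("m", ["a"], lambda m, a: None))
        assert len(g.variables) == 1 and len(g.factors) == 0


class TestInvokeSubmodel:
    def test_missing_interface_bound_to_lhs(self):
        # x_next ~ gcv(x=.., z=.., kappa=.., omega=..) binds gcv's y output
        def body(m, x_prev, z, kappa, omega):
            m.invoke(zoo.gcv(), lhs=m["x_next"], x=x_prev, z=z,
                     kappa=kappa, omega=omega)
        g = fg.materialize_model(
            fg.define_model("chain", ["x_prev", "z", "kappa", "omega"], body))
        normal = g.factors_by_label("Normal")[0]
        out_var = g.variables[normal.interfaces["out"]]
        assert out_var.name == "x_next" and out_var.path == ()

    def test_no_missing_interface_error(self):
        def body(m, a):
            inner = fg.define_model("inner", ["p"], lambda m2, p: None)
            m.invoke(inner, lhs=m["b"], p=a)
        with pytest.raises(NoMissingInterface):
            fg.materialize_model(fg.define_model("outer", ["a"], body))

    def test_multiple_missing_interfaces_error(self):
        def body(m, a):
            inner = fg.define_model("inner", ["p", "q", "r"],
                                    lambda m2, p, q, r: None)
            m.invoke(inner, lhs=m["b"], p=a)
        with pytest.raises(MultipleMissingInterfaces):
            fg.materialize_model(fg.define_model("outer", ["a"], body))

    def test_unknown_interface_error(self):
        def body(m, a):
            inner = fg.define_model("inner", ["p"], lambda m2, p: None)
            m.invoke(inner, nope=a)
        with pytest.raises(UnknownInterface):
            fg.materialize_model(fg.define_model("outer", ["a"], body))

    def test_invocation_counters_give_distinct_paths(self):
        def body(m, x_prev, z, kappa, omega):
            m.invoke(zoo.gcv(), lhs=m["a"], x=x_prev, z=z,
                     kappa=kappa, omega=omega)
            m.invoke(zoo.gcv(), lhs=m["b"], x=x_prev, z=z,
                     kappa=kappa, omega=omega)
        g = fg.materialize_model(
            fg.define_model("two", ["x_prev", "z", "kappa", "omega"], body))
        paths = sorted(c.path for c in g.context_root.walk() if c.parent)
        assert paths == [("gcv:0",), ("gcv:1",)]
        assert g.validate() == []


class TestMaterializeModel:
    def test_coin_toss_data_bound_counts(self):
        g = zoo.coin_toss(data=[1, 1, 0])
        labels = [f.label for f in g.factors.values()]
        assert labels.count("Beta") == 1 and labels.count("Bernoulli") == 3
        kinds = [v.kind for v in g.variables.values()]
        assert kinds.count("data") == 3 and kinds.count("constant") == 2
        assert kinds.count("random") == 1

    def test_gcv_unbound_matches_reference_structure(self):
        g = fg.materialize_model(zoo.gcv())
        assert g.label_degree_multiset() == [
            ("*", 3), ("+", 3), ("Normal", 3), ("exp", 2)]
        assert len(g.variables) == 8

    def test_scalar_data_binding(self):
        g = fg.materialize_model(
            fg.define_model("m", ["a"], lambda m, a: None),
            {"a": fg.Data(2.5)})
        (var,) = g.variables.values()
        assert var.kind == "data" and var.value == 2.5
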