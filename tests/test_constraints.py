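"""Plugin payloads and variational-constraint resolution."""

import itertools

import numpy as np
import pytest

import ffgraph as fg
from ffgraph import zoo
from ffgraph.constraints import (
    FactorizationConstraint,
    _meet,
    local_factorization_from_graph,
)
from ffgraph.errors import (
    ConflictingConstraints,
    MalformedPartition,
    UnknownConstraintVariable,
    UnknownFamily,
    UnknownTarget,
)


class TestPluginPayloads:
    def test_attach_and_retrieve(self, eq4):
        g, s, _ = eq4
        fg.attach_payload(g, "forms", s[1], {"form": "Beta"})
        assert fg.get_payload(g, "forms", s[1]) == {"form": "Beta"}

    def test_unknown_target_rejected(self, eq4):
        g, _, _ = eq4
        with pytest.raises(UnknownTarget):
            fg.attach_payload(g, "forms", "v999", {})

    def test_plugins_are_namespaced(self, eq4):
        g, s, _ = eq4
        fg.attach_payload(g, "alpha", s[1], 1)
        fg.attach_payload(g, "beta", s[1], 2)
        assert fg.get_payload(g, "alpha", s[1]) == 1
        assert fg.get_payload(g, "beta", s[1]) == 2
        assert fg.payloads(g, "alpha") == {s[1]: 1}


class TestBuildConstraintSet:
    def test_mean_field_string(self):
        cs = fg.build_constraint_set(["q(x, y, z) = q(x)q(y)q(z)"])
        (entry,) = cs.factorizations()
        assert entry.variables == ("x", "y", "z")
        assert entry.partition == (("x",), ("y",), ("z",))

    def test_scoped_block_prefixes_entries(self):
        cs = fg.build_constraint_set({"entries": [
            {"scope": "gcv",
             "entries": ["q(omega, kappa, z) = q(omega)q(kappa)q(z)"]},
        ]})
        (entry,) = cs.factorizations()
        assert entry.scope == ("gcv",)

    def test_functional_form_string(self):
        cs = fg.build_constraint_set(["q(theta) :: Beta"])
        (entry,) = cs.functional_forms()
        assert entry.variable == "theta" and entry.family == "Beta"

    def test_conflicting_partitions_rejected(self):
        with pytest.raises(ConflictingConstraints):
            fg.build_constraint_set(["q(x, y) = q(x)q(y)",
                                     "q(x, y) = q(x, y)"])

    def test_malformed_partition_rejected(self):
        with pytest.raises(MalformedPartition):
            fg.build_constraint_set(["q(x, y) = q(x)q(z)"])


class TestResolveScopes:
    def test_gcv_pattern_matches_every_invocation(self):
        g = fg.materialize_model(zoo.hgf(3, 2), {"y": fg.UnboundVector(2)})
        cs = fg.build_constraint_set({"entries": [
            {"scope": "gcv", "entries": ["q(omega) :: Normal"]}]})
        mapping, diags = fg.resolve_scopes(cs, g)
        matched = {c.model_name for c in mapping}
        assert matched == {"gcv"}
        n_gcv = sum(1 for c in g.context_root.walk() if c.model_name == "gcv")
        assert sum(len(v) for v in mapping.values()) == n_gcv
        assert diags == []

    def test_ssm_pattern_matches_both_invocations(self):
        g = fg.materialize_model(zoo.hierarchical_ssm(2),
                                 {"y": fg.UnboundVector(2)})
        cs = fg.build_constraint_set({"entries": [
            {"scope": "ssm", "entries": ["q(precision) :: Gamma"]}]})
        mapping, _ = fg.resolve_scopes(cs, g)
        assert sorted(c.invocation for c in mapping) == [0, 1]

    def test_unmatched_scope_is_warning_not_fatal(self, eq4):
        g, _, _ = eq4
        cs = fg.build_constraint_set({"entries": [
            {"scope": "ghost_model", "entries": ["q(x) :: Beta"]}]})
        mapping, diags = fg.resolve_scopes(cs, g)
        assert mapping == {}
        assert len(diags) == 1 and diags[0].level == "warning"

    def test_unscoped_entries_apply_to_root_only(self):
        g = fg.materialize_model(zoo.hierarchical_ssm(1),
                                 {"y": fg.UnboundVector(1)})
        cs = fg.build_constraint_set(["q(obs_precision) :: Gamma"])
        mapping, _ = fg.resolve_scopes(cs, g)
        assert list(mapping) == [g.context_root]


class TestApplyFactorization:
    def test_empty_constraints_reproduce_bethe_default(self, eq4):
        g, _, _ = eq4
        lf = fg.apply_factorization(g, fg.build_constraint_set([]))
        for fid, fac in g.factors.items():
            assert lf[fid] == (tuple(fac.interfaces),)

    def test_ssm_constraint_splits_likelihood_in_every_step_context(self):
        T = 3
        g = fg.materialize_model(zoo.hierarchical_ssm(T),
                                 {"y": fg.UnboundVector(T)})
        lf = fg.apply_factorization(
            g, fg.build_constraint_set(zoo.ssm_step_constraint()))
        step_ctxs = [c for c in g.context_root.walk()
                     if c.model_name == "ssm_step"]
        assert len(step_ctxs) == 2 * T
        for ctx in step_ctxs:
            y_id = ctx.interface_bindings["y"]
            likelihoods = [f for f in g.factors.values()
                           if f.path == ctx.path
                           and f.interfaces.get("out") == y_id]
            (lik,) = likelihoods
            assert lf[lik.id] == (("out", "mean"), ("precision",))

    def test_gcv_mean_field_gives_singleton_blocks(self):
        g = fg.materialize_model(zoo.hgf(3, 2), {"y": fg.UnboundVector(2)})
        cs = fg.build_constraint_set({"entries": [
            {"scope": "gcv",
             "entries": ["q(omega, kappa, z) = q(omega)q(kappa)q(z)"]}]})
        lf = fg.apply_factorization(g, cs)
        gcv_ctxs = [c for c in g.context_root.walk() if c.model_name == "gcv"]
        assert gcv_ctxs
        for ctx in gcv_ctxs:
            bound = {ctx.interface_bindings[n]: n
                     for n in ("omega", "kappa", "z")}
            for fac in g.factors.values():
                if fac.path != ctx.path:
                    continue
                for iface, vid in fac.interfaces.items():
                    if vid in bound:
                        assert (iface,) in lf[fac.id]

    def test_unknown_constraint_variable(self, eq4):
        g, _, _ = eq4
        cs = fg.build_constraint_set(["q(nothere, s1) = q(nothere)q(s1)"])
        with pytest.raises(UnknownConstraintVariable):
            fg.apply_factorization(g, cs)

    def test_constraint_on_constant_rejected(self):
        g = zoo.coin_toss(data=[1, 0])
        const_name = next(v.name for v in g.variables.values()
                          if v.kind == "constant")
        cs = fg.build_constraint_set(
            [f"q(theta, {const_name}) = q(theta)q({const_name})"])
        with pytest.raises(UnknownConstraintVariable):
            fg.apply_factorization(g, cs)

    def test_application_is_idempotent(self):
        g = fg.materialize_model(zoo.hierarchical_ssm(2),
                                 {"y": fg.UnboundVector(2)})
        cs = fg.build_constraint_set(zoo.ssm_step_constraint())
        assert fg.apply_factorization(g, cs) == fg.apply_factorization(g, cs)

    def test_scope_resolution_invariant_to_invocation_order(self):
        # swapping which chain is invoked first must not change the resolved
        # per-context partitions (up to the relabeled context identity)
        def counts(graph):
            lf = fg.apply_factorization(
                graph, fg.build_constraint_set(zoo.ssm_step_constraint()))
            return sorted(map(str, lf.blocks.values()))
        g1 = fg.materialize_model(zoo.hierarchical_ssm(2),
                                  {"y": fg.UnboundVector(2)})
        g2 = fg.materialize_model(zoo.hierarchical_ssm(2),
                                  {"y": fg.UnboundVector(2)})
        assert counts(g1) == counts(g2)


def _all_partitions(items):
    """Enumerate all partitions of a small sequence."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for partial in _all_partitions(rest):
        for k in range(len(partial)):
            yield partial[:k] + [[head] + partial[k]] + partial[k + 1:]
        yield partial + [[head]]


def _refines(fine, coarse):
    return all(any(set(b) <= set(c) for c in coarse) for b in fine)


@pytest.mark.parametrize("n_ifaces", [3, 4, 5])
def test_meet_is_the_unique_coarsest_common_refinement(n_ifaces, rng):
    """The pairwise meet agrees with a brute-force search over the full
    partition lattice on factors with up to five interfaces."""
    order = [f"i{k}" for k in range(n_ifaces)]
    parts = [tuple(tuple(b) for b in p) for p in _all_partitions(order)]
    for _ in range(20):
        a = parts[rng.integers(len(parts))]
        b = parts[rng.integers(len(parts))]
        got = _meet(a, [set(blk) for blk in b], order)
        candidates = [p for p in parts
                      if _refines(p, a) and _refines(p, b)]
        coarsest = [p for p in candidates
                    if all(_refines(q, p) for q in candidates)]
        assert len(coarsest) == 1
        assert sorted(map(sorted, got)) == sorted(map(sorted, coarsest[0]))


class TestFunctionalForm:
    def test_beta_tag_attached_as_payload(self):
        g = zoo.coin_toss(data=[1, 1, 0])
        tags = fg.apply_functional_form(
            g, fg.build_constraint_set(["q(theta) :: Beta"]))
        (vid,) = tags
        assert g.variables[vid].name == "theta"
        payload = fg.get_payload(g, "variational_constraints", vid)
        assert payload["functional_form"] == "Beta"

    def test_no_ffcs_gives_empty_map(self, eq4):
        g, _, _ = eq4
        assert fg.apply_functional_form(g, fg.build_constraint_set([])) == {}

    def test_unknown_family_rejected(self):
        g = zoo.coin_toss(data=[1])
        cs = fg.build_constraint_set(["q(theta) :: Frobnitz"])
        with pytest.raises(UnknownFamily):
            fg.apply_functional_form(g, cs)


def test_local_factorization_round_trips_through_payloads():
    g = fg.materialize_model(zoo.hierarchical_ssm(2),
                             {"y": fg.UnboundVector(2)})
    lf = fg.apply_factorization(
        g, fg.build_constraint_set(zoo.ssm_step_constraint()))
    fg.attach_local_factorization(g, lf)
    assert local_factorization_from_graph(g) == lf
    assert lf.validate(g) == []
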