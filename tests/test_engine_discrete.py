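"""Discrete engine against independent oracles: nested-loop enumeration,
the tree identity, the free-energy decomposition."""

import itertools
import math

import numpy as np
import pytest

import ffgraph as fg
from ffgraph import zoo
from ffgraph.errors import StateSpaceTooLarge, SupportMismatch
from conftest import build_eq4, eq4_tables


def nested_loop_marginals(graph, tables):
    """Independent oracle: explicit loops over all joint assignments."""
    latents = sorted(v for v, var in graph.variables.items()
                     if var.kind == "random")
    domains = [tables.domains[v] for v in latents]
    z = 0.0
    marg = {v: np.zeros(len(tables.domains[v])) for v in latents}
    for assignment in itertools.product(*(range(len(d)) for d in domains)):
        state = dict(zip(latents, assignment))
        p = 1.0
        for fid, fac in graph.factors.items():
            idx = []
            for iface, vid in fac.interfaces.items():
                var = graph.variables[vid]
                if var.kind == "random":
                    idx.append(state[vid])
                else:
                    idx.append(tables.domains[vid].index(var.value))
            p *= float(np.asarray(tables.tables[fid])[tuple(idx)])
        z += p
        for v in latents:
            marg[v][state[v]] += p
    return {v: m / z for v, m in marg.items()}, math.log(z)


class TestBruteForce:
    def test_single_normalized_factor(self):
        g = fg.FactorGraph()
        s = g.add_variable(g.context_root, "s")
        f = g.add_factor(g.context_root, "prior", {"out": s})
        t = fg.TableSet(domains={s: [0, 1]},
                        tables={f: np.array([0.2, 0.8])})
        res = fg.brute_force(g, t)
        assert np.allclose(res.marginals[s], [0.2, 0.8])
        assert res.log_evidence == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_eq4_matches_nested_loop_oracle(self, seed):
        g, _, _ = build_eq4()
        t = eq4_tables(g, np.random.default_rng(seed))
        res = fg.brute_force(g, t)
        marg, logz = nested_loop_marginals(g, t)
        assert res.log_evidence == pytest.approx(logz, abs=1e-12)
        for v in marg:
            assert np.allclose(res.marginals[v], marg[v], atol=1e-12)

    def test_clamped_data_matches_nested_loop_oracle(self, rng):
        g = zoo.coin_toss(data=[1, 1, 0])
        t = zoo.coin_toss_grid_tables(g, n_grid=21)
        res = fg.brute_force(g, t)
        marg, logz = nested_loop_marginals(g, t)
        theta = next(v for v, var in g.variables.items()
                     if var.name == "theta")
        assert np.allclose(res.marginals[theta], marg[theta], atol=1e-12)
        assert res.log_evidence == pytest.approx(logz, abs=1e-12)

    def test_coin_grid_posterior_mode(self):
        g = zoo.coin_toss(data=[1, 1, 0])
        t = zoo.coin_toss_grid_tables(g, n_grid=201)
        res = fg.brute_force(g, t)
        theta = next(v for v, var in g.variables.items()
                     if var.name == "theta")
        grid = np.asarray(t.domains[theta])
        mode = grid[np.argmax(res.marginals[theta])]
        assert mode == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_state_space_cap(self, eq4):
        g, _, _ = eq4
        t = eq4_tables(g, np.random.default_rng(0), domain_size=2)
        with pytest.raises(StateSpaceTooLarge):
            fg.brute_force(g, t, cap=3)


class TestSumProduct:
    def test_single_prior_factor_belief_is_normalized_factor(self):
        g = fg.FactorGraph()
        s = g.add_variable(g.context_root, "s")
        f = g.add_factor(g.context_root, "prior", {"out": s})
        t = fg.TableSet(domains={s: [0, 1, 2]},
                        tables={f: np.array([1.0, 2.0, 3.0])})
        res = fg.sum_product(g, t)
        assert np.allclose(res.belief.edge_beliefs[s], [1 / 6, 2 / 6, 3 / 6])

    @pytest.mark.parametrize("seed", range(6))
    def test_eq4_s2_message_product_equals_marginal(self, seed):
        g, s, _ = build_eq4()
        t = eq4_tables(g, np.random.default_rng(seed))
        bf = fg.brute_force(g, t)
        sp = fg.sum_product(g, t)
        assert sp.converged and sp.iterations == 1
        adj = g.variable_adjacency()
        (f1, i1), (f2, i2) = adj[s[2]]
        prod = sp.messages_to_variable[(f1, i1)] \
            * sp.messages_to_variable[(f2, i2)]
        assert np.allclose(prod / prod.sum(), bf.marginals[s[2]], atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_trees_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g, t = zoo.random_tree_model(int(rng.integers(2, 9)), rng)
        bf = fg.brute_force(g, t)
        sp = fg.sum_product(g, t)
        for v, m in bf.marginals.items():
            assert np.abs(sp.belief.edge_beliefs[v] - m).sum() < 1e-10

    def test_four_cycle_weak_coupling_converges_near_exact(self):
        g = fg.FactorGraph()
        c = g.context_root
        vs = [g.add_variable(c, f"s{k}") for k in range(4)]
        rng = np.random.default_rng(7)
        tables = {}
        domains = {v: [0, 1] for v in vs}
        for k in range(4):
            # near-uniform pairwise couplings
            table = 1.0 + 0.05 * rng.standard_normal((2, 2))
            fid = g.add_factor(c, "pair",
                               {"i": vs[k], "j": vs[(k + 1) % 4]})
            tables[fid] = table
        t = fg.TableSet(domains=domains, tables=tables)
        res = fg.sum_product(g, t, max_sweeps=500, tol=1e-12)
        assert res.converged
        bf = fg.brute_force(g, t)
        for v in vs:
            assert np.allclose(res.belief.edge_beliefs[v], bf.marginals[v],
                               atol=1e-4)

    def test_converged_tree_beliefs_satisfy_bethe_constraints(self, rng):
        g, t = zoo.random_tree_model(7, rng)
        sp = fg.sum_product(g, t)
        assert fg.check_constraints(g, sp.belief, tol=1e-9) == []


class TestBetheFreeEnergy:
    @pytest.mark.parametrize("seed", range(6))
    def test_tree_identity_total_equals_minus_log_evidence(self, seed):
        rng = np.random.default_rng(100 + seed)
        g, t = zoo.random_tree_model(int(rng.integers(2, 9)), rng)
        bf = fg.brute_force(g, t)
        sp = fg.sum_product(g, t)
        fe = fg.bethe_free_energy(g, t, sp.belief)
        assert fe.total == pytest.approx(-bf.log_evidence, abs=1e-9)
        assert fe.diagnostics == []

    def test_single_factor_total_is_minus_log_sum(self):
        g = fg.FactorGraph()
        s = g.add_variable(g.context_root, "s")
        f = g.add_factor(g.context_root, "prior", {"out": s})
        t = fg.TableSet(domains={s: [0, 1]}, tables={f: np.array([1.0, 3.0])})
        q = np.array([0.25, 0.75])
        belief = fg.Belief(node_beliefs={f: {("out",): q}},
                           edge_beliefs={s: q})
        fe = fg.bethe_free_energy(g, t, belief)
        assert fe.total == pytest.approx(-math.log(4.0), abs=1e-12)

    def test_support_mismatch_reports_infinity_with_diagnostic(self):
        g = fg.FactorGraph()
        s = g.add_variable(g.context_root, "s")
        f = g.add_factor(g.context_root, "prior", {"out": s})
        t = fg.TableSet(domains={s: [0, 1]}, tables={f: np.array([0.0, 1.0])})
        q = np.array([0.5, 0.5])
        belief = fg.Belief(node_beliefs={f: {("out",): q}},
                           edge_beliefs={s: q})
        fe = fg.bethe_free_energy(g, t, belief)
        assert math.isinf(fe.total)
        assert any("SupportMismatch" in d.message for d in fe.diagnostics)


class TestKlAndVfeDecomposition:
    def test_kl_is_zero_iff_equal(self):
        q = np.array([0.3, 0.7])
        assert fg.kl_divergence(q, q) == pytest.approx(0.0, abs=1e-15)
        p = np.array([0.4, 0.6])
        assert fg.kl_divergence(q, p) > 0

    def test_kl_point_mass_against_uniform(self):
        assert fg.kl_divergence([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_kl_support_mismatch(self):
        with pytest.raises(SupportMismatch):
            fg.kl_divergence([0.5, 0.5], [1.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_vfe_equals_kl_minus_log_evidence(self, seed):
        """F[q] = KL(q || posterior) - log evidence for arbitrary q."""
        rng = np.random.default_rng(200 + seed)
        g, _, _ = build_eq4()
        t = eq4_tables(g, rng)
        from ffgraph.engine import unnormalized_joint
        latents, joint = unnormalized_joint(g, t)
        bf = fg.brute_force(g, t)
        posterior = joint / joint.sum()
        q = rng.uniform(0.05, 1.0, size=joint.shape)
        q = q / q.sum()
        f_q = fg.joint_free_energy(g, t, q)
        kl = fg.kl_divergence(q.ravel(), posterior.ravel())
        assert f_q == pytest.approx(kl - bf.log_evidence, abs=1e-9)
        # at q = posterior the free energy attains -log evidence
        assert fg.joint_free_energy(g, t, posterior) == pytest.approx(
            -bf.log_evidence, abs=1e-9)


class TestCheckConstraints:
    def test_scaled_belief_fails_normalization(self):
        g = fg.FactorGraph()
        s = g.add_variable(g.context_root, "s")
        f = g.add_factor(g.context_root, "prior", {"out": s})
        q = np.array([0.5, 0.5])
        belief = fg.Belief(node_beliefs={f: {("out",): q}},
                           edge_beliefs={s: 2 * q})
        diags = fg.check_constraints(g, belief)
        assert any("sums to" in d.message for d in diags)

    def test_inconsistent_node_and_edge_beliefs_fail_marginalization(self):
        g = fg.FactorGraph()
        s = g.add_variable(g.context_root, "s")
        f = g.add_factor(g.context_root, "prior", {"out": s})
        belief = fg.Belief(
            node_beliefs={f: {("out",): np.array([0.9, 0.1])}},
            edge_beliefs={s: np.array([0.5, 0.5])})
        diags = fg.check_constraints(g, belief)
        assert any("deviates" in d.message for d in diags)
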