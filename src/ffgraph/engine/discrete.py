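"""Discrete reference engine: exact enumeration, sum-product message passing,
Bethe free energy, KL divergence and constraint diagnostics.

All quantities are in nats.  Observed (data) and constant variables are
clamped: their interfaces are indexed out of the factor tables before any
computation, so "evidence" always means the clamped partition sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from ..errors import NotSupported, StateSpaceTooLarge, SupportMismatch
from ..graph import Diagnostic, FactorGraph
from ..constraints import LocalFactorization


@dataclass
class TableSet:
    """Finite domains per variable and one nonnegative table per factor.

    Table axes follow the factor's interface order.
    """
    domains: dict[str, list]
    tables: dict[str, np.ndarray]

    def validate(self, graph: FactorGraph) -> list[Diagnostic]:
        out = []
        for fid, table in self.tables.items():
            fac = graph.factors.get(fid)
            if fac is None:
                out.append(Diagnostic("error", "table for unknown factor", (fid,)))
                continue
            expected = tuple(len(self.domains[v]) for v in fac.interfaces.values())
            if np.asarray(table).shape != expected:
                out.append(Diagnostic(
                    "error", f"table shape {np.asarray(table).shape} != "
                             f"domain sizes {expected}", (fid,)))
            elif np.all(np.asarray(table) == 0):
                out.append(Diagnostic("error", "factor table is all-zero", (fid,)))
            elif np.any(np.asarray(table) < 0):
                out.append(Diagnostic("error", "factor table has negative entries",
                                      (fid,)))
        return out

    def domain_size(self, var_id: str) -> int:
        return len(self.domains[var_id])


@dataclass
class Belief:
    """Node-wise and edge-wise marginal beliefs.

    ``node_beliefs[fid]`` maps a belief block (tuple of latent interface
    names, in table-axis order) to a normalized joint array; ``edge_beliefs``
    maps each latent variable id to a normalized marginal over its domain.
    """
    node_beliefs: dict[str, dict[tuple[str, ...], np.ndarray]]
    edge_beliefs: dict[str, np.ndarray]


@dataclass
class BruteForceResult:
    marginals: dict[str, np.ndarray]
    log_evidence: float
    latent_order: tuple[str, ...]


@dataclass
class SumProductResult:
    belief: Belief
    converged: bool
    iterations: int
    # factor->variable messages keyed by (factor id, interface name)
    messages_to_variable: dict[tuple[str, str], np.ndarray]
    messages_to_factor: dict[tuple[str, str], np.ndarray]


@dataclass
class FreeEnergyReport:
    node_terms: dict[str, float]
    edge_terms: dict[str, float]
    total: float
    diagnostics: list[Diagnostic] = field(default_factory=list)


# -- clamping ------------------------------------------------------------------

def _clamp_index(domain: list, value) -> int:
    for k, v in enumerate(domain):
        if v == value or np.isclose(float(v), float(value)):
            return k
    raise NotSupported(f"observed value {value!r} not in domain {domain!r}")


def _effective_factors(graph: FactorGraph, tables: TableSet):
    """Reduce each table over clamped interfaces.

    Returns {factor id: (latent (iface, var id) pairs, reduced array)}; a
    factor whose interfaces are all clamped reduces to a scalar array.
    """
    out = {}
    for fid, fac in graph.factors.items():
        table = np.asarray(tables.tables[fid], dtype=float)
        idx: list = []
        latent: list[tuple[str, str]] = []
        seen_vars = set()
        for iface, vid in fac.interfaces.items():
            var = graph.variables[vid]
            if var.kind == "random":
                if vid in seen_vars:
                    raise NotSupported(
                        f"variable {var.qualified_name} appears on two "
                        f"interfaces of factor {fac.label}")
                seen_vars.add(vid)
                latent.append((iface, vid))
                idx.append(slice(None))
            else:
                idx.append(_clamp_index(tables.domains[vid], var.value))
        out[fid] = (latent, table[tuple(idx)])
    return out


# -- exact enumeration ---------------------------------------------------------

def unnormalized_joint(graph: FactorGraph, tables: TableSet,
                       cap: int = 10 ** 7) -> tuple[tuple[str, ...], np.ndarray]:
    """The clamped product of all factors as a dense array over the latent
    variables (axis order = returned latent order)."""
    eff = _effective_factors(graph, tables)
    latents = sorted({vid for latent, _ in eff.values() for _, vid in latent})
    axis = {vid: k for k, vid in enumerate(latents)}
    shape = tuple(tables.domain_size(v) for v in latents)
    n_states = int(np.prod(shape)) if shape else 1
    if n_states > cap:
        raise StateSpaceTooLarge(
            f"{n_states} joint states exceed the enumeration cap {cap}")
    joint = np.ones(shape)
    for latent, arr in eff.values():
        if not latent:
            joint = joint * float(arr)
            continue
        axes = [axis[vid] for _, vid in latent]
        order = np.argsort(axes)
        arr_t = np.transpose(arr, order)
        expand = [1] * len(latents)
        for a in sorted(axes):
            expand[a] = shape[a]
        joint = joint * arr_t.reshape(expand)
    return tuple(latents), joint


def brute_force(graph: FactorGraph, tables: TableSet,
                cap: int = 10 ** 7) -> BruteForceResult:
    """Exact marginals and log evidence by summing the clamped joint."""
    latents, joint = unnormalized_joint(graph, tables, cap=cap)
    z = float(joint.sum())
    if z <= 0:
        raise SupportMismatch("clamped joint sums to zero; model excludes the data")
    marginals = {}
    for k, vid in enumerate(latents):
        axes = tuple(a for a in range(len(latents)) if a != k)
        m = joint.sum(axis=axes)
        marginals[vid] = m / m.sum()
    return BruteForceResult(marginals=marginals, log_evidence=math.log(z),
                            latent_order=latents)


# -- sum-product ---------------------------------------------------------------

def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s <= 0:
        raise SupportMismatch("message collapsed to zero; inconsistent tables")
    return v / s


def _factor_to_var(eff, latent, target_iface, incoming):
    """Sum the factor table against all incoming variable messages except the
    target's, leaving the target axis."""
    arr = eff
    target_axis = None
    for a, (iface, vid) in enumerate(latent):
        if iface == target_iface:
            target_axis = a
        else:
            msg = incoming[(iface, vid)]
            shape = [1] * arr.ndim
            shape[a] = len(msg)
            arr = arr * msg.reshape(shape)
    axes = tuple(a for a in range(arr.ndim) if a != target_axis)
    return arr.sum(axis=axes)


def sum_product(graph: FactorGraph, tables: TableSet,
                schedule: str = "auto", max_sweeps: int = 200,
                tol: float = 1e-12, damping: float = 0.5) -> SumProductResult:
    """Sum-product belief propagation at the Bethe default factorization.

    On forests a two-pass leaf-to-root-to-leaf schedule yields the exact
    marginals in a single sweep pair; on cyclic graphs a damped flooding
    schedule iterates until the largest message change drops below ``tol``
    (non-convergence is reported via the flag, never an exception).
    """
    eff = _effective_factors(graph, tables)
    # edges of the latent bipartite graph
    var_adj: dict[str, list[tuple[str, str]]] = {}
    for fid, (latent, _) in eff.items():
        for iface, vid in latent:
            var_adj.setdefault(vid, []).append((fid, iface))

    bip = nx.Graph()
    bip.add_nodes_from(("v", v) for v in var_adj)
    bip.add_nodes_from(("f", f) for f, (lat, _) in eff.items() if lat)
    for fid, (latent, _) in eff.items():
        for iface, vid in latent:
            bip.add_edge(("f", fid), ("v", vid))

    msg_f2v: dict[tuple[str, str], np.ndarray] = {}
    msg_v2f: dict[tuple[str, str], np.ndarray] = {}
    for fid, (latent, _) in eff.items():
        for iface, vid in latent:
            n = tables.domain_size(vid)
            msg_f2v[(fid, iface)] = np.full(n, 1.0 / n)
            msg_v2f[(fid, iface)] = np.full(n, 1.0 / n)

    def compute_v2f(vid, fid, iface):
        out = np.ones(tables.domain_size(vid))
        for (f2, i2) in var_adj[vid]:
            if (f2, i2) != (fid, iface):
                out = out * msg_f2v[(f2, i2)]
        return _normalize(out)

    def compute_f2v(fid, iface):
        latent, arr = eff[fid]
        incoming = {(i2, v2): msg_v2f[(fid, i2)] for i2, v2 in latent}
        return _normalize(_factor_to_var(arr, latent, iface, incoming))

    is_forest = bip.number_of_nodes() == 0 or nx.is_forest(bip)
    use_tree = schedule == "tree" or (schedule == "auto" and is_forest)

    if use_tree and not is_forest:
        raise NotSupported("tree schedule requested on a cyclic graph")

    if use_tree:
        # two-pass schedule: directed edges in leaf->root order, then reversed
        directed: list[tuple] = []
        for comp in nx.connected_components(bip):
            root = next(iter(sorted(comp)))
            parent = dict(nx.bfs_predecessors(bip, root))
            order = list(nx.bfs_tree(bip, root))
            for node in reversed(order):  # leaves first
                if node in parent:
                    directed.append((node, parent[node]))
            for node in order:  # root outward
                if node in parent:
                    directed.append((parent[node], node))
        for src, dst in directed:
            if src[0] == "v":
                vid, fid = src[1], dst[1]
                iface = next(i for f, i in var_adj[vid] if f == fid)
                msg_v2f[(fid, iface)] = compute_v2f(vid, fid, iface)
            else:
                fid, vid = src[1], dst[1]
                latent, _ = eff[fid]
                iface = next(i for i, v in latent if v == vid)
                msg_f2v[(fid, iface)] = compute_f2v(fid, iface)
        converged, iterations = True, 1
    else:
        converged, iterations = False, 0
        for sweep in range(1, max_sweeps + 1):
            delta = 0.0
            for fid, (latent, _) in eff.items():
                for iface, vid in latent:
                    new = compute_v2f(vid, fid, iface)
                    new = damping * msg_v2f[(fid, iface)] + (1 - damping) * new
                    delta = max(delta, float(np.abs(new - msg_v2f[(fid, iface)]).max()))
                    msg_v2f[(fid, iface)] = new
            for fid, (latent, _) in eff.items():
                for iface, vid in latent:
                    new = compute_f2v(fid, iface)
                    new = damping * msg_f2v[(fid, iface)] + (1 - damping) * new
                    delta = max(delta, float(np.abs(new - msg_f2v[(fid, iface)]).max()))
                    msg_f2v[(fid, iface)] = new
            iterations = sweep
            if delta < tol:
                converged = True
                break

    # beliefs
    edge_beliefs = {}
    for vid, adj in var_adj.items():
        b = np.ones(tables.domain_size(vid))
        for (fid, iface) in adj:
            b = b * msg_f2v[(fid, iface)]
        edge_beliefs[vid] = _normalize(b)
    node_beliefs: dict[str, dict[tuple[str, ...], np.ndarray]] = {}
    for fid, (latent, arr) in eff.items():
        if not latent:
            node_beliefs[fid] = {(): np.asarray(1.0)}
            continue
        b = arr.copy()
        for a, (iface, vid) in enumerate(latent):
            shape = [1] * b.ndim
            shape[a] = tables.domain_size(vid)
            b = b * msg_v2f[(fid, iface)].reshape(shape)
        node_beliefs[fid] = {tuple(i for i, _ in latent): b / b.sum()}

    return SumProductResult(
        belief=Belief(node_beliefs=node_beliefs, edge_beliefs=edge_beliefs),
        converged=converged, iterations=iterations,
        messages_to_variable=dict(msg_f2v), messages_to_factor=dict(msg_v2f))


# -- free energies -------------------------------------------------------------

def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(y[pos])
    return out


def kl_divergence(q, p) -> float:
    """KL(q || p) in nats for distributions on the same finite domain."""
    q = np.asarray(q, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if q.shape != p.shape:
        raise SupportMismatch("q and p live on different domains")
    if np.any((q > 0) & (p == 0)):
        raise SupportMismatch("q has mass where p has none")
    return float(np.sum(_xlogy(q, q) - _xlogy(q, p)))


def _entropy(q: np.ndarray) -> float:
    q = np.asarray(q, dtype=float)
    return float(-_xlogy(q, q).sum())


def _assemble_node_belief(blocks: dict[tuple[str, ...], np.ndarray],
                          latent: list[tuple[str, str]]) -> np.ndarray:
    """Joint q_a over the factor's latent interfaces; multi-block beliefs
    multiply as independent blocks."""
    order = [iface for iface, _ in latent]
    joint = np.ones(())
    placed: list[str] = []
    for block, arr in blocks.items():
        joint = np.multiply.outer(joint, np.asarray(arr, dtype=float))
        placed.extend(block)
    if joint.ndim != len(order):
        raise NotSupported("belief blocks do not cover the factor interfaces")
    perm = [placed.index(i) for i in order]
    return np.transpose(joint, perm)


def bethe_free_energy(graph: FactorGraph, tables: TableSet, belief: Belief,
                      local_factorization: Optional[LocalFactorization] = None,
                      ) -> FreeEnergyReport:
    """Assemble the Bethe free energy from node and edge terms.

    Node term: ``sum q_a log(q_a / f_a)`` per factor (clamped interfaces
    folded into f_a).  Edge term: ``(d_i - 1) H[q_i]`` per latent variable of
    degree d_i — the counting correction from the edge beliefs entering the
    Bethe family with negative multiplicity.  Belief mass on a
    zero-probability cell yields +inf with a support diagnostic.
    """
    eff = _effective_factors(graph, tables)
    diagnostics: list[Diagnostic] = []
    node_terms: dict[str, float] = {}
    for fid, (latent, arr) in eff.items():
        if not latent:
            node_terms[fid] = -math.log(float(arr))
            continue
        q = _assemble_node_belief(belief.node_beliefs[fid], latent)
        bad = (q > 0) & (arr == 0)
        if np.any(bad):
            diagnostics.append(Diagnostic(
                "error", "belief mass on zero-probability cell (SupportMismatch)",
                (fid,)))
            node_terms[fid] = math.inf
            continue
        node_terms[fid] = float(np.sum(_xlogy(q, q) - _xlogy(q, arr)))

    degree: dict[str, int] = {}
    for fid, (latent, _) in eff.items():
        for _, vid in latent:
            degree[vid] = degree.get(vid, 0) + 1
    edge_terms = {vid: (degree[vid] - 1) * _entropy(belief.edge_beliefs[vid])
                  for vid in degree}
    total = sum(node_terms.values()) + sum(edge_terms.values())
    return FreeEnergyReport(node_terms=node_terms, edge_terms=edge_terms,
                            total=float(total), diagnostics=diagnostics)


def joint_free_energy(graph: FactorGraph, tables: TableSet,
                      q: np.ndarray, cap: int = 10 ** 7) -> float:
    """Variational free energy ``F[q] = sum q log(q / p~)`` of an arbitrary
    normalized joint q over the latent variables (axes in the brute-force
    latent order)."""
    latents, joint = unnormalized_joint(graph, tables, cap=cap)
    q = np.asarray(q, dtype=float)
    if q.shape != joint.shape:
        raise SupportMismatch("q has the wrong shape for this model")
    if np.any((q > 0) & (joint == 0)):
        return math.inf
    return float(np.sum(_xlogy(q, q) - _xlogy(q, joint)))


# -- constraint checking -------------------------------------------------------

def check_constraints(graph: FactorGraph, belief: Belief,
                      tol: float = 1e-9) -> list[Diagnostic]:
    """Verify the normalization and marginalization constraints of the Bethe
    family: every belief sums to one, and every block marginal of a node
    belief matches the corresponding edge belief."""
    out: list[Diagnostic] = []
    for vid, q in belief.edge_beliefs.items():
        if abs(float(np.sum(q)) - 1.0) > tol:
            out.append(Diagnostic("error",
                                  f"edge belief sums to {float(np.sum(q)):.6g}",
                                  (vid,)))
    for fid, blocks in belief.node_beliefs.items():
        fac = graph.factors[fid]
        for block, arr in blocks.items():
            arr = np.asarray(arr, dtype=float)
            if abs(float(arr.sum()) - 1.0) > tol:
                out.append(Diagnostic(
                    "error", f"node belief block {block} sums to "
                             f"{float(arr.sum()):.6g}", (fid,)))
            for a, iface in enumerate(block):
                vid = fac.interfaces[iface]
                if vid not in belief.edge_beliefs:
                    continue
                axes = tuple(x for x in range(arr.ndim) if x != a)
                marg = arr.sum(axis=axes)
                err = float(np.abs(marg - belief.edge_beliefs[vid]).max())
                if err > tol:
                    out.append(Diagnostic(
                        "error", f"marginal of {iface!r} deviates from edge "
                                 f"belief by {err:.3g}", (fid, vid)))
    return out
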