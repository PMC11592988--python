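"""Closed-form CBFE coordinate ascent for the supported conjugate pairs.

The engine recognizes two tree-structured model patterns directly from the
materialized graph:

* Beta prior + Bernoulli observations (the coin model): the functional-form
  constraint ``q(theta) :: Beta`` is exact, and a single coordinate update
  lands on the conjugate posterior ``Beta(a0 + sum y, b0 + n - sum y)``.
* Normal observations with unknown mean and Gamma-distributed precision
  under a mean-field split between mean and precision: the standard
  Normal–Gamma variational updates, iterated to a fixed point.

Everything else raises :class:`~ffgraph.errors.NotSupported`.  The free
energy is evaluated in closed form after every coordinate sweep; the trace
is checked to be non-increasing (violations are reported as diagnostics,
not exceptions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special, stats

from ..constraints import LocalFactorization, PLUGIN_NAME
from ..errors import NotSupported
from ..graph import Diagnostic, FactorGraph
from .discrete import Belief

_NORMAL_LABELS = {"Normal", "NormalMeanVariance"}


@dataclass
class CbfeResult:
    """Variational parameters per latent variable plus the free-energy trace."""
    params: dict[str, tuple[str, tuple[float, ...]]]
    free_energy_trace: list[float]
    converged: bool
    iterations: int
    diagnostics: list[Diagnostic] = field(default_factory=list)

    def family(self, var_id: str) -> str:
        return self.params[var_id][0]

    def parameters(self, var_id: str) -> tuple[float, ...]:
        return self.params[var_id][1]


def _constant_value(graph: FactorGraph, vid: str):
    var = graph.variables[vid]
    return var.value if var.kind in ("constant", "data") else None


def _family_tags_from_graph(graph: FactorGraph) -> dict[str, str]:
    tags = {}
    for target, payload in graph.plugins.get(PLUGIN_NAME, {}).items():
        if isinstance(payload, dict) and "functional_form" in payload:
            tags[target] = payload["functional_form"]
    return tags


# -- Beta–Bernoulli ------------------------------------------------------------

def _match_beta_bernoulli(graph: FactorGraph):
    betas = graph.factors_by_label("Beta")
    bernoullis = graph.factors_by_label("Bernoulli")
    if len(betas) != 1 or len(betas) + len(bernoullis) != len(graph.factors):
        return None
    beta = betas[0]
    theta = beta.interfaces.get("out")
    if theta is None or graph.variables[theta].kind != "random":
        return None
    a0 = _constant_value(graph, beta.interfaces.get("a", ""))
    b0 = _constant_value(graph, beta.interfaces.get("b", ""))
    if a0 is None or b0 is None:
        return None
    ys = []
    for fac in bernoullis:
        if fac.interfaces.get("p") != theta:
            return None
        y = _constant_value(graph, fac.interfaces["out"])
        if y is None:
            return None
        ys.append(float(y))
    return theta, float(a0), float(b0), np.asarray(ys)


def _beta_free_energy(alpha, beta, a0, b0, ys):
    """F[q] = KL(q || prior) - E_q[log likelihood] for q = Beta(alpha, beta)."""
    kl = (special.betaln(a0, b0) - special.betaln(alpha, beta)
          + (alpha - a0) * special.digamma(alpha)
          + (beta - b0) * special.digamma(beta)
          + (a0 - alpha + b0 - beta) * special.digamma(alpha + beta))
    e_log_t = special.digamma(alpha) - special.digamma(alpha + beta)
    e_log_1mt = special.digamma(beta) - special.digamma(alpha + beta)
    loglik = float(np.sum(ys * e_log_t + (1.0 - ys) * e_log_1mt))
    return float(kl - loglik)


# -- Normal–Gamma --------------------------------------------------------------

def _match_normal_gamma(graph: FactorGraph):
    gammas = graph.factors_by_label("Gamma")
    likelihoods = graph.factors_by_label("NormalMeanPrecision")
    priors = [f for f in graph.factors.values() if f.label in _NORMAL_LABELS]
    if len(gammas) != 1 or len(priors) != 1 or \
            len(gammas) + len(priors) + len(likelihoods) != len(graph.factors):
        return None
    tau = gammas[0].interfaces.get("out")
    mu = priors[0].interfaces.get("out")
    if tau is None or mu is None:
        return None
    if graph.variables[tau].kind != "random" or graph.variables[mu].kind != "random":
        return None
    a0 = _constant_value(graph, gammas[0].interfaces.get("shape", ""))
    b0 = _constant_value(graph, gammas[0].interfaces.get("rate", ""))
    m0 = _constant_value(graph, priors[0].interfaces.get("mean", ""))
    v0 = _constant_value(graph, priors[0].interfaces.get("var", ""))
    if None in (a0, b0, m0, v0):
        return None
    ys = []
    for fac in likelihoods:
        if fac.interfaces.get("mean") != mu or fac.interfaces.get("precision") != tau:
            return None
        y = _constant_value(graph, fac.interfaces["out"])
        if y is None:
            return None
        ys.append(float(y))
    lik_ids = [f.id for f in likelihoods]
    return mu, tau, float(m0), float(v0), float(a0), float(b0), \
        np.asarray(ys), lik_ids


def _requires_mean_field(local_factorization: Optional[LocalFactorization],
                         lik_ids: list[str]) -> bool:
    """True iff every likelihood factor's belief separates the precision
    interface from the mean interface."""
    if local_factorization is None:
        return False
    for fid in lik_ids:
        if fid not in local_factorization.blocks:
            return False
        partition = local_factorization.blocks[fid]
        mean_block = next((b for b in partition if "mean" in b), None)
        if mean_block is None or "precision" in mean_block:
            return False
    return True


def _gauss_kl(m, v, m0, v0):
    return 0.5 * (v / v0 + (m - m0) ** 2 / v0 - 1.0 + math.log(v0 / v))


def _gamma_kl(a, b, a0, b0):
    # rate parameterization
    return float((a - a0) * special.digamma(a) - special.gammaln(a)
                 + special.gammaln(a0) + a0 * (math.log(b) - math.log(b0))
                 + a * (b0 - b) / b)


def _normal_gamma_free_energy(m, v, a, b, m0, v0, a0, b0, ys):
    e_tau = a / b
    e_log_tau = special.digamma(a) - math.log(b)
    sq = np.sum((ys - m) ** 2 + v)
    loglik = 0.5 * len(ys) * (e_log_tau - math.log(2 * math.pi)) \
        - 0.5 * e_tau * sq
    return float(_gauss_kl(m, v, m0, v0) + _gamma_kl(a, b, a0, b0) - loglik)


# -- driver --------------------------------------------------------------------

def cbfe_coordinate_ascent(graph: FactorGraph,
                           local_factorization: Optional[LocalFactorization] = None,
                           family_tags: Optional[dict[str, str]] = None,
                           max_iters: int = 50, tol: float = 1e-12,
                           seed: Optional[int] = None) -> CbfeResult:
    """Minimize the constrained Bethe free energy by coordinate ascent over
    parametric beliefs, for the supported conjugate model patterns.

    ``family_tags`` (variable id -> family) defaults to the functional-form
    payloads attached to the graph.  ``seed`` is accepted for interface
    uniformity; the conjugate updates are deterministic.
    """
    del seed  # deterministic closed-form updates
    if family_tags is None:
        family_tags = _family_tags_from_graph(graph)

    hit = _match_beta_bernoulli(graph)
    if hit is not None:
        theta, a0, b0, ys = hit
        tag = family_tags.get(theta)
        if tag is not None and tag != "Beta":
            raise NotSupported(
                f"functional form {tag!r} on the Beta-model latent is not "
                "conjugate; only Beta is supported")
        alpha, beta = a0, b0
        trace = [_beta_free_energy(alpha, beta, a0, b0, ys)]
        converged, its = False, 0
        for its in range(1, max_iters + 1):
            new_alpha = a0 + float(ys.sum())
            new_beta = b0 + float(len(ys) - ys.sum())
            delta = abs(new_alpha - alpha) + abs(new_beta - beta)
            alpha, beta = new_alpha, new_beta
            trace.append(_beta_free_energy(alpha, beta, a0, b0, ys))
            if delta < tol:
                converged = True
                break
        diagnostics = _monotonicity_diagnostics(trace)
        return CbfeResult(params={theta: ("Beta", (alpha, beta))},
                          free_energy_trace=trace, converged=converged,
                          iterations=its, diagnostics=diagnostics)

    hit = _match_normal_gamma(graph)
    if hit is not None:
        mu, tau, m0, v0, a0, b0, ys, lik_ids = hit
        if not _requires_mean_field(local_factorization, lik_ids):
            raise NotSupported(
                "the joint belief over mean and precision is not conjugate; "
                "supply a factorization constraint separating them")
        for vid, fam in ((mu, "Normal"), (tau, "Gamma")):
            tag = family_tags.get(vid)
            if tag is not None and not tag.startswith(fam):
                raise NotSupported(f"functional form {tag!r} on {vid} is not "
                                   f"conjugate (expected {fam})")
        n = len(ys)
        m, v = m0, v0
        a, b = a0, b0
        trace = [_normal_gamma_free_energy(m, v, a, b, m0, v0, a0, b0, ys)]
        converged, its = False, 0
        for its in range(1, max_iters + 1):
            e_tau = a / b
            prec = 1.0 / v0 + n * e_tau
            new_m = (m0 / v0 + e_tau * float(ys.sum())) / prec
            new_v = 1.0 / prec
            new_a = a0 + n / 2.0
            new_b = b0 + 0.5 * float(np.sum((ys - new_m) ** 2 + new_v))
            delta = abs(new_m - m) + abs(new_v - v) + abs(new_a - a) + abs(new_b - b)
            m, v, a, b = new_m, new_v, new_a, new_b
            trace.append(_normal_gamma_free_energy(m, v, a, b, m0, v0, a0, b0, ys))
            if delta < tol:
                converged = True
                break
        diagnostics = _monotonicity_diagnostics(trace)
        return CbfeResult(params={mu: ("NormalMeanVariance", (m, v)),
                                  tau: ("Gamma", (a, b))},
                          free_energy_trace=trace, converged=converged,
                          iterations=its, diagnostics=diagnostics)

    raise NotSupported(
        "no supported conjugate structure found (Beta–Bernoulli or "
        "Normal mean with Gamma precision)")


def _monotonicity_diagnostics(trace: list[float],
                              slack: float = 1e-9) -> list[Diagnostic]:
    out = []
    for k in range(1, len(trace)):
        if trace[k] > trace[k - 1] + slack:
            out.append(Diagnostic(
                "error", f"free energy increased at step {k} "
                         f"({trace[k - 1]:.9g} -> {trace[k]:.9g}) "
                         "(NonDecreasingEnergy)"))
    return out


def beta_belief_on_grid(graph: FactorGraph, result: CbfeResult,
                        n_grid: int = 201) -> tuple[Belief, np.ndarray]:
    """Discretize a converged Beta belief onto a midpoint grid, producing
    node- and edge-wise beliefs suitable for the normalization and
    marginalization checks.  Returns (belief, grid points)."""
    (theta, (family, (alpha, beta))), = result.params.items()
    if family != "Beta":
        raise NotSupported("grid discretization implemented for Beta beliefs")
    grid = (np.arange(n_grid) + 0.5) / n_grid
    q = stats.beta.pdf(grid, alpha, beta)
    q = q / q.sum()
    node_beliefs = {}
    for fid, fac in graph.factors.items():
        latent = tuple(i for i, v in fac.interfaces.items()
                       if graph.variables[v].kind == "random")
        if latent == ():
            continue
        if any(fac.interfaces[i] != theta for i in latent):
            raise NotSupported("grid discretization supports a single latent")
        node_beliefs[fid] = {latent: q.copy()}
    return Belief(node_beliefs=node_beliefs, edge_beliefs={theta: q}), grid
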