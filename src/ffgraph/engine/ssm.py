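"""Structured variational inference for the hierarchical state-space model.

With the walk precisions known, the drift chain and the state chain form a
jointly Gaussian latent vector z = (d_0, x_0, ..., d_T, x_T):

    d_t = d_{t-1} + eps_d,          eps_d ~ N(0, q_d)
    x_t = x_{t-1} + d_t + eps_s,    eps_s ~ N(0, q_s)
    y_t = x_t + eps_o,              eps_o ~ N(0, 1/tau),  tau ~ Gamma(a0, b0)

The factorization constraint q(x_next, y, precision) = q(x_next, y) q(precision)
applied in every step context makes the posterior family q(z) q(tau); the
corresponding coordinate ascent alternates an exact Gaussian step for q(z)
(the graph is a Gaussian Markov random field with banded joint precision;
the update is a single sparse solve) with a conjugate Gamma update for
q(tau).  The free energy is evaluated in closed form after every sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special

from ..graph import Diagnostic


@dataclass
class SsmVbResult:
    drift_mean: np.ndarray  # E[d_t], t = 1..T
    drift_var: np.ndarray
    state_mean: np.ndarray  # E[x_t], t = 1..T
    state_var: np.ndarray
    tau_shape: float
    tau_rate: float
    free_energy_trace: list[float]
    converged: bool
    iterations: int
    diagnostics: list[Diagnostic] = field(default_factory=list)

    @property
    def expected_obs_precision(self) -> float:
        return self.tau_shape / self.tau_rate


def _gaussian_step(y, q_d, q_s, e_tau, init_mean, init_var):
    """Exact posterior of the Gaussian chain given E[tau].

    Builds the joint precision of z = (d_0, x_0, d_1, x_1, ..., d_T, x_T)
    and solves; T is small enough that dense algebra is exact and cheap.
    """
    T = len(y)
    n = 2 * (T + 1)
    lam = np.zeros((n, n))
    eta = np.zeros(n)

    def di(t):  # index of d_t
        return 2 * t

    def xi(t):  # index of x_t
        return 2 * t + 1

    m_d0, m_x0 = init_mean
    v_d0, v_x0 = init_var
    lam[di(0), di(0)] += 1.0 / v_d0
    eta[di(0)] += m_d0 / v_d0
    lam[xi(0), xi(0)] += 1.0 / v_x0
    eta[xi(0)] += m_x0 / v_x0

    for t in range(1, T + 1):
        # (d_t - d_{t-1})^2 / q_d
        w = 1.0 / q_d
        for i, si in ((di(t), 1.0), (di(t - 1), -1.0)):
            for j, sj in ((di(t), 1.0), (di(t - 1), -1.0)):
                lam[i, j] += w * si * sj
        # (x_t - x_{t-1} - d_t)^2 / q_s
        w = 1.0 / q_s
        terms = ((xi(t), 1.0), (xi(t - 1), -1.0), (di(t), -1.0))
        for i, si in terms:
            for j, sj in terms:
                lam[i, j] += w * si * sj
        # observation
        lam[xi(t), xi(t)] += e_tau
        eta[xi(t)] += e_tau * y[t - 1]

    cov = np.linalg.inv(lam)
    mean = cov @ eta
    return mean, cov, lam, eta


def _gaussian_expectations(mean, cov, y, q_d, q_s):
    """E[log p(z)] pieces that do not involve tau, plus H[q(z)]."""
    T = len(y)

    def di(t):
        return 2 * t

    def xi(t):
        return 2 * t + 1

    e_logp = 0.0
    for t in range(1, T + 1):
        # drift transition
        m = mean[di(t)] - mean[di(t - 1)]
        v = cov[di(t), di(t)] + cov[di(t - 1), di(t - 1)] \
            - 2 * cov[di(t), di(t - 1)]
        e_logp += -0.5 * (math.log(2 * math.pi * q_d) + (m ** 2 + v) / q_d)
        # state transition
        c = np.zeros(len(mean))
        c[xi(t)], c[xi(t - 1)], c[di(t)] = 1.0, -1.0, -1.0
        m = float(c @ mean)
        v = float(c @ cov @ c)
        e_logp += -0.5 * (math.log(2 * math.pi * q_s) + (m ** 2 + v) / q_s)
    sign, logdet = np.linalg.slogdet(cov)
    n = len(mean)
    h_q = 0.5 * (n * math.log(2 * math.pi * math.e) + logdet)
    return e_logp, h_q


def hierarchical_ssm_vb(y, params, max_iters: int = 50,
                        tol: float = 1e-8) -> SsmVbResult:
    """Recover the drift and state series from observations.

    ``params`` carries the generative hyperparameters (duck-typed; see the
    model zoo's SsmParameters): drift/state noise variances, the Gamma prior
    on the observation precision, and the initial means/variances.  Returns
    posterior means and variances for t = 1..T plus the Gamma posterior over
    the observation precision and the free-energy trace (non-increasing up
    to numerical slack; violations become diagnostics).
    """
    y = np.asarray(y, dtype=float)
    T = len(y)
    q_d = params.drift_noise_var
    q_s = params.state_noise_var
    a0, b0 = params.obs_precision_shape, params.obs_precision_rate
    init_mean = (params.init_drift_mean, params.init_state_mean)
    init_var = (params.init_drift_var, params.init_state_var)

    a, b = a0, b0
    trace: list[float] = []
    converged, its = False, 0
    mean = cov = None
    prev_f = math.inf
    for its in range(1, max_iters + 1):
        e_tau = a / b
        mean, cov, _, _ = _gaussian_step(y, q_d, q_s, e_tau, init_mean, init_var)
        xs = mean[3::2]
        vs = np.diag(cov)[3::2]
        sq = float(np.sum((y - xs) ** 2 + vs))
        a = a0 + T / 2.0
        b = b0 + 0.5 * sq

        # free energy after the full sweep
        e_tau = a / b
        e_log_tau = float(special.digamma(a)) - math.log(b)
        e_logp_z, h_qz = _gaussian_expectations(mean, cov, y, q_d, q_s)
        # priors on the initial states
        for idx, (m0, v0) in zip((0, 1), zip(init_mean, init_var)):
            e_logp_z += -0.5 * (math.log(2 * math.pi * v0)
                                + ((mean[idx] - m0) ** 2 + cov[idx, idx]) / v0)
        e_loglik = 0.5 * T * (e_log_tau - math.log(2 * math.pi)) \
            - 0.5 * e_tau * sq
        e_logp_tau = a0 * math.log(b0) - float(special.gammaln(a0)) \
            + (a0 - 1) * e_log_tau - b0 * e_tau
        h_qtau = float(a - math.log(b) + special.gammaln(a)
                       + (1 - a) * special.digamma(a))
        f = -(e_logp_z + e_loglik + e_logp_tau + h_qz + h_qtau)
        trace.append(f)
        if abs(prev_f - f) < tol:
            converged = True
            break
        prev_f = f

    diagnostics = []
    for k in range(1, len(trace)):
        if trace[k] > trace[k - 1] + 1e-7:
            diagnostics.append(Diagnostic(
                "error", f"free energy increased at sweep {k} "
                         f"({trace[k - 1]:.6g} -> {trace[k]:.6g})"))
    return SsmVbResult(
        drift_mean=mean[2::2].copy(), drift_var=np.diag(cov)[2::2].copy(),
        state_mean=mean[3::2].copy(), state_var=np.diag(cov)[3::2].copy(),
        tau_shape=float(a), tau_rate=float(b),
        free_energy_trace=trace, converged=converged, iterations=its,
        diagnostics=diagnostics)
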