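"""Executable model fixtures and the synthetic time-series generator.

Every model here is built through the public builder surface, so the zoo
doubles as an end-to-end exercise of the specification language: tilde
statements, deterministic folding, compound unrolling, vector variables,
submodel invocation with missing-interface binding, and nested contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .builder import (
    ModelBuilder,
    ModelDefinition,
    UnboundVector,
    call,
    define_model,
    materialize_model,
)
from .engine.discrete import TableSet
from .graph import FactorGraph
from .registry import NodeTypeRegistry

__all__ = [
    "coin_toss_model", "coin_toss", "gcv", "gcv_lm", "hgf", "hgf_flat",
    "neural_dot", "neuron", "dense", "bnn", "ssm_step", "ssm",
    "hierarchical_ssm", "SsmParameters", "generate_ssm_data",
    "ssm_step_constraint", "coin_toss_grid_tables", "random_tree_model",
]


# -- coin toss -----------------------------------------------------------------

def _coin_toss_body(m: ModelBuilder, y):
    m.tilde("theta", call("Beta", 1, 1))
    for i in range(len(y)):
        m.tilde(y[i], call("Bernoulli", m["theta"]))


def coin_toss_model() -> ModelDefinition:
    """Beta(1, 1) prior on the bias, one Bernoulli factor per toss."""
    return define_model("coin_toss", ["y"], _coin_toss_body)


def coin_toss(n: Optional[int] = None, data=None,
              registry: Optional[NodeTypeRegistry] = None) -> FactorGraph:
    """Materialize the coin model for ``n`` latent tosses or an observed
    0/1 array."""
    if (n is None) == (data is None):
        raise ValueError("supply exactly one of n or data")
    binding = UnboundVector(n) if data is None else np.asarray(data, dtype=float)
    return materialize_model(coin_toss_model(), {"y": binding},
                             registry=registry)


# -- Gaussian with controlled variance ----------------------------------------

def _gcv_body(m: ModelBuilder, y, x, z, kappa, omega):
    # compound statement: *, +, exp and Normal materialize from one line
    m.tilde(y, call("Normal", x,
                    call("exp", call("+", call("*", kappa, z), omega))))


def _gcv_assign_body(m: ModelBuilder, y, x, z, kappa, omega):
    # the same model through deterministic := statements
    m.assign("s", call("*", kappa, z))
    m.assign("t", call("+", m["s"], omega))
    m.assign("v", call("exp", m["t"]))
    m.tilde(y, call("Normal", x, m["v"]))


def gcv(style: str = "compound") -> ModelDefinition:
    """Gaussian-with-Controlled-Variance: ``y ~ N(x, exp(kappa*z + omega))``.

    ``style`` picks the compound-statement or assignment-style body; both
    create the same factor graph.
    """
    body = {"compound": _gcv_body, "assign": _gcv_assign_body}[style]
    return define_model("gcv", ["y", "x", "z", "kappa", "omega"], body)


_GCV_LM_OBS_VAR = 1.0  # fixed observation variance of the likelihood stage


def _gcv_lm_body(m: ModelBuilder, y, x, x_prev, z, kappa, omega):
    m.invoke(gcv(), lhs=x, x=x_prev, z=z, kappa=kappa, omega=omega)
    m.tilde(y, call("Normal", x, _GCV_LM_OBS_VAR))


def gcv_lm() -> ModelDefinition:
    """gcv state transition chained with a Gaussian likelihood.

    The new state ``x`` receives gcv's missing interface, so one line both
    advances the chain and attaches the observation.
    """
    return define_model("gcv_lm", ["y", "x", "x_prev", "z", "kappa", "omega"],
                        _gcv_lm_body)


# -- hierarchical Gaussian filter ---------------------------------------------

_HGF_INIT_VAR = 1.0


def _hgf_statements(m: ModelBuilder, y, xi, kappa, omega,
                    depth: int, T: int, flat: bool):
    """Shared statement sequence for the nested and hand-flattened builds."""
    for ell in range(1, depth + 1):
        m.tilde(m.var(f"x{ell}")[0], call("Normal", 0.0, _HGF_INIT_VAR))
    for t in range(T):
        # top layer is a plain Gaussian random walk with variance xi
        m.tilde(m.var(f"x{depth}")[t + 1],
                call("Normal", m.var(f"x{depth}")[t], xi))
        for ell in range(depth - 1, 1, -1):
            if flat:
                m.tilde(m.var(f"x{ell}")[t + 1],
                        call("Normal", m.var(f"x{ell}")[t],
                             call("exp", call("+",
                                              call("*", kappa,
                                                   m.var(f"x{ell + 1}")[t + 1]),
                                              omega))))
            else:
                m.invoke(gcv(), lhs=m.var(f"x{ell}")[t + 1],
                         x=m.var(f"x{ell}")[t], z=m.var(f"x{ell + 1}")[t + 1],
                         kappa=kappa, omega=omega)
        if flat:
            m.tilde(m.var("x1")[t + 1],
                    call("Normal", m.var("x1")[t],
                         call("exp", call("+", call("*", kappa,
                                                    m.var("x2")[t + 1]),
                                          omega))))
            m.tilde(y[t], call("Normal", m.var("x1")[t + 1], _GCV_LM_OBS_VAR))
        else:
            m.invoke(gcv_lm(), lhs=m.var("x1")[t + 1], y=y[t],
                     x_prev=m.var("x1")[t], z=m.var("x2")[t + 1],
                     kappa=kappa, omega=omega)


def hgf(depth: int = 3, T: int = 3) -> ModelDefinition:
    """Hierarchical Gaussian filter built from gcv and gcv_lm submodels.

    ``depth`` latent layers: the top is a Gaussian random walk, each lower
    layer's transition variance is controlled by the layer above through a
    gcv submodel, and the bottom layer emits the observations through
    gcv_lm.  Three levels is the common default.
    """
    if depth < 2 or T < 1:
        raise ValueError("depth must be >= 2 and T >= 1")

    def body(m, y, xi, kappa, omega):
        _hgf_statements(m, y, xi, kappa, omega, depth, T, flat=False)
    return define_model("hgf", ["y", "xi", "kappa", "omega"], body)


def hgf_flat(depth: int = 3, T: int = 3) -> ModelDefinition:
    """The same filter with every submodel inlined by hand; used to check
    that nesting only renames anonymous variables."""
    if depth < 2 or T < 1:
        raise ValueError("depth must be >= 2 and T >= 1")

    def body(m, y, xi, kappa, omega):
        _hgf_statements(m, y, xi, kappa, omega, depth, T, flat=True)
    return define_model("hgf", ["y", "xi", "kappa", "omega"], body)


# -- Bayesian neural network ---------------------------------------------------

def neural_dot(dim: int) -> ModelDefinition:
    """Dot product of a ``dim``-vector input with a weight vector, squashed
    through a tanh activation — the basic neural building block."""
    def body(m: ModelBuilder, out, w, **kw):
        inp = kw["in"]
        args = [inp[i] for i in range(dim)] + [w[i] for i in range(dim)]
        m.assign("s", call("dot", *args))
        m.assign(out, call("tanh", m["s"]))
    return define_model("neural_dot", ["out", "in", "w"], body)


def neuron(dim: int) -> ModelDefinition:
    """Standard-normal weight priors feeding one neural_dot application."""
    def body(m: ModelBuilder, out, **kw):
        inp = kw["in"]
        w = m.vector("w", dim)
        for i in range(dim):
            m.tilde(w[i], call("Normal", 0.0, 1.0))
        m.invoke(neural_dot(dim), lhs=out, **{"in": inp, "w": w})
    return define_model("neuron", ["out", "in"], body)


def dense(dim_in: int, dim_out: int) -> ModelDefinition:
    """Fully connected layer: ``dim_out`` neurons sharing one input vector."""
    def body(m: ModelBuilder, out, **kw):
        inp = kw["in"]
        if out.length is None and dim_out != 1:
            raise ValueError("dense output must be bound to a vector")
        for j in range(dim_out):
            lhs = out[j] if out.length is not None else out
            m.invoke(neuron(dim_in), lhs=lhs, **{"in": inp})
    return define_model("dense", ["out", "in"], body)


def bnn(layer_sizes: Sequence[int] = (2, 4, 4, 2, 1)) -> ModelDefinition:
    """Multilayer perceptron with Bayesian weights.

    ``layer_sizes`` lists the input dimension followed by each layer's
    width; the default chains four dense layers down to a scalar output.
    """
    sizes = list(layer_sizes)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValueError("layer_sizes needs >= 2 positive entries")

    def body(m: ModelBuilder, out, **kw):
        prev = kw["in"]
        for k in range(1, len(sizes)):
            if k == len(sizes) - 1:
                target = out
            else:
                target = m.vector(f"h{k}", sizes[k])
            m.invoke(dense(sizes[k - 1], sizes[k]),
                     **{"out": target, "in": prev})
            prev = target
    return define_model("bnn", ["out", "in"], body)


# -- hierarchical state-space model -------------------------------------------

_SSM_WALK_PRECISION = 10.0  # fixed within-chain random-walk precision


def ssm_step() -> ModelDefinition:
    """One step of the state-space pattern: two Gaussians summed, a Gaussian
    state transition, and an observation with a shared precision.

    ``tmp := x_prev + u;  x_next ~ N(tmp, 1/walk);  y ~ N(x_next, 1/precision)``
    """
    def body(m: ModelBuilder, y, x_prev, u, x_next, precision):
        m.assign("tmp", call("+", x_prev, u))
        m.tilde(x_next, call("Normal", mean=m["tmp"],
                             precision=_SSM_WALK_PRECISION))
        m.tilde(y, call("Normal", mean=x_next, precision=precision))
    return define_model("ssm_step",
                        ["y", "x_prev", "u", "x_next", "precision"], body)


def ssm(T: int) -> ModelDefinition:
    """A chain of T ssm_step invocations over a shared precision."""
    def body(m: ModelBuilder, y, u, precision):
        x = m.vector("x", T + 1)
        m.tilde(x[0], call("Normal", 0.0, 1.0))
        step = ssm_step()
        for t in range(T):
            m.invoke(step, lhs=y[t], x_prev=x[t], u=u[t],
                     x_next=x[t + 1], precision=precision)
    return define_model("ssm", ["y", "u", "precision"], body)


def hierarchical_ssm(T: int) -> ModelDefinition:
    """Random walk with drift where the drift is itself a random walk.

    The ssm submodel is used exactly twice: once producing the latent drift
    series and once, driven by that drift, producing the observations.  Each
    chain's observation precision carries a Gamma prior.
    """
    def body(m: ModelBuilder, y):
        m.tilde("drift_precision", call("Gamma", 2.0, 2.0))
        m.tilde("obs_precision", call("Gamma", 2.0, 2.0))
        drift = m.vector("drift", T)
        zero = m.constant_vector("zero", np.zeros(T))
        chain = ssm(T)
        m.invoke(chain, y=drift, u=zero, precision=m["drift_precision"])
        m.invoke(chain, y=y, u=drift, precision=m["obs_precision"])
    return define_model("hierarchical_ssm", ["y"], body)


def ssm_step_constraint():
    """The structured constraint of the state-space experiment: in every
    step context, the observation belief stays joint with the new state but
    independent of the precision."""
    return {"entries": [
        {"scope": ["ssm", "ssm_step"],
         "entries": ["q(x_next, y, precision) = q(x_next, y) q(precision)"]},
    ]}


@dataclass
class SsmParameters:
    """Hyperparameters of the hierarchical state-space generator.

    Variances are in squared observation units; the observation precision
    is drawn once per dataset from the Gamma(shape, rate) hyperprior.
    """
    drift_noise_var: float = 0.01
    state_noise_var: float = 0.1
    obs_precision_shape: float = 2.0
    obs_precision_rate: float = 2.0
    init_drift_mean: float = 0.0
    init_drift_var: float = 1.0
    init_state_mean: float = 0.0
    init_state_var: float = 1.0

    def __post_init__(self):
        for name in ("drift_noise_var", "state_noise_var",
                     "obs_precision_shape", "obs_precision_rate",
                     "init_drift_var", "init_state_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_ssm_data(T: int, params: Optional[SsmParameters] = None,
                      seed: int = 0):
    """Simulate the hierarchical random walk.

    ``drift_t = drift_{t-1} + eps_d``, ``state_t = state_{t-1} + drift_t +
    eps_s``, ``obs_t = state_t + eps_o``, with the observation precision
    drawn once from the Gamma hyperprior.  A fixed seed gives bit-identical
    output.  Returns (drift, state, obs) arrays of length T.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    params = params or SsmParameters()
    rng = np.random.default_rng(seed)
    tau = rng.gamma(shape=params.obs_precision_shape,
                    scale=1.0 / params.obs_precision_rate)
    obs_sd = 1.0 / np.sqrt(tau)
    d = params.init_drift_mean \
        + np.sqrt(params.init_drift_var) * rng.standard_normal()
    x = params.init_state_mean \
        + np.sqrt(params.init_state_var) * rng.standard_normal()
    sd_d = np.sqrt(params.drift_noise_var)
    sd_s = np.sqrt(params.state_noise_var)
    drift = np.empty(T)
    state = np.empty(T)
    obs = np.empty(T)
    for t in range(T):
        d = d + sd_d * rng.standard_normal()
        x = x + d + sd_s * rng.standard_normal()
        drift[t] = d
        state[t] = x
        obs[t] = x + obs_sd * rng.standard_normal()
    return drift, state, obs


# -- discrete fixtures ---------------------------------------------------------

def coin_toss_grid_tables(graph: FactorGraph, n_grid: int = 201) -> TableSet:
    """Discretize the coin model's bias onto a midpoint grid so the exact
    enumeration oracle applies: the Beta factor becomes a density table over
    the grid, each Bernoulli factor a (toss x grid) table."""
    from scipy import stats
    grid = (np.arange(n_grid) + 0.5) / n_grid
    domains: dict[str, list] = {}
    tables: dict[str, np.ndarray] = {}
    for vid, var in graph.variables.items():
        domains[vid] = list(grid) if var.name == "theta" else [0.0, 1.0]
    for fid, fac in graph.factors.items():
        if fac.label == "Beta":
            a = graph.variables[fac.interfaces["a"]].value
            b = graph.variables[fac.interfaces["b"]].value
            col = stats.beta.pdf(grid, a, b) / n_grid
            # axes follow the interface order (out, a, b); the prior density
            # does not vary with its clamped hyperparameter interfaces
            tables[fid] = np.tile(col.reshape(-1, 1, 1), (1, 2, 2))
        elif fac.label == "Bernoulli":
            t = np.empty((2, n_grid))  # axes (out, p)
            t[0] = 1.0 - grid
            t[1] = grid
            tables[fid] = t
        else:
            raise ValueError(f"unexpected factor {fac.label!r} in coin graph")
    return TableSet(domains=domains, tables=tables)


def random_tree_model(n_vars: int, rng: np.random.Generator,
                      max_domain: int = 3):
    """Random acyclic discrete factor graph: a random tree over ``n_vars``
    variables with one pairwise factor per tree edge, a unary prior on the
    root, and positive random tables.  Returns (graph, tables)."""
    graph = FactorGraph("random_tree")
    root_ctx = graph.context_root
    domains: dict[str, list] = {}
    ids = []
    sizes = rng.integers(2, max_domain + 1, size=n_vars)
    for k in range(n_vars):
        vid = graph.add_variable(root_ctx, f"s{k}", "random")
        ids.append(vid)
        domains[vid] = list(range(int(sizes[k])))
    tables: dict[str, np.ndarray] = {}
    fid = graph.add_factor(root_ctx, "prior", {"out": ids[0]})
    tables[fid] = rng.uniform(0.1, 1.0, size=(len(domains[ids[0]]),))
    for k in range(1, n_vars):
        parent = int(rng.integers(0, k))
        fid = graph.add_factor(root_ctx, "pair",
                               {"in1": ids[parent], "in2": ids[k]})
        tables[fid] = rng.uniform(0.1, 1.0,
                                  size=(len(domains[ids[parent]]),
                                        len(domains[ids[k]])))
    return graph, TableSet(domains=domains, tables=tables)
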