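# ffgraph

A Python toolkit for specifying probabilistic models as **Forney-style
factor graphs (FFGs)** and making them executable with a reference
**Constrained Bethe Free Energy (CBFE)** engine.

Models are written as ordinary Python callables that record *tilde
statements* against a builder — no macros, no inference assumptions baked
into the model.  Materialization produces a plain graph data structure
(factor nodes, variable nodes, a context tree of submodel invocations) that
can be validated, serialized to JSON, rendered as DOT, decorated with
inference-specific plugin payloads, and executed by the bundled engine.
The intended users are researchers building hierarchical graphical models
(state-space models, hierarchical Gaussian filters, Bayesian networks of
conjugate blocks) who want a clean separation between *what the model is*
and *how inference is done*.

## The model language in one paragraph

A generative model `p(s) = ∏_a f_a(s_a)` is an FFG whose vertices are the
factors `f_a` and whose (hyper-)edges are the variables.  A statement
`θ ~ Beta(1, 1)` creates a Beta factor node, the variable `θ`, and one
constant variable node per literal.  Deterministic relations use `:=` (an
alias of `~`): when every argument is known at build time the evaluator
runs and **no node is created** (folding); otherwise a deterministic factor
is materialized.  Compound right-hand sides such as
`y ~ N(x, exp(κ·z + ω))` unroll innermost-first into `*`, `+`, `exp`, and
`Normal` nodes.  Any model is reusable as a submodel: supplying all but one
interface by keyword binds the missing interface to the statement's
left-hand side, and each invocation gets its own context (`gcv:0`,
`gcv:1`, …) so names never collide.  Grouping factors and marginalizing
their interior ("closing the box") exposes exactly the Markov blanket —
the boundary-crossing variables — which is what makes the nesting sound.

## Variational constraints

The variational family defaults to the Bethe family

    q(s) = ∏_a q_a(s_a) · ∏_i q_i(s_i)^−(d_i − 1),

with node beliefs `q_a`, edge beliefs `q_i`, and degree correction
`d_i − 1`.  The Bethe free energy

    F[q] = Σ_a ∫ q_a log (q_a / f_a) + Σ_i (d_i − 1) H[q_i]

is minimized subject to normalization and marginalization constraints.
**Factorization constraints** like `q(x, y, z) = q(x, y) q(z)` refine the
per-factor belief blocks (the resolved partition is the coarsest one
consistent with every applicable constraint); **functional-form
constraints** like `q(θ) :: Beta` pin a marginal to a family.  Constraints
are scoped: a pattern such as `["ssm", "ssm_step"]` applies to *every*
invocation of that submodel, regardless of how many times it was unrolled.

The engine makes all of this checkable at desk scale: exact enumeration,
sum-product belief propagation (exact on trees; `F = −log Z` at the fixed
point), closed-form CBFE coordinate ascent for conjugate pairs
(Beta–Bernoulli, Normal mean with Gamma precision), and a structured
Gaussian solver for the hierarchical state-space model.

## Worked example

```python
import ffgraph as fg
from ffgraph import zoo

graph = zoo.coin_toss(data=[1, 1, 0])          # θ ~ Beta(1,1); y_i ~ Bernoulli(θ)
print(len(graph.factors), len(graph.variables))

fg.apply_functional_form(graph, fg.build_constraint_set(["q(theta) :: Beta"]))
result = fg.cbfe_coordinate_ascent(graph)
print(result.params)
print([round(f, 4) for f in result.free_energy_trace])
```

prints

```
4 6
{'v3': ('Beta', (3.0, 2.0))}
[3.0, 2.4849, 2.4849]
```

Four factors (one Beta prior, three Bernoulli likelihoods) over six
variables (θ, three observations, two constants); the coordinate ascent
lands on the conjugate posterior `Beta(1 + Σy, 1 + n − Σy) = Beta(3, 2)` in
one step, and the free-energy trace is non-increasing.  The posterior mean
is 3/5 = 0.6 — after seeing two heads and a tail, the bias estimate moves
from 1/2 toward heads.

The same workflow runs from the shell.  The end-to-end state-space demo
generates data from a random walk whose drift is itself a random walk
(observation precision drawn from a Gamma(2, 2) hyperprior), builds the
nested two-chain model, applies the structured constraint
`q(x_next, y, precision) = q(x_next, y) q(precision)` in every step
context, and recovers the hidden drift:

```bash
$ ffgraph demo ssm --seed 1 --T 100 --out-dir demo
INFO ffgraph: drift RMSE 0.1612 over 100 points; wrote demo/report.json
drift_rmse=0.161179
```

An RMSE of 0.16 against an observation noise standard deviation near 1
means the smoother tracks the drift an order of magnitude more tightly
than any single observation could.

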