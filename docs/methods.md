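# Methods

This note records the modeling semantics, the variational machinery, the
defaults, and the numerical choices behind ffgraph, at the level of detail
a maintainer or reviewer needs to judge what the tests do and do not show.

## Graph data model

An FFG is stored as a strictly bipartite graph: `FactorNode`s with an
ordered interface map, and `VariableNode`s keyed by `(name, index, path)`.
Variables shared by more than two factors are kept as single hyper-edge
nodes rather than being expanded through equality factors; the expansion
exists only as a rendering option (`--strict-ffg`).  This choice matches
how hierarchical models are actually written — one state variable feeds a
transition factor, a likelihood factor and the next timestep — and keeps
submodel nesting trivial: a node records the context path of the
invocation that created it, and the Markov blanket of any factor group is
read directly off the adjacency (variables touching at least one factor
inside and one outside the group; consequently blanket(S) =
blanket(complement of S)).

Constants are materialized per statement and never deduplicated: a prior
`Beta(1, 1)` owns its two constant-1 nodes.  Anonymous intermediates from
compound unrolling are named `<lhs>_tmp_<k>` with a per-context counter
from 0, and anonymous constants `const_<k>`; the naming is deterministic so
structural tests can be exact.  Vector indices are 0-based everywhere,
including serialization.

## Statement semantics

- `lhs ~ Call(label, args)` with a **stochastic** label creates one factor,
  the lhs variable if absent, and one constant node per literal argument.
- A **deterministic** label with all-known arguments folds: the evaluator
  runs at build time and the result is bound in the context as a plain
  value — no nodes.  With at least one variable argument a deterministic
  factor is materialized (literals still become constant nodes, since they
  must appear as interfaces).  After materialization no deterministic
  factor has all non-output interfaces constant.
- `:=` is the same operation with the relation recorded for rendering.
- Compound right-hand sides unroll innermost-first, left-to-right; the
  final primitive binds the original lhs.  Materializing the compound form
  and the hand-unrolled form yields graphs equal up to anonymous renaming.
- Keyword arguments resolve through alias rules before materialization:
  `Normal(mean=m, var=v)` → `NormalMeanVariance(m, v)`,
  `Normal(ν=·, τ=·)` → `NormalWeightedMeanPrecision(·,·)`, etc.  Rules are
  matched on the exact keyword set; zero matches and multiple matches are
  distinct errors.  Positional `Normal` keeps the mean–variance convention.

Submodel invocation is keyword-only (no positional fallback): the single
interface not supplied is bound to the statement's left-hand side, created
in the parent scope if absent.  Indexed references in interface keywords
use get-or-create semantics, which is what lets a chain write
`y[t] ~ step(x_prev=x[t], x_next=x[t+1], ...)` and create both the new
state and the observation on one line.  Submodel bodies see only their
interfaces and their own locals — never the parent's locals.

## Constraint resolution

The default local belief is the full joint over each factor's interfaces
(the Bethe family); constraints only refine it.  A factorization
constraint (FC) declares a partition over named variables in some scope; a
scope pattern is a sequence of submodel names matched as a suffix of a
context's model-name path, ignoring invocation counters, so one line
constrains every copy of a submodel.  On each factor in a matched context,
an FC induces the partition {interfaces grouped by the constraint block of
their variable} ∪ {one residual block of unmentioned interfaces}; the
resolved partition is the lattice meet (coarsest common refinement) of the
default with every induced partition, which is unique and idempotent.  The
residual-block convention is a genuine design choice — the surface syntax
never shows a factor with unconstrained extra interfaces — made so the
resolution stays a true meet; its observable consequence is that a factor
touching exactly one constrained variable separates that variable from its
other interfaces.

Two FCs in one scope over the same variable set with different partitions
are rejected at build time; overlapping sets are merged silently through
the meet.  FCs may mention latent and observed (data) variables — the
structured state-space constraint `q(x_next, y, precision) =
q(x_next, y) q(precision)` names the observation — but never constants.
Functional-form constraints tag latent variables with a family label and
are stored as plugin payloads under the `variational_constraints`
namespace, so they serialize with the graph.

## The reference engine

**Exact enumeration** multiplies all factor tables over the latent
variables with observed/constant interfaces clamped (indexed out) first;
the cap on joint states defaults to 10^7.  It is the oracle for everything
else.

**Sum-product** runs a two-pass leaf→root→leaf schedule on forests (exact
in one sweep pair) and damped flooding (damping 0.5) on cyclic graphs,
with messages normalized every update.  Non-convergence is a flag, not an
exception.

**Bethe free energy**: node terms `Σ q_a log(q_a/f_a)` with clamped
interfaces folded into `f_a`, edge terms `(d_i − 1) H[q_i]` with positive
sign — the counting correction that follows from the edge beliefs entering
the Bethe family with negative multiplicity.  With every variable of
degree two this reduces to the familiar sum of node energies plus edge
entropies; the degree-weighted form is the one that satisfies the tree
identity `F = −log Z` at the belief-propagation fixed point, which the
suite verifies to 1e−9 on 200 random trees.  Belief mass on a
zero-probability cell reports `+inf` with a support diagnostic rather than
raising.

**CBFE coordinate ascent** covers the conjugate pairs where the updates
are closed-form: Beta–Bernoulli (posterior `Beta(a0+Σy, b0+n−Σy)` in one
step) and Normal-mean/Gamma-precision under a mean-field split between
mean and precision (the textbook two-block fixed point).  The free energy
is evaluated in closed form after every sweep; an increasing trace is an
internal-assertion diagnostic.  Everything else raises `NotSupported` —
deliberately: general nonlinear continuous message approximations (needed
for full posterior inference in the gcv/HGF family) are out of scope, and
those graphs are built and validated but not numerically solved.

**State-space solver.**  With the walk precisions known, the hierarchical
random walk is a Gaussian Markov random field over
`z = (d_0, x_0, …, d_T, x_T)`; the constraint family `q(z) q(τ)` makes the
coordinate ascent an exact Gaussian step (one solve against the banded
joint precision — done densely, since 2(T+1) ≈ 200 dimensions is trivial)
alternating with a conjugate Gamma update for the observation precision
from expected squared residuals.  The Gaussian step is cross-checked in
the tests against an independently written Kalman filter + RTS smoother.
The free energy (negative ELBO) uses the exact joint covariance for the
quadratic expectations and `slogdet` for the Gaussian entropy.

## The synthetic generator and its defaults

`generate_ssm_data` simulates `drift_t = drift_{t−1} + ε_d`,
`state_t = state_{t−1} + drift_t + ε_s`, `obs_t = state_t + ε_o`, with the
observation precision drawn once per dataset from its Gamma hyperprior.
Defaults: drift noise variance 0.01, state noise variance 0.1, observation
precision ~ Gamma(shape 2, rate 2) (mean 1, so observation noise SD ≈ 1),
initial states N(0, 1).  These were chosen once to produce series whose
drift moves visibly but slowly relative to the observation noise — the
regime in which recovering the drift is meaningful — and are fully
configurable.  The experiment scale is T = 100 data points.

The graph fixture `hierarchical_ssm` mirrors the generator through two
invocations of one `ssm` submodel (drift chain driven by constant zeros,
state chain driven by the drift); both chains carry a Gamma-prior
precision so the structured constraint resolves in every one of the 2T
step contexts without touching constants.  The drift chain's
output-noise channel is the ε→0 analogue of the generator's exact drift
recursion; inference for the recovery experiment runs on the conjugate
reduction described above, not on the nonlinear graph.

What passing tests show: the language semantics are exact (counts,
nesting, folding, aliasing are discrete properties), and the engine agrees
with enumeration and closed forms to near machine precision on
tree-structured, finite-domain or conjugate models.  What they do not
show: behaviour on loopy graphs beyond weakly coupled cycles, non-conjugate
continuous inference, or robustness of the generator defaults to
real-data misspecification.

## Numerical choices and degenerate inputs

Messages are normalized to sum 1 each update; evidence is recovered from
the free energy rather than message scale factors.  `0·log 0 = 0`
throughout; KL raises on support violations (q > 0 where p = 0).  Clamped
values are matched to domain entries with `isclose`.  Empty data arrays,
zero-toss coin models, single-timestep chains and empty graphs are all
legal and covered by tests.  Tolerances: 1e−10 total variation for
oracle-vs-BP agreement, 1e−9 for free-energy identities, 1e−9 per-step
slack for monotonicity; the problem sizes (≤ 8 variables and domains ≤ 4
for enumeration suites, T = 100 for the state-space experiment) keep every
check exact or near machine precision while the whole suite runs in
seconds.

## Known limitations

- The engine is a reference implementation: dense tables, Python loops,
  no message scheduling beyond trees-plus-flooding, no streaming.
- Functional-form constraints are per-variable only; joint functional-form
  constraints and chance constraints are not representable.
- FCs are interpreted within a single scope; a constraint spanning
  variables of two sibling submodels is not supported.
- The BNN fixtures build graphs (weights, dot products, activations) but
  no training or inference is provided for them.
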