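# Methods

## Scope and model classes

`ratespike` simulates networks of point neurons on an equidistant time grid
with a fixed step `dt` (ms; default 1.0, configurable per network).  Two
neuron classes share one infrastructure:

* **rate-coded** units carry a continuous instantaneous firing rate `r(t)`
  updated every step; projections contribute `sum(target)`, the aggregation
  (sum/max/min/mean) over incoming synapses of the `psp` expression
  (default `w * pre.r`, with `pre.r` read through the delay buffer);
* **spiking** units emit discrete events when a boolean spike condition
  holds, then apply reset statements and optionally enter a refractory
  period.  Incoming spikes increment a per-target conductance `g_target`
  (or execute arbitrary `pre_spike` statements).

Hybrid networks couple the two through Poisson encoders (rate → spikes) and
sliding-window decoders (spikes → rate).

## Parsing

Model text is analyzed with regular expressions plus sympy.  Special
vocabulary — `sum(target)`, random-distribution calls, `mean/min/max(...)`
reductions, `pre.X`/`post.X` — is extracted first and replaced by typed
placeholder symbols; conditionals (`if c: a else: b`, nestable) are parsed
by a small recursive splitter into sympy `Piecewise` nodes, and boolean
texts (`and`/`or`/`not`, relational operators) by a recursive
top-level-split parser, because neither is valid sympy input.  All other
arithmetic goes through `sympy.parse_expr` with every identifier bound to a
plain symbol (so `I`, `E`, `gamma` are user names, not constants) and an
explicit whitelist of C-math-library function names plus `clip`; unknown
functions are rejected at parse time.  Compiled update rules are produced
with `sympy.lambdify` over numpy, vectorized across a population or a
projection's flat synapse arrays.

Statements may span lines: a line is joined to its predecessor when
parentheses are unbalanced or either side ends/starts with an operator.
Random-distribution arguments must be numeric constants; a draw is sampled
once per step per unit and treated as constant within the step (so the two
gradient evaluations of the midpoint scheme see the same noise value).

## Numerical integration

ODEs are normalized to gradient form `dx/dt = f(...)` by solving the
declared equation for the derivative symbolically (the derivative must
appear linearly).  Builders then produce per-step update plans:

| scheme       | rule                                             | notes |
|--------------|--------------------------------------------------|-------|
| explicit     | `x += dt f(x_t)`                                 | default |
| implicit     | solve `x' = x + dt f(x')` (symbolic linear solve)| rejects nonlinear systems, names the variable |
| exponential  | `x += (1 − e^(−dt/τ_eq))(A_eq − x)`              | per-equation canonization `τ_eq·dx/dt + x = A_eq`; exact on uncoupled linear ODEs with step-constant input |
| midpoint     | `k = f(x); x += dt f(x + dt/2 k)`                | RK2; one joint k-vector for coupled systems |

Exponential-Euler canonization computes `a = ∂f/∂x`; it requires `a` free
of `x` and nonzero, giving `τ_eq = −1/a` and `A_eq = x + τ_eq f`.  `A_eq`
is evaluated on pre-update values of other state variables; the alternative
(using same-step values) would couple the equations and break the
exactness guarantee, so we fix the pre-update convention.

**Event-driven** integration applies to synaptic ODEs that are linear with
constant coefficients (`dx/dt = a x + b`, `a`, `b` built from parameters
only).  The closed form `x(Δ) = −b/a + (x₀ + b/a) e^{aΔ}` (or `x₀ + bΔ`
when `a = 0`) is applied only when a pre- or post-synaptic spike reaches
the synapse, parameterized by the elapsed time since the synapse's last
event.  Equations that are nonlinear, time-dependent, or coupled to other
state variables (e.g. the saturating NMDA conductance) are rejected at
build time with an explicit error.

## Update ordering within a model

A model's variables are partitioned into blocks: each run of consecutive
ODEs sharing a numerical method forms one jointly solved block whose
increments are all computed from pre-update values; assignments and blocks
then execute in declaration order, each seeing the already-updated values
of earlier blocks and the previous-step values of later ones.  This makes
idioms like `I = g_exc - g_inh + ...` followed by `dv/dt = ... + I` work as
written, while coupled ODE pairs (`v`, `u`) stay synchronous.  Min/max
bounds are clamped immediately after each block writes, before later
variables read the result.  Use of a name declared later in the same model
is legal and reads the previous step's value.

## The seven-stage step

1. **Propagation.**  Rate projections aggregate `psp` over delayed
   pre-synaptic rates into per-target input sums (missing targets read 0,
   so incomplete networks still run).  Spiking projections read the
   pre-population's delay buffer at each synapse's own delay and execute
   `pre_spike` statements for arriving spikes — by default
   `g_target += w`, vectorized with `np.add.at`.  Continuous spiking
   synapses (a `psp` on a spiking projection, e.g. NMDA) both fire their
   `pre_spike` statements and contribute the per-synapse `psp` sum to the
   conductance every step.
2. **Neural update.**  Blocks evaluate as above; then spike conditions are
   tested for non-refractory units, spiking ranks collected, reset
   statements applied in declaration order, and refractory counters set to
   `round(refractory/dt)` steps.  Refractory units freeze all variables
   except conductances (names `g_*`) and cannot spike.
3. **Delayed outputs.**  The new rate (or spike flag) is pushed into a
   double-ended queue whose capacity is the maximum outgoing delay,
   recomputed at compile time.  Reading at delay d returns the value from
   exactly d steps ago; the minimum delay is one step, so a spike emitted
   at step k acts on its target's update at step k+1, never k.
4. **Synaptic updates.**  Non-event-driven projection variables advance;
   `postsynaptic` (shared) variables once per post neuron, per-synapse
   variables over the flat arrays.
5. **Post-synaptic events.**  `post_spike` statements for projections
   whose post neuron fired this step.  When pre and post spikes coincide
   on one synapse, pre_spike (stage 1) precedes post_spike (stage 5) — a
   documented convention.
6. **Structural plasticity** (when started; see below).
7. **Recording.**  Monitors sample at their period; `get()` drains the
   buffers.  Conductances without a decay ODE are reset to zero at the end
   of stage 2, so monitors deliberately read them as 0 — their effect is
   visible in the variables they drive.

Event statements execute sequentially in listed order on pre-update
values, after event-driven variables have been advanced to the event time.
For the short-term-plasticity synapse this reproduces the standard
sequencing: the conductance increment `w·u·x` uses both variables before
their own updates, and `x ← x(1−u)` uses the pre-update `u`.

Event times are the **arrival** times at the synapse (emission + delay);
post events use the emission time.  With the default 1-step delay this
shifts spike-pair lags by dt relative to the emission-time convention — it
shifts, but does not rescale, the STDP window, so fitted time constants
are unaffected.  Non-rate pre-synaptic attributes referenced in synapse
expressions are read at their current values (only each population's
output — rate or spike flag — is delay-buffered).

## Connectivity

Projections store one list of (pre rank, weight, delay, synaptic
variables) per post-synaptic neuron, kept flat in post-major order with a
row-pointer index; per-post rows stay sorted by pre rank across structural
changes.  Built-in connectors: all-to-all (self-connections excluded
within one population unless opted in), independent-pairs probabilistic,
one-to-one, distance-dependent (Euclidean distance on geometry
coordinates, user kernel), user pattern functions, and delimited-text
round trip (`pre_rank post_rank weight delay_ms`).  Delays round to the
nearest multiple of dt with a logged warning and are floored at one step;
per-synapse heterogeneous delays are supported, with the pre-population
buffer sized by the maximum.  `w` and `d` are implicitly declared for
every synapse; a synapse model that declares `w` (a learning rule) shares
storage with the connector-initialized weights.

## Hybrid conversion

A Poisson unit fires with probability `rate·dt/1000` per step (rate in
Hz), a Bernoulli approximation admitting one spike per step; a warning is
emitted when the probability exceeds 0.1.  Rates come from constants,
per-unit arrays, time expressions, or — for input-driven encoders — the
unit's weighted input sum, so r = 1.0 through weight 100.0 yields 100 Hz.

The decoder maintains a circular per-step buffer of weighted arriving
spike counts over a window T (a multiple of dt, default dt) and outputs

    sum(target)(t) = count_window / (T_seconds · n_incoming_synapses)

Normalizing by T in **seconds** makes the stated calibration hold exactly
(1 Hz input at unit weight decodes to 1.0); normalizing by T in ms, as a
literal unit-free reading would suggest, is off by 10³ and contradicts the
calibration, so the seconds convention is used deliberately.  Spikes are
counted at arrival (post-delay) time.  The decoded value depends only on
events in (t−T, t], giving a step-response lag of exactly T.

## Shared-kernel projections

`SharedProjection` implements convolution and pooling for rate-coded
populations only, with learning disabled.  The kernel sum is
`out(x,y) = Σ_i Σ_j W(i,j)·pre.r(x−i, y−j)` with zero padding by default
(clamp-to-edge optional).  When shapes differ, post coordinate c maps to
the pre center `floor(c·ratio + ratio/2)` per dimension; pooling regions
take `extent = ceil(ratio)` starting at `center − extent//2`, truncated at
edges (mean-pooling divides by the actual region size).  A
lower-dimensional kernel applies per channel along the leading dims; a
filter bank adds one trailing output dimension.  Kernels larger than the
pre geometry are rejected rather than guessed at.  The implementation is a
direct gather-sum over kernel offsets (small kernels, exact zero/edge
semantics) and is cross-checked against a brute-force double loop in the
tests.

## Structural plasticity

`create_synapse`/`prune_synapse` edit single synapses; `creating`/
`pruning` rules are boolean conditions with optional `proba`, `w`, `d`
flags, started explicitly and checked at a configurable period (default
every step, with a logged efficiency warning).  Pruning evaluates on
existing synapses (per-synapse variables allowed); creating evaluates on
absent pairs and may reference only continuous pre/post variables — event
triggers are rejected at parse time.  Created synapses initialize their
variables to declared inits and participate in the very next propagation.

## Randomness and determinism

A network owns a `numpy` `SeedSequence`; every population and projection
receives a spawned child generator in creation order.  Connectivity,
initial values, per-step noise and Poisson draws all derive from these, so
a fixed seed reproduces spike rasters and recordings bit for bit — the
conductance-based benchmark fixture asserts this.  A NaN/overflow guard
scans population state every 100 steps (every step in debug mode) and
aborts naming the offending population and variable.

## Reference networks and problem sizes

* **Pulse-coupled Izhikevich network**: 1000 neurons (800 exc / 200 inh),
  all-to-all, uniform random weights (exc 0–0.5, inh 0–1.0 onto a
  subtractive inhibitory conductance), per-neuron parameter randomization
  per the original recipe, multiplicative noise 5.0/2.0 on a standard
  normal draw, dt = 1 ms.  Conductances are instantaneous (summed and
  reset each step), as in the original network.
* **Conductance-based benchmark**: 4000 integrate-and-fire neurons
  (3200/800), connection probability 0.02, exponential synapses, dt =
  0.1 ms, delay 0.1 ms.  The physiological constants (C = 200 pF, gL =
  10 nS, El = −60 mV, Ee = 0, Ei = −80, τe = 5 ms, τi = 10 ms, threshold
  −50, reset −60, refractory 5 ms, we = 6 nS, wi = 67 nS) follow the
  published Vogels–Abbott benchmark description and live in one editable
  dict; tests depend only on structure and determinism, not on these
  values.  Membrane potentials start uniform in [−60, −50] mV.
* **Hybrid demo**: the 4-level rate schedule (0/10/50/100 Hz, 250 ms
  each), 1000 Poisson encoders, 10 ms decoding window.

Tests scale these down where full sizes add nothing: determinism is
asserted on a 0.2–0.25-scale benchmark network over 150–200 ms, the
binomial goodness-of-fit for probabilistic pruning uses 2000 trials on a
16-synapse projection, and dense-integration cross-checks evaluate the
dense dt = 0.001 ms recursion in closed form per inter-event interval.

## What the synthetic fixtures do and do not show

The fixtures exercise every code path (both neuron classes, all four
schemes, event-driven synapses, delays, hybrid conversion, shared kernels,
structural rules) under known statistics, so passing tests demonstrate the
simulator's semantics: calibrations, stage ordering, exactness and
convergence orders, determinism.  They do not validate any biological
claim — parameter values are conventional, noise is white, connectivity is
unstructured — and wall-clock performance is explicitly out of scope: this
is a clarity-first, single-threaded reference implementation in
numpy/sympy, not a competitor to code-generating simulators.

## Known limitations

* One clock per network; no multi-compartment neurons; no stochastic
  differential equations (random terms in ODEs are per-step constants,
  not Wiener increments).
* Event-driven integration is available for synapse variables only, not
  for neuron equations (no next-spike-time prediction).
* Only each population's output variable is delay-buffered; other
  attributes referenced across populations are read at current values.
* Shared (population-level) parameters hold a single value; models wanting
  per-neuron values declare the parameter per-unit (as the pulse-coupled
  example does for a, b, c, d).
* The Bernoulli approximation undercounts Poisson spikes when
  rate·dt/1000 approaches 1; choose a smaller dt for high rates.
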