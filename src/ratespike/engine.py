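"""Network construction and the seven-stage simulation loop.

Each step of the fixed-dt simulation executes, strictly in order:

1. *propagation* — weighted sums of delayed pre-synaptic rates are
   accumulated into per-target inputs; spikes whose delay elapses now apply
   their ``pre_spike`` statements (by default incrementing the target
   conductance by the weight);
2. *neural update* — population variables are advanced by their update
   plans; spike conditions are then evaluated, spiking ranks collected,
   reset statements applied and refractory periods started.  Refractory
   neurons only integrate their conductances;
3. *delayed outputs* — the new firing rate (or spike flag) is pushed into
   each population's delay buffer;
4. *synaptic updates* — projection variable plans (everything that is not
   event-driven);
5. *post-synaptic events* — ``post_spike`` statements for synapses whose
   post neuron fired this step;
6. *structural plasticity* — creation/pruning rules, when started;
7. *recording* — monitors sample their variables;

after which the clock advances by dt.  All cross-population reads inside a
step observe previous-step outputs (synchronous semantics, minimal delay of
one step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from . import numerics
from .dsl import EquationError, GlobalOp, Neuron, Synapse
from .network import Population, PopulationView, Projection, _as_pop_and_ranks

log = logging.getLogger("ratespike")

_OVERFLOW = 1e30


# --------------------------------------------------------------------------
# compiled structures
# --------------------------------------------------------------------------

@dataclass
class CompiledEntry:
    name: str
    fn: object
    args: list
    aux: bool = False


@dataclass
class Block:
    """A run of variables updated together: one assignment, or a group of
    consecutive ODEs sharing a numerical method (solved jointly from
    pre-update values)."""

    kind: str                    # 'assign' | 'ode'
    entries: list                # CompiledEntry
    specs: list                  # VariableSpec per state variable
    op: str = "="                # augmented op for assignments
    locality: str = "local"


@dataclass
class CompiledStatement:
    target: str
    op: str
    fn: object
    args: list


@dataclass
class PopulationContext:
    blocks: list = field(default_factory=list)
    randoms: list = field(default_factory=list)       # (name, RandomSpec)
    globalops: list = field(default_factory=list)     # (name, GlobalOp)
    sum_targets: set = field(default_factory=set)
    input_sums: dict = field(default_factory=dict)    # target -> array
    g_auto: dict = field(default_factory=dict)        # target -> array
    g_declared: set = field(default_factory=set)
    conductance_vars: set = field(default_factory=set)
    spike_fn: object = None
    spike_args: list = field(default_factory=list)
    reset: list = field(default_factory=list)         # CompiledStatement
    refractory_steps: object = None                   # int | attr name | None
    stop_fn: object = None
    stop_args: list = field(default_factory=list)
    stop_quant: str = "any"
    rate_expr_fn: object = None                       # Poisson rate strings


@dataclass
class ProjectionContext:
    kind: str                     # 'rate' | 'event' | 'continuous' | 'custom'
    psp_fn: object = None
    psp_args: list = field(default_factory=list)
    operator: str = "sum"
    pre_spike: list = field(default_factory=list)
    post_spike: list = field(default_factory=list)
    default_fast: bool = False
    blocks: list = field(default_factory=list)        # stage-4 plans
    randoms: list = field(default_factory=list)
    globalops: list = field(default_factory=list)
    event_solution: object = None
    event_vars: list = field(default_factory=list)
    w_spec: object = None                             # bounds for w


def _rename_randoms(expr, vocab, registry, rng_prefix=""):
    """Give every random placeholder a model-unique name."""
    mapping = {}
    for ph, spec in vocab.randoms.items():
        unique = f"_rand_{len(registry)}{rng_prefix}"
        registry.append((unique, spec))
        mapping[sp.Symbol(ph)] = sp.Symbol(unique)
    return expr.xreplace(mapping) if mapping else expr


def _compile_expr(expr):
    args = sorted(str(s) for s in expr.free_symbols)
    return numerics.lambdify_expr(expr, args), args


def _compile_plan(plan):
    entries = []
    for e in plan.entries:
        fn, args = _compile_expr(e.expr)
        entries.append(CompiledEntry(e.name, fn, args, e.aux))
    return entries


def _collect_globalops(vocab, registry):
    for ph, gop in vocab.globalops.items():
        if ph not in [name for name, _ in registry]:
            registry.append((ph, gop))


def _effective_method(spec, default="explicit"):
    return default if spec.method == "inherit" else spec.method


def _build_blocks(variables, randoms, globalops, scope):
    """Partition a model's variables into sequential update blocks."""
    blocks = []
    i = 0
    specs = [v for v in variables]
    while i < len(specs):
        v = specs[i]
        if v.kind == "assignment":
            expr = _rename_randoms(v.rhs, v.vocab, randoms)
            _collect_globalops(v.vocab, globalops)
            fn, args = _compile_expr(expr)
            blocks.append(Block("assign",
                                [CompiledEntry(v.name, fn, args)],
                                [v], op=v.op, locality=v.locality))
            i += 1
            continue
        method = _effective_method(v)
        if method == "event-driven":
            i += 1        # handled by the event machinery, not stage 2/4
            continue
        group = [v]
        j = i + 1
        while (j < len(specs) and specs[j].kind == "ode"
               and _effective_method(specs[j]) == method
               and specs[j].locality == v.locality):
            group.append(specs[j])
            j += 1
        odes = []
        for g in group:
            expr = _rename_randoms(g.rhs, g.vocab, randoms)
            _collect_globalops(g.vocab, globalops)
            odes.append((g.name, expr))
        plan = numerics.build_update_plan(odes, method)
        blocks.append(Block("ode", _compile_plan(plan), group,
                            locality=v.locality))
        i = j
    return blocks


# --------------------------------------------------------------------------
# monitors and stop conditions
# --------------------------------------------------------------------------

class Monitor:
    """Records variables of a population, view or projection.

    Values are appended to internal buffers every ``period`` ms (default:
    every step); ``get()`` returns the recorded matrices (rows = time
    points, columns = units or synapses) and empties the buffers.  The
    special variable name ``'spike'`` records (time_ms, rank) events.
    """

    def __init__(self, obj, variables, period=None, dt=1.0):
        if isinstance(variables, str):
            variables = [variables]
        self.obj = obj
        self.variables = list(variables)
        self.period = dt if period is None else float(period)
        self.period_steps = max(1, int(round(self.period / dt)))
        self.state = "recording"
        self._buffers = {v: [] for v in self.variables}
        self._times = []
        self._validate()

    def _validate(self):
        for v in self.variables:
            if v == "spike":
                pop, _ = _as_pop_and_ranks(self.obj)
                if not pop.is_spiking:
                    raise EquationError(
                        "'spike' can only be recorded on spiking populations")
                continue
            try:
                self._read(v)
            except AttributeError:
                # conductances and input sums only exist once compiled
                if not (v.startswith("g_") or v.startswith("sum_")):
                    raise EquationError(
                        f"unknown variable {v!r} on {self.obj}")

    def _read(self, name):
        if isinstance(self.obj, Projection):
            return self.obj.get(name)
        return self.obj.get(name)

    def pause(self):
        self.state = "paused"

    def resume(self):
        self.state = "recording"

    def stop(self):
        self.state = "stopped"

    def record(self, step_count, t):
        if self.state != "recording":
            return
        if step_count % self.period_steps != 0:
            return
        self._times.append(t)
        for v in self.variables:
            if v == "spike":
                pop, ranks = _as_pop_and_ranks(self.obj)
                fired = np.flatnonzero(pop.spiked)
                if isinstance(self.obj, PopulationView):
                    fired = fired[np.isin(fired, ranks)]
                for r in fired:
                    self._buffers[v].append((t, int(r)))
            else:
                self._buffers[v].append(np.array(self._read(v), copy=True))

    def get(self, variable=None):
        """Return recorded values and empty the buffers."""
        if variable is not None:
            buf = self._buffers[variable]
            self._buffers[variable] = []
            return np.array(buf)
        out = {v: np.array(self._buffers[v]) for v in self.variables}
        self._buffers = {v: [] for v in self.variables}
        self._times = []
        return out

    def times(self):
        return np.array(self._times)

    def to_files(self, outdir, prefix=""):
        """Export recordings as delimited text, one file per variable;
        spikes as two-column (time_ms, rank) event lists."""
        import os
        data = self.get()
        paths = []
        for v, mat in data.items():
            path = os.path.join(outdir, f"{prefix}{v}.txt")
            if v == "spike":
                np.savetxt(path, mat.reshape(-1, 2) if mat.size else
                           np.empty((0, 2)), fmt="%.6f %d",
                           header="time_ms rank")
            else:
                header = " ".join(str(i) for i in range(
                    mat.shape[1] if mat.ndim > 1 else 1))
                np.savetxt(path, mat, header=header)
            paths.append(path)
        return paths


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

class Network:
    """Populations + projections + monitors sharing one clock.

    All randomness (initial values, connectivity, per-step noise, Poisson
    draws) derives from ``seed``: identical seeds give bit-identical spike
    rasters and recordings.
    """

    def __init__(self, dt=1.0, seed=None, debug=False):
        self.dt = float(dt)
        self.seed = seed
        self._seedseq = np.random.SeedSequence(seed)
        self.rng = np.random.default_rng(self._seedseq.spawn(1)[0])
        self.populations: list = []
        self.projections: list = []
        self.monitors: list = []
        self.step_count = 0
        self.debug = debug
        self._compiled = False

    @property
    def t(self) -> float:
        """Current time in ms."""
        return self.step_count * self.dt

    # -- construction ------------------------------------------------------
    def _child_rng(self):
        return np.random.default_rng(self._seedseq.spawn(1)[0])

    def add_population(self, pop: Population) -> Population:
        if pop.name is not None and any(
                p.name == pop.name for p in self.populations):
            raise ValueError(f"duplicate population name {pop.name!r}")
        pop.__dict__["network"] = self
        pop.__dict__["rng"] = self._child_rng()
        self.populations.append(pop)
        self._compiled = False
        return pop

    def create_population(self, geometry, neuron, name=None,
                          stop_condition=None) -> Population:
        pop = Population(geometry, neuron, name=name,
                         stop_condition=stop_condition)
        return self.add_population(pop)

    def add_projection(self, proj: Projection) -> Projection:
        proj.network = self
        proj.dt = self.dt
        proj.rng = self._child_rng()
        self.projections.append(proj)
        self._compiled = False
        return proj

    def connect(self, pre, post, target, synapse=None, name=None,
                cls=Projection, **kwargs) -> Projection:
        proj = cls(pre, post, target, synapse=synapse, name=name,
                   dt=self.dt, **kwargs)
        return self.add_projection(proj)

    def monitor(self, obj, variables, period=None) -> Monitor:
        mon = Monitor(obj, variables, period=period, dt=self.dt)
        self.monitors.append(mon)
        return mon

    def get_population(self, name) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- compilation -------------------------------------------------------
    def compile(self):
        """Build update plans, size delay buffers and resolve targets."""
        for pop in self.populations:
            max_d = 1
            for proj in self.projections:
                if proj.pre_pop is pop and proj._connected:
                    max_d = max(max_d, proj.max_delay_steps())
                window = getattr(proj, "window_steps", None)
                if proj.pre_pop is pop and window:
                    max_d = max(max_d, 1)
            if (pop.output_history is None
                    or pop.output_history.capacity < max_d):
                pop.init_output_history(max_d)
            pop._ctx = self._compile_population(pop)
        for proj in self.projections:
            proj._ctx = self._compile_projection(proj)
        self._compiled = True

    def _compile_population(self, pop) -> PopulationContext:
        ctx = PopulationContext()
        model = pop.neuron
        if not getattr(pop, "custom_update", False):
            ctx.blocks = _build_blocks(model.variables, ctx.randoms,
                                       ctx.globalops, "neuron")
            for v in model.variables:
                if _effective_method(v) == "event-driven":
                    raise EquationError(
                        "event-driven integration is only available for "
                        "synapse variables")
        # targets
        declared = {p.name for p in model.parameters} | \
                   {v.name for v in model.variables}
        referenced_g = set()
        for v in model.variables:
            for s in v.rhs.free_symbols:
                name = str(s)
                if name.startswith("g_") and name not in declared:
                    referenced_g.add(name[2:])
            for ph, tgt in v.vocab.sums.items():
                ctx.sum_targets.add(tgt)
        for proj in self.projections:
            if proj.post_pop is not pop:
                continue
            if proj.pre_pop.is_spiking and not _is_rate_kind(proj):
                referenced_g.add(proj.target)
            else:
                ctx.sum_targets.add(proj.target)
        for v in model.variables:
            if v.name.startswith("g_"):
                ctx.g_declared.add(v.name[2:])
        for tgt in referenced_g:
            name = "g_" + tgt
            if name in declared:
                ctx.g_declared.add(tgt)
            elif name not in ctx.g_auto:
                ctx.g_auto[tgt] = np.zeros(pop.size)
        ctx.conductance_vars = {"g_" + t for t in
                                (ctx.g_declared | set(ctx.g_auto))}
        for tgt in ctx.sum_targets:
            ctx.input_sums.setdefault(tgt, np.zeros(pop.size))
        # spike machinery
        if model.is_spiking and model.spike_condition is not None:
            expr = model.spike_condition.expr
            ctx.spike_fn, ctx.spike_args = _compile_expr(expr)
            for st in model.reset_statements:
                e = _rename_randoms(st.rhs, st.vocab, ctx.randoms)
                fn, args = _compile_expr(e)
                ctx.reset.append(CompiledStatement(st.target, st.op, fn,
                                                   args))
            refr = model.refractory
            if refr is None:
                ctx.refractory_steps = 0
            elif isinstance(refr, str):
                ctx.refractory_steps = refr       # resolved per spike
            else:
                ctx.refractory_steps = int(round(refr / self.dt))
        if pop.stop_condition is not None:
            cond = pop.stop_condition
            if isinstance(cond, str):
                from .dsl import parse_condition
                cond = parse_condition(cond)
            ctx.stop_fn, ctx.stop_args = _compile_expr(cond.expr)
            ctx.stop_quant = cond.quantifier
        return ctx

    def _compile_projection(self, proj) -> ProjectionContext:
        if not proj._connected:
            raise RuntimeError(
                f"projection {proj!r} has no connectivity; call a "
                "connect_* method")
        if hasattr(proj, "custom_propagate"):
            ctx = ProjectionContext("custom")
            proj_compile = getattr(proj, "compile_custom", None)
            if proj_compile is not None:
                proj_compile(self)
            return ctx
        syn = proj.synapse
        if proj.pre_pop.is_spiking and syn.psp is None:
            ctx = ProjectionContext("event")
        elif proj.pre_pop.is_spiking:
            ctx = ProjectionContext("continuous")
        else:
            ctx = ProjectionContext("rate")
        ctx.operator = syn.operator
        for v in syn.variables:
            if v.name == "w":
                ctx.w_spec = v
        # psp
        if ctx.kind in ("rate", "continuous"):
            if syn.psp is not None:
                expr = _rename_randoms(syn.psp, syn.psp_vocab, ctx.randoms)
                _collect_globalops(syn.psp_vocab, ctx.globalops)
            else:
                expr = sp.Symbol("w") * sp.Symbol("_pre_r")
            ctx.psp_fn, ctx.psp_args = _compile_expr(expr)
        # event statements
        if proj.pre_pop.is_spiking:
            stmts = syn.pre_spike
            if not stmts and ctx.kind == "event":
                from .network import DEFAULT_SPIKE_SYNAPSE
                stmts = DEFAULT_SPIKE_SYNAPSE.pre_spike
            ctx.pre_spike = self._compile_statements(stmts, ctx)
            ctx.post_spike = self._compile_statements(syn.post_spike, ctx)
            ctx.default_fast = (
                len(ctx.pre_spike) == 1 and not ctx.post_spike
                and ctx.pre_spike[0].target == "g_target"
                and ctx.pre_spike[0].op == "+="
                and ctx.pre_spike[0].args == ["w"]
                and not any(_effective_method(v) == "event-driven"
                            for v in syn.variables))
        # event-driven variables
        ed = [v for v in syn.variables
              if _effective_method(v) == "event-driven"]
        if ed:
            params = {p.name for p in syn.parameters} | {"w", "dt"}
            try:
                ctx.event_solution = numerics.build_event_solution(
                    [(v.name, v.rhs) for v in ed], parameters=params)
            except ValueError as exc:
                raise EquationError(str(exc)) from None
            ctx.event_vars = [v.name for v in ed]
        # stage-4 plans (everything not event-driven)
        stage4 = [v for v in syn.variables
                  if _effective_method(v) != "event-driven"]
        ctx.blocks = _build_blocks(stage4, ctx.randoms, ctx.globalops,
                                   "synapse")
        return ctx

    def _compile_statements(self, stmts, ctx):
        out = []
        for st in stmts:
            expr = _rename_randoms(st.rhs, st.vocab, ctx.randoms)
            fn, args = _compile_expr(expr)
            out.append(CompiledStatement(st.target, st.op, fn, args))
        return out

    # -- bindings ----------------------------------------------------------
    def _pop_bindings(self, pop, ctx):
        b = {"t": self.t, "dt": self.dt}
        b.update(pop._vals)
        for tgt, arr in ctx.input_sums.items():
            b["_sum_" + tgt] = arr
        for tgt, arr in ctx.g_auto.items():
            b["g_" + tgt] = arr
        for name, spec in ctx.randoms:
            b[name] = spec.draw(pop.rng, pop.size)
        for name, gop in ctx.globalops:
            b[name] = _global_op_value(gop, pop)
        return b

    def _target_array(self, pop, target):
        """Array receiving event/continuous input for ``target`` on pop."""
        ctx = pop._ctx
        if pop.is_spiking or getattr(pop, "custom_update", False):
            name = "g_" + target
            if target in ctx.g_declared:
                return pop._vals[name]
            if target in ctx.g_auto:
                return ctx.g_auto[target]
            if target in ctx.input_sums:       # input-driven Poisson
                return ctx.input_sums[target]
            arr = np.zeros(pop.size)
            ctx.g_auto[target] = arr
            return arr
        ctx.input_sums.setdefault(target, np.zeros(pop.size))
        return ctx.input_sums[target]

    # -- simulation --------------------------------------------------------
    def simulate(self, duration_ms):
        """Advance the network by ``round(duration/dt)`` steps."""
        if duration_ms < 0:
            raise ValueError("duration must be >= 0")
        if not self._compiled:
            self.compile()
        n_steps = int(round(duration_ms / self.dt))
        for _ in range(n_steps):
            self.step()

    def simulate_until(self, max_duration_ms, populations) -> float:
        """Simulate until a stop condition holds; returns elapsed ms."""
        if not self._compiled:
            self.compile()
        if isinstance(populations, Population):
            populations = [populations]
        n_steps = int(round(max_duration_ms / self.dt))
        for k in range(n_steps):
            self.step()
            for pop in populations:
                ctx = pop._ctx
                if ctx.stop_fn is None:
                    continue
                b = {"t": self.t, "dt": self.dt}
                b.update(pop._vals)
                for tgt, arr in ctx.input_sums.items():
                    b["_sum_" + tgt] = arr
                mask = np.broadcast_to(
                    ctx.stop_fn(*[b[a] for a in ctx.stop_args]), (pop.size,))
                hit = mask.all() if ctx.stop_quant == "all" else mask.any()
                if hit:
                    return (k + 1) * self.dt
        return n_steps * self.dt

    def step(self):
        """Execute one full seven-stage simulation step."""
        if not self._compiled:
            self.compile()
        # stage 1: propagation
        for pop in self.populations:
            for arr in pop._ctx.input_sums.values():
                arr[:] = 0.0
        for proj in self.projections:
            ctx = proj._ctx
            if ctx.kind == "custom":
                proj.custom_propagate(self)
            elif ctx.kind == "rate":
                self._propagate_rate(proj, ctx)
            elif ctx.kind == "continuous":
                # pre_spike statements still fire on arriving spikes
                # (e.g. x += w for NMDA), then the psp sum is taken
                self._propagate_events(proj, ctx)
                self._propagate_continuous(proj, ctx)
            else:
                self._propagate_events(proj, ctx)
        # stage 2: neural update
        for pop in self.populations:
            if getattr(pop, "custom_update", False):
                pop.update_step(self)
            else:
                self._update_population(pop)
        # stage 3: delayed outputs
        for pop in self.populations:
            pop.output_history.push(pop.output_value())
        # stage 4: synaptic updates
        for proj in self.projections:
            if proj._ctx.kind != "custom" and proj._ctx.blocks:
                self._update_projection(proj, proj._ctx)
        # stage 5: post-synaptic events
        for proj in self.projections:
            ctx = proj._ctx
            if ctx.kind == "custom" or not ctx.post_spike:
                continue
            if not proj.post_pop.is_spiking:
                continue
            fired = np.flatnonzero(proj.post_pop.spiked)
            if fired.size:
                idx = _row_indices(proj, fired)
                self._apply_event_statements(proj, ctx, idx)
        # stage 6: structural plasticity
        for proj in self.projections:
            if getattr(proj, "_structural_active", False):
                from .extensions import apply_structural_rules
                apply_structural_rules(proj, self)
        # stage 7: recording
        for mon in self.monitors:
            mon.record(self.step_count, self.t)
        self.step_count += 1
        if self.debug or self.step_count % 100 == 0:
            self._guard()

    # -- stage implementations --------------------------------------------
    def _delayed_pre_values(self, proj):
        """Per-synapse pre-synaptic output at the synapse's own delay."""
        buf = proj.pre_pop.output_history
        groups = proj.delay_groups()
        if len(groups) == 1:
            d = groups[0][0]
            return buf.read(d)[proj.syn_pre]
        out = np.empty(proj.nb_synapses)
        for d, _ in groups:
            mask = proj.delay_steps == d
            out[mask] = buf.read(d)[proj.syn_pre[mask]]
        return out

    def _syn_bindings(self, proj, ctx, idx=None):
        """Bindings for per-synapse expression evaluation."""
        pre, post = proj.pre_pop, proj.post_pop
        sl = slice(None) if idx is None else idx
        posts = proj.syn_post[sl]
        pres = proj.syn_pre[sl]
        n = len(posts)
        b = {"t": self.t, "dt": self.dt, "w": proj.w[sl]}
        for name, arr in proj.local_vars.items():
            b[name] = arr[sl]
        for name, val in proj.shared_params.items():
            b[name] = val
        for name, arr in proj.shared_vars.items():
            b[name] = arr[posts]
        for name, spec in ctx.randoms:
            b[name] = spec.draw(proj.rng, n)
        for name, gop in ctx.globalops:
            b[name] = _global_op_value(gop, pre if gop.side == "pre"
                                       else post)
        # pre/post attribute references
        needed = set()
        for blk in ctx.blocks:
            for e in blk.entries:
                needed.update(e.args)
        needed.update(ctx.psp_args)
        for name in needed:
            if name.startswith("_pre_"):
                attr = name[5:]
                if attr == "r" and not pre.is_spiking:
                    # the pre-synaptic rate is read through the delay buffer
                    vals = self._delayed_pre_values(proj)
                    b[name] = vals[idx] if idx is not None else vals
                else:
                    v = pre._vals[attr]
                    b[name] = np.asarray(v)[pres] if np.ndim(v) else v
            elif name.startswith("_post_"):
                v = post._vals[name[6:]]
                b[name] = np.asarray(v)[posts] if np.ndim(v) else v
        return b

    def _aggregate(self, proj, psp, operator):
        post_size = proj.post_pop.size
        if operator == "sum":
            return np.bincount(proj.syn_post, weights=psp,
                               minlength=post_size)
        rows = proj.post_rows()
        starts = proj.row_ptr[rows]
        out = np.zeros(post_size)
        if operator == "max":
            out[rows] = np.maximum.reduceat(psp, starts)
        elif operator == "min":
            out[rows] = np.minimum.reduceat(psp, starts)
        elif operator == "mean":
            sums = np.bincount(proj.syn_post, weights=psp,
                               minlength=post_size)
            counts = proj.size_per_post()
            out[rows] = sums[rows] / counts[rows]
        return out

    def _propagate_rate(self, proj, ctx):
        if proj.nb_synapses == 0:
            return
        b = self._syn_bindings(proj, ctx)
        if "_pre_r" in ctx.psp_args and "_pre_r" not in b:
            b["_pre_r"] = self._delayed_pre_values(proj)
        psp = np.broadcast_to(
            ctx.psp_fn(*[b[a] for a in ctx.psp_args]),
            (proj.nb_synapses,))
        sums = self._aggregate(proj, psp, ctx.operator)
        tgt = self._target_array(proj.post_pop, proj.target)
        tgt += sums

    def _propagate_continuous(self, proj, ctx):
        """NMDA-style transmission: psp summed every step into g_target."""
        if proj.nb_synapses == 0:
            return
        b = self._syn_bindings(proj, ctx)
        psp = np.broadcast_to(
            ctx.psp_fn(*[b[a] for a in ctx.psp_args]),
            (proj.nb_synapses,))
        sums = self._aggregate(proj, psp, ctx.operator)
        tgt = self._target_array(proj.post_pop, proj.target)
        tgt += sums

    def _propagate_events(self, proj, ctx):
        if proj.nb_synapses == 0:
            return
        buf = proj.pre_pop.output_history
        chunks = []
        for d, by_pre in proj.delay_groups():
            spikes = buf.read(d)
            for r in np.flatnonzero(spikes):
                syn = by_pre.get(int(r))
                if syn is not None:
                    chunks.append(syn)
        if not chunks:
            return
        idx = np.concatenate(chunks)
        if ctx.default_fast:
            g = self._target_array(proj.post_pop, proj.target)
            np.add.at(g, proj.syn_post[idx], proj.w[idx])
            return
        self._apply_event_statements(proj, ctx, idx, which="pre")

    def _apply_event_statements(self, proj, ctx, idx, which="post"):
        if idx.size == 0:
            return
        stmts = ctx.pre_spike if which == "pre" else ctx.post_spike
        t_now = self.t
        # event-driven variables advance before any statement reads them
        if ctx.event_solution is not None:
            elapsed = t_now - proj.last_event[idx]
            state = {n: proj.local_vars[n][idx] for n in ctx.event_vars}
            new = ctx.event_solution.apply(state, elapsed,
                                           dict(proj.shared_params,
                                                dt=self.dt))
            for n in ctx.event_vars:
                proj.local_vars[n][idx] = new[n]
            proj.last_event[idx] = t_now
        if not stmts:
            return
        pre, post = proj.pre_pop, proj.post_pop
        posts = proj.syn_post[idx]
        pres = proj.syn_pre[idx]
        local = {n: arr[idx].copy() for n, arr in proj.local_vars.items()}
        local["w"] = proj.w[idx].copy()

        def binding(name):
            if name in local:
                return local[name]
            if name == "t":
                return t_now
            if name == "dt":
                return self.dt
            if name in proj.shared_params:
                return proj.shared_params[name]
            if name in proj.shared_vars:
                return proj.shared_vars[name][posts]
            if name.startswith("_pre_"):
                v = pre._vals[name[5:]]
                return np.asarray(v)[pres] if np.ndim(v) else v
            if name.startswith("_post_"):
                v = post._vals[name[6:]]
                return np.asarray(v)[posts] if np.ndim(v) else v
            for rname, spec in ctx.randoms:
                if rname == name:
                    return spec.draw(proj.rng, idx.size)
            raise KeyError(name)

        for st in stmts:
            val = st.fn(*[binding(a) for a in st.args])
            if st.target == "g_target":
                g = self._target_array(post, proj.target)
                if st.op == "+=":
                    np.add.at(g, posts, val)
                elif st.op == "-=":
                    np.subtract.at(g, posts, val)
                elif st.op == "=":
                    g[posts] = val
                else:
                    raise EquationError(
                        f"unsupported operator {st.op} on g_target")
            elif st.target in local:
                _apply_op(local, st.target, st.op, val)
            elif st.target in proj.shared_vars:
                arr = proj.shared_vars[st.target]
                cur = arr[posts]
                tmp = {st.target: cur}
                _apply_op(tmp, st.target, st.op, val)
                arr[posts] = tmp[st.target]
            else:
                raise EquationError(f"unknown statement target {st.target}")
        for n, arr in local.items():
            if n == "w":
                proj.w[idx] = arr
                if ctx.w_spec is not None:
                    _clamp_inplace(proj.w, idx, ctx.w_spec)
            else:
                proj.local_vars[n][idx] = arr

    def _update_population(self, pop):
        ctx = pop._ctx
        b = self._pop_bindings(pop, ctx)
        refrac = pop.refractory_remaining > 0
        any_refrac = refrac.any()
        for blk in ctx.blocks:
            results = _eval_block(blk, b)
            for spec in blk.specs:
                name = spec.name
                new = np.broadcast_to(results[name],
                                      (pop.size,)).astype(float) \
                    if spec.locality == "local" else results[name]
                if blk.kind == "assign" and blk.op != "=":
                    cur = b[name]
                    new = _augment(cur, blk.op, results[name])
                if spec.locality == "shared":
                    val = float(np.asarray(new).reshape(-1)[0]) \
                        if np.ndim(new) else float(new)
                    val = _clamp_scalar(val, spec)
                    pop._vals[name] = val
                    b[name] = val
                    continue
                if any_refrac and name not in ctx.conductance_vars:
                    new = np.where(refrac, b[name], new)
                arr = pop._vals[name]
                arr[:] = new
                _clamp_array(arr, spec)
        # spike emission
        if ctx.spike_fn is not None:
            cond = np.broadcast_to(
                ctx.spike_fn(*[b[a] for a in ctx.spike_args]), (pop.size,))
            fired = cond & ~refrac
            pop.spiked[:] = fired
            ranks = np.flatnonzero(fired)
            if ranks.size:
                for st in ctx.reset:
                    args = []
                    for a in st.args:
                        v = b[a]
                        args.append(np.asarray(v)[ranks]
                                    if np.ndim(v) else v)
                    val = st.fn(*args)
                    arr = pop._vals[st.target]
                    tmp = {st.target: arr[ranks]}
                    _apply_op(tmp, st.target, st.op, val)
                    arr[ranks] = tmp[st.target]
                refr = ctx.refractory_steps
                if isinstance(refr, str):
                    v = pop._vals[refr]
                    dur = np.asarray(v)[ranks] if np.ndim(v) else v
                    if np.any(np.asarray(dur) < 0):
                        raise ValueError("negative refractory duration")
                    steps = np.rint(np.asarray(dur) / self.dt).astype(int)
                    pop.refractory_remaining[ranks] = steps
                elif refr:
                    pop.refractory_remaining[ranks] = refr
        pop.refractory_remaining[refrac] -= 1
        # instantaneous conductances reset after use
        for arr in ctx.g_auto.values():
            arr[:] = 0.0

    def _update_projection(self, proj, ctx):
        if proj.nb_synapses == 0:
            return
        b = self._syn_bindings(proj, ctx)
        posts = proj.syn_post
        for blk in ctx.blocks:
            if blk.locality == "shared":
                self._update_shared_block(proj, ctx, blk)
                # refresh per-synapse view of shared vars
                for name in proj.shared_vars:
                    b[name] = proj.shared_vars[name][posts]
                continue
            results = _eval_block(blk, b)
            for spec in blk.specs:
                name = spec.name
                new = results[name]
                if blk.kind == "assign" and blk.op != "=":
                    new = _augment(b[name], blk.op, new)
                arr = proj.w if name == "w" else proj.local_vars[name]
                arr[:] = np.broadcast_to(new, (proj.nb_synapses,))
                _clamp_array(arr, spec)
                b[name] = arr

    def _update_shared_block(self, proj, ctx, blk):
        """Postsynaptic variables are updated once per post neuron."""
        post = proj.post_pop
        rows = proj.post_rows()
        b = {"t": self.t, "dt": self.dt}
        for name, val in proj.shared_params.items():
            b[name] = val
        for name, arr in proj.shared_vars.items():
            b[name] = arr[rows]
        for name, gop in ctx.globalops:
            b[name] = _global_op_value(
                gop, proj.pre_pop if gop.side == "pre" else post)
        needed = {a for e in blk.entries for a in e.args}
        for name in needed:
            if name.startswith("_post_"):
                v = post._vals[name[6:]]
                b[name] = np.asarray(v)[rows] if np.ndim(v) else v
            elif name.startswith("_pre_"):
                raise EquationError(
                    "postsynaptic variables cannot reference pre. "
                    "attributes")
            elif name.startswith("_rand_"):
                for rname, spec in ctx.randoms:
                    if rname == name:
                        b[name] = spec.draw(proj.rng, len(rows))
        results = _eval_block(blk, b)
        for spec in blk.specs:
            new = results[spec.name]
            if blk.kind == "assign" and blk.op != "=":
                new = _augment(b[spec.name], blk.op, new)
            arr = proj.shared_vars[spec.name]
            arr[rows] = np.broadcast_to(new, (len(rows),))
            _clamp_array(arr, spec)

    def _guard(self):
        for pop in self.populations:
            for name, val in pop._vals.items():
                arr = np.asarray(val, dtype=float) \
                    if not isinstance(val, np.ndarray) else val
                if arr.dtype.kind != "f":
                    continue
                bad = ~np.isfinite(arr) | (np.abs(arr) > _OVERFLOW)
                if bad.any():
                    raise FloatingPointError(
                        f"numeric overflow/NaN in population "
                        f"{pop.name or pop!r}, variable {name!r} at "
                        f"t={self.t} ms")

    def reset_time(self):
        self.step_count = 0


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _is_rate_kind(proj):
    """True when a projection from a spiking population feeds rate-style
    input sums (custom decoders define this themselves)."""
    return hasattr(proj, "custom_propagate") and \
        getattr(proj, "feeds_sums", False)


def _row_indices(proj, post_ranks):
    chunks = [np.arange(proj.row_ptr[p], proj.row_ptr[p + 1])
              for p in post_ranks]
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def _eval_block(blk, bindings):
    overlay = {}
    results = {}
    for e in blk.entries:
        vals = []
        for a in e.args:
            if a in overlay:
                vals.append(overlay[a])
            else:
                vals.append(bindings[a])
        out = e.fn(*vals)
        if e.aux:
            overlay[e.name] = out
        else:
            results[e.name] = out
    return results


def _augment(cur, op, val):
    if op == "+=":
        return cur + val
    if op == "-=":
        return cur - val
    if op == "*=":
        return cur * val
    if op == "/=":
        return cur / val
    return val


def _apply_op(store, name, op, val):
    store[name] = _augment(store[name], op, val)


def _clamp_array(arr, spec):
    if spec.min_bound is not None or spec.max_bound is not None:
        np.clip(arr, spec.min_bound, spec.max_bound, out=arr)


def _clamp_inplace(arr, idx, spec):
    if spec.min_bound is not None or spec.max_bound is not None:
        arr[idx] = np.clip(arr[idx], spec.min_bound, spec.max_bound)


def _clamp_scalar(val, spec):
    if spec.min_bound is not None:
        val = max(val, spec.min_bound)
    if spec.max_bound is not None:
        val = min(val, spec.max_bound)
    return val


def _global_op_value(gop: GlobalOp, pop):
    arr = pop._vals[gop.var]
    if np.ndim(arr) == 0:
        return float(arr)
    if gop.op == "mean":
        return float(np.mean(arr))
    if gop.op == "max":
        return float(np.max(arr))
    if gop.op == "min":
        return float(np.min(arr))
    raise EquationError(f"unknown global operation {gop.op}")
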