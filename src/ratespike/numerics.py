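"""Numerical integration of model ODE systems.

A parsed model yields a list of ODEs in canonical gradient form
``dx/dt = f(state, inputs)``.  The builders below transform such a system
into an :class:`UpdatePlan`: an ordered list of evaluable rules giving the
next value of every variable from the pre-update state.  Four per-step
schemes are available —

* explicit (forward) Euler: gradients evaluated at t,
* implicit (backward) Euler: gradients at t+dt, requires a linear system,
* exponential Euler: exact on uncoupled linear ODEs canonized to
  ``tau_eq * dx/dt + x = A_eq``, step ``x += (1 - exp(-dt/tau_eq))*(A_eq - x)``,
* midpoint (Runge-Kutta order 2): gradient re-evaluated at t + dt/2 —

plus an event-driven mode for linear constant-coefficient synaptic ODEs,
which are advanced exactly by their closed-form solution only when a pre- or
post-synaptic spike occurs, parameterized by the elapsed time since the last
event.

All increments of a plan are computed from pre-update values before any
variable is written, so coupled equations always read the previous state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "UpdatePlan", "PlanEntry", "SteadyStateForm", "LinearEventSolution",
    "build_explicit_euler", "build_implicit_euler",
    "build_exponential_euler", "build_midpoint", "build_update_plan",
    "canonize", "build_event_solution", "advance_event", "lambdify_expr",
]

_DT = sp.Symbol("dt")
_ELAPSED = sp.Symbol("_elapsed")

#: runtime implementations for DSL-specific functions
_LAMBDIFY_MAP = {"clip": np.clip}


def lambdify_expr(expr, argnames):
    """Compile a sympy expression to a numpy-vectorized callable."""
    syms = [sp.Symbol(n) for n in argnames]
    return sp.lambdify(syms, expr, modules=[_LAMBDIFY_MAP, "numpy"])


@dataclass
class PlanEntry:
    """One rule of an update plan.

    ``aux`` entries are temporaries (e.g. midpoint slopes) evaluated into a
    scratch namespace; non-aux entries give the next value of a state
    variable and are written back only after the whole plan has been
    evaluated.
    """

    name: str
    expr: sp.Expr
    aux: bool = False


@dataclass
class UpdatePlan:
    method: str
    entries: list
    variables: list                      # state variable names, in order

    def symbols(self) -> set:
        out = set()
        for e in self.entries:
            out |= {str(s) for s in e.expr.free_symbols}
        return out - {e.name for e in self.entries if e.aux}

    def render(self) -> str:
        lines = [f"# method: {self.method}"]
        for e in self.entries:
            arrow = "=" if e.aux else "<-"
            lines.append(f"{e.name} {arrow} {e.expr}")
        return "\n".join(lines)


def _check_gradient_form(odes):
    odes = list(odes)
    names = [n for n, _ in odes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate ODE variable")
    return odes, [sp.Symbol(n) for n in names]


def build_explicit_euler(odes) -> UpdatePlan:
    """Forward Euler: x' = x + dt * f(x_t)."""
    odes, syms = _check_gradient_form(odes)
    entries = [PlanEntry(n, s + _DT * grad)
               for (n, grad), s in zip(odes, syms)]
    return UpdatePlan("explicit", entries, [n for n, _ in odes])


def build_implicit_euler(odes) -> UpdatePlan:
    """Backward Euler: solves x' = x + dt * f(x') symbolically.

    The system must be linear in its variables; a nonlinear system raises
    ``ValueError`` naming the offending variable.
    """
    odes, syms = _check_gradient_form(odes)
    next_syms = [sp.Symbol(f"_next_{n}") for n, _ in odes]
    subs = dict(zip(syms, next_syms))
    eqs = []
    for (n, grad), s, ns in zip(odes, syms, next_syms):
        eqs.append(ns - s - _DT * grad.xreplace(subs))
    try:
        a_mat, b_vec = sp.linear_eq_to_matrix(eqs, next_syms)
    except Exception:
        bad = _first_nonlinear(odes, syms)
        raise ValueError(
            f"implicit Euler requires a linear system; variable {bad!r} "
            "appears nonlinearly") from None
    sol = a_mat.LUsolve(b_vec)
    entries = [PlanEntry(n, sp.simplify(sol[i]))
               for i, (n, _) in enumerate(odes)]
    return UpdatePlan("implicit", entries, [n for n, _ in odes])


def _first_nonlinear(odes, syms):
    for n, grad in odes:
        for s in syms:
            if not grad.has(s):
                continue
            try:
                if sp.degree(sp.Poly(grad, s), s) > 1:
                    return n
            except sp.PolynomialError:
                return n
    return odes[0][0]


@dataclass
class SteadyStateForm:
    """Equivalent first-order form ``tau_eq * dx/dt + x = A_eq``."""

    tau_eq: sp.Expr
    A_eq: sp.Expr


def canonize(odes) -> dict:
    """Canonize each equation for the exponential Euler scheme.

    For ``dx/dt = f`` with ``df/dx`` free of x, the equivalent time constant
    is ``tau_eq = -1/(df/dx)`` and the steady state ``A_eq = x + tau_eq*f``.
    E.g. ``tau*dv/dt + v = g_exc*(E - v)`` canonizes to
    ``tau_eq = tau/(1 + g_exc)``, ``A_eq = g_exc*E/(1 + g_exc)``.
    """
    odes, _ = _check_gradient_form(odes)
    forms = {}
    for n, grad in odes:
        x = sp.Symbol(n)
        a = sp.simplify(sp.diff(grad, x))
        if a.has(x):
            raise ValueError(
                f"equation for {n!r} is nonlinear in {n!r}; cannot canonize "
                "for exponential Euler")
        if a == 0:
            raise ValueError(
                f"equation for {n!r} has no restoring term in {n!r}; "
                "exponential Euler is undefined")
        tau_eq = sp.simplify(-1 / a)
        A_eq = sp.simplify(x + tau_eq * grad)
        if A_eq.has(x):
            raise ValueError(
                f"equation for {n!r} cannot be canonized (steady state "
                f"still depends on {n!r})")
        forms[n] = SteadyStateForm(tau_eq, A_eq)
    return forms


def build_exponential_euler(odes) -> UpdatePlan:
    """Exponential Euler; exact for uncoupled linear ODEs with constant
    inputs over a step."""
    odes = list(odes)
    forms = canonize(odes)
    entries = []
    for n, _ in odes:
        x = sp.Symbol(n)
        f = forms[n]
        entries.append(PlanEntry(
            n, x + (1 - sp.exp(-_DT / f.tau_eq)) * (f.A_eq - x)))
    return UpdatePlan("exponential", entries, [n for n, _ in odes])


def build_midpoint(odes) -> UpdatePlan:
    """Runge-Kutta order 2: k = f(x); x' = x + dt*f(x + dt/2 * k).

    All midpoint estimates use the same jointly-evaluated k-vector.
    """
    odes, syms = _check_gradient_form(odes)
    k_syms = [sp.Symbol(f"_k_{n}") for n, _ in odes]
    entries = [PlanEntry(str(k), grad, aux=True)
               for k, (_, grad) in zip(k_syms, odes)]
    mid = {s: s + _DT / 2 * k for s, k in zip(syms, k_syms)}
    for (n, grad), s in zip(odes, syms):
        entries.append(PlanEntry(n, s + _DT * grad.xreplace(mid)))
    return UpdatePlan("midpoint", entries, [n for n, _ in odes])


_BUILDERS = {
    "explicit": build_explicit_euler,
    "implicit": build_implicit_euler,
    "exponential": build_exponential_euler,
    "midpoint": build_midpoint,
}


def build_update_plan(odes, method: str) -> UpdatePlan:
    try:
        builder = _BUILDERS[method]
    except KeyError:
        raise ValueError(f"unknown numerical method {method!r}") from None
    return builder(odes)


# --------------------------------------------------------------------------
# event-driven integration
# --------------------------------------------------------------------------

@dataclass
class LinearEventSolution:
    """Closed-form advancement of linear constant-coefficient ODEs.

    Each variable ``x`` with ``dx/dt = a*x + b`` (a, b constant over time,
    possibly involving parameters) is mapped to its exact solution after an
    elapsed time ``Delta``:

    * ``a != 0``:  ``x(Delta) = x_inf + (x(0) - x_inf) * exp(a*Delta)`` with
      ``x_inf = -b/a``;
    * ``a == 0``:  ``x(Delta) = x(0) + b*Delta``.

    Applying with elapsed 0 is the identity, and composition over split
    intervals equals a single application (semigroup property).
    """

    entries: list                        # (name, expr with _elapsed symbol)
    _compiled: dict = field(default_factory=dict, repr=False)

    @property
    def variables(self):
        return [n for n, _ in self.entries]

    def expr_for(self, name: str) -> sp.Expr:
        for n, e in self.entries:
            if n == name:
                return e
        raise KeyError(name)

    def _get_fn(self, name):
        if name not in self._compiled:
            expr = self.expr_for(name)
            args = sorted(str(s) for s in expr.free_symbols)
            self._compiled[name] = (args, lambdify_expr(expr, args))
        return self._compiled[name]

    def apply(self, state: dict, elapsed, params: dict | None = None) -> dict:
        """Advance every variable of ``state`` by ``elapsed`` ms."""
        bindings = dict(state)
        if params:
            bindings.update(params)
        bindings["_elapsed"] = elapsed
        out = dict(state)
        for name, _ in self.entries:
            args, fn = self._get_fn(name)
            out[name] = fn(*[bindings[a] for a in args])
        return out


def build_event_solution(odes, parameters=()) -> LinearEventSolution:
    """Build the exact event-driven solution of a linear ODE set.

    ``parameters`` lists symbol names treated as constants.  Equations that
    are nonlinear, coupled to another event-driven variable, or
    time-dependent are rejected (e.g. the NMDA conductance equation
    ``tau*dg/dt = -g + x*(1-g)`` must raise).
    """
    odes = list(odes)
    names = {n for n, _ in odes}
    params = set(parameters)
    entries = []
    for n, grad in odes:
        x = sp.Symbol(n)
        a = sp.simplify(sp.diff(grad, x))
        b = sp.simplify(grad - a * x)
        for part, label in ((a, "coefficient"), (b, "offset")):
            bad = {str(s) for s in part.free_symbols} - params
            bad -= {"dt"}
            if bad & names or "t" in bad:
                raise ValueError(
                    f"equation for {n!r} is not a constant-coefficient "
                    f"linear ODE ({label} depends on {sorted(bad)})")
        if a.has(x):
            raise ValueError(f"equation for {n!r} is nonlinear in {n!r}")
        if a == 0:
            expr = x + b * _ELAPSED
        else:
            x_inf = sp.simplify(-b / a)
            expr = x_inf + (x - x_inf) * sp.exp(a * _ELAPSED)
        entries.append((n, expr))
    return LinearEventSolution(entries)


def advance_event(state: dict, last_event_time: float, now: float,
                  solution: LinearEventSolution,
                  params: dict | None = None):
    """Advance ``state`` from ``last_event_time`` to ``now`` exactly.

    Returns ``(new_state, now)``; the caller stores ``now`` as the new last
    event time.  Negative elapsed times raise ``ValueError``.
    """
    elapsed = now - last_event_time
    if np.any(np.asarray(elapsed) < 0):
        raise ValueError("negative elapsed time in event-driven update")
    return solution.apply(state, elapsed, params), now
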