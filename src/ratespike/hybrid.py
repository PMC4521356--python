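"""Hybrid networks: rate-to-spike encoding and spike-to-rate decoding.

A rate-coded signal is converted to spikes by a :class:`PoissonPopulation`:
each unit fires independently per step with probability ``rate*dt/1000``
(rate in Hz, dt in ms), where the rate is a constant, a per-unit array, a
time expression such as ``"1 + sin(2*pi*t)"``, or — for input-driven
encoders — the unit's weighted input sum, so that a pre-synaptic rate of 1.0
through a weight of 1.0 produces 1 Hz Poisson trains (100.0 gives 100 Hz).

The converse conversion uses a :class:`DecodingProjection`: the input
``sum(target)`` of a post-synaptic rate neuron is the weighted count of
spikes received over a sliding window of T ms, normalized by the window
length (in seconds) and the number of incoming synapses, so 1 Hz input at
unit weight decodes to 1.0.  By default T equals dt; larger windows trade
temporal resolution (a lag of about T after a rate step) for lower variance.
"""

from __future__ import annotations

import logging

import numpy as np

from .dsl import EquationError, Neuron, parse_expression
from .network import Population, Projection
from . import numerics

log = logging.getLogger("ratespike")

__all__ = ["PoissonPopulation", "SpikeSourceArray", "DecodingProjection",
           "decoding_error"]

_POISSON_NEURON = Neuron(parameters="rates = 0.0", equations="",
                         spike="false", name="Poisson generator")


class PoissonPopulation(Population):
    """Spiking units whose spikes are drawn from a Poisson process.

    ``rates`` may be a scalar (Hz), one value per unit, or a string
    expression of ``t``; with ``target`` given instead, the rate of each
    unit is its weighted sum of inputs for that target.  The per-step
    Bernoulli approximation admits at most one spike per unit per step; a
    warning is emitted when rate*dt/1000 exceeds 0.1.
    """

    custom_update = True

    def __init__(self, geometry, rates=None, target=None, name=None,
                 rng=None):
        super().__init__(geometry, _POISSON_NEURON, name=name, rng=rng)
        if rates is None and target is None:
            raise ValueError("either rates or target must be given")
        self.__dict__["target_driven"] = target
        self.__dict__["_rate_fn"] = None
        if isinstance(rates, str):
            expr, _ = parse_expression(rates, scope="neuron")
            args = sorted(str(s) for s in expr.free_symbols)
            if set(args) - {"t", "dt"}:
                raise EquationError(
                    "rate expressions may only reference t and dt")
            self.__dict__["_rate_fn"] = (numerics.lambdify_expr(expr, args),
                                         args)
        elif rates is not None:
            self.set("rates", rates)
        self.__dict__["_warned"] = False

    def current_rates(self, net) -> np.ndarray:
        if self.target_driven is not None:
            sums = self._ctx.input_sums.get(self.target_driven)
            if sums is None:
                return np.zeros(self.size)
            return sums
        if self._rate_fn is not None:
            fn, args = self._rate_fn
            vals = {"t": net.t, "dt": net.dt}
            return np.broadcast_to(fn(*[vals[a] for a in args]),
                                   (self.size,))
        return np.broadcast_to(np.asarray(self.get("rates"), dtype=float),
                               (self.size,))

    def update_step(self, net):
        rates = self.current_rates(net)
        if np.any(rates < 0):
            raise ValueError("negative Poisson rate")
        p = rates * net.dt / 1000.0
        if not self._warned and np.any(p > 0.1):
            log.warning(
                "Poisson rate*dt/1000 exceeds 0.1; the per-step Bernoulli "
                "approximation may undercount spikes")
            self.__dict__["_warned"] = True
        p = np.minimum(p, 1.0)
        self.spiked[:] = self.rng.random(self.size) < p


_SOURCE_NEURON = Neuron(parameters="", equations="", spike="false",
                        name="spike source")


class SpikeSourceArray(Population):
    """Units that emit spikes at exact, user-given times (ms).

    Times are rounded to the simulation grid; duplicates within one step
    collapse to a single spike.  Schedules can be replaced between two
    simulate calls.
    """

    custom_update = True

    def __init__(self, spike_times, name=None, rng=None):
        n = len(spike_times)
        super().__init__(n, _SOURCE_NEURON, name=name, rng=rng)
        self.__dict__["_times"] = None
        self.set_spike_times(spike_times)

    def set_spike_times(self, spike_times):
        self.__dict__["_times"] = [np.sort(np.asarray(ts, dtype=float))
                                   for ts in spike_times]

    @property
    def spike_times(self):
        return [ts.copy() for ts in self._times]

    def update_step(self, net):
        step = net.step_count
        fired = np.zeros(self.size, dtype=bool)
        for i, ts in enumerate(self._times):
            steps = np.rint(ts / net.dt).astype(np.int64)
            if np.any(steps == step):
                fired[i] = True
        self.spiked[:] = fired


class DecodingProjection(Projection):
    """Sliding-window spike-to-rate decoder.

    Feeds the post-synaptic ``sum(target)`` with::

        (weighted count of spikes received in the last T ms)
        / (T in seconds * number of incoming synapses)

    so a pre-synaptic population firing at 1 Hz through unit weights
    decodes to 1.0.  ``window`` must be a multiple of dt (default: dt).
    The accumulator counts spikes at their arrival time (after the synaptic
    delay).
    """

    feeds_sums = True

    def __init__(self, pre, post, target, window=None, synapse=None,
                 name=None, dt=1.0, rng=None):
        super().__init__(pre, post, target, synapse=synapse, name=name,
                         dt=dt, rng=rng)
        if not self.pre_pop.is_spiking:
            raise EquationError(
                "DecodingProjection requires a spiking pre population")
        if self.post_pop.is_spiking:
            raise EquationError(
                "DecodingProjection requires a rate-coded post population")
        window = dt if window is None else float(window)
        steps = window / self.dt
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("window must be a positive multiple of dt")
        self.window = window
        self.window_steps = int(round(steps))
        self._ring = None
        self._ring_pos = 0
        self._running = None

    def compile_custom(self, net):
        n_post = self.post_pop.size
        self._ring = np.zeros((self.window_steps, n_post))
        self._ring_pos = 0
        self._running = np.zeros(n_post)
        counts = self.size_per_post().astype(float)
        with np.errstate(divide="ignore"):
            self._norm = np.where(
                counts > 0, 1.0 / (self.window / 1000.0 * counts), 0.0)

    def custom_propagate(self, net):
        """Accumulate this step's weighted spike count and expose the
        normalized window total as sum(target)."""
        buf = self.pre_pop.output_history
        col = np.zeros(self.post_pop.size)
        for d, by_pre in self.delay_groups():
            spikes = buf.read(d)
            for r in np.flatnonzero(spikes):
                syn = by_pre.get(int(r))
                if syn is not None:
                    np.add.at(col, self.syn_post[syn], self.w[syn])
        self._running += col - self._ring[self._ring_pos]
        self._ring[self._ring_pos] = col
        self._ring_pos = (self._ring_pos + 1) % self.window_steps
        out = self._running * self._norm
        ctx = self.post_pop._ctx
        ctx.input_sums.setdefault(self.target,
                                  np.zeros(self.post_pop.size))
        ctx.input_sums[self.target] += out
        return out


def decoding_error(decoded, target_rate, dt, horizon_ms=250.0):
    """Relative decoding error over a stimulation segment.

    epsilon = (1/H) * integral_0^H |r(t) - F| / F dt, evaluated as a
    step-wise sum times dt over the first ``horizon_ms`` of ``decoded``.
    A perfect decode gives 0; decoding nothing gives 1.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    decoded = np.asarray(decoded, dtype=float)
    n = int(round(horizon_ms / dt))
    seg = decoded[:n]
    return float(np.sum(np.abs(seg - target_rate) / target_rate) * dt
                 / horizon_ms)
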