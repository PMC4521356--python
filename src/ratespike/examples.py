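"""Reference networks used as worked examples and test fixtures.

Three networks exercise the three simulation regimes:

* ``build_izhikevich_net`` — the classic pulse-coupled network: 1000
  Izhikevich neurons (800 excitatory, 200 inhibitory) with all-to-all
  random connectivity and per-neuron randomized parameters, exhibiting
  population-level oscillations.
* ``build_coba_net`` — a conductance-based integrate-and-fire benchmark
  network of 4000 neurons (3200 excitatory, 800 inhibitory), sparse random
  connectivity at probability 0.02, exponentially decaying synapses,
  dt = 0.1 ms and 0.1 ms delays.  The physiological constants follow the
  published Vogels-Abbott benchmark description (see COBA_PARAMS).
* ``build_hybrid_demo`` — rate-to-spike-to-rate round trip: a rate neuron
  stepping through 0/10/50/100 Hz every 250 ms drives a 1000-unit Poisson
  encoder, decoded back by a 10 ms sliding-window projection.

Each builder takes a seed and returns a fully constructed ``Network`` plus
handles to its populations and monitors.
"""

from __future__ import annotations

import numpy as np

from .dsl import Neuron
from .engine import Network
from .hybrid import DecodingProjection, PoissonPopulation, decoding_error
from .models import standard_neuron
from .network import Uniform

__all__ = ["build_izhikevich_net", "build_coba_net", "build_hybrid_demo",
           "COBA_PARAMS", "EXAMPLES"]


def build_izhikevich_net(seed=0, n_exc=800, n_inh=200,
                         w_exc=(0.0, 0.5), w_inh=(0.0, 1.0),
                         noise_exc=5.0, noise_inh=2.0):
    """Pulse-coupled Izhikevich network (defaults: 800 exc / 200 inh).

    Per-neuron parameter randomization follows the original recipe:
    excitatory cells get c = -65 + 15 r^2, d = 8 - 6 r^2, inhibitory cells
    a = 0.02 + 0.08 r, b = 0.25 - 0.05 r, with r uniform per neuron.
    Weight ranges and noise amplitudes are exposed as arguments with the
    conventional defaults.
    """
    net = Network(dt=1.0, seed=seed)
    pop = net.create_population(n_exc + n_inh, standard_neuron("Izhikevich"),
                                name="izhikevich")
    exc = pop[:n_exc]
    inh = pop[n_exc:]
    re = pop.rng.random(n_exc)
    ri = pop.rng.random(n_inh)
    exc.a = 0.02
    exc.b = 0.2
    exc.c = -65.0 + 15.0 * re ** 2
    exc.d = 8.0 - 6.0 * re ** 2
    exc.noise = noise_exc
    inh.a = 0.02 + 0.08 * ri
    inh.b = 0.25 - 0.05 * ri
    inh.c = -65.0
    inh.d = 2.0
    inh.noise = noise_inh
    pop.v = -65.0
    pop.u = np.asarray(pop.b) * (-65.0)
    pe = net.connect(exc, pop, "exc")
    pe.connect_all_to_all(Uniform(*w_exc))
    pi = net.connect(inh, pop, "inh")
    pi.connect_all_to_all(Uniform(*w_inh))
    mon = net.monitor(pop, "spike")
    return {"network": net, "population": pop, "exc": exc, "inh": inh,
            "projections": [pe, pi], "spike_monitor": mon}


#: Physiological constants of the conductance-based benchmark network
#: (Vogels-Abbott model as described for the COBA benchmark): membrane
#: capacitance (pF), leak conductance (nS), reversal potentials (mV),
#: synaptic time constants (ms), threshold/reset, refractory period and
#: synaptic weights (nS).
COBA_PARAMS = {
    "C": 200.0, "gL": 10.0, "El": -60.0, "Ee": 0.0, "Ei": -80.0,
    "taue": 5.0, "taui": 10.0, "v_thresh": -50.0, "v_reset": -60.0,
    "refractory": 5.0, "we": 6.0, "wi": 67.0, "p": 0.02,
    "dt": 0.1, "delay": 0.1,
}


def _coba_neuron(p):
    return Neuron(
        parameters=f"""
            C = {p['C']} : population
            gL = {p['gL']} : population
            El = {p['El']} : population
            Ee = {p['Ee']} : population
            Ei = {p['Ei']} : population
            taue = {p['taue']} : population
            taui = {p['taui']} : population
            v_thresh = {p['v_thresh']} : population
            I = 0.0
        """,
        equations=f"""
            C * dv/dt = gL * (El - v) + g_exc * (Ee - v)
                + g_inh * (Ei - v) + I : init = {p['El']}
            taue * dg_exc/dt = -g_exc : exponential
            taui * dg_inh/dt = -g_inh : exponential
        """,
        spike="v > v_thresh",
        reset=f"v = {p['v_reset']}",
        refractory=p["refractory"],
        name="COBA integrate-and-fire",
    )


def build_coba_net(seed=0, scale=1.0, connectivity_file=None,
                   save_connectivity_to=None, weight_scale=1.0):
    """Sparse conductance-based IF network (3200 exc / 800 inh at scale 1).

    Connectivity can be exported and re-imported through delimited text
    files so that two runs share identical matrices.  ``weight_scale=0``
    gives the zero-weight variant (leak dynamics only, no network-driven
    spikes).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    p = COBA_PARAMS
    n_exc = int(round(3200 * scale))
    n_inh = int(round(800 * scale))
    net = Network(dt=p["dt"], seed=seed)
    pop = net.create_population(n_exc + n_inh, _coba_neuron(p), name="coba")
    exc = pop[:n_exc]
    inh = pop[n_exc:]
    pop.v = Uniform(p["El"], p["v_thresh"])
    pop.g_exc = Uniform(0.0, p["we"] * weight_scale * 2.0)
    pop.g_inh = Uniform(0.0, p["wi"] * weight_scale * 2.0)
    pe = net.connect(exc, pop, "exc")
    pi = net.connect(inh, pop, "inh")
    if connectivity_file is not None:
        pe.connect_from_file(str(connectivity_file) + ".exc")
        pi.connect_from_file(str(connectivity_file) + ".inh")
    else:
        pe.connect_fixed_probability(p["p"], p["we"] * weight_scale,
                                     delays=p["delay"])
        pi.connect_fixed_probability(p["p"], p["wi"] * weight_scale,
                                     delays=p["delay"])
    if save_connectivity_to is not None:
        pe.save_connectivity(str(save_connectivity_to) + ".exc")
        pi.save_connectivity(str(save_connectivity_to) + ".inh")
    mon = net.monitor(pop, "spike")
    return {"network": net, "population": pop, "exc": exc, "inh": inh,
            "projections": [pe, pi], "spike_monitor": mon}


HYBRID_LEVELS = (0.0, 10.0, 50.0, 100.0)
HYBRID_STEP_MS = 250.0


def build_hybrid_demo(seed=0, n_encoders=1000, window=10.0,
                      decoder_sizes=()):
    """Hybrid encode/decode demo: step-wise rates 0/10/50/100 Hz, 250 ms
    each, through a Poisson encoder and a sliding-window decoder.

    Extra rate neurons decoding from the first ``k`` Poisson units can be
    requested through ``decoder_sizes`` to study how the decoding error
    falls with the number of inputs.
    """
    net = Network(dt=1.0, seed=seed)
    schedule = ("if t < 250.0: 0.0 else: (if t < 500.0: 10.0 else: "
                "(if t < 750.0: 50.0 else: 100.0))")
    source = net.create_population(
        1, Neuron(equations=f"r = {schedule}"), name="source")
    encoder = net.add_population(
        PoissonPopulation(n_encoders, target="exc", name="encoder"))
    drive = net.connect(source, encoder, "exc")
    drive.connect_all_to_all(1.0)
    decoder = net.create_population(
        1, Neuron(equations="r = sum(exc)"), name="decoder")
    dec_proj = net.connect(encoder, decoder, "exc",
                           cls=DecodingProjection, window=window)
    dec_proj.connect_all_to_all(1.0)
    extra = []
    for k in decoder_sizes:
        popk = net.create_population(
            1, Neuron(equations="r = sum(exc)"), name=f"decoder_{k}")
        pk = net.connect(encoder[:k], popk, "exc",
                         cls=DecodingProjection, window=window)
        pk.connect_all_to_all(1.0)
        extra.append((k, popk, net.monitor(popk, "r")))
    raster = net.monitor(encoder, "spike")
    trace = net.monitor(decoder, "r")
    src_mon = net.monitor(source, "r")
    return {"network": net, "source": source, "encoder": encoder,
            "decoder": decoder, "raster": raster, "trace": trace,
            "source_trace": src_mon, "extra_decoders": extra}


def hybrid_errors(trace, dt=1.0, levels=HYBRID_LEVELS,
                  step_ms=HYBRID_STEP_MS):
    """Per-level relative decoding errors from a decoded trace of the
    standard 4-step protocol (the 0 Hz level is skipped: the error is
    normalized by the target rate)."""
    errors = {}
    for i, level in enumerate(levels):
        if level <= 0:
            continue
        lo = int(round(i * step_ms / dt))
        hi = int(round((i + 1) * step_ms / dt))
        errors[level] = decoding_error(trace[lo:hi], level, dt,
                                       horizon_ms=step_ms)
    return errors


EXAMPLES = {
    "izhikevich": {"builder": build_izhikevich_net, "dt": 1.0,
                   "duration": 1000.0},
    "coba": {"builder": build_coba_net, "dt": 0.1, "duration": 100.0},
    "hybrid": {"builder": build_hybrid_demo, "dt": 1.0, "duration": 1000.0},
}
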