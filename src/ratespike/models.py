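"""Standard neuron and synapse models.

Spiking neuron models follow the PyNN nomenclature (IF_curr_exp,
IF_cond_exp, alpha-conductance and adaptive-exponential variants,
HH_cond_exp) plus the Izhikevich neuron; the rate-coded side ships a noisy
leaky integrator.  Synapse models cover the classic rate-coded learning
rules (Hebb, Oja, IBCM), short-term plasticity (STP), online spike-timing
dependent plasticity (STDP) and continuous NMDA-style transmission.

Every model is defined as a plain DSL text block (the same format users
write), so the library doubles as a set of worked examples; retrieve the
raw text with :data:`NEURON_SOURCES` / :data:`SYNAPSE_SOURCES` and parsed
models with :func:`standard_neuron` / :func:`standard_synapse`.
"""

from __future__ import annotations

from .dsl import Neuron, Synapse

__all__ = ["standard_neuron", "standard_synapse",
           "NEURON_SOURCES", "SYNAPSE_SOURCES", "list_models"]


NEURON_SOURCES = {
    # Noisy leaky integrator: tau*dr/dt + r = sum(exc) + B + noise*U(-1,1)
    "LeakyIntegrator": dict(
        parameters="""
            tau = 10.0 : population
            B = 0.0
            noise = 0.0
        """,
        equations="""
            tau * dr/dt + r = sum(exc) + B + noise * Uniform(-1.0, 1.0)
                : min = 0.0
        """,
        name="LeakyIntegrator",
        description="Noisy leaky-integrator rate-coded neuron; the baseline "
                    "B and the multiplicative noise amplitude are per-unit.",
    ),
    # Quadratic adaptive neuron; instantaneous conductances by default, so
    # g_exc/g_inh accumulate one step's spikes and reset, as in the classic
    # pulse-coupled network recipe.
    "Izhikevich": dict(
        parameters="""
            a = 0.02
            b = 0.2
            c = -65.0
            d = 8.0
            v_thresh = 30.0
            i_offset = 0.0
            noise = 0.0
        """,
        equations="""
            I = g_exc - g_inh + noise * Normal(0.0, 1.0) + i_offset
            dv/dt = 0.04 * v^2 + 5.0 * v + 140.0 - u + I : init = -65.0
            du/dt = a * (b * v - u) : init = -13.0
        """,
        spike="v > v_thresh",
        reset="""
            v = c
            u += d
        """,
        name="Izhikevich",
        description="Izhikevich quadratic integrate-and-fire neuron with "
                    "recovery variable u.",
    ),
    "IF_curr_exp": dict(
        parameters="""
            v_rest = -65.0 : population
            cm = 1.0 : population
            tau_m = 20.0 : population
            tau_refrac = 0.1 : population
            tau_syn_E = 5.0 : population
            tau_syn_I = 5.0 : population
            v_thresh = -50.0 : population
            v_reset = -65.0 : population
            i_offset = 0.0
        """,
        equations="""
            tau_m * dv/dt = (v_rest - v)
                + tau_m / cm * (g_exc - g_inh + i_offset) : init = -65.0
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
        """,
        spike="v > v_thresh",
        reset="v = v_reset",
        refractory="tau_refrac",
        name="IF_curr_exp",
        description="Current-based integrate-and-fire with exponentially "
                    "decaying synaptic currents (PyNN-standard form).",
    ),
    "IF_cond_exp": dict(
        parameters="""
            v_rest = -65.0 : population
            cm = 1.0 : population
            tau_m = 20.0 : population
            tau_refrac = 0.1 : population
            tau_syn_E = 5.0 : population
            tau_syn_I = 5.0 : population
            e_rev_E = 0.0 : population
            e_rev_I = -70.0 : population
            v_thresh = -50.0 : population
            v_reset = -65.0 : population
            i_offset = 0.0
        """,
        equations="""
            cm * dv/dt = cm / tau_m * (v_rest - v)
                + g_exc * (e_rev_E - v) + g_inh * (e_rev_I - v)
                + i_offset : init = -65.0
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
        """,
        spike="v > v_thresh",
        reset="v = v_reset",
        refractory="tau_refrac",
        name="IF_cond_exp",
        description="Conductance-based integrate-and-fire with exponential "
                    "synapses (PyNN-standard form).",
    ),
    "IF_curr_alpha": dict(
        parameters="""
            v_rest = -65.0 : population
            cm = 1.0 : population
            tau_m = 20.0 : population
            tau_refrac = 0.1 : population
            tau_syn_E = 5.0 : population
            tau_syn_I = 5.0 : population
            v_thresh = -50.0 : population
            v_reset = -65.0 : population
            i_offset = 0.0
        """,
        equations="""
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
            tau_syn_E * dalpha_exc/dt = 2.718281828459045 * g_exc
                - alpha_exc : exponential
            tau_syn_I * dalpha_inh/dt = 2.718281828459045 * g_inh
                - alpha_inh : exponential
            tau_m * dv/dt = (v_rest - v)
                + tau_m / cm * (alpha_exc - alpha_inh + i_offset)
                : init = -65.0
        """,
        spike="v > v_thresh",
        reset="v = v_reset",
        refractory="tau_refrac",
        name="IF_curr_alpha",
        description="Current-based integrate-and-fire with alpha-shaped "
                    "synaptic currents (PyNN-standard form; externally "
                    "specified).",
    ),
    "IF_cond_alpha": dict(
        parameters="""
            v_rest = -65.0 : population
            cm = 1.0 : population
            tau_m = 20.0 : population
            tau_refrac = 0.1 : population
            tau_syn_E = 5.0 : population
            tau_syn_I = 5.0 : population
            e_rev_E = 0.0 : population
            e_rev_I = -70.0 : population
            v_thresh = -50.0 : population
            v_reset = -65.0 : population
            i_offset = 0.0
        """,
        equations="""
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
            tau_syn_E * dalpha_exc/dt = 2.718281828459045 * g_exc
                - alpha_exc : exponential
            tau_syn_I * dalpha_inh/dt = 2.718281828459045 * g_inh
                - alpha_inh : exponential
            cm * dv/dt = cm / tau_m * (v_rest - v)
                + alpha_exc * (e_rev_E - v) + alpha_inh * (e_rev_I - v)
                + i_offset : init = -65.0
        """,
        spike="v > v_thresh",
        reset="v = v_reset",
        refractory="tau_refrac",
        name="IF_cond_alpha",
        description="Conductance-based integrate-and-fire with alpha "
                    "synapses (PyNN-standard form; externally specified).",
    ),
    "EIF_cond_exp_isfa_ista": dict(
        parameters="""
            v_rest = -70.6 : population
            cm = 0.281 : population
            tau_m = 9.37 : population
            tau_refrac = 0.1 : population
            tau_syn_E = 5.0 : population
            tau_syn_I = 5.0 : population
            e_rev_E = 0.0 : population
            e_rev_I = -80.0 : population
            v_thresh = -50.4 : population
            v_reset = -70.6 : population
            v_spike = -40.0 : population
            delta_T = 2.0 : population
            tau_w = 144.0 : population
            a = 4.0 : population
            b = 0.0805 : population
            i_offset = 0.0
        """,
        equations="""
            cm * dv/dt = cm / tau_m * (v_rest - v
                + delta_T * exp((v - v_thresh) / delta_T))
                + g_exc * (e_rev_E - v) + g_inh * (e_rev_I - v)
                - w_ad + i_offset : init = -70.6
            tau_w * dw_ad/dt = a * (v - v_rest) - w_ad
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
        """,
        spike="v > v_spike",
        reset="""
            v = v_reset
            w_ad += b
        """,
        refractory="tau_refrac",
        name="EIF_cond_exp_isfa_ista",
        description="Adaptive exponential integrate-and-fire (AdEx) with "
                    "exponential conductances (PyNN-standard form; "
                    "externally specified).",
    ),
    "EIF_cond_alpha_isfa_ista": dict(
        parameters="""
            v_rest = -70.6 : population
            cm = 0.281 : population
            tau_m = 9.37 : population
            tau_refrac = 0.1 : population
            tau_syn_E = 5.0 : population
            tau_syn_I = 5.0 : population
            e_rev_E = 0.0 : population
            e_rev_I = -80.0 : population
            v_thresh = -50.4 : population
            v_reset = -70.6 : population
            v_spike = -40.0 : population
            delta_T = 2.0 : population
            tau_w = 144.0 : population
            a = 4.0 : population
            b = 0.0805 : population
            i_offset = 0.0
        """,
        equations="""
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
            tau_syn_E * dalpha_exc/dt = 2.718281828459045 * g_exc
                - alpha_exc : exponential
            tau_syn_I * dalpha_inh/dt = 2.718281828459045 * g_inh
                - alpha_inh : exponential
            cm * dv/dt = cm / tau_m * (v_rest - v
                + delta_T * exp((v - v_thresh) / delta_T))
                + alpha_exc * (e_rev_E - v) + alpha_inh * (e_rev_I - v)
                - w_ad + i_offset : init = -70.6
            tau_w * dw_ad/dt = a * (v - v_rest) - w_ad
        """,
        spike="v > v_spike",
        reset="""
            v = v_reset
            w_ad += b
        """,
        refractory="tau_refrac",
        name="EIF_cond_alpha_isfa_ista",
        description="AdEx neuron with alpha conductances (PyNN-standard "
                    "form; externally specified).",
    ),
    # Spike detection uses a rising-edge latch: `above_prev` reads the
    # previous step's `above` because it is declared first.
    "HH_cond_exp": dict(
        parameters="""
            gbar_Na = 20.0 : population
            gbar_K = 6.0 : population
            gleak = 0.01 : population
            cm = 0.2 : population
            v_offset = -63.0 : population
            e_rev_Na = 50.0 : population
            e_rev_K = -90.0 : population
            e_rev_leak = -65.0 : population
            e_rev_E = 0.0 : population
            e_rev_I = -80.0 : population
            tau_syn_E = 0.2 : population
            tau_syn_I = 2.0 : population
            i_offset = 0.0
        """,
        equations="""
            above_prev = above
            alpha_m = 0.32 * (13.0 - v + v_offset)
                / (exp((13.0 - v + v_offset) / 4.0) - 1.0)
            beta_m = 0.28 * (v - v_offset - 40.0)
                / (exp((v - v_offset - 40.0) / 5.0) - 1.0)
            alpha_h = 0.128 * exp((17.0 - v + v_offset) / 18.0)
            beta_h = 4.0 / (1.0 + exp((40.0 - v + v_offset) / 5.0))
            alpha_n = 0.032 * (15.0 - v + v_offset)
                / (exp((15.0 - v + v_offset) / 5.0) - 1.0)
            beta_n = 0.5 * exp((10.0 - v + v_offset) / 40.0)
            dm/dt = alpha_m * (1.0 - m) - beta_m * m : init = 0.05
            dh/dt = alpha_h * (1.0 - h) - beta_h * h : init = 0.6
            dn/dt = alpha_n * (1.0 - n) - beta_n * n : init = 0.32
            cm * dv/dt = gleak * (e_rev_leak - v)
                + gbar_Na * m^3 * h * (e_rev_Na - v)
                + gbar_K * n^4 * (e_rev_K - v)
                + g_exc * (e_rev_E - v) + g_inh * (e_rev_I - v)
                + i_offset : init = -65.0
            above = if v > 0.0: 1.0 else: 0.0
            tau_syn_E * dg_exc/dt = -g_exc : exponential
            tau_syn_I * dg_inh/dt = -g_inh : exponential
        """,
        spike="above > 0.5 and above_prev < 0.5",
        reset="",
        name="HH_cond_exp",
        description="Single-compartment Hodgkin-Huxley neuron with "
                    "exponential conductances (PyNN-standard form; "
                    "externally specified).  Spikes are detected on the "
                    "upward zero crossing of v; the membrane dynamics "
                    "handle reset and refractoriness themselves.",
    ),
}


SYNAPSE_SOURCES = {
    "Hebb": dict(
        parameters="eta = 0.01 : postsynaptic",
        equations="dw/dt = eta * pre.r * post.r : min = 0.0",
        name="Hebb",
        description="Plain Hebbian rate-coded learning rule.",
    ),
    "Oja": dict(
        parameters="""
            eta = 0.01 : postsynaptic
            alpha = 1.0 : postsynaptic
        """,
        equations="""
            dw/dt = eta * (pre.r * post.r - alpha * post.r^2 * w)
                : min = 0.0
        """,
        name="Oja",
        description="Oja's normalizing Hebbian rule.",
    ),
    # theta is the moving average of the squared post-synaptic rate and is
    # computed once per post-synaptic neuron (postsynaptic flag).
    "IBCM": dict(
        parameters="""
            eta = 0.01 : postsynaptic
            tau = 2000.0 : postsynaptic
        """,
        equations="""
            tau * dtheta/dt + theta = post.r^2 : postsynaptic
            dw/dt = eta * post.r * (post.r - theta) * pre.r : min = 0.0
        """,
        name="IBCM",
        description="Intrator & Cooper form of the BCM rule: Hebb-like "
                    "product of the pre-synaptic rate with a quadratic "
                    "function of the post-synaptic rate, gated by the "
                    "sliding threshold theta = E[post.r^2].",
    ),
    # On a pre-synaptic spike the conductance increment uses u and x
    # *before* their own updates, and x is updated with the pre-update u
    # (statement order below).
    "STP": dict(
        parameters="""
            tau_rec = 100.0 : postsynaptic
            tau_facil = 0.01 : postsynaptic
            U = 0.5 : postsynaptic
        """,
        equations="""
            dx/dt = (1.0 - x) / tau_rec : init = 1.0, event-driven
            du/dt = (U - u) / tau_facil : init = 0.5, event-driven
        """,
        pre_spike="""
            g_target += w * u * x
            x *= (1.0 - u)
            u += U * (1.0 - u)
        """,
        name="STP",
        description="Tsodyks-Markram short-term plasticity: recovery "
                    "variable x (depression) and utilization u "
                    "(facilitation), integrated event-driven.",
    ),
    "STDP": dict(
        parameters="""
            tau_plus = 20.0 : postsynaptic
            tau_minus = 20.0 : postsynaptic
            A_plus = 0.01 : postsynaptic
            A_minus = 0.01 : postsynaptic
            w_max = 1.0 : postsynaptic
        """,
        equations="""
            tau_plus * dApre/dt = -Apre : event-driven
            tau_minus * dApost/dt = -Apost : event-driven
        """,
        pre_spike="""
            g_target += w
            Apre += A_plus * w_max
            w = clip(w - Apost, 0.0, w_max)
        """,
        post_spike="""
            Apost += A_minus * w_max
            w = clip(w + Apre, 0.0, w_max)
        """,
        name="STDP",
        description="Online spike-timing dependent plasticity with "
                    "exponentially decaying pre/post traces (event-driven); "
                    "pre-before-post potentiates, post-before-pre "
                    "depresses; w is clipped to [0, w_max].",
    ),
    # Continuous (non-event-driven) transmission: the post-synaptic
    # conductance is the sum over synapses of g at every step (psp = g).
    "NMDA": dict(
        parameters="tau = 10.0 : postsynaptic",
        equations="""
            tau * dx/dt = -x : exponential
            tau * dg/dt = -g + x * (1.0 - g) : exponential
        """,
        psp="g",
        pre_spike="x += w",
        name="NMDA",
        description="Non-linear NMDA-style synapse: spikes increment x, "
                    "which drives the saturating conductance g; g is summed "
                    "into the post-synaptic input every step.",
    ),
}


_NEURON_CACHE: dict = {}
_SYNAPSE_CACHE: dict = {}


def standard_neuron(name: str) -> Neuron:
    """Return a parsed standard neuron model by (PyNN) name."""
    if name not in NEURON_SOURCES:
        raise KeyError(
            f"unknown neuron model {name!r}; available: "
            f"{sorted(NEURON_SOURCES)}")
    if name not in _NEURON_CACHE:
        _NEURON_CACHE[name] = Neuron(**NEURON_SOURCES[name])
    return _NEURON_CACHE[name]


def standard_synapse(name: str) -> Synapse:
    """Return a parsed standard synapse model by name."""
    if name not in SYNAPSE_SOURCES:
        raise KeyError(
            f"unknown synapse model {name!r}; available: "
            f"{sorted(SYNAPSE_SOURCES)}")
    if name not in _SYNAPSE_CACHE:
        _SYNAPSE_CACHE[name] = Synapse(**SYNAPSE_SOURCES[name])
    return _SYNAPSE_CACHE[name]


def list_models():
    return {"neurons": sorted(NEURON_SOURCES),
            "synapses": sorted(SYNAPSE_SOURCES)}
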