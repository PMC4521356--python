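"""Standard model library: every shipped model runs, and the plasticity
rules reproduce their analytic behavior."""

import numpy as np
import pytest
import sympy as sp

from ratespike import (
    Network,
    Neuron,
    PoissonPopulation,
    SpikeSourceArray,
)
from ratespike import numerics as nm
from ratespike.models import (
    NEURON_SOURCES,
    SYNAPSE_SOURCES,
    standard_neuron,
    standard_synapse,
)

RATE = Neuron(parameters="B = 0.0", equations="r = B")


class TestRegistry:
    def test_unknown_names_rejected(self):
        with pytest.raises(KeyError):
            standard_neuron("NoSuchNeuron")
        with pytest.raises(KeyError):
            standard_synapse("NoSuchSynapse")

    @pytest.mark.parametrize("name", sorted(NEURON_SOURCES))
    def test_every_neuron_simulates_100_steps(self, name):
        net = Network(dt=0.1 if name == "HH_cond_exp" else 1.0, seed=0)
        pop = net.create_population(3, standard_neuron(name))
        net.simulate(100 * net.dt)
        assert net.step_count == 100

    @pytest.mark.parametrize("name", sorted(SYNAPSE_SOURCES))
    def test_every_synapse_simulates_100_steps(self, name):
        net = Network(dt=1.0, seed=0)
        syn = standard_synapse(name)
        if name in ("STP", "STDP", "NMDA"):
            pre = net.create_population(4, standard_neuron("Izhikevich"))
            post = net.create_population(4, standard_neuron("Izhikevich"))
            pre.i_offset = 10.0
        else:
            pre = net.create_population(4, RATE)
            post = net.create_population(
                4, Neuron(equations="r = sum(exc)"))
            pre.B = 0.5
        proj = net.connect(pre, post, "exc", synapse=syn)
        proj.connect_all_to_all(0.5)
        net.simulate(100.0)
        assert net.step_count == 100


class TestLeakyIntegrator:
    def test_decays_to_zero_without_input(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, standard_neuron("LeakyIntegrator"))
        pop.r = 1.0
        net.simulate(200.0)
        assert pop.r[0] == pytest.approx(0.0, abs=1e-8)

    def test_relaxes_to_baseline(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, standard_neuron("LeakyIntegrator"))
        pop.B = 0.8
        net.simulate(300.0)
        assert pop.r[0] == pytest.approx(0.8, rel=1e-6)


class TestIzhikevich:
    def test_regular_firing_under_constant_current(self):
        """Excitatory defaults (a=0.02, b=0.2, c=-65, d=8) fire tonically
        under constant current."""
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, standard_neuron("Izhikevich"))
        pop.i_offset = 10.0
        mon = net.monitor(pop, "spike")
        net.simulate(1000.0)
        times = mon.get("spike")[:, 0]
        assert len(times) > 10
        isis = np.diff(times)[2:]          # skip transient
        assert isis.std() / isis.mean() < 0.05


class TestIFCondExp:
    def test_psp_matches_analytic_double_exponential(self):
        """Membrane deflection after one input spike matches the
        double-exponential closed form within 1% at dt=0.01 ms.

        For a small conductance transient g(t) = w exp(-t/tau_s) the
        linearized PSP is (w (E_e - v_rest)/cm) * tau_s tau_m/(tau_m-tau_s)
        * (exp(-t/tau_m) - exp(-t/tau_s)).
        """
        dt = 0.01
        w = 0.0005
        net = Network(dt=dt, seed=0)
        src = net.add_population(SpikeSourceArray([[5.0]]))
        pop = net.create_population(1, standard_neuron("IF_cond_exp"))
        net.connect(src, pop, "exc").connect_all_to_all(w, delays=dt)
        mon = net.monitor(pop, "v")
        net.simulate(60.0)
        v = mon.get("v").ravel()
        k0 = int(round(5.0 / dt)) + 1      # arrival step
        psp = v[k0:] - (-65.0)
        tau_m, tau_s, cm, e_rev = 20.0, 5.0, 1.0, 0.0
        t = (np.arange(len(psp))) * dt
        amp = w * (e_rev - (-65.0)) / cm * tau_s * tau_m / (tau_m - tau_s)
        analytic = amp * (np.exp(-t / tau_m) - np.exp(-t / tau_s))
        peak = analytic.max()
        assert np.max(np.abs(psp - analytic)) < 0.01 * peak


class TestSTP:
    def test_no_spike_fixed_points(self):
        """Without spikes, x -> 1 and u -> U asymptotically."""
        syn = standard_synapse("STP")
        odes = [(v.name, v.rhs) for v in syn.variables]
        params = {p.name for p in syn.parameters}
        sol = nm.build_event_solution(odes, parameters=params | {"w", "dt"})
        out = sol.apply({"x": 0.1, "u": 0.9}, 1e7,
                        {"tau_rec": 100.0, "tau_facil": 0.01, "U": 0.5})
        assert out["x"] == pytest.approx(1.0, abs=1e-12)
        assert out["u"] == pytest.approx(0.5, abs=1e-12)

    def test_first_spike_sequencing(self):
        """With u = x = 1 at the first spike, the conductance increment is
        w*1*1, then x <- 1*(1-1) = 0 and u <- 1 + U*(1-1) = 1 (statements
        read pre-update values in listed order)."""
        net = Network(dt=1.0, seed=0)
        src = net.add_population(SpikeSourceArray([[3.0]]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_exc / dt", spike="v > 1e9",
                      reset="v = 0.0"))
        proj = net.connect(src, tgt, "exc",
                           synapse=standard_synapse("STP"))
        proj.connect_all_to_all(1.0)
        proj.local_vars["u"][:] = 1.0
        proj.local_vars["x"][:] = 1.0
        proj.last_event[:] = 4.0       # spike arrival; no decay beforehand
        net.simulate(6.0)
        assert tgt.v[0] == pytest.approx(1.0)        # w*u*x = 1
        assert proj.local_vars["x"][0] == pytest.approx(0.0)
        assert proj.local_vars["u"][0] == pytest.approx(1.0)

    def test_event_driven_matches_dense_integration(self):
        """u/x trajectories under a fixed Poisson pre train match dense
        dt=0.001 ms integration within 1e-5 at every event."""
        rng = np.random.default_rng(42)
        times = np.unique(np.round(np.cumsum(
            rng.exponential(50.0, 30))))      # ~20 Hz train on 1 ms grid
        times = times[times < 1000.0]
        net = Network(dt=1.0, seed=0)
        src = net.add_population(SpikeSourceArray([times.tolist()]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = 0.0", spike="v > 1.0",
                      reset="v = 0.0"))
        proj = net.connect(src, tgt, "exc",
                           synapse=standard_synapse("STP"))
        proj.connect_all_to_all(1.0)
        mon = net.monitor(proj, ["u", "x"])
        net.simulate(1001.0)
        rec = mon.get()
        # dense oracle: per-step decay factors of explicit Euler at
        # dt=0.001, applied between arrival times, then the event jumps
        tau_rec, tau_facil, U = 100.0, 0.01, 0.5
        ddt = 0.001
        fx = 1.0 - ddt / tau_rec
        fu = 1.0 - ddt / tau_facil
        x_o, u_o, t_last = 1.0, 0.5, 0.0
        for t_arr in times + 1.0:             # arrival = emission + dt
            n = int(round((t_arr - t_last) / ddt))
            x_o = 1.0 + (x_o - 1.0) * fx ** n
            u_o = U + (u_o - U) * fu ** n
            # event: g uses pre-update u, x; then the updates
            x_o, u_o = x_o * (1.0 - u_o), u_o + U * (1.0 - u_o)
            t_last = t_arr
            step = int(t_arr)
            assert rec["x"][step, 0] == pytest.approx(x_o, abs=1e-5)
            assert rec["u"][step, 0] == pytest.approx(u_o, abs=1e-5)


class TestSTDP:
    def _pair_dw(self, dt_pair, seed=0, w0=0.5):
        """Weight change for an isolated pre/post spike pair separated by
        dt_pair ms (positive: pre before post)."""
        net = Network(dt=1.0, seed=seed)
        t_pre, t_post = 50.0, 50.0 + dt_pair
        src = net.add_population(SpikeSourceArray([[t_pre]]))
        post_drive = net.add_population(SpikeSourceArray([[t_post]]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_drv * 1000.0 - v",
                      spike="v > 1.0", reset="v = 0.0"))
        net.connect(post_drive, tgt, "drv").connect_all_to_all(1.0)
        proj = net.connect(src, tgt, "exc",
                           synapse=standard_synapse("STDP"))
        proj.connect_all_to_all(w0)
        net.simulate(120.0)
        return proj.w[0] - w0

    def test_pair_potentiation_value(self):
        """Pre then post 10 ms later potentiates by A+ * exp(-lag/tau+),
        with the lag measured between the synaptic events (the pre spike
        reaches the synapse one step after emission)."""
        dw = self._pair_dw(10.0)
        # pre event at 51, post drive arrives 51 -> post fires at 61
        assert dw == pytest.approx(0.01 * np.exp(-10.0 / 20.0), rel=1e-9)

    def test_zero_traces_no_change_on_lone_pre(self):
        net = Network(dt=1.0, seed=0)
        src = net.add_population(SpikeSourceArray([[10.0]]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = -v", spike="v > 1.0",
                      reset="v = 0.0"))
        proj = net.connect(src, tgt, "exc",
                           synapse=standard_synapse("STDP"))
        proj.connect_all_to_all(0.5)
        net.simulate(50.0)
        assert proj.w[0] == 0.5

    def test_window_recovery_fits_time_constants(self):
        """Scanning isolated pairs over the LTP and LTD branches recovers
        exponential windows with tau+ and tau- within 2%."""
        lags = np.arange(4.0, 41.0, 4.0)
        ltp = np.array([self._pair_dw(d) for d in lags])
        ltd = np.array([self._pair_dw(-d) for d in lags])
        assert np.all(ltp > 0) and np.all(ltd < 0)
        slope_p = np.polyfit(lags, np.log(ltp), 1)[0]
        slope_m = np.polyfit(lags, np.log(-ltd), 1)[0]
        assert -1.0 / slope_p == pytest.approx(20.0, rel=0.02)
        assert -1.0 / slope_m == pytest.approx(20.0, rel=0.02)

    def test_weight_clipped_to_bounds(self):
        net = Network(dt=1.0, seed=3)
        pre = net.add_population(PoissonPopulation(20, rates=80.0))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_exc - v * 0.1",
                      spike="v > 2.0", reset="v = 0.0"))
        proj = net.connect(pre, tgt, "exc",
                           synapse=standard_synapse("STDP"))
        proj.connect_all_to_all(0.9)
        net.simulate(2000.0)
        assert np.all(proj.w >= 0.0) and np.all(proj.w <= 1.0)


class TestIBCM:
    def test_fixed_point_at_unit_rates(self):
        """With pre = post = 1 constantly, theta -> 1 and dw/dt -> 0."""
        syn = standard_synapse("IBCM")
        net = Network(dt=1.0, seed=0)
        pre = net.create_population(1, RATE)
        post = net.create_population(1, RATE)
        pre.B, pre.r = 1.0, 1.0
        post.B, post.r = 1.0, 1.0
        proj = net.connect(pre, post, "exc", synapse=syn)
        proj.connect_all_to_all(0.1)
        proj.tau = 50.0                     # faster moving average
        net.simulate(1000.0)
        assert proj.shared_vars["theta"][0] == pytest.approx(1.0, rel=1e-6)
        w_before = proj.w[0]
        net.simulate(100.0)
        assert abs(proj.w[0] - w_before) < 1e-6


class TestNMDA:
    def test_conductance_bounded_in_unit_interval(self):
        """g stays in [0, 1] for x >= 0 (saturating (1-g) term) under
        random Poisson stimulation."""
        net = Network(dt=1.0, seed=9)
        pre = net.add_population(PoissonPopulation(10, rates=60.0))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_exc - v", spike="v > 1e9",
                      reset="v = 0.0"))
        proj = net.connect(pre, tgt, "exc",
                           synapse=standard_synapse("NMDA"))
        proj.connect_all_to_all(2.0)
        mon = net.monitor(proj, ["g", "x"])
        net.simulate(1000.0)
        rec = mon.get()
        assert np.all(rec["x"] >= 0.0)
        assert np.all(rec["g"] >= 0.0) and np.all(rec["g"] <= 1.0)

    def test_transmits_continuously(self):
        """The post-synaptic conductance follows sum of g every step, not
        just at spike times."""
        net = Network(dt=1.0, seed=1)
        pre = net.add_population(SpikeSourceArray([[5.0]]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_exc", spike="v > 1e9",
                      reset="v = 0.0"))
        proj = net.connect(pre, tgt, "exc",
                           synapse=standard_synapse("NMDA"))
        proj.connect_all_to_all(1.0)
        mon = net.monitor(tgt, "v")
        net.simulate(60.0)
        v = mon.get("v").ravel()
        # v integrates g: strictly increasing long after the single spike
        assert v[40] > v[20] > v[8] > 0.0
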