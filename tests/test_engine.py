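"""Seven-stage step semantics: ordering, spikes, refractoriness, monitors,
conditional simulation and determinism."""

import numpy as np
import pytest

from ratespike import (
    EquationError,
    Monitor,
    Network,
    Neuron,
    SpikeSourceArray,
    Synapse,
)
from ratespike.models import standard_neuron

RATE = Neuron(parameters="B = 0.0", equations="r = B")
SUMMER = Neuron(equations="r = sum(exc)")


class TestStepBasics:
    def test_rate_decay_recursion(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            1, Neuron(parameters="tau = 10.0 : population",
                      equations="tau * dr/dt + r = sum(exc) : init = 1.0"))
        vals = []
        for _ in range(5):
            net.simulate(1.0)
            vals.append(float(pop.r[0]))
        # explicit Euler: r *= (1 - dt/tau) each step
        want = [0.9 ** (k + 1) for k in range(5)]
        assert vals == pytest.approx(want, rel=1e-12)

    def test_empty_network_advances_time(self):
        net = Network(dt=0.5, seed=0)
        net.simulate(5.0)
        assert net.t == pytest.approx(5.0)
        assert net.step_count == 10

    def test_simulate_zero_noop(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, RATE)
        net.simulate(0.0)
        assert net.step_count == 0

    def test_negative_duration_rejected(self):
        net = Network(dt=1.0, seed=0)
        with pytest.raises(ValueError):
            net.simulate(-1.0)

    def test_split_simulation_identical(self):
        """Two simulate(500) calls produce the same state as one
        simulate(1000) at fixed seed (bit-identical)."""
        def run(split):
            net = Network(dt=1.0, seed=77)
            pop = net.create_population(
                20, standard_neuron("LeakyIntegrator"))
            pop.noise = 1.0
            if split:
                net.simulate(500.0)
                net.simulate(500.0)
            else:
                net.simulate(1000.0)
            return np.asarray(pop.r).copy()
        assert np.array_equal(run(True), run(False))

    def test_nan_guard_names_object(self):
        net = Network(dt=1.0, seed=0, debug=True)
        pop = net.create_population(
            1, Neuron(equations="dr/dt = r * r : init = 2.0"),
            name="exploder")
        with pytest.raises(FloatingPointError, match="exploder.*'r'"):
            net.simulate(200.0)


class TestInputSums:
    def test_weighted_sum(self):
        net = Network(dt=1.0, seed=0)
        src = net.create_population(2, RATE)
        tgt = net.create_population(1, SUMMER)
        proj = net.connect(src, tgt, "exc")
        proj.connect_all_to_all(0.5)
        src.B = np.array([1.0, 3.0])
        src.r = np.array([1.0, 3.0])
        net.simulate(1.0)
        assert tgt.r[0] == pytest.approx(0.5 * 1 + 0.5 * 3)

    def test_max_operator(self):
        net = Network(dt=1.0, seed=0)
        src = net.create_population(2, RATE)
        tgt = net.create_population(1, SUMMER)
        syn = Synapse(operator="max")
        proj = net.connect(src, tgt, "exc", synapse=syn)
        proj.connect_all_to_all(1.0)
        src.B = np.array([1.0, 3.0])
        src.r = np.array([1.0, 3.0])
        net.simulate(1.0)
        assert tgt.r[0] == pytest.approx(3.0)

    def test_mean_and_min_operators(self):
        for op, want in (("mean", 2.0), ("min", 1.0)):
            net = Network(dt=1.0, seed=0)
            src = net.create_population(2, RATE)
            tgt = net.create_population(1, SUMMER)
            proj = net.connect(src, tgt, "exc",
                               synapse=Synapse(operator=op))
            proj.connect_all_to_all(1.0)
            src.B = np.array([1.0, 3.0])
            src.r = np.array([1.0, 3.0])
            net.simulate(1.0)
            assert tgt.r[0] == pytest.approx(want)

    def test_custom_psp(self):
        net = Network(dt=1.0, seed=0)
        src = net.create_population(1, RATE)
        tgt = net.create_population(1, SUMMER)
        syn = Synapse(psp="w * log(pre.r)")
        proj = net.connect(src, tgt, "exc", synapse=syn)
        proj.connect_all_to_all(2.0)
        src.B = np.e
        src.r = np.e
        net.simulate(1.0)
        assert tgt.r[0] == pytest.approx(2.0)

    def test_missing_target_contributes_zero(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, SUMMER)   # no incoming projection
        net.simulate(2.0)
        assert pop.r[0] == 0.0

    def test_no_synapse_post_neuron_zero(self):
        net = Network(dt=1.0, seed=0)
        src = net.create_population(1, RATE)
        tgt = net.create_population(2, SUMMER)
        proj = net.connect(src, tgt, "exc")
        proj.connect_from_tuples([(0, 0, 1.0, 1.0)])
        src.B = 1.0
        src.r = 1.0
        net.simulate(1.0)
        assert tgt.r[1] == 0.0


class TestSpikes:
    def test_izhikevich_reset(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, standard_neuron("Izhikevich"))
        pop.i_offset = 10.0
        mon = net.monitor(pop, ["v", "spike"])
        net.simulate(100.0)
        out = mon.get()
        assert len(out["spike"]) > 2
        # after each spike v was reset to c
        v = out["v"].ravel()
        spike_steps = out["spike"][:, 0].astype(int)
        assert np.all(v[spike_steps] == -65.0)

    def test_no_spike_without_threshold_crossing(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, standard_neuron("Izhikevich"))
        mon = net.monitor(pop, "spike")
        net.simulate(50.0)
        assert len(mon.get("spike")) == 0

    def test_stage_order_one_step_latency(self):
        """pre_spike increments from step k spikes reach the neural update
        of step k+1 and never step k."""
        net = Network(dt=1.0, seed=0)
        src = net.add_population(SpikeSourceArray([[3.0]]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_exc / dt",
                      spike="v > 99.0", reset="v = 0.0"))
        net.connect(src, tgt, "exc").connect_all_to_all(1.0)
        mon = net.monitor(tgt, "v")
        net.simulate(8.0)
        v = mon.get("v").ravel()
        assert v[3] == 0.0 and v[4] == 1.0

    def test_refractory_freezes_all_but_conductances(self):
        net = Network(dt=0.1, seed=0)
        neuron = Neuron(
            parameters="tau = 5.0 : population",
            equations="""
                dv/dt = 10.0 : init = 0.0
                tau * dg_exc/dt = -g_exc : exponential
            """,
            spike="v > 0.5", reset="v = 0.0", refractory=2.0)
        pop = net.create_population(1, neuron)
        pop.g_exc = 1.0
        mon = net.monitor(pop, ["v", "g_exc", "spike"])
        net.simulate(10.0)
        out = mon.get()
        sp = out["spike"][:, 0]
        assert np.diff(sp)[0] == pytest.approx(2.1)       # 20 frozen steps
        # v clamped at reset value during refractory
        v = out["v"].ravel()
        first = int(round(sp[0] * 10))
        assert np.all(v[first:first + 20] == 0.0)
        # conductance kept decaying throughout
        ge = out["g_exc"].ravel()
        decay = np.exp(-0.1 / 5.0)
        assert ge[first + 5] == pytest.approx(ge[first + 4] * decay,
                                              rel=1e-9)

    def test_dynamic_refractory_from_attribute(self):
        net = Network(dt=1.0, seed=0)
        neuron = Neuron(
            parameters="refrac = 3.0",
            equations="dv/dt = 1.0 : init = 0.0",
            spike="v > 0.5", reset="v = 0.0", refractory="refrac")
        pop = net.create_population(1, neuron)
        mon = net.monitor(pop, "spike")
        net.simulate(20.0)
        sp = mon.get("spike")[:, 0]
        assert np.all(np.diff(sp) == 4.0)   # 3 frozen steps + 1 rise


class TestConductances:
    def test_instantaneous_conductance_resets(self):
        """With no ODE for g_exc, its value after the neural update is 0
        every step."""
        net = Network(dt=1.0, seed=0)
        src = net.add_population(SpikeSourceArray([[2.0]]))
        tgt = net.create_population(
            1, Neuron(equations="dv/dt = g_exc", spike="v > 99.0",
                      reset="v = 0.0"))
        net.connect(src, tgt, "exc").connect_all_to_all(5.0)
        mon = net.monitor(tgt, "g_exc")
        net.simulate(6.0)
        assert np.all(mon.get("g_exc") == 0.0)

    def test_decaying_conductance_follows_exponential(self):
        net = Network(dt=0.1, seed=0)
        src = net.add_population(SpikeSourceArray([[1.0]]))
        neuron = Neuron(
            parameters="tau = 5.0 : population",
            equations="""
                dv/dt = 0.0
                tau * dg_exc/dt = -g_exc : exponential
            """,
            spike="v > 99.0", reset="v = 0.0")
        tgt = net.create_population(1, neuron)
        net.connect(src, tgt, "exc").connect_all_to_all(1.0)
        mon = net.monitor(tgt, "g_exc")
        net.simulate(20.0)
        ge = mon.get("g_exc").ravel()
        peak = ge.max()
        k0 = int(ge.argmax())
        # pure exponential decay after the spike
        for j in (10, 50, 100):
            assert ge[k0 + j] == pytest.approx(
                peak * np.exp(-j * 0.1 / 5.0), rel=1e-9)


class TestClamping:
    def test_min_bound_enforced_everywhere(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            1, Neuron(equations="dr/dt = -5.0 : init = 1.0, min = 0.0"))
        mon = net.monitor(pop, "r")
        net.simulate(5.0)
        assert np.all(mon.get("r") >= 0.0)
        assert pop.r[0] == 0.0

    def test_max_bound(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            1, Neuron(equations="dr/dt = 5.0 : init = 0.0, max = 2.0"))
        net.simulate(5.0)
        assert pop.r[0] == 2.0


class TestMonitors:
    def test_period_row_count(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(3, RATE)
        mon = net.monitor(pop, "r", period=10.0)
        net.simulate(100.0)
        assert mon.get("r").shape == (10, 3)

    def test_get_drains(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, RATE)
        mon = net.monitor(pop, "r")
        net.simulate(5.0)
        assert mon.get("r").shape[0] == 5
        assert mon.get("r").size == 0

    def test_pause_resume(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, RATE)
        mon = net.monitor(pop, "r")
        net.simulate(3.0)
        mon.pause()
        net.simulate(4.0)
        mon.resume()
        net.simulate(2.0)
        assert mon.get("r").shape[0] == 5

    def test_unknown_variable_rejected(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, RATE)
        with pytest.raises(EquationError):
            net.monitor(pop, "bogus")

    def test_recorded_izhikevich_matches_scalar_oracle(self):
        """Recorded v of one Izhikevich neuron matches an independent
        scalar reimplementation step for step."""
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, standard_neuron("Izhikevich"))
        pop.i_offset = 6.0
        mon = net.monitor(pop, ["v", "u"])
        net.simulate(300.0)
        out = mon.get()
        # standalone scalar recursion (explicit Euler, same stage order)
        v_o, u_o = -65.0, -13.0
        a, b, c, d, thr, ioff = 0.02, 0.2, -65.0, 8.0, 30.0, 6.0
        for k in range(300):
            I = ioff
            dv = 0.04 * v_o ** 2 + 5 * v_o + 140 - u_o + I
            du = a * (b * v_o - u_o)
            v_o, u_o = v_o + dv, u_o + du
            if v_o > thr:
                v_o, u_o = c, u_o + d
            assert out["v"][k, 0] == pytest.approx(v_o, rel=1e-9)
            assert out["u"][k, 0] == pytest.approx(u_o, rel=1e-9)

    def test_export_to_files(self, tmp_path):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            2, Neuron(equations="dv/dt = 2.0", spike="v > 1.0",
                      reset="v = 0.0"))
        mon = net.monitor(pop, ["v", "spike"])
        net.simulate(5.0)
        paths = mon.to_files(tmp_path)
        assert len(paths) == 2
        v = np.loadtxt(tmp_path / "v.txt")
        assert v.shape == (5, 2)
        ev = np.loadtxt(tmp_path / "spike.txt", ndmin=2)
        assert ev.shape[1] == 2


class TestConditionalSimulation:
    def test_stop_on_ramp(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            1, Neuron(equations="r += 0.1"), stop_condition="r > 1.0")
        elapsed = net.simulate_until(100.0, pop)
        assert elapsed == 11.0
        assert pop.r[0] == pytest.approx(1.1)

    def test_condition_never_met(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(1, RATE, stop_condition="r > 1.0")
        assert net.simulate_until(25.0, pop) == 25.0

    def test_all_quantifier_waits_for_last(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            2, Neuron(parameters="speed = 0.1", equations="r += speed"),
            stop_condition="r > 1.0 : all")
        pop.speed = np.array([0.2, 0.1])
        elapsed = net.simulate_until(100.0, pop)
        assert elapsed == 11.0    # slow neuron crosses at step 11

    def test_any_quantifier_stops_on_first(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            2, Neuron(parameters="speed = 0.1", equations="r += speed"),
            stop_condition="r > 1.0")
        pop.speed = np.array([0.2, 0.1])
        assert net.simulate_until(100.0, pop) == 6.0


class TestDeclarationOrderSemantics:
    def test_later_assignment_sees_updated_value(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            1, Neuron(equations="a = t\nr = a * 2.0"))
        net.simulate(3.0)          # last update at t=2
        assert pop.a[0] == 2.0
        assert pop.r[0] == 4.0

    def test_earlier_reads_previous_step_of_later(self):
        net = Network(dt=1.0, seed=0)
        pop = net.create_population(
            1, Neuron(equations="r = q * 1.0\nq = t"))
        net.simulate(3.0)
        assert pop.q[0] == 2.0
        assert pop.r[0] == 1.0     # q from the previous step
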