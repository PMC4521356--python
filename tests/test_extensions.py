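"""Shared-kernel convolution/pooling and structural plasticity."""

import numpy as np
import pytest
from scipy import stats

from ratespike import (
    EquationError,
    Network,
    Neuron,
    Population,
    Projection,
    SharedProjection,
    Synapse,
    derive_sampling_map,
)
from ratespike.extensions import apply_structural_rules, convolve_step, \
    pool_step

RATE = Neuron(parameters="B = 0.0", equations="r = B")
SUMMER = Neuron(equations="r = sum(exc)")


def shared_net(pre_geo, post_geo, operation="sum", seed=0):
    net = Network(dt=1.0, seed=seed)
    pre = net.create_population(pre_geo, RATE)
    post = net.create_population(post_geo, SUMMER)
    proj = net.connect(pre, post, "exc", cls=SharedProjection,
                       operation=operation)
    return net, pre, post, proj


def brute_force_conv(img, kernel):
    """Independent double-loop oracle with zero padding."""
    H, W = img.shape
    kh, kw = kernel.shape
    out = np.zeros_like(img)
    for x in range(H):
        for y in range(W):
            s = 0.0
            for i in range(kh):
                for j in range(kw):
                    oi, oj = i - kh // 2, j - kw // 2
                    xx, yy = x - oi, y - oj
                    if 0 <= xx < H and 0 <= yy < W:
                        s += kernel[i, j] * img[xx, yy]
            out[x, y] = s
    return out


class TestSamplingMap:
    def test_subsampling_ratio_two(self):
        centers, extent = derive_sampling_map((200, 200), (100, 100))
        assert extent == (2, 2)
        assert list(centers[0][:4]) == [1, 3, 5, 7]

    def test_equal_shapes_identity(self):
        centers, extent = derive_sampling_map((5,), (5,))
        assert extent == (1,)
        assert list(centers[0]) == [0, 1, 2, 3, 4]

    def test_nine_to_three_partition(self):
        centers, extent = derive_sampling_map((9,), (3,))
        assert extent == (3,)
        assert list(centers[0]) == [1, 4, 7]
        # full-cover partition: regions tile the pre population
        starts = centers[0] - extent[0] // 2
        covered = sorted(int(s + o) for s in starts for o in range(3))
        assert covered == list(range(9))


class TestConvolution:
    def test_delta_kernel_identity(self, rng):
        img = rng.random((6, 6))
        k = np.zeros((3, 3))
        k[1, 1] = 1.0
        assert np.allclose(convolve_step(img, k, (6, 6)), img)

    def test_averaging_kernel_on_constant(self):
        img = np.full((10, 10), 3.7)
        k = np.full((3, 3), 1 / 9)
        out = convolve_step(img, k, (10, 10))
        assert np.allclose(out[1:-1, 1:-1], 3.7)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.random((16, 16))
        k = rng.random((3, 3))
        out = convolve_step(img, k, (16, 16))
        assert np.allclose(out, brute_force_conv(img, k), atol=1e-12)

    def test_linearity(self, rng):
        """conv(aX + bY) = a conv(X) + b conv(Y) to 1e-10."""
        x_img, y_img = rng.random((12, 12)), rng.random((12, 12))
        k = rng.standard_normal((5, 5))
        a, b = 2.3, -0.7
        lhs = convolve_step(a * x_img + b * y_img, k, (12, 12))
        rhs = a * convolve_step(x_img, k, (12, 12)) + \
            b * convolve_step(y_img, k, (12, 12))
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_edge_padding_on_constant(self):
        img = np.full((8, 8), 2.0)
        k = np.full((3, 3), 1 / 9)
        out = convolve_step(img, k, (8, 8), padding="edge")
        assert np.allclose(out, 2.0)       # no border attenuation

    def test_in_network_with_subsampling(self, rng):
        net, pre, post, proj = shared_net((8, 8), (4, 4))
        k = rng.random((3, 3))
        proj.convolve(k)
        img = rng.random((8, 8))
        pre.B = img.ravel()
        pre.r = img.ravel()
        net.simulate(1.0)
        centers, _ = derive_sampling_map((8, 8), (4, 4))
        full = brute_force_conv(img, k)
        want = full[np.ix_(centers[0], centers[1])]
        assert np.allclose(np.asarray(post.r).reshape(4, 4), want)

    def test_per_channel_mode(self, rng):
        net = Network(dt=1.0, seed=0)
        pre = net.create_population((6, 6, 3), RATE)
        post = net.create_population((6, 6, 3), SUMMER)
        proj = net.connect(pre, post, "exc", cls=SharedProjection)
        k = rng.random((3, 3))
        proj.convolve(k)
        img = rng.random((6, 6, 3))
        pre.B = img.ravel()
        pre.r = img.ravel()
        net.simulate(1.0)
        got = np.asarray(post.r).reshape(6, 6, 3)
        for c in range(3):
            assert np.allclose(got[..., c],
                               brute_force_conv(img[..., c], k))

    def test_filter_bank_mode(self, rng):
        net = Network(dt=1.0, seed=0)
        pre = net.create_population((6, 6), RATE)
        post = net.create_population((6, 6, 2), SUMMER)
        proj = net.connect(pre, post, "exc", cls=SharedProjection)
        bank = rng.random((2, 3, 3))
        proj.convolve(bank)
        img = rng.random((6, 6))
        pre.B = img.ravel()
        pre.r = img.ravel()
        net.simulate(1.0)
        got = np.asarray(post.r).reshape(6, 6, 2)
        for f in range(2):
            assert np.allclose(got[..., f],
                               brute_force_conv(img, bank[f]))

    def test_incompatible_dimensionalities(self):
        net, pre, post, proj = shared_net((8, 8), (4, 4))
        with pytest.raises(EquationError):
            proj.convolve(np.ones((3, 3, 3, 3)))

    def test_kernel_larger_than_pre_rejected(self):
        net, pre, post, proj = shared_net((4, 4), (4, 4))
        with pytest.raises(EquationError):
            proj.convolve(np.ones((5, 5)))

    def test_spiking_population_rejected(self):
        net = Network(dt=1.0, seed=0)
        spk = net.create_population(
            4, Neuron(equations="dv/dt = 0.0", spike="v > 1.0",
                      reset="v = 0.0"))
        out = net.create_population(4, SUMMER)
        with pytest.raises(EquationError):
            net.connect(spk, out, "exc", cls=SharedProjection)


class TestPooling:
    def test_auto_extent_200_to_100(self):
        net, _, _, proj = shared_net((200, 200), (100, 100),
                                     operation="max")
        proj.pooling()
        assert proj.extent == (2, 2)

    def test_max_pool_constant_field(self):
        net, pre, post, proj = shared_net((4, 4), (2, 2), operation="max")
        proj.pooling()
        pre.B = 1.25
        pre.r = np.full(16, 1.25)
        net.simulate(1.0)
        assert np.allclose(post.r, 1.25)

    def test_max_pool_matches_enumeration(self, rng):
        net, pre, post, proj = shared_net((4, 4), (2, 2), operation="max")
        proj.pooling()
        img = rng.random((4, 4))
        pre.B = img.ravel()
        pre.r = img.ravel()
        net.simulate(1.0)
        want = np.array([[img[0:2, 0:2].max(), img[0:2, 2:4].max()],
                         [img[2:4, 0:2].max(), img[2:4, 2:4].max()]])
        assert np.allclose(np.asarray(post.r).reshape(2, 2), want)

    def test_pool_bounds_property(self, rng):
        """min-pool <= mean-pool <= max-pool element-wise."""
        img = rng.random((9, 9))
        results = {}
        for op in ("min", "mean", "max"):
            results[op] = pool_step(img, (3, 3), (3, 3), op)
        assert np.all(results["min"] <= results["mean"] + 1e-15)
        assert np.all(results["mean"] <= results["max"] + 1e-15)

    def test_post_larger_than_pre_rejected(self):
        net, pre, post, proj = shared_net((2, 2), (4, 4), operation="max")
        with pytest.raises(EquationError):
            proj.pooling()


def aging_synapse():
    return Synapse(
        parameters="max_age = 10.0 : postsynaptic",
        equations="age = if pre.r * post.r > 0.9: 0.0 else: age + dt",
        pruning="age > max_age : proba=0.5",
        creating="pre.r * post.r > 0.9 : proba=1.0, w=0.5")


class TestStructuralPlasticity:
    def _net(self, seed=0, n=4, synapse=None):
        net = Network(dt=1.0, seed=seed)
        a = net.create_population(n, RATE)
        b = net.create_population(n, RATE)
        proj = net.connect(a, b, "exc", synapse=synapse or aging_synapse())
        return net, a, b, proj

    def test_create_prune_round_trip(self):
        net, a, b, proj = self._net()
        proj.connect_all_to_all(1.0)
        before = (proj.syn_pre.copy(), proj.syn_post.copy())
        proj.prune_synapse(1, 2)
        proj.create_synapse(1, 2, w=1.0)
        assert np.array_equal(proj.syn_pre, before[0])
        assert np.array_equal(proj.syn_post, before[1])

    def test_create_duplicate_and_prune_missing_rejected(self):
        net, a, b, proj = self._net()
        proj.connect_from_tuples([(0, 1, 1.0, 1.0)])
        with pytest.raises(ValueError):
            proj.create_synapse(0, 1)
        with pytest.raises(ValueError):
            proj.prune_synapse(3, 3)

    def test_created_synapse_initializes_variables(self):
        net, a, b, proj = self._net()
        proj.connect_from_tuples([(0, 0, 1.0, 1.0)])
        proj.local_vars["age"][:] = 55.0
        proj.create_synapse(1, 0, w=0.5)
        idx = proj.synapse_index(1, 0)
        assert proj.local_vars["age"][idx] == 0.0      # declared init
        assert proj.w[idx] == 0.5

    def test_created_synapse_transmits_next_step(self):
        net = Network(dt=1.0, seed=0)
        a = net.create_population(1, RATE)
        b = net.create_population(1, SUMMER)
        proj = net.connect(a, b, "exc")
        proj.connect_from_tuples([])
        a.B = 2.0
        a.r = 2.0
        net.simulate(1.0)
        assert b.r[0] == 0.0
        proj.create_synapse(0, 0, w=1.0)
        net.simulate(1.0)
        assert b.r[0] == 2.0

    def test_creating_predicate_matches_enumeration(self):
        """Created set equals exhaustive predicate evaluation (proba=1)."""
        syn = Synapse(creating="pre.r * post.r > 0.9 : proba=1.0, w=0.5")
        net, a, b, proj = self._net(n=10, synapse=syn)
        proj.connect_from_tuples([])
        rng = np.random.default_rng(5)
        ra, rb = rng.random(10), rng.random(10)
        a.B, a.r = ra, ra
        b.B, b.r = rb, rb
        proj.start_creating(period=1.0)
        net.simulate(1.0)
        want = {(i, j) for j in range(10) for i in range(10)
                if ra[i] * rb[j] > 0.9}
        got = set(zip(proj.syn_pre.tolist(), proj.syn_post.tolist()))
        assert got == want
        assert np.all(proj.w == 0.5)

    def test_probability_zero_changes_nothing(self):
        syn = Synapse(parameters="max_age = 0.0 : postsynaptic",
                      equations="age = age + dt",
                      pruning="age > max_age : proba=0.0")
        net, a, b, proj = self._net(synapse=syn)
        proj.connect_all_to_all(1.0)
        n = proj.nb_synapses
        proj.start_pruning(period=1.0)
        net.simulate(10.0)
        assert proj.nb_synapses == n

    def test_pruning_counts_binomial(self):
        """Pruned counts over repeated trials follow binomial(n, p)
        (chi-square goodness of fit not rejected at alpha=0.01)."""
        syn = Synapse(parameters="max_age = 0.0 : postsynaptic",
                      equations="age = 1.0",
                      pruning="age > max_age : proba=0.3")
        net = Network(dt=1.0, seed=123)
        a = net.create_population(4, RATE)
        b = net.create_population(4, RATE)
        proj = net.connect(a, b, "exc", synapse=syn)
        tuples = [(i, j, 1.0, 1.0) for i in range(4) for j in range(4)]
        n_syn, p = len(tuples), 0.3
        proj.start_pruning(period=1.0)
        proj._pruning_state["offset"] = 0
        counts = []
        for _ in range(2000):
            proj.connect_from_tuples(tuples)
            proj.local_vars["age"][:] = 1.0
            _, pruned = apply_structural_rules(proj, net)
            counts.append(len(pruned))
        observed = np.bincount(counts, minlength=n_syn + 1)
        expected = stats.binom.pmf(np.arange(n_syn + 1), n_syn, p) * 2000
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2
                / expected[keep]).sum()
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit

    def test_period_respected(self):
        syn = Synapse(creating="pre.r > 0.5 : proba=1.0, w=1.0")
        net, a, b, proj = self._net(n=1, synapse=syn)
        proj.connect_from_tuples([])
        a.B, a.r = 1.0, 1.0
        b.B, b.r = 1.0, 1.0
        proj.start_creating(period=5.0)
        net.simulate(1.0)
        assert proj.nb_synapses == 1     # checked at the first step

    def test_shared_projection_rejects_structural_changes(self):
        net, pre, post, proj = shared_net((4,), (4,))
        with pytest.raises(EquationError):
            proj.create_synapse(0, 0)
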