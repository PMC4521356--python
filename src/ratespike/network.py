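"""Populations, projections and connectivity.

A :class:`Population` is a homogeneous set of neurons with a geometry (an
integer or a multi-dimensional shape); internal data is always flat 1-D with
row-major coordinate-to-rank mapping.  A :class:`Projection` gathers all
synapses between two populations for one target name; its connectivity is a
per-post-neuron list of lists of (pre rank, weight, delay, local synaptic
variables), stored flat in post-major order with a row-pointer index.

Synaptic delays are expressed in milliseconds and rounded to the nearest
multiple of the integration step dt (with a logged warning when rounding is
needed); the minimal delay is one step, because neurons only see values
computed at the previous step.
"""

from __future__ import annotations

import logging
from collections import deque

import numpy as np

from .dsl import EquationError, Neuron, RandomSpec, Synapse

log = logging.getLogger("ratespike")

__all__ = [
    "Population", "PopulationView", "Projection", "DelayBuffer",
    "Uniform", "Normal", "LogNormal", "Exponential", "Gamma",
]


def Uniform(low, high):
    """Uniform random initializer/draw on [low, high]."""
    return RandomSpec("Uniform", (low, high))


def Normal(mu, sigma):
    return RandomSpec("Normal", (mu, sigma))


def LogNormal(mu, sigma):
    return RandomSpec("LogNormal", (mu, sigma))


def Exponential(scale):
    return RandomSpec("Exponential", (scale,))


def Gamma(shape, scale=1.0):
    return RandomSpec("Gamma", (shape, scale))


def delay_to_steps(delay_ms, dt) -> np.ndarray:
    """Round delays (ms) to integer steps; delays below dt are raised to dt."""
    d = np.atleast_1d(np.asarray(delay_ms, dtype=float))
    steps = np.maximum(np.rint(d / dt).astype(np.int64), 1)
    if not np.allclose(steps * dt, np.maximum(d, dt), atol=1e-9):
        log.warning("synaptic delays rounded to a multiple of dt=%g ms", dt)
    return steps


class DelayBuffer:
    """Bounded history of a per-unit output; ``read(d)`` returns the value
    from exactly ``d`` steps ago."""

    def __init__(self, initial: np.ndarray, capacity: int):
        self.capacity = int(max(capacity, 1))
        self._q = deque(maxlen=self.capacity)
        for _ in range(self.capacity):
            self._q.append(np.array(initial, copy=True))

    def push(self, value: np.ndarray) -> None:
        self._q.appendleft(np.array(value, copy=True))

    def read(self, delay_steps: int) -> np.ndarray:
        if not 1 <= delay_steps <= self.capacity:
            raise ValueError(
                f"delay {delay_steps} outside buffer capacity "
                f"{self.capacity}")
        return self._q[delay_steps - 1]


class Population:
    """A set of identical neurons with per-attribute storage.

    Local attributes are length-``size`` arrays; shared ones (``population``
    flag) are scalars.  Attributes are read and written directly
    (``pop.tau = 10``); scalars broadcast, arrays must match the size or
    geometry, and random specs draw one value per unit.
    """

    def __init__(self, geometry, neuron: Neuron, name=None, rng=None,
                 stop_condition=None):
        d = self.__dict__
        d["_vals"] = {}
        d["_locality"] = {}
        if isinstance(geometry, (int, np.integer)):
            geometry = (int(geometry),)
        geometry = tuple(int(g) for g in geometry)
        if any(g <= 0 for g in geometry):
            raise ValueError("zero-size geometry")
        d["geometry"] = geometry
        d["size"] = int(np.prod(geometry))
        d["neuron"] = neuron
        d["name"] = name
        d["rng"] = rng if rng is not None else np.random.default_rng(0)
        d["network"] = None
        d["stop_condition"] = stop_condition
        d["spiked"] = np.zeros(self.size, dtype=bool)
        d["refractory_remaining"] = np.zeros(self.size, dtype=np.int64)
        d["output_history"] = None       # sized by the network at compile
        for p in neuron.parameters:
            self._declare(p.name, p.value, p.locality, p.dtype)
        for v in neuron.variables:
            self._declare(v.name, v.init, v.locality, v.dtype)

    # -- storage -----------------------------------------------------------
    def _declare(self, name, value, locality, dtype):
        self._locality[name] = locality
        if locality == "shared":
            self._vals[name] = value
        else:
            np_dtype = {"real": float, "int": np.int64,
                        "bool": bool}.get(dtype, float)
            self._vals[name] = np.full(self.size, value, dtype=np_dtype)

    @property
    def attributes(self):
        return list(self._vals)

    @property
    def is_spiking(self):
        return self.neuron.is_spiking

    def get(self, name):
        if name not in self._vals:
            # auto-declared conductances / input sums live in the context
            ctx = self.__dict__.get("_ctx")
            if ctx is not None:
                if name.startswith("g_") and name[2:] in ctx.g_auto:
                    return ctx.g_auto[name[2:]]
                if name.startswith("sum_") and name[4:] in ctx.input_sums:
                    return ctx.input_sums[name[4:]]
            raise AttributeError(f"population has no attribute {name!r}")
        return self._vals[name]

    def set(self, name, value, ranks=None):
        if name not in self._vals:
            raise AttributeError(f"population has no attribute {name!r}")
        if self._locality[name] == "shared":
            if ranks is not None or isinstance(value, (RandomSpec,)) or \
                    np.ndim(value) > 0:
                raise ValueError(
                    f"{name!r} is shared and accepts a single value")
            self._vals[name] = type(self._vals[name])(value) \
                if not isinstance(self._vals[name], bool) else bool(value)
            return
        arr = self._vals[name]
        idx = slice(None) if ranks is None else ranks
        n = self.size if ranks is None else len(np.atleast_1d(ranks))
        if isinstance(value, RandomSpec):
            arr[idx] = value.draw(self.rng, n)
        elif np.ndim(value) == 0:
            arr[idx] = value
        else:
            value = np.asarray(value)
            if value.shape == self.geometry and ranks is None:
                value = value.ravel()
            if value.shape != (n,):
                raise ValueError(
                    f"shape mismatch for {name!r}: expected ({n},), got "
                    f"{value.shape}")
            arr[idx] = value

    def __getattr__(self, name):
        vals = self.__dict__.get("_vals")
        if vals is not None and name in vals:
            return vals[name]
        raise AttributeError(name)

    def __setattr__(self, name, value):
        if name in self.__dict__.get("_vals", {}):
            self.set(name, value)
        else:
            object.__setattr__(self, name, value)

    # -- geometry ----------------------------------------------------------
    def rank_from_coordinates(self, coord):
        return int(np.ravel_multi_index(coord, self.geometry))

    def coordinates_from_rank(self, rank):
        return tuple(int(c) for c in np.unravel_index(rank, self.geometry))

    def __getitem__(self, key):
        all_ranks = np.arange(self.size).reshape(self.geometry)
        ranks = np.atleast_1d(all_ranks[key]).ravel()
        return PopulationView(self, ranks)

    def __len__(self):
        return self.size

    def __repr__(self):
        return (f"<Population {self.name or ''} geometry={self.geometry} "
                f"model={'spiking' if self.is_spiking else 'rate'}>")

    # -- engine hooks ------------------------------------------------------
    def output_value(self) -> np.ndarray:
        """The per-unit output pushed into the delay buffer each step."""
        if self.is_spiking:
            return self.spiked
        return self._vals["r"]

    def init_output_history(self, capacity: int) -> None:
        self.__dict__["output_history"] = DelayBuffer(
            self.output_value(), capacity)


class PopulationView:
    """An ordered rank subset of a population; attribute access affects
    exactly the subset, and views compose."""

    def __init__(self, population: Population, ranks):
        d = self.__dict__
        d["population"] = population
        d["ranks"] = np.asarray(ranks, dtype=np.int64)
        if self.ranks.size and (self.ranks.min() < 0
                                or self.ranks.max() >= population.size):
            raise ValueError("view ranks out of range")

    @property
    def size(self):
        return len(self.ranks)

    @property
    def neuron(self):
        return self.population.neuron

    @property
    def is_spiking(self):
        return self.population.is_spiking

    def get(self, name):
        val = self.population.get(name)
        if self.population._locality.get(name, "local") == "shared":
            return val
        return val[self.ranks]

    def set(self, name, value):
        self.population.set(name, value, ranks=self.ranks)

    def __getattr__(self, name):
        pop = self.__dict__.get("population")
        if pop is not None and name in pop._vals:
            return self.get(name)
        raise AttributeError(name)

    def __setattr__(self, name, value):
        pop = self.__dict__.get("population")
        if pop is not None and name in pop._vals:
            self.set(name, value)
        else:
            object.__setattr__(self, name, value)

    def __getitem__(self, key):
        return PopulationView(self.population, np.atleast_1d(
            self.ranks[key]).ravel())

    def __len__(self):
        return self.size


def _as_pop_and_ranks(obj):
    if isinstance(obj, PopulationView):
        return obj.population, obj.ranks
    return obj, np.arange(obj.size)


DEFAULT_RATE_SYNAPSE = Synapse(name="default rate synapse")
DEFAULT_SPIKE_SYNAPSE = Synapse(pre_spike="g_target += w",
                                name="default spiking synapse")


class Projection:
    """All synapses between two populations (or views) for one target.

    Connectivity is list-of-lists keyed by the post-synaptic neuron, stored
    flat in post-major order: ``syn_pre``, ``syn_post``, ``w`` and
    ``delay_steps`` arrays plus per-synapse variable arrays, with
    ``row_ptr`` delimiting each post neuron's synapses.
    """

    def __init__(self, pre, post, target, synapse: Synapse | None = None,
                 name=None, dt=1.0, rng=None):
        self.pre = pre
        self.post = post
        self.target = target
        self.name = name
        self.dt = float(dt)
        self.rng = rng if rng is not None else np.random.default_rng(0)
        pre_pop, _ = _as_pop_and_ranks(pre)
        post_pop, _ = _as_pop_and_ranks(post)
        self.pre_pop = pre_pop
        self.post_pop = post_pop
        if synapse is None:
            synapse = (DEFAULT_SPIKE_SYNAPSE if pre_pop.is_spiking
                       else DEFAULT_RATE_SYNAPSE)
        self.synapse = synapse
        self.network = None
        # flat post-major storage (filled by a connector)
        self.syn_pre = np.empty(0, dtype=np.int64)
        self.syn_post = np.empty(0, dtype=np.int64)
        self.w = np.empty(0, dtype=float)
        self.delay_steps = np.empty(0, dtype=np.int64)
        self.row_ptr = np.zeros(post_pop.size + 1, dtype=np.int64)
        self.local_vars: dict = {}        # per-synapse variable arrays
        self.shared_vars: dict = {}       # postsynaptic vars: per post neuron
        self.shared_params: dict = {}
        self.last_event: np.ndarray | None = None
        self._connected = False
        self._init_parameter_storage()

    # -- parameters / variables -------------------------------------------
    def _init_parameter_storage(self):
        for p in self.synapse.parameters:
            if p.locality == "shared":
                self.shared_params[p.name] = p.value
        # local synapse parameters become per-synapse arrays on connect

    @property
    def nb_synapses(self) -> int:
        return len(self.syn_pre)

    def size_per_post(self) -> np.ndarray:
        return np.diff(self.row_ptr)

    # -- connectors --------------------------------------------------------
    def _finalize(self, syn_pre, syn_post, w, delay_ms):
        syn_pre = np.asarray(syn_pre, dtype=np.int64)
        syn_post = np.asarray(syn_post, dtype=np.int64)
        n = len(syn_pre)
        order = np.lexsort((syn_pre, syn_post))
        self.syn_pre = syn_pre[order]
        self.syn_post = syn_post[order]
        self.w = self._init_values(w, n)[order]
        delay = np.asarray(delay_ms, dtype=float)
        steps = delay_to_steps(delay if delay.ndim else
                               np.full(n, float(delay)), self.dt)
        if len(steps) == 1 and n != 1:
            steps = np.full(n, steps[0])
        self.delay_steps = steps[order] if len(steps) == n else steps
        self.row_ptr = np.zeros(self.post_pop.size + 1, dtype=np.int64)
        counts = np.bincount(self.syn_post, minlength=self.post_pop.size)
        self.row_ptr[1:] = np.cumsum(counts)
        for p in self.synapse.parameters:
            if p.locality == "local":
                self.local_vars[p.name] = np.full(n, p.value, dtype=float)
        for v in self.synapse.variables:
            if v.name == "w":
                continue   # weights live in self.w, set by the connector
            if v.locality == "shared":
                self.shared_vars[v.name] = np.full(
                    self.post_pop.size, v.init, dtype=float)
            else:
                self.local_vars[v.name] = np.full(n, v.init, dtype=float)
        if any(v.method == "event-driven" for v in self.synapse.variables):
            self.last_event = np.zeros(n, dtype=float)
        self._connected = True
        self._invalidate_caches()
        return self

    def _init_values(self, spec, n):
        if isinstance(spec, RandomSpec):
            return spec.draw(self.rng, n).astype(float)
        arr = np.asarray(spec, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if arr.shape != (n,):
            raise ValueError(f"weight array must have shape ({n},)")
        return arr.copy()

    def _pair_ranks(self):
        _, pre_ranks = _as_pop_and_ranks(self.pre)
        _, post_ranks = _as_pop_and_ranks(self.post)
        return pre_ranks, post_ranks

    def connect_all_to_all(self, weights, delays=None,
                           allow_self_connections=False):
        """One synapse for every (pre, post) pair; self-connections are
        excluded when pre and post are the same population unless opted in.
        """
        pre_ranks, post_ranks = self._pair_ranks()
        syn_post = np.repeat(post_ranks, len(pre_ranks))
        syn_pre = np.tile(pre_ranks, len(post_ranks))
        if self.pre_pop is self.post_pop and not allow_self_connections:
            keep = syn_pre != syn_post
            syn_pre, syn_post = syn_pre[keep], syn_post[keep]
        return self._finalize(syn_pre, syn_post, weights,
                              self.dt if delays is None else delays)

    def connect_fixed_probability(self, proba, weights, delays=None,
                                  allow_self_connections=False):
        """Each ordered (pre, post) pair connected independently with
        probability ``proba``."""
        if not 0.0 <= proba <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        pre_ranks, post_ranks = self._pair_ranks()
        mask = self.rng.random((len(post_ranks), len(pre_ranks))) < proba
        if self.pre_pop is self.post_pop and not allow_self_connections:
            same = post_ranks[:, None] == pre_ranks[None, :]
            mask &= ~same
        pj, pi = np.nonzero(mask)
        return self._finalize(pre_ranks[pi], post_ranks[pj], weights,
                              self.dt if delays is None else delays)

    def connect_one_to_one(self, weights=1.0, delays=None):
        pre_ranks, post_ranks = self._pair_ranks()
        if len(pre_ranks) != len(post_ranks):
            raise ValueError("one-to-one requires equal sizes")
        return self._finalize(pre_ranks, post_ranks, weights,
                              self.dt if delays is None else delays)

    def connect_from_function(self, pattern):
        """``pattern(pre, post)`` yields (pre_rank, post_rank, w, d_ms)."""
        tuples = list(pattern(self.pre, self.post))
        return self.connect_from_tuples(tuples)

    def connect_from_tuples(self, tuples):
        if not tuples:
            return self._finalize([], [], [], [])
        arr = np.asarray(tuples, dtype=float)
        syn_pre = arr[:, 0].astype(np.int64)
        syn_post = arr[:, 1].astype(np.int64)
        if syn_pre.min(initial=0) < 0 or \
                syn_pre.max(initial=-1) >= self.pre_pop.size:
            raise ValueError("pre rank out of range")
        if syn_post.min(initial=0) < 0 or \
                syn_post.max(initial=-1) >= self.post_pop.size:
            raise ValueError("post rank out of range")
        pairs = syn_post * self.pre_pop.size + syn_pre
        if len(np.unique(pairs)) != len(pairs):
            raise ValueError("duplicate (pre, post) pair")
        return self._finalize(syn_pre, syn_post, arr[:, 2], arr[:, 3])

    def connect_distance_dependent(self, weight_func, delays=None,
                                   allow_self_connections=False):
        """Connect pairs by Euclidean distance on geometry coordinates.

        ``weight_func(distance)`` returns a weight, or None/0 for no synapse;
        normalization is left to the kernel.
        """
        pre_ranks, post_ranks = self._pair_ranks()
        pre_xy = np.array([self.pre_pop.coordinates_from_rank(r)
                           for r in pre_ranks], dtype=float)
        post_xy = np.array([self.post_pop.coordinates_from_rank(r)
                            for r in post_ranks], dtype=float)
        tuples = []
        d_ms = self.dt if delays is None else delays
        for j, pr in enumerate(post_ranks):
            dist = np.linalg.norm(pre_xy - post_xy[j], axis=1)
            for i, qr in enumerate(pre_ranks):
                if (self.pre_pop is self.post_pop and qr == pr
                        and not allow_self_connections):
                    continue
                wv = weight_func(dist[i])
                if wv:
                    tuples.append((qr, pr, wv, d_ms))
        return self.connect_from_tuples(tuples)

    # -- file round trip ----------------------------------------------------
    def save_connectivity(self, path) -> None:
        """Write connectivity to disk: delimited text with a
        ``pre_rank post_rank weight delay_ms`` header, or a binary array
        container when the path ends in ``.npz``.  Both round-trip
        exactly."""
        if str(path).endswith(".npz"):
            np.savez(path, pre_rank=self.syn_pre, post_rank=self.syn_post,
                     weight=self.w, delay_ms=self.delay_steps * self.dt)
            return
        data = np.column_stack([
            self.syn_pre, self.syn_post, self.w,
            self.delay_steps * self.dt])
        np.savetxt(path, data, fmt="%d %d %.17g %.17g",
                   header="pre_rank post_rank weight delay_ms")

    def connect_from_file(self, path):
        if str(path).endswith(".npz"):
            with np.load(path) as z:
                data = np.column_stack([z["pre_rank"], z["post_rank"],
                                        z["weight"], z["delay_ms"]])
        else:
            data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            return self._finalize([], [], [], [])
        return self.connect_from_tuples(
            [tuple(row) for row in data])

    # -- structural plasticity ----------------------------------------------
    def start_creating(self, period=None):
        """Enable the synapse model's creating rule, checked every
        ``period`` ms (default: every step)."""
        if self.synapse.creating_rule is None:
            raise ValueError("synapse model defines no creating rule")
        steps = max(1, int(round((period or self.dt) / self.dt)))
        if steps == 1:
            log.warning("structural plasticity checked every step; "
                        "consider a larger period")
        self._creating_state = {"period_steps": steps, "offset": None}
        self._structural_active = True

    def stop_creating(self):
        self._creating_state = None
        self._structural_active = bool(
            getattr(self, "_pruning_state", None))

    def start_pruning(self, period=None):
        """Enable the synapse model's pruning rule."""
        if self.synapse.pruning_rule is None:
            raise ValueError("synapse model defines no pruning rule")
        steps = max(1, int(round((period or self.dt) / self.dt)))
        if steps == 1:
            log.warning("structural plasticity checked every step; "
                        "consider a larger period")
        self._pruning_state = {"period_steps": steps, "offset": None}
        self._structural_active = True

    def stop_pruning(self):
        self._pruning_state = None
        self._structural_active = bool(
            getattr(self, "_creating_state", None))

    def synapse_index(self, pre_rank, post_rank):
        lo, hi = self.row_ptr[post_rank], self.row_ptr[post_rank + 1]
        pos = np.searchsorted(self.syn_pre[lo:hi], pre_rank) + lo
        if pos < hi and self.syn_pre[pos] == pre_rank:
            return int(pos)
        return None

    def create_synapse(self, pre_rank, post_rank, w=0.0, d=None):
        """Insert one synapse, preserving per-post ordering by pre rank.

        Per-synapse variables start at their declared init values.
        """
        if self.synapse_index(pre_rank, post_rank) is not None:
            raise ValueError(
                f"synapse ({pre_rank}, {post_rank}) already exists")
        if not 0 <= pre_rank < self.pre_pop.size:
            raise ValueError("pre rank out of range")
        if not 0 <= post_rank < self.post_pop.size:
            raise ValueError("post rank out of range")
        lo, hi = self.row_ptr[post_rank], self.row_ptr[post_rank + 1]
        pos = int(np.searchsorted(self.syn_pre[lo:hi], pre_rank) + lo)
        d_steps = delay_to_steps(self.dt if d is None else d, self.dt)[0]
        self.syn_pre = np.insert(self.syn_pre, pos, pre_rank)
        self.syn_post = np.insert(self.syn_post, pos, post_rank)
        self.w = np.insert(self.w, pos, w)
        self.delay_steps = np.insert(self.delay_steps, pos, d_steps)
        inits = {p.name: p.value for p in self.synapse.parameters
                 if p.locality == "local"}
        inits.update({v.name: v.init for v in self.synapse.variables
                      if v.locality == "local"})
        for name in self.local_vars:
            self.local_vars[name] = np.insert(
                self.local_vars[name], pos, inits.get(name, 0.0))
        if self.last_event is not None:
            t_now = self.network.t if self.network is not None else 0.0
            self.last_event = np.insert(self.last_event, pos, t_now)
        self.row_ptr[post_rank + 1:] += 1
        self._invalidate_caches()

    def prune_synapse(self, pre_rank, post_rank):
        pos = self.synapse_index(pre_rank, post_rank)
        if pos is None:
            raise ValueError(f"no synapse ({pre_rank}, {post_rank})")
        self._delete_indices([pos])

    def _delete_indices(self, positions):
        positions = np.asarray(sorted(positions), dtype=np.int64)
        removed_posts = self.syn_post[positions]
        self.syn_pre = np.delete(self.syn_pre, positions)
        self.syn_post = np.delete(self.syn_post, positions)
        self.w = np.delete(self.w, positions)
        self.delay_steps = np.delete(self.delay_steps, positions)
        for name in self.local_vars:
            self.local_vars[name] = np.delete(self.local_vars[name],
                                              positions)
        if self.last_event is not None:
            self.last_event = np.delete(self.last_event, positions)
        counts = np.bincount(removed_posts, minlength=self.post_pop.size)
        self.row_ptr[1:] -= np.cumsum(counts)
        self._invalidate_caches()

    # -- attribute access ----------------------------------------------------
    def get(self, name):
        if name == "w":
            return self.w
        if name == "delay":
            return self.delay_steps * self.dt
        if name in self.local_vars:
            return self.local_vars[name]
        if name in self.shared_vars:
            return self.shared_vars[name]
        if name in self.shared_params:
            return self.shared_params[name]
        raise AttributeError(f"projection has no attribute {name!r}")

    def set(self, name, value):
        if name in self.shared_params:
            if np.ndim(value) > 0:
                raise ValueError(f"{name!r} is shared and takes one value")
            self.shared_params[name] = float(value)
            return
        if name == "w":
            object.__setattr__(self, "w",
                               self._init_values(value, self.nb_synapses))
            return
        if name in self.local_vars:
            self.local_vars[name] = self._init_values(value,
                                                      self.nb_synapses)
            return
        if name in self.shared_vars:
            arr = self.shared_vars[name]
            if np.ndim(value) == 0:
                arr[:] = value
            else:
                arr[self.post_rows()] = np.asarray(value, dtype=float)
            return
        raise AttributeError(f"projection has no attribute {name!r}")

    def post_rows(self) -> np.ndarray:
        """Ranks of post neurons that receive at least one synapse."""
        return np.flatnonzero(np.diff(self.row_ptr))

    def lil(self):
        """Connectivity as a per-post-neuron list of (pre, w, delay) rows."""
        out = {}
        for pr in self.post_rows():
            lo, hi = self.row_ptr[pr], self.row_ptr[pr + 1]
            out[int(pr)] = (self.syn_pre[lo:hi].copy(),
                            self.w[lo:hi].copy(),
                            self.delay_steps[lo:hi] * self.dt)
        return out

    # -- caches used by the engine -------------------------------------------
    def _invalidate_caches(self):
        self._delay_groups = None
        self._compiled = None

    def delay_groups(self):
        """Group synapses by delay: list of (delay_steps, per-pre lists of
        flat synapse indices) used for spike propagation."""
        if getattr(self, "_delay_groups", None) is None:
            groups = []
            for d in np.unique(self.delay_steps):
                idx = np.flatnonzero(self.delay_steps == d)
                by_pre = {}
                order = np.argsort(self.syn_pre[idx], kind="stable")
                idx = idx[order]
                pres = self.syn_pre[idx]
                starts = np.flatnonzero(np.diff(pres, prepend=-1))
                bounds = np.append(starts, len(pres))
                for k, s in enumerate(starts):
                    by_pre[int(pres[s])] = idx[s:bounds[k + 1]]
                groups.append((int(d), by_pre))
            self._delay_groups = groups
        return self._delay_groups

    def max_delay_steps(self) -> int:
        if self.nb_synapses == 0:
            return 1
        return int(self.delay_steps.max())

    def __getattr__(self, name):
        if name.startswith("_") or "local_vars" not in self.__dict__:
            raise AttributeError(name)
        try:
            return self.get(name)
        except AttributeError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):
        if "shared_params" in self.__dict__ and (
                name == "w" or name in self.local_vars
                or name in self.shared_vars or name in self.shared_params):
            self.set(name, value)
        else:
            object.__setattr__(self, name, value)

    def __repr__(self):
        return (f"<Projection {self.pre_pop.name}->{self.post_pop.name} "
                f"target={self.target!r} synapses={self.nb_synapses}>")
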