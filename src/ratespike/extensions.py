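"""Weight-sharing projections and structural plasticity.

A :class:`SharedProjection` applies one kernel to every post-synaptic
neuron instead of instantiating per-neuron weights:

* ``convolve(kernel)`` computes, for matching pre/post dimensionality,
  ``out(x, y) = sum_i sum_j W(i, j) * pre.r(x - i, y - j)``; when the
  shapes differ, each post coordinate is mapped to the center of a
  pre-synaptic region (sub-sampling).  A lower-dimensional kernel is
  applied separately along the leading dimensions (per-channel mode), and a
  filter bank adds one output dimension per filter.
* ``pooling()`` takes the max/min/mean firing rate over each post neuron's
  pre-synaptic region, without weights; the region extent is derived
  automatically from the shape ratio (e.g. 200x200 over 100x100 gives a
  2x2 area per neuron) and can be overridden.

Shared projections are rate-coded only and non-plastic.

Structural plasticity adds/removes synapses at run time, either through
``Projection.create_synapse()`` / ``prune_synapse()``, or through
``creating`` / ``pruning`` rules of the synapse model: boolean conditions
on continuous pre/post (and, for pruning, per-synapse) variables, applied
with an optional probability at a configurable check period.
"""

from __future__ import annotations

import numpy as np

from .dsl import EquationError, StructuralRule  # noqa: F401  (re-export)
from .network import Projection, _as_pop_and_ranks
from . import numerics

__all__ = ["SharedProjection", "derive_sampling_map",
            "apply_structural_rules", "StructuralRule"]


def derive_sampling_map(pre_shape, post_shape):
    """Map post coordinates to pre-region centers, with pooling extents.

    Per dimension, with ratio ``r = pre/post``, post coordinate ``c`` maps
    to the pre center ``floor(c*r + r/2)`` and the pooling extent is
    ``ceil(r)``: 200 -> 100 gives centers 1, 3, 5, ... with extent 2.
    Ratios below 1 (upsampling) are allowed for convolution.
    """
    pre_shape = tuple(int(s) for s in pre_shape)
    post_shape = tuple(int(s) for s in post_shape)
    if len(pre_shape) != len(post_shape):
        raise ValueError("pre and post must have the same dimensionality")
    if any(s <= 0 for s in pre_shape + post_shape):
        raise ValueError("shapes must be positive")
    centers, extents = [], []
    for pre_d, post_d in zip(pre_shape, post_shape):
        ratio = pre_d / post_d
        c = np.arange(post_d)
        centers.append(np.floor(c * ratio + ratio / 2).astype(np.int64))
        extents.append(int(np.ceil(ratio)))
    return centers, tuple(extents)


class SharedProjection(Projection):
    """A projection whose weights (or pooling regions) are shared by all
    post-synaptic neurons."""

    feeds_sums = True

    def __init__(self, pre, post, target, operation="sum", name=None,
                 dt=1.0, rng=None, **kwargs):
        pre_pop, _ = _as_pop_and_ranks(pre)
        post_pop, _ = _as_pop_and_ranks(post)
        if pre_pop.is_spiking or post_pop.is_spiking:
            raise EquationError(
                "shared projections are only possible for rate-coded "
                "networks")
        if kwargs.pop("synapse", None) is not None:
            raise EquationError(
                "shared projections are non-plastic and accept no synapse "
                "model")
        super().__init__(pre, post, target, synapse=None, name=name, dt=dt,
                         rng=rng)
        if operation not in ("sum", "max", "min", "mean"):
            raise ValueError(f"unknown operation {operation!r}")
        self.operation = operation
        self.mode = None          # 'convolution' | 'pooling'
        self.kernel = None
        self.padding = "zero"
        self.extent = None
        self._connected = True    # no per-synapse storage

    # -- connectors --------------------------------------------------------
    def convolve(self, weights, padding="zero"):
        """Install a shared convolution kernel (see module docstring)."""
        if self.operation != "sum":
            raise EquationError(
                "convolution requires operation='sum'; use pooling() for "
                "max/min/mean")
        if padding not in ("zero", "edge"):
            raise ValueError("padding must be 'zero' or 'edge'")
        kernel = np.asarray(weights, dtype=float)
        pre_nd = len(self.pre_pop.geometry)
        post_nd = len(self.post_pop.geometry)
        if kernel.ndim == pre_nd and post_nd == pre_nd:
            self.mode = "convolution"
        elif kernel.ndim < pre_nd and post_nd == pre_nd:
            self.mode = "channel"
            if self.pre_pop.geometry[kernel.ndim:] != \
                    self.post_pop.geometry[kernel.ndim:]:
                raise EquationError(
                    "per-channel convolution requires matching trailing "
                    "dimensions")
        elif kernel.ndim == pre_nd + 1 and post_nd == pre_nd + 1:
            self.mode = "bank"
            if self.post_pop.geometry[-1] != kernel.shape[0]:
                raise EquationError(
                    "filter bank: last post dimension must equal the "
                    "number of filters")
        else:
            raise EquationError(
                f"incompatible dimensionalities: pre {pre_nd}-d, post "
                f"{post_nd}-d, kernel {kernel.ndim}-d")
        applied = kernel.shape if self.mode == "convolution" else (
            kernel.shape if self.mode == "channel"
            else kernel.shape[1:])
        for k_d, p_d in zip(applied, self.pre_pop.geometry):
            if k_d > p_d:
                raise EquationError(
                    "kernel extent exceeds the pre-synaptic geometry")
        self.kernel = kernel
        self.padding = padding
        return self

    def pooling(self, extent=None):
        """Install a pooling region map (no weights)."""
        pre_shape = self.pre_pop.geometry
        post_shape = self.post_pop.geometry
        if len(pre_shape) != len(post_shape):
            raise EquationError(
                "pooling requires matching dimensionality")
        if any(q > p for p, q in zip(pre_shape, post_shape)):
            raise EquationError(
                "post population larger than pre in a pooled dimension")
        _, auto_extent = derive_sampling_map(pre_shape, post_shape)
        self.extent = tuple(extent) if extent is not None else auto_extent
        self.mode = "pooling"
        if self.operation == "sum":
            self.operation = "mean"
        return self

    # -- engine hooks -------------------------------------------------------
    def compile_custom(self, net):
        if self.mode is None:
            raise RuntimeError(
                "shared projection has no kernel; call convolve() or "
                "pooling()")

    def custom_propagate(self, net):
        pre_r = self.pre_pop.output_history.read(1)
        pre_arr = np.asarray(pre_r).reshape(self.pre_pop.geometry)
        if self.mode == "pooling":
            out = pool_step(pre_arr, self.post_pop.geometry, self.extent,
                            self.operation)
        elif self.mode == "convolution":
            out = convolve_step(pre_arr, self.kernel,
                                self.post_pop.geometry, self.padding)
        elif self.mode == "channel":
            out = _convolve_channels(pre_arr, self.kernel,
                                     self.post_pop.geometry, self.padding)
        else:                      # bank
            outs = [convolve_step(pre_arr, k, self.post_pop.geometry[:-1],
                                  self.padding)
                    for k in self.kernel]
            out = np.stack(outs, axis=-1)
        ctx = self.post_pop._ctx
        ctx.input_sums.setdefault(self.target,
                                  np.zeros(self.post_pop.size))
        ctx.input_sums[self.target] += out.ravel()
        return out.ravel()

    # shared projections have no synapses to save/mutate
    def create_synapse(self, *a, **k):
        raise EquationError("learning/structural changes are disabled on "
                            "shared projections")

    prune_synapse = create_synapse


def convolve_step(pre_arr, kernel, post_shape, padding="zero"):
    """Direct evaluation of the shared-kernel weighted sum.

    ``out(x) = sum_i W(i) * pre(center(x) - i)`` with offsets ``i``
    centered on the kernel; outside values are zero (or clamped to the
    edge).  When pre and post shapes match, centers are the identity.
    """
    pre_shape = pre_arr.shape
    post_shape = tuple(int(s) for s in post_shape)
    if pre_shape == post_shape:
        centers = [np.arange(s) for s in post_shape]
    else:
        centers, _ = derive_sampling_map(pre_shape, post_shape)
    nd = kernel.ndim
    out = np.zeros(post_shape)
    for idx in np.ndindex(kernel.shape):
        wv = kernel[idx]
        if wv == 0.0:
            continue
        coords, valid = [], None
        for d in range(nd):
            offset = idx[d] - kernel.shape[d] // 2
            cd = centers[d] - offset
            shape = [1] * nd
            shape[d] = len(cd)
            ok = (cd >= 0) & (cd < pre_shape[d])
            if padding == "edge":
                cd = np.clip(cd, 0, pre_shape[d] - 1)
            else:
                cd = np.clip(cd, 0, pre_shape[d] - 1)
                ok_b = ok.reshape(shape)
                valid = ok_b if valid is None else (valid & ok_b)
            coords.append(cd.reshape(shape))
        vals = pre_arr[tuple(np.broadcast_arrays(*coords))] \
            if nd > 1 else pre_arr[coords[0].ravel()].reshape(post_shape)
        if padding == "zero" and valid is not None:
            vals = np.where(np.broadcast_to(valid, post_shape), vals, 0.0)
        out += wv * vals
    return out


def _convolve_channels(pre_arr, kernel, post_shape, padding):
    k = kernel.ndim
    lead_post = post_shape[:k]
    trail = pre_arr.shape[k:]
    flat_trail = int(np.prod(trail)) if trail else 1
    moved = pre_arr.reshape(pre_arr.shape[:k] + (flat_trail,))
    outs = [convolve_step(moved[..., c], kernel, lead_post, padding)
            for c in range(flat_trail)]
    out = np.stack(outs, axis=-1)
    return out.reshape(tuple(lead_post) + trail)


def pool_step(pre_arr, post_shape, extent, operation):
    """Max/min/mean over each post neuron's pre-synaptic region.

    Regions are centered on the sampling map; at edges they truncate to
    valid pre coordinates, and mean-pooling divides by the actual region
    size.
    """
    pre_shape = pre_arr.shape
    post_shape = tuple(int(s) for s in post_shape)
    centers, _ = derive_sampling_map(pre_shape, post_shape)
    nd = len(post_shape)
    starts = [c - e // 2 for c, e in zip(centers, extent)]
    if operation == "max":
        acc = np.full(post_shape, -np.inf)
    elif operation == "min":
        acc = np.full(post_shape, np.inf)
    else:
        acc = np.zeros(post_shape)
        count = np.zeros(post_shape)
    for offs in np.ndindex(tuple(extent)):
        coords, valid = [], None
        for d in range(nd):
            cd = starts[d] + offs[d]
            ok = (cd >= 0) & (cd < pre_shape[d])
            cd = np.clip(cd, 0, pre_shape[d] - 1)
            shape = [1] * nd
            shape[d] = len(cd)
            ok_b = ok.reshape(shape)
            valid = ok_b if valid is None else (valid & ok_b)
            coords.append(cd.reshape(shape))
        vals = pre_arr[tuple(np.broadcast_arrays(*coords))] \
            if nd > 1 else pre_arr[coords[0].ravel()].reshape(post_shape)
        mask = np.broadcast_to(valid, post_shape)
        if operation == "max":
            acc = np.where(mask, np.maximum(acc, vals), acc)
        elif operation == "min":
            acc = np.where(mask, np.minimum(acc, vals), acc)
        else:
            acc += np.where(mask, vals, 0.0)
            count += mask
    if operation == "mean":
        return acc / np.maximum(count, 1)
    return acc


# --------------------------------------------------------------------------
# structural plasticity
# --------------------------------------------------------------------------

def _rule_fn(proj, rule):
    cache = proj.__dict__.setdefault("_rule_fns", {})
    if rule.kind not in cache:
        expr = rule.condition
        args = sorted(str(s) for s in expr.free_symbols)
        cache[rule.kind] = (numerics.lambdify_expr(expr, args), args)
    return cache[rule.kind]


def _rule_bindings(proj, net, name, idx=None):
    if name == "t":
        return net.t
    if name == "dt":
        return net.dt
    if name in proj.shared_params:
        return proj.shared_params[name]
    if name == "w":
        return proj.w if idx is None else proj.w[idx]
    if name in proj.local_vars:
        arr = proj.local_vars[name]
        return arr if idx is None else arr[idx]
    if name in proj.shared_vars:
        return proj.shared_vars[name][proj.syn_post if idx is None
                                      else proj.syn_post[idx]]
    raise KeyError(name)


def _due(state, net):
    if state is None:
        return False
    if state["offset"] is None:
        state["offset"] = net.step_count
    return (net.step_count - state["offset"]) % state["period_steps"] == 0


def apply_structural_rules(proj, net):
    """Evaluate creating/pruning rules once; returns (created, pruned)
    lists of (pre_rank, post_rank) pairs."""
    created, pruned = [], []
    prune_state = getattr(proj, "_pruning_state", None)
    if _due(prune_state, net) and proj.nb_synapses:
        rule = proj.synapse.pruning_rule
        fn, args = _rule_fn(proj, rule)
        vals = []
        for a in args:
            if a.startswith("_pre_"):
                v = proj.pre_pop._vals[a[5:]]
                vals.append(np.asarray(v)[proj.syn_pre]
                            if np.ndim(v) else v)
            elif a.startswith("_post_"):
                v = proj.post_pop._vals[a[6:]]
                vals.append(np.asarray(v)[proj.syn_post]
                            if np.ndim(v) else v)
            else:
                vals.append(_rule_bindings(proj, net, a))
        mask = np.broadcast_to(fn(*vals), (proj.nb_synapses,))
        if rule.proba < 1.0:
            mask = mask & (proj.rng.random(proj.nb_synapses) < rule.proba)
        doomed = np.flatnonzero(mask)
        if doomed.size:
            pruned = [(int(proj.syn_pre[i]), int(proj.syn_post[i]))
                      for i in doomed]
            proj._delete_indices(doomed)
    create_state = getattr(proj, "_creating_state", None)
    if _due(create_state, net):
        rule = proj.synapse.creating_rule
        fn, args = _rule_fn(proj, rule)
        _, pre_ranks = _as_pop_and_ranks(proj.pre)
        _, post_ranks = _as_pop_and_ranks(proj.post)
        vals = []
        for a in args:
            if a.startswith("_pre_"):
                v = proj.pre_pop._vals[a[5:]]
                vals.append(np.asarray(v)[pre_ranks][None, :]
                            if np.ndim(v) else v)
            elif a.startswith("_post_"):
                v = proj.post_pop._vals[a[6:]]
                vals.append(np.asarray(v)[post_ranks][:, None]
                            if np.ndim(v) else v)
            else:
                vals.append(_rule_bindings(proj, net, a))
        cond = np.broadcast_to(fn(*vals),
                               (len(post_ranks), len(pre_ranks)))
        exists = np.zeros((proj.post_pop.size, proj.pre_pop.size),
                          dtype=bool)
        exists[proj.syn_post, proj.syn_pre] = True
        cond = cond & ~exists[np.ix_(post_ranks, pre_ranks)]
        if rule.proba < 1.0:
            cond = cond & (proj.rng.random(cond.shape) < rule.proba)
        pj, pi = np.nonzero(cond)
        for j, i in zip(pj, pi):
            pre_r, post_r = int(pre_ranks[i]), int(post_ranks[j])
            proj.create_synapse(pre_r, post_r, w=rule.w,
                                d=rule.d if rule.d is not None else None)
            created.append((pre_r, post_r))
    return created, pruned
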