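"""LIF network simulation with exact subthreshold integration.

Synapses are instantiated from the population-level statistics of a
:class:`~mam.model_spec.NetworkSpec` by drawing source and target neurons
randomly with replacement (autapses and multapses allowed), with Gaussian
weights (wrong-sign draws redrawn) and Gaussian delays (redrawn while below
the 0.1 ms floor, then rounded to the grid).  The subthreshold dynamics

    dV/dt = -(V - E_L)/tau_m + I_s/C_m,     dI_s/dt = -I_s/tau_s

are propagated exactly over each step h by the matrix exponential of the
coupled linear system; spikes are delivered as jumps in I_s at the step
boundary after their delay (ring-buffer semantics) and threshold crossings
are detected after propagation within a step.  External drive is an
independent Poisson process per neuron of rate k_ext * nu_bg at weight J_ext,
realized as per-step Poisson counts (statistically identical at grid
resolution to individual events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_spec import NetworkSpec, NeuronParams

DEFAULT_H = 0.1  # ms
MIN_DELAY = 0.1  # ms


# ---------------------------------------------------------------------------
# synapse instantiation
# ---------------------------------------------------------------------------


@dataclass
class SynapseTable:
    """Concrete synapses: flat arrays plus per-population-pair slices.

    ``pair_slices[(i, j)]`` addresses the synapses of target population ``i``
    from source population ``j``; their count is exactly round(K_ij) * N_i.
    Neuron indices are global (grid order, populations contiguous).
    """

    source: np.ndarray  # int64, global neuron index
    target: np.ndarray  # int64
    weight: np.ndarray  # float64, pA (signed)
    delay_steps: np.ndarray  # int64, multiples of h
    h: float
    pair_slices: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.source.size

    def pair(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        sl = self.pair_slices[(i, j)]
        return self.source[sl], self.target[sl], self.weight[sl], self.delay_steps[sl]

    @property
    def delays(self) -> np.ndarray:
        """Delays in ms."""
        return self.delay_steps * self.h


def draw_truncated_delays(
    rng: np.random.Generator, n: int, d_mean: float, d_sd: float, h: float
) -> np.ndarray:
    """Gaussian delays redrawn (iteratively) while < 0.1 ms, rounded to the grid."""
    if d_sd <= 0:
        d = np.full(n, max(d_mean, MIN_DELAY))
    else:
        d = rng.normal(d_mean, d_sd, size=n)
        bad = d < MIN_DELAY
        while np.any(bad):
            d[bad] = rng.normal(d_mean, d_sd, size=int(bad.sum()))
            bad = d < MIN_DELAY
    steps = np.rint(d / h).astype(np.int64)
    return np.maximum(steps, 1)


def _draw_signed_weights(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    w = rng.normal(mean, sd, size=n)
    if mean > 0:
        bad = w < 0
    elif mean < 0:
        bad = w > 0
    else:
        return np.zeros(n)
    while np.any(bad):
        w[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        if mean > 0:
            bad = w < 0
        else:
            bad = w > 0
    return w


def draw_synapses(spec: NetworkSpec, seed: int = 0, h: float = DEFAULT_H) -> SynapseTable:
    """Instantiate all synapses of a network specification.

    Deterministic for a fixed seed: each ordered population pair uses its own
    child stream, so the realization of one pair is independent of the others.
    """
    sizes = spec.grid.sizes
    n_pop = len(spec.grid)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    K, J, D = spec.conn.K, spec.conn.J_mean, spec.conn.d_mean
    if np.any(K < 0):
        raise ValueError("indegrees must be non-negative")
    Jsd, Dsd = spec.conn.J_sd, spec.conn.d_sd

    srcs, tgts, ws, ds = [], [], [], []
    pair_slices: dict[tuple[int, int], slice] = {}
    root = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0FFEE])
    children = root.spawn(n_pop * n_pop)
    pos = 0
    for i in range(n_pop):
        for j in range(n_pop):
            count = int(np.rint(K[i, j])) * int(sizes[i])
            if count == 0 or sizes[j] == 0:
                pair_slices[(i, j)] = slice(pos, pos)
                continue
            rng = np.random.default_rng(children[i * n_pop + j])
            s = rng.integers(offsets[j], offsets[j + 1], size=count)
            t = rng.integers(offsets[i], offsets[i + 1], size=count)
            w = _draw_signed_weights(rng, count, J[i, j], Jsd[i, j])
            d = draw_truncated_delays(rng, count, D[i, j], Dsd[i, j], h)
            srcs.append(s)
            tgts.append(t)
            ws.append(w)
            ds.append(d)
            pair_slices[(i, j)] = slice(pos, pos + count)
            pos += count

    if srcs:
        source = np.concatenate(srcs)
        target = np.concatenate(tgts)
        weight = np.concatenate(ws)
        delay = np.concatenate(ds)
    else:
        source = np.empty(0, dtype=np.int64)
        target = np.empty(0, dtype=np.int64)
        weight = np.empty(0)
        delay = np.empty(0, dtype=np.int64)
    return SynapseTable(source, target, weight, delay, h, pair_slices)


# ---------------------------------------------------------------------------
# exact propagator
# ---------------------------------------------------------------------------


def exact_propagator(p: NeuronParams, h: float) -> np.ndarray:
    """One-step linear map for the subthreshold state (V - E_L, I_s).

    Closed-form matrix exponential of the coupled system; applying it n times
    equals the analytic solution at t = n h.  V in mV, I_s in pA, h in ms.
    """
    if h <= 0:
        raise ValueError("step size must be positive")
    if p.tau_m == p.tau_s:
        raise ValueError("degenerate tau_m == tau_s is not supported")
    e_m = np.exp(-h / p.tau_m)
    e_s = np.exp(-h / p.tau_s)
    p_vi = (p.tau_m * p.tau_s) / (p.C_m * (p.tau_m - p.tau_s)) * (e_m - e_s)
    return np.array([[e_m, p_vi], [0.0, e_s]])


# ---------------------------------------------------------------------------
# spike data container
# ---------------------------------------------------------------------------


@dataclass
class SpikeData:
    """Recorded spikes plus metadata.

    ``trains[label]`` is a pair of arrays (neuron index local to the
    population, spike time in ms).  Times are multiples of the step h within
    [0, duration].
    """

    trains: dict[str, tuple[np.ndarray, np.ndarray]]
    sizes: dict[str, int]
    recorded: dict[str, int]
    duration: float
    h: float
    seed: int
    record_fraction: float = 1.0

    @property
    def populations(self) -> list[str]:
        return list(self.trains)

    def population_spike_times(self, labels=None) -> np.ndarray:
        """All spike times of the given populations (default: all), sorted."""
        if labels is None:
            labels = self.populations
        parts = [self.trains[l][1] for l in labels]
        out = np.concatenate(parts) if parts else np.empty(0)
        return np.sort(out)

    def n_recorded(self, labels=None) -> int:
        if labels is None:
            labels = self.populations
        return int(sum(self.recorded[l] for l in labels))

    def mean_rate(self, label: str) -> float:
        """Time- and population-averaged rate (spikes/s) of one population."""
        idx, t = self.trains[label]
        n = self.recorded[label]
        if n == 0 or self.duration == 0:
            return 0.0
        return t.size / n / (self.duration / 1000.0)


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------


@njit(cache=False)
def _run_loop(
    n_steps,
    V,
    I_s,
    p_vv,
    p_vi,
    p_ii,
    theta_rel,
    v_r_rel,
    tau_r_steps,
    indptr,
    targets,
    weights,
    delays,
    buf,
    lam,
    J_ext,
    seed,
    spike_step,
    spike_neuron,
):  # pragma: no cover - exercised through simulate()
    np.random.seed(seed)
    n = V.size
    D = buf.shape[0]
    ref_until = np.full(n, -1, dtype=np.int64)
    n_spikes = 0
    for t in range(n_steps):
        slot = (t + 1) % D
        for i in range(n):
            if ref_until[i] > t:
                V[i] = v_r_rel
            else:
                V[i] = p_vv * V[i] + p_vi * I_s[i]
            I_s[i] = p_ii * I_s[i]
            if lam[i] > 0.0:
                I_s[i] += J_ext * np.random.poisson(lam[i])
            I_s[i] += buf[slot, i]
            buf[slot, i] = 0.0
        for i in range(n):
            if V[i] >= theta_rel and ref_until[i] <= t:
                spike_step[n_spikes] = t + 1
                spike_neuron[n_spikes] = i
                n_spikes += 1
                ref_until[i] = t + 1 + tau_r_steps
                V[i] = v_r_rel
                for k in range(indptr[i], indptr[i + 1]):
                    buf[(t + 1 + delays[k]) % D, targets[k]] += weights[k]
    return n_spikes


def simulate(
    spec: NetworkSpec,
    synapses: SynapseTable | None = None,
    duration: float = 1000.0,
    seed: int = 0,
    record_fraction: float = 1.0,
    h: float = DEFAULT_H,
    init: str = "uniform",
) -> SpikeData:
    """Integrate the network for ``duration`` ms and record spikes.

    Membrane potentials start uniformly in [V_r, theta) by default
    (``init="reset"`` starts at V_r), seed-controlled.  Deterministic for a
    fixed seed.  ``record_fraction`` keeps the first fraction of neurons of
    each population in the output (all neurons always participate in the
    dynamics).
    """
    n_steps = int(np.rint(duration / h))
    if abs(n_steps * h - duration) > 1e-9:
        raise ValueError("duration must be a multiple of the step h")
    if synapses is None:
        synapses = draw_synapses(spec, seed=seed, h=h)
    p = spec.neuron_params
    sizes = spec.grid.sizes
    n = int(sizes.sum())
    labels = spec.grid.labels
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    if n == 0 or n_steps == 0:
        return SpikeData(
            {l: (np.empty(0, np.int64), np.empty(0)) for l in labels},
            {l: int(s) for l, s in zip(labels, sizes)},
            {l: 0 for l in labels},
            duration,
            h,
            seed,
            record_fraction,
        )

    prop = exact_propagator(p, h)
    tau_r_steps = int(np.rint(p.tau_r / h))

    # CSR by source neuron
    order = np.argsort(synapses.source, kind="stable")
    tgt = synapses.target[order].astype(np.int64)
    w = synapses.weight[order].astype(np.float64)
    dly = synapses.delay_steps[order].astype(np.int64)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, synapses.source + 1, 1)
    indptr = np.cumsum(indptr)

    D = int(dly.max()) + 2 if dly.size else 2
    buf = np.zeros((D, n))

    # per-neuron external intensity per step
    k_ext_pop = spec.conn.k_ext
    lam = np.repeat(k_ext_pop * spec.conn.nu_bg * h / 1000.0, sizes)

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xD1CE])
    if init == "uniform":
        V = rng.uniform(p.V_r - p.E_L, p.theta - p.E_L, size=n)
    elif init == "reset":
        V = np.full(n, p.V_r - p.E_L)
    else:
        raise ValueError(f"unknown init mode {init!r}")
    I_s = np.zeros(n)

    cap = int(n * (n_steps // max(tau_r_steps, 1) + 2))
    spike_step = np.empty(cap, dtype=np.int64)
    spike_neuron = np.empty(cap, dtype=np.int64)
    loop_seed = int(rng.integers(0, 2**31 - 1))
    n_spikes = _run_loop(
        n_steps,
        V,
        I_s,
        prop[0, 0],
        prop[0, 1],
        prop[1, 1],
        p.theta - p.E_L,
        p.V_r - p.E_L,
        tau_r_steps,
        indptr,
        tgt,
        w,
        dly,
        buf,
        lam,
        spec.conn.J_ext,
        loop_seed,
        spike_step,
        spike_neuron,
    )
    times = spike_step[:n_spikes] * h
    neurons = spike_neuron[:n_spikes]

    trains: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sizes_d: dict[str, int] = {}
    recorded: dict[str, int] = {}
    for pi, label in enumerate(labels):
        n_rec = int(np.rint(record_fraction * sizes[pi]))
        lo = offsets[pi]
        mask = (neurons >= lo) & (neurons < lo + n_rec)
        trains[label] = (neurons[mask] - lo, times[mask])
        sizes_d[label] = int(sizes[pi])
        recorded[label] = n_rec
    return SpikeData(trains, sizes_d, recorded, duration, h, seed, record_fraction)
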