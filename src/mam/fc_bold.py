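"""Functional connectivity from synaptic inputs and Balloon-model BOLD.

The area-level functional connectivity (FC) of the network is defined as the
zero-lag Pearson correlation of the area-averaged absolute synaptic currents

    I_A(t) = (1/N_A) sum_{i in A} N_i sum_j K_ij |J_ij| (nu_j * PSC_j)(t),

with the normalized exponential postsynaptic-current kernel
``PSC_j(t) = exp(-t/tau_s)`` discretized on the 1 ms rate grid.  A
hemodynamic (Balloon) model maps the synaptic drive to a BOLD signal: gamma
kernels generate blood-flow and oxygen-metabolism responses, two nonlinear
state variables (deoxyhemoglobin q, blood volume v) evolve under the balloon
outflow law, and the relative signal change is
``dS/S = V0 [a1 (1 - q) - a2 (1 - v)]``.

Clusters of the FC graph are found by greedy agglomerative optimization of
signed modularity with the asymmetric Q* weighting (positive weights count
more than negative ones), with seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy import signal

from .model_spec import NetworkSpec
from .spike_stats import RateSeries

DT_MS = 1.0


@dataclass
class InputSeries:
    """Area-averaged absolute synaptic current per area (1 ms grid, a.u.)."""

    areas: list[str]
    values: np.ndarray  # (n_areas, T)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.areas):
            raise ValueError("one row per area required")
        if np.any(self.values < -1e-9):
            raise ValueError("synaptic input series must be non-negative")


@dataclass
class FCMatrix:
    """Zero-lag Pearson FC: symmetric, unit diagonal, values in [-1, 1]."""

    areas: list[str]
    values: np.ndarray
    valid: np.ndarray  # False where a series was constant (undefined entries)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


def _psc_kernel(tau_s: float, dt: float = DT_MS) -> np.ndarray:
    """Exponential PSC sampled on the grid, normalized to unit sum."""
    n = max(int(np.ceil(10.0 * tau_s / dt)), 2)
    k = np.exp(-np.arange(n) * dt / tau_s)
    return k / k.sum()


def synaptic_input_series(
    rates: dict[str, RateSeries] | dict[str, np.ndarray], spec: NetworkSpec
) -> InputSeries:
    """Area-averaged absolute synaptic input from population rate series.

    ``rates`` maps population labels (grid order) to 1 ms rate series.  The
    PSC kernel has unit mass, so a constant source rate nu with one incoming
    connection produces the steady value K |J| nu.
    """
    labels = spec.grid.labels
    missing = [l for l in labels if l not in rates]
    if missing:
        raise ValueError(f"rate series missing for populations: {missing[:3]}...")
    mats = []
    for l in labels:
        v = rates[l]
        mats.append(v.values if isinstance(v, RateSeries) else np.asarray(v, float))
    lengths = {m.size for m in mats}
    if len(lengths) != 1:
        raise ValueError("all rate series must have equal length")
    nu = np.vstack(mats)  # (n_pop, T)

    kern = _psc_kernel(spec.neuron_params.tau_s)
    conv = np.empty_like(nu)
    for j in range(nu.shape[0]):
        conv[j] = signal.fftconvolve(nu[j], kern)[: nu.shape[1]]

    W = spec.conn.K * np.abs(spec.conn.J_mean)  # (target, source)
    drive = W @ conv  # per target population
    sizes = spec.grid.sizes.astype(float)
    areas = spec.grid.areas
    out = np.zeros((len(areas), nu.shape[1]))
    for ai, a in enumerate(areas):
        idx = spec.grid.area_indices(a)
        n_a = sizes[idx].sum()
        if n_a > 0:
            out[ai] = sizes[idx] @ drive[idx] / n_a
    # FFT convolution roundoff can leave tiny negative values
    return InputSeries(areas, np.clip(out, 0.0, None))


def fc_matrix(inputs: InputSeries, discard_ms: float = 500.0) -> FCMatrix:
    """Pairwise zero-lag Pearson coefficients after discarding a transient."""
    start = int(np.rint(discard_ms / DT_MS))
    x = inputs.values[:, start:]
    if x.shape[1] < 2:
        raise ValueError("series too short after transient discard")
    sd = x.std(axis=1)
    ok = sd > 0
    n = x.shape[0]
    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 1.0)
    if np.any(ok):
        sub = np.corrcoef(x[ok])
        vals[np.ix_(ok, ok)] = np.atleast_2d(sub)
        np.fill_diagonal(vals, 1.0)
    valid = np.outer(ok, ok)
    np.fill_diagonal(valid, True)
    return FCMatrix(inputs.areas, vals, valid)


# ---------------------------------------------------------------------------
# Balloon model
# ---------------------------------------------------------------------------


@dataclass
class BalloonParams:
    """Hemodynamic parameters (defaults as in the canonical Balloon model)."""

    tau_f: float = 4.0  # s, flow gamma-kernel time scale
    tau_h_ratio: float = 0.242  # tau_h = ratio * tau_f
    f1: float = 1.5  # peak normalized flow gain
    delta_t: float = 1.0  # s, flow-response onset delay
    k: int = 3  # gamma kernel order
    tau_mtt: float = 3.0  # s, mean transit time
    tau: float = 10.0  # s, viscoelastic time constant
    alpha: float = 0.4  # outflow exponent
    E0: float = 0.4  # resting oxygen extraction
    a1: float = 3.4
    a2: float = 1.0
    V0: float = 0.03

    @property
    def m1(self) -> float:
        # (m1 - 1) = (f1 - 1) / 2
        return 1.0 + (self.f1 - 1.0) / 2.0

    @property
    def tau_h(self) -> float:
        return self.tau_h_ratio * self.tau_f


@dataclass
class BalloonResult:
    """Hemodynamic state trajectories on the integration grid."""

    t: np.ndarray  # s
    f: np.ndarray  # normalized blood flow
    m: np.ndarray  # normalized CMRO2
    q: np.ndarray  # normalized deoxyhemoglobin
    v: np.ndarray  # normalized blood volume
    bold: np.ndarray  # relative signal change dS/S
    params: BalloonParams = field(default_factory=BalloonParams)


def _gamma_kernel(t: np.ndarray, k: int, tau_h: float) -> np.ndarray:
    """h(t) = 1/(k tau_h (k-1)!) (t/tau_h)^k e^{-t/tau_h} (unit integral)."""
    h = np.zeros_like(t)
    pos = t >= 0
    x = t[pos] / tau_h
    h[pos] = (x**k) * np.exp(-x) / (k * tau_h * factorial(k - 1))
    return h


def _deriv(q: float, v: float, f: float, m: float, p: BalloonParams) -> tuple[float, float]:
    dv = (f - v ** (1.0 / p.alpha)) / (p.tau_mtt + p.tau)
    f_out = v ** (1.0 / p.alpha) + p.tau * dv
    dq = (m - q * f_out / v) / p.tau_mtt
    return dq, dv


def balloon_bold(
    inputs: InputSeries | np.ndarray,
    dt_ms: float = DT_MS,
    params: BalloonParams | None = None,
    dt_ode_ms: float = 10.0,
) -> BalloonResult:
    """BOLD signal from synaptic drive through the Balloon model.

    Flow ``f`` and oxygen metabolism ``m`` are gamma-kernel convolutions of
    the input (delayed by delta_t for the flow); q and v follow the balloon
    equations with the outflow law ``f_out = v^{1/alpha} + tau dv/dt``
    (solved explicitly for dv/dt), integrated with a fixed-step 4th-order
    Runge-Kutta scheme at 10 ms after resampling the input (hemodynamic time
    scales are seconds).  Accepts a single series or an :class:`InputSeries`
    (rows processed independently, stacked in the result).
    """
    if params is None:
        params = BalloonParams()
    if isinstance(inputs, InputSeries):
        rows = [
            balloon_bold(inputs.values[i], dt_ms, params, dt_ode_ms)
            for i in range(inputs.values.shape[0])
        ]
        return BalloonResult(
            rows[0].t,
            np.vstack([r.f for r in rows]),
            np.vstack([r.m for r in rows]),
            np.vstack([r.q for r in rows]),
            np.vstack([r.v for r in rows]),
            np.vstack([r.bold for r in rows]),
            params,
        )

    x = np.asarray(inputs, dtype=float)
    # resample to the ODE grid by block averaging
    ratio = int(np.rint(dt_ode_ms / dt_ms))
    if ratio > 1:
        n = (x.size // ratio) * ratio
        x = x[:n].reshape(-1, ratio).mean(axis=1)
    dt = dt_ode_ms / 1000.0  # s
    t = np.arange(x.size) * dt

    kern_t = np.arange(0.0, 8.0 * params.tau_f, dt)
    h = _gamma_kernel(kern_t, params.k, params.tau_h)
    h_delayed = _gamma_kernel(kern_t - params.delta_t, params.k, params.tau_h)
    conv_f = signal.fftconvolve(x, h_delayed)[: x.size] * dt
    conv_m = signal.fftconvolve(x, h)[: x.size] * dt
    f = 1.0 + (params.f1 - 1.0) * conv_f
    m = 1.0 + (params.m1 - 1.0) * conv_m

    q = np.ones(x.size)
    v = np.ones(x.size)
    for i in range(x.size - 1):
        f0, m0 = f[i], m[i]
        f1, m1 = f[i + 1], m[i + 1]
        fh, mh = 0.5 * (f0 + f1), 0.5 * (m0 + m1)
        k1 = _deriv(q[i], v[i], f0, m0, params)
        k2 = _deriv(q[i] + 0.5 * dt * k1[0], v[i] + 0.5 * dt * k1[1], fh, mh, params)
        k3 = _deriv(q[i] + 0.5 * dt * k2[0], v[i] + 0.5 * dt * k2[1], fh, mh, params)
        k4 = _deriv(q[i] + dt * k3[0], v[i] + dt * k3[1], f1, m1, params)
        q[i + 1] = q[i] + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        v[i + 1] = v[i] + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if v[i + 1] <= 0 or not np.isfinite(v[i + 1]):
            raise RuntimeError(
                f"Balloon integration unstable at t = {t[i + 1]:.2f} s "
                f"(v = {v[i + 1]:.3g}); reduce the input amplitude or the step"
            )
    bold = params.V0 * (params.a1 * (1.0 - q) - params.a2 * (1.0 - v))
    return BalloonResult(t, f, m, q, v, bold, params)


# ---------------------------------------------------------------------------
# FC comparison and clustering
# ---------------------------------------------------------------------------


def fc_compare(fc_a: FCMatrix | np.ndarray, fc_b: FCMatrix | np.ndarray) -> float:
    """Pearson correlation of two FC matrices over the strict upper triangle.

    Entries flagged invalid (or NaN) in either matrix are pairwise excluded;
    fewer than 3 common pairs is an error.  Symmetric in its arguments and
    invariant under common affine rescaling of the off-diagonals.
    """
    def unpack(fc):
        if isinstance(fc, FCMatrix):
            return fc.values, fc.valid
        v = np.asarray(fc, dtype=float)
        return v, np.isfinite(v)

    va, ma = unpack(fc_a)
    vb, mb = unpack(fc_b)
    if va.shape != vb.shape:
        raise ValueError("FC matrices must have equal shape")
    iu = np.triu_indices(va.shape[0], k=1)
    keep = ma[iu] & mb[iu] & np.isfinite(va[iu]) & np.isfinite(vb[iu])
    xa, xb = va[iu][keep], vb[iu][keep]
    if xa.size < 3:
        raise ValueError("fewer than 3 common FC pairs")
    return float(np.corrcoef(xa, xb)[0, 1])


def _qstar(w: np.ndarray, labels: np.ndarray) -> float:
    """Signed modularity with asymmetric positive/negative weighting (Q*)."""
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    same = labels[:, None] == labels[None, :]

    def q(mat):
        s_i = mat.sum(axis=1)
        s = s_i.sum()
        if s == 0:
            return 0.0, 0.0
        e = np.outer(s_i, s_i) / s
        return float(((mat - e) * same).sum() / s), s

    qp, sp = q(wp)
    qn, sn = q(wn)
    if sp + sn == 0:
        return 0.0
    return qp - qn * sn / (sp + sn)


def cluster_fc(fc: FCMatrix | np.ndarray, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Community labels of the signed FC graph maximizing Q*.

    Greedy agglomerative merging from singletons followed by single-node
    moves, repeated over seeded restarts with randomized scan order; the
    partition with the best Q* is returned (labels relabeled 0..k-1 by first
    appearance).
    """
    w = fc.values.copy() if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float).copy()
    w = np.where(np.isfinite(w), w, 0.0)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    rng = np.random.default_rng(seed)

    best_labels, best_q = np.zeros(n, dtype=int), -np.inf
    for _ in range(max(1, n_restarts)):
        labels = np.arange(n)
        improved = True
        while improved:
            improved = False
            # agglomerative pass
            clusters = np.unique(labels)
            best_gain, best_pair = 1e-12, None
            for ii, a in enumerate(clusters):
                for b in clusters[ii + 1 :]:
                    trial = labels.copy()
                    trial[trial == b] = a
                    gain = _qstar(w, trial) - _qstar(w, labels)
                    if gain > best_gain:
                        best_gain, best_pair = gain, (a, b)
            if best_pair is not None:
                labels[labels == best_pair[1]] = best_pair[0]
                improved = True
                continue
            # node-move pass
            for i in rng.permutation(n):
                current = _qstar(w, labels)
                options = list(np.unique(labels)) + [labels.max() + 1]
                for c in options:
                    if c == labels[i]:
                        continue
                    trial = labels.copy()
                    trial[i] = c
                    if _qstar(w, trial) > current + 1e-12:
                        labels = trial
                        improved = True
                        break
        q = _qstar(w, labels)
        if q > best_q:
            best_q, best_labels = q, labels.copy()

    _, out = np.unique(best_labels, return_inverse=True)
    order = {}
    relabeled = np.empty(n, dtype=int)
    for i, c in enumerate(out):
        order.setdefault(c, len(order))
        relabeled[i] = order[c]
    return relabeled
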