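"""Stationary mean-field theory of the LIF network.

In the diffusion approximation, a population receiving mean input ``mu`` and
variance ``sigma^2`` (measured in membrane-potential units relative to the
leak potential) fires at the Siegert rate

    1/nu = tau_r + tau_m sqrt(pi) * Integral_{y_r}^{y_th} e^{x^2}(1+erf x) dx,

with reduced, shifted bounds ``y = (V - mu)/sigma + gamma sqrt(tau_s/tau_m)``
for V in {V_r, theta} and ``gamma = |zeta(1/2)|/sqrt(2)`` correcting for
synaptic filtering to linear order in tau_s/tau_m.

Unit convention: the synaptic weight entering ``mu`` and ``sigma^2`` is the
membrane-potential jump of one spike through an exponential PSC,
``J_hat = tau_s J / C_m`` (mV for J in pA), so that

    mu_i      = tau_m sum_j K_ij J_hat_ij nu_j + tau_m k_ext,i J_hat_ext nu_bg
    sigma_i^2 = tau_m sum_j K_ij J_hat_ij^2 nu_j + tau_m k_ext,i J_hat_ext^2 nu_bg

with tau_m in seconds and rates in spikes/s.  This convention is validated
against simulation in the test suite.

Fixed points of the network are found by integrating the pseudo-time flow
``dnu/ds = Phi(nu) - nu`` with the exponential Euler scheme (step 0.1); local
stability is assessed through the eigenvalues of the effective connectivity
``G = dPhi/dnu`` (stable iff max Re(lambda) < 1), and global stability as the
fraction of random initial conditions converging to the low-activity fixed
point.

Numerics: the integrand ``e^{x^2}(1+erf x)`` equals ``erfcx(-x)`` for x <= 0
and ``2 e^{x^2} - erfcx(x)`` for x > 0.  The ``e^{x^2}`` part integrates in
closed form through the Dawson function; the erfcx part uses a precomputed
Chebyshev antiderivative (asymptotic series beyond its range).  For reduced
bounds above ~25 the rate is formed in log space and underflows cleanly to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from scipy import special

from .model_spec import NetworkSpec, NeuronParams

#: correction for synaptic filtering: |zeta(1/2)| / sqrt(2)
GAMMA = float(abs(special.zeta(0.5)) / np.sqrt(2.0))

_SQRT_PI = float(np.sqrt(np.pi))
_LOG_BRANCH = 25.0  # reduced-bound threshold for the log-space branch
_CHEB_MAX = 30.0


def _build_erfcx_antiderivative():
    interp = _cheb.Chebyshev.interpolate(special.erfcx, deg=320, domain=[0.0, _CHEB_MAX])
    return interp.integ(lbnd=0.0).trim(1e-17)


_F_CHEB = _build_erfcx_antiderivative()
_F_CHEB_END = float(_F_CHEB(_CHEB_MAX))


def _erfcx_antideriv(x: np.ndarray) -> np.ndarray:
    """F(x) = Integral_0^x erfcx(t) dt for x >= 0 (vectorized)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x <= _CHEB_MAX
    out[small] = _F_CHEB(x[small])
    if np.any(~small):
        t = x[~small]

        def asy(u):
            u2 = u * u
            return (
                np.log(u)
                + 0.25 / u2
                - 3.0 / (16.0 * u2 * u2)
                + 5.0 / (16.0 * u2 * u2 * u2)
                - 105.0 / (128.0 * u2 * u2 * u2 * u2)
            ) / _SQRT_PI

        out[~small] = _F_CHEB_END + asy(t) - asy(_CHEB_MAX)
    return out


def _siegert_from_bounds(a: np.ndarray, b: np.ndarray, tau_m: float, tau_r: float) -> np.ndarray:
    """Rate (1/s) from reduced bounds a < b; tau in seconds."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    out = np.empty(np.broadcast(a, b).shape)
    a, b = np.broadcast_arrays(a, b)

    big = b > _LOG_BRANCH
    # --- regular branch ---------------------------------------------------
    ar, br = a[~big], b[~big]
    # negative segment [a, min(b, 0)]: integrand erfcx(-x)
    i_neg = _erfcx_antideriv(np.maximum(-ar, 0.0)) - _erfcx_antideriv(np.maximum(-br, 0.0))
    # positive segment [max(a,0), b]: 2 e^{x^2} - erfcx(x)
    a0 = np.maximum(ar, 0.0)
    b0 = np.maximum(br, 0.0)
    i_exp = 2.0 * (
        np.exp(b0 * b0) * special.dawsn(b0) - np.exp(a0 * a0) * special.dawsn(a0)
    )
    i_pos = i_exp - (_erfcx_antideriv(b0) - _erfcx_antideriv(a0))
    out[~big] = 1.0 / (tau_r + tau_m * _SQRT_PI * (i_neg + i_pos))

    # --- log-space branch (strongly subthreshold) ---------------------------
    if np.any(big):
        ab, bb = a[big], b[big]
        a0 = np.maximum(ab, 0.0)
        scaled = 2.0 * (
            special.dawsn(bb) - np.exp(a0 * a0 - bb * bb) * special.dawsn(a0)
        )
        with np.errstate(divide="ignore"):
            log_nu = -(bb * bb) - np.log(tau_m * _SQRT_PI * scaled)
        out[big] = np.exp(log_nu)
    return out


def siegert_rate(
    mu: np.ndarray | float, sigma: np.ndarray | float, p: NeuronParams | None = None
) -> np.ndarray | float:
    """Stationary firing rate (spikes/s) of an LIF neuron under Gaussian input.

    ``mu`` (mV) and ``sigma`` (mV) are measured relative to the leak
    potential.  For ``sigma == 0`` the deterministic (noise-free) limit is
    returned: zero below threshold, otherwise the exact LIF period.
    """
    if p is None:
        p = NeuronParams()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    scalar = mu.ndim == 0 and sigma.ndim == 0
    mu, sigma = np.atleast_1d(mu), np.atleast_1d(sigma)
    mu, sigma = np.broadcast_arrays(mu, sigma)

    tau_m, tau_r = p.tau_m * 1e-3, p.tau_r * 1e-3
    v_r = p.V_r - p.E_L
    v_th = p.theta - p.E_L
    shift = GAMMA * np.sqrt(p.tau_s / p.tau_m)

    out = np.zeros(mu.shape)
    pos = sigma > 0
    if np.any(pos):
        aa = (v_r - mu[pos]) / sigma[pos] + shift
        bb = (v_th - mu[pos]) / sigma[pos] + shift
        out[pos] = _siegert_from_bounds(aa, bb, tau_m, tau_r)
    if np.any(~pos):
        m = mu[~pos]
        det = np.zeros(m.shape)
        above = m > v_th
        det[above] = 1.0 / (
            tau_r + tau_m * np.log((m[above] - v_r) / (m[above] - v_th))
        )
        out[~pos] = det
    return float(out[0]) if scalar else out


def _siegert_derivatives(
    mu: np.ndarray, sigma: np.ndarray, p: NeuronParams
) -> tuple[np.ndarray, np.ndarray]:
    """(dPhi/dmu, dPhi/dsigma^2) of the Siegert rate, elementwise.

    Uses d(1/nu)/dtheta = tau_m sqrt(pi) * d/dtheta Integral, with the
    integrand f(y) = e^{y^2}(1+erf y) evaluated at the shifted bounds.  Rows
    whose rate underflows to zero have zero slope.
    """
    mu = np.atleast_1d(np.asarray(mu, float))
    sigma = np.atleast_1d(np.asarray(sigma, float))
    tau_m = p.tau_m * 1e-3
    v_r = p.V_r - p.E_L
    v_th = p.theta - p.E_L
    shift = GAMMA * np.sqrt(p.tau_s / p.tau_m)

    nu = np.atleast_1d(siegert_rate(mu, sigma, p))
    a = (v_r - mu) / sigma + shift
    b = (v_th - mu) / sigma + shift

    def f(y):
        y = np.asarray(y, float)
        out = np.empty_like(y)
        neg = y <= 0
        out[neg] = special.erfcx(-y[neg])
        yp = np.minimum(y[~neg], _LOG_BRANCH + 10.0)  # guarded; paired with nu ~ 0
        out[~neg] = 2.0 * np.exp(np.minimum(yp * yp, 700.0)) - special.erfcx(yp)
        return out

    fb, fa = f(b), f(a)
    with np.errstate(over="ignore", invalid="ignore"):
        dmu = nu * nu * tau_m * _SQRT_PI * (fb - fa) / sigma
        dsig2 = (
            nu
            * nu
            * tau_m
            * _SQRT_PI
            / (2.0 * sigma**3)
            * (fb * (v_th - mu) - fa * (v_r - mu))
        )
    dmu = np.where(np.isfinite(dmu) & (nu > 0), dmu, 0.0)
    dsig2 = np.where(np.isfinite(dsig2) & (nu > 0), dsig2, 0.0)
    return dmu, dsig2


# ---------------------------------------------------------------------------
# network-level input and transfer
# ---------------------------------------------------------------------------


@dataclass
class MFInput:
    """Per-population mean input mu (mV) and variance sigma2 (mV^2)."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sigma2 < 0):
            raise ValueError("input variance must be non-negative")


def weight_matrix_mv(spec: NetworkSpec) -> tuple[np.ndarray, float]:
    """Effective weights (mV per spike): J_hat = tau_s J / C_m."""
    p = spec.neuron_params
    factor = p.tau_s / p.C_m
    return spec.conn.J_mean * factor, spec.conn.J_ext * factor


def network_input(nu: np.ndarray, spec: NetworkSpec) -> MFInput:
    """Mean and variance of the input to each population at rates ``nu``.

    ``nu`` may be a vector (n_pop,) or a batch (m, n_pop); output matches.
    """
    nu = np.asarray(nu, dtype=float)
    n = len(spec.grid)
    if nu.shape[-1] != n:
        raise ValueError("rate vector length must equal the number of populations")
    J, J_ext = weight_matrix_mv(spec)
    K = spec.conn.K
    tau_m = spec.neuron_params.tau_m * 1e-3
    ext = spec.conn.k_ext * spec.conn.nu_bg
    mu = tau_m * (nu @ (K * J).T + ext * J_ext)
    sigma2 = tau_m * (nu @ (K * J * J).T + ext * J_ext * J_ext)
    return MFInput(mu, sigma2)


def transfer(nu: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Phi(nu): population rates implied by the input at rates ``nu``."""
    mf = network_input(nu, spec)
    return siegert_rate(mf.mu, np.sqrt(mf.sigma2), spec.neuron_params)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------


@dataclass
class FixedPointReport:
    """One stationary rate vector with its stability diagnostics."""

    rates: np.ndarray  # spikes/s
    residual: float  # max |Phi(nu*) - nu*|
    converged: bool
    label: str = ""  # "LA" or "HA" (set when two or more fixed points exist)
    basin_count: int = 0  # number of initial conditions that led here
    eigenvalues: np.ndarray | None = None
    max_eig_real: float | None = None
    critical_eigenvector: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))


DEDUP_RTOL = 1e-3  # relative L-infinity dedup radius for distinct fixed points


def _pseudo_time_integrate(
    nu0: np.ndarray,
    spec: NetworkSpec,
    tol: float,
    h: float,
    max_steps: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential Euler on dnu/ds = Phi(nu) - nu for a batch of initial states.

    Returns (final rates, final residuals, converged flags).  Converged rows
    are frozen early to keep large batches cheap.
    """
    nu = np.array(nu0, dtype=float, copy=True)
    if nu.ndim == 1:
        nu = nu[None, :]
    m = nu.shape[0]
    decay = np.exp(-h)
    resid = np.full(m, np.inf)
    active = np.arange(m)
    for _ in range(max_steps):
        phi = np.atleast_2d(transfer(nu[active], spec))
        r = np.max(np.abs(phi - nu[active]), axis=1)
        resid[active] = r
        nu[active] = phi + (nu[active] - phi) * decay
        # the max-norm residual is not strictly monotone along the flow, so
        # freeze a row only once it is comfortably below the tolerance
        keep = r >= 0.05 * tol
        active = active[keep]
        if active.size == 0:
            break
    # final residual at the (already advanced) state
    done = resid < tol
    if np.any(done):
        phi = np.atleast_2d(transfer(nu[done], spec))
        resid[done] = np.max(np.abs(phi - nu[done]), axis=1)
    return nu, resid, resid < tol


def _cluster_rates(points: np.ndarray, rtol: float = DEDUP_RTOL) -> tuple[np.ndarray, np.ndarray]:
    """Greedy dedup of rate vectors by relative L-infinity distance."""
    reps: list[np.ndarray] = []
    assign = np.empty(points.shape[0], dtype=int)
    for i, x in enumerate(points):
        placed = False
        for ci, r in enumerate(reps):
            scale = max(1.0, float(np.max(np.abs(r))), float(np.max(np.abs(x))))
            if np.max(np.abs(x - r)) / scale < rtol:
                assign[i] = ci
                placed = True
                break
        if not placed:
            reps.append(x)
            assign[i] = len(reps) - 1
    return np.array(reps), assign


def find_fixed_points(
    spec: NetworkSpec,
    initial_conditions: np.ndarray | None = None,
    tol: float = 1e-9,
    h: float = 0.1,
    max_steps: int = 20000,
    compute_stability: bool = True,
) -> list[FixedPointReport]:
    """Locate stationary rate vectors by pseudo-time integration.

    ``initial_conditions`` is an (m, n_pop) array of non-negative rates
    (default: zeros plus a 200 spikes/s vector, probing both the low- and the
    high-activity basin).  Distinct fixed points are deduplicated by relative
    L-infinity distance; non-converged runs are reported (``converged=False``)
    rather than dropped.  When at least two fixed points are found, the one
    with the smallest mean rate is labeled "LA" and the one with the largest
    "HA".
    """
    n = len(spec.grid)
    if initial_conditions is None:
        initial_conditions = np.vstack([np.zeros(n), np.full(n, 200.0)])
    ics = np.atleast_2d(np.asarray(initial_conditions, dtype=float))
    if np.any(ics < 0):
        raise ValueError("initial rates must be non-negative")
    finals, resid, conv = _pseudo_time_integrate(ics, spec, tol, h, max_steps)

    reports: list[FixedPointReport] = []
    if np.any(conv):
        reps, assign = _cluster_rates(finals[conv])
        counts = np.bincount(assign, minlength=len(reps))
        for ci, rep in enumerate(reps):
            members = np.flatnonzero(conv)[assign == ci]
            best = members[np.argmin(resid[members])]
            rpt = FixedPointReport(
                rates=finals[best],
                residual=float(resid[best]),
                converged=True,
                basin_count=int(counts[ci]),
            )
            if compute_stability:
                G, eig = effective_connectivity(spec, rpt.rates, tol=max(tol * 10, 1e-6))
                rpt.eigenvalues = eig
                rpt.max_eig_real = float(np.max(eig.real))
                rpt.critical_eigenvector = _critical_eigenvector(G, eig)
            reports.append(rpt)
    for i in np.flatnonzero(~conv):
        reports.append(
            FixedPointReport(
                rates=finals[i],
                residual=float(resid[i]),
                converged=False,
                warnings=["pseudo-time integration did not converge"],
            )
        )
    converged_reports = [r for r in reports if r.converged]
    if len(converged_reports) >= 2:
        by_rate = sorted(converged_reports, key=lambda r: r.mean_rate)
        by_rate[0].label = "LA"
        by_rate[-1].label = "HA"
    elif len(converged_reports) == 1:
        converged_reports[0].label = "LA"
    reports.sort(key=lambda r: (not r.converged, r.mean_rate))
    return reports


def _critical_eigenvector(G: np.ndarray, eig: np.ndarray) -> np.ndarray:
    _, vecs = np.linalg.eig(G)
    idx = int(np.argmax(eig.real))
    v = vecs[:, idx]
    return np.abs(v) / np.linalg.norm(v)


def effective_connectivity(
    spec: NetworkSpec, nu_star: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian G of Phi at ``nu_star`` and its eigenvalues.

    G_ij = dPhi_i/dmu_i * dmu_i/dnu_j + dPhi_i/dsigma_i^2 * dsigma_i^2/dnu_j
    with dmu_i/dnu_j = tau_m K_ij J_hat_ij and
    dsigma_i^2/dnu_j = tau_m K_ij J_hat_ij^2.  A perturbation around a fixed
    point decays iff max Re(eigenvalues) < 1.  If ``nu_star`` is not a fixed
    point within ``tol`` a warning is emitted.
    """
    nu_star = np.asarray(nu_star, dtype=float)
    resid = float(np.max(np.abs(transfer(nu_star, spec) - nu_star)))
    if resid > tol:
        warnings.warn(
            f"effective_connectivity evaluated away from a fixed point "
            f"(residual {resid:.3g} > tol {tol:.3g})",
            stacklevel=2,
        )
    mf = network_input(nu_star, spec)
    sigma = np.sqrt(mf.sigma2)
    dmu, dsig2 = _siegert_derivatives(mf.mu, sigma, spec.neuron_params)
    J, _ = weight_matrix_mv(spec)
    K = spec.conn.K
    tau_m = spec.neuron_params.tau_m * 1e-3
    G = dmu[:, None] * (tau_m * K * J) + dsig2[:, None] * (tau_m * K * J * J)
    eig = np.linalg.eigvals(G)
    return G, eig


def global_stability(
    spec: NetworkSpec,
    n_init: int = 1000,
    seed: int = 0,
    rate_max: float = 200.0,
    tol: float = 1e-7,
    h: float = 0.1,
    max_steps: int = 20000,
) -> tuple[float, list[FixedPointReport]]:
    """Fraction of random initial conditions converging to the LA fixed point.

    Initial rates are i.i.d. uniform on [0, rate_max] per population,
    seed-controlled.  Returns (fraction, fixed-point reports with basin
    counts).  Raises if no converged fixed point is found.
    """
    rng = np.random.default_rng(seed)
    n = len(spec.grid)
    ics = rng.uniform(0.0, rate_max, size=(n_init, n))
    reports = find_fixed_points(
        spec, ics, tol=tol, h=h, max_steps=max_steps, compute_stability=False
    )
    converged = [r for r in reports if r.converged]
    if not converged:
        raise RuntimeError("global stability undefined: no converged fixed point")
    la = min(converged, key=lambda r: r.mean_rate)
    n_conv = sum(r.basin_count for r in converged)
    if n_conv < n_init:
        warnings.warn(
            f"{n_init - n_conv} of {n_init} initial conditions did not converge",
            stacklevel=2,
        )
    return la.basin_count / n_init, reports
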