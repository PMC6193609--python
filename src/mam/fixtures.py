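"""Seeded fixtures: toy bistable networks, downscaled multi-area specs,
planted-lag rate series, planted VAR processes, and planted-partition FC
matrices.

Every fixture is reproducible bit-exactly from (recipe, seed).  The toy
bistable network is verified at generation time to possess the requested
number of mean-field fixed points; the small multi-area fixture applies all
structural rules of the full construction (laminar populations, the kappa
external-drive rule, cortico-cortical chi scaling) at population sizes of
order 10^2-10^3.  Downscaling preserves indegrees, not connection
probabilities, and optionally applies a variance-compensating weight rescale
(J ~ 1/sqrt(indegree scale)); the distortion introduced by downscaling is
thereby an explicit knob rather than a hidden consequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import meanfield
from .model_spec import (
    ConnectivityModel,
    NetworkSpec,
    NeuronParams,
    Population,
    PopulationGrid,
    SynthParams,
    psp_to_psc,
    synth_connectome,
)


@dataclass(frozen=True)
class FixtureRecipe:
    """Declarative fixture request: kind, parameters, seed."""

    kind: str  # toy_bistable | small_multiarea | planted_lags | planted_var | planted_blocks
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class Fixture:
    """Generated artifact with its documented ground truth."""

    kind: str
    data: Any
    truth: dict
    seed: int


class BistabilityError(RuntimeError):
    """Raised when a requested attractor structure is not achieved."""


# ---------------------------------------------------------------------------
# toy bistable E-I network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyBistableParams:
    """Two-population E-I network with a bistable mean-field landscape.

    Strong recurrent excitation creates a high-activity attractor pinned by
    the refractory saturation of the transfer function; a moderate external
    drive keeps a low-activity attractor.  ``excitation_scale`` multiplies the
    recurrent E-to-E weight (the knob that erodes the low-activity basin).
    """

    n_e: int = 400
    n_i: int = 100
    k_ee: float = 240.0
    k_ei: float = 35.0  # E <- I
    k_ie: float = 190.0  # I <- E
    k_ii: float = 30.0
    g: float = 5.0
    k_ext_e: float = 640.0
    k_ext_i: float = 580.0
    nu_bg: float = 10.0
    psp_peak: float = 0.15  # mV
    excitation_scale: float = 1.0
    d_e: float = 1.5  # ms
    d_i: float = 0.75


def _toy_spec(tp: ToyBistableParams, seed: int) -> NetworkSpec:
    p = NeuronParams()
    grid = PopulationGrid(
        [Population("TOY", "23", "E"), Population("TOY", "23", "I")], [tp.n_e, tp.n_i]
    )
    J = psp_to_psc(tp.psp_peak, p)
    K = np.array([[tp.k_ee, tp.k_ei], [tp.k_ie, tp.k_ii]])
    Jm = np.array(
        [
            [J * tp.excitation_scale, -tp.g * J],
            [J, -tp.g * J],
        ]
    )
    d = np.array([[tp.d_e, tp.d_i], [tp.d_e, tp.d_i]])
    conn = ConnectivityModel(
        K=K,
        J_mean=Jm,
        d_mean=d,
        k_ext=np.array([tp.k_ext_e, tp.k_ext_i], dtype=float),
        nu_bg=tp.nu_bg,
        J_ext=J,
        g=tp.g,
    )
    return NetworkSpec(p, grid, conn, seed=seed)


def make_toy_bistable(
    params: ToyBistableParams | None = None,
    seed: int = 0,
    variant: str = "bistable",
    verify: bool = True,
) -> NetworkSpec:
    """Toy E-I network whose mean-field map has two fixed points.

    ``variant="inhibition_dominated"`` strengthens inhibition so that only the
    low-activity fixed point survives.  The attractor count is verified at
    generation time from a grid of initial conditions (raise:
    :class:`BistabilityError`).
    """
    if params is None:
        params = ToyBistableParams()
    if variant == "inhibition_dominated":
        params = replace(params, k_ei=4.0 * params.k_ei, g=11.0, excitation_scale=0.8)
    elif variant != "bistable":
        raise ValueError(f"unknown variant {variant!r}")
    spec = _toy_spec(params, seed)
    if verify:
        n_fp = len(_verified_fixed_points(spec))
        want = 1 if variant == "inhibition_dominated" else 2
        if n_fp != want:
            raise BistabilityError(
                f"variant {variant!r} produced {n_fp} fixed points, expected {want}"
            )
    return spec


def make_balanced_ei(n_e: int = 1600, n_i: int = 400, seed: int = 0) -> NetworkSpec:
    """Monostable balanced E-I network safe for mean-field comparison.

    Weights are the unscaled intra-areal values (small relative to threshold),
    so the diffusion approximation holds tightly and 10 s simulated rates
    match the Siegert fixed point within a few percent.
    """
    tp = ToyBistableParams(
        n_e=n_e,
        n_i=n_i,
        k_ee=300.0,
        k_ei=120.0,
        k_ie=250.0,
        k_ii=100.0,
        g=5.0,
        k_ext_e=800.0,
        k_ext_i=760.0,
    )
    return _toy_spec(tp, seed)


def _verified_fixed_points(spec: NetworkSpec):
    grid_1d = np.array([0.0, 20.0, 60.0, 150.0, 300.0, 480.0])
    ics = np.array([[a, b] for a in grid_1d for b in grid_1d])
    reports = meanfield.find_fixed_points(spec, ics, tol=1e-9, compute_stability=False)
    return [r for r in reports if r.converged]


# ---------------------------------------------------------------------------
# downscaled multi-area network
# ---------------------------------------------------------------------------


def make_small_multiarea(
    n_areas: int = 4,
    scale: float = 0.005,
    indegree_scale: float = 0.05,
    chi: float = 1.0,
    chi_I: float | None = None,
    seed: int = 0,
    **overrides,
) -> NetworkSpec:
    """Downscaled multi-area network with all structural rules applied.

    ``scale`` multiplies population sizes (target: order 10^2-10^3 neurons per
    population); ``indegree_scale`` multiplies all indegrees with the
    variance-compensating weight rescale enabled.  Cortico-cortical weights
    are scaled by ``chi`` (onto inhibitory targets by ``chi_I * chi``).
    Warns if a nonempty population ends up with fewer than 10 neurons.
    """
    if not 2 <= n_areas <= 8:
        raise ValueError("n_areas must lie in [2, 8]")
    params = SynthParams(
        size_scale=scale,
        indegree_scale=indegree_scale,
        compensate_weights=True,
        chi=chi,
        chi_I=chi_I,
        **overrides,
    )
    spec = synth_connectome(n_areas, params, seed=seed)
    sizes = spec.grid.sizes
    if np.any((sizes > 0) & (sizes < 10)):
        warnings.warn("downscaling produced populations with fewer than 10 neurons",
                      stacklevel=2)
    return spec


# ---------------------------------------------------------------------------
# planted analysis fixtures
# ---------------------------------------------------------------------------


def _planted_lags(params: dict, seed: int) -> Fixture:
    shifts = params.get("shifts_ms", {"A": 0.0, "B": 5.0, "C": 12.0, "D": 7.0})
    duration = int(params.get("duration_ms", 20000))
    noise_sd = float(params.get("noise_sd", 0.1))
    smooth = float(params.get("signal_smooth_ms", 10.0))
    rng = np.random.default_rng(seed)
    pad = int(max(abs(s) for s in shifts.values())) + 1
    base = gaussian_filter1d(rng.standard_normal(duration + 2 * pad), smooth)
    base = (base - base.min()) / base.std()
    data = {}
    for name, s in shifts.items():
        k = int(np.rint(s))
        sig = base[pad + k : pad + k + duration]
        data[name] = np.clip(sig + noise_sd * rng.standard_normal(duration), 0.0, None)
    return Fixture("planted_lags", data, {"shifts_ms": dict(shifts)}, seed)


def _planted_var(params: dict, seed: int) -> Fixture:
    n = int(params.get("n_series", 2))
    T = int(params.get("T", 50000))
    order = int(params.get("order", 2))
    coef = float(params.get("coupling", 0.5))
    rng = np.random.default_rng(seed)
    A = np.zeros((order, n, n))
    A[0] += np.eye(n) * 0.4
    if order > 1:
        A[1] += np.eye(n) * 0.2
    # planted directed edge x0 -> x1
    A[0, 1, 0] = coef
    comp = np.zeros((n * order, n * order))
    for k in range(order):
        comp[:n, k * n : (k + 1) * n] = A[k]
    if order > 1:
        comp[n:, :-n] = np.eye(n * (order - 1))
    rad = np.max(np.abs(np.linalg.eigvals(comp)))
    if rad >= 1.0:
        raise ValueError(f"planted VAR is unstable (spectral radius {rad:.3f})")
    x = np.zeros((n, T + 200))
    eps = rng.standard_normal((n, T + 200))
    for t in range(order, T + 200):
        acc = eps[:, t].copy()
        for k in range(order):
            acc += A[k] @ x[:, t - 1 - k]
        x[:, t] = acc
    edges = np.zeros((n, n), dtype=bool)
    edges[1, 0] = True  # target row, source column
    return Fixture(
        "planted_var",
        x[:, 200:],
        {"coefficients": A, "edges": edges, "spectral_radius": float(rad)},
        seed,
    )


def _planted_blocks(params: dict, seed: int) -> Fixture:
    sizes = list(params.get("block_sizes", [6, 5, 5]))
    w_in = float(params.get("within", 0.8))
    w_out = float(params.get("between", -0.4))
    noise = float(params.get("noise_sd", 0.1))
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    w = np.where(labels[:, None] == labels[None, :], w_in, w_out).astype(float)
    e = noise * rng.standard_normal((n, n))
    w = w + 0.5 * (e + e.T)
    np.fill_diagonal(w, 1.0)
    w = np.clip(w, -1.0, 1.0)
    return Fixture("planted_blocks", w, {"labels": labels}, seed)


def make_planted_series(kind: str, params: dict | None = None, seed: int = 0) -> Fixture:
    """Planted-ground-truth fixtures for the analysis modules."""
    params = params or {}
    makers = {
        "planted_lags": _planted_lags,
        "planted_var": _planted_var,
        "planted_blocks": _planted_blocks,
    }
    if kind not in makers:
        raise ValueError(f"unknown planted fixture kind {kind!r}")
    return makers[kind](params, seed)


def make_fixture(recipe: FixtureRecipe):
    """Dispatch a declarative fixture recipe."""
    if recipe.kind == "toy_bistable":
        return make_toy_bistable(seed=recipe.seed, **recipe.params)
    if recipe.kind == "small_multiarea":
        return make_small_multiarea(seed=recipe.seed, **recipe.params)
    return make_planted_series(recipe.kind, recipe.params, recipe.seed)
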