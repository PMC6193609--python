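"""Network specifications: population sizes, indegrees, weights, delays, drives.

A :class:`NetworkSpec` is the complete blueprint of one model instance.  Areas
are laminar cortical patches (default 1 mm^2) with an excitatory and an
inhibitory population per layer (2/3, 4, 5, 6); areas of the lowest
architectural type lack layer 4.  Connectivity is population-specific but
otherwise random: the spec stores population-level indegrees ``K`` (synapses
per target neuron), weight statistics (pA), delay statistics (ms) and the
external Poisson drive per population.

The construction rules implemented here follow the multi-area construction
principles: population sizes as density x thickness x patch area, local
indegrees as a ratio-preserving rescaling of a reference laminar microcircuit,
uniform external indegrees per area with a selective boost of the deep
excitatory populations (the kappa rule), cortico-cortical weight scaling
(chi, chi_I), and linear distance-dependent delays.  A seeded synthetic
connectome generator emulates the large-scale regularities (architectural-type
gradient of densities, exponential distance rule, laminar feedforward/feedback
source and target patterns) so that no anatomical database is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from scipy import integrate, stats

LAYERS = ("23", "4", "5", "6")
CELL_TYPES = ("E", "I")

#: radius (mm) of a disk of area 1 mm^2
PATCH_RADIUS_MM = float(1.0 / np.sqrt(np.pi))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron with exponential postsynaptic currents.

    Defaults are the standard laminar-microcircuit values: tau_m = 10 ms,
    tau_r = 2 ms, tau_s = 0.5 ms, C_m = 250 pF, V_r = -65 mV, theta = -50 mV,
    E_L = -65 mV.
    """

    tau_m: float = 10.0  # membrane time constant (ms)
    tau_r: float = 2.0  # absolute refractory period (ms)
    tau_s: float = 0.5  # PSC time constant (ms)
    C_m: float = 250.0  # membrane capacitance (pF)
    V_r: float = -65.0  # reset potential (mV)
    theta: float = -50.0  # firing threshold (mV)
    E_L: float = -65.0  # leak potential (mV)

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_r", "tau_s", "C_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.theta > self.V_r:
            raise ValueError("firing threshold must exceed the reset potential")


@dataclass(frozen=True)
class AreaSpec:
    """Architectural description of one cortical area.

    ``layer_thicknesses`` (mm), ``neuron_densities`` (neurons/mm^3) and
    ``excitatory_fraction`` are keyed by layer ("23", "4", "5", "6"); a layer
    absent from the maps (or with zero thickness) contributes no populations.
    """

    name: str
    architectural_type: int
    layer_thicknesses: dict[str, float]
    neuron_densities: dict[str, float]
    excitatory_fraction: dict[str, float]
    has_L4: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.architectural_type <= 8:
            raise ValueError("architectural type must lie in 2..8")
        for layer, th in self.layer_thicknesses.items():
            if th < 0:
                raise ValueError(f"negative thickness for layer {layer} in {self.name}")
        for layer, rho in self.neuron_densities.items():
            if rho < 0:
                raise ValueError(f"negative density for layer {layer} in {self.name}")
        for layer, f in self.excitatory_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"excitatory fraction outside [0,1] in {self.name}")

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(l for l in LAYERS if (l != "4" or self.has_L4))

    def mean_density(self) -> float:
        """Thickness-weighted mean neuron density over the present layers."""
        th = np.array([self.layer_thicknesses.get(l, 0.0) for l in self.layers])
        rho = np.array([self.neuron_densities.get(l, 0.0) for l in self.layers])
        total = th.sum()
        if total == 0:
            return 0.0
        return float((th * rho).sum() / total)


@dataclass(frozen=True)
class Population:
    area: str
    layer: str  # "23", "4", "5", "6"
    cell_type: str  # "E" or "I"

    @property
    def label(self) -> str:
        return f"{self.area}-{self.layer}{self.cell_type}"


class PopulationGrid:
    """Ordered list of (area, layer, cell type) populations with sizes.

    Order: areas in input order; within an area layers 2/3, 4, 5, 6; E before
    I.  An area lacking layer 4 contributes 6 populations, otherwise 8.
    """

    def __init__(self, populations: Sequence[Population], sizes: Sequence[int]):
        sizes = np.asarray(sizes, dtype=np.int64)
        if len(populations) != len(sizes):
            raise ValueError("populations and sizes must have equal length")
        if np.any(sizes < 0):
            raise ValueError("population sizes must be non-negative")
        self.populations = list(populations)
        self.sizes = sizes
        self._index = {p.label: i for i, p in enumerate(self.populations)}

    def __len__(self) -> int:
        return len(self.populations)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PopulationGrid)
            and self.populations == other.populations
            and np.array_equal(self.sizes, other.sizes)
        )

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    @property
    def areas(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p.area, None)
        return list(seen)

    def index(self, label: str) -> int:
        return self._index[label]

    def area_indices(self, area: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.populations) if p.area == area])

    def area_of(self) -> np.ndarray:
        """Integer area id per population (input order of areas)."""
        order = {a: i for i, a in enumerate(self.areas)}
        return np.array([order[p.area] for p in self.populations])

    def to_dict(self) -> dict:
        return {
            "populations": [[p.area, p.layer, p.cell_type] for p in self.populations],
            "sizes": self.sizes.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationGrid":
        pops = [Population(*row) for row in d["populations"]]
        return cls(pops, d["sizes"])


@dataclass
class ConnectivityModel:
    """Population-level connectivity statistics.

    ``K[i, j]`` is the mean number of synapses a neuron of target population
    ``i`` receives from source population ``j``.  ``J_mean`` holds signed PSC
    amplitudes in pA (negative for inhibitory sources), ``J_sd = 0.1 |J_mean|``.
    Delays are Gaussian with ``d_sd = 0.5 d_mean``; local inhibitory delays are
    half the excitatory ones.  ``k_ext`` is the external Poisson indegree per
    population at rate ``nu_bg`` and weight ``J_ext``.
    """

    K: np.ndarray
    J_mean: np.ndarray
    d_mean: np.ndarray
    k_ext: np.ndarray
    nu_bg: float = 10.0  # spikes/s per external source
    J_ext: float = 87.8  # pA
    g: float = 11.0  # relative inhibitory strength
    chi: float = 1.0
    chi_I: float = 1.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.J_mean = np.asarray(self.J_mean, dtype=float)
        self.d_mean = np.asarray(self.d_mean, dtype=float)
        self.k_ext = np.asarray(self.k_ext, dtype=float)
        n = self.K.shape[0]
        for name, arr in (("K", self.K), ("J_mean", self.J_mean), ("d_mean", self.d_mean)):
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be square with matching dimension")
        if self.k_ext.shape != (n,):
            raise ValueError("k_ext must be a vector matching the grid length")
        if np.any(self.K < 0):
            raise ValueError("indegrees must be non-negative")
        if np.any(self.d_mean < 0):
            raise ValueError("mean delays must be non-negative")

    @property
    def J_sd(self) -> np.ndarray:
        return 0.1 * np.abs(self.J_mean)

    @property
    def d_sd(self) -> np.ndarray:
        return 0.5 * self.d_mean

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectivityModel):
            return NotImplemented
        scalars = all(
            getattr(self, f) == getattr(other, f)
            for f in ("nu_bg", "J_ext", "g", "chi", "chi_I", "kappa")
        )
        return scalars and all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("K", "J_mean", "d_mean", "k_ext")
        )


@dataclass
class NetworkSpec:
    """Complete blueprint of one model instance."""

    neuron_params: NeuronParams
    grid: PopulationGrid
    conn: ConnectivityModel
    seed: int = 0
    areas: list[AreaSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.grid)
        if self.conn.K.shape != (n, n):
            raise ValueError("connectivity dimensions must equal the grid length")

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkSpec):
            return NotImplemented
        return (
            self.neuron_params == other.neuron_params
            and self.grid == other.grid
            and self.conn == other.conn
            and self.seed == other.seed
            and self.areas == other.areas
        )

    # -- masks -----------------------------------------------------------
    def cc_mask(self) -> np.ndarray:
        """Boolean matrix: True where source and target areas differ."""
        aid = self.grid.area_of()
        return aid[:, None] != aid[None, :]

    def target_is_excitatory(self) -> np.ndarray:
        return np.array([p.cell_type == "E" for p in self.grid.populations])

    def source_is_excitatory(self) -> np.ndarray:
        return self.target_is_excitatory()

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "mam-network-spec",
            "version": 1,
            "seed": self.seed,
            "neuron_params": asdict(self.neuron_params),
            "grid": self.grid.to_dict(),
            "conn": {
                "K": self.conn.K.tolist(),
                "J_mean": self.conn.J_mean.tolist(),
                "d_mean": self.conn.d_mean.tolist(),
                "k_ext": self.conn.k_ext.tolist(),
                "nu_bg": self.conn.nu_bg,
                "J_ext": self.conn.J_ext,
                "g": self.conn.g,
                "chi": self.conn.chi,
                "chi_I": self.conn.chi_I,
                "kappa": self.conn.kappa,
            },
            "areas": [
                {
                    "name": a.name,
                    "architectural_type": a.architectural_type,
                    "layer_thicknesses": a.layer_thicknesses,
                    "neuron_densities": a.neuron_densities,
                    "excitatory_fraction": a.excitatory_fraction,
                    "has_L4": a.has_L4,
                }
                for a in self.areas
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        if d.get("format") != "mam-network-spec":
            raise ValueError("not a network-spec document (missing format tag)")
        conn = ConnectivityModel(
            K=np.array(d["conn"]["K"]),
            J_mean=np.array(d["conn"]["J_mean"]),
            d_mean=np.array(d["conn"]["d_mean"]),
            k_ext=np.array(d["conn"]["k_ext"]),
            nu_bg=d["conn"]["nu_bg"],
            J_ext=d["conn"]["J_ext"],
            g=d["conn"]["g"],
            chi=d["conn"]["chi"],
            chi_I=d["conn"]["chi_I"],
            kappa=d["conn"]["kappa"],
        )
        areas = [AreaSpec(**a) for a in d.get("areas", [])]
        return cls(
            neuron_params=NeuronParams(**d["neuron_params"]),
            grid=PopulationGrid.from_dict(d["grid"]),
            conn=conn,
            seed=d["seed"],
            areas=areas,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# construction operations
# ---------------------------------------------------------------------------


def build_population_grid(areas: Sequence[AreaSpec], patch_area: float = 1.0) -> PopulationGrid:
    """Population sizes as density x thickness x patch area x cell-type fraction.

    Sizes are rounded half-to-even (unbiased over many populations).  Layers
    absent from an area contribute no populations.
    """
    if patch_area <= 0:
        raise ValueError("patch_area must be positive")
    pops: list[Population] = []
    sizes: list[int] = []
    for area in areas:
        for layer in area.layers:
            th = area.layer_thicknesses.get(layer, 0.0)
            rho = area.neuron_densities.get(layer, 0.0)
            fe = area.excitatory_fraction.get(layer, 0.8)
            n_total = rho * th * patch_area
            for ct in CELL_TYPES:
                frac = fe if ct == "E" else 1.0 - fe
                pops.append(Population(area.name, layer, ct))
                sizes.append(int(np.rint(n_total * frac)))
    return PopulationGrid(pops, sizes)


def scale_local_indegrees(
    K_template: np.ndarray,
    area: AreaSpec | None = None,
    *,
    factor: float | None = None,
    template_density: float | None = None,
    target_total_indegree: float | None = None,
) -> np.ndarray:
    """Rescale a reference microcircuit indegree block to one area.

    All pairwise indegree ratios of the returned block equal those of the
    template: the block is ``factor * K_template`` for a single area-specific
    conversion factor.  The default budget rule takes
    ``factor = template_density / area_density`` (constant synaptic volume:
    indegree inversely proportional to neuron density); alternatively the
    factor may be given directly or derived from a requested mean total
    indegree per target neuron.
    """
    K_template = np.asarray(K_template, dtype=float)
    if np.any(K_template < 0):
        raise ValueError("template indegrees must be non-negative")
    if factor is None:
        if target_total_indegree is not None:
            template_total = K_template.sum(axis=1).mean()
            if template_total == 0:
                if target_total_indegree > 0:
                    raise ValueError(
                        "requested a nonzero synapse budget for an all-zero template"
                    )
                factor = 0.0
            else:
                factor = target_total_indegree / template_total
        elif area is not None and template_density is not None:
            rho = area.mean_density()
            if rho <= 0:
                raise ValueError("area density must be positive for the budget rule")
            factor = template_density / rho
        else:
            raise ValueError(
                "provide factor, target_total_indegree, or area with template_density"
            )
    if factor < 0:
        raise ValueError("conversion factor must be non-negative")
    return factor * K_template


def kappa_ratio_6e(kappa: float) -> float:
    """External-indegree ratio K_6E,ext / K_ext under the kappa rule.

    The 5E drive is multiplied by kappa directly; the 6E drive increases
    linearly in kappa, anchored at (1, 1) and (1.15, 1.5), i.e. with slope
    10/3.
    """
    if kappa < 1:
        raise ValueError("kappa rule is undefined below the baseline kappa = 1")
    return 1.0 + (10.0 / 3.0) * (kappa - 1.0)


def external_indegrees(
    total_external: float,
    sizes: Sequence[int],
    populations: Sequence[tuple[str, str]],
    kappa: float = 1.0,
    has_L4: bool = True,
) -> np.ndarray:
    """Distribute an area's external-synapse budget over its populations.

    Baseline: all neurons of the area receive the same external indegree
    ``total_external / sum(sizes)``.  The drive onto 5E is multiplied by
    ``kappa`` and onto 6E by ``1 + (10/3)(kappa - 1)``; in areas lacking layer
    4, the 2/3E and 5E drives are additionally increased by 20% to compensate
    for the missing granular input.

    ``populations`` lists (layer, cell_type) tuples in grid order.
    """
    if kappa < 1:
        raise ValueError("kappa rule is undefined below the baseline kappa = 1")
    sizes = np.asarray(sizes, dtype=float)
    n_total = sizes.sum()
    baseline = total_external / n_total if n_total > 0 else 0.0
    k_ext = np.full(len(populations), baseline, dtype=float)
    for i, (layer, ct) in enumerate(populations):
        if ct != "E":
            continue
        if layer == "5":
            k_ext[i] *= kappa
        elif layer == "6":
            k_ext[i] *= kappa_ratio_6e(kappa)
        if not has_L4 and layer in ("23", "5"):
            k_ext[i] *= 1.2
    return k_ext


def psp_to_psc(psp_peak: float, p: NeuronParams | None = None) -> float:
    """PSC amplitude (pA) whose peak voltage deflection equals ``psp_peak`` (mV).

    For an exponential PSC ``I(t) = J exp(-t/tau_s)`` the subthreshold LIF
    response (relative to rest) is

        V(t) = (J / C_m) * tau_m tau_s / (tau_m - tau_s)
               * (exp(-t/tau_m) - exp(-t/tau_s)),

    which peaks at ``t* = ln(tau_m/tau_s) tau_m tau_s / (tau_m - tau_s)``.
    The map is linear in ``psp_peak``.
    """
    if p is None:
        p = NeuronParams()
    if p.tau_m == p.tau_s:
        raise ValueError("degenerate tau_m == tau_s is not supported")
    return psp_peak / psc_to_psp_peak(1.0, p)


def psc_to_psp_peak(J: float, p: NeuronParams | None = None) -> float:
    """Closed-form peak voltage deflection (mV) of a single exponential PSC."""
    if p is None:
        p = NeuronParams()
    if p.tau_m == p.tau_s:
        raise ValueError("degenerate tau_m == tau_s is not supported")
    tm, ts = p.tau_m, p.tau_s
    pref = tm * ts / (tm - ts)
    t_star = np.log(tm / ts) * pref
    return float(J / p.C_m * pref * (np.exp(-t_star / tm) - np.exp(-t_star / ts)))


def apply_cc_scaling(spec: NetworkSpec, chi: float, chi_I: float | None = None) -> NetworkSpec:
    """Scale cortico-cortical weights: onto E targets by chi, onto I by chi_I*chi.

    Local (intra-areal) weights are untouched.  At chi = 1 the inhibitory
    factor is forced to 1 so that cortico-cortical weights equal local ones;
    for chi > 1 the default chi_I = 2 balances the added excitation.
    """
    if chi < 1:
        raise ValueError("chi must be >= 1")
    if chi == 1.0:
        chi_I = 1.0
    elif chi_I is None:
        chi_I = 2.0
    cc = spec.cc_mask()
    exc_t = spec.target_is_excitatory()
    J = spec.conn.J_mean.copy()
    J[cc & exc_t[:, None]] *= chi
    J[cc & ~exc_t[:, None]] *= chi_I * chi
    conn = replace(spec.conn, J_mean=J, chi=chi, chi_I=chi_I)
    return NetworkSpec(spec.neuron_params, spec.grid, conn, spec.seed, spec.areas)


def delay_params(s: float, v_t: float = 3.5) -> tuple[float, float]:
    """Inter-area delay statistics: d = s / v_t (ms), sd = d / 2.

    ``s`` in mm, ``v_t`` in m/s; mm / (m/s) = ms.
    """
    if v_t <= 0:
        raise ValueError("transmission speed must be positive")
    if s < 0:
        raise ValueError("distance must be non-negative")
    d = s / v_t
    return d, d / 2.0


def local_synapse_fraction(
    profile_sd: float,
    patch_radius: float = PATCH_RADIUS_MM,
    outer_radius: float | None = None,
) -> float:
    """Fraction of a patch neuron's intra-areal partners that lie in the patch.

    Connection probability decays with distance as a Gaussian of SD
    ``profile_sd`` (mm).  Sources are uniform in the patch disk, which sits in
    the centre of a larger disk representing the full area (default outer
    radius: 10 x patch radius).  For a source at radius r0, the squared
    distance of a Gaussian-displaced partner from the centre is noncentral
    chi-squared with 2 degrees of freedom, giving the in-disk probability in
    closed form.
    """
    if patch_radius <= 0:
        raise ValueError("patch radius must be positive")
    if outer_radius is None:
        outer_radius = 10.0 * patch_radius
    if outer_radius < patch_radius:
        raise ValueError("outer radius must be at least the patch radius")
    if profile_sd < 0:
        raise ValueError("profile SD must be non-negative")
    if profile_sd == 0:
        return 1.0

    def p_in(r0: np.ndarray, radius: float) -> np.ndarray:
        return stats.ncx2.cdf((radius / profile_sd) ** 2, df=2, nc=(r0 / profile_sd) ** 2)

    def weighted(radius: float) -> float:
        val, _ = integrate.quad(
            lambda r0: p_in(r0, radius) * 2.0 * r0 / patch_radius**2,
            0.0,
            patch_radius,
            limit=200,
        )
        return val

    num = weighted(patch_radius)
    den = weighted(outer_radius)
    if den == 0:
        return 1.0
    return float(num / den)


# ---------------------------------------------------------------------------
# reference laminar microcircuit template
# ---------------------------------------------------------------------------

# Connection probabilities of the standard 8-population laminar microcircuit
# (1 mm^2 of early sensory cortex); rows = targets, cols = sources, order
# 23E 23I 4E 4I 5E 5I 6E 6I.
MICROCIRCUIT_CONN_PROB = np.array(
    [
        [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0000, 0.0076, 0.0000],
        [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0000, 0.0042, 0.0000],
        [0.0077, 0.0059, 0.0497, 0.1350, 0.0067, 0.0003, 0.0453, 0.0000],
        [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0000, 0.1057, 0.0000],
        [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0000],
        [0.0548, 0.0269, 0.0257, 0.0022, 0.0600, 0.3158, 0.0086, 0.0000],
        [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252],
        [0.0364, 0.0010, 0.0034, 0.0005, 0.0277, 0.0080, 0.0658, 0.1443],
    ]
)

# Population sizes of the reference microcircuit (same order).
MICROCIRCUIT_SIZES = np.array([20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948])


def microcircuit_indegrees(
    conn_prob: np.ndarray | None = None, sizes: np.ndarray | None = None
) -> np.ndarray:
    """Indegree template K'_ij = -N_j ln(1 - p_ij) of the reference circuit."""
    if conn_prob is None:
        conn_prob = MICROCIRCUIT_CONN_PROB
    if sizes is None:
        sizes = MICROCIRCUIT_SIZES
    return -np.asarray(sizes, float)[None, :] * np.log1p(-np.asarray(conn_prob, float))


# ---------------------------------------------------------------------------
# synthetic connectome generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic-connectome generator.

    The generator emulates the construction regularities of the macaque
    visual-cortex connectome rather than reproducing published matrices:
    neuron density increases with architectural type while the total synapse
    budget per neuron decreases with it (constant synaptic volume), inter-area
    connection density falls off exponentially with distance, and the
    supragranular-source fraction (SLN) follows a logistic function of the
    architectural-type difference, shaping laminar feedforward/feedback
    patterns.
    """

    patch_area: float = 1.0  # mm^2
    distance_range: tuple[float, float] = (5.0, 60.0)  # mm, uniform sampling
    distance_decay: float = 0.19  # 1/mm, exponential distance rule
    sln_slope: float = 1.0  # logistic slope vs architectural-type difference
    sln_midpoint: float = 0.0
    density_range: tuple[float, float] = (35000.0, 80000.0)  # neurons/mm^3, type 2..8
    base_total_indegree: float = 9500.0  # synapses per neuron at the densest area
    cc_fraction: float = 0.15  # cortico-cortical share of the synapse budget
    ext_fraction: float = 0.35  # external share of the synapse budget
    psp_peak: float = 0.15  # mV, mean PSP of an excitatory synapse
    weight_factor: float = 1.0  # common multiplier on all synaptic weights
    g: float = 11.0
    chi: float = 1.0
    chi_I: float | None = None
    kappa: float = 1.125
    nu_bg: float = 10.0
    v_t: float = 3.5  # m/s
    d_e_local: float = 1.5  # ms
    size_scale: float = 1.0  # multiplies population sizes (downscaling)
    indegree_scale: float = 1.0  # multiplies all indegrees (downscaling)
    compensate_weights: bool = False  # J -> J / sqrt(indegree_scale)


# relative laminar thickness profile (mm) and excitatory fractions
_THICKNESS_PROFILE = {"23": 0.75, "4": 0.35, "5": 0.45, "6": 0.45}
_EXC_FRACTION = {"23": 0.78, "4": 0.80, "5": 0.82, "6": 0.83}
# laminar target patterns of cortico-cortical synapses
_FF_TARGET = {"23": 0.30, "4": 0.50, "5": 0.10, "6": 0.10}
_FB_TARGET = {"23": 0.25, "4": 0.15, "5": 0.30, "6": 0.30}


def _synth_areas(n_areas: int, params: SynthParams) -> list[AreaSpec]:
    types = np.rint(np.linspace(8, 2, n_areas)).astype(int)
    areas = []
    dmin, dmax = params.density_range
    for i, t in enumerate(types):
        has_l4 = bool(t > 2)
        density = dmin + (dmax - dmin) * (t - 2) / 6.0
        layers = [l for l in LAYERS if (l != "4" or has_l4)]
        thick = {l: _THICKNESS_PROFILE[l] for l in layers}
        dens = {l: density * (1.25 if l == "4" else 1.0) for l in layers}
        frac = {l: _EXC_FRACTION[l] for l in layers}
        areas.append(
            AreaSpec(
                name=f"A{i:02d}T{t}",
                architectural_type=int(t),
                layer_thicknesses=thick,
                neuron_densities=dens,
                excitatory_fraction=frac,
                has_L4=has_l4,
            )
        )
    return areas


def synth_connectome(
    n_areas: int, params: SynthParams | None = None, seed: int = 0
) -> NetworkSpec:
    """Generate a seeded synthetic multi-area network specification.

    Deterministic for a fixed seed.  Inter-area indegrees decay exponentially
    with the sampled distances; the supragranular-source fraction follows a
    logistic of the architectural-type difference; neuron densities increase
    and synapse budgets per neuron decrease with architectural type.
    """
    if n_areas < 2:
        raise ValueError("need at least 2 areas")
    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(seed)
    p = NeuronParams()

    areas = _synth_areas(n_areas, params)
    # scaled population sizes
    base_grid = build_population_grid(areas, params.patch_area)
    sizes = np.rint(base_grid.sizes * params.size_scale).astype(np.int64)
    grid = PopulationGrid(base_grid.populations, sizes)
    n = len(grid)

    # pairwise distances (mm), symmetric, seeded
    lo, hi = params.distance_range
    dist = rng.uniform(lo, hi, size=(n_areas, n_areas))
    dist = np.triu(dist, 1)
    dist = dist + dist.T

    densities = np.array([a.mean_density() for a in areas])
    rho_ref = densities.max()
    # constant synaptic volume: budget per neuron ~ 1/density
    total_budget = params.base_total_indegree * rho_ref / densities

    K = np.zeros((n, n))
    K_template = microcircuit_indegrees()
    tpl_labels = [f"{l}{ct}" for l in LAYERS for ct in CELL_TYPES]

    # local blocks: ratio-preserving rescale of the reference microcircuit
    local_budget = (1.0 - params.cc_fraction - params.ext_fraction) * total_budget
    for ai, area in enumerate(areas):
        idx = grid.area_indices(area.name)
        pop_keys = [f"{grid.populations[i].layer}{grid.populations[i].cell_type}" for i in idx]
        rows = [tpl_labels.index(k) for k in pop_keys]
        block_tpl = K_template[np.ix_(rows, rows)]
        block = scale_local_indegrees(block_tpl, target_total_indegree=local_budget[ai])
        K[np.ix_(idx, idx)] = block

    # cortico-cortical blocks: exponential distance rule + SLN laminar patterns
    types = np.array([a.architectural_type for a in areas], dtype=float)
    for ti, tgt in enumerate(areas):
        w = np.exp(-params.distance_decay * dist[ti])
        w[ti] = 0.0
        wsum = w.sum()
        if wsum == 0:
            continue
        cc_budget = params.cc_fraction * total_budget[ti]
        tidx = grid.area_indices(tgt.name)
        for si, src in enumerate(areas):
            if si == ti or w[si] == 0.0:
                continue
            budget_as = cc_budget * w[si] / wsum
            sln = 1.0 / (
                1.0
                + np.exp(
                    -params.sln_slope * (types[si] - types[ti] - params.sln_midpoint)
                )
            )
            # source populations: 2/3E supragranular, 5E/6E infragranular
            src_frac = {"23E": sln, "5E": (1.0 - sln) / 2.0, "6E": (1.0 - sln) / 2.0}
            # target laminar pattern blends feedforward and feedback motifs
            tgt_frac = {
                l: sln * _FF_TARGET[l] + (1.0 - sln) * _FB_TARGET[l] for l in LAYERS
            }
            present = [l for l in LAYERS if (l != "4" or tgt.has_L4)]
            norm = sum(tgt_frac[l] for l in present)
            sidx = grid.area_indices(src.name)
            for i in tidx:
                pop_i = grid.populations[i]
                f_l = tgt_frac[pop_i.layer] / norm
                for j in sidx:
                    pop_j = grid.populations[j]
                    key = f"{pop_j.layer}{pop_j.cell_type}"
                    if key not in src_frac or not src.has_L4 and key == "4E":
                        continue
                    # same indegree for E and I neurons within a target layer
                    K[i, j] = budget_as * f_l * src_frac[key]

    # external completion: budget minus realized local + cc synapses
    k_ext = np.zeros(n)
    for ai, area in enumerate(areas):
        idx = grid.area_indices(area.name)
        used = K[idx].sum(axis=1)
        total_ext = float(
            np.maximum(total_budget[ai] - used, 0.0) @ sizes[idx].astype(float)
        )
        pops = [(grid.populations[i].layer, grid.populations[i].cell_type) for i in idx]
        k_ext[idx] = external_indegrees(
            total_ext, sizes[idx], pops, kappa=params.kappa, has_L4=area.has_L4
        )

    # downscaling of indegrees with optional variance-compensating weights
    K *= params.indegree_scale
    k_ext *= params.indegree_scale

    # weights
    J_unit = psp_to_psc(params.psp_peak, p) * params.weight_factor
    if params.compensate_weights and params.indegree_scale != 1.0:
        J_unit /= np.sqrt(params.indegree_scale)
    src_exc = np.array([pop.cell_type == "E" for pop in grid.populations])
    J = np.where(
        np.broadcast_to(src_exc[None, :], (n, n)), J_unit, -params.g * J_unit
    ).astype(float)
    # the 4E -> 2/3E projection is doubled within each area
    for area in areas:
        if not area.has_L4:
            continue
        i = grid.index(f"{area.name}-23E")
        j = grid.index(f"{area.name}-4E")
        J[i, j] *= 2.0

    # delays: local fixed means (inhibitory half), inter-area distance-based
    d = np.zeros((n, n))
    aid = grid.area_of()
    local = aid[:, None] == aid[None, :]
    d[local & src_exc[None, :]] = params.d_e_local
    d[local & ~src_exc[None, :]] = params.d_e_local / 2.0
    for ti in range(n_areas):
        for si in range(n_areas):
            if si == ti:
                continue
            dm, _ = delay_params(dist[ti, si], params.v_t)
            d[np.ix_(np.flatnonzero(aid == ti), np.flatnonzero(aid == si))] = dm

    conn = ConnectivityModel(
        K=K,
        J_mean=J,
        d_mean=d,
        k_ext=k_ext,
        nu_bg=params.nu_bg,
        J_ext=J_unit,
        g=params.g,
        kappa=params.kappa,
    )
    spec = NetworkSpec(p, grid, conn, seed=seed, areas=areas)
    if params.chi != 1.0 or params.chi_I is not None:
        spec = apply_cc_scaling(spec, params.chi, params.chi_I)
    return spec
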