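"""Population-level causal and structural interaction analysis.

Conditional Granger causality on 1 ms population rate series: for each target
population a vector-autoregressive (VAR) model with a maximal lag of 25 ms is
fitted by ordinary least squares twice -- once with all eligible source
populations and once without the probed source -- and the source is flagged
causal when Levene's test finds the residual variances of the two fits
significantly different (p < alpha, default 0.05; more robust than the F-test
for non-normal residuals).  Only sources forming on average more than one
synapse per target neuron are eligible.

Structural interactions are summarized by the population-level gain matrix
G_ij = K_ij |J_ij| dPhi_i/dmu + K_ij J_ij^2 dPhi_i/dsigma^2 evaluated at
given rates, normalized by the real part of its leading eigenvalue (so the
normalized matrix sits at criticality, max Re(lambda') = 1).  Edge distances
d_ij = log(1/w_ij) turn weight products into distance sums (negative for
w > 1), and Bellman-Ford -- which, unlike Dijkstra, tolerates negative edge
distances -- yields the dominant (shortest) paths between all populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .meanfield import _siegert_derivatives, network_input, weight_matrix_mv
from .model_spec import NetworkSpec

MAX_LAG_MS_DEFAULT = 25
ELIGIBILITY_SYNAPSES = 1.0  # strict: K_ij > 1 synapse per target neuron


@dataclass
class GrangerResult:
    """Per ordered pair (target i, source j): p-value and significance."""

    populations: list[str]
    pvalues: np.ndarray  # (n, n), NaN where untested
    significant: np.ndarray  # bool
    eligible: np.ndarray  # bool
    alpha: float
    max_lag_ms: int

    def __post_init__(self) -> None:
        if np.any(self.significant & ~self.eligible):
            raise ValueError("significance implies eligibility")


def eligibility_mask(spec: NetworkSpec) -> np.ndarray:
    """Sources forming > 1 synapse per target neuron (strict), off-diagonal."""
    el = spec.conn.K > ELIGIBILITY_SYNAPSES
    np.fill_diagonal(el, False)
    return el


def _lagged_design(x: np.ndarray, cols: list[int], max_lag: int) -> np.ndarray:
    """Design matrix of lags 1..max_lag of the given series (plus intercept)."""
    T = x.shape[1]
    n_rows = T - max_lag
    out = np.empty((n_rows, 1 + len(cols) * max_lag))
    out[:, 0] = 1.0
    k = 1
    for c in cols:
        for lag in range(1, max_lag + 1):
            out[:, k] = x[c, max_lag - lag : T - lag]
            k += 1
    return out


def granger_significance(
    pop_rates: np.ndarray,
    spec: NetworkSpec | None = None,
    eligible: np.ndarray | None = None,
    max_lag_ms: int = MAX_LAG_MS_DEFAULT,
    alpha: float = 0.05,
    center: str = "mean",
    fdr: bool = False,
    labels: list[str] | None = None,
) -> GrangerResult:
    """Conditional Granger causality with Levene significance on rate series.

    ``pop_rates`` is an (n_pop, T) array of 1 ms population rate histograms
    (used unsmoothed).  Eligibility comes from the spec's indegrees (strict
    K > 1 rule) or an explicit boolean mask.  ``center="mean"`` is the
    classical Levene test; ``center="median"`` selects the robust
    (Brown-Forsythe) variant.  ``fdr=True`` applies Benjamini-Hochberg across
    all tested pairs (off by default, matching the per-pair p < alpha rule).
    Rank-deficient designs mark the pair untestable (NaN p-value).
    """
    x = np.atleast_2d(np.asarray(pop_rates, dtype=float))
    n, T = x.shape
    if eligible is None:
        if spec is None:
            raise ValueError("provide a spec or an eligibility mask")
        eligible = eligibility_mask(spec)
    eligible = np.asarray(eligible, dtype=bool)
    if labels is None:
        labels = spec.grid.labels if spec is not None else [f"p{i}" for i in range(n)]
    max_lag = int(max_lag_ms)
    if T <= 2 * max_lag:
        raise ValueError("series too short for the requested VAR lag")

    pvals = np.full((n, n), np.nan)
    for i in range(n):
        sources = [j for j in range(n) if eligible[i, j] and j != i]
        if not sources:
            continue
        cols = [i] + sources
        X = _lagged_design(x, cols, max_lag)
        y = x[i, max_lag:]
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            continue  # rank-deficient: pairs stay untestable
        res_full = y - X @ beta
        for j in sources:
            keep = np.ones(X.shape[1], dtype=bool)
            pos = 1 + (cols.index(j)) * max_lag
            keep[pos : pos + max_lag] = False
            Xr = X[:, keep]
            br, _, rr, _ = np.linalg.lstsq(Xr, y, rcond=None)
            if rr < Xr.shape[1]:
                continue
            res_red = y - Xr @ br
            _, p = stats.levene(res_full, res_red, center=center)
            pvals[i, j] = p

    tested = np.isfinite(pvals)
    if fdr and tested.any():
        flat = pvals[tested]
        order = np.argsort(flat)
        m = flat.size
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((flat[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out = pvals.copy()
        out[tested] = np.clip(adj, 0, 1)
        pvals = out
    sig = tested & (pvals < alpha) & eligible
    return GrangerResult(labels, pvals, sig, eligible, alpha, max_lag)


# ---------------------------------------------------------------------------
# gain matrix and dominant paths
# ---------------------------------------------------------------------------


def gain_matrix(
    spec: NetworkSpec, nu_star: np.ndarray, use_abs_weights: bool = True
) -> np.ndarray:
    """Population-level gain matrix at the supplied rates.

    G_ij = tau_m K_ij |J_ij| dPhi_i/dmu_i + tau_m K_ij J_ij^2 dPhi_i/dsigma_i^2
    with the mean-field derivative terms evaluated at ``nu_star``.  With
    ``use_abs_weights=False`` the signed weights are kept, in which case G is
    the Jacobian of the input-to-rate map.
    """
    if nu_star is None:
        raise ValueError("rates are required to evaluate the gain matrix")
    nu_star = np.asarray(nu_star, dtype=float)
    mf = network_input(nu_star, spec)
    dmu, dsig2 = _siegert_derivatives(mf.mu, np.sqrt(mf.sigma2), spec.neuron_params)
    J, _ = weight_matrix_mv(spec)
    K = spec.conn.K
    tau_m = spec.neuron_params.tau_m * 1e-3
    Jw = np.abs(J) if use_abs_weights else J
    return dmu[:, None] * (tau_m * K * Jw) + dsig2[:, None] * (tau_m * K * J * J)


def normalize_gain(G: np.ndarray) -> np.ndarray:
    """Divide G elementwise by Re(lambda_max) so max Re eigenvalue equals 1."""
    G = np.asarray(G, dtype=float)
    eig = np.linalg.eigvals(G)
    lam = eig[np.argmax(eig.real)]
    if lam.real <= 0:
        raise ValueError("leading eigenvalue has non-positive real part")
    return G / lam.real


@dataclass
class PathReport:
    """All-pairs shortest paths on the gain graph."""

    labels: list[str]
    distance: dict = field(default_factory=dict)  # (src, tgt) -> total distance
    path: dict = field(default_factory=dict)  # (src, tgt) -> node index sequence


def shortest_paths(G_prime: np.ndarray, labels: list[str] | None = None) -> PathReport:
    """Bellman-Ford dominant paths with distances d_ij = log(1/w_ij).

    The graph has an edge from source j to target i for every positive weight
    ``w_ij = G'_ij``; distances are negative where w > 1, which Bellman-Ford
    handles.  A negative-total-distance cycle is an error that names the
    cycle.  Path distances equal -log of the product of edge weights.
    """
    W = np.asarray(G_prime, dtype=float)
    n = W.shape[0]
    if labels is None:
        labels = [f"p{i}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                g.add_edge(j, i, weight=float(np.log(1.0 / W[i, j])))
    report = PathReport(list(labels))
    for src in range(n):
        try:
            dist, path = nx.single_source_bellman_ford(g, src)
        except nx.NetworkXUnbounded as err:
            cycle = nx.find_negative_cycle(g, src)
            raise ValueError(f"negative-distance cycle detected: {cycle}") from err
        for tgt, d in dist.items():
            if tgt == src:
                continue
            report.distance[(src, tgt)] = float(d)
            report.path[(src, tgt)] = list(path[tgt])
    return report


# ---------------------------------------------------------------------------
# laminar categorization
# ---------------------------------------------------------------------------


def categorize_interactions(pairs_mask: np.ndarray, spec: NetworkSpec) -> dict:
    """Aggregate interaction counts by laminar pattern and area category.

    Area pairs are categorized by the sign of the architectural-type
    difference: "high_to_low" (source type > target type, feedforward-like),
    "horizontal" (equal types), "low_to_high" (feedback-like); intra-area
    pairs count as "local".  Within each category, flagged (i, j) entries of
    ``pairs_mask`` are tallied by (source layer+type, target layer+type).
    """
    mask = np.asarray(pairs_mask, dtype=bool)
    types = {a.name: a.architectural_type for a in spec.areas}
    if not types:
        raise ValueError("spec carries no area descriptions")
    pops = spec.grid.populations
    out: dict[str, dict[tuple[str, str], int]] = {
        "high_to_low": {},
        "horizontal": {},
        "low_to_high": {},
        "local": {},
    }
    for i, tgt in enumerate(pops):
        for j, src in enumerate(pops):
            if not mask[i, j]:
                continue
            if src.area == tgt.area:
                cat = "local"
            else:
                d = types[src.area] - types[tgt.area]
                cat = "high_to_low" if d > 0 else ("low_to_high" if d < 0 else "horizontal")
            key = (f"{src.layer}{src.cell_type}", f"{tgt.layer}{tgt.cell_type}")
            out[cat][key] = out[cat].get(key, 0) + 1
    return out


def path_membership_mask(report: PathReport, n: int) -> np.ndarray:
    """Boolean (target, source) mask of edges used by any shortest path."""
    mask = np.zeros((n, n), dtype=bool)
    for nodes in report.path.values():
        for a, b in zip(nodes[:-1], nodes[1:]):
            mask[b, a] = True  # edge a -> b targets b
    return mask
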