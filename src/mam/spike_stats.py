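"""Single-neuron and population statistics of spiking activity.

Instantaneous rates are spike histograms with 1 ms bins averaged over a
population or area, optionally convolved with a Gaussian kernel whose width
minimizes an unbiased MISE estimator (fixed-kernel bandwidth optimization).
Irregularity is quantified by the revised local variation LvR (0 for periodic,
~1 for Poisson firing, corrected for refractoriness), synchrony by mean
pairwise Pearson correlations of 1 ms single-cell histograms on a subsample
of neurons, and spectral content by Welch periodograms (boxcar window,
segment 1024, overlap 1000 at the 1 kHz grid).  Recordings are split into
low- and high-fluctuation phases by the spectral power below 40 Hz in
consecutive 10 s intervals.  Per-neuron rate distributions exclude neurons
below a minimum rate (default 0.56 spikes/s) and support proportional
subsampling via largest-remainder apportionment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulator import SpikeData

BIN_MS = 1.0
FS = 1000.0  # Hz, sampling rate of the 1 ms grid
DEFAULT_MIN_RATE = 0.56  # spikes/s, exclusion threshold
LVR_R_DEFAULT = 5.0  # ms, refractoriness constant of the LvR statistic


@dataclass
class RateSeries:
    """Population- or area-averaged firing rate on a uniform 1 ms grid."""

    values: np.ndarray  # spikes/s
    scope: str
    kernel_sd: float | None = None  # ms, set when smoothed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("rates must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Bin centers in ms."""
        return (np.arange(self.values.size) + 0.5) * BIN_MS


@dataclass
class PhaseLabels:
    """Low/high-fluctuation label per consecutive interval (no gaps)."""

    labels: list[str]  # "low" or "high"
    band_power: np.ndarray
    interval_s: float = 10.0
    threshold: float = 0.0


def _resolve_scope(spikes: SpikeData, scope) -> tuple[list[str], str]:
    """Scope may be a population label, an area name, or a list of labels."""
    if scope is None:
        return spikes.populations, "all"
    if isinstance(scope, str):
        if scope in spikes.trains:
            return [scope], scope
        labels = [l for l in spikes.populations if l.split("-")[0] == scope]
        if not labels:
            raise KeyError(f"unknown population or area {scope!r}")
        return labels, scope
    return list(scope), "+".join(scope)


def rate_histogram(spikes: SpikeData, scope=None) -> RateSeries:
    """Population-averaged instantaneous rate: counts per 1 ms bin / (N * 1 ms)."""
    labels, name = _resolve_scope(spikes, scope)
    n_bins = int(np.rint(spikes.duration / BIN_MS))
    t = spikes.population_spike_times(labels)
    counts = np.histogram(t, bins=n_bins, range=(0.0, spikes.duration))[0]
    n_neurons = spikes.n_recorded(labels)
    if n_neurons == 0:
        return RateSeries(np.zeros(n_bins), name)
    return RateSeries(counts / n_neurons / (BIN_MS / 1000.0), name)


# ---------------------------------------------------------------------------
# kernel-smoothed rates with bandwidth optimization
# ---------------------------------------------------------------------------


def _gauss(x: np.ndarray, sd: float) -> np.ndarray:
    return np.exp(-0.5 * (x / sd) ** 2) / (np.sqrt(2.0 * np.pi) * sd)


def _kernel_cost(acorr: np.ndarray, lags: np.ndarray, n: int, w: float) -> float:
    """Unbiased MISE estimate for a Gaussian kernel of SD ``w`` (ms).

    C(w) = (1/n^2) sum_{i,j} k_{sqrt2 w}(dt) - (2/n^2) sum_{i!=j} k_w(dt),
    evaluated through the autocorrelation of the 1 ms count histogram.
    """
    term1 = float(acorr @ _gauss(lags, np.sqrt(2.0) * w))
    pair = float(acorr @ _gauss(lags, w)) - n * _gauss(np.zeros(1), w)[0]
    return (term1 - 2.0 * pair) / n**2


def optimal_kernel_rate(series: RateSeries, bandwidth: float | None = None) -> RateSeries:
    """Gaussian-kernel smoothed rate with MISE-optimal bandwidth.

    The bandwidth (kernel SD, ms) is selected on a log-spaced grid by
    minimizing the unbiased MISE estimator of the underlying rate profile;
    pass ``bandwidth`` to skip selection.  The kernel is sampled on the 1 ms
    grid and normalized to unit sum, so the smoothed series conserves the
    total spike count up to edge effects.  An all-zero series is returned
    unchanged.
    """
    x = series.values
    n_bins = x.size
    # counts per bin (the series is counts / (N * dt)); scale is irrelevant
    # to the argmin, so work with the values directly as weights.
    total = x.sum()
    if total == 0 or n_bins == 0:
        return RateSeries(x.copy(), series.scope, kernel_sd=bandwidth)

    if bandwidth is None:
        # autocorrelation of the histogram at 1 ms lags
        full = signal.fftconvolve(x, x[::-1])
        mid = n_bins - 1
        w_grid = np.geomspace(1.0, max(2.0, n_bins / 10.0), 40)
        max_lag = min(mid, int(np.ceil(6 * w_grid[-1])))
        lags = np.arange(-max_lag, max_lag + 1, dtype=float)
        acorr = full[mid - max_lag : mid + max_lag + 1]
        n_eff = total  # plays the role of the spike count
        costs = [_kernel_cost(acorr, lags, n_eff, w) for w in w_grid]
        bandwidth = float(w_grid[int(np.argmin(costs))])

    half = int(np.ceil(5.0 * bandwidth))
    support = np.arange(-half, half + 1, dtype=float)
    kern = _gauss(support, bandwidth)
    kern /= kern.sum()
    smooth = signal.fftconvolve(x, kern, mode="same")
    smooth = np.clip(smooth, 0.0, None)
    return RateSeries(smooth, series.scope, kernel_sd=bandwidth)


# ---------------------------------------------------------------------------
# irregularity and synchrony
# ---------------------------------------------------------------------------


def lvr(spike_times: np.ndarray, R_refr: float = LVR_R_DEFAULT) -> float:
    """Revised local variation of one spike train (times in ms).

    LvR = 3/(n-1) sum_i (1 - 4 I_i I_{i+1} / (I_i + I_{i+1})^2)
                        (1 + 4 R / (I_i + I_{i+1}))

    over consecutive inter-spike intervals I.  Zero for a periodic train,
    ~1 for Poisson firing.  Undefined (NaN) for fewer than 3 spikes.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if t.size < 3:
        return float("nan")
    isi = np.diff(t)
    i1, i2 = isi[:-1], isi[1:]
    s = i1 + i2
    terms = (1.0 - 4.0 * i1 * i2 / s**2) * (1.0 + 4.0 * R_refr / s)
    return float(3.0 / (isi.size - 1) * terms.sum())


def _single_cell_histograms(
    spikes: SpikeData, labels: list[str], n_sample: int, seed: int
) -> np.ndarray:
    """Binned (1 ms) spike histograms of a seeded subsample of active neurons."""
    n_bins = int(np.rint(spikes.duration / BIN_MS))
    cells: list[tuple[str, int]] = []
    for l in labels:
        idx, _ = spikes.trains[l]
        for i in sorted(set(idx.tolist())):
            cells.append((l, i))
    if len(cells) > n_sample:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(cells), size=n_sample, replace=False)
        cells = [cells[i] for i in sorted(pick.tolist())]
    out = np.zeros((len(cells), n_bins))
    for row, (l, i) in enumerate(cells):
        idx, t = spikes.trains[l]
        out[row] = np.histogram(t[idx == i], bins=n_bins, range=(0.0, spikes.duration))[0]
    return out


def pairwise_correlation(
    spikes: SpikeData, scope=None, n_sample: int = 2000, seed: int = 0
) -> float:
    """Mean Pearson coefficient over distinct pairs of a neuron subsample.

    Single-cell spike histograms with 1 ms bins; only neurons with at least
    one emitted spike are eligible; the whole eligible set is used when it is
    smaller than ``n_sample``.  Deterministic given the seed.
    """
    labels, _ = _resolve_scope(spikes, scope)
    hists = _single_cell_histograms(spikes, labels, n_sample, seed)
    if hists.shape[0] < 2:
        return float("nan")
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(hists)
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    return float(np.nanmean(vals))


def correlation_matrix(
    spikes: SpikeData, scope=None, n_sample: int = 2000, seed: int = 0
) -> np.ndarray:
    """Full Pearson matrix of the subsampled single-cell histograms."""
    labels, _ = _resolve_scope(spikes, scope)
    hists = _single_cell_histograms(spikes, labels, n_sample, seed)
    with np.errstate(invalid="ignore"):
        return np.corrcoef(hists)


# ---------------------------------------------------------------------------
# spectra and fluctuation phases
# ---------------------------------------------------------------------------


def welch_psd(
    series: RateSeries | np.ndarray, nperseg: int = 1024, noverlap: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with a boxcar window on the 1 kHz grid.

    Segment length 1024 samples with 1000 overlapping points; a series
    shorter than one segment falls back to a single periodogram (with a
    warning).
    """
    x = series.values if isinstance(series, RateSeries) else np.asarray(series, float)
    if x.size < nperseg:
        warnings.warn(
            "series shorter than one Welch segment; returning a single periodogram",
            stacklevel=2,
        )
        nperseg = x.size
        noverlap = 0
    return signal.welch(x, fs=FS, window="boxcar", nperseg=nperseg, noverlap=noverlap)


def classify_fluctuation_phases(
    series: RateSeries | np.ndarray, theta_fluct: float, interval_s: float = 10.0
) -> PhaseLabels:
    """Label consecutive 10 s intervals low/high by spectral power below 40 Hz.

    Per interval, the Welch PSD is integrated over [0, 40] Hz; intervals with
    power <= ``theta_fluct`` are "low", the others "high".  A partial trailing
    interval is discarded.  The published threshold (0.8e8) presupposes a
    particular spectral normalization and neuron count, so the threshold is
    an explicit argument here.
    """
    x = series.values if isinstance(series, RateSeries) else np.asarray(series, float)
    n_per = int(np.rint(interval_s * FS))
    n_int = x.size // n_per
    labels: list[str] = []
    power = np.zeros(n_int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_int):
            seg = x[k * n_per : (k + 1) * n_per]
            f, p = welch_psd(seg - seg.mean())
            band = f <= 40.0
            power[k] = np.trapezoid(p[band], f[band])
            labels.append("low" if power[k] <= theta_fluct else "high")
    return PhaseLabels(labels, power, interval_s, theta_fluct)


# ---------------------------------------------------------------------------
# per-neuron rate distributions
# ---------------------------------------------------------------------------


def largest_remainder_apportionment(sizes: np.ndarray, total: int) -> np.ndarray:
    """Distribute ``total`` samples over groups in proportion to ``sizes``."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.sum() == 0:
        return np.zeros(sizes.size, dtype=int)
    quota = total * sizes / sizes.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def rate_distribution(
    spikes: SpikeData,
    scope=None,
    min_rate: float = DEFAULT_MIN_RATE,
    target_count: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-neuron time-averaged rates, excluding neurons below ``min_rate``.

    With ``target_count`` the recorded neurons are first subsampled across
    populations in proportion to the population sizes (largest-remainder
    apportionment, without replacement, seed-controlled), then the rate
    threshold is applied.
    """
    labels, _ = _resolve_scope(spikes, scope)
    dur_s = spikes.duration / 1000.0
    per_pop: list[np.ndarray] = []
    for l in labels:
        idx, _ = spikes.trains[l]
        counts = np.bincount(idx, minlength=spikes.recorded[l])
        per_pop.append(counts / dur_s if dur_s > 0 else counts.astype(float))
    if target_count is not None:
        rng = np.random.default_rng(seed)
        alloc = largest_remainder_apportionment(
            np.array([spikes.sizes[l] for l in labels]), target_count
        )
        picked = []
        for rates, k in zip(per_pop, alloc):
            k = min(int(k), rates.size)
            if k == 0:
                continue
            sel = np.sort(rng.choice(rates.size, size=k, replace=False))
            picked.append(rates[sel])
        per_pop = picked
    rates = np.concatenate(per_pop) if per_pop else np.empty(0)
    return rates[rates >= min_rate]
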