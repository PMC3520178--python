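"""Offline spike-train and navigation analysis.

Post-stimulus time histograms (PSTH) and their areas, first-spike
latencies, normalized cross-correlograms with the C_peak synchrony
summary, robot navigation performance metrics, and a small two-group
statistical comparison helper (normality-gated parametric vs
non-parametric test choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PSTH",
    "Correlogram",
    "NavigationMetrics",
    "GroupComparison",
    "compute_psth",
    "first_spike_latency",
    "cross_correlogram",
    "c_peak",
    "navigation_metrics",
    "compare_groups",
]


# --------------------------------------------------------------------------
# PSTH
# --------------------------------------------------------------------------


@dataclass
class PSTH:
    """Trial-averaged post-stimulus histogram.

    ``values[b]`` is the spike count in bin ``b`` summed over trials and
    divided by the number of trials (the probability of evoking a spike
    in that bin); ``area`` is the sum over bins, i.e. the mean number of
    evoked spikes per stimulus within the window.
    """

    stim_electrode: int | None
    rec_electrode: int | None
    bin_s: float
    window_s: float
    n_trials: int
    values: np.ndarray

    @property
    def area(self) -> float:
        return float(self.values.sum())

    @property
    def bin_edges(self) -> np.ndarray:
        n_bins = len(self.values)
        return np.arange(n_bins + 1) * self.bin_s


def compute_psth(
    spikes: np.ndarray,
    stim_times: np.ndarray,
    window_s: float = 0.600,
    bin_s: float = 0.004,
    stim_electrode: int | None = None,
    rec_electrode: int | None = None,
) -> PSTH:
    """PSTH of one spike train around a set of stimulus times.

    Bins are half-open ``[stim + k*bin, stim + (k+1)*bin)``; spikes beyond
    the window are ignored.  Default 4 ms bins over 600 ms (150 bins).
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("PSTH requires at least one stimulus")
    spikes = np.sort(np.asarray(spikes, dtype=float))
    n_bins = int(round(window_s / bin_s))
    counts = np.zeros(n_bins)
    for t0 in stim_times:
        rel = spikes[np.searchsorted(spikes, t0, "left"):np.searchsorted(spikes, t0 + window_s, "left")] - t0
        # epsilon guards the half-open bin edges against float representation
        idx = np.floor(rel / bin_s + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1.0)
    return PSTH(
        stim_electrode=stim_electrode,
        rec_electrode=rec_electrode,
        bin_s=bin_s,
        window_s=window_s,
        n_trials=len(stim_times),
        values=counts / len(stim_times),
    )


def first_spike_latency(
    spikes: np.ndarray,
    stim_times: np.ndarray,
    window_s: float = 0.600,
    censor: bool = False,
) -> np.ndarray:
    """Per-stimulus latency (ms) of the first spike in ``(stim, stim+window]``.

    Stimuli with no spike inside the window contribute no latency sample by
    default; with ``censor=True`` they contribute the window length instead.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("latency requires at least one stimulus")
    spikes = np.sort(np.asarray(spikes, dtype=float))
    out = []
    for t0 in stim_times:
        i = np.searchsorted(spikes, t0, "right")
        if i < len(spikes) and spikes[i] - t0 <= window_s:
            out.append((spikes[i] - t0) * 1e3)
        elif censor:
            out.append(window_s * 1e3)
    return np.asarray(out)


# --------------------------------------------------------------------------
# Cross-correlogram
# --------------------------------------------------------------------------


@dataclass
class Correlogram:
    """Normalized spike-train cross-correlogram over lags in [-T, T].

    ``values[b]`` counts the (x_i, y_j) pairs whose lag ``y_j - x_i``
    falls in bin ``b``, divided by sqrt(N_x * N_y).
    """

    pair: tuple[int, int] | None
    half_width_s: float
    bin_s: float
    values: np.ndarray

    @property
    def lags_s(self) -> np.ndarray:
        n = len(self.values)
        return (np.arange(n) - n // 2) * self.bin_s


def cross_correlogram(
    x: np.ndarray,
    y: np.ndarray,
    half_width_s: float = 0.050,
    bin_s: float = 0.001,
    pair: tuple[int, int] | None = None,
) -> Correlogram:
    """Count y-spikes in lag bins around each x-spike, sqrt(NxNy)-normalized.

    Satisfies C_xy(tau) = C_yx(-tau).  Lag bins are centred on multiples of
    ``bin_s`` (the zero-lag bin is centred on 0).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("cross-correlogram requires two non-empty trains")
    n_half = int(round(half_width_s / bin_s))
    n_bins = 2 * n_half + 1
    edges = (np.arange(n_bins + 1) - n_half - 0.5) * bin_s
    lo = np.searchsorted(y, x + edges[0], "left")
    hi = np.searchsorted(y, x + edges[-1], "left")
    per = hi - lo
    total = int(per.sum())
    if total == 0:
        counts = np.zeros(n_bins)
    else:
        # flat indices of every y spike inside each x spike's lag window
        offsets = np.concatenate([[0], np.cumsum(per)[:-1]])
        flat = np.arange(total) - np.repeat(offsets, per) + np.repeat(lo, per)
        diffs = y[flat] - np.repeat(x, per)
        bins = np.floor((diffs - edges[0]) / bin_s).astype(np.int64)
        np.clip(bins, 0, n_bins - 1, out=bins)
        counts = np.bincount(bins, minlength=n_bins).astype(float)
    counts /= np.sqrt(float(x.size) * float(y.size))
    return Correlogram(pair=pair, half_width_s=half_width_s, bin_s=bin_s, values=counts)


def c_peak(corr: Correlogram, halo_bins: int = 2, mode: str = "mean") -> float:
    """Summary of the correlogram around its maximum.

    ``mode='mean'`` (default) averages the values over the maximum bin
    +/- ``halo_bins``; ``'peak'`` returns the maximum bin alone;
    ``'integral'`` sums over the halo.
    """
    v = corr.values
    k = int(np.argmax(v))
    lo, hi = max(0, k - halo_bins), min(len(v), k + halo_bins + 1)
    if mode == "mean":
        return float(v[lo:hi].mean())
    if mode == "peak":
        return float(v[k])
    if mode == "integral":
        return float(v[lo:hi].sum())
    raise ValueError(f"unknown c_peak mode {mode!r}")


# --------------------------------------------------------------------------
# Navigation metrics
# --------------------------------------------------------------------------


@dataclass
class NavigationMetrics:
    """Robot performance summary for one run."""

    n_hits: int
    hits_per_s: float
    total_path_px: float
    mean_distance_between_hits_px: float   # NaN when fewer than one full interval
    inter_hit_distances_px: np.ndarray


def navigation_metrics(runlog) -> NavigationMetrics:
    """Performance of a run: path length, hits/s, mean path between hits.

    The path between hits is measured from each post-collision relocation
    to the next collision; the segment from run start to the first hit is
    not an inter-hit interval and is excluded.
    """
    traj = np.asarray(runlog.trajectory)
    if traj.shape[0] < 2 or runlog.duration <= 0:
        raise ValueError("navigation metrics require a sampled trajectory of positive duration")
    xy = traj[:, 1:3]
    steps = np.hypot(*np.diff(xy, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    t = traj[:, 0]

    def path_at(time: float) -> float:
        return float(np.interp(time, t, cum))

    hits = [ev for ev in runlog.collisions]
    distances = []
    for k in range(1, len(hits)):
        start = runlog.relocations[k - 1].time if k - 1 < len(runlog.relocations) else hits[k - 1].time
        distances.append(path_at(hits[k].time) - path_at(start))
    distances_arr = np.asarray(distances)
    return NavigationMetrics(
        n_hits=len(hits),
        hits_per_s=len(hits) / runlog.duration,
        total_path_px=float(cum[-1]),
        mean_distance_between_hits_px=float(distances_arr.mean()) if distances else float("nan"),
        inter_hit_distances_px=distances_arr,
    )


# --------------------------------------------------------------------------
# Group comparison
# --------------------------------------------------------------------------


@dataclass
class GroupComparison:
    test: str                   # 't-test' | 'mann-whitney' | 'degenerate'
    statistic: float
    p_value: float
    significant: bool
    normal_a: bool
    normal_b: bool


def compare_groups(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Two-group comparison with a normality-gated test choice.

    Kolmogorov-Smirnov normality (Lilliefors variant, parameters
    estimated from the data) decides between a parametric test (two-sample
    t-test, the two-group case of one-way ANOVA) and the Mann-Whitney U
    test.  Constant samples are reported as degenerate.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = np.allclose(a.mean(), b.mean())
        return GroupComparison("degenerate", 0.0, 1.0 if same else 0.0, not same, False, False)

    def _normal(s: np.ndarray) -> bool:
        if np.ptp(s) == 0:
            return False
        from statsmodels.stats.diagnostic import lilliefors

        return lilliefors(s, dist="norm")[1] > alpha

    na, nb = _normal(a), _normal(b)
    if na and nb:
        stat, p = stats.ttest_ind(a, b, alternative=alternative)
        test = "t-test"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative=alternative)
        test = "mann-whitney"
    return GroupComparison(test, float(stat), float(p), bool(p < alpha), na, nb)
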