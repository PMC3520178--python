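"""Raw-trace synthesis, spike detection and stimulus-artifact blanking.

The control loop consumes spike time stamps directly, but the detection
path is implemented and validated end-to-end: a synthetic 10 kHz voltage
trace (Gaussian noise + stereotyped biphasic spike waveforms + saturating
stimulus artifacts) is thresholded with a differential peak-to-peak rule
at k times the per-channel noise SD, and events falling within the
blanking interval after a stimulus are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = [
    "RawTrace",
    "DetectionParams",
    "spike_waveform",
    "synthesize_trace",
    "compute_threshold",
    "detect_spikes",
    "blank_artifacts",
]

DEFAULT_FS_HZ = 10_000.0


@dataclass
class RawTrace:
    """Single-channel extracellular voltage trace in microvolts."""

    electrode: int
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def save(self, path: str | Path) -> None:
        """Binary array file with a small text header (fs, electrode, units)."""
        with open(path, "wb") as fh:
            fh.write(f"# electrode={self.electrode} fs={self.fs:g} units=uV dtype=float64\n".encode())
            fh.write(self.samples.tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "RawTrace":
        with open(path, "rb") as fh:
            header = fh.readline().decode().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            samples = np.frombuffer(fh.read(), dtype=meta["dtype"])
        return cls(electrode=int(meta["electrode"]), fs=float(meta["fs"]), samples=samples.copy())


@dataclass
class DetectionParams:
    """Differential peak-to-peak spike detection parameters."""

    threshold_k: float = 6.5          # multiples of the noise SD (typ. 6-7)
    window_ms: float = 2.0            # peak-to-peak search window
    dead_time_ms: float = 1.0         # refractory after a detection
    artifact_k: float = 10.0          # artifact threshold, multiples of spike threshold
    blank_ms: float = 4.0             # post-stimulus blanking

    def __post_init__(self) -> None:
        if self.blank_ms < 0:
            raise ValueError("blanking duration must be non-negative")
        if self.window_ms <= 0 or self.dead_time_ms < 0:
            raise ValueError("invalid detection window or dead time")


# --------------------------------------------------------------------------
# Trace synthesis (validation fixture for the detection path)
# --------------------------------------------------------------------------


def spike_waveform(fs: float = DEFAULT_FS_HZ, amplitude_pp: float = 100.0) -> np.ndarray:
    """Stereotyped biphasic extracellular spike, ~1 ms support.

    A sharp negative lobe followed by a slower positive overshoot; scaled
    so the peak-to-peak excursion equals ``amplitude_pp`` (uV).
    """
    t = np.arange(0, 0.0012, 1.0 / fs)
    w = -np.exp(-((t - 0.0003) / 0.00012) ** 2) + 0.45 * np.exp(-((t - 0.0007) / 0.00025) ** 2)
    return w * amplitude_pp / np.ptp(w)


def synthesize_trace(
    spike_times: np.ndarray,
    noise_sd: float,
    stim_times: np.ndarray = (),
    fs: float = DEFAULT_FS_HZ,
    duration: float = 1.0,
    seed: int | None = None,
    electrode: int = 0,
    amplitude_pp: float = 100.0,
    artifact_amp: float = 2000.0,
    lfp_fraction: float = 0.5,
) -> RawTrace:
    """Gaussian noise + spike waveforms + saturating stimulus artifacts.

    The channel noise is a Gaussian mixture of a fast (white) component
    and a slow local-field/drift component, as on a raw extracellular
    trace; ``lfp_fraction`` is the slow component's share of the total
    noise variance and the overall sample SD equals ``noise_sd``.  The
    peak-to-peak signal-to-noise ratio is ``amplitude_pp / noise_sd``.
    Artifacts are large biphasic square deflections of ~2 ms at each
    stimulus time.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() >= duration):
        raise ValueError("spike times must lie within [0, duration)")
    if not (0.0 <= lfp_fraction < 1.0):
        raise ValueError("lfp_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if noise_sd > 0:
        x = rng.normal(0.0, noise_sd * np.sqrt(1.0 - lfp_fraction), n)
        if lfp_fraction > 0:
            from scipy.signal import butter, lfilter

            b, a = butter(2, min(10.0 / (fs / 2), 0.99))
            slow = lfilter(b, a, rng.normal(0.0, 1.0, n))
            sd = slow.std()
            if sd > 0:
                x += slow * (noise_sd * np.sqrt(lfp_fraction) / sd)
    else:
        x = np.zeros(n)

    w = spike_waveform(fs, amplitude_pp)
    for t in spike_times:
        i = int(round(t * fs))
        j = min(n, i + len(w))
        x[i:j] += w[: j - i]

    art_half = int(round(0.001 * fs))
    for t in np.asarray(stim_times, dtype=float):
        i = int(round(t * fs))
        if i >= n:
            continue
        j1 = min(n, i + art_half)
        j2 = min(n, i + 2 * art_half)
        x[i:j1] += artifact_amp
        x[j1:j2] -= artifact_amp
    return RawTrace(electrode=electrode, fs=fs, samples=x)


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------


def compute_threshold(trace: RawTrace, params: DetectionParams | None = None) -> float:
    """Per-channel threshold: k times a robust estimate of the noise SD.

    The SD is estimated as median(|x|)/0.6745 (median absolute deviation
    of a zero-mean Gaussian), which resists contamination by spikes.
    """
    params = params or DetectionParams()
    if len(trace.samples) == 0:
        raise ValueError("empty trace")
    if len(trace.samples) < trace.fs:
        raise ValueError("threshold estimation needs at least 1 s of samples")
    sd = float(np.median(np.abs(trace.samples - np.median(trace.samples))) / 0.6745)
    return params.threshold_k * sd


def detect_spikes(
    trace: RawTrace, threshold: float, params: DetectionParams | None = None
) -> np.ndarray:
    """Differential peak-to-peak spike detection.

    A spike is emitted wherever the peak-to-peak excursion within the
    sliding search window exceeds the threshold; its timestamp is the
    absolute-maximum deflection of the triggering segment, and further
    detections are suppressed for the dead time.  The rule is invariant
    to a polarity flip of the trace.
    """
    params = params or DetectionParams()
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = trace.samples
    if len(x) == 0:
        return np.empty(0)
    win = max(2, int(round(params.window_ms * 1e-3 * trace.fs)))
    p2p = maximum_filter1d(x, win) - minimum_filter1d(x, win)
    above = p2p > threshold
    if not above.any():
        return np.empty(0)

    # contiguous above-threshold runs -> one candidate event each
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(x)]])

    half = win // 2
    times = []
    for s, e in zip(starts, ends):
        lo, hi = max(0, s - half), min(len(x), e + half)
        k = lo + int(np.argmax(np.abs(x[lo:hi])))
        times.append(k / trace.fs)
    times = np.asarray(sorted(times))

    dead = params.dead_time_ms * 1e-3
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= dead:
            kept.append(t)
            last = t
    return np.asarray(kept)


def blank_artifacts(
    spikes: np.ndarray, stim_times: np.ndarray, blank_ms: float = 4.0
) -> np.ndarray:
    """Remove spike timestamps within [stim, stim + blank) of any stimulus.

    The interval is half-open: an event exactly ``blank_ms`` after a
    stimulus is retained.  Idempotent; never adds events.
    """
    if blank_ms < 0:
        raise ValueError("blanking duration must be non-negative")
    spikes = np.asarray(spikes, dtype=float)
    stim_times = np.asarray(stim_times, dtype=float)
    if spikes.size == 0 or stim_times.size == 0:
        return spikes.copy()
    blank = blank_ms * 1e-3
    idx = np.searchsorted(stim_times, spikes, "right") - 1
    has_prev = idx >= 0
    within = np.zeros(len(spikes), dtype=bool)
    within[has_prev] = spikes[has_prev] - stim_times[idx[has_prev]] < blank
    return spikes[~within]
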