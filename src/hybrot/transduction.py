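"""Bi-directional interface between culture and robot.

Linear rate decoding (area spike counts -> wheel speed) and coding
(proximity -> stimulation rate), regular pulse scheduling with phase
carry across the 100 ms control windows, and the collision-triggered
tetanus rule.

Decoding, per side i and window t (f in spikes per window per electrode):

    omega_i = (f_{i,t} + f_{i,t-1}) / (2 f_i^MAX) * (omega_i^MAX - omega_i^min)
              + omega_i^min          for f_{i,t} <  f_i^MAX
    omega_i = omega_i^MAX            for f_{i,t} >= f_i^MAX

Coding, per side i with proximity r_i in [0, 1]:

    s_i = (s_i^MAX - s_i^min) * r_i + s_i^min
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .culture import SpikeData, StimPulse

__all__ = [
    "DecodingParams",
    "CodingParams",
    "PulsePhase",
    "area_firing_rate",
    "decode_wheel_speed",
    "encode_stim_rate",
    "schedule_pulses",
    "tetanus_on_collision",
    "TETANUS_RATE_HZ",
    "TETANUS_DURATION_S",
]

logger = logging.getLogger(__name__)

CONTROL_WINDOW_S = 0.100
TETANUS_RATE_HZ = 20.0
TETANUS_DURATION_S = 2.0


@dataclass
class DecodingParams:
    """Per-side decoding parameters (spikes -> wheel speed)."""

    electrodes: tuple[int, ...]            # output area, 8-10 electrodes
    omega_max: float = 40.0                # px/s
    omega_min: float = 20.0                # px/s
    f_max: float = 1.0                     # spikes per window per electrode
    window_s: float = CONTROL_WINDOW_S

    def __post_init__(self) -> None:
        if self.omega_min > self.omega_max:
            raise ValueError("omega_min must not exceed omega_max")
        if self.f_max <= 0 or self.window_s <= 0:
            raise ValueError("f_max and window must be positive")
        if len(self.electrodes) == 0:
            raise ValueError("output area must be non-empty")


@dataclass
class CodingParams:
    """Per-side coding parameters (proximity -> stimulation rate)."""

    electrode: int                         # input site
    s_max: float = 2.0                     # Hz
    s_min: float = 0.2                     # Hz
    pulse_amplitude: float = 1.0
    pulse_duration: float = 500e-6         # s

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_min <= self.s_max):
            raise ValueError("need 0 <= s_min <= s_max")


def area_firing_rate(
    spikes: SpikeData, area: tuple[int, ...], t0: float, window_s: float = CONTROL_WINDOW_S
) -> float:
    """Spikes per window averaged over the area's electrodes.

    Counts spikes on the area electrodes in the half-open window
    ``[t0, t0 + window_s)`` and divides by the number of electrodes, so
    the result is independent of the area size.
    """
    if len(area) == 0:
        raise ValueError("output area must be non-empty")
    return spikes.count_in(area, t0, t0 + window_s) / len(area)


def decode_wheel_speed(f_t: float, f_tm1: float, p: DecodingParams) -> float:
    """Linear rate decoder with a two-window average and saturation.

    Monotone non-decreasing in both rate arguments and bounded in
    ``[omega_min, omega_max]``; zero activity yields the minimum speed,
    and the current window's rate reaching f_max saturates the wheel.
    """
    if f_t < 0 or f_tm1 < 0:
        raise ValueError("firing rates must be non-negative")
    if f_t >= p.f_max:
        return p.omega_max
    omega = (f_t + f_tm1) / (2.0 * p.f_max) * (p.omega_max - p.omega_min) + p.omega_min
    return float(min(omega, p.omega_max))


def encode_stim_rate(r: float, p: CodingParams) -> float:
    """Affine proximity-to-rate coder: s = (s_max - s_min) * r + s_min."""
    if not (0.0 <= r <= 1.0):
        logger.warning("proximity %.3f outside [0, 1]; clipping", r)
        r = float(np.clip(r, 0.0, 1.0))
    return (p.s_max - p.s_min) * r + p.s_min


@dataclass
class PulsePhase:
    """Phase carry for regular pulse scheduling across windows."""

    next_time: float | None = None


def schedule_pulses(
    rate_hz: float,
    t0: float,
    window_s: float,
    phase: PulsePhase,
    electrode: int,
    kind: str = "sensory",
) -> list[StimPulse]:
    """Regular pulses at period 1/rate within ``[t0, t0 + window_s)``.

    The phase is carried across windows so the long-run delivered rate
    converges to the commanded rate (count over any interval differs from
    rate x interval by less than one).  A zero rate emits nothing and
    leaves the phase unchanged.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if rate_hz == 0:
        return []
    period = 1.0 / rate_hz
    t = phase.next_time if phase.next_time is not None else t0
    if t < t0:
        t = t0
    out = []
    while t < t0 + window_s - 1e-12:
        out.append(StimPulse(electrode=electrode, time=t, kind=kind))
        t += period
    phase.next_time = t
    return out


def tetanus_on_collision(
    side: str,
    input_electrodes: dict[str, int],
    start_time: float,
    rate_hz: float = TETANUS_RATE_HZ,
    duration_s: float = TETANUS_DURATION_S,
) -> list[StimPulse]:
    """Tetanic train (20 Hz, 2 s) to the same-side input electrode.

    During its delivery the control loop suspends sensory stimulation and
    holds the robot at the relocated pose; overlapping requests are
    queued by the session driver, never interleaved.
    """
    if side not in input_electrodes:
        raise ValueError(f"unresolved collision side {side!r}")
    electrode = input_electrodes[side]
    n = int(round(rate_hz * duration_s))
    period = 1.0 / rate_hz
    return [
        StimPulse(electrode=electrode, time=start_time + k * period, kind="tetanus")
        for k in range(n)
    ]
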