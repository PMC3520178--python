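"""Experimental session orchestration.

The five-phase protocol of a closed-loop session:

1. spontaneous screening of input-site candidates,
2. serial probe stimulation (40 stimuli per candidate) and PSTH mapping,
3. closed-loop run without the plasticity rule,
4. closed-loop run with the collision-triggered tetanus,
5. evaluation via navigation metrics.

Also provides the control conditions: open loop (decoding spontaneous
activity, no stimulation) and "empty" MEA (detection events are the
false-positive process of the noise-only signal path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, signals, transduction
from .culture import CultureState, SpikeData, StimPulse, potentiate, simulate_window
from .robot import (
    Arena,
    RobotState,
    detect_collision,
    relocate_after_collision,
    sense,
    step_kinematics,
)
from .transduction import (
    CONTROL_WINDOW_S,
    TETANUS_DURATION_S,
    CodingParams,
    DecodingParams,
    PulsePhase,
    area_firing_rate,
    decode_wheel_speed,
    encode_stim_rate,
    schedule_pulses,
    tetanus_on_collision,
)

__all__ = [
    "ProtocolError",
    "IOAssignment",
    "SessionConfig",
    "PSTHMap",
    "RunLog",
    "screen_inputs",
    "probe_and_map",
    "select_io",
    "calibrate_decoding",
    "run_session",
]

MFR_THRESHOLD_HZ = 0.1
PROBE_STIMULI_PER_CHANNEL = 40
PROBE_ISI_S = 5.0


class ProtocolError(RuntimeError):
    """A protocol phase could not proceed (e.g. no qualifying electrodes)."""


# --------------------------------------------------------------------------
# Phase 1: input screening
# --------------------------------------------------------------------------


def screen_inputs(
    spont: SpikeData,
    layout,
    n_candidates: int = 8,
    mfr_threshold_hz: float = MFR_THRESHOLD_HZ,
    max_spikes_per_train: int = 400,
) -> list[int]:
    """Select candidate input electrodes from spontaneous activity.

    Electrodes must sustain a mean firing rate above the threshold
    (0.1 spikes/s); qualifying electrodes are ranked ascending by their
    mean pairwise C_peak against all other qualifying electrodes, so the
    least synchronized sites come first.  Ties break by electrode id.
    For the ranking, long trains are thinned to a deterministic stride
    subsample (C_peak is a normalized rate, so ranking is preserved).
    """
    if spont.duration < 300.0 - 1e-9:
        raise ValueError("screening requires >= 300 s of spontaneous recording")
    if not (8 <= n_candidates <= 10):
        raise ValueError("the candidate set holds 8-10 electrodes")
    rates = {int(e): len(spont.train(e)) / spont.duration for e in layout.electrode_ids}
    qualifying = sorted(e for e, r in rates.items() if r > mfr_threshold_hz)
    if len(qualifying) < 2:
        raise ProtocolError(
            f"only {len(qualifying)} electrodes exceed {mfr_threshold_hz} spikes/s; "
            "culture unsuitable for stimulation mapping"
        )

    def thin(train: np.ndarray) -> np.ndarray:
        if len(train) <= max_spikes_per_train:
            return train
        stride = int(np.ceil(len(train) / max_spikes_per_train))
        return train[::stride]

    thinned = {e: thin(spont.train(e)) for e in qualifying}
    mean_cpeak = {}
    for e in qualifying:
        vals = [
            analysis.c_peak(analysis.cross_correlogram(thinned[e], thinned[o]))
            for o in qualifying
            if o != e
        ]
        mean_cpeak[e] = float(np.mean(vals)) if vals else 0.0
    ranked = sorted(qualifying, key=lambda e: (mean_cpeak[e], e))
    return ranked[: min(n_candidates, len(ranked))]


# --------------------------------------------------------------------------
# Phase 2: probe stimulation and PSTH mapping
# --------------------------------------------------------------------------


@dataclass
class PSTHMap:
    """PSTHs for every (stimulation site, recording site) pair."""

    psths: dict[tuple[int, int], analysis.PSTH]
    stim_log: list[StimPulse]
    stim_times: dict[int, np.ndarray]

    def area(self, stim: int, rec: int) -> float:
        return self.psths[(stim, rec)].area

    def areas(self) -> pd.DataFrame:
        """Recording electrodes as rows, stimulation sites as columns."""
        stims = sorted({s for s, _ in self.psths})
        recs = sorted({r for _, r in self.psths})
        return pd.DataFrame(
            [[self.psths[(s, r)].area for s in stims] for r in recs],
            index=recs,
            columns=stims,
        )


def probe_and_map(
    culture: CultureState,
    candidates: list[int],
    n_stimuli: int = PROBE_STIMULI_PER_CHANNEL,
    isi_s: float = PROBE_ISI_S,
    psth_window_s: float = 0.600,
    psth_bin_s: float = 0.004,
) -> PSTHMap:
    """Deliver the serial probe trains and compute the full PSTH map.

    Each candidate receives ``n_stimuli`` probe pulses at the given
    inter-stimulus interval, one candidate after another; PSTHs are then
    computed for all recording sites against each stimulation site.
    """
    if not candidates:
        raise ValueError("no probe candidates")
    psths: dict[tuple[int, int], analysis.PSTH] = {}
    stim_log: list[StimPulse] = []
    stim_times: dict[int, np.ndarray] = {}
    tail = max(psth_window_s, 0.1)
    for cand in candidates:
        t0 = culture.time
        pulses = [
            StimPulse(electrode=cand, time=t0 + 0.5 + k * isi_s, kind="probe")
            for k in range(n_stimuli)
        ]
        block = 0.5 + n_stimuli * isi_s + tail
        spikes = simulate_window(culture, block, pulses)
        stim_log.extend(pulses)
        times = np.array([p.time for p in pulses])
        stim_times[cand] = times
        for rec in culture.layout.electrode_ids:
            rec = int(rec)
            psths[(cand, rec)] = analysis.compute_psth(
                spikes.train(rec),
                times,
                window_s=psth_window_s,
                bin_s=psth_bin_s,
                stim_electrode=cand,
                rec_electrode=rec,
            )
    return PSTHMap(psths=psths, stim_log=stim_log, stim_times=stim_times)


# --------------------------------------------------------------------------
# I/O selection
# --------------------------------------------------------------------------


@dataclass
class IOAssignment:
    """Input electrodes and output areas for the two robot sides."""

    input_left: int
    input_right: int
    output_left: tuple[int, ...]
    output_right: tuple[int, ...]
    selectivity_left: tuple[float, ...] = ()
    selectivity_right: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        areas = set(self.output_left) | set(self.output_right)
        if self.input_left in areas or self.input_right in areas:
            raise ValueError("input electrodes must not belong to output areas")
        if set(self.output_left) & set(self.output_right):
            raise ValueError("output areas must be disjoint")
        for area in (self.output_left, self.output_right):
            if not (8 <= len(area) <= 10):
                raise ValueError("each output area holds 8-10 electrodes")

    @property
    def mean_selectivity(self) -> float:
        both = self.selectivity_left + self.selectivity_right
        return float(np.mean(both)) if both else float("nan")


def bisector_distance(area_a: float, area_b: float) -> float:
    """Distance of the PSTH-area point (area_A, area_B) from the bisector."""
    return abs(area_a - area_b) / np.sqrt(2.0)


def select_io(psth_map: PSTHMap | pd.DataFrame, n_outputs: int = 8) -> IOAssignment:
    """Choose the input pair and output areas from the PSTH bisector plot.

    For every pair of candidate inputs (A, B) each recording electrode
    gives a point (area_A, area_B); its selectivity is the distance from
    the bisector, |area_A - area_B|/sqrt(2).  The pair maximizing the
    summed selectivity of the best ``n_outputs`` electrodes on each side
    of the bisector wins; those electrodes become the two output areas
    (electrodes nearer the A axis respond to A and drive the left wheel).
    Accepts a :class:`PSTHMap` or its PSTH-area table directly.
    """
    areas = psth_map.areas() if isinstance(psth_map, PSTHMap) else psth_map
    stims = list(areas.columns)
    if len(stims) < 2:
        raise ProtocolError("I/O selection needs at least two stimulation sites")
    best = None
    for i, a in enumerate(stims):
        for b in stims[i + 1:]:
            recs = [r for r in areas.index if r not in (a, b)]
            d = {r: bisector_distance(areas.at[r, a], areas.at[r, b]) for r in recs}
            side_a = sorted(
                (r for r in recs if areas.at[r, a] > areas.at[r, b] and d[r] > 0),
                key=lambda r: (-d[r], r),
            )
            side_b = sorted(
                (r for r in recs if areas.at[r, b] > areas.at[r, a] and d[r] > 0),
                key=lambda r: (-d[r], r),
            )
            if len(side_a) < n_outputs or len(side_b) < n_outputs:
                continue
            sel_a = side_a[:n_outputs]
            sel_b = side_b[:n_outputs]
            score = sum(d[r] for r in sel_a) + sum(d[r] for r in sel_b)
            key = (score, -a, -b)
            if best is None or key > best[0]:
                best = (key, a, b, sel_a, sel_b, d)
    if best is None:
        raise ProtocolError(
            f"no input pair yields {n_outputs} selective electrodes per side"
        )
    _, a, b, sel_a, sel_b, d = best
    return IOAssignment(
        input_left=a,
        input_right=b,
        output_left=tuple(sel_a),
        output_right=tuple(sel_b),
        selectivity_left=tuple(d[r] for r in sel_a),
        selectivity_right=tuple(d[r] for r in sel_b),
    )


def calibrate_decoding(
    spont: SpikeData,
    io: IOAssignment,
    omega_min: float = 20.0,
    omega_max: float = 40.0,
    quantile: float = 0.9,
    f_floor: float = 0.5,
    window_s: float = CONTROL_WINDOW_S,
) -> tuple[DecodingParams, DecodingParams]:
    """Set each side's f_max from the observed spontaneous window rates.

    The experimenter fixes omega and f_max per wheel before a run; here
    f_max is the given quantile of the area's spontaneous per-window
    firing rate (floored), so that the two wheels are balanced against
    baseline asymmetries and burst-driven rate excursions saturate either
    wheel with comparable probability.
    """
    n_win = int(spont.duration / window_s)
    if n_win < 100:
        raise ValueError("calibration needs a spontaneous recording of >= 10 s")

    def f_max_for(area: tuple[int, ...]) -> float:
        f = [
            area_firing_rate(spont, area, spont.t_start + k * window_s, window_s)
            for k in range(n_win)
        ]
        return max(f_floor, float(np.quantile(f, quantile)))

    left = DecodingParams(
        electrodes=io.output_left,
        omega_min=omega_min,
        omega_max=omega_max,
        f_max=f_max_for(io.output_left),
        window_s=window_s,
    )
    right = DecodingParams(
        electrodes=io.output_right,
        omega_min=omega_min,
        omega_max=omega_max,
        f_max=f_max_for(io.output_right),
        window_s=window_s,
    )
    return left, right


# --------------------------------------------------------------------------
# Phases 3-4: the closed-loop run (and open / empty controls)
# --------------------------------------------------------------------------


@dataclass
class SessionConfig:
    """One robot run's configuration."""

    mode: str = "closed"                  # closed | open | empty
    plasticity: bool = False
    duration_s: float = 1200.0            # 20-min run by default
    seed: int = 0
    window_s: float = CONTROL_WINDOW_S
    decoding_left: DecodingParams | None = None
    decoding_right: DecodingParams | None = None
    coding_left: CodingParams | None = None
    coding_right: CodingParams | None = None
    freeze_during_tetanus: bool = True
    noise_sd_uv: float = 10.0             # empty-mode noise amplitude
    start_heading: float = 0.35           # radians; avoids axis-aligned symmetry

    def __post_init__(self) -> None:
        if self.mode not in ("closed", "open", "empty"):
            raise ValueError(f"unknown session mode {self.mode!r}")
        if self.duration_s <= 0:
            raise ValueError("run duration must be positive")


@dataclass
class CollisionEvent:
    time: float
    x: float
    y: float
    side: str


@dataclass
class RelocationEvent:
    time: float
    x: float
    y: float


@dataclass
class TetanusEvent:
    time: float
    electrode: int
    side: str


@dataclass
class RunLog:
    """Time-aligned record of one robot run."""

    config: SessionConfig
    windows: pd.DataFrame                 # t, r_left, r_right, s_left, s_right,
                                          # f_left, f_right, omega_left, omega_right
    trajectory: np.ndarray                # (n, 4): t, x, y, heading (10 Hz)
    collisions: list[CollisionEvent]
    relocations: list[RelocationEvent]
    tetani: list[TetanusEvent]
    spikes: SpikeData | None = None

    @property
    def duration(self) -> float:
        return self.config.duration_s

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.windows.to_csv(directory / "windows.tsv", sep="\t", index=False)
        np.savetxt(
            directory / "trajectory.tsv",
            self.trajectory,
            fmt="%.6f",
            delimiter="\t",
            header="t\tx\ty\theading",
            comments="",
        )
        with open(directory / "events.tsv", "w") as fh:
            fh.write("kind\ttime\ta\tb\tc\n")
            for ev in self.collisions:
                fh.write(f"collision\t{ev.time:.3f}\t{ev.x:.3f}\t{ev.y:.3f}\t{ev.side}\n")
            for ev in self.relocations:
                fh.write(f"relocation\t{ev.time:.3f}\t{ev.x:.3f}\t{ev.y:.3f}\t\n")
            for ev in self.tetani:
                fh.write(f"tetanus\t{ev.time:.3f}\t{ev.electrode}\t{ev.side}\t\n")
        if self.spikes is not None:
            self.spikes.to_tsv(directory / "spikes.tsv")


class _EmptyMEA:
    """Noise-only signal source for the "empty" control condition.

    Detection events are the false positives of the peak-to-peak detector
    on pure Gaussian noise.  The per-electrode event rate is measured at
    session start by running the actual detection path on synthesized
    noise (the same calibration that sets thresholds in phase 1), then
    events are drawn as a Poisson process at that measured rate.
    """

    def __init__(self, electrodes: list[int], noise_sd: float, seed: int):
        self.electrodes = electrodes
        self.rng = np.random.default_rng(seed)
        params = signals.DetectionParams()
        calib = signals.synthesize_trace(
            np.empty(0), noise_sd, duration=60.0, seed=int(self.rng.integers(2**31 - 1))
        )
        thr = signals.compute_threshold(calib, params)
        fp = signals.detect_spikes(calib, thr, params)
        self.fp_rate_hz = len(fp) / calib.duration
        self.time = 0.0

    def window(self, duration: float) -> SpikeData:
        t0 = self.time
        trains = {}
        for e in self.electrodes:
            n = self.rng.poisson(self.fp_rate_hz * duration)
            if n:
                trains[e] = np.sort(self.rng.uniform(t0, t0 + duration, n))
        self.time = t0 + duration
        return SpikeData(trains, t0, self.time)


def run_session(
    cfg: SessionConfig,
    culture: CultureState | None,
    arena: Arena,
    io: IOAssignment | None,
) -> RunLog:
    """Run one robot session (phase 3 or 4, or a control condition).

    Per 100 ms window: sense -> per-side proximity -> encode and schedule
    stimulation (closed mode only) -> advance the culture in lockstep ->
    per-area firing rates -> decode wheel speeds -> step the robot at
    10 Hz.  Collisions trigger relocation and, with the plasticity flag,
    a same-side tetanus during which stimulation is suspended and the
    robot is held in place.
    """
    if cfg.mode != "empty":
        if culture is None or io is None:
            raise ValueError(f"{cfg.mode} mode requires a culture and an I/O assignment")
    rng = np.random.default_rng(cfg.seed)

    if cfg.mode == "empty":
        electrodes_l = tuple(range(8))
        electrodes_r = tuple(range(8, 16))
        source = _EmptyMEA(
            list(electrodes_l + electrodes_r),
            cfg.noise_sd_uv,
            int(rng.integers(2**31 - 1)),
        )
    else:
        electrodes_l = io.output_left
        electrodes_r = io.output_right
        source = None

    dec_l = cfg.decoding_left or DecodingParams(electrodes=electrodes_l)
    dec_r = cfg.decoding_right or DecodingParams(electrodes=electrodes_r)
    cod_l = cfg.coding_left or (CodingParams(electrode=io.input_left) if io else None)
    cod_r = cfg.coding_right or (CodingParams(electrode=io.input_right) if io else None)
    inputs = {"left": cod_l.electrode, "right": cod_r.electrode} if io else {}

    c = arena.size / 2.0
    robot = RobotState(x=c, y=c, heading=cfg.start_heading)
    start_pose = RobotState(x=c, y=c, heading=cfg.start_heading)

    n_windows = int(round(cfg.duration_s / cfg.window_s))
    phase_l, phase_r = PulsePhase(), PulsePhase()
    f_prev_l = f_prev_r = 0.0
    tetanus_windows_left = 0
    tetanus_electrode: int | None = None
    queued_tetanus: str | None = None
    pending_pulses: list[StimPulse] = []

    rows = []
    traj = [(0.0, robot.x, robot.y, robot.heading)]
    collisions: list[CollisionEvent] = []
    relocations: list[RelocationEvent] = []
    tetani: list[TetanusEvent] = []
    spike_blocks: list[SpikeData] = []
    t_offset = culture.time if culture is not None else 0.0

    for k in range(n_windows):
        t = k * cfg.window_s
        # the signal source's clock is authoritative for pulse scheduling
        bio_t = source.time if cfg.mode == "empty" else culture.time

        readings = sense(arena, robot)
        r_l, r_r = readings.proximity_left, readings.proximity_right

        in_tetanus = tetanus_windows_left > 0
        s_l = s_r = 0.0
        w_end = bio_t + cfg.window_s - 1e-9
        window_pulses = [p for p in pending_pulses if p.time < w_end]
        pending_pulses = [p for p in pending_pulses if p.time >= w_end]
        if cfg.mode == "closed" and not in_tetanus:
            s_l = encode_stim_rate(r_l, cod_l)
            s_r = encode_stim_rate(r_r, cod_r)
            window_pulses += schedule_pulses(
                s_l, bio_t, cfg.window_s, phase_l, cod_l.electrode
            )
            window_pulses += schedule_pulses(
                s_r, bio_t, cfg.window_s, phase_r, cod_r.electrode
            )

        if cfg.mode == "empty":
            spikes = source.window(cfg.window_s)
        else:
            spikes = simulate_window(culture, cfg.window_s, window_pulses)
        spike_blocks.append(spikes)

        f_l = area_firing_rate(spikes, dec_l.electrodes, spikes.t_start, cfg.window_s)
        f_r = area_firing_rate(spikes, dec_r.electrodes, spikes.t_start, cfg.window_s)
        w_l = decode_wheel_speed(f_l, f_prev_l, dec_l)
        w_r = decode_wheel_speed(f_r, f_prev_r, dec_r)
        f_prev_l, f_prev_r = f_l, f_r

        if in_tetanus and cfg.freeze_during_tetanus:
            tetanus_windows_left -= 1
            if tetanus_windows_left == 0 and culture is not None:
                potentiate(culture, tetanus_electrode)
                tetanus_electrode = None
                if queued_tetanus is not None:
                    side = queued_tetanus
                    queued_tetanus = None
                    _start_tetanus(
                        side, inputs, culture, cfg, tetani, pending_pulses, t
                    )
                    tetanus_windows_left = int(round(TETANUS_DURATION_S / cfg.window_s))
                    tetanus_electrode = inputs[side]
        else:
            if in_tetanus:  # non-freezing variant still counts down
                tetanus_windows_left -= 1
                if tetanus_windows_left == 0 and culture is not None:
                    potentiate(culture, tetanus_electrode)
                    tetanus_electrode = None
            robot.omega_left, robot.omega_right = w_l, w_r
            robot = step_kinematics(robot, cfg.window_s)
            hit, side = detect_collision(arena, robot)
            if hit:
                collisions.append(CollisionEvent(t + cfg.window_s, robot.x, robot.y, side))
                robot = relocate_after_collision(
                    arena, np.asarray(traj), robot, fallback=start_pose
                )
                relocations.append(
                    RelocationEvent(t + cfg.window_s, robot.x, robot.y)
                )
                if cfg.plasticity and cfg.mode != "empty":
                    if tetanus_windows_left > 0:
                        queued_tetanus = queued_tetanus or side
                    else:
                        _start_tetanus(
                            side, inputs, culture, cfg, tetani, pending_pulses, t
                        )
                        tetanus_windows_left = int(
                            round(TETANUS_DURATION_S / cfg.window_s)
                        )
                        tetanus_electrode = inputs[side]

        traj.append((t + cfg.window_s, robot.x, robot.y, robot.heading))
        rows.append((t, r_l, r_r, s_l, s_r, f_l, f_r, w_l, w_r))
        if not np.all(np.isfinite(rows[-1])):
            raise FloatingPointError(f"non-finite loop quantity at window {k}")

    merged: dict[int, list[np.ndarray]] = {}
    for block in spike_blocks:
        for e, train in block.trains.items():
            merged.setdefault(e, []).append(train)
    all_spikes = SpikeData(
        {e: np.concatenate(parts) for e, parts in merged.items()},
        spike_blocks[0].t_start,
        spike_blocks[-1].t_stop,
    )
    windows = pd.DataFrame(
        rows,
        columns=[
            "t", "r_left", "r_right", "s_left", "s_right",
            "f_left", "f_right", "omega_left", "omega_right",
        ],
    )
    return RunLog(
        config=cfg,
        windows=windows,
        trajectory=np.asarray(traj),
        collisions=collisions,
        relocations=relocations,
        tetani=tetani,
        spikes=all_spikes,
    )


def _start_tetanus(side, inputs, culture, cfg, tetani, pending_pulses, t):
    electrode = inputs[side]
    start = culture.time  # next window begins here
    pending_pulses.extend(
        tetanus_on_collision(side, inputs, start)
    )
    tetani.append(TetanusEvent(t + cfg.window_s, electrode, side))
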