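"""Surrogate spiking culture on a multi-electrode array.

A current-based leaky integrate-and-fire (LIF) network with short-term
synaptic depression stands in for a dissociated hippocampal culture grown
over a 59-electrode MEA (8x8 grid, corners excluded, one reference site,
200 um pitch).  Depression is what terminates network bursts; an
independent low-rate background drive ignites them.  Two topologies are
supported:

* ``random`` -- distance-dependent connectivity over the whole culture
  area, producing synchronized network-wide bursts;
* ``modular`` -- the population is split by a horizontal midline into two
  compartments joined only by a small number of "bridge" synapses routed
  through two corridor positions, emulating a PDMS confinement mask with
  two microchannels.  Bursts then stay mostly compartment-confined and
  pairwise correlation across the midline drops.

Electrical stimulation is modelled as a suprathreshold current kick
delivered, with fixed probability per pulse, to every neuron within the
stimulation radius of the pulsed electrode.  A 20 Hz / 2 s tetanus
potentiates the outgoing excitatory weights of the recruited neurons
multiplicatively (gain ``eta``), clipped at a weight ceiling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "ElectrodeLayout",
    "SpikeData",
    "StimPulse",
    "CultureConfig",
    "CultureState",
    "build_culture",
    "simulate_window",
    "apply_tetanus",
    "potentiate",
]

# --------------------------------------------------------------------------
# Electrode layout
# --------------------------------------------------------------------------

ELECTRODE_PITCH_UM = 200.0
_CORNER_IDS = (11, 18, 81, 88)
_REFERENCE_ID = 15  # replaced by the ground electrode on the physical device


@dataclass(frozen=True)
class ElectrodeLayout:
    """59 active sites of an 8x8 MEA grid (corners + reference excluded).

    Electrode ids follow the column-row convention (id = 10*col + row,
    both 1-based); positions are in micrometres with 200 um pitch.
    ``compartment`` labels each electrode 'top' or 'bottom' when the
    culture is grown under a two-compartment confinement mask.
    """

    electrode_ids: np.ndarray          # (59,) int
    positions: np.ndarray              # (59, 2) float, um
    compartment: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.electrode_ids) != 59:
            raise ValueError(f"expected 59 electrodes, got {len(self.electrode_ids)}")
        if self.compartment is not None and len(self.compartment) != 59:
            raise ValueError("compartment labels must cover all electrodes")

    @classmethod
    def mea_8x8(cls, modular: bool = False) -> "ElectrodeLayout":
        ids, pos = [], []
        for col in range(1, 9):
            for row in range(1, 9):
                eid = 10 * col + row
                if eid in _CORNER_IDS or eid == _REFERENCE_ID:
                    continue
                ids.append(eid)
                pos.append(((col - 1) * ELECTRODE_PITCH_UM, (row - 1) * ELECTRODE_PITCH_UM))
        ids_arr = np.asarray(ids, dtype=np.int64)
        pos_arr = np.asarray(pos, dtype=np.float64)
        comp = None
        if modular:
            midline = pos_arr[:, 1].mean()
            comp = tuple("top" if y < midline else "bottom" for y in pos_arr[:, 1])
        return cls(ids_arr, pos_arr, comp)

    def index_of(self, electrode_id: int) -> int:
        idx = np.flatnonzero(self.electrode_ids == electrode_id)
        if idx.size == 0:
            raise KeyError(f"electrode {electrode_id} not in layout")
        return int(idx[0])

    def position_of(self, electrode_id: int) -> np.ndarray:
        return self.positions[self.index_of(electrode_id)]

    def compartment_of(self, electrode_id: int) -> str:
        if self.compartment is None:
            raise ValueError("layout carries no compartment labels")
        return self.compartment[self.index_of(electrode_id)]


# --------------------------------------------------------------------------
# Spike data container
# --------------------------------------------------------------------------


class SpikeData:
    """Per-electrode spike timestamps over a recording interval.

    The lossless event representation used throughout: a mapping
    electrode_id -> sorted array of spike times in seconds, plus the
    interval ``[t_start, t_stop)`` it covers.
    """

    def __init__(self, trains: Mapping[int, np.ndarray], t_start: float, t_stop: float):
        if t_stop < t_start:
            raise ValueError("t_stop must be >= t_start")
        self.trains = {int(k): np.asarray(v, dtype=np.float64) for k, v in trains.items()}
        self.t_start = float(t_start)
        self.t_stop = float(t_stop)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def electrodes(self) -> list[int]:
        return sorted(self.trains)

    def train(self, electrode_id: int) -> np.ndarray:
        return self.trains.get(int(electrode_id), np.empty(0))

    def n_spikes(self) -> int:
        return sum(len(v) for v in self.trains.values())

    def mean_firing_rates(self) -> dict[int, float]:
        """Spikes per second per electrode over the covered interval."""
        if self.duration <= 0:
            raise ValueError("zero-duration recording has no rates")
        return {e: len(t) / self.duration for e, t in self.trains.items()}

    def count_in(self, electrodes: Iterable[int], t0: float, t1: float) -> int:
        """Total spikes on ``electrodes`` within the half-open window [t0, t1)."""
        total = 0
        for e in electrodes:
            t = self.train(e)
            total += int(np.searchsorted(t, t1, "left") - np.searchsorted(t, t0, "left"))
        return total

    def concat(self, other: "SpikeData") -> "SpikeData":
        if abs(other.t_start - self.t_stop) > 1e-9:
            raise ValueError("recordings are not contiguous")
        trains: dict[int, np.ndarray] = {}
        for e in set(self.trains) | set(other.trains):
            trains[e] = np.concatenate([self.train(e), other.train(e)])
        return SpikeData(trains, self.t_start, other.t_stop)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Two-column tab-separated text (electrode_id, spike_time_s), time-sorted."""
        rows = []
        for e, t in self.trains.items():
            rows.append(np.column_stack([np.full(len(t), e, dtype=np.float64), t]))
        if rows:
            arr = np.concatenate(rows)
            arr = arr[np.argsort(arr[:, 1], kind="stable")]
        else:
            arr = np.empty((0, 2))
        with open(path, "w") as fh:
            fh.write(f"# t_start={self.t_start:.9g}\tt_stop={self.t_stop:.9g}\n")
            for e, t in arr:
                fh.write(f"{int(e)}\t{t:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpikeData":
        t_start, t_stop = 0.0, 0.0
        ids, times = [], []
        with open(path) as fh:
            header = fh.readline().strip()
            for part in header.lstrip("# ").split("\t"):
                key, val = part.split("=")
                if key == "t_start":
                    t_start = float(val)
                elif key == "t_stop":
                    t_stop = float(val)
            for line in fh:
                e, t = line.split("\t")
                ids.append(int(e))
                times.append(float(t))
        trains: dict[int, list[float]] = {}
        for e, t in zip(ids, times):
            trains.setdefault(e, []).append(t)
        return cls({e: np.sort(v) for e, v in trains.items()}, t_start, t_stop)

    def to_npz(self, path: str | Path) -> None:
        """Binary container for long runs: one dataset per electrode."""
        payload = {f"e{e}": t for e, t in self.trains.items()}
        payload["_interval"] = np.array([self.t_start, self.t_stop])
        np.savez_compressed(path, **payload)

    @classmethod
    def from_npz(cls, path: str | Path) -> "SpikeData":
        with np.load(path) as data:
            t0, t1 = data["_interval"]
            trains = {int(k[1:]): data[k] for k in data.files if k != "_interval"}
        return cls(trains, float(t0), float(t1))


# --------------------------------------------------------------------------
# Stimulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StimPulse:
    """A single biphasic voltage pulse delivered through one electrode."""

    electrode: int
    time: float                    # onset, s (absolute biological time)
    amplitude: float = 1.0         # model current units (relative kick scale)
    duration: float = 500e-6       # s; 500 us biphasic pulse
    kind: str = "probe"            # probe | sensory | tetanus

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.kind not in ("probe", "sensory", "tetanus"):
            raise ValueError(f"unknown pulse kind {self.kind!r}")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class CultureConfig:
    """Parameters of the surrogate culture.

    Membrane potentials are in mV-like model units (threshold 20, reset 0);
    times in seconds, distances in micrometres.
    """

    topology: str = "random"               # random | modular
    n_neurons: int = 400
    excitatory_fraction: float = 0.75      # cultures are 70-80% excitatory
    n_bridges: int = 20                    # modular only: inter-compartment synapses
    seed: int = 0

    # LIF membrane
    tau_m: float = 0.030                   # s
    v_threshold: float = 20.0
    v_reset: float = 0.0
    refractory: float = 0.003              # s
    dt: float = 0.5e-3                     # s, fixed Euler step

    # Connectivity (probability decays gently with distance; dissociated
    # cultures grow mm-scale axons, so the decay length exceeds the array)
    conn_p_max: float = 0.2
    conn_lambda_um: float = 2000.0
    # confined compartments develop denser, shorter-range local circuitry
    modular_p_max: float = 0.6
    modular_lambda_um: float = 300.0
    w_exc: float = 4.0                     # mean excitatory kick, model mV
    inhibition_ratio: float = 3.0          # |w_inh| = ratio * w_exc
    w_ceiling: float = 18.0                # hard upper bound on any excitatory weight
    bridge_weight: float = 10.0            # modular corridor synapses

    # Short-term depression (terminates bursts)
    depression_u: float = 0.5              # fraction of resources used per spike
    tau_recovery: float = 2.0              # s

    # Background drive
    bg_rate: float = 30.0                  # Hz of background kicks per neuron
    bg_amp: float = 4.2                    # model mV per background kick

    # Intrinsically excitable subpopulation (ignites bursts)
    pacemaker_fraction: float = 0.1
    pacemaker_bias: tuple[float, float] = (8.0, 13.0)  # per-neuron bias range, model mV

    # Slow excitability drift (minute-scale firing-rate nonstationarity of
    # cultures): independent Ornstein-Uhlenbeck modulation of each
    # pacemaker's bias
    drift_sd: float = 0.3                  # relative modulation amplitude
    drift_tau: float = 60.0                # s

    # Electrode coupling
    capture_radius_um: float = 100.0       # half the pitch: recording areas disjoint
    stim_radius_um: float = 150.0
    stim_recruit_prob: float = 0.8         # per-pulse recruitment probability

    # Tetanic potentiation
    eta: float = 0.2                       # multiplicative gain per tetanus
    potentiation_decay_tau: float | None = None   # s; None = no decay
    pathway_specific: bool = True          # False = network-wide strengthening

    # Culture geometry (um); the electrode grid spans [0, 1400]^2
    extent: tuple[float, float, float, float] = (-100.0, 1500.0, -100.0, 1500.0)

    def __post_init__(self) -> None:
        if self.topology not in ("random", "modular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0.0 < self.excitatory_fraction < 1.0):
            raise ValueError("excitatory_fraction must be in (0, 1)")
        if self.topology == "modular" and self.n_bridges < 0:
            raise ValueError("n_bridges must be >= 0")
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        for name in ("tau_m", "refractory", "dt", "tau_recovery", "w_ceiling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bg_rate < 0 or self.bg_amp < 0:
            raise ValueError("background drive must be non-negative")
        if not (0.0 < self.depression_u <= 1.0):
            raise ValueError("depression_u must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        data["extent"] = list(self.extent)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CultureConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("extent", "pacemaker_bias"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# --------------------------------------------------------------------------
# Culture state
# --------------------------------------------------------------------------


@dataclass
class CultureState:
    config: CultureConfig
    layout: ElectrodeLayout
    neuron_pos: np.ndarray             # (n, 2) um
    is_excitatory: np.ndarray          # (n,) bool
    bias: np.ndarray                   # (n,) resting drive; nonzero for pacemakers
    drift: np.ndarray                  # (n,) slow OU modulation of the bias
    weights: np.ndarray                # (n, n) base weights, W[i, j] = i -> j
    potentiation: np.ndarray           # (n,) outgoing multiplicative factor
    v: np.ndarray                      # (n,) membrane potential
    depression: np.ndarray             # (n,) synaptic resource in [0, 1]
    refrac_steps_left: np.ndarray      # (n,) int32
    syn_input: np.ndarray              # (n,) delayed synaptic current buffer
    neuron_electrode: np.ndarray       # (n,) index into layout, -1 = uncaptured
    rng: np.random.Generator
    time: float = 0.0

    def effective_weights(self) -> np.ndarray:
        """Base weights scaled by per-neuron potentiation, clipped at ceiling."""
        w = self.weights * self.potentiation[:, None]
        np.clip(w, None, self.config.w_ceiling, out=w)
        # inhibitory rows are negative; the ceiling only caps excitation
        return w

    def neurons_near(self, electrode_id: int, radius_um: float) -> np.ndarray:
        p = self.layout.position_of(electrode_id)
        d = np.hypot(*(self.neuron_pos - p).T)
        return np.flatnonzero(d <= radius_um)


def build_culture(config: CultureConfig, layout: ElectrodeLayout) -> CultureState:
    """Construct a seeded culture on the given electrode layout.

    Neurons are scattered uniformly over the culture extent; connection
    probability decays exponentially with somatic distance.  In modular
    mode all cross-midline connections are removed and replaced by
    ``n_bridges`` synapses routed through two corridor positions.
    """
    if config.topology == "modular" and layout.compartment is None:
        raise ValueError("modular culture requires a layout with compartment labels")

    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    x0, x1, y0, y1 = config.extent
    pos = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])

    n_exc = int(round(n * config.excitatory_fraction))
    is_exc = np.zeros(n, dtype=bool)
    is_exc[rng.permutation(n)[:n_exc]] = True

    # a sparse subpopulation sits near threshold and fires spontaneously,
    # seeding network bursts (burst ignition sites of mature cultures)
    bias = np.zeros(n)
    n_pace = int(round(n * config.pacemaker_fraction))
    pacemakers = rng.permutation(n)[:n_pace]
    bias[pacemakers] = rng.uniform(*config.pacemaker_bias, n_pace)

    # distance-dependent connectivity
    dx = pos[:, 0][:, None] - pos[:, 0][None, :]
    dy = pos[:, 1][:, None] - pos[:, 1][None, :]
    dist = np.hypot(dx, dy)
    p_conn = config.conn_p_max * np.exp(-dist / config.conn_lambda_um)
    np.fill_diagonal(p_conn, 0.0)

    midline = 0.5 * (y0 + y1)
    if config.topology == "modular":
        # confinement walls redirect neurite growth: compartments develop a
        # denser, shorter-range local circuit than an unconfined culture
        same_side = (pos[:, 1] < midline)[:, None] == (pos[:, 1] < midline)[None, :]
        p_local = config.modular_p_max * np.exp(-dist / config.modular_lambda_um)
        p_conn = np.where(same_side, p_local, 0.0)
    adj = rng.random((n, n)) < p_conn

    w = np.zeros((n, n))
    # heterogeneous synaptic strengths; inhibition is stronger per synapse
    mag = rng.gamma(4.0, scale=config.w_exc / 4.0, size=(n, n))
    w[adj & is_exc[:, None]] = mag[adj & is_exc[:, None]]
    w[adj & ~is_exc[:, None]] = -config.inhibition_ratio * mag[adj & ~is_exc[:, None]]
    np.clip(w, -config.w_ceiling * config.inhibition_ratio, config.w_ceiling, out=w)

    if config.topology == "modular" and config.n_bridges > 0:
        # bridge synapses through two corridor x-positions on the midline
        span = x1 - x0
        corridors = np.array([x0 + span / 3.0, x0 + 2.0 * span / 3.0])
        top = np.flatnonzero(pos[:, 1] < midline)
        bottom = np.flatnonzero(pos[:, 1] >= midline)
        exc_top = top[is_exc[top]]
        exc_bottom = bottom[is_exc[bottom]]
        for b in range(config.n_bridges):
            cx = corridors[b % 2]
            src_pool, dst_pool = (exc_top, exc_bottom) if b % 2 == 0 else (exc_bottom, exc_top)
            # prefer neurons near the corridor mouth on each side
            src_w = np.exp(-np.abs(pos[src_pool, 0] - cx) / 150.0)
            dst_w = np.exp(-np.abs(pos[dst_pool, 0] - cx) / 150.0)
            src = rng.choice(src_pool, p=src_w / src_w.sum())
            dst = rng.choice(dst_pool, p=dst_w / dst_w.sum())
            w[src, dst] = config.bridge_weight

    # nearest electrode within the capture radius records a neuron's spikes
    d_to_el = np.hypot(
        pos[:, 0][:, None] - layout.positions[:, 0][None, :],
        pos[:, 1][:, None] - layout.positions[:, 1][None, :],
    )
    nearest = np.argmin(d_to_el, axis=1)
    captured = d_to_el[np.arange(n), nearest] <= config.capture_radius_um
    neuron_electrode = np.where(captured, nearest, -1).astype(np.int64)

    return CultureState(
        config=config,
        layout=layout,
        neuron_pos=pos,
        is_excitatory=is_exc,
        bias=bias,
        drift=np.zeros(n),
        weights=w,
        potentiation=np.ones(n),
        v=np.zeros(n),
        depression=np.ones(n),
        refrac_steps_left=np.zeros(n, dtype=np.int32),
        syn_input=np.zeros(n),
        neuron_electrode=neuron_electrode,
        rng=rng,
        time=0.0,
    )


# --------------------------------------------------------------------------
# Simulation kernel
# --------------------------------------------------------------------------


@njit(cache=True)
def _lif_kernel(
    v, x, refrac, syn_in, w, bias,
    n_steps, dt, tau_m, v_th, v_reset, refrac_steps,
    dep_u, tau_rec, bg_lam, bg_amp, stim_kick,
    pulse_steps, pulse_ptr, recruited,
    spike_t, spike_i, seed, t0,
):  # pragma: no cover - exercised via simulate_window
    np.random.seed(seed)
    n = v.shape[0]
    decay = dt / tau_m
    rec = dt / tau_rec
    count = 0
    p_idx = 0
    for step in range(n_steps):
        # membrane leak toward per-neuron bias + delayed synaptic input
        for i in range(n):
            if refrac[i] > 0:
                refrac[i] -= 1
                v[i] = v_reset
            else:
                v[i] += (bias[i] - v[i]) * decay + syn_in[i]
            syn_in[i] = 0.0
            x[i] += (1.0 - x[i]) * rec

        # background drive: Poisson-distributed kicks across the population
        k = np.random.poisson(bg_lam)
        for _ in range(k):
            i = np.random.randint(0, n)
            if refrac[i] == 0:
                v[i] += bg_amp

        # electrical stimulation scheduled at this step
        while p_idx < pulse_steps.shape[0] and pulse_steps[p_idx] == step:
            for j in range(pulse_ptr[p_idx], pulse_ptr[p_idx + 1]):
                i = recruited[j]
                if refrac[i] == 0:
                    v[i] += stim_kick
            p_idx += 1

        # threshold crossing -> spike, reset, propagate with depression
        for i in range(n):
            if refrac[i] == 0 and v[i] >= v_th:
                spike_t[count] = t0 + (step + 1) * dt
                spike_i[count] = i
                count += 1
                v[i] = v_reset
                refrac[i] = refrac_steps
                xi = x[i]
                for j in range(n):
                    wij = w[i, j]
                    if wij != 0.0:
                        syn_in[j] += wij * xi
                x[i] = xi * (1.0 - dep_u)
    return count


_CHUNK_S = 2.0


def simulate_window(
    state: CultureState, duration: float, pulses: Sequence[StimPulse] = ()
) -> SpikeData:
    """Advance the culture by ``duration`` seconds and return recorded spikes.

    Each stimulus pulse injects a suprathreshold current kick into the
    neurons within the stimulation radius of its electrode, each recruited
    independently with the configured probability.  A neuron's spike is
    recorded on an electrode iff the neuron lies within the capture radius.
    Deterministic given the culture's seed and the pulse schedule.
    """
    cfg = state.config
    if duration < 0:
        raise ValueError("duration must be non-negative")
    t_begin = state.time
    if duration == 0:
        return SpikeData({}, t_begin, t_begin)
    for p in sorted(pulses, key=lambda q: q.time):
        if not (t_begin - 1e-9 <= p.time < t_begin + duration - 1e-9):
            raise ValueError(
                f"pulse at t={p.time:.6f} outside window [{t_begin:.6f}, {t_begin + duration:.6f})"
            )

    w_eff = state.effective_weights()
    dt = cfg.dt
    refrac_steps = max(1, int(round(cfg.refractory / dt)))
    bg_lam = cfg.bg_rate * dt * cfg.n_neurons
    stim_kick = 1.5 * cfg.v_threshold
    pulses = sorted(pulses, key=lambda q: q.time)

    all_t: list[np.ndarray] = []
    all_i: list[np.ndarray] = []
    n_total_steps = int(round(duration / dt))
    step_offset = 0
    while step_offset < n_total_steps:
        n_steps = min(int(round(_CHUNK_S / dt)), n_total_steps - step_offset)
        chunk_t0 = t_begin + step_offset * dt
        chunk_t1 = chunk_t0 + n_steps * dt
        chunk_pulses = [p for p in pulses if chunk_t0 - 1e-9 <= p.time < chunk_t1 - 1e-9]

        pulse_steps = np.empty(len(chunk_pulses), dtype=np.int64)
        ptr = [0]
        recruited: list[np.ndarray] = []
        for k, p in enumerate(chunk_pulses):
            pulse_steps[k] = min(n_steps - 1, int(round((p.time - chunk_t0) / dt)))
            near = state.neurons_near(p.electrode, cfg.stim_radius_um)
            hit = near[state.rng.random(near.size) < cfg.stim_recruit_prob]
            recruited.append(hit)
            ptr.append(ptr[-1] + hit.size)
        ptr_arr = np.asarray(ptr, dtype=np.int64)
        recruited_arr = (
            np.concatenate(recruited).astype(np.int64) if recruited else np.empty(0, np.int64)
        )

        # slow excitability drift, updated per chunk (OU process)
        if cfg.drift_sd > 0 and cfg.drift_tau > 0:
            a = n_steps * dt / cfg.drift_tau
            state.drift += -state.drift * a + cfg.drift_sd * np.sqrt(2.0 * a) * state.rng.normal(
                size=state.drift.shape
            )
        bias_eff = state.bias * np.maximum(0.0, 1.0 + state.drift)

        # hard physical cap: one spike per refractory period per neuron
        cap = cfg.n_neurons * (n_steps // refrac_steps + 2)
        spike_t = np.empty(cap)
        spike_i = np.empty(cap, dtype=np.int64)
        kernel_seed = int(state.rng.integers(0, 2**31 - 1))
        count = _lif_kernel(
            state.v, state.depression, state.refrac_steps_left, state.syn_input, w_eff,
            bias_eff,
            n_steps, dt, cfg.tau_m, cfg.v_threshold, cfg.v_reset, refrac_steps,
            cfg.depression_u, cfg.tau_recovery, bg_lam, cfg.bg_amp, stim_kick,
            pulse_steps, ptr_arr, recruited_arr,
            spike_t, spike_i, kernel_seed, chunk_t0,
        )
        all_t.append(spike_t[:count].copy())
        all_i.append(spike_i[:count].copy())
        step_offset += n_steps

    if np.isnan(state.v).any():
        raise FloatingPointError("NaN in membrane variables")

    times = np.concatenate(all_t)
    nids = np.concatenate(all_i)
    elec = state.neuron_electrode[nids]
    trains: dict[int, np.ndarray] = {}
    for k in np.unique(elec):
        if k < 0:
            continue
        trains[int(state.layout.electrode_ids[k])] = np.sort(times[elec == k])
    state.time = t_begin + n_total_steps * dt
    _decay_potentiation(state, n_total_steps * dt)
    return SpikeData(trains, t_begin, state.time)


def _decay_potentiation(state: CultureState, elapsed: float) -> None:
    tau = state.config.potentiation_decay_tau
    if tau is not None and elapsed > 0:
        f = np.exp(-elapsed / tau)
        state.potentiation = 1.0 + (state.potentiation - 1.0) * f


# --------------------------------------------------------------------------
# Tetanus
# --------------------------------------------------------------------------


def apply_tetanus(
    state: CultureState,
    electrode: int,
    rate: float = 20.0,
    duration: float = 2.0,
    start_time: float | None = None,
) -> list[StimPulse]:
    """Schedule a tetanic pulse train (default 20 Hz for 2 s) on one electrode.

    Returns the pulse train (``rate * duration`` pulses at regular spacing,
    starting at ``start_time`` or the culture's current time).  After those
    pulses have been simulated, call :func:`potentiate` to apply the
    weight-strengthening rule.
    """
    state.layout.index_of(electrode)  # raises if absent
    t0 = state.time if start_time is None else start_time
    n_pulses = int(round(rate * duration))
    period = 1.0 / rate
    return [
        StimPulse(electrode=electrode, time=t0 + k * period, kind="tetanus")
        for k in range(n_pulses)
    ]


def potentiate(state: CultureState, electrode: int, eta: float | None = None) -> None:
    """Multiplicatively strengthen outgoing excitatory weights after a tetanus.

    In pathway-specific mode only the excitatory neurons within the
    stimulation radius of the tetanized electrode are potentiated; in
    network-wide mode every excitatory neuron is.  Effective weights are
    clipped at the configured ceiling.
    """
    cfg = state.config
    gain = cfg.eta if eta is None else eta
    if gain == 0:
        return
    if cfg.pathway_specific:
        area = state.neurons_near(electrode, cfg.stim_radius_um)
        area = area[state.is_excitatory[area]]
    else:
        area = np.flatnonzero(state.is_excitatory)
    state.potentiation[area] *= 1.0 + gain
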