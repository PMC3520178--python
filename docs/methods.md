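# Methods

This note documents the models inside `hybrot`, the parameter choices
that matter, what the surrogate culture does and does not emulate, and
the numerical conventions. Units: seconds, micrometres, pixels; membrane
quantities are in mV-like model units with a firing threshold of 20.

## Surrogate culture

### Neuron and synapse model

Current-based leaky integrate-and-fire neurons on a fixed 0.5 ms Euler
grid:

    dV/dt = (bias − V)/τ_m + synaptic input,   spike when V ≥ 20, reset to 0

with τ_m = 30 ms and a 3 ms absolute refractory period. Each presynaptic
spike delivers an instantaneous kick `w_ij · x_i` one step later, where
`x_i ∈ [0, 1]` is the presynaptic short-term-depression resource:
`x → x(1 − U)` on each spike (U = 0.5) and recovers with τ_rec = 2 s.
Depression is what terminates network bursts; its recovery time also sets
how quickly evoked responses regenerate under repeated stimulation, which
is why the closed-loop stimulation ceiling (2 Hz) sits near 1/τ_rec.

Excitatory kicks are gamma-distributed with mean 4 (shape 4); inhibitory
synapses are 3× stronger and sign-inverted; 75% of neurons are
excitatory. Effective excitatory weights are clipped at a ceiling of 18.

### Drive and burst ignition

Every neuron receives independent background kicks (30 Hz, amplitude
4.2). On its own this keeps the population far below threshold; network
bursts are ignited by a sparse intrinsically excitable subpopulation
(10% of neurons) whose resting bias is drawn uniformly from [8, 13],
placing them within noise reach of threshold. This mirrors the burst
initiation sites of mature dissociated cultures. Each pacemaker's bias
is additionally modulated by an independent Ornstein–Uhlenbeck process
(relative SD 0.3, τ = 60 s) emulating the minute-scale firing-rate
nonstationarity of real cultures.

### Topologies

Neurons are scattered uniformly over a 1600×1600 µm field centred on the
electrode grid.

* **Random**: connection probability `0.2 · exp(−d/2000 µm)` — nearly
  uniform across the array (dissociated cultures grow mm-scale axons),
  mean in-degree ≈ 50. Bursts are network-wide and strongly synchronized.
* **Modular**: the field is split at the horizontal midline; within a
  compartment the probability is `0.6 · exp(−d/300 µm)` (confinement
  walls redirect neurite growth into a denser, shorter-range local
  circuit with a similar in-degree), and exactly `n_bridges` = 20
  excitatory synapses cross the midline, routed through two corridor
  positions at 1/3 and 2/3 of the width (the two microchannels of the
  confinement mask). Compartments burst largely independently.

The two connectivity ranges are deliberate: local wiring inside
compartments makes single-pulse responses graded and reliable (needed
for closed-loop steering), while the long-range wiring of the
unconfined culture removes spatial response structure, so that its
input/output selectivity reflects only the intrinsic heterogeneity of a
sparse random graph.

### Electrode coupling and stimulation

A neuron's spikes are recorded on the nearest electrode if it lies
within the 100 µm capture radius (half the 200 µm pitch, so recording
areas never overlap); ~78% of neurons are captured. A stimulus pulse
recruits each neuron within 150 µm of its electrode independently with
probability 0.8 and drives it suprathreshold — variable electrical
recruitment of the local population.

### Tetanus and potentiation

A tetanus is 40 pulses at 20 Hz (2 s). After its delivery the outgoing
weights of the excitatory neurons in the stimulated area are multiplied
by (1 + η), η = 0.2 by default, clipped at the weight ceiling. The
direction (strengthening) is the modelled claim; the magnitude of η is a
free parameter — no quantitative effect size is available to pin it.
A network-wide mode (`pathway_specific=False`) and an optional
exponential decay of the potentiation factor are exposed because the
persistence and spatial extent of the real effect are uncertain; the
default is pathway-specific and non-decaying within a session.

The recommended potentiation readout is the *early* (first 100 ms) PSTH
area of the stimulated compartment, which isolates the strengthened
synaptic pathway; full 600 ms areas include burst reverberation whose
trial-to-trial variance can mask a +20% pathway change in a single
40-probe session.

## Signal path

Raw traces are synthesized at 10 kHz: a stereotyped ~1 ms biphasic spike
waveform (negative lobe then positive overshoot, scaled to a requested
peak-to-peak amplitude) plus channel noise plus large saturating biphasic
artifacts at stimulus times. The channel noise is a Gaussian mixture of
a fast white component and a slow local-field/drift component (default
half the variance each, slow component low-passed at 10 Hz); the total
sample SD equals the requested `noise_sd`. This matters quantitatively:
a millisecond-scale peak-to-peak detector thresholded at 6.5× the
*raw-trace* SD then operates at ≈ 9× the fast-noise SD, giving a
false-positive rate far below 0.1 events/s — on purely white noise of
the same total SD the same threshold would false-positive at ~0.5/s,
which is not how raw MEA channels behave.

Detection: per-channel threshold = k × (median |x| / 0.6745) (median
absolute deviation resists spike contamination), k = 6.5; the
peak-to-peak excursion over a sliding 2 ms window is compared with the
threshold; each contiguous supra-threshold run yields one event,
time-stamped at the absolute-maximum deflection, and further events are
suppressed for a 1 ms dead time. The rule is invariant to a polarity
flip. Blanking removes events in the half-open interval [stim,
stim + 4 ms).

The control loop consumes spike events directly from the surrogate (the
loop's data is a series of time stamps); trace synthesis + detection is
validated by a dedicated end-to-end path (≥95% recovery at peak-to-peak
SNR 10) rather than being run inside the loop, which keeps sessions fast.
The empty-MEA control draws its "detections" as a Poisson process whose
rate is measured at session start by running the real detector on 60 s
of synthesized noise — with the LFP-aware noise model this measured rate
is typically zero, and the empty robot runs almost exactly straight.

## Robot and arena

400×400 px occupancy map with a circular boundary (radius 199 px so the
outer pixel ring is occupied) and, by default, three round obstacles of
radius 15–30 px placed disjointly at seeded random positions, keeping a
40 px free disc at the centre where runs start. Collision and clearance
queries use a Euclidean distance transform of the free space.

Six sensors at ±30°, ±45°, ±90° from the heading ray-cast at 0.5 px
steps; reading = clamp((d_centre − 5)/400, 0, 1), i.e. 0 at contact.
The per-side proximity fed to the coder is r = 1 − mean(same-side
readings), 1 at contact. Positive angular offsets are the robot's left
under the kinematic convention dθ/dt = (ω_R − ω_L)/L: the faster wheel
is on the obstacle side, so the robot turns away. The axle width
L = 10 px (the robot diameter; not otherwise constrained) and motion is
integrated exactly along circular arcs at 10 Hz.

Collision: centre within 5 px (the robot radius) of occupied space; the
contact side is the side with larger proximity, ties broken to the left.
Relocation: the most recent trajectory sample with ≥ 20 px clearance,
heading preserved; hence no inter-hit path can be shorter than
20 − 5 = 15 px. Relocation preserves heading because nothing indicates
re-orientation; a perfectly straight (empty-MEA) robot therefore
re-approaches the same contact repeatedly, and its mean inter-hit
distance is a *single* draw of the contact geometry (≈ 15/sin of the
incidence angle) rather than an average — the main source of variance in
the empty condition (see Limitations).

## Transduction and protocol

Decoding and coding follow the linear rate equations quoted in the
README, in 100 ms non-overlapping windows; `f` is spikes per window per
electrode, so `f^MAX` is independent of the area size. Stimulation
pulses are placed regularly at period 1/s with the phase carried across
windows (delivered count per interval within one pulse of rate ×
interval). Tetani never overlap: at most one additional tetanus queues
during an ongoing one, and the robot is held at its relocated pose while
a tetanus is delivered (configurable).

Session phases: (1) ≥300 s spontaneous screening — electrodes with MFR
> 0.1 spikes/s ranked ascending by mean pairwise C_peak (least
synchronized first), top 8 kept; (2) serial probing, 40 stimuli per
candidate (ISI 5 s nominally; scaled sessions use ≥0.7 s, chosen so the
600 ms PSTH windows of successive stimuli cannot overlap — note 0.5 s
would violate that); (3–4) 20 min closed-loop runs without/with the
tetanus rule (scaled studies use 300 s); (5) evaluation.

I/O selection: for every candidate pair (A, B), each recording
electrode's PSTH areas give a point (area_A, area_B) and a selectivity
|area_A − area_B|/√2 (distance from the bisector). The pair maximizing
the summed selectivity of the best 8 electrodes on each side wins; the
electrodes nearer the A axis form the output area that drives the wheel
on A's side. Pair ranking by summed top-8 selectivity is this package's
operationalization of "keep the selective pathways"; output areas are
fixed at 8 electrodes (8–10 accepted).

Decoder calibration: each side's `f^MAX` is set to the 0.9 quantile of
that area's spontaneous per-window rate (floored at 0.5), with
ω ∈ [20, 40] px/s. These are the quantities an experimenter fixes per
preparation before a run; quantile calibration balances the two wheels
against baseline rate asymmetries (without it, a persistent left/right
rate imbalance turns the robot in stable circles) and lets burst-driven
rate excursions saturate either wheel with comparable probability.
Coding uses s ∈ [0.2, 2.0] Hz: the ceiling sits near the synaptic
recovery rate, above which evoked responses depress away.

## Statistics

Group contrasts use the Mann–Whitney U test one-sided in the direction
under test; the generic two-group helper first checks normality
(Lilliefors/Kolmogorov–Smirnov with estimated parameters) on both
samples and uses a t-test (the two-group case of one-way ANOVA) only
when both pass, α = 0.05. Latency samples exclude stimuli with no spike
within the 600 ms window (censoring at 600 ms is available behind a
flag). C_peak is the mean of the correlogram over its maximum bin ± 2
bins (peak-only and integral variants exist); correlograms use
T = 50 ms, Δτ = 1 ms, normalized by √(N_x N_y).

## Problem sizes and runtimes

The packaged studies are desk-scale by design: 400-neuron cultures,
300 s spontaneous recordings and robot runs, 6 + 6 cultures per group
contrast, 5 seeds per control condition, 6 paired plasticity sessions,
probe phases of 6 candidates × 40 stimuli. The full test suite runs in
about two minutes and `scripts/acceptance.py` in about two minutes on a
single desktop core (the LIF kernel is numba-compiled and runs ~500×
real time).

## What the surrogate does and does not show

The surrogate reproduces the target phenomenology: synchronized network
bursts in random cultures and much lower pairwise correlation across
modular ones; compartment-confined evoked responses with shorter
first-spike latencies on the stimulated side; higher bisector
selectivity of the selected I/O pathways under confinement; a
straight-line empty-MEA robot; and a closed-loop navigation advantage
over the open-loop and empty controls, further improved (or at least not
harmed) by the collision tetanus.

Caveats a user should know:

* The electrophysiological contrasts (synchrony, latency confinement)
  are large and stable across seeds. The *navigation* contrasts are
  directional but noisy at n = 5–6 runs: a single run's mean inter-hit
  distance is dominated by wall-interaction geometry (most values fall
  in 25–45 px regardless of condition), the empty condition's score is a
  single geometry draw per arena, and occasional well-wired cultures
  produce outlier closed-loop runs several times better than the median.
  With the packaged seeds the orderings hold; other seed draws can
  produce ties or reversals of the closed-vs-control means, as is
  expected for behavioural comparisons at this sample size. The bisector
  (selectivity) contrast is likewise significant with the packaged
  seeds but sensitive to the probing regime — it sharpens with longer
  inter-stimulus intervals, because synaptic recovery restores the
  full-burst responses that separate confined from unconfined cultures.
* The surrogate's neurons are point LIF units; there is no extracellular
  field model, no spike sorting, and electrode waveforms are stereotyped.
  Passing the signal-path tests says the detection chain is implemented
  correctly, not that it would perform identically on real recordings.
* Potentiation is a single multiplicative rule applied at tetanus end;
  real tetanus effects build during the train, mix facilitation and
  depression, and decay on multiple timescales.
* Sensor readings are noiseless and the robot's kinematics are exact;
  real platforms add sensor noise and latency that this model
  intentionally omits.
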