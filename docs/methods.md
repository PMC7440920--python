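# Model and methods

`sleepreplay` simulates a minimal thalamocortical circuit that learns
spike-sequence memories in an awake-like state through spike-timing
dependent plasticity (STDP), transitions to slow-wave-sleep-like (N3)
dynamics, and is analyzed for recall performance, spontaneous replay
during Up states, and reorganization of the plastic synaptic matrix.
This note documents the model equations, the parameters that matter,
the numerical choices, and the limits of what desk-scale simulations
can show.

## Circuit

Four one-dimensional populations: cortical pyramidal cells (PY, 500 at
full scale) and interneurons (IN, 100), thalamocortical relay cells
(TC, 100) and reticular cells (RE, 100). All projections are
topographic and radius-limited; a source neuron contacts targets within
a fixed radius of its block-centered image in the target population
(`center = floor((i + 0.5) N_t / N_s)`, truncated at the array edges —
the trained regions are interior, so truncation does not touch them).
Radii: PY→PY AMPA 20, PY→PY NMDA 5, PY→IN (AMPA/NMDA) 1, IN→PY GABA_A
5, TC→PY 15, TC→IN 3, PY→TC 10, PY→RE 8, TC→RE 8, RE→TC (GABA_A and
GABA_B) 8, RE→RE GABA_A 5. Only PY→PY AMPA is probabilistic (p = 0.6)
and plastic; its initial weights are Gaussian (default mean 0.075 uS,
SD 10 % of the mean, truncated to [0, g_max]). The mean is a free
constant of this implementation; it is chosen above the 0.065 uS
threshold used by the connection-class analysis, which the original
analysis requires to sit below the initial mean.

## Neurons

All neurons are Hodgkin–Huxley conductance models. Cortical cells have
two compartments. The dendrite integrates

    C_m dV_D/dt = −I_Na − I_NaP − I_Km − I_KCa − ACh_gkl·I_KL − I_HVA
                  − I_L − g(V_D − V_S) − I_syn

and the axo-somatic compartment is treated as fast: its current balance
`g(V_D − V_S) = −I_Na^S − I_NaP^S − I_K^S − I_L^S` is linear in `V_S`
once gating is frozen for the step and is solved in closed form every
step. IN cells are the same model without persistent sodium. Thalamic
cells are one-compartment with fast Na/K, the low-threshold Ca2+
current I_T (rebound bursting), and — in TC only — the
hyperpolarization-activated current I_h whose activation is
`m_inf = 1/(1 + exp((V + 75 + HA_gh)/5.5))`, shifted by the histamine
level.

Every current has the form `I = g m^M h^N (V − E)`. The paper series
this model descends from defers the per-current rate functions to prior
work, so this implementation uses standard published kinetics:
Traub-type Na/K (voltage-shifted), a sigmoidal persistent-Na
activation, Destexhe-type I_M, an instantaneous Hill form for I_KCa
driven by an intracellular Ca pool filled by I_HVA (cortex) or I_T
(thalamus), and Destexhe-type I_T for TC and RE. Gating follows
`dx/dt = −(x − x_inf)/tau_x` with `tau_x = 1/((alpha+beta) Q_T)` for
rate-form gates; `Q_T = 2.3^((36−23)/10) = 2.9529` is applied uniformly.
Gates specified as `(x_inf, tau)` pairs use their published
(temperature-adjusted) time constants directly.

Conductances are normalized to the compartment capacitance (units
mV/ms per unit driving force). They were calibrated once against the
dynamical contracts of the model — awake: asynchronous background
firing with no network-wide silent period; N3: Up/Down alternation
below 1 Hz — and are exposed in `CorticalParams` / `ThalamicParams`.

## Arousal states

The awake↔N3 switch is an instantaneous change of neuromodulation
scalars. Printed constants: GABA_A scaling 0.22 (awake) / 0.44 (N3)
for IN-sourced synapses and 0.6 / 1.2 for RE-sourced synapses; AMPA
scaling 0.133 / 0.4332 for PY→PY and 0.6 / 1.2 for TC→cortex.
Calibration constants of this implementation: the potassium-leak
multipliers per cell class (`ach_gkl_*`; awake 0.25–0.3, N3 1.0–1.2),
the TC I_h activation shift (`ha_gh`; −8 mV awake, 0 mV N3), and a
cholinergic suppression factor on the cortical Ca2+-dependent K+
conductance (`ach_gkca`; awake < 1, N3 = 1). The last is an extension
beyond the source model's ACh targets (K-leak and AMPA): cholinergic
suppression of the slow AHP is well documented physiologically, and at
desk scale it is what reconciles tonic asynchronous awake firing with
the strong spike-frequency adaptation that paces N3 Up states.

## Synapses

Each synapse carries an open-channel fraction O that jumps by
`D·(1 − O)` on a presynaptic spike and decays exponentially
(AMPA 3 ms, NMDA 100 ms, GABA_A 7 ms, GABA_B 200 ms). The current is
`I = scale · g · O · (V − E)` with E_AMPA = E_NMDA = 0 mV,
E_GABA_A = −70 mV, E_GABA_B = −95 mV, and a voltage-dependent
magnesium-block factor `1/(1 + 0.28 e^(−0.062 V))` multiplying NMDA.
GABA_B is modeled as a slow K-like conductance without an explicit
G-protein cascade. `scale` folds the arousal modulation and one global
conversion constant `syn_gain` (uS to mV/ms; the model's only
area/capacitance normalization).

Intracortical AMPA synapses depress short-term:
`D = 1 − (1 − D_i (1 − U)) e^(−Δt/τ)` with U = 0.073 per spike and
τ = 700 ms.

Miniature PSPs occur at PY→PY, PY→IN (AMPA) and IN→PY (GABA_A)
synapses with amplitudes 0.03 / 0.02 / 0.02 uS. Arrival is an
inhomogeneous Poisson process whose rate, reset at each presynaptic
spike at t0, is `λ(t) = (2/(1 + e^(−(t−t0)/υ)) − 1)/250` per ms
(υ = 30): zero immediately after a spike, saturating at 4 Hz. Events
are sampled by thinning against the 4 Hz envelope. Two deliberate
choices: (a) mini amplitudes are *not* multiplied by the arousal
AMPA/GABA factors — modulation applies to evoked transmission only.
This keeps the spontaneous noise floor state-independent, so the awake
state can be noise-driven and asynchronous while the N3 state ignites
through its 3.26-fold stronger evoked recurrence; with state-scaled
minis no desk-scale parameter regime satisfied both contracts.
(b) A `mini_gain` factor compensates the reduced per-neuron synapse
count of desk-scale networks (a fifth of full scale), keeping the
summed mini bombardment per neuron comparable to the full circuit.
Minis bypass short-term depression and saturate nowhere; their
amplitude floor is 0.

## Plasticity

PY→PY AMPA weights follow STDP with the asymmetric kernel
`F(Δt) = A₊ e^(−|Δt|/τ₊)` for Δt > 0 and `−A₋ e^(−|Δt|/τ₋)` for
Δt < 0 (Δt = post − pre), A₊ = A₋ = 0.002, τ₊ = τ₋ = 20 ms. Updates
are `g ← clip(g + g_max F, 0, g_max)` and mini amplitudes follow with
coupling f = 0.01. During sequence training A₋ is reduced to 0.001
(attentional/cholinergic potentiation bias); testing and sleep use the
balanced rule (configurable off, and LTD/LTP-biased sleep variants
A₊ = 0.0019 or 0.0021 are provided). Pairing is nearest-spike and
event-driven: a postsynaptic spike potentiates against the most recent
presynaptic spike, a presynaptic spike depresses against the most
recent postsynaptic spike, and exact coincidences within one
integration step produce no update (the kernel is undefined at 0 and
the case has measure zero).

## Protocols

A memory is an ordered word of five letter groups of 10 adjacent PY
cells (full scale: S1 = A(200–209)…E(240–249); S2 = the non-linear
W(360–369), V(350–359), X, Y, Z; S1* = S1 reversed). Training
stimulates each group with a 10 ms DC pulse, 5 ms between groups, one
trial per second; testing cues only the first group and reads the
response in a 350 ms window; probing stimulates each group alone.
Sleep phases deliver no stimulation. The DC amplitude is not a printed
quantity; it is calibrated per configuration by bisection as the
smallest amplitude that makes an isolated awake PY spike during a
pulse, times a safety factor, and logged.

Every experiment starts with an unrecorded run-in (default 1.5 s) so
phase rasters reflect the stationary regime rather than the
initial-condition transient.

## Analysis

* Recall: per group, the mean instantaneous rate in the 350 ms
  post-cue window is binned at 1 ms and smoothed with a Gaussian
  kernel of 50 ms total window (σ = 12.5 ms); groups order by
  smoothed-peak time (ties break by sequence position). The string
  match against the ideal order is
  `SM = (2N − Σᵢ |L(S_sub[i]) − i|)/(2 |ideal|)`; a trial succeeds at
  SM ≥ 0.8 and performance is the percent of successful trials.
  Worked values: SM(ACBDE|ABCDE) = 0.8, SM(EDCBA|ABCDE) = −0.2,
  SM(ABC|ABCDE) = 0.6.
* Up states: spikes chaining within 15 ms form candidates; candidates
  separated by silent gaps shorter than 300 ms merge (a Down state
  must last 300 ms); intervals with fewer than 5 spikes are discarded
  as spontaneous activity, and intervals longer than 5 s are discarded
  as continuous (non-oscillatory) firing, so awake-like activity
  contains no Up states by construction.
* Group activations: ≥ 5 distinct members (half a group) spiking
  within 15 ms; the activation instant is the mean first-spike time of
  the earliest 5 members in the window. A full-sequence replay is a
  complete ordered chain of activations; the count per Up state is the
  maximum number of disjoint ordered passes.
* Per-synapse replay: within each Up state, nearest pre/post spike
  lags transform through the balanced STDP kernel and sum; a positive
  net marks the synapse as preferentially replayed. Reliability =
  replayed in more than 66 % of all Up states of the sleep phase.
* Synaptic-input asymmetry: for each neuron of the interior groups,
  the summed incoming weight from the preceding (`l`) vs following
  (`r`) group, within-group edges excluded. (The source text describes
  the right-side total once as outgoing; the accompanying results
  describe both sides as received input, which is what is implemented.)
  The weight directionality index embeds (l, r) in the unit square —
  each side divided by the maximum single-side total in the analyzed
  set — and is the distance from the center scaled by 1/√0.5 so that
  one-sided input maps to 1 (the raw Euclidean form alone peaks at
  0.707, contradicting the stated one-sided value of 1).
* Response delays: first-spike latency per neuron after probing the
  left vs right neighboring group; the signed delay directionality is
  `(Δt_S1* − Δt_S1)/(Δt_S1* + Δt_S1)`.
* Connection classes: an anatomically reciprocal pair is functionally
  recurrent when both directed weights exceed the threshold
  (full-scale 0.065 uS; scaled as the same fraction of the initial
  mean at other scales) and unidirectional when exactly one does;
  anatomically one-way edges above threshold are unidirectional.

## Numerics

Fixed-step integration, default dt = 0.02 ms, exponential-Euler for
all gating (exact for frozen rates; keeps gates in [0, 1] at any
step). The network kernel evaluates gating steady states and decay
factors from voltage-indexed lookup tables on a 0.05 mV grid built per
run from the exact rate functions; the interpolation error is below
1e−5 and the kernel is cross-checked against the exact reference
stepper in the test suite. Halving dt moves single-neuron spike times
by well under 1 ms per spike. Spikes are somatic (TC/RE: membrane)
zero crossings with a 3 ms refractory guard. Blow-ups (non-finite or
|V| > 500 mV) abort the run with phase context.

Determinism: one master seed derives the connectivity, initial
weights, initial-condition jitter, frozen per-neuron excitability
offsets, and a per-phase kernel seed for the mini process; identical
configurations reproduce rasters bit-for-bit.

## Desk-scale presets and what they can show

The `*-mini` presets shrink the circuit to 100 PY / 20 IN / 20 TC /
20 RE with groups of 5 and a plastic radius of 10, preserving the
2:1 radius-to-group-size ratio that carries sequence propagation, and
use phase durations of tens of seconds: 12-trial test phases, 30
trials of first-sequence training, 60 trials of competing-sequence
training, and 75 s of sleep. The competing-sequence duration is a
deliberate point on the interference curve: about 80 % of the ~75
trials that fully erase the first trace at this scale, mirroring the
full-scale protocol's choice to stop new training before the old
memory is destroyed (sleep cannot rescue a fully erased trace). The
weight bound g_max = 0.25 uS (3.3x the initial mean) gives trained
pathways enough headroom to dominate recall at this reduced
connectivity. Synthetic-raster generators
(`sleepreplay.fixtures`) plant known Up/Down structure, ordered
replays, and latencies to validate the analysis operations exactly.

Desk-scale runs reproduce the qualitative phenomena — training-induced
weight asymmetry and recall improvement, interference from training
the reversed sequence, spontaneous sequence replay during N3 Up
states, and replay-driven reorganization — but with far fewer neurons
per group, fewer Up states per sleep phase, and 10-trial test phases,
all effect sizes are smaller and noisier than the full-scale, 10-seed,
hundreds-of-seconds protocols. Recall percentages at this scale have
~10-point granularity and should be compared as medians across seeds.
The generator emulates none of the biological variability beyond
Poisson minis and frozen heterogeneity; passing desk-scale tests shows
internal consistency of mechanism and analysis, not quantitative
agreement with in vivo data.

## Known limitations

* No hippocampal/sharp-wave-ripple input; replay is purely cortical.
* No REM-like state, no N2 spindle machinery beyond what the TC/RE
  loop produces incidentally.
* No homeostatic synaptic mechanisms (deliberate: the source model has
  none), so LTD/LTP-biased sleep drifts net synaptic mass.
* The somatic compartment is algebraic; axial currents during the
  spike peak are therefore instantaneous.
* GABA_B lacks second-messenger kinetics.
* Desk-scale statistics are directional rather than quantitative (see
  above).
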