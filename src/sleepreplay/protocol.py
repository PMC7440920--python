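"""Arousal states, stimulation schedules, and experiment orchestration.

An experiment is an ordered list of phases (test / train /
interleaved-train / probe / sleep) executed on a single persistent
network.  Training and testing always run in the awake state; sleep
phases switch the neuromodulatory scalars to the N3 constants and
deliver no stimulation.

The awake <-> N3 transition is an instantaneous change of the
modulation scalars (printed constants): GABA_A scaling 0.22 -> 0.44 for
IN-sourced and 0.6 -> 1.2 for RE-sourced synapses, cortical AMPA
scaling 0.133 -> 0.4332 (PY->PY) and 0.6 -> 1.2 (TC->cortex), plus the
calibrated potassium-leak scalars (ACh) and the TC h-current activation
shift (HA).

Sequence stimulation follows the 10 ms pulse / 5 ms inter-group gap /
1 s trial-period scheme; testing cues only the first group of a
sequence; probing stimulates each group alone in separate trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import RecallTrial, SpikeRecord, score_test_phase
from .engine import NetworkState, StimulusEvent
from .hh_neurons import (CorticalNeuronState, CorticalParams, ThalamicParams,
                         step_cortical_neuron)
from .network import PopulationLayout, WeightMatrix, default_projections
from .synapses import DepressionParams, MiniParams, STDPParams

__all__ = [
    "ArousalState",
    "arousal_parameters",
    "SequenceSpec",
    "make_sequence",
    "Phase",
    "ExperimentConfig",
    "ExperimentResult",
    "training_schedule",
    "test_schedule",
    "probe_schedule",
    "interleaved_schedule",
    "calibrate_pulse_amplitude",
    "run_experiment",
]


@dataclass(frozen=True)
class ArousalState:
    """Neuromodulation scalars of one arousal state.

    The four GABA/AMPA factors are the printed constants; the
    potassium-leak scalars (``ach_gkl_*``, multiplying each neuron
    type's baseline K-leak conductance) and the h-current shift
    ``ha_gh`` (mV) are calibration constants of this implementation,
    chosen so that the awake state fires asynchronously and the N3 state
    produces <1 Hz Up/Down alternation.
    """

    name: str
    gamma_gabaa_in: float
    gamma_gabaa_re: float
    ach_ampa_py: float
    ach_ampa_tc: float
    ach_gkl_py: float
    ach_gkl_in: float
    ach_gkl_tc: float
    ach_gkl_re: float
    ha_gh: float
    ach_gkca: float = 1.0   # cholinergic suppression of the slow AHP (I_KCa)


_AROUSAL_TABLE = {
    "awake": ArousalState(
        name="awake", gamma_gabaa_in=0.22, gamma_gabaa_re=0.6,
        ach_ampa_py=0.133, ach_ampa_tc=0.6,
        ach_gkl_py=0.25, ach_gkl_in=0.25, ach_gkl_tc=0.3, ach_gkl_re=0.3,
        ha_gh=-8.0, ach_gkca=0.6),
    "N3": ArousalState(
        name="N3", gamma_gabaa_in=0.44, gamma_gabaa_re=1.2,
        ach_ampa_py=0.4332, ach_ampa_tc=1.2,
        ach_gkl_py=1.2, ach_gkl_in=1.2, ach_gkl_tc=1.0, ach_gkl_re=1.0,
        ha_gh=0.0, ach_gkca=1.0),
}


def arousal_parameters(name: str) -> ArousalState:
    """The modulation constants of a named arousal state (awake | N3)."""
    try:
        return _AROUSAL_TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown arousal state {name!r}; known: "
            f"{sorted(_AROUSAL_TABLE)}") from None


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered 'word' of neuron-group 'letters' defining one memory."""

    label: str
    letters: tuple[str, ...]
    groups: dict[str, np.ndarray]
    pulse_ms: float = 10.0
    gap_ms: float = 5.0
    period_ms: float = 1000.0

    def group(self, letter: str) -> np.ndarray:
        return self.groups[letter]

    @property
    def ideal(self) -> str:
        return "".join(self.letters)

    @property
    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.groups[c] for c in self.letters])

    def reversed(self, label: str | None = None) -> "SequenceSpec":
        """The same groups activated in reverse order (S1 -> S1*)."""
        return replace(self, label=label or self.label + "*",
                       letters=tuple(reversed(self.letters)))


def make_sequence(label: str, start: int, group_size: int = 10,
                  n_groups: int = 5, letters: str | None = None,
                  order: tuple[int, ...] | None = None) -> SequenceSpec:
    """Build a sequence of contiguous PY groups starting at ``start``.

    ``order`` permutes the *activation* order over the spatial blocks,
    e.g. the non-linear W-V-X-Y-Z sequence activates block 1 before
    block 0.
    """
    letters = letters or "ABCDEFGHIJ"[:n_groups]
    order = order or tuple(range(n_groups))
    groups = {}
    ordered_letters = []
    for letter, block in zip(letters, order):
        ids = np.arange(start + block * group_size,
                        start + (block + 1) * group_size, dtype=np.int64)
        groups[letter] = ids
        ordered_letters.append(letter)
    return SequenceSpec(label=label, letters=tuple(ordered_letters),
                        groups=groups)


def sequence_s1(group_size: int = 10, start: int = 200) -> SequenceSpec:
    """S1: groups A..E over contiguous ascending blocks (full scale
    200-249)."""
    return make_sequence("S1", start, group_size, 5, "ABCDE")


def sequence_s2(group_size: int = 10, start: int = 350) -> SequenceSpec:
    """S2: the non-linear word W-V-X-Y-Z (full scale 350-399, W=360-369
    activated first)."""
    return make_sequence("S2", start, group_size, 5, "WVXYZ",
                         order=(1, 0, 2, 3, 4))


# ---------------------------------------------------------------------------
# Stimulation schedules
# ---------------------------------------------------------------------------

def _group_block(seq: SequenceSpec, letter: str) -> tuple[int, int]:
    ids = seq.group(letter)
    return int(ids.min()), int(ids.max())


def training_schedule(seq: SequenceSpec, t0: float, duration_ms: float,
                      amplitude: float) -> list[StimulusEvent]:
    """Sequential group pulses: group k starts at trial_start + k * 15 ms
    (10 ms pulse + 5 ms gap), one trial per second."""
    if duration_ms < seq.period_ms:
        raise ValueError("training phase shorter than one trial period")
    events = []
    step = seq.pulse_ms + seq.gap_ms
    for trial in range(int(duration_ms // seq.period_ms)):
        base = t0 + trial * seq.period_ms
        for k, letter in enumerate(seq.letters):
            lo, hi = _group_block(seq, letter)
            events.append(StimulusEvent(base + k * step,
                                        base + k * step + seq.pulse_ms,
                                        lo, hi, amplitude))
    return events


def test_schedule(seq: SequenceSpec, t0: float, duration_ms: float,
                  amplitude: float) -> list[StimulusEvent]:
    """Cue only the first group of the sequence, once per trial."""
    if duration_ms < seq.period_ms:
        raise ValueError("test phase shorter than one trial period")
    events = []
    lo, hi = _group_block(seq, seq.letters[0])
    for trial in range(int(duration_ms // seq.period_ms)):
        base = t0 + trial * seq.period_ms
        events.append(StimulusEvent(base, base + seq.pulse_ms, lo, hi,
                                    amplitude))
    return events


def probe_schedule(seq: SequenceSpec, t0: float,
                   amplitude: float) -> list[StimulusEvent]:
    """Stimulate every group independently, one per trial (response-delay
    probing)."""
    events = []
    for k, letter in enumerate(seq.letters):
        lo, hi = _group_block(seq, letter)
        base = t0 + k * seq.period_ms
        events.append(StimulusEvent(base, base + seq.pulse_ms, lo, hi,
                                    amplitude))
    return events


def interleaved_schedule(seq_a: SequenceSpec, seq_b: SequenceSpec,
                         t0: float, duration_ms: float,
                         amplitude: float) -> list[StimulusEvent]:
    """Alternate single full-sequence trials of two sequences (even
    trials -> A, odd -> B)."""
    events = []
    step_a = seq_a.pulse_ms + seq_a.gap_ms
    for trial in range(int(duration_ms // seq_a.period_ms)):
        seq = seq_a if trial % 2 == 0 else seq_b
        step = seq.pulse_ms + seq.gap_ms
        base = t0 + trial * seq.period_ms
        for k, letter in enumerate(seq.letters):
            lo, hi = _group_block(seq, letter)
            events.append(StimulusEvent(base + k * step,
                                        base + k * step + seq.pulse_ms,
                                        lo, hi, amplitude))
    return events


# ---------------------------------------------------------------------------
# Phases and configuration
# ---------------------------------------------------------------------------

PHASE_KINDS = ("test", "train", "interleaved-train", "probe", "sleep", "rest")
STDP_MODES = ("balanced", "training", "off", "ltd_biased", "ltp_biased")


@dataclass(frozen=True)
class Phase:
    """One phase of an experiment.

    ``sequences`` names the sequence(s) stimulated (empty for sleep);
    the arousal state is awake for everything except sleep.  ``stdp``
    defaults per kind: training phases use the potentiation-biased rule
    (A- = 0.001), everything else the balanced rule.
    """

    kind: str
    duration_ms: float
    sequences: tuple[str, ...] = ()
    label: str = ""
    stdp: str = ""

    def __post_init__(self):
        if self.kind not in PHASE_KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.kind in ("sleep", "rest") and self.sequences:
            raise ValueError(f"{self.kind} phases deliver no stimulation")
        if self.kind in ("test", "train", "probe") and len(self.sequences) != 1:
            raise ValueError(f"{self.kind} phase needs exactly one sequence")
        if self.kind == "interleaved-train" and len(self.sequences) != 2:
            raise ValueError("interleaved training needs two sequences")
        if self.stdp and self.stdp not in STDP_MODES:
            raise ValueError(f"unknown STDP mode {self.stdp!r}")
        if self.duration_ms <= 0:
            raise ValueError("phase duration must be positive")
        if not self.label:
            tag = "+".join(self.sequences) if self.sequences else self.kind
            object.__setattr__(self, "label",
                               f"{self.kind}-{tag}" if self.sequences else tag)

    @property
    def arousal(self) -> str:
        return "N3" if self.kind == "sleep" else "awake"

    def stdp_mode(self) -> str:
        if self.stdp:
            return self.stdp
        return "training" if self.kind in ("train", "interleaved-train") \
            else "balanced"


@dataclass
class ExperimentConfig:
    """The single source of truth for one run."""

    layout: PopulationLayout = field(default_factory=PopulationLayout)
    sequences: dict[str, SequenceSpec] = field(default_factory=dict)
    phases: list[Phase] = field(default_factory=list)
    seed: int = 0
    radius_scale: float = 1.0
    pypy_radius: int | None = None     # explicit override of the plastic radius
    weight_mean: float = 0.075
    weight_std: float = 0.0075
    g_max: float = 0.25
    dt: float = 0.02
    syn_gain: float = 1.5
    mini_gain: float = 1.2
    settle_ms: float = 1500.0              # unrecorded run-in before phase 0
    stim_amplitude: float | None = None    # None -> calibrate by bisection
    py_params: CorticalParams = field(default_factory=CorticalParams)
    tc_params: ThalamicParams = field(default_factory=ThalamicParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    conductances: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stdp.g_max != self.g_max:
            self.stdp = replace(self.stdp, g_max=self.g_max)

    def build_network(self) -> NetworkState:
        projections = default_projections(self.radius_scale,
                                          g_pypy_ampa=self.weight_mean,
                                          conductances=self.conductances)
        if self.pypy_radius is not None:
            projections = [replace(p, radius=self.pypy_radius)
                           if p.name == "PY-PY.AMPA" else p
                           for p in projections]
        return NetworkState(
            self.layout, projections, seed=self.seed,
            py_params=self.py_params, tc_params=self.tc_params,
            stdp=self.stdp, weight_mean=self.weight_mean,
            weight_std=self.weight_std, dt=self.dt, syn_gain=self.syn_gain,
            mini_gain=self.mini_gain)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    spikes: dict[str, SpikeRecord]
    snapshots: list[WeightMatrix]
    stim_times: dict[str, list[float]]
    log: dict

    def snapshot(self, label: str) -> WeightMatrix:
        for wm in self.snapshots:
            if wm.label == label:
                return wm
        raise KeyError(f"no snapshot labeled {label!r}; have "
                       f"{[w.label for w in self.snapshots]}")

    def recall_trials(self, phase_label: str, threshold: float = 0.8
                      ) -> list[RecallTrial]:
        """Score the cued trials of a test phase."""
        phase = next(p for p in self.config.phases if p.label == phase_label)
        seq = self.config.sequences[phase.sequences[0]]
        return score_test_phase(self.spikes[phase_label], seq,
                                self.stim_times[phase_label],
                                threshold=threshold)


def calibrate_pulse_amplitude(py_params: CorticalParams,
                              arousal: ArousalState,
                              pulse_ms: float = 10.0,
                              dt: float = 0.02,
                              safety: float = 1.5,
                              tol: float = 0.05) -> float:
    """Smallest DC amplitude that makes an isolated awake PY neuron spike
    during a training pulse, found by bisection and scaled by ``safety``.

    The network's own pulse amplitude is this calibrated value; the
    pulse timing (10 ms / 5 ms / 1 s) carries the sequence information.
    """
    def spikes_at(amp: float) -> bool:
        st = CorticalNeuronState()
        # settle to rest first
        for _ in range(int(200.0 / dt)):
            st = step_cortical_neuron(st, py_params, 0.0, 0.0,
                                      arousal.ach_gkl_py, dt)
        for _ in range(int(pulse_ms / dt)):
            st = step_cortical_neuron(st, py_params, 0.0, amp,
                                      arousal.ach_gkl_py, dt)
            if st.v_s >= 0.0:
                return True
        return False

    lo, hi = 0.0, 1.0
    while not spikes_at(hi):
        hi *= 2.0
        if hi > 200.0:
            raise RuntimeError("pulse-amplitude calibration failed to "
                               "elicit a spike")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi * safety


def _stdp_for(mode: str, base: STDPParams) -> STDPParams:
    if mode == "balanced":
        return base
    if mode == "training":
        return base.training()
    if mode == "off":
        return replace(base, enabled=False)
    if mode == "ltd_biased":
        return base.ltd_biased()
    if mode == "ltp_biased":
        return base.ltp_biased()
    raise ValueError(mode)


def run_experiment(config: ExperimentConfig,
                   progress: bool = False) -> ExperimentResult:
    """Execute all phases in order on one persistent network.

    Returns per-phase spike rasters, weight snapshots at every phase
    boundary (label ``baseline`` before the first phase, ``post-<phase>``
    after each), the cue times of every stimulated phase, and a run log.
    Fully deterministic given the config seed.
    """
    labels = [p.label for p in config.phases]
    if len(set(labels)) != len(labels):
        raise ValueError(f"phase labels must be unique, got {labels}")
    net = config.build_network()
    amp = config.stim_amplitude
    if amp is None:
        amp = calibrate_pulse_amplitude(net.py_params,
                                        arousal_parameters("awake"),
                                        dt=config.dt)
    spikes: dict[str, SpikeRecord] = {}
    stim_times: dict[str, list[float]] = {}
    log: dict = {"stim_amplitude": amp, "phases": []}
    import time as _time
    if config.settle_ms > 0 and config.phases:
        # unrecorded run-in: absorbs the initial-condition transient so
        # phase rasters reflect the stationary regime
        net.set_arousal(arousal_parameters(config.phases[0].arousal))
        net.set_stdp(replace(config.stdp, enabled=False))
        net.run(config.settle_ms, seed=(config.seed * 1009 + 999) % (2 ** 31 - 1),
                record=False)
    snapshots = [net.snapshot_weights("baseline")]
    for idx, phase in enumerate(config.phases):
        t0 = net.time_ms
        net.set_arousal(arousal_parameters(phase.arousal))
        net.set_stdp(_stdp_for(phase.stdp_mode(), config.stdp))
        events: list[StimulusEvent] = []
        if phase.kind == "train":
            seq = config.sequences[phase.sequences[0]]
            events = training_schedule(seq, t0, phase.duration_ms, amp)
        elif phase.kind == "test":
            seq = config.sequences[phase.sequences[0]]
            events = test_schedule(seq, t0, phase.duration_ms, amp)
        elif phase.kind == "probe":
            seq = config.sequences[phase.sequences[0]]
            events = probe_schedule(seq, t0, amp)
        elif phase.kind == "interleaved-train":
            sa = config.sequences[phase.sequences[0]]
            sb = config.sequences[phase.sequences[1]]
            events = interleaved_schedule(sa, sb, t0, phase.duration_ms, amp)
        wall = _time.perf_counter()
        ids, times = net.run(phase.duration_ms, events,
                             seed=(config.seed * 1009 + idx * 13 + 1)
                             % (2 ** 31 - 1))
        wall = _time.perf_counter() - wall
        spikes[phase.label] = SpikeRecord(ids, times, phase.label,
                                          duration_ms=phase.duration_ms)
        if phase.kind in ("test", "probe"):
            if phase.kind == "test":
                stim_times[phase.label] = [
                    e.t_on for e in events]
            else:
                stim_times[phase.label] = [e.t_on for e in events]
        snapshots.append(net.snapshot_weights(f"post-{phase.label}"))
        log["phases"].append({"label": phase.label, "kind": phase.kind,
                              "t0_ms": t0, "duration_ms": phase.duration_ms,
                              "n_spikes": int(len(ids)),
                              "wall_s": round(wall, 2)})
        if progress:
            print(f"[{phase.label}] {phase.duration_ms / 1000:.0f} s bio, "
                  f"{len(ids)} spikes, {wall:.1f} s wall")
    return ExperimentResult(config, spikes, snapshots, stim_times, log)
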