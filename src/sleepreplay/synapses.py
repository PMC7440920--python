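"""Synaptic kinetics and plasticity.

Covers the four receptor types of the network (AMPA, NMDA, GABA_A,
GABA_B), miniature PSPs, short-term depression of intracortical AMPA
synapses, and the spike-timing-dependent plasticity (STDP) rule applied
to PY->PY AMPA weights.

The STDP kernel is the standard asymmetric double exponential

    F(dt) =  A+ exp(-|dt| / tau+)   if dt > 0   (post after pre)
            -A- exp(-|dt| / tau-)   if dt < 0   (pre after post)

with defaults A+/- = 0.002 and tau+/- = 20 ms; during sequence training
A- is reduced to 0.001 (cholinergic potentiation bias).  Weight updates
are ``g <- clip(g + g_max F(dt), 0, g_max)`` and mini amplitudes follow
with the slower coupling ``A_mini <- max(0, A_mini + f A_PY-PY F(dt))``,
f = 0.01.  Exact coincidences (dt == 0) produce no update.

Short-term depression follows the synaptic-resource recovery law

    D = 1 - (1 - D_i (1 - U)) exp(-(t - t_i) / tau_rec)

with U = 0.073 used per presynaptic spike and tau_rec = 700 ms.

Miniature PSP arrival is an inhomogeneous Poisson process whose rate,
reset at each presynaptic spike time t0, is

    lambda(t) = (2 / (1 + exp(-(t - t0) / upsilon)) - 1) / 250   [1/ms]

i.e. zero immediately after a presynaptic spike, saturating at 4 Hz;
samples are drawn by thinning against the 4 Hz envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "STDPParams",
    "DepressionParams",
    "MiniParams",
    "SynapseState",
    "stdp_kernel",
    "apply_stdp",
    "depression_update",
    "mini_rate",
    "mini_release_time",
    "synaptic_current",
    "advance_channel_kinetics",
]

MINI_RATE_SCALE = 1.0 / 250.0   # saturation rate, spikes/ms (= 4 Hz)


@dataclass(frozen=True)
class STDPParams:
    """Amplitudes and time constants of the plasticity rule."""

    a_plus: float = 0.002
    a_minus: float = 0.002
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    f_mini: float = 0.01          # coupling of mini amplitude to STDP
    g_max: float = 0.25           # hard weight bounds [0, g_max], uS
    enabled: bool = True

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")

    def training(self) -> "STDPParams":
        """Potentiation-biased variant used during awake sequence training."""
        return replace(self, a_minus=0.001)

    def ltd_biased(self) -> "STDPParams":
        return replace(self, a_plus=0.0019, a_minus=0.002)

    def ltp_biased(self) -> "STDPParams":
        return replace(self, a_plus=0.0021, a_minus=0.002)


@dataclass(frozen=True)
class DepressionParams:
    u: float = 0.073              # resources used per action potential
    tau_rec: float = 700.0        # recovery time constant, ms

    def __post_init__(self):
        if not 0.0 <= self.u < 1.0:
            raise ValueError("U must lie in [0, 1)")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")


@dataclass(frozen=True)
class MiniParams:
    """Per-connection-class miniature-PSP parameters."""

    g_pypy: float = 0.03          # uS, PY->PY AMPA minis
    g_pyin: float = 0.02          # uS, PY->IN AMPA minis
    g_inpy: float = 0.02          # uS, IN->PY GABA_A minis
    upsilon: float = 30.0         # rise parameter of the release-rate law


@dataclass
class SynapseState:
    """State of a single plastic AMPA synapse (used in unit-level tests;
    the network engine keeps the same quantities in flat arrays)."""

    open_fraction: float = 0.0
    weight: float = 0.075
    mini_amplitude: float = 0.03
    depression: float = 1.0
    last_presyn_time: float = -1.0e9


@njit(cache=True, inline="always")
def _stdp_f(delta_t, a_plus, a_minus, tau_plus, tau_minus):
    if delta_t > 0.0:
        return a_plus * math.exp(-delta_t / tau_plus)
    if delta_t < 0.0:
        return -a_minus * math.exp(delta_t / tau_minus)
    return 0.0


def stdp_kernel(delta_t: float, params: STDPParams = STDPParams()) -> float:
    """STDP weight-change factor F for a post-minus-pre spike lag (ms).

    dt = 0 (exact coincidence) is treated as no update.
    """
    return float(_stdp_f(float(delta_t), params.a_plus, params.a_minus,
                         params.tau_plus, params.tau_minus))


def apply_stdp(weight: float, mini_amplitude: float, delta_t: float,
               params: STDPParams = STDPParams(),
               a_pypy: float = 0.03) -> tuple[float, float]:
    """Apply one pairing event to a weight and its mini amplitude.

    ``weight' = clip(weight + g_max F(dt), 0, g_max)`` and
    ``mini' = max(0, mini + f * A_PY-PY * F(dt))`` where ``a_pypy`` is the
    PY->PY mini conductance scale.
    """
    f = stdp_kernel(delta_t, params)
    w = min(params.g_max, max(0.0, weight + params.g_max * f))
    m = max(0.0, mini_amplitude + params.f_mini * a_pypy * f)
    return w, m


def depression_update(d_i: float, elapsed: float,
                      params: DepressionParams = DepressionParams()) -> float:
    """Available synaptic resources a time ``elapsed`` after the last
    presynaptic event, which left the pre-event resource level ``d_i``.

    Evaluates D = 1 - (1 - D_i (1 - U)) exp(-elapsed / tau_rec); the
    product D_i (1 - U) is the resource level immediately *after* the
    event, so D -> 1 monotonically as elapsed grows.
    """
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    if not 0.0 < d_i <= 1.0:
        raise ValueError("D_i must lie in (0, 1]")
    return 1.0 - (1.0 - d_i * (1.0 - params.u)) * math.exp(-elapsed / params.tau_rec)


@njit(cache=True, inline="always")
def _mini_rate(t, t0, upsilon):
    if t < t0:
        return 0.0
    return (2.0 / (1.0 + math.exp(-(t - t0) / upsilon)) - 1.0) * MINI_RATE_SCALE


def mini_rate(t: float, t0: float, upsilon: float = 30.0) -> float:
    """Instantaneous mini-release rate (1/ms) a time ``t`` given the last
    presynaptic spike at ``t0``: zero at t0, saturating at 1/250 per ms."""
    return float(_mini_rate(t, t0, upsilon))


def mini_release_time(t0: float, upsilon: float = 30.0,
                      rng: np.random.Generator | None = None,
                      start: float | None = None) -> float:
    """Draw the next spontaneous release time after ``t0``.

    The arrival process is inhomogeneous Poisson with the sigmoidal rate
    above; sampling uses thinning against the saturation rate 1/250 ms^-1.
    ``start`` (default ``t0``) is the time from which to search forward.
    """
    if rng is None:
        rng = np.random.default_rng()
    t = t0 if start is None else float(start)
    lam_max = MINI_RATE_SCALE
    while True:
        t += rng.exponential(1.0 / lam_max)
        if rng.random() * lam_max <= _mini_rate(t, t0, upsilon):
            return t


def synaptic_current(g_syn: float, open_fraction: float, v: float,
                     e_syn: float, modulation_scale: float = 1.0) -> float:
    """Postsynaptic current I = scale * g * [O] * (V - E_syn).

    ``modulation_scale`` carries the arousal-state factor (ACh_AMPA for
    AMPA synapses, gamma_GABAA for GABA_A synapses).
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError("open fraction must lie in [0, 1]")
    return modulation_scale * g_syn * open_fraction * (v - e_syn)


def advance_channel_kinetics(state: SynapseState,
                             presyn_spikes,
                             duration: float,
                             dt: float = 0.02,
                             tau_decay: float = 3.0,
                             depression: DepressionParams | None = DepressionParams(),
                             record: bool = False):
    """Advance the open-channel fraction of one synapse through a spike train.

    On each presynaptic spike the open fraction jumps by ``D (1 - O)``
    (release scaled by the available resources) and decays exponentially
    with ``tau_decay`` in between; with ``depression=None`` the resource
    variable is pinned at 1.  Returns the final state, or ``(state,
    trace)`` with a per-step O array when ``record`` is true.
    """
    spikes = list(presyn_spikes)
    if any(b < a for a, b in zip(spikes, spikes[1:])):
        raise ValueError("presynaptic spike times must be sorted")
    o = state.open_fraction
    # d_i = resource level immediately before the most recent event; the
    # recovery law depression_update() folds the U consumption of that
    # event into its own formula.
    d_i = state.depression
    t_last = state.last_presyn_time
    n_steps = int(round(duration / dt))
    trace = np.empty(n_steps) if record else None
    k = 0
    decay = math.exp(-dt / tau_decay)
    for i in range(n_steps):
        t = i * dt
        while k < len(spikes) and spikes[k] <= t:
            if depression is None:
                avail = 1.0
            elif t_last <= -1e8:
                avail = d_i
            else:
                avail = depression_update(d_i, spikes[k] - t_last, depression)
            o = o + avail * (1.0 - o)
            d_i = avail
            t_last = spikes[k]
            k += 1
        o *= decay
        if record:
            trace[i] = o
    if depression is not None and t_last > -1e8:
        d_now = depression_update(d_i, n_steps * dt - t_last, depression)
    else:
        d_now = d_i
    out = SynapseState(open_fraction=o, weight=state.weight,
                       mini_amplitude=state.mini_amplitude,
                       depression=d_now, last_presyn_time=t_last)
    return (out, trace) if record else out
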