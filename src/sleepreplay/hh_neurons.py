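"""Single-neuron Hodgkin-Huxley dynamics.

Two neuron classes are implemented:

* two-compartment cortical neurons (pyramidal PY and interneuron IN): a
  dendritic compartment integrated in time carrying ``I_Na``, ``I_NaP``
  (PY only), ``I_Km``, ``I_KCa``, ``I_HVA``, a K+ leak scaled by the
  cholinergic factor ``ACh_gkl`` and a Cl- leak, coupled to a fast
  axo-somatic compartment whose voltage is obtained from an algebraic
  current balance ``g (V_D - V_S) = -I_Na^S - I_NaP^S - I_K^S`` solved in
  closed form each step (all somatic currents are linear in ``V_S`` once
  the gating variables are frozen for the step);
* one-compartment thalamic neurons (relay TC and reticular RE) carrying
  fast ``I_Na``/``I_K``, a low-threshold Ca2+ current ``I_T`` (rebound
  bursts), the h-current ``I_h`` (TC only, histamine-shifted activation)
  and leaks.

Gating variables follow dx/dt = -(x - x_inf)/tau_x with
tau_x = 1/((alpha + beta) * QT) for rate-form gates; gates specified
directly as (x_inf, tau) pairs fold the temperature factor into their
published time constants.  Integration uses the exponential-Euler
(exact relaxation) update, which keeps every gate in [0, 1] for any dt.

The per-current rate functions are standard published kinetics
(Traub-type Na/K, Destexhe-type I_T/I_M/I_h); maximal conductances are
exposed through :class:`CorticalParams` / :class:`ThalamicParams` and the
experiment config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

from numba import njit

__all__ = [
    "temperature_factor",
    "ih_steady_state",
    "GatingState",
    "gating_step",
    "CorticalParams",
    "ThalamicParams",
    "CorticalNeuronState",
    "ThalamicNeuronState",
    "step_cortical_neuron",
    "step_thalamic_neuron",
    "QT_DEFAULT",
]

_JIT = dict(cache=True, fastmath=True, inline="always")


def temperature_factor(Q: float, T: float) -> float:
    """Temperature scaling factor ``QT = Q**((T - 23) / 10)``.

    With the defaults Q = 2.3 and T = 36 degC this evaluates to 2.9529.

    Raises
    ------
    ValueError
        If ``Q`` is not positive.
    """
    if Q <= 0:
        raise ValueError(f"temperature base Q must be positive, got {Q!r}")
    return float(Q) ** ((float(T) - 23.0) / 10.0)


QT_DEFAULT = temperature_factor(2.3, 36.0)


@njit(**_JIT)
def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / math.expm1(x / y)


# --- fast Na+ / delayed-rectifier K+ (Traub-type, voltage-shifted) ----------

@njit(**_JIT)
def na_alpha_m(V, vshift):
    return 0.32 * _vtrap(13.0 - (V - vshift), 4.0)


@njit(**_JIT)
def na_beta_m(V, vshift):
    return 0.28 * _vtrap((V - vshift) - 40.0, 5.0)


@njit(**_JIT)
def na_alpha_h(V, vshift):
    return 0.128 * math.exp((17.0 - (V - vshift)) / 18.0)


@njit(**_JIT)
def na_beta_h(V, vshift):
    return 4.0 / (1.0 + math.exp((40.0 - (V - vshift)) / 5.0))


@njit(**_JIT)
def k_alpha_n(V, vshift):
    return 0.032 * _vtrap(15.0 - (V - vshift), 5.0)


@njit(**_JIT)
def k_beta_n(V, vshift):
    return 0.5 * math.exp((10.0 - (V - vshift)) / 40.0)


# --- persistent Na+ ---------------------------------------------------------

@njit(**_JIT)
def nap_m_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 42.0) / 5.0))


# --- slow non-inactivating K+ (M-current) -----------------------------------

@njit(**_JIT)
def km_n_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))


@njit(**_JIT)
def km_tau(V):
    return 1000.0 / (3.3 * (math.exp((V + 35.0) / 20.0) + math.exp(-(V + 35.0) / 20.0)))


# --- high-voltage-activated Ca2+ --------------------------------------------

@njit(**_JIT)
def hva_m_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 20.0) / 9.0))


# --- Ca2+-dependent K+ (instantaneous Hill activation) ----------------------

@njit(**_JIT)
def kca_m(ca, kd):
    return ca * ca / (ca * ca + kd * kd)


# --- low-threshold Ca2+ (I_T), thalamocortical variant ----------------------

@njit(**_JIT)
def it_tc_m_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 57.0) / 6.2))


@njit(**_JIT)
def it_tc_tau_m(V):
    return 0.612 + 1.0 / (math.exp(-(V + 132.0) / 16.7) + math.exp((V + 16.8) / 18.2))


@njit(**_JIT)
def it_tc_h_inf(V):
    return 1.0 / (1.0 + math.exp((V + 81.0) / 4.0))


@njit(**_JIT)
def it_tc_tau_h(V):
    if V < -80.0:
        return math.exp((V + 467.0) / 66.6) / 3.74
    return (28.0 + math.exp(-(V + 22.0) / 10.5)) / 3.74


# --- low-threshold Ca2+ (I_Ts), reticular variant ---------------------------

@njit(**_JIT)
def it_re_m_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 52.0) / 7.4))


@njit(**_JIT)
def it_re_tau_m(V):
    return 1.0 + 0.33 / (math.exp((V + 27.0) / 10.0) + math.exp(-(V + 102.0) / 15.0))


@njit(**_JIT)
def it_re_h_inf(V):
    return 1.0 / (1.0 + math.exp((V + 80.0) / 5.0))


@njit(**_JIT)
def it_re_tau_h(V):
    return 28.3 + 0.33 / (math.exp((V + 48.0) / 4.0) + math.exp(-(V + 407.0) / 50.0))


# --- hyperpolarization-activated mixed cation current (I_h, TC only) --------

@njit(**_JIT)
def _ih_m_inf(V, ha_shift):
    return 1.0 / (1.0 + math.exp((V + 75.0 + ha_shift) / 5.5))


def ih_steady_state(V: float, HA_gh: float = 0.0) -> float:
    """Steady-state activation of the TC h-current.

    ``m_inf = 1 / (1 + exp((V + 75 + HA_gh) / 5.5))``.  The histamine
    level enters as the activation-curve shift ``HA_gh`` (mV); raising it
    moves the curve to more hyperpolarized potentials, reducing I_h at a
    fixed voltage.
    """
    return float(_ih_m_inf(float(V), float(HA_gh)))


@njit(**_JIT)
def ih_tau(V):
    return 20.0 + 1000.0 / (math.exp((V + 71.5) / 14.2) + math.exp(-(V + 89.0) / 11.6))


# ---------------------------------------------------------------------------
# Generic gating-variable contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingState:
    """A single activation/inactivation gate with voltage-dependent rates."""

    value: float
    rate_alpha: Callable[[float], float]
    rate_beta: Callable[[float], float]

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"gating value must lie in [0, 1], got {self.value}")


def gating_step(x: GatingState, V: float, dt: float, QT: float = 1.0) -> GatingState:
    """Advance a gate by ``dt`` using the exact exponential-relaxation update.

    x(t + dt) = x_inf + (x - x_inf) exp(-dt / tau),  tau = 1/((a + b) QT).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = x.rate_alpha(V)
    b = x.rate_beta(V)
    if a + b <= 0:
        raise ZeroDivisionError(f"degenerate gating rates at V={V}: alpha+beta={a + b}")
    x_inf = a / (a + b)
    tau = 1.0 / ((a + b) * QT)
    new = x_inf + (x.value - x_inf) * math.exp(-dt / tau)
    return replace(x, value=min(1.0, max(0.0, new)))


@njit(**_JIT)
def _relax(x, x_inf, tau, dt):
    return x_inf + (x - x_inf) * math.exp(-dt / tau)


# ---------------------------------------------------------------------------
# Cortical two-compartment neuron
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorticalParams:
    """Maximal conductances and passive parameters of a PY or IN neuron.

    Conductance units are normalized to the dendritic capacitance so that
    ``g * (V - E)`` is a voltage rate in mV/ms.  ``has_nap=False`` yields
    the interneuron variant (no persistent sodium).
    """

    cm: float = 1.0
    g_na_dend: float = 1.0
    g_nap: float = 0.1
    g_km: float = 0.025
    g_kca: float = 0.8
    g_hva: float = 0.015
    g_kl: float = 0.045          # base K-leak; multiplied by ACh_gkl
    g_leak: float = 0.035        # Cl- leak
    e_leak: float = -55.0
    e_na: float = 50.0
    e_k: float = -90.0
    e_ca: float = 140.0
    g_couple: float = 2.0        # dendro-somatic coupling
    g_na_soma: float = 300.0
    g_k_soma: float = 60.0
    g_nap_soma: float = 0.1
    g_leak_soma: float = 0.1
    vshift_na: float = -55.0     # voltage shift of Traub Na/K kinetics
    kd_kca: float = 1.0          # uM, half-activation of I_KCa
    ca_gain: float = 1.0         # uM per (mV/ms) of HVA current
    ca_rest: float = 0.05        # uM
    tau_ca: float = 1000.0       # ms
    tau_nap: float = 0.2         # ms
    tau_hva: float = 2.0         # ms
    has_nap: bool = True

    def interneuron(self) -> "CorticalParams":
        return replace(self, has_nap=False, g_nap=0.0, g_nap_soma=0.0)


@dataclass
class CorticalNeuronState:
    """Mutable state of one two-compartment cortical neuron."""

    v_d: float = -68.0
    v_s: float = -68.0
    na_m_d: float = 0.0
    na_h_d: float = 1.0
    km_n: float = 0.0
    hva_m: float = 0.0
    ca: float = 0.05
    na_m_s: float = 0.0
    na_h_s: float = 1.0
    k_n_s: float = 0.0


@njit(cache=True, fastmath=True)
def _cortical_step(v_d, v_s, na_m_d, na_h_d, km_n, hva_m, ca,
                   na_m_s, na_h_s, k_n_s,
                   i_syn, i_dc, ach_gkl, dt, qt,
                   cm, g_na_dend, g_nap, g_km, g_kca, g_hva, g_kl, g_leak,
                   e_leak, e_na, e_k, e_ca, g_couple, g_na_soma, g_k_soma,
                   g_nap_soma, g_leak_soma, vshift, kd_kca, ca_gain, ca_rest,
                   tau_ca, tau_nap, tau_hva):
    """Advance one cortical neuron by ``dt``; returns the new state tuple.

    ``i_syn`` is the total synaptic current with the usual outward-positive
    convention ``I = g [O] (V - E)`` (it enters the balance with a minus
    sign); ``i_dc`` is an injected depolarizing drive in mV/ms.
    """
    # -- somatic gating advances against the previous somatic voltage
    a = na_alpha_m(v_s, vshift)
    b = na_beta_m(v_s, vshift)
    na_m_s = _relax(na_m_s, a / (a + b), 1.0 / ((a + b) * qt), dt)
    a = na_alpha_h(v_s, vshift)
    b = na_beta_h(v_s, vshift)
    na_h_s = _relax(na_h_s, a / (a + b), 1.0 / ((a + b) * qt), dt)
    a = k_alpha_n(v_s, vshift)
    b = k_beta_n(v_s, vshift)
    k_n_s = _relax(k_n_s, a / (a + b), 1.0 / ((a + b) * qt), dt)

    # -- dendritic gating
    a = na_alpha_m(v_d, vshift)
    b = na_beta_m(v_d, vshift)
    na_m_d = _relax(na_m_d, a / (a + b), 1.0 / ((a + b) * qt), dt)
    a = na_alpha_h(v_d, vshift)
    b = na_beta_h(v_d, vshift)
    na_h_d = _relax(na_h_d, a / (a + b), 1.0 / ((a + b) * qt), dt)
    km_n = _relax(km_n, km_n_inf(v_d), km_tau(v_d) / qt, dt)
    hva_m = _relax(hva_m, hva_m_inf(v_d), tau_hva, dt)

    # -- dendritic currents
    i_na = g_na_dend * na_m_d ** 3 * na_h_d * (v_d - e_na)
    i_nap = g_nap * nap_m_inf(v_d) * (v_d - e_na)
    i_km = g_km * km_n * (v_d - e_k)
    i_kca = g_kca * kca_m(ca, kd_kca) * (v_d - e_k)
    i_hva = g_hva * hva_m * hva_m * (v_d - e_ca)
    i_kl = g_kl * (v_d - e_k)
    i_leak = g_leak * (v_d - e_leak)

    # -- intracellular calcium driven by HVA influx
    influx = -i_hva
    if influx < 0.0:
        influx = 0.0
    ca = ca + dt * (ca_gain * influx - (ca - ca_rest) / tau_ca)

    dv = (-i_na - i_nap - i_km - i_kca - ach_gkl * i_kl - i_hva - i_leak
          - g_couple * (v_d - v_s) - i_syn + i_dc) / cm
    v_d = v_d + dt * dv

    # -- axo-somatic compartment: algebraic current balance
    #    g (V_D - V_S) = I_Na^S + I_NaP^S + I_K^S + I_L^S
    #    with gating frozen every term is linear in V_S.
    g1 = g_na_soma * na_m_s ** 3 * na_h_s
    g2 = g_nap_soma * nap_m_inf(v_s)
    g3 = g_k_soma * k_n_s ** 4
    v_s = ((g_couple * v_d + (g1 + g2) * e_na + g3 * e_k + g_leak_soma * e_leak)
           / (g_couple + g1 + g2 + g3 + g_leak_soma))

    return v_d, v_s, na_m_d, na_h_d, km_n, hva_m, ca, na_m_s, na_h_s, k_n_s


def step_cortical_neuron(state: CorticalNeuronState,
                         params: CorticalParams,
                         i_syn: float = 0.0,
                         i_dc: float = 0.0,
                         ach_gkl: float = 1.0,
                         dt: float = 0.02,
                         qt: float = QT_DEFAULT) -> CorticalNeuronState:
    """Advance a two-compartment cortical neuron by one time step.

    Raises
    ------
    FloatingPointError
        If the voltage leaves the physically plausible range (numerical
        blow-up), naming the offending values.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    out = _cortical_step(
        state.v_d, state.v_s, state.na_m_d, state.na_h_d, state.km_n,
        state.hva_m, state.ca, state.na_m_s, state.na_h_s, state.k_n_s,
        i_syn, i_dc, ach_gkl, dt, qt,
        p.cm, p.g_na_dend, p.g_nap if p.has_nap else 0.0, p.g_km, p.g_kca,
        p.g_hva, p.g_kl, p.g_leak, p.e_leak, p.e_na, p.e_k, p.e_ca,
        p.g_couple, p.g_na_soma, p.g_k_soma,
        p.g_nap_soma if p.has_nap else 0.0, p.g_leak_soma, p.vshift_na,
        p.kd_kca, p.ca_gain, p.ca_rest, p.tau_ca, p.tau_nap, p.tau_hva)
    new = CorticalNeuronState(*out)
    if not (math.isfinite(new.v_d) and math.isfinite(new.v_s)) or abs(new.v_d) > 500:
        raise FloatingPointError(
            f"cortical neuron voltage blew up: V_D={new.v_d}, V_S={new.v_s}")
    return new


# ---------------------------------------------------------------------------
# Thalamic one-compartment neurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThalamicParams:
    """Conductances of a one-compartment TC or RE neuron (mV/ms units)."""

    cm: float = 1.0
    g_na: float = 90.0
    g_k: float = 12.0
    g_t: float = 2.2
    g_h: float = 0.1             # TC only; RE sets has_ih=False
    g_kl: float = 0.03
    g_leak: float = 0.05
    e_leak: float = -70.0
    e_na: float = 50.0
    e_k: float = -95.0
    e_ca: float = 140.0
    e_h: float = -40.0
    vshift_na: float = -50.0
    ca_gain: float = 0.3
    ca_rest: float = 0.05
    tau_ca: float = 100.0
    has_ih: bool = True          # False -> reticular (RE) variant

    def reticular(self) -> "ThalamicParams":
        return replace(self, has_ih=False, g_h=0.0, e_leak=-77.0, g_t=1.8,
                       g_kl=0.012)


@dataclass
class ThalamicNeuronState:
    v: float = -68.0
    na_m: float = 0.0
    na_h: float = 1.0
    k_n: float = 0.0
    t_m: float = 0.0
    t_h: float = 0.3
    h_m: float = 0.1
    ca: float = 0.05


@njit(cache=True, fastmath=True)
def _thalamic_step(v, na_m, na_h, k_n, t_m, t_h, h_m, ca,
                   i_syn, i_dc, ach_gkl, ha_gh, dt, qt,
                   cm, g_na, g_k, g_t, g_h, g_kl, g_leak,
                   e_leak, e_na, e_k, e_ca, e_h, vshift,
                   ca_gain, ca_rest, tau_ca, is_tc):
    a = na_alpha_m(v, vshift)
    b = na_beta_m(v, vshift)
    na_m = _relax(na_m, a / (a + b), 1.0 / ((a + b) * qt), dt)
    a = na_alpha_h(v, vshift)
    b = na_beta_h(v, vshift)
    na_h = _relax(na_h, a / (a + b), 1.0 / ((a + b) * qt), dt)
    a = k_alpha_n(v, vshift)
    b = k_beta_n(v, vshift)
    k_n = _relax(k_n, a / (a + b), 1.0 / ((a + b) * qt), dt)

    if is_tc:
        t_m = _relax(t_m, it_tc_m_inf(v), it_tc_tau_m(v), dt)
        t_h = _relax(t_h, it_tc_h_inf(v), it_tc_tau_h(v), dt)
        h_m = _relax(h_m, _ih_m_inf(v, ha_gh), ih_tau(v), dt)
        i_h = g_h * h_m * (v - e_h)
    else:
        t_m = _relax(t_m, it_re_m_inf(v), it_re_tau_m(v), dt)
        t_h = _relax(t_h, it_re_h_inf(v), it_re_tau_h(v), dt)
        i_h = 0.0

    i_na = g_na * na_m ** 3 * na_h * (v - e_na)
    i_k = g_k * k_n ** 4 * (v - e_k)
    i_t = g_t * t_m * t_m * t_h * (v - e_ca)
    i_kl = g_kl * (v - e_k)
    i_leak = g_leak * (v - e_leak)

    influx = -i_t
    if influx < 0.0:
        influx = 0.0
    ca = ca + dt * (ca_gain * influx - (ca - ca_rest) / tau_ca)

    dv = (-i_na - i_k - i_t - i_h - ach_gkl * i_kl - i_leak - i_syn + i_dc) / cm
    v = v + dt * dv
    return v, na_m, na_h, k_n, t_m, t_h, h_m, ca


def step_thalamic_neuron(state: ThalamicNeuronState,
                         params: ThalamicParams,
                         i_syn: float = 0.0,
                         i_dc: float = 0.0,
                         ach_gkl: float = 1.0,
                         ha_gh: float = 0.0,
                         dt: float = 0.02,
                         qt: float = QT_DEFAULT) -> ThalamicNeuronState:
    """Advance a one-compartment thalamic (TC or RE) neuron by one step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    out = _thalamic_step(
        state.v, state.na_m, state.na_h, state.k_n, state.t_m, state.t_h,
        state.h_m, state.ca, i_syn, i_dc, ach_gkl, ha_gh, dt, qt,
        p.cm, p.g_na, p.g_k, p.g_t, p.g_h if p.has_ih else 0.0, p.g_kl,
        p.g_leak, p.e_leak, p.e_na, p.e_k, p.e_ca, p.e_h, p.vshift_na,
        p.ca_gain, p.ca_rest, p.tau_ca, p.has_ih)
    new = ThalamicNeuronState(*out)
    if not math.isfinite(new.v) or abs(new.v) > 500:
        raise FloatingPointError(f"thalamic neuron voltage blew up: V={new.v}")
    return new
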