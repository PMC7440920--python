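"""Network integration engine.

Internal module: assembles the per-population state arrays and the flat
synapse arrays for a thalamocortical network and advances them with a
single numba kernel at a fixed time step (default 0.02 ms).

Conventions
-----------
* Neurons carry global indices in population order PY, IN, TC, RE.
* Synapses live in flat parallel arrays; every synapse has an
  open-channel fraction O in [0, 1] that jumps by ``D (1 - O)`` on a
  presynaptic spike (D = available resources, pinned at 1 for synapses
  without short-term depression) and decays exponentially otherwise.
  The postsynaptic current is ``scale * w * O * (V - E)`` with the
  arousal-state modulation factor folded into ``scale`` per phase, and
  an additional voltage-dependent magnesium-block factor for NMDA.
* Miniature PSPs are sampled per synapse by thinning an inhomogeneous
  Poisson process whose rate resets at each presynaptic spike; accepted
  events bump per-neuron mini conductance accumulators.
* STDP applies to the PY->PY AMPA block only, event-driven with
  nearest-spike pairing: a postsynaptic spike potentiates against the
  most recent presynaptic spike, a presynaptic spike depresses against
  the most recent postsynaptic spike, and exact coincidences (same
  step) are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .hh_neurons import (CorticalParams, QT_DEFAULT, ThalamicParams,
                         _ih_m_inf, hva_m_inf, ih_tau, it_re_h_inf,
                         it_re_m_inf, it_re_tau_h, it_re_tau_m, it_tc_h_inf,
                         it_tc_m_inf, it_tc_tau_h, it_tc_tau_m, k_alpha_n,
                         k_beta_n, km_n_inf, km_tau, na_alpha_h, na_alpha_m,
                         na_beta_h, na_beta_m, nap_m_inf)
from .network import (PopulationLayout, ProjectionSpec, WeightMatrix,
                      build_connectivity, init_weights)
from .synapses import MINI_RATE_SCALE, DepressionParams, MiniParams, STDPParams

E_AMPA = 0.0
E_NMDA = 0.0
E_GABA_A = -70.0
E_GABA_B = -95.0

TAU_AMPA = 3.0
TAU_NMDA = 100.0
TAU_GABA_A = 7.0
TAU_GABA_B = 200.0

_RECEPTOR_E = {"AMPA": E_AMPA, "NMDA": E_NMDA,
               "GABA_A": E_GABA_A, "GABA_B": E_GABA_B}
_RECEPTOR_TAU = {"AMPA": TAU_AMPA, "NMDA": TAU_NMDA,
                 "GABA_A": TAU_GABA_A, "GABA_B": TAU_GABA_B}


@dataclass
class StimulusEvent:
    """A DC pulse delivered to a contiguous block of PY dendrites."""

    t_on: float
    t_off: float
    first: int      # first PY index (population-local)
    last: int       # inclusive
    amplitude: float


def _csr(keys: np.ndarray, n_keys: int, n_items: int | None = None):
    """Group item indices by key: returns (indptr, order)."""
    if n_items is None:
        n_items = len(keys)
    order = np.argsort(keys, kind="stable").astype(np.int64)
    counts = np.bincount(keys, minlength=n_keys)
    indptr = np.zeros(n_keys + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, order


class NetworkState:
    """All mutable arrays of one network instance plus its construction
    metadata.  Built once per experiment; phases advance it in place."""

    def __init__(self, layout: PopulationLayout,
                 projections: list[ProjectionSpec],
                 seed: int,
                 py_params: CorticalParams = CorticalParams(),
                 in_params: CorticalParams | None = None,
                 tc_params: ThalamicParams = ThalamicParams(),
                 re_params: ThalamicParams | None = None,
                 stdp: STDPParams = STDPParams(),
                 depression: DepressionParams = DepressionParams(),
                 minis: MiniParams = MiniParams(),
                 weight_mean: float = 0.075,
                 weight_std: float = 0.0075,
                 dt: float = 0.02,
                 qt: float = QT_DEFAULT,
                 syn_gain: float = 1.5,
                 mini_gain: float = 1.2,
                 bias_std: float = 0.15):
        self.layout = layout
        self.projections = projections
        self.seed = seed
        self.dt = dt
        self.qt = qt
        self.py_params = py_params
        self.in_params = in_params or py_params.interneuron()
        self.tc_params = tc_params
        self.re_params = re_params or tc_params.reticular()
        self.stdp = stdp
        self.depression = depression
        self.minis = minis
        # conversion from uS synaptic conductance to voltage rate
        # (1 / (membrane area x specific capacitance)); one global
        # calibration constant for all receptors
        self.syn_gain = syn_gain
        # finite-size compensation of the spontaneous (mini) drive: a
        # reduced network has proportionally fewer synapses per neuron,
        # so the summed mini bombardment is scaled up to keep the
        # per-neuron noise level comparable to the full-scale circuit
        self.mini_gain = mini_gain
        self.time_ms = 0.0

        rng = np.random.default_rng(seed)
        n = layout.total

        # ---- synapse arrays -------------------------------------------
        src_all, tgt_all, g_all, e_all, tau_all = [], [], [], [], []
        depress_all, proj_id = [], []
        self._proj_slices: dict[str, slice] = {}
        plastic_slice = None
        for p_idx, proj in enumerate(projections):
            s, t = build_connectivity(layout, proj,
                                      seed=int(rng.integers(2 ** 31)))
            off_s = layout.offset(proj.source)
            off_t = layout.offset(proj.target)
            start = len(src_all)
            src_all.extend(s + off_s)
            tgt_all.extend(t + off_t)
            if proj.plastic:
                if plastic_slice is not None:
                    raise ValueError("only one plastic projection supported")
                plastic_slice = slice(start, start + len(s))
                w0 = init_weights(s, t, layout.n_py, weight_mean,
                                  weight_std, stdp.g_max,
                                  seed=int(rng.integers(2 ** 31)))
                g_all.extend(w0.weights)
            else:
                g_all.extend([proj.g_syn] * len(s))
            e_all.extend([_RECEPTOR_E[proj.receptor]] * len(s))
            tau_all.extend([_RECEPTOR_TAU[proj.receptor]] * len(s))
            intracortical_ampa = (proj.receptor == "AMPA"
                                  and proj.source == "PY"
                                  and proj.target in ("PY", "IN"))
            depress_all.extend([intracortical_ampa] * len(s))
            proj_id.extend([p_idx] * len(s))
            self._proj_slices[proj.name] = slice(start, start + len(s))
        if plastic_slice is None:
            plastic_slice = slice(0, 0)
        self.plastic_slice = plastic_slice

        self.syn_src = np.asarray(src_all, dtype=np.int64)
        self.syn_tgt = np.asarray(tgt_all, dtype=np.int64)
        self.syn_w = np.asarray(g_all, dtype=np.float64)
        self.syn_e = np.asarray(e_all, dtype=np.float64)
        self.syn_tau = np.asarray(tau_all, dtype=np.float64)
        self.syn_proj = np.asarray(proj_id, dtype=np.int64)
        self.syn_scale = np.ones(len(self.syn_src))
        self.syn_is_nmda = np.array(
            [projections[p].receptor == "NMDA" for p in self.syn_proj],
            dtype=np.bool_)
        self.syn_depress = np.asarray(depress_all, dtype=np.bool_)
        self.syn_O = np.zeros(len(self.syn_src))
        self.syn_Di = np.ones(len(self.syn_src))
        self.syn_last_pre = np.full(len(self.syn_src), -1.0e9)

        # minis: PY->PY AMPA (plastic amplitude), PY->IN AMPA, IN->PY GABA_A
        self.syn_mini_amp = np.zeros(len(self.syn_src))
        for name, amp in (("PY-PY.AMPA", minis.g_pypy),
                          ("PY-IN.AMPA", minis.g_pyin),
                          ("IN-PY.GABA_A", minis.g_inpy)):
            if name in self._proj_slices:
                self.syn_mini_amp[self._proj_slices[name]] = amp
        self.syn_has_mini = self.syn_mini_amp > 0
        self.syn_mini_next = np.full(len(self.syn_src), np.inf)
        first = rng.exponential(1.0 / MINI_RATE_SCALE,
                                size=int(self.syn_has_mini.sum()))
        self.syn_mini_next[self.syn_has_mini] = first
        self.mini_upsilon = minis.upsilon

        # adjacency: all synapses by global source; plastic by source/target
        self.src_indptr, self.src_order = _csr(self.syn_src, n)
        pl = np.arange(plastic_slice.start, plastic_slice.stop)
        p_src = self.syn_src[pl]
        p_tgt = self.syn_tgt[pl]
        indptr, order = _csr(p_src, layout.n_py)
        self.pl_out_indptr, self.pl_out_edges = indptr, pl[order]
        indptr, order = _csr(p_tgt, layout.n_py)
        self.pl_in_indptr, self.pl_in_edges = indptr, pl[order]

        # ---- neuron state ---------------------------------------------
        def jitter(nn, base):
            return base + rng.normal(0.0, 1.5, size=nn)

        n_py, n_in = layout.n_py, layout.n_in
        n_tc, n_re = layout.n_tc, layout.n_re
        self.py = {
            "v_d": jitter(n_py, -68.0), "v_s": jitter(n_py, -68.0),
            "na_m_d": np.zeros(n_py), "na_h_d": np.ones(n_py),
            "km_n": np.zeros(n_py), "hva_m": np.zeros(n_py),
            "ca": np.full(n_py, py_params.ca_rest),
            "na_m_s": np.zeros(n_py), "na_h_s": np.ones(n_py),
            "k_n_s": np.zeros(n_py),
        }
        self.inn = {
            "v_d": jitter(n_in, -68.0), "v_s": jitter(n_in, -68.0),
            "na_m_d": np.zeros(n_in), "na_h_d": np.ones(n_in),
            "km_n": np.zeros(n_in), "hva_m": np.zeros(n_in),
            "ca": np.full(n_in, py_params.ca_rest),
            "na_m_s": np.zeros(n_in), "na_h_s": np.ones(n_in),
            "k_n_s": np.zeros(n_in),
        }
        self.tc = {
            "v": jitter(n_tc, -68.0), "na_m": np.zeros(n_tc),
            "na_h": np.ones(n_tc), "k_n": np.zeros(n_tc),
            "t_m": np.zeros(n_tc), "t_h": np.full(n_tc, 0.3),
            "h_m": np.full(n_tc, 0.1),
            "ca": np.full(n_tc, tc_params.ca_rest),
        }
        self.re = {
            "v": jitter(n_re, -68.0), "na_m": np.zeros(n_re),
            "na_h": np.ones(n_re), "k_n": np.zeros(n_re),
            "t_m": np.zeros(n_re), "t_h": np.full(n_re, 0.3),
            "ca": np.full(n_re, self.re_params.ca_rest),
        }
        self.last_spike = np.full(n, -1.0e9)
        self.mini_acc = np.zeros((n, 2))   # [:, 0] AMPA-like, [:, 1] GABA-like
        # frozen per-PY excitability heterogeneity (constant bias current,
        # mV/ms) - spreads intrinsic rates so the awake state stays
        # asynchronous
        self.py_bias = rng.normal(0.0, bias_std, size=n_py)

    # -- helpers --------------------------------------------------------

    def projection_slice(self, name: str) -> slice:
        return self._proj_slices[name]

    def set_arousal(self, state) -> None:
        """Apply an ArousalState's modulation scalars to the synapse
        scale factors (the per-neuron K-leak scalars and the HA shift are
        read by the kernel at run time from the state itself)."""
        self._arousal = state
        for proj in self.projections:
            sl = self._proj_slices[proj.name]
            scale = 1.0
            if proj.receptor == "AMPA":
                if proj.source == "PY" and proj.target == "PY":
                    scale = state.ach_ampa_py
                elif proj.source == "TC" and proj.target in ("PY", "IN"):
                    scale = state.ach_ampa_tc
            elif proj.receptor == "GABA_A":
                if proj.source == "IN":
                    scale = state.gamma_gabaa_in
                elif proj.source == "RE":
                    scale = state.gamma_gabaa_re
            self.syn_scale[sl] = scale * self.syn_gain

    def snapshot_weights(self, label: str) -> WeightMatrix:
        sl = self.plastic_slice
        off = self.layout.offset("PY")
        return WeightMatrix(
            n_py=self.layout.n_py,
            pre=self.syn_src[sl] - off, post=self.syn_tgt[sl] - off,
            weights=self.syn_w[sl].copy(), g_max=self.stdp.g_max,
            label=label, time_ms=self.time_ms, seed=self.seed)

    def set_stdp(self, params: STDPParams) -> None:
        self.stdp = params

    # -- main entry -----------------------------------------------------

    def _gating_tables(self):
        """Voltage-indexed tables of x_inf and exp(-dt/tau) per gate.

        Built from the exact rate functions on a 0.05 mV grid and
        linearly interpolated in the kernel; cached per (dt, qt,
        HA shift) since the h-current activation curve moves with the
        arousal state.
        """
        ha = self._arousal.ha_gh
        key = (self.dt, self.qt, ha)
        cache = getattr(self, "_lut_cache", None)
        if cache is None:
            cache = self._lut_cache = {}
        if key in cache:
            return cache[key]
        dt, qt = self.dt, self.qt
        v = np.arange(LUT_V0, LUT_V1 + LUT_DV, LUT_DV)
        n = len(v)

        def ab_rows(alpha, beta, vshift):
            a = np.array([alpha(float(x), vshift) for x in v])
            b = np.array([beta(float(x), vshift) for x in v])
            return a / (a + b), np.exp(-dt * (a + b) * qt)

        def cortical(par):
            lut = np.empty((10, n))
            vs = par.vshift_na
            lut[0], lut[1] = ab_rows(na_alpha_m, na_beta_m, vs)
            lut[2], lut[3] = ab_rows(na_alpha_h, na_beta_h, vs)
            lut[4], lut[5] = ab_rows(k_alpha_n, k_beta_n, vs)
            lut[6] = [km_n_inf(float(x)) for x in v]
            lut[7] = [math.exp(-dt * qt / km_tau(float(x))) for x in v]
            lut[8] = [nap_m_inf(float(x)) for x in v]
            lut[9] = [hva_m_inf(float(x)) for x in v]
            return lut

        def thalamic(par, is_tc):
            lut = np.empty((12 if is_tc else 10, n))
            vs = par.vshift_na
            lut[0], lut[1] = ab_rows(na_alpha_m, na_beta_m, vs)
            lut[2], lut[3] = ab_rows(na_alpha_h, na_beta_h, vs)
            lut[4], lut[5] = ab_rows(k_alpha_n, k_beta_n, vs)
            if is_tc:
                lut[6] = [it_tc_m_inf(float(x)) for x in v]
                lut[7] = [math.exp(-dt / it_tc_tau_m(float(x))) for x in v]
                lut[8] = [it_tc_h_inf(float(x)) for x in v]
                lut[9] = [math.exp(-dt / it_tc_tau_h(float(x))) for x in v]
                lut[10] = [_ih_m_inf(float(x), ha) for x in v]
                lut[11] = [math.exp(-dt / ih_tau(float(x))) for x in v]
            else:
                lut[6] = [it_re_m_inf(float(x)) for x in v]
                lut[7] = [math.exp(-dt / it_re_tau_m(float(x))) for x in v]
                lut[8] = [it_re_h_inf(float(x)) for x in v]
                lut[9] = [math.exp(-dt / it_re_tau_h(float(x))) for x in v]
            return lut

        tables = (cortical(self.py_params), cortical(self.in_params),
                  thalamic(self.tc_params, True),
                  thalamic(self.re_params, False))
        cache[key] = tables
        return tables

    def run(self, duration_ms: float, stimuli: list[StimulusEvent] | None = None,
            seed: int = 0, record: bool = True):
        """Advance the network by ``duration_ms``; returns (ids, times)
        global spike arrays (empty when ``record`` is false)."""
        if not hasattr(self, "_arousal"):
            raise RuntimeError("set_arousal() must be called before run()")
        stimuli = sorted(stimuli or [], key=lambda e: e.t_on)
        n_steps = int(round(duration_ms / self.dt))
        ev_on = np.array([e.t_on for e in stimuli])
        ev_off = np.array([e.t_off for e in stimuli])
        ev_lo = np.array([e.first for e in stimuli], dtype=np.int64)
        ev_hi = np.array([e.last for e in stimuli], dtype=np.int64)
        ev_amp = np.array([e.amplitude for e in stimuli])
        ar = self._arousal
        cap = max(1000, int(self.layout.total * duration_ms / 1000.0 * 250))
        out_ids = np.empty(cap, dtype=np.int64)
        out_t = np.empty(cap)
        p, i_, t_, r_ = (self.py_params, self.in_params, self.tc_params,
                         self.re_params)
        sd = self.stdp
        a_pypy = self.minis.g_pypy
        gkca_scale = getattr(ar, "ach_gkca", 1.0)

        def cpar(q):
            return np.array([
                q.cm, q.g_na_dend, q.g_nap if q.has_nap else 0.0, q.g_km,
                q.g_kca * gkca_scale, q.g_hva, q.g_kl, q.g_leak, q.e_leak,
                q.e_na, q.e_k, q.e_ca, q.g_couple, q.g_na_soma, q.g_k_soma,
                q.g_nap_soma if q.has_nap else 0.0, q.g_leak_soma,
                q.kd_kca, q.ca_gain, q.ca_rest, q.tau_ca,
                math.exp(-self.dt / q.tau_hva)])

        def tpar(q, is_tc):
            return np.array([
                q.cm, q.g_na, q.g_k, q.g_t,
                q.g_h if q.has_ih else 0.0, q.g_kl, q.g_leak, q.e_leak,
                q.e_na, q.e_k, q.e_ca, q.e_h, q.ca_gain, q.ca_rest,
                q.tau_ca, 1.0 if (is_tc and q.has_ih) else 0.0])

        py_lut, in_lut, tc_lut, re_lut = self._gating_tables()
        decay = np.exp(-self.dt / self.syn_tau)
        off_in = self.layout.offset("IN")
        off_tc = self.layout.offset("TC")
        off_re = self.layout.offset("RE")
        n_spk = _run_kernel(
            n_steps, self.dt, self.time_ms, int(seed),
            # PY
            self.py["v_d"], self.py["v_s"], self.py["na_m_d"],
            self.py["na_h_d"], self.py["km_n"], self.py["hva_m"],
            self.py["ca"], self.py["na_m_s"], self.py["na_h_s"],
            self.py["k_n_s"], cpar(p), py_lut,
            # IN
            self.inn["v_d"], self.inn["v_s"], self.inn["na_m_d"],
            self.inn["na_h_d"], self.inn["km_n"], self.inn["hva_m"],
            self.inn["ca"], self.inn["na_m_s"], self.inn["na_h_s"],
            self.inn["k_n_s"], cpar(i_), in_lut,
            # TC / RE
            self.tc["v"], self.tc["na_m"], self.tc["na_h"], self.tc["k_n"],
            self.tc["t_m"], self.tc["t_h"], self.tc["h_m"], self.tc["ca"],
            tpar(t_, True), tc_lut,
            self.re["v"], self.re["na_m"], self.re["na_h"], self.re["k_n"],
            self.re["t_m"], self.re["t_h"], self.re["ca"],
            tpar(r_, False), re_lut,
            off_in, off_tc, off_re,
            # modulation
            ar.ach_gkl_py, ar.ach_gkl_in, ar.ach_gkl_tc, ar.ach_gkl_re,
            # synapses
            self.syn_src, self.syn_tgt, self.syn_w, self.syn_scale,
            self.syn_e, decay, self.syn_is_nmda, self.syn_depress,
            self.syn_O, self.syn_Di, self.syn_last_pre,
            self.depression.u, self.depression.tau_rec,
            # minis
            self.syn_has_mini, self.syn_mini_amp, self.syn_mini_next,
            self.mini_upsilon, self.mini_gain * self.syn_gain, self.mini_acc,
            # adjacency
            self.src_indptr, self.src_order,
            self.pl_out_indptr, self.pl_out_edges,
            self.pl_in_indptr, self.pl_in_edges,
            # STDP
            sd.enabled, sd.a_plus, sd.a_minus, sd.tau_plus, sd.tau_minus,
            sd.f_mini, sd.g_max, a_pypy,
            # stimulation
            self.py_bias, ev_on, ev_off, ev_lo, ev_hi, ev_amp,
            # recording
            self.last_spike, out_ids, out_t, record)
        if n_spk < 0:
            raise FloatingPointError(
                f"numerical blow-up at t~{self.time_ms:.1f}+ ms "
                f"(phase advanced {duration_ms} ms requested)")
        self.time_ms += duration_ms
        return out_ids[:n_spk].copy(), out_t[:n_spk].copy()


LUT_V0 = -130.0
LUT_V1 = 60.0
LUT_DV = 0.05


@njit(cache=True, fastmath=True, inline="always")
def _lut_pos(v):
    pos = (v - LUT_V0) / LUT_DV
    if pos < 0.0:
        pos = 0.0
    elif pos > (LUT_V1 - LUT_V0) / LUT_DV - 1.0:
        pos = (LUT_V1 - LUT_V0) / LUT_DV - 1.0
    i = int(pos)
    return i, pos - i


@njit(cache=True, fastmath=True, inline="always")
def _lk(lut, row, i, f):
    a = lut[row, i]
    return a + f * (lut[row, i + 1] - a)


@njit(cache=True, fastmath=True)
def _run_kernel(n_steps, dt, t0, seed,
                py_vd, py_vs, py_mnd, py_hnd, py_km, py_hva, py_ca,
                py_mns, py_hns, py_kns, py_par, py_lut,
                in_vd, in_vs, in_mnd, in_hnd, in_km, in_hva, in_ca,
                in_mns, in_hns, in_kns, in_par, in_lut,
                tc_v, tc_mn, tc_hn, tc_kn, tc_tm, tc_th, tc_hm, tc_ca,
                tc_par, tc_lut,
                re_v, re_mn, re_hn, re_kn, re_tm, re_th, re_ca,
                re_par, re_lut,
                off_in, off_tc, off_re,
                gkl_py, gkl_in, gkl_tc, gkl_re,
                syn_src, syn_tgt, syn_w, syn_scale, syn_e, syn_decay,
                syn_nmda, syn_depress, syn_O, syn_Di, syn_last_pre,
                dep_u, dep_tau,
                syn_has_mini, syn_mini_amp, syn_mini_next, mini_ups,
                mini_gain, mini_acc,
                src_indptr, src_order,
                pl_out_indptr, pl_out_edges, pl_in_indptr, pl_in_edges,
                stdp_on, a_plus, a_minus, tau_plus, tau_minus,
                f_mini, g_max, a_pypy,
                py_bias, ev_on, ev_off, ev_lo, ev_hi, ev_amp,
                last_spike, out_ids, out_t, record):
    np.random.seed(seed)
    n_py = py_vd.shape[0]
    n_in = in_vd.shape[0]
    n_tc = tc_v.shape[0]
    n_re = re_v.shape[0]
    n_tot = n_py + n_in + n_tc + n_re
    n_syn = syn_src.shape[0]

    vglob = np.empty(n_tot)
    i_syn = np.empty(n_tot)
    stim = np.zeros(n_py)
    mini_decay_a = math.exp(-dt / TAU_AMPA)
    mini_decay_g = math.exp(-dt / TAU_GABA_A)

    spikers = np.empty(n_tot, dtype=np.int64)
    spiked_now = np.zeros(n_tot, dtype=np.bool_)

    n_ev = ev_on.shape[0]
    ev_ptr = 0
    n_spk = 0
    cap = out_ids.shape[0]

    for i in range(n_py):
        vglob[i] = py_vd[i]
    for i in range(n_in):
        vglob[off_in + i] = in_vd[i]
    for i in range(n_tc):
        vglob[off_tc + i] = tc_v[i]
    for i in range(n_re):
        vglob[off_re + i] = re_v[i]

    for step in range(n_steps):
        t = t0 + step * dt

        # -- stimulation pulse edges
        while ev_ptr < n_ev and ev_on[ev_ptr] <= t:
            for j in range(ev_lo[ev_ptr], ev_hi[ev_ptr] + 1):
                stim[j] += ev_amp[ev_ptr]
            ev_ptr += 1
        for q in range(ev_ptr):
            if ev_off[q] > t - dt and ev_off[q] <= t:
                for j in range(ev_lo[q], ev_hi[q] + 1):
                    stim[j] -= ev_amp[q]

        # -- synaptic currents
        for i in range(n_tot):
            i_syn[i] = 0.0
        for k in range(n_syn):
            o = syn_O[k]
            if o > 1e-7:
                tgt = syn_tgt[k]
                v = vglob[tgt]
                g = syn_scale[k] * syn_w[k] * o
                if syn_nmda[k]:
                    g *= 1.0 / (1.0 + 0.28 * math.exp(-0.062 * v))
                i_syn[tgt] += g * (v - syn_e[k])
                syn_O[k] = o * syn_decay[k]
            elif o != 0.0:
                syn_O[k] = 0.0

        # -- miniature PSPs (thinning against the saturation envelope)
        for k in range(n_syn):
            if syn_has_mini[k]:
                while syn_mini_next[k] <= t:
                    t_ref = syn_last_pre[k]
                    lam = 0.0
                    if syn_mini_next[k] > t_ref:
                        lam = (2.0 / (1.0 + math.exp(
                            -(syn_mini_next[k] - t_ref) / mini_ups)) - 1.0) \
                            * MINI_RATE_SCALE
                    if np.random.random() * MINI_RATE_SCALE <= lam:
                        tgt = syn_tgt[k]
                        col = 1 if syn_e[k] < -30.0 else 0
                        # spontaneous events: arousal scaling applies to
                        # evoked transmission only
                        mini_acc[tgt, col] += mini_gain * syn_mini_amp[k]
                    syn_mini_next[k] += np.random.exponential(
                        1.0 / MINI_RATE_SCALE)

        # -- mini currents and decay
        for i in range(n_tot):
            ga = mini_acc[i, 0]
            gg = mini_acc[i, 1]
            if ga > 1e-9:
                i_syn[i] += ga * (vglob[i] - E_AMPA)
                mini_acc[i, 0] = ga * mini_decay_a
            if gg > 1e-9:
                i_syn[i] += gg * (vglob[i] - E_GABA_A)
                mini_acc[i, 1] = gg * mini_decay_g

        n_now = 0

        # -- cortical populations (PY then IN)
        for pop in range(2):
            if pop == 0:
                nn = n_py
                off = 0
                par = py_par
                lut = py_lut
                gkl_mod = gkl_py
            else:
                nn = n_in
                off = off_in
                par = in_par
                lut = in_lut
                gkl_mod = gkl_in
            (cm, gnad, gnap, gkm, gkca, ghva, gkl, gleak, eleak, ena, ek,
             eca, gc, gnas, gks, gnaps, gls, kd, cagain, carest, tauca,
             e_hva) = (par[0], par[1], par[2], par[3], par[4], par[5],
                       par[6], par[7], par[8], par[9], par[10], par[11],
                       par[12], par[13], par[14], par[15], par[16],
                       par[17], par[18], par[19], par[20], par[21])
            for i in range(nn):
                g_id = off + i
                if pop == 0:
                    v_d = py_vd[i]
                    v_s = py_vs[i]
                    m_d = py_mnd[i]
                    h_d = py_hnd[i]
                    km = py_km[i]
                    hva = py_hva[i]
                    ca = py_ca[i]
                    m_s = py_mns[i]
                    h_s = py_hns[i]
                    n_s = py_kns[i]
                    drive = stim[i] + py_bias[i]
                else:
                    v_d = in_vd[i]
                    v_s = in_vs[i]
                    m_d = in_mnd[i]
                    h_d = in_hnd[i]
                    km = in_km[i]
                    hva = in_hva[i]
                    ca = in_ca[i]
                    m_s = in_mns[i]
                    h_s = in_hns[i]
                    n_s = in_kns[i]
                    drive = 0.0

                # somatic gating against the previous somatic voltage
                i0, f = _lut_pos(v_s)
                x = _lk(lut, 0, i0, f)
                m_s = x + (m_s - x) * _lk(lut, 1, i0, f)
                x = _lk(lut, 2, i0, f)
                h_s = x + (h_s - x) * _lk(lut, 3, i0, f)
                x = _lk(lut, 4, i0, f)
                n_s = x + (n_s - x) * _lk(lut, 5, i0, f)
                nap_s = _lk(lut, 8, i0, f)

                # dendritic gating
                i0, f = _lut_pos(v_d)
                x = _lk(lut, 0, i0, f)
                m_d = x + (m_d - x) * _lk(lut, 1, i0, f)
                x = _lk(lut, 2, i0, f)
                h_d = x + (h_d - x) * _lk(lut, 3, i0, f)
                x = _lk(lut, 6, i0, f)
                km = x + (km - x) * _lk(lut, 7, i0, f)
                x = _lk(lut, 9, i0, f)
                hva = x + (hva - x) * e_hva
                nap_d = _lk(lut, 8, i0, f)

                # dendritic currents
                i_na = gnad * m_d * m_d * m_d * h_d * (v_d - ena)
                i_nap = gnap * nap_d * (v_d - ena)
                i_km = gkm * km * (v_d - ek)
                i_kca = gkca * (ca * ca / (ca * ca + kd * kd)) * (v_d - ek)
                i_hva = ghva * hva * hva * (v_d - eca)
                i_kl = gkl * (v_d - ek)
                i_leak = gleak * (v_d - eleak)

                influx = -i_hva
                if influx < 0.0:
                    influx = 0.0
                ca = ca + dt * (cagain * influx - (ca - carest) / tauca)

                dv = (-i_na - i_nap - i_km - i_kca - gkl_mod * i_kl - i_hva
                      - i_leak - gc * (v_d - v_s) - i_syn[g_id] + drive) / cm
                v_d = v_d + dt * dv

                # axo-somatic algebraic balance (linear in V_S with
                # gating frozen)
                g1 = gnas * m_s * m_s * m_s * h_s
                g2 = gnaps * nap_s
                g3 = gks * n_s * n_s * n_s * n_s
                vs_new = ((gc * v_d + (g1 + g2) * ena + g3 * ek + gls * eleak)
                          / (gc + g1 + g2 + g3 + gls))

                if pop == 0:
                    py_vd[i] = v_d
                    py_vs[i] = vs_new
                    py_mnd[i] = m_d
                    py_hnd[i] = h_d
                    py_km[i] = km
                    py_hva[i] = hva
                    py_ca[i] = ca
                    py_mns[i] = m_s
                    py_hns[i] = h_s
                    py_kns[i] = n_s
                else:
                    in_vd[i] = v_d
                    in_vs[i] = vs_new
                    in_mnd[i] = m_d
                    in_hnd[i] = h_d
                    in_km[i] = km
                    in_hva[i] = hva
                    in_ca[i] = ca
                    in_mns[i] = m_s
                    in_hns[i] = h_s
                    in_kns[i] = n_s
                vglob[g_id] = v_d
                if vs_new >= 0.0 and v_s < 0.0 and t - last_spike[g_id] > 3.0:
                    spikers[n_now] = g_id
                    n_now += 1
                if v_d != v_d or abs(v_d) > 500.0:
                    return -1

        # -- thalamic populations (TC then RE)
        for pop in range(2):
            if pop == 0:
                nn = n_tc
                off = off_tc
                par = tc_par
                lut = tc_lut
                gkl_mod = gkl_tc
            else:
                nn = n_re
                off = off_re
                par = re_par
                lut = re_lut
                gkl_mod = gkl_re
            (cm, gna, gk, gt, gh, gkl, gleak, eleak, ena, ek, eca, eh,
             cagain, carest, tauca, has_ih) = (
                par[0], par[1], par[2], par[3], par[4], par[5], par[6],
                par[7], par[8], par[9], par[10], par[11], par[12], par[13],
                par[14], par[15])
            for i in range(nn):
                g_id = off + i
                if pop == 0:
                    v = tc_v[i]
                    m = tc_mn[i]
                    h = tc_hn[i]
                    kn = tc_kn[i]
                    tm = tc_tm[i]
                    th = tc_th[i]
                    hm = tc_hm[i]
                    ca = tc_ca[i]
                else:
                    v = re_v[i]
                    m = re_mn[i]
                    h = re_hn[i]
                    kn = re_kn[i]
                    tm = re_tm[i]
                    th = re_th[i]
                    hm = 0.0
                    ca = re_ca[i]

                i0, f = _lut_pos(v)
                x = _lk(lut, 0, i0, f)
                m = x + (m - x) * _lk(lut, 1, i0, f)
                x = _lk(lut, 2, i0, f)
                h = x + (h - x) * _lk(lut, 3, i0, f)
                x = _lk(lut, 4, i0, f)
                kn = x + (kn - x) * _lk(lut, 5, i0, f)
                x = _lk(lut, 6, i0, f)
                tm = x + (tm - x) * _lk(lut, 7, i0, f)
                x = _lk(lut, 8, i0, f)
                th = x + (th - x) * _lk(lut, 9, i0, f)
                if has_ih > 0.5:
                    x = _lk(lut, 10, i0, f)
                    hm = x + (hm - x) * _lk(lut, 11, i0, f)
                    i_h = gh * hm * (v - eh)
                else:
                    i_h = 0.0

                i_na = gna * m * m * m * h * (v - ena)
                i_k = gk * kn * kn * kn * kn * (v - ek)
                i_t = gt * tm * tm * th * (v - eca)
                i_kl = gkl * (v - ek)
                i_leak = gleak * (v - eleak)

                influx = -i_t
                if influx < 0.0:
                    influx = 0.0
                ca = ca + dt * (cagain * influx - (ca - carest) / tauca)

                v_new = v + dt * (-i_na - i_k - i_t - i_h - gkl_mod * i_kl
                                  - i_leak - i_syn[g_id]) / cm

                if pop == 0:
                    tc_v[i] = v_new
                    tc_mn[i] = m
                    tc_hn[i] = h
                    tc_kn[i] = kn
                    tc_tm[i] = tm
                    tc_th[i] = th
                    tc_hm[i] = hm
                    tc_ca[i] = ca
                else:
                    re_v[i] = v_new
                    re_mn[i] = m
                    re_hn[i] = h
                    re_kn[i] = kn
                    re_tm[i] = tm
                    re_th[i] = th
                    re_ca[i] = ca
                vglob[g_id] = v_new
                if v_new >= 0.0 and v < 0.0 and t - last_spike[g_id] > 3.0:
                    spikers[n_now] = g_id
                    n_now += 1
                if v_new != v_new or abs(v_new) > 500.0:
                    return -1

        if n_now > 0:
            for si in range(n_now):
                spiked_now[spikers[si]] = True

            for si in range(n_now):
                nid = spikers[si]

                # STDP with nearest-spike pairing; exact coincidences
                # (same integration step) are skipped
                if stdp_on and nid < n_py:
                    for e in range(pl_in_indptr[nid], pl_in_indptr[nid + 1]):
                        k = pl_in_edges[e]
                        pre = syn_src[k]
                        if spiked_now[pre] or last_spike[pre] < -1.0e8:
                            continue
                        dtau = t - last_spike[pre]
                        fval = a_plus * math.exp(-dtau / tau_plus)
                        w = syn_w[k] + g_max * fval
                        syn_w[k] = g_max if w > g_max else w
                        mamp = syn_mini_amp[k] + f_mini * a_pypy * fval
                        syn_mini_amp[k] = mamp if mamp > 0.0 else 0.0
                    for e in range(pl_out_indptr[nid], pl_out_indptr[nid + 1]):
                        k = pl_out_edges[e]
                        post = syn_tgt[k]
                        if spiked_now[post] or last_spike[post] < -1.0e8:
                            continue
                        dtau = last_spike[post] - t   # negative
                        fval = -a_minus * math.exp(dtau / tau_minus)
                        w = syn_w[k] + g_max * fval
                        syn_w[k] = 0.0 if w < 0.0 else w
                        mamp = syn_mini_amp[k] + f_mini * a_pypy * fval
                        syn_mini_amp[k] = mamp if mamp > 0.0 else 0.0

                # transmitter release on every outgoing synapse
                for e in range(src_indptr[nid], src_indptr[nid + 1]):
                    k = src_order[e]
                    if syn_depress[k]:
                        if syn_last_pre[k] < -1.0e8:
                            avail = syn_Di[k]
                        else:
                            avail = 1.0 - (1.0 - syn_Di[k] * (1.0 - dep_u)) \
                                * math.exp(-(t - syn_last_pre[k]) / dep_tau)
                        syn_O[k] += avail * (1.0 - syn_O[k])
                        syn_Di[k] = avail
                    else:
                        syn_O[k] += 1.0 - syn_O[k]
                    syn_last_pre[k] = t

                last_spike[nid] = t
                if record and n_spk < cap:
                    out_ids[n_spk] = nid
                    out_t[n_spk] = t
                    n_spk += 1

            for si in range(n_now):
                spiked_now[spikers[si]] = False

    return n_spk
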