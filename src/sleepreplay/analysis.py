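"""Quantitative readouts of simulated rasters and weight snapshots.

This module is deliberately independent of the simulator: every function
consumes a :class:`SpikeRecord` (neuron id / spike time events) or a
:class:`~sleepreplay.network.WeightMatrix`, whether produced by
:func:`~sleepreplay.protocol.run_experiment` or planted synthetically by
:mod:`sleepreplay.fixtures`.

Main readouts
-------------
* sequence recall: smoothed group firing-rate peaks ordered in a 350 ms
  window after the cue, scored against the ideal order with the
  string-match (SM) measure; a trial counts as recalled at SM >= 0.8;
* slow-oscillation structure: Up states detected by 15 ms spike chaining
  separated by >= 300 ms silent (Down) periods;
* replay: group-activation chains within Up states (full-sequence
  replay) and per-synapse nearest-pair STDP-weighted net scores (partial
  replay), with a 66 %-of-Up-states reliability criterion;
* synaptic organization: net left/right group input per neuron, the
  weight- and delay-based directionality indices, reciprocal-pair weight
  scatter, and functionally recurrent vs unidirectional counts under a
  weight threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .network import WeightMatrix
from .synapses import STDPParams, stdp_kernel

__all__ = [
    "SpikeRecord",
    "UpStateInterval",
    "RecallTrial",
    "recall_order",
    "string_match",
    "performance",
    "detect_up_states",
    "group_activation_times",
    "count_sequence_replays",
    "synapse_replay_table",
    "net_left_right_inputs",
    "weight_directionality_index",
    "delay_directionality",
    "response_delays",
    "probe_response_delays",
    "classify_connections",
    "weight_pair_scatter",
]


@dataclass(frozen=True)
class SpikeRecord:
    """An immutable raster: parallel neuron-id / spike-time arrays sorted
    by time, with a phase label."""

    ids: np.ndarray
    times: np.ndarray
    label: str = ""
    duration_ms: float = 0.0

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=np.int64)
        times = np.asarray(self.times, dtype=np.float64)
        if ids.shape != times.shape:
            raise ValueError("ids and times must have equal length")
        if np.any(np.diff(times) < 0):
            order = np.argsort(times, kind="stable")
            ids, times = ids[order], times[order]
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "times", times)
        if self.duration_ms == 0.0 and len(times):
            object.__setattr__(self, "duration_ms", float(times[-1]))

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, neuron_ids: Iterable[int]) -> "SpikeRecord":
        sel = np.isin(self.ids, np.fromiter(neuron_ids, dtype=np.int64))
        return SpikeRecord(self.ids[sel], self.times[sel], self.label,
                           self.duration_ms)

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        sel = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(self.ids[sel], self.times[sel], self.label,
                           self.duration_ms)

    def save(self, path: str | Path) -> None:
        """Three-column delimited text: time_ms, neuron_id, label."""
        with open(path, "w") as fh:
            fh.write("# time_ms\tneuron_id\tphase\n")
            for t, i in zip(self.times, self.ids):
                fh.write(f"{t:.3f}\t{i}\t{self.label}\n")

    @classmethod
    def load(cls, path: str | Path, duration_ms: float = 0.0) -> "SpikeRecord":
        times, ids, label = [], [], ""
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                times.append(float(parts[0]))
                ids.append(int(parts[1]))
                label = parts[2]
        return cls(np.array(ids, dtype=np.int64), np.array(times), label,
                   duration_ms)


@dataclass(frozen=True)
class UpStateInterval:
    start: float
    end: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("Up state must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RecallTrial:
    stim_time: float
    order: str
    score: float
    success: bool


# ---------------------------------------------------------------------------
# Sequence recall
# ---------------------------------------------------------------------------

def recall_order(spikes: SpikeRecord, seq, stim_time: float,
                 window_ms: float = 350.0, kernel_ms: float = 50.0,
                 grid_ms: float = 1.0) -> str:
    """Detected letter order after a first-group cue at ``stim_time``.

    For each group of the sequence the mean instantaneous firing rate of
    its neurons inside ``[stim_time, stim_time + window_ms]`` is binned on
    a 1 ms grid and smoothed with a Gaussian kernel of total window
    ``kernel_ms`` (sigma = window / 4).  Groups that fired at least once
    are ordered by the time of their smoothed-rate peak; exact peak-time
    ties break by ascending group position in the sequence.
    """
    n_bins = int(round(window_ms / grid_ms))
    sigma = kernel_ms / 4.0 / grid_ms
    peaks: list[tuple[float, int, str]] = []
    for pos, letter in enumerate(seq.letters):
        members = seq.group(letter)
        sel = (np.isin(spikes.ids, members)
               & (spikes.times >= stim_time)
               & (spikes.times < stim_time + window_ms))
        if not np.any(sel):
            continue
        rel = spikes.times[sel] - stim_time
        hist, _ = np.histogram(rel, bins=n_bins, range=(0.0, window_ms))
        rate = gaussian_filter1d(hist.astype(float) / len(members), sigma)
        peaks.append((float(np.argmax(rate)) * grid_ms, pos, letter))
    peaks.sort(key=lambda p: (p[0], p[1]))
    return "".join(p[2] for p in peaks)


def string_match(s_test: str, ideal: str) -> float:
    """String-match similarity between a recalled order and the ideal one.

    ``SM = (2 N - sum_i |L(S_sub[i]) - i|) / (2 |ideal|)`` where N is the
    recalled length, ``S_sub`` the ideal sequence restricted to recalled
    letters, and ``L`` the 1-based position in the recalled string.
    Perfect recall scores 1; missing letters cap the score below 1; a
    fully reversed recall scores negative.

    Raises
    ------
    ValueError
        If the recalled string has duplicates or letters outside ``ideal``.
    """
    if len(set(s_test)) != len(s_test):
        raise ValueError(f"duplicate letters in recalled order {s_test!r}")
    if not set(s_test) <= set(ideal):
        raise ValueError(f"letters {set(s_test) - set(ideal)} not in ideal")
    n = len(s_test)
    s_sub = [c for c in ideal if c in s_test]
    total = sum(abs((s_test.index(c) + 1) - (i + 1))
                for i, c in enumerate(s_sub))
    return (2.0 * n - total) / (2.0 * len(ideal))


def performance(trials: Sequence[RecallTrial] | Sequence[float],
                threshold: float = 0.8) -> float:
    """Percent of trials recalled with SM >= threshold."""
    if len(trials) == 0:
        raise ValueError("performance of an empty trial list is undefined")
    scores = [t.score if isinstance(t, RecallTrial) else float(t)
              for t in trials]
    return 100.0 * sum(s >= threshold for s in scores) / len(scores)


def score_test_phase(spikes: SpikeRecord, seq, stim_times: Sequence[float],
                     threshold: float = 0.8, window_ms: float = 350.0
                     ) -> list[RecallTrial]:
    """Score every cue of a test phase (convenience wrapper)."""
    trials = []
    ideal = "".join(seq.letters)
    for t in stim_times:
        order = recall_order(spikes, seq, t, window_ms=window_ms)
        sm = string_match(order, ideal)
        trials.append(RecallTrial(t, order, sm, sm >= threshold))
    return trials


# ---------------------------------------------------------------------------
# Up states and replay
# ---------------------------------------------------------------------------

def detect_up_states(spikes: SpikeRecord, window_ms: float = 15.0,
                     min_down_ms: float = 300.0, min_spikes: int = 5,
                     max_duration_ms: float = 5000.0) -> list[UpStateInterval]:
    """Detect Up states of the slow oscillation from a pooled raster.

    Spikes separated by at most ``window_ms`` chain into candidate
    intervals; candidates separated by silent gaps shorter than
    ``min_down_ms`` merge (a true Down state must last at least 300 ms).
    Intervals with fewer than ``min_spikes`` spikes are discarded as
    spontaneous activity, and intervals longer than ``max_duration_ms``
    are discarded as continuous (non-oscillatory) firing - continuous
    awake-like spiking therefore yields no Up states.
    """
    t = spikes.times
    if len(t) == 0:
        return []
    # chain into candidate runs
    gaps = np.diff(t)
    breaks = np.nonzero(gaps > window_ms)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(t) - 1]))
    runs = [(t[a], t[b], b - a + 1) for a, b in zip(starts, ends)]
    # merge runs separated by less than a Down state
    merged: list[list[float]] = []
    for s, e, n in runs:
        if merged and s - merged[-1][1] < min_down_ms:
            merged[-1][1] = e
            merged[-1][2] += n
        else:
            merged.append([s, e, n])
    out = []
    for s, e, n in merged:
        if n < min_spikes:
            continue
        if e - s > max_duration_ms:
            continue
        if e <= s:
            e = s + 1e-9
        out.append(UpStateInterval(s, e))
    return out


def group_activation_times(spikes: SpikeRecord, group: Iterable[int],
                           window_ms: float = 15.0, threshold: int = 5
                           ) -> np.ndarray:
    """Times at which a neuron group is active.

    A group is active when at least ``threshold`` distinct member neurons
    spike inside a ``window_ms`` window; the activation instant is the
    mean of the first spike times of the earliest ``threshold`` distinct
    neurons in that window.  Detection windows do not overlap.
    """
    sub = spikes.subset(group)
    t, ids = sub.times, sub.ids
    out = []
    i = 0
    n = len(t)
    while i < n:
        win_start = t[i]
        j = i
        seen: dict[int, float] = {}
        while j < n and t[j] <= win_start + window_ms:
            if ids[j] not in seen:
                seen[ids[j]] = t[j]
            j += 1
        if len(seen) >= threshold:
            first = sorted(seen.values())[:threshold]
            out.append(float(np.mean(first)))
            # advance past this detection window entirely
            while i < n and t[i] <= win_start + window_ms:
                i += 1
        else:
            i += 1
    return np.asarray(out)


def count_sequence_replays(activations: Mapping[str, Sequence[float]],
                           letters: Sequence[str]) -> int:
    """Count complete ordered replays of a sequence from per-letter
    activation times.

    All activations merge into one time-sorted stream; a replay is one
    complete ordered chain of all transitions, each activation serving at
    most one replay.  The count is the maximum number of disjoint ordered
    passes, found by the stage-counter scan (an arriving letter advances
    one partial chain waiting for it; a chain completing the last letter
    increments the count).
    """
    stream = sorted((t, letter) for letter in letters
                    for t in activations.get(letter, ()))
    pos = {c: k for k, c in enumerate(letters)}
    stages = [0] * len(letters)   # stages[k]: partial chains ending at k
    count = 0
    for _, letter in stream:
        k = pos[letter]
        if k == 0:
            stages[0] += 1
        elif stages[k - 1] > 0:
            stages[k - 1] -= 1
            if k == len(letters) - 1:
                count += 1
            else:
                stages[k] += 1
    return count


def _nearest_pair_net(pre: np.ndarray, post: np.ndarray,
                      params: STDPParams) -> float:
    """Net STDP-like score over nearest pre/post pairings.

    Each presynaptic spike pairs with its nearest postsynaptic spike and
    vice versa; lags transform through the (balanced) STDP kernel and
    sum.  Positive net = causal (pre-before-post) ordering dominates.
    """
    if len(pre) == 0 or len(post) == 0:
        return 0.0
    net = 0.0
    for t in pre:
        k = np.searchsorted(post, t)
        best = None
        for cand in (k - 1, k):
            if 0 <= cand < len(post):
                if best is None or abs(post[cand] - t) < abs(best - t):
                    best = post[cand]
        net += stdp_kernel(best - t, params)
    for t in post:
        k = np.searchsorted(pre, t)
        best = None
        for cand in (k - 1, k):
            if 0 <= cand < len(pre):
                if best is None or abs(pre[cand] - t) < abs(best - t):
                    best = pre[cand]
        net += stdp_kernel(t - best, params)
    return net


def synapse_replay_table(spikes: SpikeRecord,
                         upstates: Sequence[UpStateInterval],
                         synapses: Sequence[tuple[int, int]],
                         params: STDPParams | None = None,
                         reliability: float = 0.66) -> pd.DataFrame:
    """Per-synapse replay counts over the Up states of a sleep phase.

    For every directed synapse and every Up state, the lags between
    nearest pre/post spike pairs inside the Up state are transformed by a
    balanced STDP-like kernel and summed; a positive net marks the
    synapse as preferentially replayed in that Up state.  The returned
    frame has one row per synapse with the replay count, the number of Up
    states, and a ``reliable`` flag (count > ``reliability`` fraction of
    all Up states).
    """
    if params is None:
        params = STDPParams()  # balanced kernel
    by_neuron: dict[int, np.ndarray] = {}
    needed = {n for s in synapses for n in s}
    for n in needed:
        by_neuron[n] = spikes.times[spikes.ids == n]
    rows = []
    n_up = len(upstates)
    for pre_id, post_id in synapses:
        pre_all = by_neuron[pre_id]
        post_all = by_neuron[post_id]
        count = 0
        for up in upstates:
            pre = pre_all[(pre_all >= up.start) & (pre_all <= up.end)]
            post = post_all[(post_all >= up.start) & (post_all <= up.end)]
            if _nearest_pair_net(pre, post, params) > 0:
                count += 1
        rows.append((pre_id, post_id, count, n_up,
                     n_up > 0 and count > reliability * n_up))
    return pd.DataFrame(rows, columns=["pre", "post", "replay_count",
                                       "n_upstates", "reliable"])


# ---------------------------------------------------------------------------
# Synaptic-input asymmetry and directionality
# ---------------------------------------------------------------------------

def net_left_right_inputs(wm: WeightMatrix, seq) -> pd.DataFrame:
    """Net incoming weight from the left vs right neighboring group.

    For each neuron of the interior groups of ``seq`` (positions
    1..n-2), ``left`` sums the weights of synapses it receives from the
    preceding group and ``right`` those from the following group
    (within-group edges excluded by construction).  The ``diff`` column
    (left - right) is the input-asymmetry statistic.
    """
    dense = wm.dense()
    rows = []
    letters = seq.letters
    for pos in range(1, len(letters) - 1):
        prev_ids = seq.group(letters[pos - 1])
        next_ids = seq.group(letters[pos + 1])
        for neuron in seq.group(letters[pos]):
            l = float(dense[prev_ids, neuron].sum())
            r = float(dense[next_ids, neuron].sum())
            rows.append((int(neuron), letters[pos], l, r, l - r))
    return pd.DataFrame(rows, columns=["neuron", "group", "left", "right",
                                       "diff"])


def weight_directionality_index(left, right, normalize: bool = True):
    """Per-neuron directionality of synaptic input, in [0, 1].

    The (left, right) totals embed into the unit square - when
    ``normalize`` is true each side divides by the maximum single-side
    total of the analyzed set - and the index is the Euclidean distance
    from the square's center scaled by 1/sqrt(0.5), so that purely
    one-sided input maps to 1 and symmetric input to 0.
    """
    l = np.atleast_1d(np.asarray(left, dtype=float))
    r = np.atleast_1d(np.asarray(right, dtype=float))
    if normalize:
        top = max(l.max(initial=0.0), r.max(initial=0.0))
        if top > 0:
            l, r = l / top, r / top
    idx = np.sqrt((l - 0.5) ** 2 + (r - 0.5) ** 2) / math.sqrt(0.5)
    return idx if np.ndim(left) or np.ndim(right) else float(idx[0])


def delay_directionality(dt_s1: float, dt_s1star: float,
                         signed: bool = True) -> float:
    """Response-delay directionality ``(dt_S1* - dt_S1)/(dt_S1* + dt_S1)``
    (signed, in [-1, 1]) or its absolute value (unsigned, in [0, 1]).

    Raises
    ------
    ValueError
        If either delay is non-positive.
    """
    if dt_s1 <= 0 or dt_s1star <= 0:
        raise ValueError("response delays must be positive")
    v = (dt_s1star - dt_s1) / (dt_s1star + dt_s1)
    return v if signed else abs(v)


def response_delays(spikes: SpikeRecord, neuron_ids: Iterable[int],
                    stim_time: float, window_ms: float = 200.0
                    ) -> dict[int, float]:
    """First-spike latency of each neuron after a probe stimulus.

    Neurons that do not fire within ``window_ms`` map to ``nan``.
    """
    out: dict[int, float] = {}
    for n in neuron_ids:
        t = spikes.times[(spikes.ids == n) & (spikes.times >= stim_time)
                         & (spikes.times < stim_time + window_ms)]
        out[int(n)] = float(t[0] - stim_time) if len(t) else float("nan")
    return out


def probe_response_delays(spikes: SpikeRecord, seq,
                          probe_times: Mapping[str, float],
                          window_ms: float = 200.0) -> pd.DataFrame:
    """Left/right response delays of interior-group neurons.

    ``probe_times`` maps each letter to the onset of the trial in which
    that group alone was stimulated.  For every neuron of the interior
    groups the frame holds its first-spike latency after stimulation of
    the preceding (``dt_left``) and following (``dt_right``) group and
    the signed delay-directionality index; neurons missing a response
    on either side carry NaN.
    """
    rows = []
    letters = seq.letters
    for pos in range(1, len(letters) - 1):
        left_t = probe_times[letters[pos - 1]]
        right_t = probe_times[letters[pos + 1]]
        members = seq.group(letters[pos])
        d_left = response_delays(spikes, members, left_t, window_ms)
        d_right = response_delays(spikes, members, right_t, window_ms)
        for n in members:
            dl, dr = d_left[int(n)], d_right[int(n)]
            idx = (delay_directionality(dl, dr)
                   if dl > 0 and dr > 0 else float("nan"))
            rows.append((int(n), letters[pos], dl, dr, idx))
    return pd.DataFrame(rows, columns=["neuron", "group", "dt_left",
                                       "dt_right", "signed_index"])


# ---------------------------------------------------------------------------
# Connection classes
# ---------------------------------------------------------------------------

def _reciprocal_pairs(wm: WeightMatrix) -> tuple[np.ndarray, np.ndarray]:
    mask = wm.mask()
    recip = mask & mask.T
    i, j = np.nonzero(np.triu(recip, k=1))
    return i, j


def classify_connections(wm: WeightMatrix, threshold: float = 0.065
                         ) -> tuple[int, int]:
    """Counts of functionally recurrent and unidirectional connections.

    An anatomically reciprocal neuron pair is *functionally recurrent*
    when both directed weights exceed ``threshold`` and *functionally
    unidirectional* when exactly one does; anatomically one-way edges
    above threshold also count as unidirectional.
    """
    dense = wm.dense()
    mask = wm.mask()
    i, j = _reciprocal_pairs(wm)
    fwd = dense[i, j] > threshold
    bwd = dense[j, i] > threshold
    n_rec = int(np.sum(fwd & bwd))
    n_uni = int(np.sum(fwd ^ bwd))
    oneway = mask & ~mask.T
    a, b = np.nonzero(oneway)
    n_uni += int(np.sum(dense[a, b] > threshold))
    return n_rec, n_uni


def weight_pair_scatter(wm: WeightMatrix) -> np.ndarray:
    """(w_forward, w_backward) for every anatomically reciprocal pair.

    Forward is the ascending-index direction (the S1 direction under the
    canonical sequence layout).  Returns an (n_pairs, 2) array.
    """
    dense = wm.dense()
    i, j = _reciprocal_pairs(wm)
    return np.column_stack((dense[i, j], dense[j, i]))
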