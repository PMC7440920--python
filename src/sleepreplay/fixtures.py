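"""Synthetic rasters and weight matrices with planted structure.

The analysis operations (Up-state detection, replay counting, recall
scoring, directionality indices) are validated against rasters whose
ground truth is known by construction: planted Up/Down alternation,
planted ordered group activations, planted first-spike latencies, and
random weight matrices.  Every generator is deterministic given its
seed and returns both the data and the planted metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import SpikeRecord
from .network import WeightMatrix

__all__ = [
    "planted_upstate_raster",
    "planted_replay_raster",
    "planted_recall_raster",
    "planted_latency_raster",
    "random_weight_matrix",
]


@dataclass(frozen=True)
class PlantedUpStates:
    record: SpikeRecord
    intervals: list[tuple[float, float]]


def planted_upstate_raster(n_neurons: int = 50, n_up: int = 8,
                           up_ms: float = 200.0, down_ms: float = 500.0,
                           rate_hz: float = 40.0, seed: int = 0
                           ) -> PlantedUpStates:
    """Alternating dense-firing Up states and silent Down states.

    During each Up interval every neuron fires as an independent Poisson
    process at ``rate_hz``; Down intervals are fully silent.  The first
    Up state starts one Down interval after t = 0.
    """
    rng = np.random.default_rng(seed)
    ids, times, intervals = [], [], []
    t = down_ms
    for _ in range(n_up):
        for n in range(n_neurons):
            k = rng.poisson(rate_hz * up_ms / 1000.0)
            times.extend(rng.uniform(t, t + up_ms, size=k))
            ids.extend([n] * k)
        intervals.append((t, t + up_ms))
        t += up_ms + down_ms
    rec = SpikeRecord(np.array(ids, dtype=np.int64), np.array(times),
                      "planted-upstates", duration_ms=t)
    return PlantedUpStates(rec, intervals)


@dataclass(frozen=True)
class PlantedReplays:
    record: SpikeRecord
    intervals: list[tuple[float, float]]
    replays_per_up: list[int]
    groups: dict[str, np.ndarray]
    letters: tuple[str, ...]


def planted_replay_raster(group_size: int = 10, n_groups: int = 5,
                          n_up: int = 6, replays: tuple[int, ...] | None = None,
                          gap_ms: float = 12.0, down_ms: float = 500.0,
                          seed: int = 0) -> PlantedReplays:
    """Up states containing a planted number of full ordered sequence
    passes (every group activates with all members synchronous within
    1 ms, groups separated by ``gap_ms``)."""
    rng = np.random.default_rng(seed)
    letters = tuple("ABCDEFGHIJ"[:n_groups])
    groups = {c: np.arange(i * group_size, (i + 1) * group_size,
                           dtype=np.int64)
              for i, c in enumerate(letters)}
    if replays is None:
        replays = tuple(rng.integers(0, 3) for _ in range(n_up))
    ids, times, intervals = [], [], []
    t = down_ms
    for r in replays:
        start = t
        for _ in range(max(r, 1) if r else 1):
            if r == 0:
                # activity without an ordered pass: reversed order
                seq_letters = letters[::-1]
            else:
                seq_letters = letters
            for c in seq_letters:
                for n in groups[c]:
                    ids.append(n)
                    times.append(t + rng.uniform(0.0, 1.0))
                t += gap_ms
            if r == 0:
                break
        intervals.append((start, t))
        t += down_ms
    rec = SpikeRecord(np.array(ids, dtype=np.int64), np.array(times),
                      "planted-replays", duration_ms=t)
    return PlantedReplays(rec, intervals, list(replays), groups, letters)


def planted_recall_raster(seq, stim_time: float, order: str,
                          spacing_ms: float = 40.0, jitter_ms: float = 2.0,
                          n_spikes: int = 6, seed: int = 0,
                          silent: str = "") -> SpikeRecord:
    """A test-trial raster whose groups peak in a prescribed order.

    Group ``order[k]`` fires a burst centered ``(k+1) * spacing_ms``
    after the cue; letters in ``silent`` do not fire at all.
    """
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for k, letter in enumerate(order):
        if letter in silent:
            continue
        center = stim_time + (k + 1) * spacing_ms
        for n in seq.group(letter):
            for _ in range(n_spikes):
                ids.append(n)
                times.append(center + rng.normal(0.0, jitter_ms))
    return SpikeRecord(np.array(ids, dtype=np.int64), np.array(times),
                       "planted-recall", duration_ms=stim_time + 1000.0)


def planted_latency_raster(neuron_ids, stim_time: float,
                           latencies_ms, n_extra: int = 0,
                           seed: int = 0) -> SpikeRecord:
    """First-spike latencies planted exactly; optional later extra spikes
    must not change the measured first-spike latency."""
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for n, lat in zip(neuron_ids, latencies_ms):
        if np.isnan(lat):
            continue
        ids.append(n)
        times.append(stim_time + lat)
        for _ in range(n_extra):
            ids.append(n)
            times.append(stim_time + lat + rng.uniform(5.0, 50.0))
    return SpikeRecord(np.array(ids, dtype=np.int64), np.array(times),
                       "planted-latency", duration_ms=stim_time + 500.0)


def random_weight_matrix(n_py: int = 30, radius: int = 6, p: float = 0.6,
                         mean: float = 0.075, std: float = 0.015,
                         g_max: float = 0.15, seed: int = 0) -> WeightMatrix:
    """A radius-limited random PY->PY weight matrix for analysis tests."""
    rng = np.random.default_rng(seed)
    pre, post = [], []
    for i in range(n_py):
        for j in range(max(0, i - radius), min(n_py, i + radius + 1)):
            if i != j and rng.random() < p:
                pre.append(i)
                post.append(j)
    w = np.clip(rng.normal(mean, std, size=len(pre)), 0.0, g_max)
    return WeightMatrix(n_py=n_py, pre=np.array(pre, dtype=np.int64),
                        post=np.array(post, dtype=np.int64), weights=w,
                        g_max=g_max, label="random-fixture", seed=seed)
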