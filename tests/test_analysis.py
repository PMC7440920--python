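"""Analysis readouts validated against planted fixtures and independent
brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sleepreplay.analysis import (SpikeRecord, UpStateInterval,
                                  classify_connections,
                                  count_sequence_replays,
                                  delay_directionality, detect_up_states,
                                  group_activation_times,
                                  net_left_right_inputs, performance,
                                  recall_order, response_delays,
                                  string_match, synapse_replay_table,
                                  weight_directionality_index,
                                  weight_pair_scatter)
from sleepreplay.fixtures import (planted_latency_raster,
                                  planted_recall_raster,
                                  planted_replay_raster,
                                  planted_upstate_raster,
                                  random_weight_matrix)
from sleepreplay.protocol import make_sequence
from sleepreplay.synapses import STDPParams, stdp_kernel


@pytest.fixture
def seq():
    return make_sequence("S1", start=0, group_size=10, n_groups=5,
                         letters="ABCDE")


# ---------------------------------------------------------------------------
# String match and performance
# ---------------------------------------------------------------------------

class TestStringMatch:
    @pytest.mark.parametrize("test, ideal, expected", [
        ("ABCDE", "ABCDE", 1.0),    # perfect recall
        ("ACBDE", "ABCDE", 0.8),    # one adjacent swap
        ("EDCBA", "ABCDE", -0.2),   # full reversal scores negative
        ("ABC", "ABCDE", 0.6),      # truncated recall capped below 1
        ("", "ABCDE", 0.0),
        ("BA", "ABCDE", 0.2),
    ])
    def test_worked_examples(self, test, ideal, expected):
        assert string_match(test, ideal) == pytest.approx(expected)

    def test_one_iff_complete_and_ordered(self):
        ideal = "ABCDE"
        for perm in itertools.permutations(ideal):
            s = "".join(perm)
            sm = string_match(s, ideal)
            assert sm <= 1.0
            assert (sm == 1.0) == (s == ideal)
        for s in ("ABCD", "ACD", "A"):
            assert string_match(s, ideal) < 1.0

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            string_match("AAB", "ABCDE")

    def test_foreign_letters_rejected(self):
        with pytest.raises(ValueError):
            string_match("ABX", "ABCDE")

    @given(st.permutations(list("ABCDE")))
    @settings(deadline=None, max_examples=60)
    def test_matches_direct_formula(self, perm):
        # independent evaluation of the printed definition
        s = "".join(perm)
        ideal = "ABCDE"
        n = len(s)
        s_sub = [c for c in ideal if c in s]
        total = sum(abs((s.index(c) + 1) - (i + 1))
                    for i, c in enumerate(s_sub))
        assert string_match(s, ideal) == pytest.approx(
            (2 * n - total) / (2 * len(ideal)))


class TestPerformance:
    def test_all_and_none(self):
        assert performance([1.0] * 8) == 100.0
        assert performance([0.2] * 8) == 0.0

    def test_counting(self):
        scores = [0.9] * 7 + [0.5] * 3
        assert performance(scores, threshold=0.8) == 70.0

    def test_trial_order_invariance(self):
        scores = [0.9, 0.1, 0.85, 0.7, 1.0]
        assert performance(scores) == performance(scores[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            performance([])


# ---------------------------------------------------------------------------
# Recall order
# ---------------------------------------------------------------------------

class TestRecallOrder:
    def test_planted_order_recovered(self, seq):
        rec = planted_recall_raster(seq, 1000.0, "ABCDE", spacing_ms=40.0)
        assert recall_order(rec, seq, 1000.0) == "ABCDE"

    def test_silent_group_omitted(self, seq):
        rec = planted_recall_raster(seq, 1000.0, "ABCDE", silent="D")
        assert recall_order(rec, seq, 1000.0) == "ABCE"

    def test_tie_breaks_by_sequence_position(self, seq):
        # B and C peak at exactly the same time: B precedes C in the
        # output by the documented deterministic tie rule
        ids, times = [], []
        for letter, t in (("A", 50.0), ("B", 120.0), ("C", 120.0)):
            for n in seq.group(letter):
                ids.append(n)
                times.append(t)
        rec = SpikeRecord(np.array(ids), np.array(times))
        assert recall_order(rec, seq, 0.0) == "ABC"

    def test_window_excludes_late_activity(self, seq):
        rec = planted_recall_raster(seq, 1000.0, "ABC", spacing_ms=40.0)
        late = planted_recall_raster(seq, 1400.0, "DE", spacing_ms=30.0)
        both = SpikeRecord(np.concatenate([rec.ids, late.ids]),
                           np.concatenate([rec.times, late.times]))
        # D/E bursts fall past the 350 ms window
        assert recall_order(both, seq, 1000.0, window_ms=350.0) == "ABC"

    def test_empty_raster_empty_order(self, seq):
        rec = SpikeRecord(np.array([], dtype=int), np.array([]))
        assert recall_order(rec, seq, 0.0) == ""


# ---------------------------------------------------------------------------
# Up states
# ---------------------------------------------------------------------------

def brute_force_upstates(times, window=15.0, min_down=300.0, min_spikes=5,
                         max_dur=5000.0):
    """Quadratic reference implementation: chain, merge, filter."""
    times = sorted(times)
    if not times:
        return []
    runs = [[times[0], times[0], 1]]
    for t in times[1:]:
        if t - runs[-1][1] <= window:
            runs[-1][1] = t
            runs[-1][2] += 1
        else:
            runs.append([t, t, 1])
    merged = [runs[0]]
    for s, e, n in runs[1:]:
        if s - merged[-1][1] < min_down:
            merged[-1][1] = e
            merged[-1][2] += n
        else:
            merged.append([s, e, n])
    return [(s, e) for s, e, n in merged
            if n >= min_spikes and 0 < e - s <= max_dur]


class TestDetectUpStates:
    def test_planted_intervals_recovered(self):
        fx = planted_upstate_raster(n_up=8, up_ms=200.0, down_ms=500.0,
                                    seed=3)
        ups = detect_up_states(fx.record)
        assert len(ups) == 8
        for u, (s, e) in zip(ups, fx.intervals):
            assert abs(u.start - s) <= 15.0
            assert abs(u.end - e) <= 15.0

    def test_continuous_firing_yields_none(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 30000, size=20000))
        rec = SpikeRecord(np.zeros(len(t), dtype=int), t)
        assert detect_up_states(rec) == []

    def test_empty_raster(self):
        rec = SpikeRecord(np.array([], dtype=int), np.array([]))
        assert detect_up_states(rec) == []

    def test_down_state_requirement_merges_close_bursts(self):
        # two bursts 200 ms apart are one Up state (no 300 ms Down
        # between them)
        t = np.concatenate([np.linspace(0, 100, 50),
                            np.linspace(300, 400, 50)])
        rec = SpikeRecord(np.zeros(100, dtype=int), t)
        ups = detect_up_states(rec)
        assert len(ups) == 1

    @given(st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force_on_random_rasters(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 200))
        t = np.sort(rng.uniform(0, 5000, size=n))
        rec = SpikeRecord(np.zeros(n, dtype=int), t)
        got = [(u.start, u.end) for u in detect_up_states(rec)]
        want = brute_force_upstates(t.tolist())
        assert len(got) == len(want)
        for (a, b), (c, d) in zip(got, want):
            assert a == pytest.approx(c) and b == pytest.approx(d)


# ---------------------------------------------------------------------------
# Group activations and replay counting
# ---------------------------------------------------------------------------

class TestGroupActivation:
    def test_synchronous_group(self):
        rec = SpikeRecord(np.arange(10), np.full(10, 100.0))
        out = group_activation_times(rec, range(10))
        assert len(out) == 1 and out[0] == pytest.approx(100.0)

    def test_below_threshold_no_activation(self):
        rec = SpikeRecord(np.arange(4), np.full(4, 100.0))
        assert len(group_activation_times(rec, range(10))) == 0

    def test_activation_instant_is_mean_of_first_threshold_spikes(self):
        rec = SpikeRecord(np.arange(5), np.array([100., 101., 102., 103.,
                                                  104.]))
        out = group_activation_times(rec, range(10), threshold=5)
        assert out[0] == pytest.approx(102.0)

    def test_distinct_neurons_required(self):
        # one neuron firing five times must not trigger an activation
        rec = SpikeRecord(np.zeros(5, dtype=int),
                          np.array([100., 101., 102., 103., 104.]))
        assert len(group_activation_times(rec, range(10))) == 0

    def test_repeated_activations_non_overlapping(self):
        t = np.concatenate([np.full(10, 100.0), np.full(10, 400.0)])
        rec = SpikeRecord(np.tile(np.arange(10), 2), t)
        out = group_activation_times(rec, range(10))
        assert len(out) == 2


class TestReplayCounting:
    def test_single_ordered_pass(self):
        acts = {c: [10.0 * (i + 1)] for i, c in enumerate("ABCDE")}
        assert count_sequence_replays(acts, tuple("ABCDE")) == 1

    def test_wrong_final_transition(self):
        acts = {"A": [10], "B": [20], "C": [30], "E": [40], "D": [50]}
        assert count_sequence_replays(acts, tuple("ABCDE")) == 0

    def test_two_disjoint_passes(self):
        acts = {c: [10.0 * (i + 1), 100.0 + 10 * (i + 1)]
                for i, c in enumerate("ABCDE")}
        assert count_sequence_replays(acts, tuple("ABCDE")) == 2

    @given(st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=100)
    def test_count_matches_exhaustive_oracle(self, seed):
        # oracle: exhaustive backtracking over every way of assigning
        # activations to disjoint ordered passes
        rng = np.random.default_rng(seed)
        letters = tuple("ABC")
        acts = {c: sorted(rng.uniform(0, 100,
                                      size=rng.integers(0, 5)).tolist())
                for c in letters}
        stream = tuple(c for _, c in
                       sorted((t, c) for c in letters for t in acts[c]))

        from functools import lru_cache

        @lru_cache(maxsize=None)
        def best(remaining):
            top = 0
            n = len(remaining)
            # choose indices of one ordered occurrence, then recurse
            def occurrences(start, stage, used):
                nonlocal top
                if stage == len(letters):
                    rest = tuple(c for i, c in enumerate(remaining)
                                 if i not in used)
                    top = max(top, 1 + best(rest))
                    return
                for i in range(start, n):
                    if remaining[i] == letters[stage]:
                        occurrences(i + 1, stage + 1, used | {i})
            occurrences(0, 0, frozenset())
            return top

        assert count_sequence_replays(acts, letters) == best(stream)


class TestSynapseReplayTable:
    def test_single_causal_pair_counted(self):
        rec = SpikeRecord(np.array([0, 1]), np.array([100.0, 105.0]))
        ups = [UpStateInterval(0.0, 200.0)]
        table = synapse_replay_table(rec, ups, [(0, 1)])
        assert table.loc[0, "replay_count"] == 1

    def test_symmetric_pairs_cancel(self):
        # post-then-pre and pre-then-post at the same lag under the
        # balanced kernel: net zero, not counted
        rec = SpikeRecord(np.array([1, 0, 0, 1]),
                          np.array([100.0, 105.0, 300.0, 305.0]))
        ups = [UpStateInterval(0.0, 400.0)]
        table = synapse_replay_table(rec, ups, [(0, 1)])
        assert table.loc[0, "replay_count"] == 0

    def test_reliability_threshold(self):
        # positive in 2 of 3 Up states: 2/3 > 0.66 must hold strictly
        ids, times = [], []
        for start in (100.0, 1100.0):
            ids += [0, 1]
            times += [start, start + 5.0]
        ids += [1, 0]
        times += [2100.0, 2105.0]
        rec = SpikeRecord(np.array(ids), np.array(times))
        ups = [UpStateInterval(0, 500), UpStateInterval(1000, 1500),
               UpStateInterval(2000, 2500)]
        table = synapse_replay_table(rec, ups, [(0, 1)])
        assert table.loc[0, "replay_count"] == 2
        assert bool(table.loc[0, "reliable"]) is (2 > 0.66 * 3)

    def test_hand_computed_kernel_sums(self):
        # one Up state, pre at 100, posts at 104 and 130: pre pairs with
        # the nearer post (+4), each post pairs with the pre (+4, +30)
        rec = SpikeRecord(np.array([0, 1, 1]), np.array([100.0, 104.0,
                                                         130.0]))
        ups = [UpStateInterval(0, 200)]
        p = STDPParams()
        expected = stdp_kernel(4.0, p) * 2 + stdp_kernel(30.0, p)
        table = synapse_replay_table(rec, ups, [(0, 1)], params=p)
        assert table.loc[0, "replay_count"] == (1 if expected > 0 else 0)
        assert expected > 0


# ---------------------------------------------------------------------------
# Synaptic input asymmetry and directionality
# ---------------------------------------------------------------------------

class TestNetLeftRight:
    def test_uniform_weights_symmetric(self, seq):
        n = 64
        pre, post = [], []
        for pos in range(4):
            for a in range(pos * 10, pos * 10 + 10):
                for b in range((pos + 1) * 10, (pos + 1) * 10 + 10):
                    pre.append(a)
                    post.append(b)
                    pre.append(b)
                    post.append(a)
        from sleepreplay.network import WeightMatrix
        wm = WeightMatrix(n, np.array(pre), np.array(post),
                          np.full(len(pre), 0.05), g_max=0.15)
        df = net_left_right_inputs(wm, seq)
        assert np.allclose(df["left"], 0.5)
        assert np.allclose(df["right"], 0.5)
        assert np.allclose(df["diff"], 0.0)

    def test_matches_brute_force_on_random_fixture(self, seq):
        wm = random_weight_matrix(n_py=50, radius=12, seed=5)
        df = net_left_right_inputs(wm, seq).set_index("neuron")
        dense = wm.dense()
        letters = seq.letters
        for pos in range(1, 4):
            for neuron in seq.group(letters[pos]):
                l = sum(dense[p, neuron] for p in seq.group(letters[pos - 1]))
                r = sum(dense[p, neuron] for p in seq.group(letters[pos + 1]))
                assert df.loc[neuron, "left"] == pytest.approx(l)
                assert df.loc[neuron, "right"] == pytest.approx(r)

    def test_interior_groups_only(self, seq):
        wm = random_weight_matrix(n_py=50, radius=12, seed=6)
        df = net_left_right_inputs(wm, seq)
        assert set(df["group"]) == {"B", "C", "D"}
        assert len(df) == 30


class TestWeightDirectionality:
    def test_center_zero(self):
        assert weight_directionality_index(0.5, 0.5, normalize=False) == \
            pytest.approx(0.0)

    def test_one_sided_input_is_one(self):
        assert weight_directionality_index(1.0, 0.0, normalize=False) == \
            pytest.approx(1.0)

    def test_half_sided(self):
        assert weight_directionality_index(1.0, 0.5, normalize=False) == \
            pytest.approx(0.5 / math.sqrt(0.5))

    def test_swap_invariance(self):
        l = np.array([0.9, 0.2, 0.7])
        r = np.array([0.1, 0.6, 0.7])
        a = weight_directionality_index(l, r, normalize=False)
        b = weight_directionality_index(r, l, normalize=False)
        assert np.allclose(a, b)

    def test_normalization_embeds_unit_square(self):
        idx = weight_directionality_index(np.array([2.0, 0.0]),
                                          np.array([0.0, 2.0]))
        assert np.allclose(idx, 1.0)


class TestDelayDirectionality:
    def test_equal_delays_zero(self):
        assert delay_directionality(20.0, 20.0) == 0.0

    def test_limit_plus_one(self):
        assert delay_directionality(1e-12, 10.0) == pytest.approx(1.0)

    def test_formula_evaluation(self):
        assert delay_directionality(30.0, 10.0) == pytest.approx(-0.5)
        assert delay_directionality(30.0, 10.0, signed=False) == \
            pytest.approx(0.5)

    def test_antisymmetric_under_sequence_swap(self):
        assert delay_directionality(12.0, 30.0) == pytest.approx(
            -delay_directionality(30.0, 12.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            delay_directionality(0.0, 5.0)


class TestResponseDelays:
    def test_planted_latencies_recovered(self):
        lats = [5.0, 12.5, 33.0]
        rec = planted_latency_raster([3, 4, 5], 200.0, lats, n_extra=3,
                                     seed=1)
        out = response_delays(rec, [3, 4, 5], 200.0)
        for n, lat in zip([3, 4, 5], lats):
            assert out[n] == pytest.approx(lat)

    def test_missing_response_flagged_nan(self):
        rec = planted_latency_raster([3], 200.0, [10.0])
        out = response_delays(rec, [3, 4], 200.0)
        assert math.isnan(out[4])

    def test_first_spike_only(self):
        rec = SpikeRecord(np.array([7, 7, 7]), np.array([210.0, 215.0,
                                                         260.0]))
        assert response_delays(rec, [7], 200.0)[7] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Connection classes
# ---------------------------------------------------------------------------

def _wm_from_edges(n, edges):
    from sleepreplay.network import WeightMatrix
    pre, post, w = zip(*edges)
    return WeightMatrix(n, np.array(pre), np.array(post), np.array(w),
                        g_max=0.2)


class TestClassifyConnections:
    def test_both_above_recurrent(self):
        wm = _wm_from_edges(5, [(0, 1, 0.1), (1, 0, 0.1)])
        assert classify_connections(wm, 0.065) == (1, 0)

    def test_one_above_unidirectional(self):
        wm = _wm_from_edges(5, [(0, 1, 0.1), (1, 0, 0.05)])
        assert classify_connections(wm, 0.065) == (0, 1)

    def test_all_below_none(self):
        wm = _wm_from_edges(5, [(0, 1, 0.05), (1, 0, 0.05), (2, 3, 0.02)])
        assert classify_connections(wm, 0.065) == (0, 0)

    def test_anatomically_oneway_counted(self):
        wm = _wm_from_edges(5, [(2, 3, 0.1)])
        assert classify_connections(wm, 0.065) == (0, 1)

    def test_pair_conservation_on_random_fixture(self):
        wm = random_weight_matrix(n_py=40, radius=8, seed=9)
        mask = wm.mask()
        recip_pairs = int(np.sum(np.triu(mask & mask.T, k=1)))
        n_rec, n_uni = classify_connections(wm, 0.065)
        oneway = int(np.sum(mask & ~mask.T))
        assert n_rec <= recip_pairs
        assert n_uni <= recip_pairs + oneway


class TestWeightPairScatter:
    def test_symmetric_matrix_on_diagonal(self):
        wm = _wm_from_edges(6, [(0, 1, 0.07), (1, 0, 0.07),
                                (2, 3, 0.11), (3, 2, 0.11)])
        pts = weight_pair_scatter(wm)
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_hand_built_point_set(self):
        wm = _wm_from_edges(6, [(0, 1, 0.07), (1, 0, 0.02),
                                (2, 4, 0.11), (4, 2, 0.05),
                                (3, 5, 0.09)])
        pts = weight_pair_scatter(wm)
        got = {tuple(np.round(p, 6)) for p in pts}
        assert got == {(0.07, 0.02), (0.11, 0.05)}

    def test_count_equals_reciprocal_pairs(self):
        wm = random_weight_matrix(n_py=40, radius=8, seed=11)
        mask = wm.mask()
        assert len(weight_pair_scatter(wm)) == int(
            np.sum(np.triu(mask & mask.T, k=1)))


# ---------------------------------------------------------------------------
# SpikeRecord I/O
# ---------------------------------------------------------------------------

class TestSpikeRecordIO:
    def test_round_trip(self, tmp_path):
        fx = planted_upstate_raster(seed=4)
        path = tmp_path / "r.tsv"
        fx.record.save(path)
        back = SpikeRecord.load(path)
        assert np.array_equal(back.ids, fx.record.ids)
        assert np.allclose(back.times, fx.record.times, atol=1e-3)

    def test_sorted_on_construction(self):
        rec = SpikeRecord(np.array([1, 2]), np.array([50.0, 10.0]))
        assert rec.times[0] == 10.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SpikeRecord(np.array([1]), np.array([1.0, 2.0]))


class TestProbeResponseDelays:
    def test_planted_probe_delays_and_index(self):
        from sleepreplay.analysis import probe_response_delays
        seq = make_sequence("S", start=0, group_size=2, n_groups=3,
                            letters="ABC")
        # probe A at t=0, B at 1000, C at 2000; group B neurons (2, 3)
        # respond 10/30 ms after the A probe and 30/10 ms after C
        ids = np.array([2, 3, 2, 3])
        times = np.array([10.0, 30.0, 2030.0, 2010.0])
        rec = SpikeRecord(ids, times)
        df = probe_response_delays(rec, seq, {"A": 0.0, "B": 1000.0,
                                              "C": 2000.0})
        df = df.set_index("neuron")
        assert df.loc[2, "dt_left"] == pytest.approx(10.0)
        assert df.loc[2, "dt_right"] == pytest.approx(30.0)
        assert df.loc[2, "signed_index"] == pytest.approx(0.5)
        assert df.loc[3, "signed_index"] == pytest.approx(-0.5)

    def test_missing_side_gives_nan(self):
        from sleepreplay.analysis import probe_response_delays
        seq = make_sequence("S", start=0, group_size=2, n_groups=3,
                            letters="ABC")
        rec = SpikeRecord(np.array([2]), np.array([15.0]))
        df = probe_response_delays(rec, seq, {"A": 0.0, "B": 1000.0,
                                              "C": 2000.0})
        df = df.set_index("neuron")
        assert math.isnan(df.loc[2, "signed_index"])
        assert math.isnan(df.loc[3, "dt_left"])
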