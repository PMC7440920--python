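# sleepreplay

A thalamocortical spiking-network model of sequence learning, sleep
replay, and protection from catastrophic forgetting — for computational
neuroscientists studying how slow-wave sleep reorganizes synaptic
memory traces.

## The science

The model is a Hodgkin–Huxley conductance-based circuit: one cortical
layer (excitatory pyramidal cells PY, inhibitory interneurons IN) and
one thalamic layer (relay cells TC, reticular cells RE), wired with
radius-limited topographic projections. Only PY→PY AMPA synapses are
plastic, governed by spike-timing dependent plasticity

    F(Δt) =  A₊ e^(−|Δt|/τ₊)   Δt > 0
            −A₋ e^(−|Δt|/τ₋)   Δt < 0,     g ← clip(g + g_max F, 0, g_max)

with A₊ = A₋ = 0.002, τ± = 20 ms (A₋ = 0.001 during training). Switching
between an awake-like state (asynchronous firing) and N3 slow-wave
sleep (<1 Hz Up/Down alternation) is modeled by neuromodulation
scalars on GABA_A, cortical AMPA, and potassium leak conductances.

A memory is an ordered "word" of neuron-group "letters" (e.g.
A→B→C→D→E), trained by sequential 10 ms DC pulses with 5 ms gaps, one
trial per second, and tested by cueing only the first group. Recall is
scored with the string match

    SM = (2N − Σᵢ |L(S_sub[i]) − i|) / (2 |ideal|),

counting a trial as recalled at SM ≥ 0.8. Training a second sequence
S1* (the same neurons in reverse order) interferes with S1 —
catastrophic forgetting — and a subsequent period of simulated N3
sleep, during which both traces replay spontaneously within Up states,
reverses the damage and orthogonalizes the two memories onto distinct
synapse subsets.

The analysis suite detects Up states (15 ms spike chaining, ≥300 ms
Down states), counts full-sequence replays from group activations,
scores per-synapse replay reliability with an STDP-like kernel,
measures per-neuron left/right synaptic-input asymmetry and
directionality indices, and classifies reciprocal synapse pairs as
functionally recurrent vs unidirectional under a weight threshold.

See `docs/methods.md` for the full model description and the
desk-scale calibration choices.

## Worked example

```python
from sleepreplay import (ExperimentConfig, Phase, PopulationLayout,
                         make_sequence, run_experiment, performance,
                         detect_up_states)

s1 = make_sequence("S1", start=40, group_size=5, n_groups=5)
cfg = ExperimentConfig(
    layout=PopulationLayout(100, 20, 20, 20),
    radius_scale=0.2, pypy_radius=10,
    sequences={"S1": s1},
    phases=[Phase("test", 10000.0, ("S1",), label="before"),
            Phase("train", 60000.0, ("S1",), label="train"),
            Phase("test", 10000.0, ("S1",), label="after"),
            Phase("sleep", 30000.0, label="sleep")],
    seed=2)
res = run_experiment(cfg)
for label in ("before", "after"):
    trials = res.recall_trials(label)
    print(label, f"{performance(trials):.0f}%",
          [t.order for t in trials])
ups = detect_up_states(res.spikes["sleep"].subset(range(40, 65)))
print("sleep Up states:", len(ups))
```

prints (seed 2):

```
before 10% ['ACBED', 'ABCE', 'ABE', 'ABDEC', 'ABEDC', 'ACEDB', 'AC', 'ACBD', 'ADCE', 'AECDB']
after 80% ['ACBD', 'ABCDE', 'ABCDE', 'ABDCE', 'ABCDE', 'ABCDE', 'ABCDE', 'ACBDE', 'ABECD', 'ABCDE']
sleep Up states: 16
```

Before training, the cue completes the sequence only occasionally (10 %
of trials reach SM ≥ 0.8); after a minute of training most cues recall
the full ordered word (80 %), and the subsequent sleep phase shows
Up/Down alternation whose Up states carry replay. The same protocols are
available from the shell:

```
sleepreplay presets
sleepreplay run --preset fig5-mini --seed 1 --out runs/fig5
sleepreplay analyze --run runs/fig5
```

The `forgetting-full` preset reproduces the full-scale geometry
(500 PY, hundreds of seconds per phase) for the long-training
experiments — e.g. extending S1* training toward 400 s drives the
first memory back to its naive baseline — but needs hours of CPU time
and is not part of the test suite.

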