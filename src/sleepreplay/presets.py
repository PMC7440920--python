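"""Named preset experiments.

Desk-scale presets shrink the circuit by a factor of five (100 PY /
20 IN / 20 TC / 20 RE, groups of 5 neurons) while preserving the
2:1 ratio of the plastic-projection radius to group size that carries
sequence propagation, and shorten phase durations to tens of seconds.
The ``full-scale`` preset reproduces the 500-PY geometry with
full-length phases (minutes of biological time per phase; not intended
for routine test runs).
"""

from __future__ import annotations

from .network import PopulationLayout
from .protocol import ExperimentConfig, Phase, make_sequence

__all__ = ["available_presets", "make_preset"]

# desk-scale geometry: 5 groups of 5 over PY 40-64; the control sequence
# S2 occupies PY 70-94 with the non-linear W-V-X-Y-Z activation order
_MINI = dict(layout=PopulationLayout(100, 20, 20, 20),
             radius_scale=0.2, pypy_radius=10, group_size=5,
             s1_start=40, s2_start=70,
             test_ms=12000.0, train_ms=30000.0, train2_ms=60000.0,
             sleep_ms=75000.0)

_FULL = dict(layout=PopulationLayout(500, 100, 100, 100),
             radius_scale=1.0, pypy_radius=None, group_size=10,
             s1_start=200, s2_start=350,
             test_ms=25000.0, train_ms=200000.0, train2_ms=300000.0,
             sleep_ms=600000.0)


def _sequences(geom):
    s1 = make_sequence("S1", geom["s1_start"], geom["group_size"], 5, "ABCDE")
    s2 = make_sequence("S2", geom["s2_start"], geom["group_size"], 5,
                       "WVXYZ", order=(1, 0, 2, 3, 4))
    return s1, s2


def _base_config(geom, seed):
    return dict(layout=geom["layout"], radius_scale=geom["radius_scale"],
                pypy_radius=geom["pypy_radius"], seed=seed)


def _n3_only(geom, seed):
    return ExperimentConfig(phases=[Phase("sleep", geom["sleep_ms"],
                                          label="sleep")],
                            sequences={}, **_base_config(geom, seed))


def _awake_only(geom, seed):
    return ExperimentConfig(phases=[Phase("rest", geom["sleep_ms"],
                                          label="rest")],
                            sequences={}, **_base_config(geom, seed))


def _fig2(geom, seed):
    """Two spatially separated sequences, then sleep."""
    s1, s2 = _sequences(geom)
    t, tr, sl = geom["test_ms"], geom["train_ms"], geom["sleep_ms"]
    phases = [
        Phase("test", t, ("S1",), label="t0-S1"),
        Phase("test", t, ("S2",), label="t0-S2"),
        Phase("train", tr, ("S1",), label="train-S1"),
        Phase("test", t, ("S1",), label="t1-S1"),
        Phase("train", tr, ("S2",), label="train-S2"),
        Phase("test", t, ("S1",), label="t2-S1"),
        Phase("test", t, ("S2",), label="t2-S2"),
        Phase("sleep", sl, label="sleep"),
        Phase("test", t, ("S1",), label="t3-S1"),
        Phase("test", t, ("S2",), label="t3-S2"),
    ]
    return ExperimentConfig(phases=phases, sequences={"S1": s1, "S2": s2},
                            **_base_config(geom, seed))


def _forgetting(geom, seed, sleep=True):
    """Sequential S1 -> S1* training (competing memories), optionally
    followed by N3 sleep."""
    s1, _ = _sequences(geom)
    s1r = s1.reversed("S1*")
    t, tr, tr2 = geom["test_ms"], geom["train_ms"], geom["train2_ms"]
    phases = [
        Phase("test", t, ("S1",), label="t0-S1"),
        Phase("test", t, ("S1*",), label="t0-S1*"),
        Phase("train", tr, ("S1",), label="train-S1"),
        Phase("test", t, ("S1",), label="t1-S1"),
        Phase("test", t, ("S1*",), label="t1-S1*"),
        Phase("train", tr2, ("S1*",), label="train-S1*"),
        Phase("test", t, ("S1",), label="t2-S1"),
        Phase("test", t, ("S1*",), label="t2-S1*"),
    ]
    if sleep:
        phases += [
            Phase("sleep", geom["sleep_ms"], label="sleep"),
            Phase("test", t, ("S1",), label="t3-S1"),
            Phase("test", t, ("S1*",), label="t3-S1*"),
        ]
    return ExperimentConfig(phases=phases, sequences={"S1": s1, "S1*": s1r},
                            **_base_config(geom, seed))


def _fig5(geom, seed):
    """S1 / S2 / S1* sequential training followed by sleep (snapshot
    labels baseline, post-train-S1, post-train-S2, post-train-S1*,
    post-sleep)."""
    s1, s2 = _sequences(geom)
    s1r = s1.reversed("S1*")
    t, tr, tr2 = geom["test_ms"], geom["train_ms"], geom["train2_ms"]
    phases = [
        Phase("train", tr, ("S1",), label="train-S1"),
        Phase("train", tr, ("S2",), label="train-S2"),
        Phase("train", tr2, ("S1*",), label="train-S1*"),
        Phase("sleep", geom["sleep_ms"], label="sleep"),
    ]
    return ExperimentConfig(phases=phases,
                            sequences={"S1": s1, "S2": s2, "S1*": s1r},
                            **_base_config(geom, seed))


def _interleaved(geom, seed):
    s1, _ = _sequences(geom)
    s1r = s1.reversed("S1*")
    t = geom["test_ms"]
    phases = [
        Phase("test", t, ("S1",), label="t0-S1"),
        Phase("interleaved-train", 2 * geom["train_ms"], ("S1", "S1*"),
              label="interleave"),
        Phase("test", t, ("S1",), label="t1-S1"),
        Phase("test", t, ("S1*",), label="t1-S1*"),
    ]
    return ExperimentConfig(phases=phases, sequences={"S1": s1, "S1*": s1r},
                            **_base_config(geom, seed))


def _probe(geom, seed):
    """Train S1, then probe every group independently (response-delay
    analysis)."""
    s1, _ = _sequences(geom)
    s1r = s1.reversed("S1*")
    phases = [
        Phase("train", geom["train_ms"], ("S1",), label="train-S1"),
        Phase("probe", 5 * s1.period_ms, ("S1",), label="probe-S1"),
        Phase("probe", 5 * s1.period_ms, ("S1*",), label="probe-S1*"),
    ]
    return ExperimentConfig(phases=phases, sequences={"S1": s1, "S1*": s1r},
                            **_base_config(geom, seed))


# minimal geometry for smoke runs and CI of the orchestration layer
_TINY = dict(layout=PopulationLayout(48, 10, 10, 10),
             radius_scale=0.2, pypy_radius=6, group_size=3,
             s1_start=4, s2_start=24,
             test_ms=2000.0, train_ms=3000.0, train2_ms=2000.0,
             sleep_ms=3000.0)

_PRESETS = {
    "smoke": (_forgetting, _TINY),
    "n3-mini": (_n3_only, _MINI),
    "awake-mini": (_awake_only, _MINI),
    "fig2-mini": (_fig2, _MINI),
    "fig5-mini": (_fig5, _MINI),
    "forgetting-mini": (_forgetting, _MINI),
    "interleaved-mini": (_interleaved, _MINI),
    "probe-mini": (_probe, _MINI),
    "fig2-full": (_fig2, _FULL),
    "fig5-full": (_fig5, _FULL),
    "forgetting-full": (_forgetting, _FULL),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def make_preset(name: str, seed: int = 0, **geom_overrides) -> ExperimentConfig:
    """Build a preset :class:`ExperimentConfig`.

    Raises
    ------
    KeyError
        For unknown names, listing the alternatives.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(available_presets())}")
    fn, geom = _PRESETS[name]
    geom = dict(geom)
    geom.update(geom_overrides)
    return fn(geom, seed)
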