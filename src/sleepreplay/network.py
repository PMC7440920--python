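"""Thalamocortical network construction.

The network is a one-dimensional topographic arrangement of four
populations (PY, IN, TC, RE).  Every projection is radius-limited: a
source neuron i contacts target neurons j with
``|center(i) - j| <= radius`` where ``center(i) = round(i * N_target /
N_source)`` maps the source index into target coordinates (self
connections excluded for within-population projections, boundaries
truncated).  PY->PY AMPA edges additionally pass an independent
Bernoulli(0.6) draw; all other projections are deterministic.  Only
PY->PY AMPA weights are plastic; they are initialized from a Gaussian
truncated to [0, g_max].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PopulationLayout",
    "ProjectionSpec",
    "WeightMatrix",
    "default_projections",
    "build_connectivity",
    "init_weights",
    "save_weights",
    "load_weights",
]

POPULATIONS = ("PY", "IN", "TC", "RE")


@dataclass(frozen=True)
class PopulationLayout:
    """Population sizes and contiguous global index ranges.

    Full scale is 500 PY / 100 IN / 100 TC / 100 RE; ``scaled`` builds a
    desk-scale layout from a reduction factor.
    """

    n_py: int = 500
    n_in: int = 100
    n_tc: int = 100
    n_re: int = 100

    def __post_init__(self):
        for name in ("n_py", "n_in", "n_tc", "n_re"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def scaled(cls, factor: int) -> "PopulationLayout":
        return cls(500 // factor, 100 // factor, 100 // factor, 100 // factor)

    def size(self, pop: str) -> int:
        return {"PY": self.n_py, "IN": self.n_in,
                "TC": self.n_tc, "RE": self.n_re}[pop]

    @property
    def total(self) -> int:
        return self.n_py + self.n_in + self.n_tc + self.n_re

    def offset(self, pop: str) -> int:
        """Global index of the first neuron of a population (order PY, IN,
        TC, RE)."""
        off = {"PY": 0, "IN": self.n_py, "TC": self.n_py + self.n_in,
               "RE": self.n_py + self.n_in + self.n_tc}
        return off[pop]

    def population_of(self, global_id: int) -> str:
        if not 0 <= global_id < self.total:
            raise IndexError(f"neuron id {global_id} outside layout")
        for pop in POPULATIONS:
            off = self.offset(pop)
            if off <= global_id < off + self.size(pop):
                return pop
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ProjectionSpec:
    """One radius-limited projection between two populations."""

    source: str
    target: str
    receptor: str                 # AMPA | NMDA | GABA_A | GABA_B
    radius: int
    g_syn: float                  # per-synapse maximal conductance, uS
    probability: float = 1.0
    plastic: bool = False

    def __post_init__(self):
        if self.source not in POPULATIONS or self.target not in POPULATIONS:
            raise ValueError(f"unknown population in {self.source}->{self.target}")
        if self.receptor not in ("AMPA", "NMDA", "GABA_A", "GABA_B"):
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("connection probability must lie in (0, 1]")

    @property
    def name(self) -> str:
        return f"{self.source}-{self.target}.{self.receptor}"


def default_projections(radius_scale: float = 1.0,
                        g_pypy_ampa: float = 0.075,
                        conductances: dict | None = None) -> list[ProjectionSpec]:
    """The thirteen projections of the thalamocortical circuit.

    Radii follow the full-scale values (PY-PY AMPA 20, PY-PY NMDA 5,
    PY-IN 1, IN-PY 5, TC-PY 15, TC-IN 3, PY-TC 10, PY-RE 8, TC-RE 8,
    RE-TC 8 for both GABA receptors, RE-RE 5) multiplied by
    ``radius_scale`` for reduced layouts.  Per-synapse conductances are
    model calibration constants overridable through ``conductances``
    (keyed by projection name).
    """
    def r(x):
        return max(1, int(round(x * radius_scale)))

    g = {
        "PY-PY.AMPA": g_pypy_ampa,
        "PY-PY.NMDA": 0.006,
        "PY-IN.AMPA": 0.12,
        "PY-IN.NMDA": 0.005,
        "IN-PY.GABA_A": 0.24,
        "TC-PY.AMPA": 0.05,
        "TC-IN.AMPA": 0.04,
        "PY-TC.AMPA": 0.025,
        "PY-RE.AMPA": 0.045,
        "TC-RE.AMPA": 0.05,
        "RE-TC.GABA_A": 0.05,
        "RE-TC.GABA_B": 0.004,
        "RE-RE.GABA_A": 0.08,
    }
    if conductances:
        g.update(conductances)
    mk = ProjectionSpec
    return [
        mk("TC", "RE", "AMPA", r(8), g["TC-RE.AMPA"]),
        mk("RE", "TC", "GABA_A", r(8), g["RE-TC.GABA_A"]),
        mk("RE", "TC", "GABA_B", r(8), g["RE-TC.GABA_B"]),
        mk("RE", "RE", "GABA_A", r(5), g["RE-RE.GABA_A"]),
        mk("PY", "PY", "AMPA", r(20), g["PY-PY.AMPA"],
           probability=0.6, plastic=True),
        mk("PY", "PY", "NMDA", r(5), g["PY-PY.NMDA"]),
        mk("PY", "IN", "AMPA", r(1), g["PY-IN.AMPA"]),
        mk("PY", "IN", "NMDA", r(1), g["PY-IN.NMDA"]),
        mk("IN", "PY", "GABA_A", r(5), g["IN-PY.GABA_A"]),
        mk("TC", "PY", "AMPA", r(15), g["TC-PY.AMPA"]),
        mk("TC", "IN", "AMPA", r(3), g["TC-IN.AMPA"]),
        mk("PY", "TC", "AMPA", r(10), g["PY-TC.AMPA"]),
        mk("PY", "RE", "AMPA", r(8), g["PY-RE.AMPA"]),
    ]


def build_connectivity(layout: PopulationLayout, spec: ProjectionSpec,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Realize one projection as parallel (source, target) index arrays.

    Indices are population-local.  Deterministic given ``seed``; the
    Bernoulli draw only applies when ``spec.probability < 1``.

    Raises
    ------
    ValueError
        If the radius exceeds the target population size.
    """
    n_src = layout.size(spec.source)
    n_tgt = layout.size(spec.target)
    if spec.radius >= n_tgt:
        raise ValueError(
            f"radius {spec.radius} too large for target population "
            f"{spec.target} of size {n_tgt}")
    rng = np.random.default_rng(seed)
    src_list: list[int] = []
    tgt_list: list[int] = []
    same = spec.source == spec.target
    for i in range(n_src):
        # block-centered topographic mapping; symmetric under index
        # reversal so the anatomy has no directional bias
        center = int(np.floor((i + 0.5) * n_tgt / n_src))
        center = min(center, n_tgt - 1)
        lo = max(0, center - spec.radius)
        hi = min(n_tgt - 1, center + spec.radius)
        for j in range(lo, hi + 1):
            if same and j == i:
                continue
            if spec.probability >= 1.0 or rng.random() < spec.probability:
                src_list.append(i)
                tgt_list.append(j)
    return (np.asarray(src_list, dtype=np.int64),
            np.asarray(tgt_list, dtype=np.int64))


@dataclass
class WeightMatrix:
    """A snapshot of the plastic PY->PY AMPA layer.

    ``pre``/``post`` are the anatomical edge lists (population-local PY
    indices), ``weights`` the per-edge strengths in uS.  Metadata records
    the phase label, biological time of the snapshot, and the
    connectivity seed.
    """

    n_py: int
    pre: np.ndarray
    post: np.ndarray
    weights: np.ndarray
    g_max: float
    label: str = ""
    time_ms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (len(self.pre) == len(self.post) == len(self.weights)):
            raise ValueError("edge arrays must have equal length")
        if np.any(self.pre == self.post):
            raise ValueError("self-connections are not allowed")
        if np.any(self.weights < 0) or np.any(self.weights > self.g_max + 1e-12):
            raise ValueError("weights outside [0, g_max]")

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def dense(self) -> np.ndarray:
        """Dense (n_py, n_py) weight array; absent edges are 0."""
        w = np.zeros((self.n_py, self.n_py))
        w[self.pre, self.post] = self.weights
        return w

    def mask(self) -> np.ndarray:
        m = np.zeros((self.n_py, self.n_py), dtype=bool)
        m[self.pre, self.post] = True
        return m


def init_weights(pre: np.ndarray, post: np.ndarray, n_py: int,
                 mean: float, std: float, g_max: float, seed: int,
                 label: str = "baseline") -> WeightMatrix:
    """Gaussian initial weights truncated to [0, g_max] by redrawing.

    Raises
    ------
    ValueError
        If ``mean`` is outside [0, g_max] or ``std`` is negative.
    """
    if not 0.0 <= mean <= g_max:
        raise ValueError(f"mean {mean} outside [0, g_max={g_max}]")
    if std < 0:
        raise ValueError("std must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(pre)
    w = rng.normal(mean, std, size=n) if std > 0 else np.full(n, mean)
    bad = (w < 0) | (w > g_max)
    while np.any(bad):
        w[bad] = rng.normal(mean, std, size=int(bad.sum()))
        bad = (w < 0) | (w > g_max)
    return WeightMatrix(n_py=n_py, pre=pre, post=post, weights=w,
                        g_max=g_max, label=label, seed=seed)


def save_weights(wm: WeightMatrix, path: str | Path) -> None:
    """Write a snapshot as tab-separated ``source  target  weight`` with a
    JSON metadata sidecar at ``<path>.meta.json``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tweight\n")
        for s, t, w in zip(wm.pre, wm.post, wm.weights):
            fh.write(f"{s}\t{t}\t{w:.17g}\n")
    meta = {"n_py": wm.n_py, "g_max": wm.g_max, "label": wm.label,
            "time_ms": wm.time_ms, "seed": wm.seed, "n_edges": wm.n_edges}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_weights(path: str | Path) -> WeightMatrix:
    """Read a snapshot written by :func:`save_weights`.

    Raises
    ------
    ValueError
        On malformed rows (reported with the 1-based line number) or if
        the edge list disagrees with the sidecar metadata.
    """
    path = Path(path)
    pre, post, w = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, "
                                 f"got {len(parts)}")
            try:
                pre.append(int(parts[0]))
                post.append(int(parts[1]))
                w.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    with open(path.with_suffix(path.suffix + ".meta.json")) as fh:
        meta = json.load(fh)
    if meta["n_edges"] != len(pre):
        raise ValueError(
            f"{path}: sidecar lists {meta['n_edges']} edges, file has {len(pre)}")
    return WeightMatrix(n_py=meta["n_py"], pre=np.array(pre, dtype=np.int64),
                        post=np.array(post, dtype=np.int64),
                        weights=np.array(w), g_max=meta["g_max"],
                        label=meta["label"], time_ms=meta["time_ms"],
                        seed=meta["seed"])
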