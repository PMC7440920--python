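"""Network construction: radius-limited topographic connectivity, the
probabilistic plastic layer, Gaussian weight initialization, and
snapshot serialization."""

import numpy as np
import pytest

from sleepreplay.network import (PopulationLayout, ProjectionSpec,
                                 WeightMatrix, build_connectivity,
                                 default_projections, init_weights,
                                 load_weights, save_weights)


class TestLayout:
    def test_full_scale_counts(self):
        lay = PopulationLayout()
        assert (lay.n_py, lay.n_in, lay.n_tc, lay.n_re) == (500, 100, 100, 100)

    def test_offsets_disjoint_and_ordered(self):
        lay = PopulationLayout(100, 20, 20, 20)
        offs = [lay.offset(p) for p in ("PY", "IN", "TC", "RE")]
        assert offs == [0, 100, 120, 140]
        assert lay.population_of(119) == "IN"
        assert lay.population_of(140) == "RE"
        with pytest.raises(IndexError):
            lay.population_of(160)

    def test_scaled(self):
        lay = PopulationLayout.scaled(5)
        assert (lay.n_py, lay.n_in) == (100, 20)

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            PopulationLayout(n_py=0)


class TestBuildConnectivity:
    def test_radius_zero_identity(self):
        lay = PopulationLayout(20, 20, 20, 20)
        spec = ProjectionSpec("PY", "IN", "AMPA", radius=0, g_syn=0.1)
        src, tgt = build_connectivity(lay, spec, seed=0)
        assert np.array_equal(src, np.arange(20))
        assert np.array_equal(tgt, np.arange(20))

    def test_radius_respected_exhaustively(self):
        lay = PopulationLayout(30, 10, 10, 10)
        for spec in default_projections(radius_scale=0.25):
            src, tgt = build_connectivity(lay, spec, seed=3)
            n_s, n_t = lay.size(spec.source), lay.size(spec.target)
            centers = np.minimum(np.floor((src + 0.5) * n_t / n_s),
                                 n_t - 1).astype(int)
            assert np.all(np.abs(centers - tgt) <= spec.radius)

    def test_no_self_connections(self):
        lay = PopulationLayout(50, 10, 10, 10)
        spec = ProjectionSpec("PY", "PY", "AMPA", radius=10, g_syn=0.1,
                              probability=0.6)
        src, tgt = build_connectivity(lay, spec, seed=1)
        assert not np.any(src == tgt)

    def test_pypy_out_degree_binomial(self):
        # interior neuron expects 0.6 * (2R+1-1) partners
        lay = PopulationLayout(500, 100, 100, 100)
        spec = ProjectionSpec("PY", "PY", "AMPA", radius=20, g_syn=0.1,
                              probability=0.6)
        src, tgt = build_connectivity(lay, spec, seed=2)
        interior = (src >= 20) & (src < 480)
        deg = np.bincount(src[interior], minlength=500)[20:480]
        expected = 0.6 * 40
        sigma = np.sqrt(40 * 0.6 * 0.4)
        assert abs(deg.mean() - expected) < 3 * sigma / np.sqrt(len(deg))

    def test_edge_count_binomially_consistent_across_seeds(self):
        lay = PopulationLayout(100, 20, 20, 20)
        spec = ProjectionSpec("PY", "PY", "AMPA", radius=10, g_syn=0.1,
                              probability=0.6)
        n_possible = sum(
            min(99, i + 10) - max(0, i - 10) for i in range(100))
        counts = [len(build_connectivity(lay, spec, seed=s)[0])
                  for s in range(50)]
        p_hat = np.mean(counts) / n_possible
        se = np.sqrt(0.6 * 0.4 / (n_possible * 50))
        assert abs(p_hat - 0.6) < 4 * se

    def test_determinism_and_seed_sensitivity(self):
        lay = PopulationLayout(100, 20, 20, 20)
        spec = ProjectionSpec("PY", "PY", "AMPA", radius=10, g_syn=0.1,
                              probability=0.6)
        a1 = build_connectivity(lay, spec, seed=7)
        a2 = build_connectivity(lay, spec, seed=7)
        b = build_connectivity(lay, spec, seed=8)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])
        assert not (len(a1[0]) == len(b[0])
                    and np.array_equal(a1[1], b[1]))

    def test_index_reversal_symmetry(self):
        # the anatomy has no directional bias: reversing all indices maps
        # the edge set onto itself
        lay = PopulationLayout(40, 8, 8, 8)
        spec = ProjectionSpec("PY", "IN", "AMPA", radius=2, g_syn=0.1)
        src, tgt = build_connectivity(lay, spec, seed=0)
        edges = set(zip(src.tolist(), tgt.tolist()))
        mirrored = {(39 - s, 7 - t) for s, t in edges}
        assert edges == mirrored

    def test_oversized_radius_rejected(self):
        lay = PopulationLayout(10, 5, 5, 5)
        spec = ProjectionSpec("PY", "IN", "AMPA", radius=5, g_syn=0.1)
        with pytest.raises(ValueError):
            build_connectivity(lay, spec, seed=0)

    def test_projection_validation(self):
        with pytest.raises(ValueError):
            ProjectionSpec("PY", "XX", "AMPA", 5, 0.1)
        with pytest.raises(ValueError):
            ProjectionSpec("PY", "PY", "AMPA", 5, 0.1, probability=0.0)
        with pytest.raises(ValueError):
            ProjectionSpec("PY", "PY", "GLU", 5, 0.1)


class TestDefaultProjections:
    def test_full_scale_radii(self):
        radii = {p.name: p.radius for p in default_projections()}
        assert radii["PY-PY.AMPA"] == 20
        assert radii["PY-PY.NMDA"] == 5
        assert radii["TC-PY.AMPA"] == 15
        assert radii["RE-TC.GABA_B"] == 8
        assert radii["RE-RE.GABA_A"] == 5
        assert radii["PY-IN.AMPA"] == 1

    def test_only_pypy_ampa_plastic_and_probabilistic(self):
        for p in default_projections():
            if p.name == "PY-PY.AMPA":
                assert p.plastic and p.probability == 0.6
            else:
                assert not p.plastic and p.probability == 1.0


class TestInitWeights:
    def _mask(self, n=200, seed=0):
        lay = PopulationLayout(n, 20, 20, 20)
        spec = ProjectionSpec("PY", "PY", "AMPA", radius=10, g_syn=0.1,
                              probability=0.6)
        return build_connectivity(lay, spec, seed=seed), n

    def test_zero_std_gives_exact_mean(self):
        (pre, post), n = self._mask()
        wm = init_weights(pre, post, n, 0.075, 0.0, 0.15, seed=0)
        assert np.all(wm.weights == 0.075)

    def test_sample_mean_close_to_configured(self):
        (pre, post), n = self._mask()
        wm = init_weights(pre, post, n, 0.075, 0.0075, 0.15, seed=1)
        se = 0.0075 / np.sqrt(len(wm.weights))
        assert abs(wm.weights.mean() - 0.075) < 3 * se

    def test_truncation_bounds(self):
        (pre, post), n = self._mask()
        wm = init_weights(pre, post, n, 0.02, 0.05, 0.15, seed=2)
        assert wm.weights.min() >= 0.0
        assert wm.weights.max() <= 0.15

    def test_mean_outside_bounds_rejected(self):
        (pre, post), n = self._mask()
        with pytest.raises(ValueError):
            init_weights(pre, post, n, 0.2, 0.01, 0.15, seed=0)


class TestWeightMatrixIO:
    def _wm(self, seed=0):
        (pre, post), n = TestInitWeights()._mask(100, seed)
        return init_weights(pre, post, n, 0.075, 0.0075, 0.15, seed=seed,
                            label="post-sleep")

    def test_round_trip_bit_identical(self, tmp_path):
        wm = self._wm()
        path = tmp_path / "w.tsv"
        save_weights(wm, path)
        back = load_weights(path)
        assert np.array_equal(back.pre, wm.pre)
        assert np.array_equal(back.post, wm.post)
        assert np.array_equal(back.weights, wm.weights)
        assert back.label == "post-sleep"

    def test_load_rejects_mismatched_sidecar(self, tmp_path):
        wm = self._wm()
        path = tmp_path / "w.tsv"
        save_weights(wm, path)
        with open(path, "a") as fh:
            fh.write("0\t5\t0.05\n")
        with pytest.raises(ValueError, match="edges"):
            load_weights(path)

    def test_load_reports_malformed_line_number(self, tmp_path):
        wm = self._wm()
        path = tmp_path / "w.tsv"
        save_weights(wm, path)
        lines = path.read_text().splitlines()
        lines[3] = "not\ta-number\tnope"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=":4"):
            load_weights(path)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="self-connections"):
            WeightMatrix(10, [1], [1], [0.05], g_max=0.15)
        with pytest.raises(ValueError, match="outside"):
            WeightMatrix(10, [1], [2], [0.2], g_max=0.15)

    def test_dense_and_mask_agree(self):
        wm = self._wm()
        dense = wm.dense()
        mask = wm.mask()
        assert np.all((dense > 0) <= mask)
        assert mask.sum() == wm.n_edges
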