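import numpy as np
import pytest
from scipy.stats import spearmanr

from dynmod.signed_modularity import (
    Partition,
    canonicalize_labels,
    detect_modules,
    null_model,
    qstar,
    within_module_degree_z,
)
from dynmod.windows import ConnectivityMatrix, WindowConfig, dynamic_graphs

from _oracles import qstar_direct, zscores_direct


def two_triangle_graph():
    """Two positive triangles joined by negative edges; planted 2-partition."""
    w = np.full((6, 6), -0.4)
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                w[i, j] = 0.8
    np.fill_diagonal(w, 1.0)
    return w


class TestQstar:
    def test_all_in_one_partition_of_positive_graph_is_zero(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 1.0, (8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        assert qstar(w, np.ones(8, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        w = two_triangle_graph()
        planted = np.array([1, 1, 1, 2, 2, 2])
        assert qstar(w, planted) == pytest.approx(qstar_direct(w, planted), abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(10):
            w = rng.uniform(-1, 1, (7, 7))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 1.0)
            labels = rng.integers(1, 4, 7)
            assert qstar(w, labels) == pytest.approx(qstar_direct(w, labels), abs=1e-12)

    def test_planted_partition_beats_merged(self):
        w = two_triangle_graph()
        planted = np.array([1, 1, 1, 2, 2, 2])
        merged = np.ones(6, dtype=int)
        assert qstar(w, planted) > qstar(w, merged)

    def test_rejects_asymmetric(self):
        w = np.eye(4)
        w[0, 1] = 0.5
        with pytest.raises(ValueError):
            qstar(w, np.ones(4, dtype=int))


class TestDetectModules:
    def test_recovers_planted_two_blocks(self):
        w = two_triangle_graph()
        part = detect_modules(w, n_restarts=5, seed=0)
        assert part.n_modules == 2
        assert np.array_equal(part.labels, np.array([1, 1, 1, 2, 2, 2]))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(-1, 1, (15, 15))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        p1 = detect_modules(w, n_restarts=5, seed=123)
        p2 = detect_modules(w, n_restarts=5, seed=123)
        assert np.array_equal(p1.labels, p2.labels) and p1.qstar == p2.qstar

    def test_detected_at_least_all_in_one(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            w = rng.uniform(-1, 1, (10, 10))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 1.0)
            part = detect_modules(w, n_restarts=5, seed=rng)
            assert part.qstar >= qstar(w, np.ones(10, dtype=int)) - 1e-12


class TestCanonicalization:
    def test_idempotent_and_qstar_preserving(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(5, 9, 12)
        labels[0] = 7
        canon = canonicalize_labels(labels)
        assert canon[0] == 1
        assert np.array_equal(canonicalize_labels(canon), canon)
        w = rng.uniform(-1, 1, (12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        assert qstar(w, labels) == pytest.approx(qstar(w, canon), abs=1e-12)

    def test_partition_validates_contiguity(self):
        with pytest.raises(ValueError):
            Partition(labels=np.array([1, 3, 3]), n_modules=2, qstar=0.0)


class TestNullModel:
    def test_weight_multiset_preserved_exactly(self, stationary_series):
        g = dynamic_graphs(stationary_series, WindowConfig(11)).graphs[0]
        nm = null_model(g, seed=1)
        iu = np.triu_indices(g.n_nodes, 1)
        assert np.array_equal(np.sort(nm.weights[iu]), np.sort(g.weights[iu]))

    def test_strength_sequences_approximately_preserved(self):
        # unequal blocks give a heterogeneous strength sequence, making rank
        # preservation a meaningful target
        from dynmod.synthetic_bold import StateSpec, SwitchingGroundTruth, generate_bold

        spec = StateSpec(1, np.array([1] * 5 + [2] * 7 + [3] * 12), 0.8, -0.2)
        truth = SwitchingGroundTruth.from_sequence(np.ones(100, dtype=int), [spec])
        ts = generate_bold(truth, noise_sd=0.25, seed=7)
        g = dynamic_graphs(ts, WindowConfig(11)).graphs[0]
        for seed in (2, 3, 4):
            nm = null_model(g, seed=seed)
            w0 = g.weights - np.eye(g.n_nodes)
            w1 = nm.weights - np.eye(g.n_nodes)
            for sign in (1.0, -1.0):
                s0 = np.clip(sign * w0, 0, None).sum(1)
                s1 = np.clip(sign * w1, 0, None).sum(1)
                assert spearmanr(s0, s1).statistic >= 0.8

    def test_null_qstar_below_planted_qstar(self):
        w = two_triangle_graph()
        orig = detect_modules(w, n_restarts=5, seed=0).qstar
        nulls = [
            detect_modules(null_model(w, seed=s), n_restarts=5, seed=0).qstar
            for s in range(20)
        ]
        assert np.median(nulls) < orig

    def test_constant_weight_graph_unchanged(self):
        w = np.full((10, 10), 0.5)
        np.fill_diagonal(w, 1.0)
        nm = null_model(w, seed=3)
        assert np.allclose(nm.weights, w)
        assert qstar(nm.weights, np.ones(10, dtype=int)) == pytest.approx(
            qstar(w, np.ones(10, dtype=int)), abs=1e-12
        )


class TestWithinModuleZ:
    def test_identical_strengths_give_zero(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 1.0)
        z = within_module_degree_z(w, np.array([1, 1, 1, 2, 2, 2])).within_module_z
        assert np.allclose(z, 0.0)

    def test_zero_mean_within_each_module(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(-1, 1, (12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        labels = np.array([1] * 5 + [2] * 4 + [3] * 3)
        z = within_module_degree_z(w, labels).within_module_z
        for lab in (1, 2, 3):
            assert z[labels == lab].mean() == pytest.approx(0.0, abs=1e-9)

    def test_matches_two_pass_oracle(self):
        w = np.array(
            [
                [1.0, 0.9, 0.1, -0.2, 0.3],
                [0.9, 1.0, 0.4, -0.1, 0.2],
                [0.1, 0.4, 1.0, 0.6, -0.3],
                [-0.2, -0.1, 0.6, 1.0, 0.5],
                [0.3, 0.2, -0.3, 0.5, 1.0],
            ]
        )
        labels = np.array([1, 1, 1, 2, 2])
        z = within_module_degree_z(w, labels).within_module_z
        assert np.allclose(z, zscores_direct(w - np.eye(5), labels), atol=1e-12)

    def test_singleton_module_is_zero(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 1.0)
        z = within_module_degree_z(w, np.array([1, 2, 2, 2])).within_module_z
        assert z[0] == 0.0

    def test_positive_mode_clips_negative_weights(self):
        w = np.array(
            [
                [1.0, 0.5, -0.8],
                [0.5, 1.0, 0.2],
                [-0.8, 0.2, 1.0],
            ]
        )
        labels = np.ones(3, dtype=int)
        z_pos = within_module_degree_z(w, labels, weight_mode="positive").within_module_z
        clipped = np.clip(w - np.eye(3), 0, None)
        assert np.allclose(z_pos, zscores_direct(clipped, labels), atol=1e-12)
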