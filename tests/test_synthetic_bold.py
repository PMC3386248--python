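import numpy as np
import pytest

from dynmod.synthetic_bold import (
    RoiTimeSeries,
    StateSpec,
    SwitchingGroundTruth,
    generate_bold,
    generate_cohort,
    generate_state_sequence,
)


class TestStateSpec:
    def test_rejects_non_contiguous_labels(self):
        with pytest.raises(ValueError, match="contiguous"):
            StateSpec(1, np.array([1, 1, 3, 3]), 0.5, -0.1)

    def test_rejects_non_psd_structure(self):
        # three tiny blocks with strong mutual anticorrelation cannot be a
        # valid correlation matrix
        cmap = np.array([1, 1, 2, 2, 3, 3])
        with pytest.raises(ValueError, match="positive semi-definite"):
            StateSpec(1, cmap, 0.5, -0.6)

    def test_rho_bounds(self):
        cmap = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError):
            StateSpec(1, cmap, 1.2, -0.1)
        with pytest.raises(ValueError):
            StateSpec(1, cmap, 0.5, 0.3)

    def test_correlation_matrix_blocks(self):
        spec = StateSpec(1, np.array([1, 1, 2, 2]), 0.6, -0.2)
        corr = spec.correlation()
        assert corr[0, 1] == 0.6
        assert corr[0, 2] == -0.2
        assert np.all(np.diag(corr) == 1.0)


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        seq = generate_state_sequence(100, np.eye(2), [1.0, 0.0], seed=0)
        assert np.all(seq == 1)
        truth = SwitchingGroundTruth.from_sequence(
            seq, [StateSpec(i, np.array([1, 1, 2, 2]), 0.5, -0.1) for i in (1, 2)]
        )
        assert truth.occupancy == {1: 1.0}

    def test_occupancy_law_of_large_numbers(self):
        trans = np.array([[0.5, 0.5], [0.5, 0.5]])
        seq = generate_state_sequence(10000, trans, [0.5, 0.5], seed=42)
        # independent tally
        tally = sum(1 for s in seq if s == 1) / len(seq)
        assert abs(tally - 0.5) < 0.02

    def test_length_one_sequence(self):
        seq = generate_state_sequence(1, np.eye(3), [0.0, 1.0, 0.0], seed=0)
        assert seq.shape == (1,) and seq[0] == 2

    def test_non_stochastic_row_names_offender(self):
        trans = np.array([[0.5, 0.5], [0.3, 0.3]])
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            generate_state_sequence(10, trans, [1.0, 0.0], seed=0)

    def test_deterministic_under_seed(self):
        trans = np.array([[0.7, 0.3], [0.4, 0.6]])
        a = generate_state_sequence(200, trans, [0.5, 0.5], seed=9)
        b = generate_state_sequence(200, trans, [0.5, 0.5], seed=9)
        assert np.array_equal(a, b)

    def test_occupancy_matches_sequence_tally_exactly(self):
        trans = np.array([[0.9, 0.1], [0.2, 0.8]])
        specs = [StateSpec(i, np.array([1, 1, 2, 2]), 0.5, -0.1) for i in (1, 2)]
        seq = generate_state_sequence(97, trans, [0.5, 0.5], seed=3)
        truth = SwitchingGroundTruth.from_sequence(seq, specs)
        for sid, frac in truth.occupancy.items():
            assert frac == np.mean(seq == sid)


class TestGenerateBold:
    def test_single_state_correlations_converge(self):
        cmap = np.array([1] * 10 + [2] * 10)
        spec = StateSpec(1, cmap, 0.8, -0.3)
        truth = SwitchingGroundTruth.from_sequence(np.ones(5000, dtype=int), [spec])
        ts = generate_bold(truth, noise_sd=0.0, seed=11)
        corr = np.corrcoef(ts.data.T)
        within = corr[0, 1:10]
        between = corr[:10, 10:].ravel()
        assert np.all(np.abs(within - 0.8) < 0.05)
        assert np.all(np.abs(between + 0.3) < 0.05)

    def test_noise_dominated_limit(self):
        cmap = np.array([1] * 5 + [2] * 5)
        spec = StateSpec(1, cmap, 0.8, -0.3)
        truth = SwitchingGroundTruth.from_sequence(np.ones(5000, dtype=int), [spec])
        ts = generate_bold(truth, noise_sd=100.0, smoothing_halfwidth=0, seed=12)
        corr = np.corrcoef(ts.data.T)
        off = corr[np.triu_indices(10, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_bit_identical_under_seed(self):
        cmap = np.array([1, 1, 2, 2])
        spec = StateSpec(1, cmap, 0.5, -0.2)
        truth = SwitchingGroundTruth.from_sequence(np.ones(50, dtype=int), [spec])
        a = generate_bold(truth, noise_sd=0.3, seed=5)
        b = generate_bold(truth, noise_sd=0.3, seed=5)
        assert np.array_equal(a.data, b.data)


class TestRoiTimeSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            RoiTimeSeries(np.zeros((5, 1)), 3.0, ["a"])
        with pytest.raises(ValueError):
            RoiTimeSeries(np.full((5, 2), np.nan), 3.0, ["a", "b"])
        with pytest.raises(ValueError):
            RoiTimeSeries(np.zeros((5, 2)), 3.0, ["a", "a"])


class TestGenerateCohort:
    SPECS = [
        StateSpec(1, np.array([1, 1, 2, 2]), 0.6, -0.2),
        StateSpec(2, np.array([1, 2, 1, 2]), 0.6, -0.2),
    ]

    def test_single_subject_cohort(self):
        cohort = generate_cohort(
            {"A": 1}, {"A": np.eye(2)}, self.SPECS, T=30, seed=0
        )
        assert len(cohort) == 1 and cohort[0].group == "A"
        assert cohort[0].timeseries.data.shape == (30, 4)

    def test_mismatched_group_labels_error(self):
        with pytest.raises(ValueError, match="group labels"):
            generate_cohort({"A": 1}, {"B": np.eye(2)}, self.SPECS, T=10, seed=0)

    def test_deterministic_and_truths_retained(self):
        kw = dict(
            n_per_group={"A": 2, "B": 2},
            group_transitions={"A": np.eye(2), "B": np.array([[0.0, 1.0], [1.0, 0.0]])},
            specs=self.SPECS,
            T=40,
            seed=77,
        )
        c1 = generate_cohort(**kw)
        c2 = generate_cohort(**kw)
        for s1, s2 in zip(c1, c2):
            assert np.array_equal(s1.timeseries.data, s2.timeseries.data)
            assert np.array_equal(s1.truth.state_sequence, s2.truth.state_sequence)

    def test_biased_group_has_higher_occupancy(self):
        # group B biased toward state 2; tally wins over 100 seeded replicates
        biased = np.array([[0.2, 0.8], [0.1, 0.9]])
        fair = np.array([[0.8, 0.2], [0.9, 0.1]])
        wins = 0
        for rep in range(100):
            cohort = generate_cohort(
                {"A": 3, "B": 3},
                {"A": fair, "B": biased},
                self.SPECS,
                T=100,
                noise_sd=0.0,
                seed=rep,
            )
            occ = {"A": [], "B": []}
            for subj in cohort:
                occ[subj.group].append(subj.truth.occupancy.get(2, 0.0))
            wins += np.mean(occ["B"]) > np.mean(occ["A"])
        assert wins >= 95
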