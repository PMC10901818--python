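import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spreadpred import (ExperimentConfig, fit_and_predict, kendall_tau,
                        r_squared, recognition_rate, run_experiment,
                        split_nodes)

from .oracles import brute_kendall_tau_b


class TestSplit:
    def test_sizes_and_disjointness(self):
        rng = np.random.default_rng(0)
        train, test = split_nodes(100, 0.1, rng)
        assert len(train) == 10 and len(test) == 90
        assert len(np.intersect1d(train, test)) == 0

    def test_same_seed_same_split(self):
        a = split_nodes(50, 0.2, np.random.default_rng(5))
        b = split_nodes(50, 0.2, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])

    def test_inclusion_frequency_uniform(self):
        # each node lands in S_q with probability q (binomial CI over resamples)
        rng = np.random.default_rng(1)
        counts = np.zeros(50)
        reps = 4000
        for _ in range(reps):
            train, _ = split_nodes(50, 0.1, rng)
            counts[train] += 1
        freq = counts / reps
        se = np.sqrt(0.1 * 0.9 / reps)
        assert (np.abs(freq - 0.1) < 5 * se).all()

    def test_too_small_training_set_rejected(self):
        with pytest.raises(ValueError):
            split_nodes(10, 0.1, np.random.default_rng(0))


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_predictor_is_zero(self):
        y = np.array([1.0, 2, 3, 4])
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_value(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_training_mean_identity(self):
        # on the test set, the constant train-mean predictor has r2 <= 0,
        # with equality iff the train and test means coincide
        y_test = np.array([1.0, 2.0, 3.0])
        assert r_squared(y_test, np.full(3, y_test.mean())) == pytest.approx(0)
        assert r_squared(y_test, np.full(3, 5.0)) < 0


class TestKendallTau:
    def test_identical_and_reversed(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example(self):
        # pairs: (1,2) tied in a only -> T; (2,3) tied in b only -> U;
        # (1,3) concordant => 1/sqrt(2*2)
        assert kendall_tau([1, 1, 2], [1, 2, 2]) == pytest.approx(0.5)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])

    def test_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 20, size=200).astype(float)
        b = a + rng.integers(-3, 4, size=200)
        assert kendall_tau(a, b) == pytest.approx(brute_kendall_tau_b(a, b))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=30)
        b = rng.normal(size=30) + a
        tau = kendall_tau(a, b)
        assert kendall_tau(np.exp(a), b) == pytest.approx(tau)
        assert kendall_tau(a, 3 * b + 7) == pytest.approx(tau)


class TestRecognitionRate:
    def test_perfect(self):
        s = np.arange(20.0)
        assert recognition_rate(s, s, 10) == pytest.approx(1.0)

    def test_half_overlap(self):
        s = np.arange(20.0)
        s_hat = s.copy()
        s_hat[19], s_hat[0] = s_hat[0], s_hat[19]  # displace one of top-2
        assert recognition_rate(s_hat, s, 10) == pytest.approx(0.5)

    def test_reversed_is_zero(self):
        s = np.arange(20.0)
        assert recognition_rate(-s, s, 10) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            recognition_rate(np.array([]), np.array([]), 10)

    def test_ceiling_keeps_one_element(self):
        s = np.arange(5.0)
        assert recognition_rate(s, s, 10) == pytest.approx(1.0)  # m = ceil(0.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40)
        s_hat = rng.normal(size=40)
        r = recognition_rate(s_hat, s, 10)
        assert recognition_rate(np.expm1(s_hat), s**3, 10) == pytest.approx(r)


class TestFitAndPredict:
    def _smooth_data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 3))
        y = x[:, 0]
        return x, y

    def test_self_consistency_single_feature_target(self):
        x, y = self._smooth_data()
        train = np.arange(0, 300, 3)
        test = np.setdiff1d(np.arange(300), train)
        yhat = fit_and_predict(x, y, train, test, seed=0)
        assert r_squared(y[test], yhat) > 0.9

    def test_permuted_pairing_destroys_signal(self):
        x, y = self._smooth_data()
        rng = np.random.default_rng(1)
        y_perm = rng.permutation(y)
        train = np.arange(0, 300, 3)
        test = np.setdiff1d(np.arange(300), train)
        yhat = fit_and_predict(x, y_perm, train, test, seed=0)
        assert r_squared(y_perm[test], yhat) < 0.2

    def test_ridge_recovers_linear_target(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 3.0])
        train, test = np.arange(100), np.arange(100, 200)
        yhat = fit_and_predict(x, y, train, test, regressor="ridge", seed=0)
        assert r_squared(y[test], yhat) > 0.99

    def test_constant_target_warns_and_predicts_constant(self):
        x = np.random.default_rng(0).random((20, 2))
        y = np.full(20, 3.0)
        with pytest.warns(UserWarning, match="constant"):
            yhat = fit_and_predict(x, y, np.arange(10), np.arange(10, 20))
        np.testing.assert_allclose(yhat, 3.0)

    def test_misaligned_features_rejected(self):
        with pytest.raises(ValueError):
            fit_and_predict(np.ones((5, 2)), np.ones(6),
                            np.arange(3), np.arange(3, 5))


class TestRunExperiment:
    def test_aggregation_arithmetic(self):
        rng = np.random.default_rng(4)
        x = rng.random((80, 2))
        y = x[:, 0] + 0.01 * rng.normal(size=80)
        single = run_experiment(x, y, ExperimentConfig(realizations=1,
                                                       rng_seed=9))
        many = run_experiment(x, y, ExperimentConfig(realizations=5,
                                                     rng_seed=9))
        assert single.mean["r2"] == single.per_realization["r2"].iloc[0]
        assert many.mean["r2"] == pytest.approx(
            many.per_realization["r2"].mean())
        # same root seed -> realization 0 identical
        assert many.per_realization["r2"].iloc[0] == single.mean["r2"]

    def test_monotone_degree_function_recovery(self):
        # influence a noisy monotone function of degree: NWC features at
        # any K >= 1 must rank-predict it well (tau > 0.8)
        import networkx as nx

        from spreadpred import UndirectedGraph, nwc_iterate

        # graph with degrees spread evenly over 1..60
        g = UndirectedGraph.from_networkx(
            nx.havel_hakimi_graph(list(range(1, 61)) * 2))
        rng = np.random.default_rng(12)
        signal = g.degrees.astype(float) ** 1.5
        noise_sd = 0.1 * (signal.max() - signal.min())
        influence = signal + noise_sd * rng.normal(size=g.node_count)
        rep = run_experiment(nwc_iterate(g, 2).values, influence,
                             ExperimentConfig(realizations=10, rng_seed=1))
        assert rep.mean["kendall"] > 0.8

    def test_csv_contains_aggregate_rows(self, tmp_path):
        rng = np.random.default_rng(5)
        x = rng.random((60, 2))
        y = x[:, 0]
        rep = run_experiment(x, y, ExperimentConfig(realizations=3, rng_seed=0))
        rep.to_csv(tmp_path / "eval.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "eval.csv")
        assert list(df["realization"].astype(str)) == ["0", "1", "2",
                                                       "mean", "std"]
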