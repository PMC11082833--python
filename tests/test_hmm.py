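import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from ptrburst.hmm import (
    BinaryStateMatrix,
    EmbeddingConfig,
    PosteriorMatrix,
    embed,
    fit,
    lifetimes,
    loglik,
    loglik_bruteforce,
    threshold,
)

from conftest import random_model


class TestEmbed:
    def test_230ms_window_at_100hz_gives_23_lags(self):
        assert EmbeddingConfig(window=0.230, fs=100.0).n_lags == 23

    def test_even_rounding_forced_odd(self):
        assert EmbeddingConfig(window=0.100, fs=100.0).n_lags % 2 == 1

    def test_constant_series_gives_identical_valid_columns(self):
        emb = embed(np.full(50, 2.0), EmbeddingConfig(window=0.05, fs=100.0))
        cols = emb.matrix[:, emb.valid]
        assert np.all(cols == cols[:, :1])

    def test_impulse_lands_at_shifted_column(self):
        cfg = EmbeddingConfig(window=0.05, fs=100.0)  # 5 lags
        x = np.zeros(30)
        t0 = 14
        x[t0] = 1.0
        emb = embed(x, cfg)
        half = (cfg.n_lags - 1) // 2
        for ell in range(cfg.n_lags):
            lag = ell - half
            row = emb.matrix[ell]
            assert row.sum() == 1.0
            assert row[t0 - lag] == 1.0

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            embed(np.zeros(10), EmbeddingConfig(window=0.230, fs=100.0))


class TestFit:
    def test_single_state_posterior_is_all_ones(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2, 200))
        model, post = fit(X, K=1, seed=0, n_restarts=1, max_iter=10)
        assert np.allclose(post.gamma, 1.0)
        assert np.allclose(model.transition, [[1.0]])

    def test_two_state_hmm_recovered_from_simulation(self):
        # planted 2-state HMM with covariances I and 9I
        rng = np.random.default_rng(1)
        T, d = 5000, 2
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        states = np.empty(T, dtype=int)
        states[0] = 0
        for t in range(1, T):
            states[t] = rng.choice(2, p=A[states[t - 1]])
        X = rng.standard_normal((T, d))
        X[states == 1] *= 3.0
        model, post = fit(X.T, K=2, seed=0, n_restarts=3, max_iter=100)
        decoded = post.gamma.argmax(axis=0)
        confusion = np.zeros((2, 2))
        for s, p in zip(states, decoded):
            confusion[s, p] += 1
        rows, cols = linear_sum_assignment(-confusion)
        accuracy = confusion[rows, cols].sum() / T
        assert accuracy >= 0.95

    def test_loglik_trajectory_non_decreasing(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 400))
        X[:, 100:200] *= 4.0
        model, _ = fit(X, K=2, seed=1, n_restarts=2, max_iter=50)
        traj = np.array(model.loglik_trajectory)
        assert np.all(np.diff(traj) >= -1e-8 * np.maximum(1.0, np.abs(traj[:-1])))

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((2, 300))
        m1, p1 = fit(X, K=2, seed=5, n_restarts=2, max_iter=20)
        m2, p2 = fit(X, K=2, seed=5, n_restarts=2, max_iter=20)
        assert np.array_equal(p1.gamma, p2.gamma)
        assert np.array_equal(m1.covariances, m2.covariances)


class TestLoglikOracle:
    def test_forward_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            K = int(rng.integers(2, 4))
            d = int(rng.integers(1, 4))
            T = int(rng.integers(5, 9))
            model = random_model(rng, K, d)
            X = rng.standard_normal((T, d))
            assert abs(loglik(model, X) - loglik_bruteforce(model, X)) < 1e-8

    def test_single_state_loglik_is_gaussian_sum(self):
        rng = np.random.default_rng(11)
        model = random_model(rng, 1, 2)
        X = rng.standard_normal((6, 2))
        expected = multivariate_normal(
            mean=np.zeros(2), cov=model.covariances[0]
        ).logpdf(X).sum() + np.log(model.initial[0])
        assert abs(loglik(model, X) - expected) < 1e-8

    def test_single_sample_is_mixture_marginal(self):
        rng = np.random.default_rng(12)
        model = random_model(rng, 3, 2)
        x = rng.standard_normal((1, 2))
        dens = [
            model.initial[k]
            * multivariate_normal(mean=np.zeros(2), cov=model.covariances[k]).pdf(x[0])
            for k in range(3)
        ]
        assert abs(loglik(model, x) - np.log(sum(dens))) < 1e-8

    def test_oracle_rejects_large_instances(self):
        rng = np.random.default_rng(13)
        model = random_model(rng, 2, 2)
        with pytest.raises(ValueError):
            loglik_bruteforce(model, rng.standard_normal((11, 2)))

    def test_state_permutation_leaves_loglik_unchanged(self):
        rng = np.random.default_rng(14)
        model = random_model(rng, 3, 2)
        X = rng.standard_normal((40, 2))
        perm = np.array([2, 0, 1])
        from ptrburst.hmm import TdeHmmModel

        permuted = TdeHmmModel(
            K=3,
            transition=model.transition[np.ix_(perm, perm)],
            initial=model.initial[perm],
            covariances=model.covariances[perm],
        )
        assert abs(loglik(model, X) - loglik(permuted, X)) < 1e-8

    def test_forward_agrees_with_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(15)
        model = random_model(rng, 3, 2)
        X = rng.standard_normal((200, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = np.zeros((3, 2))
        ref.covars_ = model.covariances
        assert abs(loglik(model, X) - ref.score(X)) < 1e-6


class TestThreshold:
    def test_two_thirds_rule(self):
        gamma = np.array([[0.70, 0.50], [0.20, 0.30], [0.10, 0.20]])
        onoff = threshold(PosteriorMatrix(gamma)).onoff
        assert onoff[:, 0].tolist() == [1, 0, 0]
        assert onoff[:, 1].tolist() == [0, 0, 0]

    def test_exact_threshold_is_off(self):
        gamma = np.array([[2.0 / 3.0], [1.0 / 6.0], [1.0 / 6.0]])
        assert threshold(PosteriorMatrix(gamma)).onoff.sum() == 0

    def test_threshold_outside_unit_interval_rejected(self):
        gamma = PosteriorMatrix(np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError):
            threshold(gamma, 1.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
    def test_mutual_exclusivity_above_half(self, raw):
        col = np.array(raw) / sum(raw)
        onoff = threshold(PosteriorMatrix(col[:, None]), 0.55).onoff
        assert onoff.sum() <= 1


class TestLifetimes:
    def test_three_sample_run_is_30ms(self):
        onoff = BinaryStateMatrix(np.array([[0, 1, 1, 1, 0]], dtype=np.uint8))
        table = lifetimes(onoff, 100.0, region_name="r")
        assert len(table) == 1
        assert np.isclose(table.duration_s.iloc[0], 0.030)
        assert np.isclose(table.onset_s.iloc[0], 0.01)

    def test_all_zeros_gives_empty_table(self):
        onoff = BinaryStateMatrix(np.zeros((2, 50), dtype=np.uint8))
        assert lifetimes(onoff, 100.0).empty

    def test_run_split_at_concatenation_boundary(self):
        row = np.zeros(20, dtype=np.uint8)
        row[8:14] = 1
        table = lifetimes(
            BinaryStateMatrix(row[None, :]), 100.0, boundaries=[10],
            segment_labels=["p0", "p1"],
        )
        assert len(table) == 2
        assert np.isclose(table.duration_s.tolist(), [0.02, 0.04]).all()
        assert table.participant.tolist() == ["p0", "p1"]

    def test_invalid_fs_rejected(self):
        onoff = BinaryStateMatrix(np.zeros((1, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            lifetimes(onoff, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_total_on_time_preserved(self, bits):
        row = np.array(bits, dtype=np.uint8)
        table = lifetimes(BinaryStateMatrix(row[None, :]), 100.0)
        assert np.isclose(table.duration_s.sum() * 100.0, row.sum())
        assert (table.offset_s > table.onset_s).all()
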