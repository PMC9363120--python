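"""KL-NMF: loss, updates, rescaling, identification, transform, experiments."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from fragsig.histograms import HistogramMatrix
from fragsig.nmf import (KLNMF, fit_nmf, holdout_experiment, kl_divergence,
                         max_cosine_similarity, rescale, stability_experiment,
                         transform_weights, transform_weights_array,
                         tumor_signature_index)


def norm_matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    labels = labels or [f"s{i}" for i in range(values.shape[0])]
    return HistogramMatrix(labels, np.arange(30, 30 + values.shape[1]), values,
                           normalized=True)


class TestKLDivergence:
    def test_exact_reconstruction_is_zero(self):
        rng = np.random.default_rng(0)
        W, H = rng.random((4, 2)), rng.random((2, 6))
        assert kl_divergence(W @ H, W, H) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_formula(self):
        # 1*log(1/2) - 1 + 2 = 1 - log 2
        assert kl_divergence([[1.0]], [[1.0]], [[2.0]]) == pytest.approx(
            1.0 - np.log(2.0))

    def test_zero_observation_contributes_model_mass(self):
        # V=0 where WH=3: the 0*log0 term vanishes, leaving -0 + 3
        assert kl_divergence([[0.0]], [[1.0]], [[3.0]]) == pytest.approx(3.0)

    def test_zero_model_with_positive_observation_is_infinite(self):
        assert kl_divergence([[1.0]], [[0.0]], [[1.0]]) == np.inf

    def test_negative_input_fatal(self):
        with pytest.raises(ValueError):
            kl_divergence([[-1.0]], [[1.0]], [[1.0]])


class TestRescale:
    def test_rows_become_stochastic(self):
        W, H = rescale(np.array([[2.0, 2.0]]), np.array([[1.0, 3.0], [1.0, 1.0]]))
        np.testing.assert_allclose(H[0], [0.25, 0.75])
        np.testing.assert_allclose(W.sum(axis=1), 1.0)

    def test_already_stochastic_unchanged(self):
        W = np.array([[0.3, 0.7]])
        H = np.array([[0.5, 0.5], [0.2, 0.8]])
        W2, H2 = rescale(W, H)
        np.testing.assert_allclose(W2, W)
        np.testing.assert_allclose(H2, H)

    def test_zero_row_fatal(self):
        with pytest.raises(ValueError):
            rescale(np.array([[0.0, 0.0]]), np.ones((2, 3)))

    def test_normalized_reconstruction_invariant(self):
        rng = np.random.default_rng(1)
        W, H = rng.random((5, 3)), rng.random((3, 8))
        W2, H2 = rescale(W, H)
        R1, R2 = W @ H, W2 @ H2
        np.testing.assert_allclose(R1 / R1.sum(axis=1, keepdims=True),
                                   R2 / R2.sum(axis=1, keepdims=True))


class TestFit:
    def test_rank_one_exact(self):
        w = np.array([1.0, 2.0, 0.5, 3.0])
        h = np.array([0.2, 0.5, 0.1, 0.2])
        fact = fit_nmf(norm_matrix(np.outer(w, h)), k=1, restarts=3, seed=0)
        assert fact.loss < 1e-8
        np.testing.assert_allclose(fact.W, 1.0)

    def test_loss_history_non_increasing(self):
        rng = np.random.default_rng(2)
        model = KLNMF(n_components=2, n_restarts=3, max_iter=200,
                      random_state=3).fit(
            rng.random((8, 12)) / 12)
        diffs = np.diff(model.loss_history_)
        assert np.all(diffs <= 1e-10 * np.abs(model.loss_history_[:-1]).max())

    def test_more_restarts_never_worse(self):
        V = norm_matrix(np.random.default_rng(4).random((10, 15)))
        losses = [fit_nmf(V, k=3, restarts=r, max_iter=300, seed=5).loss
                  for r in (1, 3, 8)]
        assert losses[0] >= losses[1] >= losses[2]

    def test_factors_row_stochastic(self):
        fact = fit_nmf(norm_matrix(np.random.default_rng(6).random((6, 9))),
                       k=2, restarts=2, seed=6)
        np.testing.assert_allclose(fact.W.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(fact.H.sum(axis=1), 1.0, atol=1e-9)

    def test_non_normalized_input_fatal(self):
        m = HistogramMatrix(["a", "b"], np.arange(30, 33),
                            np.array([[1, 2, 3], [4, 5, 6]]), normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            fit_nmf(m, k=1)

    def test_k_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            fit_nmf(norm_matrix(np.ones((2, 4))), k=3)

    def test_seed_reproducible(self):
        V = norm_matrix(np.random.default_rng(7).random((6, 10)))
        a = fit_nmf(V, k=2, restarts=4, seed=11)
        b = fit_nmf(V, k=2, restarts=4, seed=11)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_not_worse_than_sklearn_mu(self):
        # independent implementation of the same objective and updates
        from sklearn.decomposition import NMF as SkNMF
        rng = np.random.default_rng(8)
        V = rng.random((15, 25))
        V /= V.sum(axis=1, keepdims=True)
        mine = KLNMF(n_components=3, n_restarts=10, max_iter=2000, tol=1e-9,
                     random_state=0).fit(V)
        sk = SkNMF(3, solver="mu", beta_loss="kullback-leibler", init="random",
                   max_iter=2000, tol=1e-9, random_state=0).fit(V)
        sk_loss = kl_divergence(V, sk.transform(V), sk.components_)
        assert mine.reconstruction_err_ <= sk_loss * 1.05


class TestTumorSignatureIndex:
    def test_lower_mean_length_wins(self):
        H = np.zeros((2, 671))
        H[0, 166 - 30] = 1.0   # mean 166
        H[1, 145 - 30] = 1.0   # mean 145
        fact = _fake_fact(H)
        assert tumor_signature_index(fact) == 1

    def test_k1_returns_zero(self):
        H = np.zeros((1, 671))
        H[0, 100] = 1.0
        assert tumor_signature_index(_fake_fact(H)) == 0

    def test_tie_breaks_low_index(self, caplog):
        H = np.zeros((2, 671))
        H[0, 50] = 1.0
        H[1, 50] = 1.0
        assert tumor_signature_index(_fake_fact(H)) == 0


def _fake_fact(H):
    from fragsig.nmf import Factorization
    k = H.shape[0]
    return Factorization(W=np.ones((1, k)) / k, H=H, loss=0.0, k=k, restarts=1,
                         seed=0, iterations_run=0, row_labels=["s"],
                         lengths=np.arange(30, 30 + H.shape[1]))


class TestTransform:
    def setup_method(self):
        rng = np.random.default_rng(9)
        H = rng.random((2, 20))
        self.H = H / H.sum(axis=1, keepdims=True)

    def test_row_equal_to_signature(self):
        # multiplicative updates approach the simplex boundary at O(1/iter),
        # so the inactive weight decays slowly; 1e-5 is the practical
        # precision at 2e4 iterations
        W = transform_weights_array(self.H[0], self.H, max_iter=20_000,
                                    tol=1e-14)
        np.testing.assert_allclose(W[0], [1.0, 0.0], atol=1e-5)

    def test_constructed_mixture(self):
        v = 0.3 * self.H[0] + 0.7 * self.H[1]
        W = transform_weights_array(v, self.H)
        np.testing.assert_allclose(W[0], [0.3, 0.7], atol=1e-4)

    def test_refit_consistency(self):
        rng = np.random.default_rng(10)
        V = norm_matrix(rng.random((12, 20)))
        fact = fit_nmf(V, k=2, restarts=5, max_iter=4000, tol=1e-10, seed=1)
        W = transform_weights(V, fact.H, max_iter=4000, tol=1e-10)
        assert np.abs(W - fact.W).sum(axis=1).max() < 1e-3

    def test_grid_mismatch_fatal(self):
        with pytest.raises(ValueError, match="grid"):
            transform_weights_array(np.ones(5) / 5, self.H)


class TestCosineSimilarity:
    def test_identical_sets(self):
        H = np.random.default_rng(11).random((3, 10))
        np.testing.assert_allclose(max_cosine_similarity(H, H), 1.0)

    def test_disjoint_support_zero(self):
        a = np.array([[1.0, 1.0, 0.0, 0.0]])
        b = np.array([[0.0, 0.0, 1.0, 1.0]])
        assert max_cosine_similarity(a, b)[0] == pytest.approx(0.0)

    def test_closed_form(self):
        a, b = np.array([[1.0, 1.0]]), np.array([[1.0, 0.0]])
        assert max_cosine_similarity(a, b)[0] == pytest.approx(1 / np.sqrt(2))

    def test_zero_norm_fatal(self):
        with pytest.raises(ValueError):
            max_cosine_similarity(np.zeros((1, 3)), np.ones((1, 3)))


class TestExperiments:
    def _cohort(self):
        from fragsig.histograms import normalize_rows
        from fragsig.synthetic import CohortConfig, simulate_cohort
        m, truth = simulate_cohort(cohort=CohortConfig(
            n_samples=16, depth=20_000, seed=5))
        return normalize_rows(m), truth

    def test_stability_bookkeeping_and_monotonicity(self):
        norm, _ = self._cohort()
        df = stability_experiment(norm, k=2, subset_sizes=[4, 12],
                                  replicates=3, seed=1, restarts=3,
                                  max_iter=500)
        assert len(df) == 2 * 3 * 2
        by_size = df.groupby("subset_size")["similarity"].mean()
        assert by_size[12] >= by_size[4] - 0.02

    def test_holdout_output_and_truth_correlation(self):
        norm, truth = self._cohort()
        df = holdout_experiment(norm, truth.tumor_weight.to_numpy(), k=2,
                                repeats=3, seed=2, restarts=3, max_iter=800)
        assert list(df.columns) == ["repeat", "train_correlation",
                                    "test_correlation"]
        assert len(df) == 3
        assert df.train_correlation.min() > 0.9

    def test_holdout_too_few_rows_fatal(self):
        V = norm_matrix(np.random.default_rng(3).random((3, 8)))
        with pytest.raises(ValueError):
            holdout_experiment(V, np.arange(3.0), k=2)
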