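import numpy as np
import pytest
from scipy.special import expit, logit

from gosepred.cohort import encode_design
from gosepred.polr import (
    PolrError,
    PolrFit,
    RankDeficientError,
    polr_fit,
    polr_fit_reduced,
    polr_negloglik,
    polr_predict,
)


def brute_force_negloglik(beta, zeta, X, y):
    """Independent oracle: per-observation category probability summation."""
    zeta_ext = np.concatenate([[-np.inf], zeta, [np.inf]])
    total = 0.0
    for xi, yi in zip(X, y):
        eta = float(np.dot(xi, beta))
        p = expit(zeta_ext[yi] - eta) - expit(zeta_ext[yi - 1] - eta)
        total -= np.log(p)
    return total


class TestNegloglik:
    def test_single_observation_half(self):
        # y=1, beta=0, zeta_1=0: -log logistic(0) = log 2
        value = polr_negloglik(np.zeros(1), np.array([0.0]), np.array([[0.0]]), [1])
        assert value == pytest.approx(np.log(2), abs=1e-12)

    def test_binary_reduction_to_logistic(self, rng):
        # 2-level outcome: equals binary logistic NLL with intercept -zeta_1
        n = 50
        X = rng.standard_normal((n, 2))
        beta = np.array([0.5, -0.3])
        zeta = np.array([0.4])
        y = rng.integers(1, 3, size=n)
        ours = polr_negloglik(beta, zeta, X, y)
        # binary logistic: P(y=2) = logistic(x.beta - zeta_1)
        p2 = expit(X @ beta - zeta[0])
        manual = -np.sum(np.where(y == 2, np.log(p2), np.log(1 - p2)))
        assert ours == pytest.approx(manual, abs=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n, p, k = 30, 3, 8
            X = rng.standard_normal((n, p))
            beta = rng.standard_normal(p)
            zeta = np.sort(rng.standard_normal(k - 1) * 2)
            zeta += np.arange(k - 1) * 1e-6  # ensure strictly increasing
            y = rng.integers(1, k + 1, size=n)
            ours = polr_negloglik(beta, zeta, X, y)
            oracle = brute_force_negloglik(beta, zeta, X, y)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_non_increasing_zeta_rejected(self):
        with pytest.raises(PolrError, match="increasing"):
            polr_negloglik(np.zeros(1), np.array([1.0, 0.5]), np.zeros((2, 1)), [1, 2])


class TestFit:
    def test_intercept_only_closed_form(self):
        # counts (25, 25, 25, 25): cutpoints are logits of cumulative props
        y = np.repeat([1, 2, 3, 4], 25)
        fit = polr_fit(np.empty((100, 0)), y)
        expected = logit([0.25, 0.5, 0.75])
        np.testing.assert_allclose(fit.zeta, expected, atol=1e-6)

    def test_intercept_only_probs_equal_frequencies(self, rng):
        y = rng.choice([1, 2, 3, 5, 8], size=400, p=[0.3, 0.1, 0.25, 0.15, 0.2])
        fit = polr_fit(np.empty((400, 0)), y)
        probs = polr_predict(fit, np.empty((400, 0)))
        freqs = np.bincount(y, minlength=9)[1:] / y.size
        np.testing.assert_allclose(probs[0], freqs, atol=1e-6)

    def test_parameter_recovery(self, rng):
        # simulate from beta_true = (+0.8, -0.5) at n=5000
        n = 5000
        X = rng.standard_normal((n, 2))
        beta_true = np.array([0.8, -0.5])
        zeta_true = np.array([-1.5, -0.5, 0.5, 1.5])
        cum = expit(zeta_true[None, :] - (X @ beta_true)[:, None])
        y = 1 + (rng.uniform(size=n)[:, None] > cum).sum(1)
        fit = polr_fit(X, y)
        assert fit.converged
        assert np.abs(fit.beta - beta_true).max() < 0.15
        assert np.abs(fit.zeta - zeta_true).max() < 0.15

    def test_zeta_strictly_increasing(self, uppsala_cohort):
        design = encode_design(uppsala_cohort)
        fit = polr_fit(design, uppsala_cohort.data["gose"].to_numpy(int))
        assert np.all(np.diff(fit.zeta) > 0)

    def test_optimum_beats_truth(self, rng):
        n = 1000
        X = rng.standard_normal((n, 2))
        beta_true = np.array([0.6, -0.4])
        zeta_true = np.array([-1.0, 0.0, 1.0])
        cum = expit(zeta_true[None, :] - (X @ beta_true)[:, None])
        y = 1 + (rng.uniform(size=n)[:, None] > cum).sum(1)
        fit = polr_fit(X, y)
        nll_fit = polr_negloglik(fit.beta, fit.zeta, X, y)
        nll_true = polr_negloglik(beta_true, zeta_true, X, y)
        assert nll_fit <= nll_true + 1e-8

    def test_affine_equivariance(self, rng):
        n = 800
        X = rng.standard_normal((n, 1))
        cum = expit(np.array([-0.5, 0.5])[None, :] - (X[:, 0] * 0.7)[:, None])
        y = 1 + (rng.uniform(size=n)[:, None] > cum).sum(1)
        fit1 = polr_fit(X, y)
        fit2 = polr_fit(X * 10.0, y)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] / 10.0, rel=1e-4)
        np.testing.assert_allclose(fit1.zeta, fit2.zeta, rtol=1e-4)

    def test_rank_deficient_names_columns(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        y = rng.integers(1, 4, size=50)
        with pytest.raises(RankDeficientError, match="x2"):
            polr_fit(X, y)

    def test_single_level_rejected(self):
        with pytest.raises(PolrError, match="distinct"):
            polr_fit(np.zeros((10, 1)), [3] * 10)

    def test_complete_separation_flagged(self):
        X = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        y = np.concatenate([np.ones(20, int), np.full(20, 8)])
        fit = polr_fit(X, y)
        assert not fit.converged  # separation: no silent success

    def test_reduced_fit_drops_constant_column(self, rng):
        X = np.column_stack([rng.standard_normal(60), np.zeros(60)])
        y = rng.integers(1, 4, size=60)
        fit = polr_fit_reduced(X, y)
        assert fit.beta[1] == 0.0
        assert len(fit.beta) == 2

    def test_serialization_roundtrip(self, uppsala_cohort):
        design = encode_design(uppsala_cohort)
        fit = polr_fit(design, uppsala_cohort.data["gose"].to_numpy(int))
        back = PolrFit.from_dict(fit.to_dict())
        np.testing.assert_allclose(back.beta, fit.beta)
        np.testing.assert_allclose(back.zeta, fit.zeta)
        assert back.observed_levels == fit.observed_levels


class TestPredict:
    def test_null_beta_constant_vectors(self):
        fit = PolrFit(
            beta=np.zeros(1),
            zeta=logit(np.linspace(0.1, 0.9, 7)),
            columns=["x0"],
            observed_levels=tuple(range(1, 9)),
            n_obs=10,
            loglik=0.0,
            converged=True,
        )
        probs = polr_predict(fit, np.random.default_rng(0).standard_normal((5, 1)))
        assert np.allclose(probs, probs[0])
        implied = np.diff(np.concatenate([[0], np.linspace(0.1, 0.9, 7), [1]]))
        np.testing.assert_allclose(probs[0], implied, atol=1e-12)

    def test_rows_sum_to_one(self, uppsala_cohort):
        design = encode_design(uppsala_cohort)
        fit = polr_fit(design, uppsala_cohort.data["gose"].to_numpy(int))
        probs = polr_predict(fit, design)
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-12)
        assert probs.min() >= 0

    def test_cumulative_monotone(self, uppsala_cohort):
        design = encode_design(uppsala_cohort)
        fit = polr_fit(design, uppsala_cohort.data["gose"].to_numpy(int))
        cum = np.cumsum(polr_predict(fit, design), axis=1)
        assert np.all(np.diff(cum, axis=1) >= -1e-12)

    def test_extreme_eta_concentrates_on_8(self):
        fit = PolrFit(
            beta=np.array([5.0]),
            zeta=np.linspace(-3, 3, 7),
            columns=["x0"],
            observed_levels=tuple(range(1, 9)),
            n_obs=10,
            loglik=0.0,
            converged=True,
        )
        probs = polr_predict(fit, np.array([[100.0]]))
        assert probs[0, 7] == pytest.approx(1.0, abs=1e-9)

    def test_unobserved_levels_zero_mass(self, rng):
        X = rng.standard_normal((200, 1))
        y = rng.choice([1, 3, 8], size=200)
        fit = polr_fit(X, y)
        probs = polr_predict(fit, X)
        assert fit.observed_levels == (1, 3, 8)
        for lvl in (2, 4, 5, 6, 7):
            assert np.all(probs[:, lvl - 1] == 0.0)
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-12)
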