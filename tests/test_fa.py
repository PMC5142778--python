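"""Factor analysis: EM fitting, likelihoods, model selection, metrics."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from popdim.fa import (
    FAModel,
    SharedSpectrum,
    cv_select_m,
    fit_fa,
    log_likelihood,
    mode_variance_fractions,
    per_mode_percent_shared_variance,
    percent_shared_variance,
    shared_dimensionality,
    shared_spectrum,
)
from popdim.synth import GenerativeFASpec, sample_fa_counts


def random_model(rng, n=12, m=3):
    L = rng.standard_normal((n, m))
    psi = rng.uniform(0.5, 2.0, size=n)
    return FAModel(mu=rng.standard_normal(n), L=L, psi=psi, m=m)


class TestLogLikelihood:
    def test_standard_normal_at_mean(self):
        """m=0, Psi=I, single centered observation -> -(n/2) ln(2 pi)."""
        n = 7
        model = FAModel(mu=np.zeros(n), L=np.zeros((n, 0)), psi=np.ones(n), m=0)
        ll = log_likelihood(np.zeros((1, n)), model)
        assert ll == pytest.approx(-n / 2 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_dense_covariance_oracle(self):
        """Woodbury-based likelihood equals scipy's dense MVN density to 1e-8."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            model = random_model(rng, n=10, m=3)
            x = rng.standard_normal((20, 10)) * 2 + model.mu
            dense = multivariate_normal(
                mean=model.mu, cov=model.total_covariance()
            ).logpdf(x)
            assert log_likelihood(x, model) == pytest.approx(
                dense.sum(), rel=1e-10, abs=1e-8
            )

    def test_observation_at_mean_adds_log_normalizer(self):
        rng = np.random.default_rng(1)
        model = random_model(rng, n=6, m=2)
        x = rng.standard_normal((5, 6))
        base = log_likelihood(x, model)
        plus = log_likelihood(np.vstack([x, model.mu]), model)
        sign, logdet = np.linalg.slogdet(2 * np.pi * model.total_covariance())
        assert plus - base == pytest.approx(-0.5 * logdet, rel=1e-10)


class TestFit:
    def test_m0_model_is_sample_variances(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 5)) * np.array([1, 2, 3, 4, 5.0])
        model = fit_fa(x, 0)
        assert model.L.shape == (5, 0)
        np.testing.assert_allclose(model.psi, x.var(axis=0), rtol=1e-12)
        assert shared_dimensionality(model) == 0
        per_neuron, pop = percent_shared_variance(model)
        assert pop == 0.0 and np.all(per_neuron == 0.0)

    def test_em_loglik_nondecreasing(self, three_factor_spec):
        counts = sample_fa_counts(three_factor_spec, 300, seed=3)
        model = fit_fa(counts, 3)
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-9 * np.abs(model.loglik_trace[:-1]))

    def test_generative_recovery(self, three_factor_spec):
        """2000 trials from a known 3-factor model: shared covariance
        recovered to < 15% relative Frobenius error."""
        counts = sample_fa_counts(three_factor_spec, 2000, seed=4)
        model = fit_fa(counts, 3)
        truth = three_factor_spec.L @ three_factor_spec.L.T
        err = np.linalg.norm(model.shared_covariance() - truth) / np.linalg.norm(truth)
        assert err < 0.15

    def test_recovery_improves_with_trials(self, three_factor_spec):
        truth = three_factor_spec.L @ three_factor_spec.L.T
        errs = []
        for n in (500, 2000, 8000):
            counts = sample_fa_counts(three_factor_spec, n, seed=5)
            model = fit_fa(counts, 3)
            errs.append(
                np.linalg.norm(model.shared_covariance() - truth)
                / np.linalg.norm(truth)
            )
        assert errs[0] > errs[1] > errs[2]

    def test_zero_variance_neuron_rejected(self):
        x = np.random.default_rng(0).standard_normal((50, 4))
        x[:, 2] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_fa(x, 1)

    def test_m_too_large_rejected(self):
        x = np.random.default_rng(0).standard_normal((50, 4))
        with pytest.raises(ValueError, match="at most"):
            fit_fa(x, 4)

    def test_few_trials_warns(self):
        x = np.random.default_rng(0).standard_normal((5, 8))
        with pytest.warns(UserWarning, match="trials"):
            fit_fa(x, 1)

    def test_matches_sklearn_fit(self, three_factor_spec):
        """Independent EM route (scikit-learn) lands on the same shared
        covariance on well-conditioned data."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        counts = sample_fa_counts(three_factor_spec, 2000, seed=6)
        x = np.asarray(counts.counts, dtype=float)
        ours = fit_fa(x, 3)
        theirs = sklearn.FactorAnalysis(n_components=3, tol=1e-6, max_iter=2000).fit(x)
        shared_theirs = theirs.components_.T @ theirs.components_
        rel = np.linalg.norm(ours.shared_covariance() - shared_theirs) / np.linalg.norm(
            shared_theirs
        )
        assert rel < 0.05


class TestCVSelection:
    def test_recovers_true_rank(self, three_factor_spec):
        counts = sample_fa_counts(three_factor_spec, 2000, seed=7)
        m_star, scores = cv_select_m(counts, m_grid=list(range(0, 7)), seed=0)
        assert m_star == 3
        assert scores[3] > scores[0]

    def test_independent_data_selects_zero(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1200, 80)) * rng.uniform(0.5, 2, size=80) + 5
        m_star, _ = cv_select_m(x, m_grid=[0, 1, 2, 3], seed=0)
        assert m_star == 0

    def test_singleton_grid(self):
        x = np.random.default_rng(9).standard_normal((40, 6))
        m_star, scores = cv_select_m(x, m_grid=[0], seed=0)
        assert m_star == 0 and set(scores) == {0}

    def test_too_few_trials_rejected(self):
        x = np.random.default_rng(0).standard_normal((3, 5))
        with pytest.raises(ValueError, match="fold"):
            cv_select_m(x, m_grid=[0, 1], folds=4)

    def test_grid_must_include_zero(self):
        x = np.random.default_rng(0).standard_normal((40, 5))
        with pytest.raises(ValueError, match="include 0"):
            cv_select_m(x, m_grid=[1, 2])


class TestMetrics:
    def test_d_shared_arithmetic_examples(self):
        spec = SharedSpectrum(
            eigenvalues=np.array([10.0, 0.2]), modes=np.eye(2)
        )
        assert shared_dimensionality(spec) == 1
        spec = SharedSpectrum(eigenvalues=np.ones(50), modes=np.eye(50))
        assert shared_dimensionality(spec) == 48

    def test_percent_shared_variance_examples(self):
        model = FAModel(
            mu=np.zeros(1), L=np.array([[1.0]]), psi=np.array([1.0]), m=1
        )
        per_neuron, pop = percent_shared_variance(model)
        assert per_neuron[0] == pytest.approx(50.0)
        # psi -> 0 limit approaches 100%
        model.psi = np.array([1e-12])
        assert percent_shared_variance(model)[0][0] == pytest.approx(100.0)

    def test_two_neuron_single_mode_per_mode_value(self):
        model = FAModel(
            mu=np.zeros(2), L=np.array([[1.0], [1.0]]), psi=np.ones(2), m=1
        )
        vals = per_mode_percent_shared_variance(model)
        assert vals.shape == (1,)
        assert vals[0] == pytest.approx(50.0)
        # m=1: the single entry equals the population mean
        assert vals[0] == pytest.approx(percent_shared_variance(model)[1])

    def test_mode_fraction_examples(self):
        spec = SharedSpectrum(eigenvalues=np.array([3.0, 1.0]), modes=np.eye(2))
        np.testing.assert_allclose(mode_variance_fractions(spec), [75.0, 25.0])
        model = FAModel(mu=np.zeros(3), L=np.zeros((3, 0)), psi=np.ones(3), m=0)
        assert mode_variance_fractions(shared_spectrum(model)).size == 0

    def test_identities_on_random_models(self):
        """Per-neuron percent shared variance equals the sum over modes of
        the per-mode split; mode fractions sum to 100%; trace identity."""
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = rng.integers(3, 20)
            m = rng.integers(1, n)
            model = random_model(rng, n=int(n), m=int(m))
            spec = shared_spectrum(model)

            shared_k = np.einsum("ij,ij->i", model.L, model.L)
            total_k = shared_k + model.psi
            per_neuron, _ = percent_shared_variance(model)
            contrib = spec.eigenvalues[None, :] * spec.modes**2
            np.testing.assert_allclose(
                per_neuron, 100.0 * contrib.sum(axis=1) / total_k, atol=1e-10
            )
            assert mode_variance_fractions(spec).sum() == pytest.approx(
                100.0, abs=1e-10
            )
            assert spec.eigenvalues.sum() == pytest.approx(
                shared_k.sum(), rel=1e-8
            )
            assert np.all(np.diff(spec.eigenvalues) <= 1e-12)
            np.testing.assert_allclose(
                spec.modes.T @ spec.modes, np.eye(spec.m), atol=1e-10
            )

    def test_d_shared_bounded_by_m_and_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            model = random_model(rng, n=15, m=int(rng.integers(1, 12)))
            assert shared_dimensionality(model) <= model.m
        # appending additional uncorrelated factor structure cannot shrink
        # d_shared on constructed spectra
        eig = np.sort(rng.uniform(0.5, 2, size=6))[::-1]
        base = SharedSpectrum(eigenvalues=eig, modes=np.eye(6))
        grown = SharedSpectrum(
            eigenvalues=np.sort(np.concatenate([eig, [eig[-1]]]))[::-1],
            modes=np.eye(7)[:, :7],
        )
        assert shared_dimensionality(grown) >= shared_dimensionality(base)
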