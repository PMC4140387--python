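import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from lcasim import (
    DesignCell,
    ParameterSet,
    PopulationSpec,
    build_population_spec,
    detect_boundary,
    e_step,
    fit,
    generate_dataset,
    loglikelihood,
    m_step,
    pattern_probabilities,
)


def _params(gamma, crp):
    return ParameterSet(gamma=np.asarray(gamma, float), crp=np.atleast_2d(crp))


def _random_spec(rng, C, J):
    raw = rng.uniform(0.2, 1.0, C)
    gamma = raw / raw.sum()
    crp = rng.uniform(0.05, 0.95, (C, J))
    beta0 = np.log(gamma / gamma[-1])
    return PopulationSpec(gamma=gamma, crp=crp, beta0=beta0, beta1=np.zeros(C),
                          has_covariate=False)


class TestLoglikelihood:
    def test_single_class_collapses_to_bernoulli(self):
        rng = np.random.default_rng(0)
        crp = np.array([[0.3, 0.8, 0.6]])
        y = (rng.random((50, 3)) < 0.5).astype(np.int8)
        from lcasim import Dataset

        d = Dataset(responses=y, covariate=None, true_class=np.ones(50, dtype=int))
        ll = loglikelihood(_params([1.0], crp), d)
        expected = stats.bernoulli.logpmf(y, crp[0]).sum()
        assert ll == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("C,J,seed", [(2, 4, 1), (2, 6, 2), (3, 5, 3), (3, 8, 4)])
    def test_matches_pattern_enumeration_oracle(self, C, J, seed):
        """Observed-data log-likelihood equals the brute-force mixture enumeration."""
        rng = np.random.default_rng(seed)
        spec = _random_spec(rng, C, J)
        d = generate_dataset(spec, 300, seed=seed + 100)
        probs = pattern_probabilities(spec)
        expected = sum(np.log(probs[tuple(row)]) for row in d.responses)
        got = loglikelihood(ParameterSet.from_spec(spec), d)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_label_permutation_invariance(self, spec3_low_j5):
        d = generate_dataset(spec3_low_j5, 200, seed=9)
        p = ParameterSet.from_spec(spec3_low_j5)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            assert loglikelihood(p.permuted(perm), d) == pytest.approx(
                loglikelihood(p, d), rel=1e-12
            )

    def test_label_permutation_invariance_with_covariate(self, spec2_cov_large_j8):
        d = generate_dataset(spec2_cov_large_j8, 200, seed=9)
        p = ParameterSet.from_spec(spec2_cov_large_j8)
        assert loglikelihood(p.permuted((1, 0)), d) == pytest.approx(
            loglikelihood(p, d), rel=1e-12
        )

    def test_zero_probability_observation_reports_neg_inf(self):
        from lcasim import Dataset

        params = _params([0.5, 0.5], [[1.0, 1.0], [1.0, 1.0]])
        d = Dataset(responses=np.array([[1, 0]], dtype=np.int8), covariate=None,
                    true_class=np.array([1]))
        assert loglikelihood(params, d) == -np.inf


class TestESten:
    def test_identical_crps_return_prior(self):
        from lcasim import Dataset

        params = _params([0.7, 0.3], [[0.6, 0.4], [0.6, 0.4]])
        y = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        d = Dataset(responses=y, covariate=None, true_class=np.ones(3, dtype=int))
        post = e_step(params, d)
        np.testing.assert_allclose(post, np.tile([0.7, 0.3], (3, 1)), atol=1e-12)

    def test_deterministic_indicator(self):
        from lcasim import Dataset

        params = _params([0.5, 0.5], [[1.0], [0.0]])
        d = Dataset(responses=np.array([[1]], dtype=np.int8), covariate=None,
                    true_class=np.array([1]))
        np.testing.assert_allclose(e_step(params, d), [[1.0, 0.0]])

    def test_hand_normalized_two_class_posterior(self, spec2_high_j4):
        """y = (1,1,0,0): class terms 0.67*0.9^2*0.1^2 and 0.33*0.9^4."""
        from lcasim import Dataset

        d = Dataset(responses=np.array([[1, 1, 0, 0]], dtype=np.int8), covariate=None,
                    true_class=np.array([1]))
        t1 = 0.67 * 0.9 * 0.9 * 0.1 * 0.1
        t2 = 0.33 * 0.9 ** 4
        post = e_step(ParameterSet.from_spec(spec2_high_j4), d)
        np.testing.assert_allclose(post[0], [t1 / (t1 + t2), t2 / (t1 + t2)], rtol=1e-12)

    def test_rows_sum_to_one(self, spec3_low_j5):
        d = generate_dataset(spec3_low_j5, 500, seed=2)
        post = e_step(ParameterSet.from_spec(spec3_low_j5), d)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_impossible_observation_rejected_by_name(self):
        from lcasim import Dataset

        params = _params([0.5, 0.5], [[1.0, 1.0], [1.0, 1.0]])
        d = Dataset(responses=np.array([[1, 1], [1, 0]], dtype=np.int8), covariate=None,
                    true_class=np.array([1, 1]))
        with pytest.raises(ValueError, match="observation 1"):
            e_step(params, d)


class TestMStep:
    def test_hard_assignment_recovers_within_class_means(self, spec2_high_j8):
        d = generate_dataset(spec2_high_j8, 500, seed=4)
        post = np.zeros((d.n, 2))
        post[np.arange(d.n), d.true_class - 1] = 1.0
        params = m_step(post, d, has_covariate=False)
        for c in (0, 1):
            np.testing.assert_allclose(
                params.crp[c], d.responses[d.true_class == c + 1].mean(axis=0), atol=1e-12
            )
            assert params.gamma[c] == pytest.approx((d.true_class == c + 1).mean())

    def test_all_mass_on_one_class_is_degenerate(self, spec2_high_j8):
        from lcasim import DegenerateClassError

        d = generate_dataset(spec2_high_j8, 500, seed=4)
        post = np.column_stack([np.ones(d.n), np.zeros(d.n)])
        with pytest.raises(DegenerateClassError):
            m_step(post, d, has_covariate=False)

    def test_logistic_m_step_matches_fractional_glm(self, spec2_cov_large_j8):
        """For C = 2 the weighted multinomial logit is a fractional-response
        logistic GLM; statsmodels provides the independent solution."""
        d = generate_dataset(spec2_cov_large_j8, 2000, seed=6)
        post = e_step(ParameterSet.from_spec(spec2_cov_large_j8), d)
        params = m_step(post, d, has_covariate=True)
        X = sm.add_constant(d.covariate)
        glm = sm.GLM(post[:, 0], X, family=sm.families.Binomial()).fit()
        assert params.beta0[0] == pytest.approx(glm.params[0], abs=1e-6)
        assert params.beta1[0] == pytest.approx(glm.params[1], abs=1e-6)


class TestFit:
    def test_loglik_trace_monotone(self, spec3_low_j5):
        d = generate_dataset(spec3_low_j5, 300, seed=8)
        res = fit(d, ParameterSet.from_spec(spec3_low_j5))
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-10 * np.abs(res.loglik_trace[:-1]))

    def test_fixed_point_converges_immediately(self, spec2_high_j8):
        d = generate_dataset(spec2_high_j8, 800, seed=10)
        first = fit(d, ParameterSet.from_spec(spec2_high_j8), tol=1e-12)
        assert first.converged
        again = fit(d, first.estimate)
        assert again.converged and again.n_iterations <= 2
        np.testing.assert_allclose(again.estimate.crp, first.estimate.crp, atol=1e-5)

    def test_permuted_start_yields_permuted_solution(self, spec2_high_j8):
        d = generate_dataset(spec2_high_j8, 800, seed=10)
        a = fit(d, ParameterSet.from_spec(spec2_high_j8))
        b = fit(d, ParameterSet.from_spec(spec2_high_j8).permuted((1, 0)))
        assert b.loglik == pytest.approx(a.loglik, rel=1e-9)
        np.testing.assert_allclose(b.estimate.crp, a.estimate.crp[::-1], atol=1e-4)

    def test_posterior_rows_sum_to_one(self, small_dataset, true_start):
        res = fit(small_dataset, true_start)
        np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_crp_recovery_at_large_n(self, spec2_high_j8):
        """Across 100 replications at n = 2000, mean absolute relative CRP
        bias stays below 5% (Monte-Carlo consistency of the EM estimator)."""
        biases = []
        for s in range(100):
            d = generate_dataset(spec2_high_j8, 2000, seed=1000 + s)
            res = fit(d, ParameterSet.from_spec(spec2_high_j8))
            assert res.converged
            biases.append(
                np.abs(res.estimate.crp - spec2_high_j8.crp) / spec2_high_j8.crp
            )
        assert np.mean(biases) < 0.05

    def test_nonconvergence_flag_when_iterations_exhausted(self, spec3_low_j5):
        d = generate_dataset(spec3_low_j5, 200, seed=1)
        res = fit(d, ParameterSet.from_spec(spec3_low_j5), max_iter=3)
        assert not res.converged
        assert res.n_iterations == 3


class TestDetectBoundary:
    def test_flags_and_count(self):
        params = _params([0.5, 0.5], [[1.0, 0.5, 1e-5, 0.3], [0.0, 0.99995, 0.7, 0.4]])
        mask, count = detect_boundary(params)
        assert count == 4
        assert mask[0, 0] and mask[0, 2] and mask[1, 0] and mask[1, 1]
        assert not mask[0, 1]

    def test_full_boundary_model(self):
        params = _params([0.5, 0.5], np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]]))
        _, count = detect_boundary(params)
        assert count == 8
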