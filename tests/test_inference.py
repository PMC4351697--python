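import numpy as np
import pytest

from asehmm import (
    ModelParameters,
    build_emission_table,
    call_genotypes,
    default_initial_parameters,
    em_fit,
    estimate_ase_ratio,
    forward_backward,
    ingest_biallelic,
    make_state_space,
    simulate_dataset,
    SimulationScenario,
    validate_parameters,
)
from asehmm.core_model import ASE_HIGH, HET, NO_CALL, AlleleCountMatrix
from asehmm.inference import PosteriorResult
from conftest import brute_force_posteriors, random_parameters


class TestForwardBackward:
    def test_single_position_chain_is_bayes_rule(self, ase_space, rng):
        theta = random_parameters(ase_space, rng)
        logb = rng.normal(size=(1, 5))
        gamma, xi, ll = forward_backward(logb, theta, ase_space)
        post = theta.pi * np.exp(logb[0])
        assert np.allclose(gamma[0], post / post.sum(), atol=1e-12)
        assert ll == pytest.approx(np.log(post.sum()), abs=1e-12)

    def test_uninformative_emissions_give_marginal_chain(self, ase_space, rng):
        theta = random_parameters(ase_space, rng)
        L = 6
        gamma, xi, ll = forward_backward(np.zeros((L, 5)), theta, ase_space)
        marg = theta.pi.copy()
        for l in range(L):
            assert np.allclose(gamma[l], marg, atol=1e-10)
            marg = marg @ theta.A
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_matches_exhaustive_path_enumeration(self, ase_space, rng):
        for _ in range(5):
            L = int(rng.integers(2, 6))
            theta = random_parameters(ase_space, rng)
            logb = rng.normal(scale=2.0, size=(L, 5))
            gamma, xi, ll = forward_backward(logb, theta, ase_space)
            g0, x0, l0 = brute_force_posteriors(logb, theta.A, theta.pi)
            assert np.allclose(gamma, g0, atol=1e-10)
            assert np.allclose(xi, x0, atol=1e-10)
            assert ll == pytest.approx(l0, abs=1e-10)

    def test_posterior_rows_normalize_and_xi_is_consistent(self, ase_space, rng):
        theta = random_parameters(ase_space, rng)
        logb = rng.normal(size=(8, 5))
        gamma, xi, ll = forward_backward(logb, theta, ase_space)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        # row k of xi sums to expected occupancy of k over l = 1..L-1
        assert np.allclose(xi.sum(axis=1), gamma[:-1].sum(axis=0), atol=1e-8)

    def test_impossible_observation_is_reported_with_site(self, ase_space, rng):
        theta = random_parameters(ase_space, rng)
        logb = np.zeros((3, 5))
        logb[2] = -np.inf
        with pytest.raises(ValueError, match="SNP 2"):
            forward_backward(logb, theta, ase_space)


class TestEMFit:
    def test_single_em_update_matches_baum_welch_ratio(self, nase_space):
        # 1 individual, 2 SNPs: the transition update must equal expected
        # transition counts over expected occupancy from the exact posterior
        counts = ingest_biallelic([[4, 3]], [[2, 2]])
        theta0 = default_initial_parameters(nase_space)
        logb = build_emission_table(counts, nase_space, theta0).logb
        g, x, ll = brute_force_posteriors(logb[0], theta0.A, theta0.pi)
        fit = em_fit(counts, nase_space, init_theta=theta0, max_iter=1)
        expected_A = x / x.sum(axis=1, keepdims=True)
        assert np.allclose(fit.theta_hat.A, expected_A, atol=1e-8)
        assert np.allclose(fit.theta_hat.pi, g[0], atol=1e-8)

    def test_loglik_monotone_on_simulated_data(self, ase_space):
        scn = SimulationScenario(n=8, L=10, lambda_=16, ld=0.5, seed=3)
        data = simulate_dataset(scn)
        fit = em_fit(data.counts, ase_space, max_iter=40)
        assert np.all(np.diff(fit.loglik_trace) > -1e-8)

    def test_degenerate_all_reference_data(self, nase_space):
        counts = ingest_biallelic(np.full((4, 6), 9), np.zeros((4, 6), int))
        fit = em_fit(counts, nase_space, max_iter=100)
        assert np.all(np.diff(fit.loglik_trace) > -1e-8)
        assert fit.theta_hat.pi[0] > 0.99
        assert fit.theta_hat.A[0, 0] > 0.99
        assert fit.theta_hat.e < 1e-4

    def test_fitted_parameters_are_stochastic(self, ase_space):
        scn = SimulationScenario(n=6, L=8, lambda_=8, ld=0.5, seed=11)
        data = simulate_dataset(scn)
        fit = em_fit(data.counts, ase_space, max_iter=20)
        assert np.allclose(fit.theta_hat.A.sum(axis=1), 1.0, atol=1e-10)
        assert fit.theta_hat.pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_allele_relabeling_symmetry(self, ase_space):
        # A<->T swap with mirrored initialization gives the mirrored fit
        scn = SimulationScenario(n=8, L=10, lambda_=16, ld=0.5, seed=5)
        data = simulate_dataset(scn)
        perm = [4, 1, 3, 2, 0]  # AA<->TT, balanced het fixed, HIGH<->LOW
        init = default_initial_parameters(ase_space)
        fit = em_fit(data.counts, ase_space, init_theta=init, max_iter=30)
        swapped = AlleleCountMatrix(counts=data.counts.counts[..., ::-1].copy())
        mirr = ModelParameters(
            A=init.A[np.ix_(perm, perm)], pi=init.pi[perm], e=init.e,
            alpha1=init.beta2, beta1=init.alpha2,
            alpha2=init.beta1, beta2=init.alpha1)
        fit2 = em_fit(swapped, ase_space, init_theta=mirr, max_iter=30)
        assert fit2.posterior.loglik == pytest.approx(fit.posterior.loglik,
                                                      abs=1e-6)
        assert np.allclose(fit2.theta_hat.A, fit.theta_hat.A[np.ix_(perm, perm)],
                           atol=1e-5)

    def test_shape_estimation_is_available_and_monotone(self, ase_space):
        scn = SimulationScenario(n=6, L=8, lambda_=16, ld=0.5, seed=21)
        data = simulate_dataset(scn)
        fit = em_fit(data.counts, ase_space, max_iter=15, estimate_shapes=True)
        assert np.all(np.diff(fit.loglik_trace) > -1e-8)
        assert fit.theta_hat.alpha1 != 30.0  # shapes actually moved


class TestCalling:
    def _posterior(self, gamma):
        gamma = np.asarray(gamma, dtype=float)
        return PosteriorResult(gamma=gamma, xi_sums=np.zeros(2),
                               loglik_per_individual=np.zeros(gamma.shape[0]))

    def test_map_call_projects_to_heterozygote_with_status(self, ase_space):
        gamma = np.array([[[0.1, 0.2, 0.5, 0.1, 0.1]]])
        counts = ingest_biallelic([[5]], [[3]])
        calls = call_genotypes(self._posterior(gamma), counts, ase_space)
        assert calls.calls[0, 0] == HET
        assert calls.ase_status[0, 0] == ASE_HIGH
        assert calls.posterior_max[0, 0] == pytest.approx(0.5)

    def test_zero_read_sites_become_noncalls_when_requested(self, ase_space):
        gamma = np.array([[[0.9, 0.025, 0.025, 0.025, 0.025]]])
        counts = ingest_biallelic([[0]], [[0]])
        calls = call_genotypes(self._posterior(gamma), counts, ase_space,
                               noncall_on_zero=True)
        assert calls.calls[0, 0] == NO_CALL
        calls2 = call_genotypes(self._posterior(gamma), counts, ase_space)
        assert calls2.calls[0, 0] != NO_CALL

    def test_exact_tie_calls_lowest_state_index(self, ase_space):
        gamma = np.array([[[0.4, 0.1, 0.1, 0.0, 0.4]]])
        counts = ingest_biallelic([[2]], [[2]])
        calls = call_genotypes(self._posterior(gamma), counts, ase_space)
        assert calls.map_state[0, 0] == 1

    def test_min_posterior_threshold_masks_weak_calls(self, ase_space):
        gamma = np.array([[[0.3, 0.25, 0.15, 0.15, 0.15]]])
        counts = ingest_biallelic([[2]], [[2]])
        calls = call_genotypes(self._posterior(gamma), counts, ase_space,
                               min_posterior=0.5)
        assert calls.calls[0, 0] == NO_CALL


class TestAseRatio:
    def _theta(self, space, e=0.0):
        M = space.M
        theta = ModelParameters(A=np.eye(M), pi=np.full(M, 1 / M), e=e,
                                e_bounds=(0.0, 0.5),
                                alpha1=30.0, beta1=10.0, alpha2=10.0, beta2=30.0)
        return validate_parameters(theta, space)

    def test_point_state_posteriors_give_point_ratios(self, ase_space):
        theta = self._theta(ase_space)
        x = np.array([3, 0, 0, 3])
        assert estimate_ase_ratio(x, np.eye(5)[1], theta) == pytest.approx(0.5)
        assert estimate_ase_ratio(x, np.eye(5)[0], theta) == pytest.approx(1.0)

    def test_beta_state_ratio_matches_dense_grid_oracle(self, ase_space):
        theta = self._theta(ase_space, e=0.0)
        x = np.array([30.0, 0, 0, 10.0])
        val = estimate_ase_ratio(x, np.eye(5)[2], theta)
        d = np.linspace(0.5, 1.0, 100001)[1:-1]
        from asehmm import rescaled_beta_logpdf
        w = np.exp(rescaled_beta_logpdf(d, 0.5, 1.0, 30, 10)
                   + 30 * np.log(d) + 10 * np.log1p(-d))
        oracle = np.trapezoid(d * w, d) / np.trapezoid(w, d)
        assert val == pytest.approx(oracle, abs=1e-6)

    def test_rejected_for_nase_variant(self, nase_space):
        theta = ModelParameters(A=np.eye(3), pi=np.full(3, 1 / 3), e=0.01)
        with pytest.raises(ValueError, match="ASE"):
            estimate_ase_ratio(np.array([1, 0, 0, 1]), np.full(3, 1 / 3),
                               theta, space=nase_space)
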