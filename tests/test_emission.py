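import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from asehmm import (
    DeltaSpec,
    ModelParameters,
    allele_probability_vector,
    build_emission_table,
    emission_logprob,
    ingest_biallelic,
    make_state_space,
    rescaled_beta_logpdf,
    validate_parameters,
)
from conftest import count_vectors_with_total


def default_theta(space):
    M = space.M
    A = np.full((M, M), 0.3 / (M - 1))
    np.fill_diagonal(A, 0.7)
    theta = ModelParameters(A=A, pi=np.full(M, 1 / M), e=0.01,
                            alpha1=30.0, beta1=10.0, alpha2=10.0, beta2=30.0)
    return validate_parameters(theta, space)


class TestAlleleProbabilityVector:
    @pytest.mark.parametrize("delta,e,expected", [
        (1.0, 0.03, (0.97, 0.01, 0.01, 0.01)),
        (0.5, 0.0, (0.5, 0.0, 0.0, 0.5)),
        (0.75, 0.03, (0.73, 0.01, 0.01, 0.25)),
    ])
    def test_known_values(self, delta, e, expected):
        p = allele_probability_vector(delta, e)
        assert np.allclose(p, expected, atol=1e-12)
        assert abs(p.sum() - 1.0) < 1e-12

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 1), st.floats(0, 0.5))
    def test_components_sum_to_one_and_are_nonnegative(self, delta, e):
        p = allele_probability_vector(delta, e)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            allele_probability_vector(1.2, 0.01)
        with pytest.raises(ValueError):
            allele_probability_vector(0.5, 0.9)


class TestRescaledBeta:
    def test_unit_support_matches_standard_beta(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0.5, 40, 2)
            x = rng.uniform(0.01, 0.99)
            assert rescaled_beta_logpdf(x, 0, 1, a, b) == pytest.approx(
                beta_dist.logpdf(x, a, b), abs=1e-10)

    def test_density_integrates_to_one_on_support(self):
        val, err = quad(lambda x: np.exp(rescaled_beta_logpdf(x, 0.5, 1.0, 30, 10)),
                        0.5, 1.0)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_open_support_boundaries_have_zero_density(self):
        assert rescaled_beta_logpdf(0.5, 0.5, 1.0, 30, 10) == -np.inf
        assert rescaled_beta_logpdf(1.0, 0.5, 1.0, 30, 10) == -np.inf
        assert rescaled_beta_logpdf(0.3, 0.5, 1.0, 30, 10) == -np.inf

    def test_invalid_support_or_shapes_rejected(self):
        with pytest.raises(ValueError):
            rescaled_beta_logpdf(0.7, 0.9, 0.5, 2, 2)
        with pytest.raises(ValueError):
            rescaled_beta_logpdf(0.7, 0.5, 1.0, -2, 2)


class TestEmissionLogprob:
    def test_certain_outcome_has_probability_one(self):
        lp = emission_logprob(np.array([7, 0, 0, 0]), DeltaSpec("point", value=1.0), 0.0)
        assert lp == pytest.approx(0.0, abs=1e-12)

    def test_impossible_outcome_is_minus_inf_not_error(self):
        lp = emission_logprob(np.array([3, 0, 0, 1]), DeltaSpec("point", value=0.0), 0.0)
        assert lp == -np.inf

    def test_beta_state_quadrature_matches_dense_grid_oracle(self):
        # brute-force oracle: 1e5-point trapezoid over the marginal integrand
        x = np.array([6.0, 0, 0, 2.0])
        e, S, U, a, b = 0.01, 0.5, 1.0, 30.0, 10.0
        spec = DeltaSpec("rescaled_beta", support=(S, U), alpha=a, beta=b)
        lp = emission_logprob(x, spec, e, quad_nodes=64)
        d = np.linspace(S, U, 100001)[1:-1]
        from scipy.special import gammaln
        logcoef = gammaln(x.sum() + 1) - gammaln(x + 1).sum()
        P = allele_probability_vector(d, e)
        integrand = np.exp(
            rescaled_beta_logpdf(d, S, U, a, b) + (x[None, :] * np.log(P)).sum(axis=1)
        )
        oracle = np.log(np.trapezoid(integrand, d)) + logcoef
        assert lp == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_emission_normalizes_over_all_outcomes(self, ase_space, n):
        theta = default_theta(ase_space)
        vectors = count_vectors_with_total(n)
        for st_ in ase_space.states:
            spec = st_.delta.resolve(theta)
            total = sum(np.exp(emission_logprob(v.astype(float), spec, theta.e))
                        for v in vectors)
            assert total == pytest.approx(1.0, abs=1e-8), st_.label


class TestEmissionTable:
    def test_zero_coverage_site_is_uninformative(self, ase_space):
        theta = default_theta(ase_space)
        acm = ingest_biallelic([[0]], [[0]])
        tab = build_emission_table(acm, ase_space, theta)
        assert np.array_equal(tab.logb[0, 0], np.zeros(5))

    def test_mirror_symmetry_under_allele_swap(self, ase_space, rng):
        # swapping A<->T counts maps state 1<->5 and 3<->4 when the two
        # beta-shape pairs are mirrored
        theta = default_theta(ase_space)
        counts = rng.integers(0, 15, size=(2, 6, 4))
        counts[..., 1] = counts[..., 2] = 0
        from asehmm.core_model import AlleleCountMatrix
        tab = build_emission_table(AlleleCountMatrix(counts=counts), ase_space, theta)
        swapped = counts[..., ::-1].copy()
        tab2 = build_emission_table(AlleleCountMatrix(counts=swapped), ase_space, theta)
        perm = [4, 1, 3, 2, 0]  # 1<->5, 3<->4 (shapes mirrored by symmetry)
        assert np.allclose(tab.logb, tab2.logb[:, :, perm], atol=1e-10)

    def test_point_state_table_normalizes_by_enumeration(self, nase_space):
        theta = validate_parameters(
            ModelParameters(A=np.eye(3), pi=np.full(3, 1 / 3), e=0.02), nase_space)
        vectors = count_vectors_with_total(2)
        from asehmm.core_model import AlleleCountMatrix
        acm = AlleleCountMatrix(counts=vectors.reshape(1, -1, 4))
        tab = build_emission_table(acm, nase_space, theta)
        sums = np.exp(tab.logb[0]).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_quadrature_converged_at_default_node_count(self, ase_space, rng):
        theta = default_theta(ase_space)
        counts = rng.multinomial(200, [0.7, 0.005, 0.005, 0.29],
                                 size=(2, 5))
        from asehmm.core_model import AlleleCountMatrix
        acm = AlleleCountMatrix(counts=counts.reshape(2, 5, 4))
        t64 = build_emission_table(acm, ase_space, theta, quad_nodes=64)
        t128 = build_emission_table(acm, ase_space, theta, quad_nodes=128)
        assert np.max(np.abs(t64.logb - t128.logb)) < 1e-8
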