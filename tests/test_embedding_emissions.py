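"""Gaussian emission densities, the mixture prior, and temperature effects."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dphmm.embedding_emissions import (
    EmbeddingEmissionSet,
    EmbeddingPrior,
    VAR_FLOOR,
    background_log_density,
    embedding_emission_grid,
    fit_embedding_prior,
    gaussian_log_density,
    init_emissions_from_prior,
    joint_emission_log_prob,
    prior_log_density,
    softplus,
    softplus_inv,
)


def _ems(mu, var, tau=1.0, bg_mean=None, bg_var=None):
    mu = np.atleast_2d(mu)
    var = np.atleast_2d(var)
    r = mu.shape[1]
    return EmbeddingEmissionSet(
        mu=mu,
        s_raw=softplus_inv(var - VAR_FLOOR),
        tau=tau,
        bg_mean=np.zeros(r) if bg_mean is None else bg_mean,
        bg_var=np.ones(r) if bg_var is None else bg_var,
    )


class TestGaussianLogDensity:
    def test_at_mean_unit_variance(self):
        x = np.zeros(16)
        assert gaussian_log_density(x, x, np.ones(16)) == pytest.approx(
            -8.0 * np.log(2 * np.pi), rel=1e-12
        )

    def test_one_dimensional_closed_form(self):
        val = gaussian_log_density(np.array([1.0]), np.array([0.0]), np.array([1.0]))
        assert val == pytest.approx(-0.5 * (np.log(2 * np.pi) + 1.0), rel=1e-12)

    def test_matches_scipy_reference(self, rng):
        for _ in range(10):
            x = rng.normal(0, 2, 5)
            m = rng.normal(0, 2, 5)
            v = rng.uniform(0.1, 3, 5)
            ref = multivariate_normal.logpdf(x, mean=m, cov=np.diag(v))
            assert gaussian_log_density(x, m, v) == pytest.approx(ref, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            gaussian_log_density(np.zeros(3), np.zeros(4), np.ones(4))

    def test_integrates_to_one(self):
        """Quadrature over [-10, 10] of the 1-D unit density gives 1."""
        from scipy.integrate import quad

        f = lambda x: np.exp(
            gaussian_log_density(np.array([x]), np.array([0.0]), np.array([1.0]))
        )
        total, _ = quad(f, -10, 10)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestJointEmission:
    @pytest.mark.parametrize(
        "aa,emb,tau,expected",
        [(-2.3, -7.0, 0.0, -2.3), (-2.3, -7.0, 1.0, -9.3), (0.0, -3.0, 0.5, -1.5)],
    )
    def test_temperature_scaling(self, aa, emb, tau, expected):
        assert joint_emission_log_prob(aa, emb, tau) == pytest.approx(expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            joint_emission_log_prob(0.0, 0.0, -0.1)


class TestEmissionGrid:
    def test_tau_zero_gives_zeros(self, rng):
        ems = _ems(rng.normal(0, 1, (4, 3)), np.ones((4, 3)), tau=0.0)
        grid = embedding_emission_grid(ems, rng.normal(0, 1, (6, 3)))
        assert np.all(grid == 0.0)

    def test_single_state_single_position(self, rng):
        mu = rng.normal(0, 1, (1, 3))
        var = rng.uniform(0.5, 2, (1, 3))
        ems = _ems(mu, var, tau=0.7)
        x = rng.normal(0, 1, (1, 3))
        grid = embedding_emission_grid(ems, x)
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(
            0.7 * gaussian_log_density(x[0], mu[0], ems.var[0]), rel=1e-10
        )

    def test_matches_loop_reference(self, rng):
        ems = _ems(rng.normal(0, 1, (5, 4)), rng.uniform(0.2, 2, (5, 4)), tau=1.3)
        x = rng.normal(0, 1, (7, 4))
        grid = embedding_emission_grid(ems, x)
        for i in range(5):
            for j in range(7):
                assert grid[i, j] == pytest.approx(
                    1.3 * gaussian_log_density(x[j], ems.mu[i], ems.var[i]), abs=1e-10
                )

    def test_dimension_mismatch_rejected(self, rng):
        ems = _ems(np.zeros((2, 4)), np.ones((2, 4)))
        with pytest.raises(ValueError):
            embedding_emission_grid(ems, np.zeros((3, 5)))


class TestEmbeddingPrior:
    def test_single_component_reduces_to_gaussian(self, rng):
        mu = rng.normal(0, 1, (3, 4))
        prior = EmbeddingPrior(np.array([1.0]), np.zeros((1, 4)), np.ones((1, 4)))
        ems = _ems(mu, np.ones((3, 4)))
        expected = sum(
            gaussian_log_density(mu[i], np.zeros(4), np.ones(4)) for i in range(3)
        )
        assert prior_log_density(ems, prior) == pytest.approx(expected, rel=1e-12)

    def test_peak_at_heaviest_component(self):
        """Well-separated mixture: density at a component mean is its peak."""
        r = 4
        means = np.stack([np.full(r, 50.0), np.full(r, -50.0)])
        prior = EmbeddingPrior(np.array([0.7, 0.3]), means, np.full((2, r), 0.1))
        ems = _ems(means[:1], np.ones((1, r)))
        peak = gaussian_log_density(means[0], means[0], np.full(r, 0.1))
        assert prior_log_density(ems, prior) == pytest.approx(
            np.log(0.7) + peak, abs=1e-6
        )

    def test_no_match_states_gives_zero(self):
        prior = EmbeddingPrior.standard(4)
        ems = _ems(np.zeros((0, 4)).reshape(0, 4), np.ones((0, 4)).reshape(0, 4))
        assert prior_log_density(ems, prior) == 0.0

    def test_permutation_invariance(self, rng):
        means = rng.normal(0, 3, (3, 4))
        variances = rng.uniform(0.2, 2, (3, 4))
        w = np.array([0.5, 0.3, 0.2])
        ems = _ems(rng.normal(0, 2, (5, 4)), np.ones((5, 4)))
        perm = [2, 0, 1]
        a = prior_log_density(ems, EmbeddingPrior(w, means, variances))
        b = prior_log_density(
            ems, EmbeddingPrior(w[perm], means[perm], variances[perm])
        )
        assert a == pytest.approx(b, rel=1e-12)


class TestFitEmbeddingPrior:
    def test_two_component_recovery(self, rng):
        truth = np.stack([np.full(3, 2.0), np.full(3, -2.0)])
        labels = rng.integers(0, 2, 600)
        x = truth[labels] + 0.3 * rng.standard_normal((600, 3))
        prior = fit_embedding_prior(x, C=2, seed=0)
        # match components to truth by nearest mean
        order = np.argsort(prior.means[:, 0])[::-1]
        assert np.abs(prior.means[order] - truth).max() < 0.1

    def test_single_component_closed_form(self, rng):
        x = rng.normal(1.0, 2.0, (200, 3))
        prior = fit_embedding_prior(x, C=1, seed=0)
        assert prior.means[0] == pytest.approx(x.mean(axis=0), abs=1e-8)
        assert prior.variances[0] == pytest.approx(
            x.var(axis=0) + VAR_FLOOR, rel=1e-6
        )

    def test_identical_points_clamp_at_floor(self):
        x = np.ones((20, 3))
        prior = fit_embedding_prior(x, C=1, seed=0)
        assert np.all(prior.variances <= 2 * VAR_FLOOR)

    def test_invalid_component_count(self):
        with pytest.raises(ValueError):
            fit_embedding_prior(np.zeros((5, 2)), C=0)
        with pytest.raises(ValueError, match="at least"):
            fit_embedding_prior(np.zeros((2, 2)), C=3)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(0, 1, (100, 4))
        a = fit_embedding_prior(x, C=3, seed=7)
        b = fit_embedding_prior(x, C=3, seed=7)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)


class TestInitFromPrior:
    def test_deterministic_under_seed(self, rng):
        prior = EmbeddingPrior(
            np.array([0.4, 0.6]), rng.normal(0, 2, (2, 4)), rng.uniform(0.5, 2, (2, 4))
        )
        a = init_emissions_from_prior(prior, 5, seed=3)
        b = init_emissions_from_prior(prior, 5, seed=3)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.s_raw, b.s_raw)

    def test_floored_single_component_pins_means(self):
        prior = EmbeddingPrior(
            np.array([1.0]), np.full((1, 3), 2.5), np.full((1, 3), VAR_FLOOR)
        )
        ems = init_emissions_from_prior(prior, 4, seed=0)
        assert np.abs(ems.mu - 2.5).max() < 0.05

    def test_sampled_mean_obeys_law_of_large_numbers(self, rng):
        prior = EmbeddingPrior(
            np.array([0.3, 0.7]),
            np.stack([np.full(2, 3.0), np.full(2, -1.0)]),
            np.ones((2, 2)),
        )
        ems = init_emissions_from_prior(prior, 10_000, seed=1)
        mix_mean = prior.weights @ prior.means
        _, total_var = prior.moment_match()
        se = np.sqrt(total_var / 10_000)
        assert np.all(np.abs(ems.mu.mean(axis=0) - mix_mean) < 3 * se)


class TestTauMonotonicity:
    def test_viterbi_switches_once_with_temperature(self):
        """With residues tied, raising tau flips the path toward the state
        whose embedding model fits, and the flip is monotone."""
        from dphmm.msa_io import Sequence
        from dphmm.phmm_core import ProfileHMM, viterbi_decode

        hmm = ProfileHMM.uniform(2)
        # make the M1 route strictly preferred on transitions alone
        hmm.begin_logits = np.log(np.array([0.8, 0.2]))
        r = 3
        ems = _ems(
            mu=np.stack([np.full(r, 5.0), np.zeros(r)]),
            var=np.ones((2, r)),
        )
        x = np.zeros((1, r))  # embedding matches state 2, not state 1
        seq = Sequence("s", "A")
        used_m2 = []
        for tau in np.linspace(0.0, 2.0, 11):
            ems.tau = tau
            extra_m = embedding_emission_grid(ems, x)[None]
            extra_i = background_log_density(ems, x)[None]
            path, _ = viterbi_decode(hmm, seq, extra_m, extra_i)
            used_m2.append(("M", 1) in path.states)
        assert used_m2[0] is False  # residue-only: transition-preferred path
        assert used_m2[-1] is True  # embeddings dominate at high tau
        flips = sum(a != b for a, b in zip(used_m2, used_m2[1:]))
        assert flips == 1  # a single monotone switch

    def test_softplus_inverse_round_trip(self, rng):
        x = rng.uniform(0.01, 5.0, 20)
        assert softplus(softplus_inv(x)) == pytest.approx(x, rel=1e-10)
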