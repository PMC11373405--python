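"""Forward/Viterbi correctness against path enumeration, and the priors."""

import itertools

import numpy as np
import pytest

from dphmm.msa_io import Sequence
from dphmm.phmm_core import (
    DirichletMixture,
    EncodedBatch,
    ProfileHMM,
    amino_prior_grad,
    amino_prior_log_density,
    forward_backward,
    forward_log_likelihood,
    viterbi_decode,
)

from conftest import PARAM_NAMES, random_hmm
from oracles import brute_force_loglik, brute_force_viterbi

AA = "ACDEFGHIKLMNPQRSTVWY"


def _oracle_tables(hmm, seq):
    batch = EncodedBatch.from_sequences([seq])
    EM = hmm.match_log_emissions()[:, batch.obs[0]]
    EI = hmm.insert_log_emissions()[batch.obs[0]]
    return hmm.transition_log_table(), EM, EI


def _random_case(rng):
    hmm = random_hmm(rng, int(rng.integers(1, 4)))
    T = int(rng.integers(1, 5))
    seq = Sequence("s", "".join(AA[i] for i in rng.integers(0, 20, T)))
    return hmm, seq


class TestForward:
    def test_matches_path_enumeration(self, rng):
        """Forward equals the brute-force sum over all enumerated paths."""
        for _ in range(60):
            hmm, seq = _random_case(rng)
            ll = forward_log_likelihood(hmm, EncodedBatch.from_sequences([seq]))[0]
            assert ll == pytest.approx(
                brute_force_loglik(*_oracle_tables(hmm, seq)), abs=1e-10
            )

    def test_zero_extra_term_is_identity(self, rng):
        hmm, seq = _random_case(rng)
        batch = EncodedBatch.from_sequences([seq])
        base = forward_log_likelihood(hmm, batch)
        zm = np.zeros((1, hmm.length, len(seq)))
        zi = np.zeros((1, len(seq)))
        assert forward_log_likelihood(hmm, batch, zm, zi)[0] == base[0]

    def test_deterministic_model_gives_logprob_zero(self):
        """A model that can only generate one sequence assigns it prob 1."""
        hmm = ProfileHMM.uniform(3)
        big = 60.0
        hmm.match_logits = np.full((3, 20), -big)
        for i, a in enumerate("ACD"):
            hmm.match_logits[i, AA.index(a)] = big
        hmm.begin_logits = np.array([big, -big])
        hmm.flank_n_logits = np.array([-big, big])
        hmm.flank_c_logits = np.array([-big, big])
        hmm.match_trans_logits = np.tile([big, -big, -big], (2, 1)).astype(float)
        ll = forward_log_likelihood(
            hmm, EncodedBatch.from_sequences([Sequence("s", "ACD")])
        )[0]
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_nonfinite_parameters_rejected(self, rng):
        hmm, seq = _random_case(rng)
        hmm.match_logits[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            forward_log_likelihood(hmm, EncodedBatch.from_sequences([seq]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            EncodedBatch.from_sequences([])

    def test_batch_matches_single(self, rng):
        """Padded-batch likelihoods equal per-sequence runs."""
        hmm = random_hmm(rng, 3)
        seqs = [
            Sequence(f"s{i}", "".join(AA[j] for j in rng.integers(0, 20, rng.integers(1, 7))))
            for i in range(6)
        ]
        batch_ll = forward_log_likelihood(hmm, EncodedBatch.from_sequences(seqs))
        for k, s in enumerate(seqs):
            single = forward_log_likelihood(hmm, EncodedBatch.from_sequences([s]))[0]
            assert batch_ll[k] == pytest.approx(single, abs=1e-12)


class TestViterbi:
    def test_matches_path_maximum(self, rng):
        for _ in range(60):
            hmm, seq = _random_case(rng)
            _, lp = viterbi_decode(hmm, seq)
            assert lp == pytest.approx(
                brute_force_viterbi(*_oracle_tables(hmm, seq)), abs=1e-10
            )

    def test_never_exceeds_forward(self, rng):
        """max-path probability <= sum-over-paths probability, 200 trials."""
        for _ in range(200):
            hmm, seq = _random_case(rng)
            _, lp = viterbi_decode(hmm, seq)
            ll = forward_log_likelihood(hmm, EncodedBatch.from_sequences([seq]))[0]
            assert lp <= ll + 1e-9

    def test_single_path_model_recovers_it(self):
        hmm = ProfileHMM.uniform(2)
        big = 60.0
        hmm.begin_logits = np.array([big, -big])
        hmm.flank_n_logits = np.array([-big, big])
        hmm.flank_c_logits = np.array([-big, big])
        hmm.match_trans_logits = np.array([[big, -big, -big]], dtype=float)
        seq = Sequence("s", "AC")
        path, lp = viterbi_decode(hmm, seq)
        kinds = [s for s in path.states]
        assert kinds == [("B", 0), ("M", 0), ("M", 1), ("E", 0)]
        ll = forward_log_likelihood(hmm, EncodedBatch.from_sequences([seq]))[0]
        assert lp == pytest.approx(ll, abs=1e-6)

    def test_tie_prefers_match_over_delete(self):
        """Two exactly tied paths: the end state takes the Match arrival.

        Paths B->M1->D2->E and B->D1->M2->E are made exactly
        equiprobable; the tie at the end state is resolved toward the
        path arriving from the final Match state.
        """
        hmm = ProfileHMM.uniform(2)
        # begin uniform; M1 -> D2 has prob 1/3, so set D1 -> M2 to 1/3 too
        hmm.delete_trans_logits = np.log(np.array([[1 / 3, 2 / 3]]))
        seq = Sequence("s", "A")
        from oracles import enumerate_paths

        tr, EM, EI = _oracle_tables(hmm, seq)
        tied = sorted(lp for lp, _ in enumerate_paths(tr, EM, EI))[-2:]
        assert tied[0] == pytest.approx(tied[1], abs=1e-12)  # genuinely tied
        path, _ = viterbi_decode(hmm, seq)
        assert path.states == [("B", 0), ("D", 0), ("M", 1), ("E", 0)]

    def test_emitted_state_count_equals_length(self, rng):
        for _ in range(30):
            hmm, seq = _random_case(rng)
            path, _ = viterbi_decode(hmm, seq)
            assert len(path.emitted_states()) == len(seq)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        """Gradient of the forward log-likelihood, checked to 1e-4 relative."""
        hmm = random_hmm(rng, 3, scale=1.0)
        seqs = [
            Sequence(f"s{i}", "".join(AA[j] for j in rng.integers(0, 6, rng.integers(2, 7))))
            for i in range(5)
        ]
        batch = EncodedBatch.from_sequences(seqs)
        _, grads = forward_backward(hmm, batch)
        eps = 1e-6
        for name in PARAM_NAMES:
            arr = getattr(hmm, name)
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + eps
                up = forward_log_likelihood(hmm, batch).sum()
                arr[idx] = orig - eps
                down = forward_log_likelihood(hmm, batch).sum()
                arr[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(
                    fd, rel=1e-4, abs=1e-6
                ), name

    def test_posterior_occupancy_sums_to_one_per_position(self, rng):
        """Every emitted residue is explained by exactly one emitting state."""
        hmm = random_hmm(rng, 3)
        seq = Sequence("s", "ACDEF")
        batch = EncodedBatch.from_sequences([seq])
        _, grads = forward_backward(hmm, batch)
        per_pos = grads["bar_extra_match"][0].sum(axis=0) + grads["bar_extra_insert"][0]
        assert np.allclose(per_pos, 1.0, atol=1e-9)


class TestNormalization:
    def test_total_probability_approaches_one(self):
        """Sum of P(S) over all 2-letter sequences up to length 12 is ~1."""
        hmm = ProfileHMM.uniform(3)
        hmm.match_logits = np.full((3, 20), -40.0)
        hmm.match_logits[:, :2] = [[2.0, 0.0], [0.0, 2.0], [2.0, 0.0]]
        hmm.insert_logits = np.full(20, -40.0)
        hmm.insert_logits[:2] = 0.0
        hmm.flank_n_logits = np.array([-2.0, 2.0])
        hmm.flank_c_logits = np.array([-2.0, 2.0])
        hmm.begin_logits = np.array([2.0, -2.0])
        hmm.match_trans_logits = np.tile([2.0, -2.0, -2.0], (2, 1))
        hmm.insert_trans_logits = np.tile([1.0, -1.0], (2, 1))
        hmm.delete_trans_logits = np.tile([1.0, -1.0], (2, 1))
        total = 0.0
        for length in range(1, 13):
            seqs = [
                Sequence(f"x{k}", "".join(t))
                for k, t in enumerate(itertools.product("AC", repeat=length))
            ]
            total += float(
                np.exp(forward_log_likelihood(hmm, EncodedBatch.from_sequences(seqs))).sum()
            )
        assert 0.999 <= total <= 1.0 + 1e-9


class TestAminoPrior:
    def test_uniform_dirichlet_is_constant(self, rng):
        """alpha=1 density is log Gamma(20) per state, whatever the emissions."""
        from scipy.special import gammaln

        prior = DirichletMixture(np.array([1.0]), np.ones((1, 20)))
        for L in (1, 3):
            hmm = random_hmm(rng, L)
            assert amino_prior_log_density(hmm, prior) == pytest.approx(
                L * gammaln(20), rel=1e-12
            )

    def test_two_component_mixture_matches_direct_formula(self, rng):
        from scipy.stats import dirichlet as scipy_dirichlet

        a1 = rng.uniform(0.5, 3.0, 20)
        a2 = rng.uniform(0.5, 3.0, 20)
        w = 0.3
        prior = DirichletMixture(np.array([w, 1 - w]), np.stack([a1, a2]))
        hmm = random_hmm(rng, 1)
        p = hmm.match_probs()[0]
        expected = np.logaddexp(
            np.log(w) + scipy_dirichlet.logpdf(p, a1),
            np.log(1 - w) + scipy_dirichlet.logpdf(p, a2),
        )
        assert amino_prior_log_density(hmm, prior) == pytest.approx(expected, abs=1e-10)

    def test_invalid_simplex_rejected(self):
        prior = DirichletMixture.symmetric()
        with pytest.raises(ValueError):
            prior.log_density(np.full(20, 0.1))  # sums to 2

    def test_gradient_matches_finite_differences(self, rng):
        hmm = random_hmm(rng, 2, scale=0.5)
        prior = DirichletMixture(
            np.array([0.6, 0.4]),
            np.stack([rng.uniform(0.5, 2, 20), rng.uniform(0.5, 2, 20)]),
        )
        g = amino_prior_grad(hmm, prior)
        eps = 1e-6
        for idx in [(0, 0), (1, 7), (0, 19)]:
            orig = hmm.match_logits[idx]
            hmm.match_logits[idx] = orig + eps
            up = amino_prior_log_density(hmm, prior)
            hmm.match_logits[idx] = orig - eps
            down = amino_prior_log_density(hmm, prior)
            hmm.match_logits[idx] = orig
            assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-5, abs=1e-8)


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        hmm = random_hmm(rng, 4)
        p = tmp_path / "model.json"
        hmm.to_json(p)
        back = ProfileHMM.from_json(p)
        assert back.length == hmm.length
        for name in PARAM_NAMES:
            assert np.array_equal(getattr(back, name), getattr(hmm, name))

    def test_transition_rows_normalize(self, rng):
        hmm = random_hmm(rng, 3)
        tr = hmm.transition_log_table()
        assert np.exp(tr["nn"]) + np.exp(tr["nb"]) == pytest.approx(1.0, abs=1e-9)
        assert np.exp([tr["mm"][0], tr["mi"][0], tr["md"][0]]).sum() == pytest.approx(
            1.0, abs=1e-9
        )
        assert hmm.match_probs().sum(axis=1) == pytest.approx(np.ones(3), abs=1e-9)
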