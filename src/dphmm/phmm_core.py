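"""Profile hidden Markov model: parameterization, likelihood, decoding.

The model is the standard profile topology (match/insert/delete chains,
silent begin/end, and left/right flanking insert states).  All
parameters are stored unconstrained and mapped to probabilities by a
per-state softmax at use time, which makes plain gradient ascent on the
log-likelihood well-posed.  The forward log-likelihood is exactly
differentiable: :func:`forward_backward` returns analytic gradients
with respect to every unconstrained parameter, obtained by a reverse
sweep of the log-space dynamic program (the forward–backward
expected-count identity).

An optional ``extra_emission`` hook adds a per-(state, position)
log-density to the amino-acid emission term before path summation; the
embedding emission model plugs in through this hook.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln, log_softmax, softmax

from . import _dp
from .msa_io import ALPHABET, AMINO_ACIDS, Sequence

PROB_FLOOR = 1e-16
SCHEMA_VERSION = "dphmm-hmm-1"

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
#: Log-emission used for 'X' in every emitting state: state-independent,
#: so unknown residues influence neither the alignment nor the gradient.
_X_LOGPROB = float(np.log(1.0 / 20.0))


def encode(residues: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in residues], dtype=np.int64)


@dataclass
class EncodedBatch:
    """Padded integer encoding of a set of sequences."""

    identifiers: list[str]
    obs: np.ndarray  # (n, T_max) int, padded with 0 beyond each length
    lengths: np.ndarray  # (n,)

    @classmethod
    def from_sequences(cls, seqs: list[Sequence]) -> "EncodedBatch":
        if not seqs:
            raise ValueError("empty batch")
        if any(len(s) == 0 for s in seqs):
            raise ValueError("empty sequence in batch")
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        obs = np.zeros((len(seqs), int(lengths.max())), dtype=np.int64)
        for k, s in enumerate(seqs):
            obs[k, : len(s)] = encode(s.residues)
        return cls([s.identifier for s in seqs], obs, lengths)

    @property
    def n(self) -> int:
        return len(self.lengths)

    def subset(self, idx) -> "EncodedBatch":
        idx = np.asarray(idx)
        t = int(self.lengths[idx].max())
        return EncodedBatch(
            [self.identifiers[i] for i in idx], self.obs[idx, :t], self.lengths[idx]
        )


@dataclass
class StatePath:
    """A path of states through the profile, in generative order.

    ``states`` holds ``(kind, index)`` tuples with kinds
    ``N B M I D E C``; ``M/I/N/C`` entries each emit one residue.
    """

    states: list[tuple[str, int]]

    EMITTING = ("N", "M", "I", "C")

    def emitted_states(self) -> list[tuple[str, int]]:
        return [s for s in self.states if s[0] in self.EMITTING]

    def __len__(self) -> int:
        return len(self.states)


def _uniform_logits(shape):
    return np.zeros(shape)


@dataclass
class ProfileHMM:
    """Transition and amino-acid emission parameters of the profile topology.

    All fields ending in ``_logits`` are unconstrained; probabilities
    are softmax(logits) with a floor of ``1e-16`` before taking logs.
    """

    length: int
    match_logits: np.ndarray  # (L, 20)
    insert_logits: np.ndarray  # (20,), shared by inserts and both flanks
    flank_n_logits: np.ndarray  # (2,): [loop, exit]
    flank_c_logits: np.ndarray  # (2,): [loop, exit]
    begin_logits: np.ndarray  # (2,): [-> M_1, -> D_1]
    match_trans_logits: np.ndarray  # (L-1, 3): [-> M, -> I, -> D]
    insert_trans_logits: np.ndarray  # (L-1, 2): [-> M, loop]
    delete_trans_logits: np.ndarray  # (L-1, 2): [-> M, -> D]

    @classmethod
    def uniform(cls, length: int) -> "ProfileHMM":
        if length < 1:
            raise ValueError("model length must be >= 1")
        K = max(length - 1, 0)
        return cls(
            length=length,
            match_logits=_uniform_logits((length, 20)),
            insert_logits=_uniform_logits(20),
            flank_n_logits=_uniform_logits(2),
            flank_c_logits=_uniform_logits(2),
            begin_logits=_uniform_logits(2),
            match_trans_logits=_uniform_logits((K, 3)),
            insert_trans_logits=_uniform_logits((K, 2)),
            delete_trans_logits=_uniform_logits((K, 2)),
        )

    # -- probability-space views ------------------------------------------
    def match_probs(self) -> np.ndarray:
        """(L, 20) match emission distributions."""
        return softmax(self.match_logits, axis=-1)

    def insert_probs(self) -> np.ndarray:
        return softmax(self.insert_logits)

    def _emission_table(self, logits) -> np.ndarray:
        lp = np.log(softmax(logits, axis=-1) + PROB_FLOOR)
        lp = np.atleast_2d(lp)
        return np.concatenate([lp, np.full((lp.shape[0], 1), _X_LOGPROB)], axis=1)

    def match_log_emissions(self) -> np.ndarray:
        """(L, 21) log emission table including the 'X' column."""
        return self._emission_table(self.match_logits)

    def insert_log_emissions(self) -> np.ndarray:
        return self._emission_table(self.insert_logits)[0]

    def transition_log_table(self) -> dict:
        def ls(z):
            return np.log(softmax(z, axis=-1) + PROB_FLOOR)

        fn, fc, bg = ls(self.flank_n_logits), ls(self.flank_c_logits), ls(self.begin_logits)
        tr = {
            "nn": fn[0], "nb": fn[1],
            "cc": fc[0], "ct": fc[1],
            "bm": bg[0], "bd": bg[1],
        }
        if self.length > 1:
            m = ls(self.match_trans_logits)
            i = ls(self.insert_trans_logits)
            d = ls(self.delete_trans_logits)
            tr.update(
                mm=m[:, 0], mi=m[:, 1], md=m[:, 2],
                im=i[:, 0], ii=i[:, 1],
                dm=d[:, 0], dd=d[:, 1],
            )
        else:
            z = np.zeros(0)
            tr.update(mm=z, mi=z, md=z, im=z, ii=z, dm=z, dd=z)
        return tr

    def validate(self) -> None:
        for name in (
            "match_logits", "insert_logits", "flank_n_logits", "flank_c_logits",
            "begin_logits", "match_trans_logits", "insert_trans_logits",
            "delete_trans_logits",
        ):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite parameters in {name}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {"schema": SCHEMA_VERSION, "length": self.length}
        for name in (
            "match_logits", "insert_logits", "flank_n_logits", "flank_c_logits",
            "begin_logits", "match_trans_logits", "insert_trans_logits",
            "delete_trans_logits",
        ):
            payload[name] = getattr(self, name).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema {payload.get('schema')!r}")
        kwargs = {
            k: np.asarray(payload[k], dtype=float)
            for k in payload
            if k.endswith("_logits")
        }
        return cls(length=int(payload["length"]), **kwargs)


def _emission_grids(hmm, batch, extra_match=None, extra_insert=None):
    """Assemble full (n, L, T) match and (n, T) insert emission tables."""
    em_aa = hmm.match_log_emissions()  # (L, 21)
    ins_aa = hmm.insert_log_emissions()  # (21,)
    EM = em_aa[:, batch.obs].transpose(1, 0, 2)  # (n, L, T)
    EI = ins_aa[batch.obs]  # (n, T)
    if extra_match is not None:
        if extra_match.shape != EM.shape:
            raise ValueError(
                f"extra_emission shape {extra_match.shape} != {EM.shape}"
            )
        EM = EM + extra_match
    if extra_insert is not None:
        EI = EI + extra_insert
    return EM, EI


def forward_log_likelihood(hmm, batch, extra_match=None, extra_insert=None):
    """Per-sequence forward log-likelihoods ``log P(S)`` (shape (n,)).

    ``extra_match``/``extra_insert`` add per-(state, position)
    log-densities to the emission term before the path sum — the hook
    through which embedding emissions enter the joint model.
    """
    hmm.validate()
    EM, EI = _emission_grids(hmm, batch, extra_match, extra_insert)
    ll, _ = _dp.forward_pass(EM, EI, hmm.transition_log_table(), batch.lengths)
    return ll


def forward_backward(hmm, batch, extra_match=None, extra_insert=None):
    """Log-likelihoods plus exact gradients of their sum.

    Returns ``(ll, grads)``; ``grads`` maps every ``*_logits`` field of
    the model to the gradient of ``sum(ll)`` and additionally carries
    ``bar_extra_match``/``bar_extra_insert``, the adjoints of the extra
    emission grids (equal to posterior state occupancies, used both for
    embedding-parameter gradients and posterior decoding).
    """
    hmm.validate()
    EM, EI = _emission_grids(hmm, batch, extra_match, extra_insert)
    tr = hmm.transition_log_table()
    ll, state = _dp.forward_pass(EM, EI, tr, batch.lengths)
    bar_EM, bar_EI, tc = _dp.backward_pass(EM, EI, tr, batch.lengths, state)

    L = hmm.length
    obs_flat = batch.obs.reshape(-1)
    # emission-logit gradients via expected symbol counts ('X' is constant)
    cm = np.zeros((L, 21))
    bar_m = bar_EM.transpose(1, 0, 2).reshape(L, -1)
    for i in range(L):
        cm[i] = np.bincount(obs_flat, weights=bar_m[i], minlength=21)
    ci = np.bincount(obs_flat, weights=bar_EI.reshape(-1), minlength=21)

    def softmax_chain(counts, logits):
        p = softmax(logits, axis=-1)
        tot = counts.sum(axis=-1, keepdims=True)
        return counts - p * tot

    grads = {
        "match_logits": softmax_chain(cm[:, :20], hmm.match_logits),
        "insert_logits": softmax_chain(ci[:20], hmm.insert_logits),
        "flank_n_logits": softmax_chain(
            np.array([tc["nn"], tc["nb"]]), hmm.flank_n_logits
        ),
        "flank_c_logits": softmax_chain(
            np.array([tc["cc"], tc["ct"]]), hmm.flank_c_logits
        ),
        "begin_logits": softmax_chain(
            np.array([tc["bm"], tc["bd"]]), hmm.begin_logits
        ),
        "bar_extra_match": bar_EM,
        "bar_extra_insert": bar_EI,
    }
    if L > 1:
        grads["match_trans_logits"] = softmax_chain(
            np.stack([tc["mm"], tc["mi"], tc["md"]], axis=1), hmm.match_trans_logits
        )
        grads["insert_trans_logits"] = softmax_chain(
            np.stack([tc["im"], tc["ii"]], axis=1), hmm.insert_trans_logits
        )
        grads["delete_trans_logits"] = softmax_chain(
            np.stack([tc["dm"], tc["dd"]], axis=1), hmm.delete_trans_logits
        )
    else:
        grads["match_trans_logits"] = np.zeros((0, 3))
        grads["insert_trans_logits"] = np.zeros((0, 2))
        grads["delete_trans_logits"] = np.zeros((0, 2))
    return ll, grads


def viterbi_decode(hmm, seq, extra_match=None, extra_insert=None):
    """Most probable state path for one sequence and its log-probability.

    ``seq`` may be a :class:`~dphmm.msa_io.Sequence` or an encoded int
    vector.  Ties prefer Match over Delete over Insert.  The returned
    path log-probability never exceeds the forward log-likelihood.
    """
    hmm.validate()
    if isinstance(seq, Sequence):
        obs = encode(seq.residues)
    else:
        obs = np.asarray(seq, dtype=np.int64)
    if obs.size == 0:
        raise ValueError("empty sequence")
    batch = EncodedBatch(["_"], obs[None, :], np.array([obs.size]))
    EM, EI = _emission_grids(hmm, batch, extra_match, extra_insert)
    path, logprob = _dp.viterbi_single(EM[0], EI[0], hmm.transition_log_table())
    return StatePath(path), logprob


# -- amino-acid prior ------------------------------------------------------


@dataclass
class DirichletMixture:
    """Mixture of Dirichlet densities over the 20-simplex."""

    weights: np.ndarray  # (M,)
    alphas: np.ndarray  # (M, 20)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.alphas = np.atleast_2d(np.asarray(self.alphas, dtype=float))
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.alphas <= 0):
            raise ValueError("concentration parameters must be positive")

    @classmethod
    def symmetric(cls, alpha: float = 1.1) -> "DirichletMixture":
        return cls(np.array([1.0]), np.full((1, 20), alpha))

    def log_density(self, p: np.ndarray) -> np.ndarray:
        """Log mixture density at each row of ``p`` (rows on the simplex)."""
        p = np.atleast_2d(p)
        if np.any(p <= 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("emission rows must lie on the open simplex")
        lognorm = gammaln(self.alphas.sum(axis=1)) - gammaln(self.alphas).sum(axis=1)
        comp = lognorm[None, :] + (np.log(p)[:, None, :] * (self.alphas - 1.0)[None, :, :]).sum(axis=2)
        comp = comp + np.log(self.weights)[None, :]
        m = comp.max(axis=1)
        return m + np.log(np.exp(comp - m[:, None]).sum(axis=1))

    def grad_wrt_p(self, p: np.ndarray) -> np.ndarray:
        """d log-density / d p, row-wise (for chaining through softmax)."""
        p = np.atleast_2d(p)
        lognorm = gammaln(self.alphas.sum(axis=1)) - gammaln(self.alphas).sum(axis=1)
        comp = (
            np.log(self.weights)[None, :]
            + lognorm[None, :]
            + (np.log(p)[:, None, :] * (self.alphas - 1.0)[None, :, :]).sum(axis=2)
        )
        resp = softmax(comp, axis=1)  # (n, M)
        return np.einsum("nm,mk->nk", resp, self.alphas - 1.0) / p


def amino_prior_log_density(hmm: ProfileHMM, prior: DirichletMixture) -> float:
    """Sum over match states of the log mixture-of-Dirichlet density."""
    if hmm.length == 0:
        return 0.0
    return float(prior.log_density(hmm.match_probs()).sum())


def amino_prior_grad(hmm: ProfileHMM, prior: DirichletMixture) -> np.ndarray:
    """Gradient of the prior log-density with respect to ``match_logits``."""
    p = hmm.match_probs()
    g = prior.grad_wrt_p(p)
    return p * (g - (p * g).sum(axis=1, keepdims=True))
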