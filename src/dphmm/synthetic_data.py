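"""Generators for simulated protein families and planted-signal embeddings.

These produce every fixture the test-bench needs without network
access: families sampled from a known profile HMM (with their true
alignments), and families whose amino-acid profile is deliberately
ambiguous between two column assignments while planted embedding
vectors disambiguate — emulating the situation where residue identity
alone cannot resolve an alignment but contextual embeddings can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedder import EmbeddingCache
from .msa_io import AMINO_ACIDS, MultipleAlignment, PairwiseAlignment, Sequence
from .msa_decode import paths_to_msa
from .phmm_core import ProfileHMM, StatePath

REFERENCE_SUBSET_SIZE = 10


def _logit(p, floor=1e-9):
    return np.log(np.clip(np.asarray(p, dtype=float), floor, None))


def sample_from_hmm(hmm: ProfileHMM, n: int, seed: int = 0):
    """Draw ``n`` sequences from the generative process, with true paths.

    Returns ``(sequences, paths)``; deterministic given ``seed``.
    Sequences that come out empty (all-delete paths with no flank
    emissions) are resampled, so exactly ``n`` non-empty sequences are
    returned.
    """
    rng = np.random.default_rng(seed)
    L = hmm.length
    match_p = hmm.match_probs()
    ins_p = hmm.insert_probs()
    tr = {k: np.exp(v) for k, v in hmm.transition_log_table().items()}

    def draw(p):
        return AMINO_ACIDS[rng.choice(20, p=p / p.sum())]

    seqs, paths = [], []
    while len(seqs) < n:
        states: list[tuple[str, int]] = []
        residues: list[str] = []
        while rng.random() < tr["nn"] / (tr["nn"] + tr["nb"]):
            states.append(("N", 0)); residues.append(draw(ins_p))
        states.append(("B", 0))
        go_match = rng.random() < tr["bm"] / (tr["bm"] + tr["bd"])
        i = 0
        kind = "M" if go_match else "D"
        while True:
            if kind == "M":
                states.append(("M", i)); residues.append(draw(match_p[i]))
                if i == L - 1:
                    break
                u = rng.random() * (tr["mm"][i] + tr["mi"][i] + tr["md"][i])
                if u < tr["mm"][i]:
                    i += 1
                elif u < tr["mm"][i] + tr["mi"][i]:
                    kind = "I"
                else:
                    kind, i = "D", i + 1
            elif kind == "I":
                states.append(("I", i)); residues.append(draw(ins_p))
                if rng.random() < tr["im"][i] / (tr["im"][i] + tr["ii"][i]):
                    kind, i = "M", i + 1
            else:  # D
                states.append(("D", i))
                if i == L - 1:
                    break
                if rng.random() < tr["dm"][i] / (tr["dm"][i] + tr["dd"][i]):
                    kind, i = "M", i + 1
                else:
                    i += 1
        states.append(("E", 0))
        while rng.random() < tr["cc"] / (tr["cc"] + tr["ct"]):
            states.append(("C", 0)); residues.append(draw(ins_p))
        if not residues:
            continue
        seqs.append(Sequence(f"seq{len(seqs)}", "".join(residues)))
        paths.append(StatePath(states))
    return seqs, paths


def _family_hmm(L_M: int, conservation: float, indel_rate: float, rng) -> ProfileHMM:
    hmm = ProfileHMM.uniform(L_M)
    if np.isinf(conservation):
        probs = np.full((L_M, 20), 1e-9)
        probs[np.arange(L_M), rng.choice(20, L_M)] = 1.0
    else:
        probs = rng.dirichlet(np.full(20, 1.0 / conservation), size=L_M)
    hmm.match_logits = _logit(probs)
    hmm.insert_logits = np.zeros(20)  # uniform background
    rho = indel_rate
    hmm.begin_logits = _logit([1 - rho, rho])
    hmm.flank_n_logits = _logit([rho, 1 - rho])
    hmm.flank_c_logits = _logit([rho, 1 - rho])
    if L_M > 1:
        K = L_M - 1
        hmm.match_trans_logits = np.tile(_logit([1 - 2 * rho, rho, rho]), (K, 1))
        hmm.insert_trans_logits = np.tile(_logit([1 - rho, rho]), (K, 1))
        hmm.delete_trans_logits = np.tile(_logit([1 - rho, rho]), (K, 1))
    return hmm


def make_family(
    L_M: int = 8,
    n: int = 300,
    conservation: float = 10.0,
    indel_rate: float = 0.03,
    seed: int = 0,
):
    """A random peaked profile, ``n`` sampled sequences, and the true MSA.

    Match emissions are drawn from a symmetric Dirichlet with
    concentration ``1/conservation`` (one-hot in the limit
    ``conservation -> inf``); indel events open and extend with
    probability ``indel_rate``.  The first ``min(10, n)`` sequences are
    the designated reference subset.  Returns
    ``(hmm, sequences, true_msa, reference_ids)``.
    """
    rng = np.random.default_rng(seed)
    hmm = _family_hmm(L_M, conservation, indel_rate, rng)
    seqs, paths = sample_from_hmm(hmm, n, seed=int(rng.integers(2**31)))
    true_msa = paths_to_msa(seqs, paths, L_M)
    reference_ids = [s.identifier for s in seqs[: min(REFERENCE_SUBSET_SIZE, n)]]
    return hmm, seqs, true_msa, reference_ids


@dataclass
class AmbiguousFamilyParams:
    """Knobs for the planted-signal ambiguous family.

    The profile is a tandem repeat: ``motif_length`` columns whose
    amino-acid distributions are duplicated in a second half, so a
    sequence carrying one motif copy fits either half equally well on
    residues alone.  Each true column carries a distinct planted
    embedding direction of norm ``signal_strength`` on top of unit
    noise, so embeddings identify the column (and in particular the
    half).  ``signal_strength=0`` makes embeddings uninformative.
    """

    motif_length: int = 5
    n: int = 200
    conservation: float = 10.0
    signal_strength: float = 4.0
    r: int = 16
    fraction_full: float = 0.4
    seed: int = 0


def make_ambiguous_family_with_embedding_signal(params: AmbiguousFamilyParams | None = None, seed: int | None = None):
    """Family whose alignment is residue-ambiguous but embedding-resolvable.

    Sequences carry both motif copies (fraction ``fraction_full``) or a
    single copy (the rest, split evenly between first-half-only and
    second-half-only with the other half deleted).  Returns
    ``(sequences, true_msa, cache, half_labels)`` where ``cache`` is a
    drop-in compressed-embedding cache of r-dimensional planted vectors
    and ``half_labels`` maps each (identifier, residue index) to the
    sub-profile half its true column belongs to.
    """
    p = params or AmbiguousFamilyParams()
    if seed is not None:
        p = AmbiguousFamilyParams(**{**p.__dict__, "seed": seed})
    rng = np.random.default_rng(p.seed)
    k = p.motif_length
    L_M = 2 * k
    motif = rng.dirichlet(np.full(20, 1.0 / p.conservation), size=k)
    col_probs = np.vstack([motif, motif])  # identical marginals per half

    if L_M > p.r:
        raise ValueError("2 * motif_length must not exceed the embedding rank r")
    directions, _ = np.linalg.qr(rng.standard_normal((p.r, L_M)))
    directions = directions.T  # (L_M, r), orthonormal planted directions

    kinds = rng.choice(
        3, size=p.n, p=[p.fraction_full, (1 - p.fraction_full) / 2, (1 - p.fraction_full) / 2]
    )
    seqs, paths, data, labels = [], [], {}, {}
    for s in range(p.n):
        cols = {
            0: list(range(L_M)),          # both copies
            1: list(range(k)),            # first half only
            2: list(range(k, L_M)),       # second half only
        }[int(kinds[s])]
        residues = "".join(
            AMINO_ACIDS[rng.choice(20, p=col_probs[c])] for c in cols
        )
        states: list[tuple[str, int]] = [("B", 0)]
        prev = -1
        for c in cols:
            states.extend(("D", d) for d in range(prev + 1, c))
            states.append(("M", c))
            prev = c
        states.extend(("D", d) for d in range(prev + 1, L_M))
        states.append(("E", 0))
        ident = f"seq{s}"
        seqs.append(Sequence(ident, residues))
        paths.append(StatePath(states))
        emb = (
            p.signal_strength * directions[cols]
            + rng.standard_normal((len(cols), p.r))
        )
        data[ident] = emb
        labels[ident] = [0 if c < k else 1 for c in cols]
    true_msa = paths_to_msa(seqs, paths, L_M)
    cache = EmbeddingCache(data, {"schema": "synthetic-planted", "seed": p.seed})
    return seqs, true_msa, cache, labels


def make_planted_scoring_pairs(
    n_pairs: int = 40,
    length: int = 12,
    d: int = 32,
    pool: int = 16,
    signal: float = 3.0,
    noise: float = 0.5,
    seed: int = 0,
):
    """Embedded sequence pairs whose aligned residues share a latent direction.

    A pool of ``pool`` orthonormal directions in R^d represents
    conserved-column identities.  For each pair, ``length`` directions
    are drawn without replacement; residue ``i`` of both sequences gets
    ``signal * u_i`` plus isotropic Gaussian noise of scale ``noise``
    (sub-unit by default: embeddings of a conserved column cluster
    tightly relative to between-column distances) and the supervision
    is the identity alignment.  Returns a list of
    ``(embS, embT, PairwiseAlignment)`` suitable for scoring-model
    pretraining.
    """
    if length > pool:
        raise ValueError("length must not exceed the direction pool size")
    if pool > d:
        raise ValueError("direction pool cannot exceed the embedding dimension")
    rng = np.random.default_rng(seed)
    u, _ = np.linalg.qr(rng.standard_normal((d, pool)))
    u = u.T  # (pool, d), orthonormal rows
    pairs = []
    for k in range(n_pairs):
        cols = rng.choice(pool, size=length, replace=False)
        embS = signal * u[cols] + noise * rng.standard_normal((length, d))
        embT = signal * u[cols] + noise * rng.standard_normal((length, d))
        pa = PairwiseAlignment(f"a{k}", f"b{k}", [(i, i) for i in range(length)])
        pairs.append((embS, embT, pa))
    return pairs
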