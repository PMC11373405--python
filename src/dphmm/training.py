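"""Unsupervised fitting of the model to unaligned sequences.

The objective is the mean per-sequence forward log-likelihood of the
joint (amino acid, embedding) emission model plus the amino-acid
Dirichlet prior and the embedding Gaussian-mixture prior, both scaled
by 1/n.  All parameters are updated by Adam ascent on exact analytic
gradients over shuffled mini-batches; several independently seeded
model replicas are trained and the one with the highest final
objective is kept.

With ``frozen_insertions`` (the default) the shared insert/flank
amino-acid distribution stays at its background initialization and the
insert/flank embedding density is a fixed moment-matched background,
so only match states learn embedding emissions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from ._optim import Adam
from .embedding_emissions import (
    EmbeddingEmissionSet,
    EmbeddingPrior,
    fit_embedding_prior,
    init_emissions_from_prior,
    prior_grad_mu,
    prior_log_density,
)
from .msa_io import Sequence
from .phmm_core import (
    DirichletMixture,
    EncodedBatch,
    ProfileHMM,
    amino_prior_grad,
    amino_prior_log_density,
    forward_backward,
    forward_log_likelihood,
)

logger = logging.getLogger(__name__)

_HMM_PARAM_NAMES = (
    "match_logits", "insert_logits", "flank_n_logits", "flank_c_logits",
    "begin_logits", "match_trans_logits", "insert_trans_logits",
    "delete_trans_logits",
)


@dataclass
class TrainingConfig:
    use_embeddings: bool = False
    frozen_insertions: bool = True
    tau: float = 1.0
    batch_size: int = 256
    learning_rate: float = 0.05
    emb_learning_rate: float = 0.005
    max_epochs: int = 200
    patience: int = 10
    replicas: int = 4
    seed: int = 0
    model_length: int | None = None
    length_cap_factor: float = 10.0
    prior_components: int = 32

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        for name in ("batch_size", "max_epochs", "patience", "replicas"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    hmm: ProfileHMM
    ems: EmbeddingEmissionSet | None
    trace: list[float]
    config: TrainingConfig
    seed: int

    @property
    def final_objective(self) -> float:
        return self.trace[-1]


def _padded_embeddings(batch: EncodedBatch, cache) -> np.ndarray:
    missing = [i for i in batch.identifiers if i not in cache]
    if missing:
        raise ValueError(f"missing cache entries for: {missing}")
    r = cache.get(batch.identifiers[0]).shape[1]
    X = np.zeros((batch.n, batch.obs.shape[1], r))
    for k, ident in enumerate(batch.identifiers):
        x = cache.get(ident)
        if x.shape[0] != batch.lengths[k]:
            raise ValueError(f"cached embedding rows != length for {ident!r}")
        X[k, : x.shape[0]] = x
    return X


def _extra_grids_batched(ems: EmbeddingEmissionSet, X: np.ndarray):
    """Tempered match and background emission grids for a padded batch.

    ``X`` is (n, T, r); returns ``extra_match`` (n, L, T) and
    ``extra_insert`` (n, T).
    """
    var = ems.var
    inv = 1.0 / var
    logdet = np.log(2.0 * np.pi * var).sum(axis=1)  # (L,)
    # ||x - mu||^2_var expanded: x^2/v - 2 x mu/v + mu^2/v
    a = np.einsum("ntr,lr->nlt", X**2, inv)
    b = np.einsum("ntr,lr->nlt", X, ems.mu * inv)
    c = (ems.mu**2 * inv).sum(axis=1)  # (L,)
    dens = -0.5 * (logdet[None, :, None] + a - 2 * b + c[None, :, None])
    bg_inv = 1.0 / ems.bg_var
    bg_logdet = np.log(2.0 * np.pi * ems.bg_var).sum()
    bg = -0.5 * (
        bg_logdet
        + (X**2 * bg_inv).sum(axis=2)
        - 2 * (X * (ems.bg_mean * bg_inv)).sum(axis=2)
        + (ems.bg_mean**2 * bg_inv).sum()
    )
    return ems.tau * dens, ems.tau * bg


def _embedding_grads(ems: EmbeddingEmissionSet, X: np.ndarray, bar: np.ndarray):
    """Gradients of sum(ll) w.r.t. mu and s_raw from the emission adjoints."""
    var = ems.var
    W = bar.sum(axis=(0, 2))  # (L,)
    S1 = np.einsum("nlt,ntr->lr", bar, X)
    S2 = np.einsum("nlt,ntr->lr", bar, X**2)
    dmu = ems.tau * (S1 - W[:, None] * ems.mu) / var
    dvar = ems.tau * (
        (S2 - 2 * ems.mu * S1 + W[:, None] * ems.mu**2) / (2 * var**2)
        - W[:, None] / (2 * var)
    )
    ds_raw = dvar * expit(ems.s_raw)
    return dmu, ds_raw


def objective(hmm, ems, batch, cache, amino_prior, emb_prior) -> float:
    """Mean forward log-likelihood plus priors scaled by 1/n."""
    if ems is not None:
        X = _padded_embeddings(batch, cache)
        extra_m, extra_i = _extra_grids_batched(ems, X)
        ll = forward_log_likelihood(hmm, batch, extra_m, extra_i)
    else:
        ll = forward_log_likelihood(hmm, batch)
    total = float(ll.mean())
    n = batch.n
    if amino_prior is not None:
        total += amino_prior_log_density(hmm, amino_prior) / n
    if ems is not None and emb_prior is not None:
        total += prior_log_density(ems, emb_prior) / n
    return total


def _init_hmm(L_M: int, rng: np.random.Generator) -> ProfileHMM:
    hmm = ProfileHMM.uniform(L_M)
    hmm.match_logits = rng.normal(0.0, 0.2, (L_M, 20))
    hmm.insert_logits = np.zeros(20)
    jit = lambda shape: rng.normal(0.0, 0.1, shape)
    hmm.begin_logits = np.log([0.9, 0.1]) + jit(2)
    hmm.flank_n_logits = np.log([0.3, 0.7]) + jit(2)
    hmm.flank_c_logits = np.log([0.3, 0.7]) + jit(2)
    if L_M > 1:
        K = L_M - 1
        hmm.match_trans_logits = np.tile(np.log([0.85, 0.075, 0.075]), (K, 1)) + jit((K, 3))
        hmm.insert_trans_logits = np.tile(np.log([0.7, 0.3]), (K, 1)) + jit((K, 2))
        hmm.delete_trans_logits = np.tile(np.log([0.7, 0.3]), (K, 1)) + jit((K, 2))
    return hmm


def _fit_replica(batch, X, config, amino_prior, emb_prior, seed) -> TrainedModel:
    rng = np.random.default_rng(seed)
    n = batch.n
    hmm = _init_hmm(
        config.model_length or _default_length(batch), rng
    )
    ems = None
    params = {name: getattr(hmm, name) for name in _HMM_PARAM_NAMES}
    lr = {name: config.learning_rate for name in _HMM_PARAM_NAMES}
    if config.use_embeddings:
        ems = init_emissions_from_prior(
            emb_prior, hmm.length, seed=int(rng.integers(2**31)), tau=config.tau
        )
        params["mu"] = ems.mu
        params["s_raw"] = ems.s_raw
        lr["mu"] = lr["s_raw"] = config.emb_learning_rate
    frozen = {"insert_logits"} if config.frozen_insertions else set()
    opt = Adam({k: v for k, v in params.items() if k not in frozen}, lr)

    trace: list[float] = []
    best, since_best = -np.inf, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_ll = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            sub = batch.subset(idx)
            B = len(idx)
            if config.use_embeddings:
                Xs = X[idx, : sub.obs.shape[1]]
                extra_m, extra_i = _extra_grids_batched(ems, Xs)
                ll, grads = forward_backward(hmm, sub, extra_m, extra_i)
            else:
                ll, grads = forward_backward(hmm, sub)
            epoch_ll += float(ll.sum())
            g = {name: grads[name] / B for name in _HMM_PARAM_NAMES}
            g["match_logits"] = g["match_logits"] + amino_prior_grad(hmm, amino_prior) / n
            if config.use_embeddings:
                dmu, ds = _embedding_grads(ems, Xs, grads["bar_extra_match"])
                g["mu"] = dmu / B + prior_grad_mu(ems, emb_prior) / n
                g["s_raw"] = ds / B
            opt.step({k: -v for k, v in g.items() if k not in frozen})
        obj = epoch_ll / n
        obj += amino_prior_log_density(hmm, amino_prior) / n
        if config.use_embeddings:
            obj += prior_log_density(ems, emb_prior) / n
        trace.append(obj)
        logger.info("replica seed=%d epoch=%d objective=%.4f", seed, epoch, obj)
        if obj > best + 1e-4:
            best, since_best = obj, 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return TrainedModel(hmm, ems, trace, config, seed)


def _default_length(batch: EncodedBatch) -> int:
    return max(int(np.median(batch.lengths)), 1)


def fit(
    seqs: list[Sequence],
    cache=None,
    config: TrainingConfig | None = None,
    amino_prior: DirichletMixture | None = None,
    emb_prior: EmbeddingPrior | None = None,
) -> list[TrainedModel]:
    """Train ``config.replicas`` independently seeded models.

    Returns one :class:`TrainedModel` per replica (pick with
    :func:`select_best`).  When embeddings are enabled and no prior is
    given, a mixture prior is first fitted to the cached compressed
    embeddings of the input residues.
    """
    config = config or TrainingConfig()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = np.array([len(s) for s in seqs])
    cap = config.length_cap_factor * np.median(lengths)
    too_long = [s.identifier for s in seqs if len(s) > cap]
    if too_long:
        raise ValueError(
            f"sequences longer than {config.length_cap_factor}x the median "
            f"length: {too_long[:5]} — raise length_cap_factor or remove them"
        )
    if len(set(s.residues for s in seqs)) == 1 and lengths[0] == 1:
        warnings.warn("degenerate family: all inputs are one identical residue")
    batch = EncodedBatch.from_sequences(seqs)
    amino_prior = amino_prior or DirichletMixture.symmetric()
    X = None
    if config.use_embeddings:
        if cache is None:
            raise ValueError("use_embeddings requires a compressed-embedding cache")
        X = _padded_embeddings(batch, cache)
        if emb_prior is None:
            vectors = np.concatenate(
                [cache.get(i) for i in batch.identifiers], axis=0
            )
            C = min(config.prior_components, len(vectors))
            emb_prior = fit_embedding_prior(vectors, C, seed=config.seed)
    return [
        _fit_replica(batch, X, config, amino_prior, emb_prior, config.seed + k)
        for k in range(config.replicas)
    ]


def select_best(models: list[TrainedModel]) -> TrainedModel:
    """Replica with the highest final objective; ties go to the smallest seed."""
    if not models:
        raise ValueError("no models to select from")
    return max(models, key=lambda m: (m.final_objective, -m.seed))
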