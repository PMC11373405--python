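"""Low-rank bilinear residue-pair scoring model.

A pair of d-dimensional residue embeddings ``x, y`` is scored by the
symmetric bilinear form ``x^T W y`` with ``W = R R^T`` and
``R in R^{d x r}`` (r << d), passed through a logistic sigmoid so each
entry can be read as the probability that the two residues align.  The
same factor ``R`` doubles as the compression map ``emb -> emb @ R``
used by the alignment model, so scoring with compressed embeddings is
identical to scoring with raw ones.

Pretraining treats every residue pair of a supervised pairwise
alignment as an independent binary classification example and minimizes
a positively reweighted cross entropy with Adam; only ``R`` is
trainable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from ._optim import Adam
from .msa_io import PairwiseAlignment

SCHEMA_VERSION = "dphmm-scoring-1"
CLAMP = 1e-7


@dataclass
class ScoringModel:
    """The d x r factor R; implied W = R R^T is PSD by construction."""

    R: np.ndarray
    activation: str = "logistic-sigmoid"

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2:
            raise ValueError("R must be a d x r matrix")

    @property
    def d(self) -> int:
        return self.R.shape[0]

    @property
    def r(self) -> int:
        return self.R.shape[1]

    def provenance_hash(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.d}x{self.r}:{self.activation}:".encode())
        h.update(np.ascontiguousarray(self.R).tobytes())
        return h.hexdigest()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "schema": SCHEMA_VERSION,
                    "d": self.d,
                    "r": self.r,
                    "activation": self.activation,
                    "R": self.R.reshape(-1).tolist(),  # row-major
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema {payload.get('schema')!r}")
        R = np.asarray(payload["R"], dtype=float).reshape(payload["d"], payload["r"])
        return cls(R, payload["activation"])

    @classmethod
    def random_init(cls, d: int, r: int, seed: int = 0) -> "ScoringModel":
        if r >= d:
            raise ValueError("low-rank requirement: r must be < d")
        rng = np.random.default_rng(seed)
        return cls(rng.standard_normal((d, r)) / np.sqrt(d))


def parameter_count(model: ScoringModel) -> int:
    """Trainable entries: d*r (the factor only, never the full d x d W)."""
    return model.d * model.r


def compress(emb: np.ndarray, model: ScoringModel) -> np.ndarray:
    """Compress raw (L, d) embeddings to (L, r): ``emb @ R``."""
    emb = np.asarray(emb, dtype=float)
    if emb.shape[-1] != model.d:
        raise ValueError(f"embedding dim {emb.shape[-1]} != model d {model.d}")
    return emb @ model.R


def score_matrix(embS: np.ndarray, embT: np.ndarray, model: ScoringModel) -> np.ndarray:
    """(L1, L2) residue–residue alignment probabilities.

    ``A = sigmoid(embS R (embT R)^T)``; entry (i, j) scores how well
    residue i of S aligns with residue j of T.
    """
    u = compress(embS, model)
    v = compress(embT, model)
    return expit(u @ v.T)


def pair_target_matrix(pa: PairwiseAlignment, L1: int, L2: int) -> np.ndarray:
    """Binary (L1, L2) supervision matrix: 1 at each aligned (i, j)."""
    t = np.zeros((L1, L2))
    for i, j in pa.pairs:
        if not (0 <= i < L1 and 0 <= j < L2):
            raise ValueError(f"aligned pair ({i}, {j}) out of range ({L1}, {L2})")
        t[i, j] = 1.0
    return t


def bce_loss(A: np.ndarray, target: np.ndarray, pos_weight: float = 1.0) -> float:
    """Mean binary cross entropy with reweighted positives.

    Scores are clamped to [1e-7, 1 - 1e-7] before the logs so exact 0/1
    predictions stay finite.
    """
    A = np.asarray(A, dtype=float)
    target = np.asarray(target, dtype=float)
    if A.shape != target.shape:
        raise ValueError("score/target shape mismatch")
    A = np.clip(A, CLAMP, 1.0 - CLAMP)
    loss = -(pos_weight * target * np.log(A) + (1.0 - target) * np.log(1.0 - A))
    return float(loss.mean())


def _default_pos_weight(target: np.ndarray) -> float:
    pos = target.sum()
    if pos == 0:
        return 1.0
    return float((target.size - pos) / pos)


def pretrain_scoring_model(
    training_pairs,
    r: int,
    epochs: int = 30,
    learning_rate: float = 1e-3,
    seed: int = 0,
    pos_weight: float | None = None,
):
    """Fit R by Adam on the residue-pair classification loss.

    ``training_pairs`` is a list of ``(embS, embT, PairwiseAlignment)``
    with raw d-dimensional embeddings; each pair's score matrix is one
    optimization step.  Positives are reweighted by the per-pair
    negative/positive ratio unless ``pos_weight`` is given.  Returns
    ``(ScoringModel, per-epoch mean loss trace)``; ``epochs=0`` returns
    the seeded random initialization untouched.
    """
    if not training_pairs:
        raise ValueError("need at least one training pair")
    d = np.asarray(training_pairs[0][0]).shape[1]
    for embS, embT, _ in training_pairs:
        if embS.shape[1] != d or embT.shape[1] != d:
            raise ValueError("all embeddings must share dimension d")
    model = ScoringModel.random_init(d, r, seed)
    targets = [
        pair_target_matrix(pa, embS.shape[0], embT.shape[0])
        for embS, embT, pa in training_pairs
    ]
    weights = [
        pos_weight if pos_weight is not None else _default_pos_weight(t)
        for t in targets
    ]
    opt = Adam({"R": model.R}, learning_rate)
    trace = []
    for _ in range(epochs):
        losses = []
        for (embS, embT, _), t, w in zip(training_pairs, targets, weights):
            u = embS @ model.R
            v = embT @ model.R
            A = expit(u @ v.T)
            losses.append(bce_loss(A, t, w))
            # d(mean BCE)/dZ with Z the bilinear logits
            dZ = (w * t * (A - 1.0) + (1.0 - t) * A) / t.size
            gR = embS.T @ dZ @ v + embT.T @ dZ.T @ u
            opt.step({"R": gR})
        trace.append(float(np.mean(losses)))
    return model, trace
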