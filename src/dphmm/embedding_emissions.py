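"""Embedding emissions at match states and the Gaussian mixture prior.

Match state ``M_i`` emits, jointly with an amino acid, a compressed
embedding vector under a diagonal Gaussian ``N(mu_i, sigma_i)``; a
temperature ``tau`` tempers the embedding density so the joint emission
log-probability is ``log P(S_j|q) + tau * log N(x_j; mu_i, sigma_i)``.
Insert and flank states use a single frozen background Gaussian
obtained by moment-matching the prior mixture.  A C-component diagonal
Gaussian mixture acts as a prior over the match means ``mu_i`` and is
the source of their initialization.

Variances are parameterized as ``softplus(raw) + VAR_FLOOR`` so they
stay positive under gradient ascent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

VAR_FLOOR = 1e-6
PRIOR_SCHEMA_VERSION = "dphmm-embedding-prior-1"
EMS_SCHEMA_VERSION = "dphmm-embedding-emissions-1"


def softplus(x):
    return np.logaddexp(x, 0.0)


def softplus_inv(y):
    # inverse of softplus for y > 0
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def gaussian_log_density(x, mean, var):
    """Log density of a diagonal multivariate normal.

    ``-1/2 * sum_k [log(2 pi var_k) + (x_k - mean_k)^2 / var_k]``;
    broadcasts over leading axes of ``x``.
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if x.shape[-1] != mean.shape[-1] or mean.shape[-1] != var.shape[-1]:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, mean {mean.shape}, var {var.shape}"
        )
    if np.any(var < VAR_FLOOR * 0.999):
        raise ValueError("variance below floor")
    q = (x - mean) ** 2 / var
    return -0.5 * (np.log(2.0 * np.pi * var) + q).sum(axis=-1)


def joint_emission_log_prob(aa_log_prob, emb_log_density, tau):
    """Tempered joint emission: ``log P(S_j|q) + tau * log P(x_j|q)``."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return aa_log_prob + tau * emb_log_density


@dataclass
class EmbeddingPrior:
    """C-component diagonal Gaussian mixture over match-state means."""

    weights: np.ndarray  # (C,)
    means: np.ndarray  # (C, r)
    variances: np.ndarray  # (C, r)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("mixture variances must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @classmethod
    def standard(cls, r: int, C: int = 1) -> "EmbeddingPrior":
        """Unit-Gaussian fallback prior (used when nothing was fitted)."""
        return cls(np.full(C, 1.0 / C), np.zeros((C, r)), np.ones((C, r)))

    def component_log_densities(self, x) -> np.ndarray:
        """(n, C) log N(x; mu_c, sigma_c) for rows of ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = (x[:, None, :] - self.means[None, :, :]) ** 2 / self.variances[None, :, :]
        return -0.5 * (
            np.log(2.0 * np.pi * self.variances).sum(axis=1)[None, :] + d.sum(axis=2)
        )

    def log_density(self, x) -> np.ndarray:
        comp = self.component_log_densities(x) + np.log(self.weights)[None, :]
        return logsumexp(comp, axis=1)

    def moment_match(self):
        """Mean and total variance of the mixture (one Gaussian summary)."""
        m = self.weights @ self.means
        v = self.weights @ (self.variances + self.means**2) - m**2
        return m, np.maximum(v, VAR_FLOOR)

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n (component index, vector) samples from the mixture."""
        comps = rng.choice(self.n_components, size=n, p=self.weights)
        x = self.means[comps] + rng.standard_normal((n, self.dim)) * np.sqrt(
            self.variances[comps]
        )
        return comps, x

    def parameter_count(self) -> int:
        c, r = self.means.shape
        return c * r + c * r + c

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "schema": PRIOR_SCHEMA_VERSION,
                    "weights": self.weights.tolist(),
                    "means": self.means.tolist(),
                    "variances": self.variances.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EmbeddingPrior":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != PRIOR_SCHEMA_VERSION:
            raise ValueError(f"unsupported schema {payload.get('schema')!r}")
        return cls(
            np.asarray(payload["weights"]),
            np.asarray(payload["means"]),
            np.asarray(payload["variances"]),
        )


@dataclass
class EmbeddingEmissionSet:
    """Per-match-state diagonal Gaussians plus the frozen background.

    ``mu`` are the match means; variances are
    ``softplus(s_raw) + VAR_FLOOR``.  ``bg_mean``/``bg_var`` define the
    insert/flank background Gaussian, which is never trained.
    """

    mu: np.ndarray  # (L, r)
    s_raw: np.ndarray  # (L, r), unconstrained
    tau: float
    bg_mean: np.ndarray  # (r,)
    bg_var: np.ndarray  # (r,)

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    @property
    def var(self) -> np.ndarray:
        return softplus(self.s_raw) + VAR_FLOOR

    @property
    def r(self) -> int:
        return self.mu.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "schema": EMS_SCHEMA_VERSION,
                    "mu": self.mu.tolist(),
                    "s_raw": self.s_raw.tolist(),
                    "tau": self.tau,
                    "bg_mean": self.bg_mean.tolist(),
                    "bg_var": self.bg_var.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EmbeddingEmissionSet":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != EMS_SCHEMA_VERSION:
            raise ValueError(f"unsupported schema {payload.get('schema')!r}")
        return cls(
            np.asarray(payload["mu"]),
            np.asarray(payload["s_raw"]),
            float(payload["tau"]),
            np.asarray(payload["bg_mean"]),
            np.asarray(payload["bg_var"]),
        )


def embedding_emission_grid(ems: EmbeddingEmissionSet, compressed: np.ndarray) -> np.ndarray:
    """(L_M, L) grid of tempered match-state embedding log-densities.

    Entry ``(i, j) = tau * log N(x_j; mu_i, sigma_i)`` for the j-th row
    of ``compressed``.  This is the ``extra_emission`` hook of the core
    forward/Viterbi algorithms; the companion background term for
    insert/flank states comes from :func:`background_log_density`.
    """
    compressed = np.asarray(compressed, dtype=float)
    if compressed.ndim != 2 or compressed.shape[1] != ems.r:
        raise ValueError(
            f"compressed embeddings have shape {compressed.shape}, expected (*, {ems.r})"
        )
    var = ems.var
    # (L, T): broadcast states against positions
    diff = compressed[None, :, :] - ems.mu[:, None, :]
    logdet = np.log(2.0 * np.pi * var).sum(axis=1)
    dens = -0.5 * (logdet[:, None] + (diff**2 / var[:, None, :]).sum(axis=2))
    return ems.tau * dens


def background_log_density(ems: EmbeddingEmissionSet, compressed: np.ndarray) -> np.ndarray:
    """(L,) tempered background log-density for insert/flank states."""
    return ems.tau * gaussian_log_density(compressed, ems.bg_mean, ems.bg_var)


def prior_log_density(ems: EmbeddingEmissionSet, prior: EmbeddingPrior) -> float:
    """``sum_i log sum_c pi_c N(mu_i; mu_c, sigma_c)`` via log-sum-exp."""
    if ems.mu.shape[0] == 0:
        return 0.0
    return float(prior.log_density(ems.mu).sum())


def prior_grad_mu(ems: EmbeddingEmissionSet, prior: EmbeddingPrior) -> np.ndarray:
    """Gradient of :func:`prior_log_density` with respect to ``mu``."""
    comp = prior.component_log_densities(ems.mu) + np.log(prior.weights)[None, :]
    resp = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))  # (L, C)
    pull = (prior.means[None, :, :] - ems.mu[:, None, :]) / prior.variances[None, :, :]
    return np.einsum("lc,lcr->lr", resp, pull)


def fit_embedding_prior(column_embeddings, C: int, seed: int = 0) -> EmbeddingPrior:
    """EM-fit a C-component diagonal Gaussian mixture to residue embeddings.

    ``column_embeddings`` is an (n, r) array or list of r-vectors,
    typically embeddings of residues from densely populated alignment
    columns.  Deterministic given ``seed``; degenerate inputs clamp the
    variance at the floor instead of failing.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    x = np.atleast_2d(np.asarray(column_embeddings, dtype=float))
    if len(x) < C:
        raise ValueError(f"need at least C={C} vectors, got {len(x)}")
    gm = GaussianMixture(
        n_components=C,
        covariance_type="diag",
        init_params="k-means++",
        max_iter=200,
        tol=1e-6,
        reg_covar=VAR_FLOOR,
        random_state=seed,
    )
    gm.fit(x)
    return EmbeddingPrior(
        gm.weights_, gm.means_, np.maximum(gm.covariances_, VAR_FLOOR)
    )


def init_emissions_from_prior(
    prior: EmbeddingPrior, L_M: int, seed: int = 0, tau: float = 1.0
) -> EmbeddingEmissionSet:
    """Draw match means from the prior; variances copy the sampled component.

    The insert/flank background Gaussian moment-matches the prior
    mixture and is frozen thereafter.
    """
    rng = np.random.default_rng(seed)
    comps, mu = prior.sample(L_M, rng)
    var = np.maximum(prior.variances[comps], VAR_FLOOR * 2)
    bg_mean, bg_var = prior.moment_match()
    return EmbeddingEmissionSet(
        mu=mu,
        s_raw=softplus_inv(np.maximum(var - VAR_FLOOR, 1e-9)),
        tau=tau,
        bg_mean=bg_mean,
        bg_var=bg_var,
    )


def collect_column_embeddings(msa, cache, max_gap_fraction: float = 0.5) -> np.ndarray:
    """Embeddings of residues in densely populated alignment columns.

    A column qualifies when at most ``max_gap_fraction`` of its rows are
    gaps; the compressed embedding of every residue in a qualifying
    column is returned (stacked row-wise).
    """
    cols = msa.column_residue_indices()
    n = msa.n_rows
    out = []
    for col in cols:
        if len(col) >= (1.0 - max_gap_fraction) * n and len(col) > 0:
            for row, residx in col.items():
                out.append(cache.get(msa.identifiers[row])[residx])
    if not out:
        raise ValueError("no densely populated columns found")
    return np.asarray(out)
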