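"""Pluggable per-residue embedding providers and the compressed cache.

An embedder maps a protein sequence to an (L, d) matrix with one row
per residue; row ``j`` must be deterministic given the sequence and the
spec, and must depend on the local context of position ``j``.  Real
protein language models plug in through :func:`register_embedder`; the
package ships a deterministic synthetic embedder whose row for position
``j`` is a pseudo-random unit-variance vector keyed by the w-residue
window centered at ``j``, so identical contexts give identical vectors
and any context change moves the vector.

Compressed embeddings (``emb @ R``) are precomputed once for all input
sequences and cached in an HDF5 container with a JSON provenance
sidecar; a cache built under a different embedder spec or scoring model
is refused unless explicitly overwritten.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from .msa_io import Sequence
from .scoring_model import ScoringModel, compress

CACHE_SCHEMA_VERSION = "dphmm-cache-1"
_PAD = "^"


@dataclass(frozen=True)
class EmbedderSpec:
    """Identifies an embedder and its hyperparameters."""

    name: str = "synthetic"
    dim: int = 32
    window: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("context window must be odd and positive")


_REGISTRY: dict[str, callable] = {}


def register_embedder(name: str, fn) -> None:
    """Register ``fn(seq: Sequence, spec: EmbedderSpec) -> (L, d) array``."""
    _REGISTRY[name] = fn


_window_vectors: dict[tuple, np.ndarray] = {}


def _vector_for_window(window: str, spec: EmbedderSpec) -> np.ndarray:
    key = (spec.seed, spec.dim, window)
    v = _window_vectors.get(key)
    if v is None:
        digest = hashlib.blake2b(
            f"{spec.seed}|{spec.dim}|{window}".encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        v = rng.standard_normal(spec.dim)
        if len(_window_vectors) < 200_000:
            _window_vectors[key] = v
    return v


def _synthetic_embed(seq: Sequence, spec: EmbedderSpec) -> np.ndarray:
    half = spec.window // 2
    padded = _PAD * half + seq.residues + _PAD * half
    return np.stack(
        [
            _vector_for_window(padded[j : j + spec.window], spec)
            for j in range(len(seq))
        ]
    )


register_embedder("synthetic", _synthetic_embed)


def embed(seq: Sequence, spec: EmbedderSpec) -> np.ndarray:
    """(L, d) per-residue embedding matrix for ``seq``."""
    try:
        fn = _REGISTRY[spec.name]
    except KeyError:
        raise ValueError(
            f"unknown embedder {spec.name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    out = np.asarray(fn(seq, spec))
    if out.shape != (len(seq), spec.dim):
        raise ValueError(
            f"embedder {spec.name!r} returned shape {out.shape}, "
            f"expected {(len(seq), spec.dim)}"
        )
    return out


@dataclass
class EmbeddingCache:
    """Identifier -> (L, r) compressed embedding matrices, with provenance."""

    data: dict[str, np.ndarray]
    provenance: dict

    def get(self, identifier: str) -> np.ndarray:
        try:
            return self.data[identifier]
        except KeyError:
            raise KeyError(f"no cached embeddings for {identifier!r}") from None

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.data

    def __len__(self) -> int:
        return len(self.data)


def _provenance(spec: EmbedderSpec, model: ScoringModel) -> dict:
    return {
        "schema": CACHE_SCHEMA_VERSION,
        "embedder": asdict(spec),
        "scoring_hash": model.provenance_hash(),
    }


def precompute_compressed(
    seqs: list[Sequence],
    spec: EmbedderSpec,
    model: ScoringModel,
    cache_path: str | Path | None = None,
    overwrite: bool = False,
) -> EmbeddingCache:
    """Embed, compress and cache all sequences.

    With a ``cache_path``, an existing cache whose provenance matches is
    loaded instead of recomputed; a provenance mismatch raises unless
    ``overwrite=True``.  Without a path the cache is built in memory.
    """
    if model.d != spec.dim:
        raise ValueError(f"scoring model d={model.d} != embedder dim {spec.dim}")
    prov = _provenance(spec, model)
    if cache_path is not None:
        cache_path = Path(cache_path)
        sidecar = cache_path.with_suffix(cache_path.suffix + ".json")
        if cache_path.exists():
            if not sidecar.exists():
                raise ValueError(f"cache {cache_path} has no provenance sidecar")
            existing = json.loads(sidecar.read_text())
            if existing != prov:
                if not overwrite:
                    raise ValueError(
                        f"cache {cache_path} was built under different provenance; "
                        "pass overwrite=True to rebuild"
                    )
            else:
                cache = load_cache(cache_path)
                if all(s.identifier in cache for s in seqs):
                    return cache
    data = {
        s.identifier: compress(embed(s, spec), model) for s in seqs
    }
    cache = EmbeddingCache(data, prov)
    if cache_path is not None:
        save_cache(cache, cache_path)
    return cache


def save_cache(cache: EmbeddingCache, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for ident, arr in cache.data.items():
            f.create_dataset(ident, data=arr)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(cache.provenance))


def load_cache(path: str | Path) -> EmbeddingCache:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    data = {}
    with h5py.File(path, "r") as f:
        for ident in f:
            data[ident] = f[ident][()]
    return EmbeddingCache(data, provenance)
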