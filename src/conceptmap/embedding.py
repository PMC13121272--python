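"""Embedding backends, the persisted embedding store, and top-k ranking.

Prediction is *atomic* nearest-neighbour retrieval: every source and target
concept name is embedded once into a unit-norm vector, vectors live in a
store keyed by concept identity, and suggestions for a source are the k
targets with the highest cosine similarity.

The built-in :class:`LexicalHashEmbedder` represents a name by a hashed bag
of character n-grams passed through a trainable square projection ``W``
(identity at initialization).  ``W`` is exactly the parameter set the
contrastive trainer updates; transformer sentence-embedding backends can be
plugged in behind the same :class:`EmbeddingBackend` contract.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import sparse

from .models import SourceConcept, TargetConcept, Vocabulary

__all__ = [
    "EmbeddingBackend",
    "LexicalHashEmbedder",
    "EmbeddingStore",
    "SuggestionList",
    "cosine_similarity",
    "build_store",
    "predict_topk",
]


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract every embedding backend satisfies.

    ``embed`` must be deterministic for a fixed backend state, and equal
    normalized strings must embed identically.
    """

    dimension: int
    trainable: bool

    def embed(self, name: str) -> np.ndarray: ...

    def embed_batch(self, names: Sequence[str]) -> np.ndarray: ...

    def fingerprint(self) -> str: ...


def _l2_normalize_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    safe = np.where(norms == 0.0, 1.0, norms)
    return matrix / safe


class LexicalHashEmbedder:
    """Hashed character n-gram embedder with a trainable projection.

    Each whitespace token of the (already normalized) name is padded with
    word-boundary markers ``<`` and ``>`` and decomposed into character
    n-grams of length 2–4; n-gram counts are hashed into ``dimension``
    buckets, L2-normalized, and projected by ``W`` (``dimension`` x
    ``dimension``, identity at init).  The output is re-normalized to unit
    length; only the empty name yields the zero vector.

    Hash collisions are accepted as representation noise — at the default
    dimension of 1024 they perturb similarities slightly but systematically,
    the same way for every name.
    """

    trainable = True

    def __init__(
        self,
        dimension: int = 1024,
        ngram_range: tuple[int, int] = (2, 4),
        hash_seed: int = 0,
    ):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = int(dimension)
        self.ngram_range = (int(ngram_range[0]), int(ngram_range[1]))
        self.hash_seed = int(hash_seed)
        self.W = np.eye(self.dimension, dtype=np.float64)
        self.state_version = 0
        self._feature_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._key = self.hash_seed.to_bytes(8, "little", signed=True)

    # -- feature extraction -------------------------------------------------

    def _hash(self, gram: str) -> int:
        digest = hashlib.blake2b(
            gram.encode("utf-8"), digest_size=8, key=self._key
        ).digest()
        return int.from_bytes(digest, "little") % self.dimension

    def _features(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Hashed n-gram counts as (bucket indices, counts), cached per name."""
        cached = self._feature_cache.get(name)
        if cached is not None:
            return cached
        lo, hi = self.ngram_range
        counts: dict[int, float] = {}
        for token in name.split():
            padded = f"<{token}>"
            for n in range(lo, hi + 1):
                for i in range(len(padded) - n + 1):
                    idx = self._hash(padded[i : i + n])
                    counts[idx] = counts.get(idx, 0.0) + 1.0
        idx = np.fromiter(counts.keys(), dtype=np.intp, count=len(counts))
        val = np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
        order = np.argsort(idx)
        result = (idx[order], val[order])
        self._feature_cache[name] = result
        return result

    def feature_matrix(self, names: Sequence[str]) -> sparse.csr_matrix:
        """Sparse matrix of L2-normalized hashed n-gram count rows."""
        indptr = [0]
        indices: list[np.ndarray] = []
        data: list[np.ndarray] = []
        for name in names:
            idx, val = self._features(name)
            norm = np.linalg.norm(val)
            indices.append(idx)
            data.append(val / norm if norm > 0 else val)
            indptr.append(indptr[-1] + len(idx))
        return sparse.csr_matrix(
            (
                np.concatenate(data) if data else np.empty(0),
                np.concatenate(indices) if indices else np.empty(0, dtype=np.intp),
                np.asarray(indptr, dtype=np.intp),
            ),
            shape=(len(names), self.dimension),
        )

    # -- embedding ----------------------------------------------------------

    def embed_batch(self, names: Sequence[str]) -> np.ndarray:
        feats = self.feature_matrix(names)
        projected = feats @ self.W.T
        return _l2_normalize_rows(np.asarray(projected))

    def embed(self, name: str) -> np.ndarray:
        if name == "":
            warnings.warn("embedding an empty name yields the zero vector")
            return np.zeros(self.dimension)
        return self.embed_batch([name])[0]

    # -- state --------------------------------------------------------------

    def set_projection(self, W: np.ndarray) -> None:
        W = np.asarray(W, dtype=np.float64)
        if W.shape != (self.dimension, self.dimension):
            raise ValueError(f"projection must be {self.dimension}x{self.dimension}")
        self.W = W
        self.state_version += 1

    def get_state(self) -> dict:
        return {"W": self.W.copy(), "state_version": self.state_version}

    def set_state(self, state: dict) -> None:
        self.set_projection(state["W"])
        self.state_version = int(state["state_version"])

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(
            json.dumps(
                [
                    type(self).__name__,
                    self.dimension,
                    list(self.ngram_range),
                    self.hash_seed,
                    self.state_version,
                ]
            ).encode()
        )
        h.update(np.ascontiguousarray(self.W).tobytes())
        return h.hexdigest()


# -- similarity ---------------------------------------------------------------


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity clamped to [-1, 1]; 0 when either vector is zero."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


# -- store --------------------------------------------------------------------


@dataclass
class EmbeddingStore:
    """Persisted embeddings for one backend state.

    Vectors are grouped into a target block (in vocabulary order) and a
    source block (keyed by :attr:`SourceConcept.key`).  The fingerprint ties
    the store to the exact backend state that produced it; any state change
    invalidates the store.
    """

    fingerprint: str
    dimension: int
    target_ids: list[str]
    target_vectors: np.ndarray
    source_keys: list[str]
    source_vectors: np.ndarray
    _target_index: dict[str, int] = field(init=False, repr=False)
    _source_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._target_index = {t: i for i, t in enumerate(self.target_ids)}
        self._source_index = {s: i for i, s in enumerate(self.source_keys)}

    def __len__(self) -> int:
        return len(self.target_ids) + len(self.source_keys)

    def get(self, kind: str, identifier: str) -> np.ndarray:
        if kind == "target":
            return self.target_vectors[self._target_index[identifier]]
        if kind == "source":
            return self.source_vectors[self._source_index[identifier]]
        raise KeyError(f"unknown entry kind {kind!r}")

    @property
    def entries(self) -> dict[tuple[str, str], np.ndarray]:
        out: dict[tuple[str, str], np.ndarray] = {}
        for i, t in enumerate(self.target_ids):
            out[("target", t)] = self.target_vectors[i]
        for i, s in enumerate(self.source_keys):
            out[("source", s)] = self.source_vectors[i]
        return out

    def source_vector(self, source: SourceConcept) -> np.ndarray:
        return self.get("source", source.key)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "vectors.npz",
            target_vectors=self.target_vectors.astype(np.float32),
            source_vectors=self.source_vectors.astype(np.float32),
        )
        meta = {
            "fingerprint": self.fingerprint,
            "dimension": self.dimension,
            "target_ids": self.target_ids,
            "source_keys": self.source_keys,
        }
        (directory / "store.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingStore":
        directory = Path(directory)
        meta = json.loads((directory / "store.json").read_text())
        arrays = np.load(directory / "vectors.npz")
        return cls(
            fingerprint=meta["fingerprint"],
            dimension=meta["dimension"],
            target_ids=meta["target_ids"],
            target_vectors=arrays["target_vectors"].astype(np.float64),
            source_keys=meta["source_keys"],
            source_vectors=arrays["source_vectors"].astype(np.float64),
        )


def build_store(
    backend: EmbeddingBackend,
    vocabulary: Vocabulary,
    sources: Iterable[SourceConcept] = (),
) -> EmbeddingStore:
    """Embed every target and source concept in one pass.

    Names are embedded once per unique normalized string; concepts sharing a
    normalized name share a vector (they are lexically identical to the
    model).
    """
    sources = list(sources)
    names = [c.normalized_name for c in vocabulary] + [
        s.normalized_name for s in sources
    ]
    unique = sorted(set(names))
    vectors = backend.embed_batch(unique)
    index = {n: i for i, n in enumerate(unique)}
    n_t = len(vocabulary)
    target_vectors = np.array(
        [vectors[index[n]] for n in names[:n_t]]
    ).reshape(n_t, backend.dimension)
    source_vectors = np.array(
        [vectors[index[n]] for n in names[n_t:]]
    ).reshape(len(sources), backend.dimension)
    return EmbeddingStore(
        fingerprint=backend.fingerprint(),
        dimension=backend.dimension,
        target_ids=[c.concept_id for c in vocabulary],
        target_vectors=target_vectors,
        source_keys=[s.key for s in sources],
        source_vectors=source_vectors,
    )


# -- ranking ------------------------------------------------------------------


@dataclass
class SuggestionList:
    """Ranked mapping suggestions for one source concept."""

    source: SourceConcept
    candidates: list[tuple[TargetConcept, float]]
    k: int

    def __post_init__(self) -> None:
        sims = [s for _, s in self.candidates]
        if any(b > a + 1e-12 for a, b in zip(sims, sims[1:])):
            raise ValueError("candidate similarities must be non-increasing")
        ids = [t.concept_id for t, _ in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate targets in suggestion list")

    @property
    def top(self) -> tuple[TargetConcept, float]:
        return self.candidates[0]


def ranked_order(similarities: np.ndarray, concept_ids: Sequence[str]) -> np.ndarray:
    """Indices of targets by descending similarity, ties by concept_id asc."""
    ids = np.asarray(concept_ids)
    return np.lexsort((ids, -np.asarray(similarities)))


def predict_topk(
    store: EmbeddingStore,
    source: SourceConcept,
    vocabulary: Vocabulary,
    k: int = 5,
) -> SuggestionList:
    """The k vocabulary entries closest to the source by cosine similarity.

    Similarity ties are broken by ``concept_id`` ascending so rankings are
    reproducible.  Pass ``k = len(vocabulary)`` to obtain the full ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(vocabulary) == 0:
        raise ValueError("cannot rank against an empty vocabulary")
    svec = store.source_vector(source)
    sims = np.clip(store.target_vectors @ svec, -1.0, 1.0)
    if not np.any(svec):
        sims = np.zeros(len(vocabulary))
    order = ranked_order(sims, store.target_ids)
    k_eff = min(k, len(vocabulary))
    candidates = [
        (vocabulary.get(store.target_ids[i]), float(sims[i])) for i in order[:k_eff]
    ]
    return SuggestionList(source=source, candidates=candidates, k=k_eff)
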