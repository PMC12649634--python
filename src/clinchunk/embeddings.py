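"""Embedding backends and vector math for the chunkers and retriever.

The default backend (:class:`HashEmbedder`) hashes character 3-grams into a
fixed number of buckets with a salted FNV-1a hash and L2-normalizes the
count vector.  It is fully deterministic and offline: texts that share
vocabulary score high cosine similarity, texts with disjoint vocabulary
score near zero, which is all the threshold logic downstream needs.
External transformer backends can be registered through the same protocol
but are never required.

TF-IDF vectorization (used by the semantic cluster chunker) delegates to
scikit-learn's ``TfidfVectorizer`` with its default weighting — raw term
counts, smoothed idf ``ln((1+n)/(1+df)) + 1``, L2-normalized rows, no
stop-word removal — but with this package's tokenizer so that the term
definition is consistent everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .text import tokenize

__all__ = [
    "EmbeddingBackend",
    "HashEmbedder",
    "get_backend",
    "register_backend",
    "hash_embed",
    "cosine_similarity",
    "centroid",
    "TfidfModel",
    "fit_tfidf",
    "transform_tfidf",
]

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1
_SALT = b"clinchunk.v1:"


def _fnv1a(data: bytes) -> int:
    h = _FNV_OFFSET
    for byte in _SALT + data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


# bucket cache: (gram, dim) -> index.  Gram inventories are tiny in practice.
_BUCKET_CACHE: dict[tuple[str, int], int] = {}


def hash_embed(text: str, dim: int = 512) -> np.ndarray:
    """Character 3-gram hashing embedding, L2-normalized.

    Whitespace is collapsed and text lowercased before 3-grams are taken;
    texts shorter than 3 characters contribute themselves as a single gram.
    Empty text maps to the all-zero vector.
    """
    if dim < 16:
        raise ValueError(f"dim must be >= 16, got {dim}")
    vec = np.zeros(dim, dtype=np.float64)
    norm_text = " ".join(text.split()).lower()
    if not norm_text:
        return vec
    grams = (
        [norm_text[i : i + 3] for i in range(len(norm_text) - 2)]
        if len(norm_text) >= 3
        else [norm_text]
    )
    for gram in grams:
        key = (gram, dim)
        idx = _BUCKET_CACHE.get(key)
        if idx is None:
            idx = _fnv1a(gram.encode("utf-8")) % dim
            _BUCKET_CACHE[key] = idx
        vec[idx] += 1.0
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract every embedding backend satisfies."""

    name: str
    dim: int
    deterministic: bool

    def embed(self, text: str) -> np.ndarray: ...

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray: ...


@dataclass
class HashEmbedder:
    """Deterministic offline backend built on :func:`hash_embed`."""

    dim: int = 512
    name: str = "hash"
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.dim < 16:
            raise ValueError(f"dim must be >= 16, got {self.dim}")

    def embed(self, text: str) -> np.ndarray:
        return hash_embed(text, self.dim)

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        if not texts:
            return np.zeros((0, self.dim))
        return np.stack([self.embed(t) for t in texts])


_BACKEND_FACTORIES: dict[str, Callable[[int], EmbeddingBackend]] = {}


def register_backend(name: str, factory: Callable[[int], EmbeddingBackend]) -> None:
    """Register an external backend factory under ``external:<name>``."""
    _BACKEND_FACTORIES[name] = factory


def get_backend(spec: str = "hash", dim: int = 512) -> EmbeddingBackend:
    """Resolve a backend from a config key: ``hash`` or ``external:<name>``."""
    if spec == "hash":
        return HashEmbedder(dim=dim)
    if spec.startswith("external:"):
        name = spec.split(":", 1)[1]
        if name not in _BACKEND_FACTORIES:
            raise ValueError(f"unknown external backend {name!r}")
        return _BACKEND_FACTORIES[name](dim)
    raise ValueError(f"unknown embedding backend {spec!r}")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either is all-zero."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def centroid(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """L2-normalized arithmetic mean; an all-zero mean stays all-zero."""
    if len(vectors) == 0:
        raise ValueError("centroid of an empty vector list is undefined")
    mat = np.asarray(vectors, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError("all vectors must share a dimension")
    mean = mat.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm > 0:
        mean = mean / norm
    return mean


@dataclass
class TfidfModel:
    """Fitted TF-IDF weighting: vocabulary, smoothed idf and corpus size."""

    vocabulary: dict[str, int]
    idf: np.ndarray
    n_docs: int
    _vectorizer: TfidfVectorizer = field(repr=False)


def fit_tfidf(texts: Sequence[str]) -> TfidfModel:
    """Fit TF-IDF weights on a corpus of texts."""
    if not texts or all(not tokenize(t) for t in texts):
        raise ValueError("fit_tfidf requires at least one non-empty text")
    vectorizer = TfidfVectorizer(
        tokenizer=tokenize,
        preprocessor=lambda x: x,
        token_pattern=None,
        lowercase=False,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    vectorizer.fit(texts)
    return TfidfModel(
        vocabulary=dict(vectorizer.vocabulary_),
        idf=vectorizer.idf_.copy(),
        n_docs=len(texts),
        _vectorizer=vectorizer,
    )


def transform_tfidf(model: TfidfModel, texts: Sequence[str]) -> sp.csr_matrix:
    """Weight ``texts`` with a fitted model; unseen-only texts give zero rows."""
    return model._vectorizer.transform(texts)
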