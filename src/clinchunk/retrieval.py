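"""Exact cosine top-k retrieval over chunk embeddings, plus a BM25 baseline.

The index stores one L2-normalized vector per chunk (the indexed text is
``header\\nbody`` when a micro-header is present).  Search is exhaustive —
at desk scale an exact scan is both fast enough and testable against a
brute-force oracle; an approximate-nearest-neighbor backend could be
slotted in behind the same interface but is deliberately not implemented.

BM25 uses the non-negative Okapi idf variant
``idf(t) = ln((N - df + 0.5)/(df + 0.5) + 1)`` with the usual saturation
and length normalization, reported separately from dense retrieval (never
fused).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chunkers import Chunk, ChunkSet
from .embeddings import EmbeddingBackend

__all__ = [
    "VectorIndex",
    "RetrievalResult",
    "build_index",
    "query_top_k",
    "bm25_scores",
    "bm25_top_k",
]


@dataclass
class VectorIndex:
    chunk_ids: list[str]
    matrix: np.ndarray  # (n_chunks, dim), rows unit-norm or all-zero
    backend_name: str
    dim: int

    def __len__(self) -> int:
        return len(self.chunk_ids)

    def vector(self, chunk_id: str) -> np.ndarray:
        return self.matrix[self.chunk_ids.index(chunk_id)]


@dataclass
class RetrievalResult:
    query_id: str
    ranked: list[tuple[str, float]]  # (chunk_id, score), scores non-increasing

    @property
    def chunk_ids(self) -> list[str]:
        return [cid for cid, _ in self.ranked]


def build_index(chunks: ChunkSet | Sequence[Chunk], backend: EmbeddingBackend) -> VectorIndex:
    """Embed every chunk's indexed text (header + body) into a flat index."""
    chunk_list = list(chunks)
    if not chunk_list:
        raise ValueError("cannot build an index from an empty chunk set")
    matrix = backend.embed_batch([c.indexed_text for c in chunk_list])
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    np.divide(matrix, norms, out=matrix, where=norms > 0)
    return VectorIndex(
        chunk_ids=[c.chunk_id for c in chunk_list],
        matrix=matrix,
        backend_name=backend.name,
        dim=backend.dim,
    )


def query_top_k(
    index: VectorIndex,
    query: str,
    k: int = 5,
    backend: EmbeddingBackend | None = None,
    query_id: str = "q",
) -> RetrievalResult:
    """Exact cosine scores against all entries; ties broken by chunk_id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if backend is None:
        raise ValueError("an embedding backend is required")
    if backend.name != index.backend_name or backend.dim != index.dim:
        raise ValueError(
            f"backend mismatch: index built with {index.backend_name}/{index.dim}, "
            f"queried with {backend.name}/{backend.dim}"
        )
    qvec = backend.embed(query)
    qnorm = np.linalg.norm(qvec)
    if qnorm > 0:
        qvec = qvec / qnorm
    scores = index.matrix @ qvec
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], index.chunk_ids[i]))
    ranked = [(index.chunk_ids[i], float(scores[i])) for i in order[:k]]
    return RetrievalResult(query_id=query_id, ranked=ranked)


def bm25_scores(
    corpus: Sequence[Sequence[str]],
    query: Sequence[str],
    k1: float = 1.2,
    b: float = 0.75,
) -> list[float]:
    """Okapi BM25 scores of every corpus document for one query."""
    if not corpus:
        raise ValueError("BM25 requires a non-empty corpus")
    n_docs = len(corpus)
    lengths = [len(d) for d in corpus]
    avglen = sum(lengths) / n_docs if sum(lengths) else 1.0
    df: dict[str, int] = {}
    for doc in corpus:
        for term in set(doc):
            df[term] = df.get(term, 0) + 1
    scores = [0.0] * n_docs
    for term in set(query):
        d_f = df.get(term)
        if not d_f:
            continue
        idf = math.log((n_docs - d_f + 0.5) / (d_f + 0.5) + 1.0)
        for i, doc in enumerate(corpus):
            tf = doc.count(term)
            if tf == 0:
                continue
            denom = tf + k1 * (1.0 - b + b * lengths[i] / avglen)
            scores[i] += idf * tf * (k1 + 1.0) / denom
    return scores


def bm25_top_k(
    chunks: ChunkSet | Sequence[Chunk],
    query_tokens: Sequence[str],
    k: int = 5,
    k1: float = 1.2,
    b: float = 0.75,
    tokenizer=None,
    query_id: str = "q",
) -> RetrievalResult:
    """Rank chunks lexically with BM25 over their indexed text."""
    from .text import tokenize as _tok

    tok = tokenizer or _tok
    chunk_list = list(chunks)
    if not chunk_list:
        raise ValueError("cannot rank an empty chunk set")
    corpus = [tok(c.indexed_text) for c in chunk_list]
    scores = bm25_scores(corpus, list(query_tokens), k1=k1, b=b)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], chunk_list[i].chunk_id))
    ranked = [(chunk_list[i].chunk_id, float(scores[i])) for i in order[:k]]
    return RetrievalResult(query_id=query_id, ranked=ranked)
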