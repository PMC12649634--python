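"""The four segmentation strategies plus the fixed-token-window baseline.

Strategies
----------
``recursive_char``
    Paragraph → sentence → subordinate-punctuation → raw-character splitting,
    greedily merged up to a character cap, with a duplicated overlap prefix
    between consecutive chunks (the classic recursive character splitter).
``fixed_token``
    Sliding token windows (250/400/600 tokens in the reference
    configuration) with a fixed token overlap.
``semantic_cluster``
    Sentence-level TF-IDF + k-means; each cluster, concatenated in original
    order, becomes one chunk.
``proposition``
    Atomic assertions extracted per sentence (rule-based by default, an LLM
    extractor can be plugged in), greedily grouped under a word cap with a
    centroid-relatedness gate.
``adaptive``
    Similarity-threshold boundary detection over sentence embeddings with
    dual (last-sentence OR span-centroid) continuity, a word cap and
    minimum span, linker-aware boundary repair, and heuristic micro-headers.

Every chunk records character-span provenance; spans duplicated by overlap
are kept separate from the non-overlapping provenance so that coverage can
be audited exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._wordlists import STOPWORDS, VERB_CUES
from .embeddings import EmbeddingBackend, centroid, cosine_similarity, fit_tfidf, transform_tfidf
from .text import (
    Document,
    Sentence,
    count_words,
    segment_sentences,
    split_paragraphs,
    token_spans,
    tokenize,
)

__all__ = [
    "Chunk",
    "ChunkSet",
    "Proposition",
    "DEFAULT_LINKERS",
    "recursive_char_chunk",
    "fixed_token_window_chunk",
    "semantic_cluster_chunk",
    "extract_propositions",
    "rule_based_extractor",
    "proposition_chunk",
    "proposition_chunk_document",
    "adaptive_chunk",
    "generate_micro_header",
    "write_jsonl",
    "read_jsonl",
]

#: Subordinating tokens that signal a sentence continues the previous
#: instruction (directive/timing/exception units).
DEFAULT_LINKERS = frozenset({"for", "until", "unless", "after", "within"})

HEADER_FALLBACK = "no header available"


@dataclass(frozen=True)
class Chunk:
    """One retrieval unit produced by a segmentation strategy."""

    chunk_id: str
    doc_id: str
    strategy: str
    body: str
    word_count: int
    sentence_indices: tuple[int, ...] = ()
    char_spans: tuple[tuple[int, int], ...] = ()
    overlap_char_spans: tuple[tuple[int, int], ...] = ()
    overlap_sentence_indices: tuple[int, ...] = ()
    header: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.body:
            raise ValueError("chunk body must be non-empty")

    @property
    def indexed_text(self) -> str:
        """Text seen by the retriever: header prepended when present."""
        return f"{self.header}\n{self.body}" if self.header else self.body

    def to_dict(self) -> dict:
        return {
            "chunk_id": self.chunk_id,
            "doc_id": self.doc_id,
            "strategy": self.strategy,
            "sentence_indices": list(self.sentence_indices),
            "char_spans": [list(s) for s in self.char_spans],
            "overlap_char_spans": [list(s) for s in self.overlap_char_spans],
            "overlap_sentence_indices": list(self.overlap_sentence_indices),
            "header": self.header,
            "body": self.body,
            "word_count": self.word_count,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Chunk":
        return cls(
            chunk_id=d["chunk_id"],
            doc_id=d["doc_id"],
            strategy=d["strategy"],
            body=d["body"],
            word_count=d["word_count"],
            sentence_indices=tuple(d["sentence_indices"]),
            char_spans=tuple(tuple(s) for s in d["char_spans"]),
            overlap_char_spans=tuple(tuple(s) for s in d["overlap_char_spans"]),
            overlap_sentence_indices=tuple(d["overlap_sentence_indices"]),
            header=d["header"],
            flags=tuple(d["flags"]),
        )


@dataclass
class ChunkSet:
    """Ordered chunks from one document/strategy plus every parameter used."""

    doc_id: str
    strategy: str
    chunks: list[Chunk]
    params: dict

    def __iter__(self):
        return iter(self.chunks)

    def __len__(self) -> int:
        return len(self.chunks)


def _chunk_id(doc_id: str, strategy: str, i: int) -> str:
    return f"{doc_id}:{strategy}:{i:04d}"


def write_jsonl(chunk_set: ChunkSet) -> str:
    """Serialize a ChunkSet to JSON Lines (metadata line first)."""
    meta = {
        "doc_id": chunk_set.doc_id,
        "strategy": chunk_set.strategy,
        "params": chunk_set.params,
    }
    lines = [json.dumps({"_meta": meta}, sort_keys=True, ensure_ascii=False)]
    lines.extend(
        json.dumps(c.to_dict(), sort_keys=True, ensure_ascii=False) for c in chunk_set.chunks
    )
    return "\n".join(lines) + "\n"


def read_jsonl(text: str) -> ChunkSet:
    """Inverse of :func:`write_jsonl`; the round-trip is bit-exact."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty chunk file")
    meta = json.loads(lines[0])["_meta"]
    chunks = [Chunk.from_dict(json.loads(ln)) for ln in lines[1:]]
    return ChunkSet(meta["doc_id"], meta["strategy"], chunks, meta["params"])


# ---------------------------------------------------------------------------
# Recursive character chunking
# ---------------------------------------------------------------------------

_SUBORDINATE = re.compile(r"[,;]")


def _recursive_units(doc: Document, max_chars: int) -> list[tuple[int, int]]:
    """Split hierarchy paragraph → sentence → punctuation → raw characters."""
    units: list[tuple[int, int]] = []
    for para in split_paragraphs(doc):
        if para.char_end - para.char_start <= max_chars:
            units.append((para.char_start, para.char_end))
            continue
        for sent in segment_sentences(para.text):
            s = para.char_start + sent.char_start
            e = para.char_start + sent.char_end
            if e - s <= max_chars:
                units.append((s, e))
                continue
            units.extend(_punct_units(doc.text, s, e, max_chars))
    return units


def _punct_units(text: str, s: int, e: int, max_chars: int) -> list[tuple[int, int]]:
    cuts = [s] + [s + m.end() for m in _SUBORDINATE.finditer(text[s:e])] + [e]
    out: list[tuple[int, int]] = []
    for a, b in zip(cuts, cuts[1:]):
        seg = text[a:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        a2, b2 = a + lead, b - trail
        if a2 >= b2:
            continue
        if b2 - a2 <= max_chars:
            out.append((a2, b2))
        else:  # raw character fallback
            out.extend(
                (a2 + i, min(a2 + i + max_chars, b2)) for i in range(0, b2 - a2, max_chars)
            )
    return out


def recursive_char_chunk(
    doc: Document, max_chars: int = 1000, overlap_chars: int = 100
) -> ChunkSet:
    """Recursive character splitting with greedy merge and overlap prefix.

    Adjacent units are merged while the chunk body (including any overlap
    prefix) stays within ``max_chars``.  Each chunk after the first starts
    with the trailing ``<= overlap_chars`` of the previous chunk, snapped to
    a unit boundary when one lies inside the overlap window.
    """
    if not 0 <= overlap_chars < max_chars:
        raise ValueError("require 0 <= overlap_chars < max_chars")
    params = {"max_chars": max_chars, "overlap_chars": overlap_chars}
    units = _recursive_units(doc, max_chars)
    chunks: list[Chunk] = []
    cur: list[tuple[int, int]] = []
    prefix: tuple[int, int] | None = None  # duplicated span within prev chunk

    def finalize() -> None:
        nonlocal cur, prefix
        if not cur:
            return
        main_s, main_e = cur[0][0], cur[-1][1]
        body_s = prefix[0] if prefix is not None else main_s
        body = doc.text[body_s:main_e]
        i = len(chunks)
        chunks.append(
            Chunk(
                chunk_id=_chunk_id(doc.doc_id, "recursive_char", i),
                doc_id=doc.doc_id,
                strategy="recursive_char",
                body=body,
                word_count=count_words(body),
                char_spans=((main_s, main_e),),
                overlap_char_spans=(prefix,) if prefix is not None else (),
                flags=("overlap_prefix",) if prefix is not None else (),
            )
        )

    def shrink_prefix(u: tuple[int, int]) -> None:
        # keep the body (prefix start .. unit end) within the cap
        nonlocal prefix
        if prefix is not None and u[1] - prefix[0] > max_chars:
            new_start = max(prefix[0], u[1] - max_chars)
            prefix = None if new_start >= prefix[1] else (new_start, prefix[1])

    for u in units:
        if not cur:
            shrink_prefix(u)
            cur = [u]
            continue
        body_s = prefix[0] if prefix is not None else cur[0][0]
        if u[1] - body_s <= max_chars:
            cur.append(u)
        else:
            prev_units = cur
            finalize()
            prefix = _overlap_span(prev_units, overlap_chars)
            shrink_prefix(u)
            cur = [u]
    finalize()
    return ChunkSet(doc.doc_id, "recursive_char", chunks, params)


def _overlap_span(
    prev_units: list[tuple[int, int]], overlap_chars: int
) -> tuple[int, int] | None:
    if overlap_chars == 0 or not prev_units:
        return None
    end = prev_units[-1][1]
    window_start = end - overlap_chars
    boundaries = [s for s, _ in prev_units if window_start <= s < end]
    if boundaries:
        return (min(boundaries), end)
    return (max(window_start, prev_units[0][0]), end)


# ---------------------------------------------------------------------------
# Fixed token windows
# ---------------------------------------------------------------------------


def fixed_token_window_chunk(doc: Document, window: int, overlap: int = 50) -> ChunkSet:
    """Cut the token stream into fixed windows with a duplicated overlap."""
    if window < 1 or not 0 <= overlap < window:
        raise ValueError("require window >= 1 and 0 <= overlap < window")
    params = {"window": window, "overlap": overlap}
    spans = token_spans(doc.text)
    n = len(spans)
    chunks: list[Chunk] = []
    stride = window - overlap
    s = 0
    while s < n:
        e = min(s + window, n)
        body_s, body_e = spans[s][0], spans[e - 1][1]
        ns = s if not chunks else s + overlap  # non-overlap token start
        body = doc.text[body_s:body_e]
        chunks.append(
            Chunk(
                chunk_id=_chunk_id(doc.doc_id, "fixed_token", len(chunks)),
                doc_id=doc.doc_id,
                strategy="fixed_token",
                body=body,
                word_count=count_words(body),
                char_spans=((spans[ns][0], body_e),),
                overlap_char_spans=((body_s, spans[s + overlap - 1][1]),) if ns > s else (),
                flags=("overlap_prefix",) if ns > s else (),
            )
        )
        if e >= n:
            break
        s += stride
    return ChunkSet(doc.doc_id, "fixed_token", chunks, params)


# ---------------------------------------------------------------------------
# Semantic cluster chunking
# ---------------------------------------------------------------------------


def semantic_cluster_chunk(doc: Document, k: int = 6, seed: int = 42) -> ChunkSet:
    """TF-IDF sentence vectors + k-means; one chunk per cluster.

    ``k`` is clamped to the sentence count.  Sentences in one cluster are
    concatenated in original document order; chunks are ordered by their
    smallest sentence index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = {"k": k, "seed": seed}
    sentences = segment_sentences(doc.text)
    n = len(sentences)
    if n == 0:
        return ChunkSet(doc.doc_id, "semantic_cluster", [], params)
    k_eff = min(k, n)
    params["k_effective"] = k_eff
    if k_eff == n:
        labels = np.arange(n)
    else:
        model = fit_tfidf([s.text for s in sentences])
        rows = transform_tfidf(model, [s.text for s in sentences])
        km = KMeans(n_clusters=k_eff, random_state=seed, n_init=10, init="k-means++")
        labels = km.fit_predict(rows)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    ordered = sorted((g for g in groups.values() if g), key=lambda g: g[0])
    chunks: list[Chunk] = []
    for g in ordered:
        body = " ".join(sentences[i].text for i in g)
        chunks.append(
            Chunk(
                chunk_id=_chunk_id(doc.doc_id, "semantic_cluster", len(chunks)),
                doc_id=doc.doc_id,
                strategy="semantic_cluster",
                body=body,
                word_count=count_words(body),
                sentence_indices=tuple(g),
                char_spans=tuple((sentences[i].char_start, sentences[i].char_end) for i in g),
            )
        )
    return ChunkSet(doc.doc_id, "semantic_cluster", chunks, params)


# ---------------------------------------------------------------------------
# Proposition chunking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Proposition:
    """An atomic assertion extracted from one sentence."""

    source_sentence_index: int
    text: str
    word_count: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("proposition text must be non-empty")
        if self.word_count == 0:
            object.__setattr__(self, "word_count", count_words(self.text))


_CONJ = re.compile(r",\s+(and|but|or)\b", re.IGNORECASE)


def _has_verb_cue(text: str) -> bool:
    for tok in tokenize(text):
        if tok in VERB_CUES:
            return True
        if len(tok) >= 4 and tok.endswith(("ed", "ing")):
            return True
        if len(tok) > 3 and tok.endswith("s"):
            return True
    return False


def rule_based_extractor(text: str) -> list[str]:
    """Split a sentence into atomic assertions.

    Splits at semicolons, and at ", and" / ", but" / ", or" when both sides
    carry a finite-verb cue.  A deterministic stand-in for an LLM extractor.
    """
    pieces: list[str] = []
    for part in text.split(";"):
        part = part.strip()
        if part:
            pieces.extend(_split_conjunction(part))
    return pieces


def _split_conjunction(part: str) -> list[str]:
    for m in _CONJ.finditer(part):
        left = part[: m.start()].strip().rstrip(",")
        right = part[m.start(1) :].strip()
        if left and right and _has_verb_cue(left) and _has_verb_cue(right):
            return [left] + _split_conjunction(right)
    return [part]


def extract_propositions(
    sentence: Sentence | str,
    extractor: Callable[[str], list[str]] | None = None,
) -> list[Proposition]:
    """Extract the distinct propositions contained in one sentence."""
    if isinstance(sentence, str):
        text, idx = sentence, 0
    else:
        text, idx = sentence.text, sentence.index
    if not text.strip():
        return []
    extractor = extractor or rule_based_extractor
    props = [p.strip() for p in extractor(text)]
    return [Proposition(idx, p) for p in props if p]


def proposition_chunk(
    props: Sequence[Proposition],
    backend: EmbeddingBackend,
    max_words: int = 500,
    relatedness_threshold: float = 0.5,
    doc_id: str = "doc",
    sentences: Sequence[Sentence] | None = None,
) -> ChunkSet:
    """Greedy left-to-right grouping of propositions into chunks.

    A new chunk starts when adding the next proposition would exceed
    ``max_words``, or when its embedding is less related than
    ``relatedness_threshold`` to the centroid of the current chunk's
    proposition embeddings.  A single proposition longer than ``max_words``
    becomes its own oversize chunk.
    """
    if max_words < 1:
        raise ValueError("max_words must be >= 1")
    params = {
        "max_words": max_words,
        "relatedness_threshold": relatedness_threshold,
        "backend": backend.name,
        "oversize_chunks": [],
    }
    groups: list[tuple[list[Proposition], list[str]]] = []
    cur: list[Proposition] = []
    cur_vecs: list[np.ndarray] = []
    cur_words = 0
    for p in props:
        v = backend.embed(p.text)
        if p.word_count > max_words:
            if cur:
                groups.append((cur, []))
            groups.append(([p], ["oversize_proposition"]))
            cur, cur_vecs, cur_words = [], [], 0
            continue
        if cur and (
            cur_words + p.word_count > max_words
            or cosine_similarity(v, centroid(cur_vecs)) < relatedness_threshold
        ):
            groups.append((cur, []))
            cur, cur_vecs, cur_words = [], [], 0
        cur.append(p)
        cur_vecs.append(v)
        cur_words += p.word_count
    if cur:
        groups.append((cur, []))

    chunks: list[Chunk] = []
    claimed: set[int] = set()
    sent_by_idx = {s.index: s for s in sentences} if sentences else {}
    for gi, (group, flags) in enumerate(groups):
        body = " ".join(p.text for p in group)
        src = sorted({p.source_sentence_index for p in group})
        own = [i for i in src if i not in claimed]
        shared = [i for i in src if i in claimed]
        claimed.update(own)
        char_spans = tuple(
            (sent_by_idx[i].char_start, sent_by_idx[i].char_end) for i in own if i in sent_by_idx
        )
        overlap_spans = tuple(
            (sent_by_idx[i].char_start, sent_by_idx[i].char_end)
            for i in shared
            if i in sent_by_idx
        )
        all_flags = list(flags) + (["shared_sentence"] if shared else [])
        if "oversize_proposition" in flags:
            params["oversize_chunks"].append(gi)
        chunks.append(
            Chunk(
                chunk_id=_chunk_id(doc_id, "proposition", gi),
                doc_id=doc_id,
                strategy="proposition",
                body=body,
                word_count=count_words(body),
                sentence_indices=tuple(own),
                char_spans=char_spans,
                overlap_char_spans=overlap_spans,
                overlap_sentence_indices=tuple(shared),
                flags=tuple(all_flags),
            )
        )
    return ChunkSet(doc_id, "proposition", chunks, params)


def proposition_chunk_document(
    doc: Document,
    backend: EmbeddingBackend,
    extractor: Callable[[str], list[str]] | None = None,
    max_words: int = 500,
    relatedness_threshold: float = 0.5,
) -> ChunkSet:
    """Segment, extract propositions, and group them — the full strategy."""
    sentences = segment_sentences(doc.text)
    props: list[Proposition] = []
    for s in sentences:
        props.extend(extract_propositions(s, extractor))
    return proposition_chunk(
        props,
        backend,
        max_words=max_words,
        relatedness_threshold=relatedness_threshold,
        doc_id=doc.doc_id,
        sentences=sentences,
    )


# ---------------------------------------------------------------------------
# Adaptive chunking
# ---------------------------------------------------------------------------


def adaptive_chunk(
    doc: Document,
    backend: EmbeddingBackend,
    threshold: float = 0.80,
    max_words: int = 500,
    min_words: int = 60,
    overlap_token_cap: int = 30,
    linkers: frozenset[str] | set[str] = DEFAULT_LINKERS,
    combiner: str = "or",
    strict: bool = False,
    header_min_words: int = 5,
    header_max_words: int = 15,
) -> ChunkSet:
    """Similarity-threshold adaptive chunking with micro-headers.

    A sentence joins the active chunk iff its cosine similarity to the last
    sentence or to the span centroid meets ``threshold`` (``combiner``
    selects OR/AND; ``strict`` switches >= to >) and the word cap holds.
    Boundary repairs, in order: linker repair (a chunk-opening sentence
    whose first token is a linker is appended to the previous chunk when it
    fits, else the previous chunk's tail is duplicated as an overlap
    prefix), then minimum-span merge (short chunks merge into their
    predecessor; the first chunk merges into its successor).  Every final
    chunk gets a heuristic micro-header.
    """
    if not 0 < threshold <= 1:
        raise ValueError("require 0 < threshold <= 1")
    if not 0 < min_words < max_words:
        raise ValueError("require 0 < min_words < max_words")
    if overlap_token_cap < 0:
        raise ValueError("overlap_token_cap must be >= 0")
    if combiner not in {"or", "and"}:
        raise ValueError("combiner must be 'or' or 'and'")
    linkers = frozenset(w.lower() for w in linkers)
    params = {
        "threshold": threshold,
        "max_words": max_words,
        "min_words": min_words,
        "overlap_token_cap": overlap_token_cap,
        "linkers": sorted(linkers),
        "combiner": combiner,
        "strict": strict,
        "backend": backend.name,
    }
    sentences = segment_sentences(doc.text)
    n = len(sentences)
    if n == 0:
        params["pre_repair_boundaries"] = []
        params["pre_repair_chunk_count"] = 0
        return ChunkSet(doc.doc_id, "adaptive", [], params)
    vecs = backend.embed_batch([s.text for s in sentences])
    wc = [count_words(s.text) for s in sentences]

    def meets(sim: float) -> bool:
        return sim > threshold if strict else sim >= threshold

    # --- pure single pass (pre-repair boundaries) ---
    groups: list[list[int]] = []
    active = [0]
    active_words = wc[0]
    for i in range(1, n):
        sim_last = cosine_similarity(vecs[i], vecs[active[-1]])
        sim_cent = cosine_similarity(vecs[i], centroid([vecs[j] for j in active]))
        if combiner == "or":
            ok = meets(sim_last) or meets(sim_cent)
        else:
            ok = meets(sim_last) and meets(sim_cent)
        if ok and active_words + wc[i] <= max_words:
            active.append(i)
            active_words += wc[i]
        else:
            groups.append(active)
            active = [i]
            active_words = wc[i]
    groups.append(active)
    params["pre_repair_boundaries"] = [g[0] for g in groups]
    params["pre_repair_chunk_count"] = len(groups)

    # --- repair 1: linker-aware boundary repair ---
    # each working chunk: dict(sents, ov_sents, ov_raw, flags)
    work = [{"sents": list(groups[0]), "ov_sents": [], "ov_raw": None, "flags": set()}]
    for g in groups[1:]:
        g = list(g)
        prev = work[-1]
        ov_sents: list[int] = []
        ov_raw: tuple[int, int] | None = None
        flags: set[str] = set()
        while g:
            toks = tokenize(sentences[g[0]].text)
            if not toks or toks[0] not in linkers:
                break
            if sum(wc[j] for j in prev["sents"]) + wc[g[0]] <= max_words:
                prev["sents"].append(g.pop(0))
                prev["flags"].add("linker_repair")
            else:
                ov_sents, ov_raw = _adaptive_overlap(
                    sentences, prev["sents"], overlap_token_cap
                )
                if ov_sents or ov_raw:
                    flags.add("linker_overlap")
                break
        if g:
            work.append({"sents": g, "ov_sents": ov_sents, "ov_raw": ov_raw, "flags": flags})

    # --- repair 2: minimum-span merge ---
    def words_of(c: dict) -> int:
        return sum(wc[j] for j in c["sents"])

    if len(work) > 1 and words_of(work[0]) < min_words:
        nxt = work[1]
        nxt["sents"] = work[0]["sents"] + nxt["sents"]
        nxt["ov_sents"], nxt["ov_raw"] = [], None  # contiguous after merge
        nxt["flags"] |= work[0]["flags"] | {"min_span_merge"}
        work = work[1:]
    i = 1
    while i < len(work):
        if words_of(work[i]) < min_words:
            prev = work[i - 1]
            prev["sents"] = prev["sents"] + work[i]["sents"]
            prev["flags"] |= work[i]["flags"] | {"min_span_merge"}
            del work[i]
        else:
            i += 1

    # --- finalize with micro-headers ---
    chunks: list[Chunk] = []
    for c in work:
        sents = c["sents"]
        main_s = sentences[sents[0]].char_start
        main_e = sentences[sents[-1]].char_end
        main_text = doc.text[main_s:main_e]
        if c["ov_sents"]:
            ov_s = sentences[c["ov_sents"][0]].char_start
            ov_e = sentences[c["ov_sents"][-1]].char_end
            overlap_spans: tuple[tuple[int, int], ...] = ((ov_s, ov_e),)
            body = doc.text[ov_s:main_e]
        elif c["ov_raw"] is not None:
            ov_s, ov_e = c["ov_raw"]
            overlap_spans = ((ov_s, ov_e),)
            body = doc.text[ov_s:main_e]
        else:
            overlap_spans = ()
            body = main_text
        fl = set(c["flags"])
        if count_words(main_text) > max_words:
            fl.add("over_max")
        chunks.append(
            Chunk(
                chunk_id=_chunk_id(doc.doc_id, "adaptive", len(chunks)),
                doc_id=doc.doc_id,
                strategy="adaptive",
                body=body,
                word_count=count_words(body),
                sentence_indices=tuple(sents),
                char_spans=((main_s, main_e),),
                overlap_char_spans=overlap_spans,
                overlap_sentence_indices=tuple(c["ov_sents"]),
                header=generate_micro_header(main_text, header_min_words, header_max_words),
                flags=tuple(sorted(fl)),
            )
        )
    return ChunkSet(doc.doc_id, "adaptive", chunks, params)


def _adaptive_overlap(
    sentences: Sequence[Sentence], prev_sents: list[int], cap: int
) -> tuple[list[int], tuple[int, int] | None]:
    """Trailing tokens of the previous chunk, whole sentences preferred."""
    if cap == 0:
        return [], None
    chosen: list[int] = []
    total = 0
    for j in reversed(prev_sents):
        ntok = len(tokenize(sentences[j].text))
        if total + ntok > cap:
            break
        chosen.insert(0, j)
        total += ntok
    if chosen:
        return chosen, None
    # last sentence alone exceeds the cap: duplicate its trailing `cap` tokens
    last = sentences[prev_sents[-1]]
    spans = token_spans(last.text)
    if not spans:
        return [], None
    tail = spans[-cap:] if len(spans) > cap else spans
    return [], (last.char_start + tail[0][0], last.char_end)


# ---------------------------------------------------------------------------
# Micro-headers
# ---------------------------------------------------------------------------


def generate_micro_header(body: str, min_words: int = 5, max_words: int = 15) -> str:
    """Heuristic noun-phrase-style title for a chunk body.

    Stop words are removed; contiguous 1–4-token content phrases are scored
    by ``frequency × length`` with deterministic tie-breaks (earliest
    occurrence, then lexicographic).  The top phrase is title-cased and
    padded with next-ranked distinct phrases up to ``min_words``, truncated
    at ``max_words``.  Bodies with no content tokens yield the exact
    fallback ``"no header available"``.
    """
    tokens = tokenize(body)
    runs: list[list[str]] = []
    cur: list[str] = []
    for tok in tokens:
        if tok in STOPWORDS:
            if cur:
                runs.append(cur)
                cur = []
        else:
            cur.append(tok)
    if cur:
        runs.append(cur)
    if not runs:
        return HEADER_FALLBACK
    counts: dict[tuple[str, ...], int] = {}
    first_seen: dict[tuple[str, ...], int] = {}
    pos = 0
    for run in runs:
        for i in range(len(run)):
            for L in range(1, min(4, len(run) - i) + 1):
                phrase = tuple(run[i : i + L])
                counts[phrase] = counts.get(phrase, 0) + 1
                first_seen.setdefault(phrase, pos + i)
        pos += len(run)
    ranked = sorted(
        counts,
        key=lambda p: (-counts[p] * len(p), first_seen[p], " ".join(p)),
    )
    header: list[str] = list(ranked[0])
    used = {ranked[0]}
    for phrase in ranked[1:]:
        if len(header) >= min_words:
            break
        if phrase in used:
            continue
        header.extend(phrase)
        used.add(phrase)
    header = header[:max_words]
    return " ".join(w.capitalize() if w.isalpha() else w for w in header)
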