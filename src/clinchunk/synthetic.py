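"""Seeded generator of clinical-style synthetic corpora with ground truth.

The generator emulates the *statistical* structure of clinical aftercare
prose that the chunkers and evaluator assume — topical sections with
distinct vocabularies, instruction units (directive + timing + exception
sentences using linker words), and per-query relevant spans — without any
attempt at medically meaningful content.  Topic vocabularies are disjoint
pseudo-words, so under the hash embedding backend vocabulary overlap maps
directly onto cosine similarity: within-section sentences score high,
cross-section sentences score near zero, giving controllable ground-truth
structure.  Queries mix section-specific words with shared "lay" words to
emulate the query–document phrasing gap.

Every artifact is a pure function of its spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chunkers import Chunk, ChunkSet
from .evaluation import LikertRating, RelevanceJudgment
from .text import Document, Sentence, segment_sentences

__all__ = [
    "CorpusSpec",
    "GroundTruth",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_queries",
    "label_chunks",
    "simulate_ratings",
]

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"
_SHARED_VOCAB_SIZE = 60


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    The corpus is hierarchical, the way aftercare references are organized:
    a handful of *major divisions* (every ``super_group_size`` consecutive
    sections share a ``core_size``-word core vocabulary) each containing
    several topical sections with their own vocabularies.  Every body
    sentence of a section repeats a fixed *theme stem* — the division core
    followed by ``theme_size`` section words — the way clinical prose keeps
    naming its subject.  Under the hash embedding backend this anchors
    within-section similarity above the adaptive join threshold, keeps
    sibling sections (same division) moderately confusable, and keeps
    unrelated sections near zero.
    """

    n_sections: int = 24
    sentences_per_section: tuple[int, int] = (12, 18)
    topic_vocab_size: int = 12
    theme_size: int = 5
    super_group_size: int = 4
    core_size: int = 3
    shared_vocab_fraction: float = 0.25
    instruction_unit: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        lo, hi = self.sentences_per_section
        if not 1 <= lo <= hi:
            raise ValueError("invalid sentences_per_section range")
        if self.super_group_size < 1 or self.core_size < 0:
            raise ValueError("invalid division structure")
        own = self.topic_vocab_size - self.core_size
        if own < 2 or not 1 <= self.theme_size <= own:
            raise ValueError(
                "require core_size + theme_size <= topic_vocab_size with "
                ">= 2 section-own words"
            )
        if not 0 <= self.shared_vocab_fraction < 1:
            raise ValueError("shared_vocab_fraction must lie in [0, 1)")

    @property
    def n_divisions(self) -> int:
        return (self.n_sections + self.super_group_size - 1) // self.super_group_size


@dataclass(frozen=True)
class GroundTruth:
    """query_id -> (target section, half-open sentence-index span)."""

    targets: Mapping[str, tuple[int, tuple[int, int]]]

    def span(self, query_id: str) -> tuple[int, int]:
        return self.targets[query_id][1]


@dataclass
class SyntheticCorpus:
    document: Document
    sections: list[tuple[int, int]]  # half-open sentence-index ranges
    topic_vocabs: list[list[str]]
    shared_vocab: list[str]
    instruction_units: list[tuple[int, tuple[int, int]]]  # (section, sent range)
    spec: CorpusSpec
    sentences: list[Sentence] = field(default_factory=list)


def _make_words(rng: np.random.Generator, count: int) -> list[str]:
    """Unique 3-syllable pseudo-words (consonant-vowel structure)."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < count:
        w = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(3)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a sectioned document; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    own_size = spec.topic_vocab_size - spec.core_size
    n_words = (
        _SHARED_VOCAB_SIZE
        + spec.n_divisions * spec.core_size
        + spec.n_sections * own_size
    )
    all_words = _make_words(rng, n_words)
    shared = all_words[:_SHARED_VOCAB_SIZE]
    pos = _SHARED_VOCAB_SIZE
    cores: list[list[str]] = []
    for _ in range(spec.n_divisions):
        cores.append(all_words[pos : pos + spec.core_size])
        pos += spec.core_size
    topic_vocabs: list[list[str]] = []
    for i in range(spec.n_sections):
        own = all_words[pos : pos + own_size]
        pos += own_size
        # section vocabulary = division core + section-own words
        topic_vocabs.append(cores[i // spec.super_group_size] + own)

    def draw_words(section: int, n: int, shared_fraction: float) -> list[str]:
        out = []
        for _ in range(n):
            if rng.random() < shared_fraction:
                out.append(shared[rng.integers(len(shared))])
            else:
                vocab = topic_vocabs[section]
                out.append(vocab[rng.integers(len(vocab))])
        return out

    f = spec.shared_vocab_fraction
    # timing/exception qualifiers lean on generic vocabulary (the phrasing
    # of "call the office", "in the first days") rather than the topic stem
    qualifier_fraction = 0.5 if f > 0 else 0.0

    def body_sentence(sec: int) -> list[str]:
        # theme stem: division core then the section's own theme words,
        # always contiguous and in fixed order; surrounded by variable
        # words mixing section vocabulary with domain-common vocabulary
        stem = topic_vocabs[sec][: spec.core_size + spec.theme_size]
        lead = draw_words(sec, 1, f)
        tail = draw_words(sec, int(rng.integers(4, 9)), f)
        return lead + stem + tail

    lo, hi = spec.sentences_per_section
    paragraphs: list[str] = []
    sections: list[tuple[int, int]] = []
    units: list[tuple[int, tuple[int, int]]] = []
    sent_cursor = 0
    for sec in range(spec.n_sections):
        n_sent = int(rng.integers(lo, hi + 1))
        sent_words: list[list[str]] = [body_sentence(sec) for _ in range(n_sent)]
        if spec.instruction_unit and n_sent >= 5:
            # directive + timing + exception triple, mid-section; the two
            # qualifier sentences open with a linker and drop the theme stem
            p = int(rng.integers(1, n_sent - 3))
            timing_linker = ["after", "within"][int(rng.integers(2))]
            exception_linker = ["unless", "until"][int(rng.integers(2))]
            sent_words[p + 1] = [timing_linker] + draw_words(
                sec, int(rng.integers(8, 11)), qualifier_fraction
            )
            sent_words[p + 2] = [exception_linker] + draw_words(
                sec, int(rng.integers(8, 11)), qualifier_fraction
            )
            units.append((sec, (sent_cursor + p, sent_cursor + p + 3)))
        texts = [ws[0].capitalize() + " " + " ".join(ws[1:]) + "." for ws in sent_words]
        paragraphs.append(" ".join(texts))
        sections.append((sent_cursor, sent_cursor + n_sent))
        sent_cursor += n_sent

    doc = Document(doc_id=f"synthetic-{spec.seed}", text="\n\n".join(paragraphs))
    sentences = segment_sentences(doc.text)
    if len(sentences) != sent_cursor:  # pragma: no cover - construction guard
        raise AssertionError("generated sentence count does not match segmentation")
    return SyntheticCorpus(
        document=doc,
        sections=sections,
        topic_vocabs=topic_vocabs,
        shared_vocab=shared,
        instruction_units=units,
        spec=spec,
        sentences=sentences,
    )


def generate_queries(
    corpus: SyntheticCorpus,
    n_topic_words: int = 3,
    n_shared_words: int = 4,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """One query per section, phrased from that section's vocabulary.

    Queries mix ``n_topic_words`` section words with ``n_shared_words``
    shared words (the phrasing gap), shuffled.  The ground-truth span of a
    query is its section's sentence-index range.
    """
    rng = np.random.default_rng(corpus.spec.seed + 101)
    queries: list[tuple[str, str]] = []
    targets: dict[str, tuple[int, tuple[int, int]]] = {}
    for sec, span in enumerate(corpus.sections):
        vocab = corpus.topic_vocabs[sec]
        words = list(rng.choice(vocab, size=min(n_topic_words, len(vocab)), replace=False))
        words += list(rng.choice(corpus.shared_vocab, size=n_shared_words, replace=False))
        rng.shuffle(words)
        qid = f"q{sec:03d}"
        queries.append((qid, " ".join(words)))
        targets[qid] = (sec, span)
    return queries, GroundTruth(targets=targets)


def _merged_intervals(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _chunk_sentence_ids(chunk: Chunk, sentences: Sequence[Sentence]) -> set[int]:
    """Sentences a chunk contains through its non-overlap provenance."""
    if chunk.sentence_indices:
        return set(chunk.sentence_indices)
    intervals = _merged_intervals(chunk.char_spans)
    out: set[int] = set()
    for s in sentences:
        if any(a <= s.char_start and s.char_end <= b for a, b in intervals):
            out.add(s.index)
    return out


def label_chunks(
    chunks: ChunkSet,
    gt: GroundTruth,
    sentences: Sequence[Sentence],
    min_fraction: float = 0.5,
) -> dict[str, RelevanceJudgment]:
    """Mechanical relevance rule operationalizing a topical-match judgment.

    A chunk is relevant to a query iff, through its non-overlap provenance,
    it *covers* the query's ground-truth span (contains at least
    ``min_fraction`` of the span's sentences) or is *about* it (at least
    ``min_fraction`` of the chunk's own sentences lie in the span).  A
    window that merely grazes a topic boundary with a stray sentence is
    noise, not topical evidence, and counts as a false positive when
    retrieved; likewise overlap duplicates confer no relevance.
    """
    contained = {c.chunk_id: _chunk_sentence_ids(c, sentences) for c in chunks}
    judgments: dict[str, RelevanceJudgment] = {}
    for qid, (_, (lo, hi)) in sorted(gt.targets.items()):
        span = set(range(lo, hi))
        rel = set()
        for cid, ids in contained.items():
            if not ids:
                continue
            hits = len(ids & span)
            if hits == 0:
                continue
            covers = hits >= min_fraction * len(span)
            about = hits >= min_fraction * len(ids)
            if covers or about:
                rel.add(cid)
        judgments[qid] = RelevanceJudgment(query_id=qid, relevant_ids=frozenset(rel))
    return judgments


def simulate_ratings(
    probabilities: Mapping[str, Sequence[float]],
    n_items: int,
    seed: int,
    dimension: str = "accuracy",
) -> list[LikertRating]:
    """Seeded categorical 3-point ratings per condition."""
    rng = np.random.default_rng(seed)
    out: list[LikertRating] = []
    for condition in sorted(probabilities):
        p = np.asarray(probabilities[condition], dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid score probabilities for {condition!r}")
        draws = rng.choice([1, 2, 3], size=n_items, p=p)
        out.extend(
            LikertRating(f"{condition}-{i:04d}", condition, dimension, int(s))
            for i, s in enumerate(draws)
        )
    return out
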