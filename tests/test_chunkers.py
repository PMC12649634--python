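"""Segmentation strategies: examples, caps, coverage, repairs, oracles."""

import itertools
import random

import numpy as np
import pytest

from clinchunk.chunkers import (
    HEADER_FALLBACK,
    adaptive_chunk,
    extract_propositions,
    fixed_token_window_chunk,
    generate_micro_header,
    proposition_chunk,
    proposition_chunk_document,
    read_jsonl,
    recursive_char_chunk,
    semantic_cluster_chunk,
    write_jsonl,
)
from clinchunk.embeddings import centroid, cosine_similarity, fit_tfidf, transform_tfidf
from clinchunk.pipeline import RunConfig, chunk_document
from clinchunk.text import Document, Sentence, count_words, segment_sentences, token_spans

STRATEGIES = ("recursive_char", "fixed_token", "semantic_cluster", "proposition", "adaptive")


def make_doc(paragraphs, doc_id="doc"):
    return Document(doc_id, "\n\n".join(paragraphs))


def topic_sentences(stem_words, n, tag):
    """Sentences sharing a fixed stem, high mutual hash-cosine."""
    return [
        f"{' '.join(stem_words)} {tag}{i} extra{i} note{i}.".capitalize()
        for i in range(n)
    ]


STEM_A = ["alpha", "bravo", "charlie", "delta", "echo", "foxtrot", "golf", "hotel", "india"]
STEM_B = ["zulu", "yankee", "xray", "whisky", "victor", "uniform", "tango", "sierra", "romeo"]


# ---------------------------------------------------------------------------
# recursive character chunking
# ---------------------------------------------------------------------------


class TestRecursiveChar:
    def test_under_cap_single_chunk(self):
        doc = make_doc(["word " * 99 + "word."])
        cs = recursive_char_chunk(doc)
        assert len(cs) == 1
        assert cs.chunks[0].body == doc.text
        assert cs.chunks[0].overlap_char_spans == ()

    def test_empty_document(self):
        assert len(recursive_char_chunk(Document("d", ""))) == 0

    def test_two_long_paragraphs_overlap_prefix(self):
        para = ("splint care is essential after surgery and swelling " * 13).strip()
        assert 650 <= len(para) <= 750
        doc = make_doc([para, para])
        cs = recursive_char_chunk(doc, max_chars=1000, overlap_chars=100)
        assert len(cs) == 2
        first, second = cs.chunks
        assert len(first.body) <= 1000 and len(second.body) <= 1000
        (ov,) = second.overlap_char_spans
        assert ov[1] - ov[0] <= 100
        assert second.body.startswith(doc.text[ov[0] : ov[1]])
        assert "overlap_prefix" in second.flags

    def test_cap_and_reconstruction(self, corpus_doc):
        cs = recursive_char_chunk(corpus_doc)
        assert all(len(c.body) <= 1000 for c in cs.chunks)
        # stripping the duplicated prefixes and concatenating reconstructs the
        # document from the first covered character onward
        start = cs.chunks[0].char_spans[0][0]
        rebuilt = cs.chunks[0].body
        for prev, cur in zip(cs.chunks, cs.chunks[1:]):
            rebuilt += corpus_doc.text[prev.char_spans[-1][1] : cur.char_spans[-1][1]]
        assert rebuilt == corpus_doc.text[start:]

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            recursive_char_chunk(Document("d", "x"), max_chars=100, overlap_chars=100)


# ---------------------------------------------------------------------------
# fixed token windows
# ---------------------------------------------------------------------------


class TestFixedToken:
    def test_exact_window_single_chunk(self):
        doc = Document("d", " ".join(f"t{i}" for i in range(250)))
        assert len(fixed_token_window_chunk(doc, 250)) == 1

    def test_stride_arithmetic(self):
        doc = Document("d", " ".join(f"t{i}" for i in range(300)))
        cs = fixed_token_window_chunk(doc, 250, 50)
        assert len(cs) == 2
        spans = token_spans(doc.text)
        first, second = cs.chunks
        assert first.body == doc.text[spans[0][0] : spans[249][1]]
        assert second.body == doc.text[spans[200][0] : spans[299][1]]
        # non-overlap provenance of window 2 starts at token 250
        assert second.char_spans[0][0] == spans[250][0]
        (ov,) = second.overlap_char_spans
        assert ov == (spans[200][0], spans[249][1])

    def test_empty_document(self):
        assert len(fixed_token_window_chunk(Document("d", ""), 250)) == 0

    def test_nonoverlap_spans_partition_tokens(self, corpus_doc):
        for window in (250, 400, 600):
            cs = fixed_token_window_chunk(corpus_doc, window)
            spans = token_spans(corpus_doc.text)
            covered = []
            for c in cs.chunks:
                (a, b) = c.char_spans[0]
                covered.extend(t for s, e, t in spans if a <= s and e <= b)
            assert covered == [t for _, _, t in spans]


# ---------------------------------------------------------------------------
# semantic cluster chunking
# ---------------------------------------------------------------------------


class TestSemanticCluster:
    def test_k_clamped_to_sentence_count(self):
        doc = Document("d", "One here. Two here. Three here. Four here.")
        cs = semantic_cluster_chunk(doc, k=6)
        assert len(cs) == 4
        assert cs.params["k_effective"] == 4

    def test_single_sentence(self):
        doc = Document("d", "Only one sentence here.")
        cs = semantic_cluster_chunk(doc, k=6)
        assert len(cs) == 1
        assert cs.chunks[0].body == "Only one sentence here."

    def test_two_topic_partition_matches_sse_oracle(self):
        sents = topic_sentences(STEM_A[:5], 4, "aa") + topic_sentences(STEM_B[:5], 4, "bb")
        doc = Document("d", " ".join(sents))
        cs = semantic_cluster_chunk(doc, k=2, seed=42)
        got = sorted((frozenset(c.sentence_indices) for c in cs.chunks), key=min)

        # oracle: exhaustive 2-partition minimizing within-cluster SSE on the
        # TF-IDF rows
        texts = [s.text for s in segment_sentences(doc.text)]
        model = fit_tfidf(texts)
        rows = transform_tfidf(model, texts).toarray()

        def sse(idx):
            if not idx:
                return 0.0
            sub = rows[list(idx)]
            return float(((sub - sub.mean(axis=0)) ** 2).sum())

        best = min(
            (
                (sse(g1) + sse(set(range(8)) - set(g1)), frozenset(g1))
                for r in range(1, 8)
                for g1 in itertools.combinations(range(8), r)
            ),
            key=lambda t: t[0],
        )[1]
        oracle = sorted([best, frozenset(range(8)) - best], key=min)
        assert got == oracle
        assert oracle == [frozenset(range(4)), frozenset(range(4, 8))]

    def test_zero_sentences(self):
        assert len(semantic_cluster_chunk(Document("d", ""), k=6)) == 0


# ---------------------------------------------------------------------------
# propositions
# ---------------------------------------------------------------------------


class TestPropositions:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Remove the splint on day 7; begin saline irrigation on day 8.", 2),
            ("The splint stays on for one week.", 1),
            ("", 0),
            ("Remove the splint on day 7, and begin saline irrigation.", 2),
            ("Use cold compresses, and saline.", 1),  # no verb cue on the right
        ],
    )
    def test_extraction(self, text, expected):
        assert len(extract_propositions(text)) == expected

    def test_content_preserved(self):
        text = "Remove the splint on day 7; begin saline irrigation on day 8."
        props = extract_propositions(Sentence(3, 0, len(text), text))
        joined = " ".join(p.text for p in props)
        for token in ("remove", "splint", "begin", "saline", "irrigation"):
            assert token in joined.lower()
        assert all(p.source_sentence_index == 3 for p in props)

    def test_word_cap_grouping(self, backend):
        props = extract_propositions(("splint care " * 100).strip() + ".")
        assert props[0].word_count == 200
        cs = proposition_chunk(props * 3, backend)
        assert len(cs) == 2
        sizes = [c.word_count for c in cs.chunks]
        assert sizes[0] == 400 and sizes[1] == 200  # 200+200 <= 500 < 600

    def test_related_small_props_single_chunk(self, backend):
        props = extract_propositions("Splint care matters; splint care helps healing.")
        cs = proposition_chunk(props, backend)
        assert len(cs) == 1

    def test_unrelated_proposition_breaks(self, backend):
        props = (
            extract_propositions(" ".join(STEM_A) + " is removed.")
            + extract_propositions(" ".join(STEM_B) + " is started.")
        )
        cs = proposition_chunk(props, backend)
        assert len(cs) == 2

    def test_oversize_proposition_flagged(self, backend):
        props = [extract_propositions(("word " * 600).strip() + ".")[0]]
        cs = proposition_chunk(props, backend)
        assert len(cs) == 1
        assert "oversize_proposition" in cs.chunks[0].flags

    def test_empty_list(self, backend):
        assert len(proposition_chunk([], backend)) == 0


# ---------------------------------------------------------------------------
# adaptive chunking
# ---------------------------------------------------------------------------


class TestAdaptive:
    def test_single_sentence(self, backend):
        cs = adaptive_chunk(Document("d", "Keep the splint dry."), backend)
        assert len(cs) == 1
        assert cs.chunks[0].header is not None

    def test_identical_sentences_one_chunk(self, backend):
        doc = Document("d", " ".join(["Splint care helps healing every single day."] * 8))
        cs = adaptive_chunk(doc, backend)
        assert len(cs) == 1

    def test_two_topic_boundary(self, backend):
        sents = topic_sentences(STEM_A, 8, "aa") + topic_sentences(STEM_B, 8, "bb")
        doc = Document("d", " ".join(sents))
        cs = adaptive_chunk(doc, backend)
        assert len(cs) == 2
        assert cs.chunks[0].sentence_indices == tuple(range(8))
        assert cs.chunks[1].sentence_indices == tuple(range(8, 16))
        assert all(c.header for c in cs.chunks)

    def test_linker_repair_appends_to_previous(self, backend):
        sents = topic_sentences(STEM_A, 7, "aa")
        linker_sent = "Unless generic advice applies call the clinic office first today."
        sents_b = topic_sentences(STEM_B, 7, "bb")
        doc = Document("d", " ".join(sents + [linker_sent] + sents_b))
        cs = adaptive_chunk(doc, backend)
        assert len(cs) == 2
        assert 7 in cs.chunks[0].sentence_indices  # linker sentence rescued
        assert "linker_repair" in cs.chunks[0].flags
        assert cs.chunks[1].sentence_indices == tuple(range(8, 15))

    def test_linker_overlap_when_append_does_not_fit(self, backend):
        sent_a = "Alpha bravo charlie delta echo foxtrot golf hotel india juliet."
        linker = "Unless zulu yankee xray whisky victor uniform tango sierra romeo."
        doc = Document("d", " ".join([sent_a] * 3 + [linker]))
        cs = adaptive_chunk(
            doc, backend, max_words=30, min_words=5, overlap_token_cap=12
        )
        assert len(cs) == 2
        second = cs.chunks[1]
        assert "linker_overlap" in second.flags
        (ov,) = second.overlap_char_spans
        # duplicated prefix is the previous chunk's last whole sentence
        assert doc.text[ov[0] : ov[1]] == sent_a
        assert second.body.startswith(sent_a)

    def test_min_span_merge(self, backend):
        # a short trailing topic gets merged into its predecessor
        sents = topic_sentences(STEM_A, 8, "aa") + topic_sentences(STEM_B, 2, "bb")
        doc = Document("d", " ".join(sents))
        cs = adaptive_chunk(doc, backend)
        assert len(cs) == 1
        assert "min_span_merge" in cs.chunks[0].flags

    def test_pre_repair_boundaries_match_bruteforce(self, backend):
        rng = random.Random(99)
        pools = [STEM_A, STEM_B, ["mike", "november", "oscar", "papa", "quebec"]]
        for case in range(15):
            n = rng.randint(2, 8)
            sents = []
            for _ in range(n):
                pool = rng.choice(pools)
                words = [rng.choice(pool) for _ in range(rng.randint(4, 9))]
                sents.append(" ".join(words).capitalize() + ".")
            doc = Document(f"d{case}", " ".join(sents))
            threshold = rng.choice([0.3, 0.5, 0.7, 0.8])
            cs = adaptive_chunk(doc, backend, threshold=threshold, min_words=1)
            assert cs.params["pre_repair_boundaries"] == _reference_boundaries(
                doc, backend, threshold, 500
            )

    def test_raising_threshold_never_reduces_chunks(self, backend, corpus_doc):
        doc = Document("d", corpus_doc.text[:4000])
        counts = [
            adaptive_chunk(doc, backend, threshold=t).params["pre_repair_chunk_count"]
            for t in (0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert counts == sorted(counts)


def _reference_boundaries(doc, backend, threshold, max_words):
    """Independent evaluation of the join rule from a similarity matrix."""
    sentences = segment_sentences(doc.text)
    vecs = [backend.embed(s.text) for s in sentences]
    sim = [[cosine_similarity(a, b) for b in vecs] for a in vecs]
    wc = [count_words(s.text) for s in sentences]
    boundaries = [0]
    active = [0]
    for i in range(1, len(sentences)):
        cen = centroid([vecs[j] for j in active])
        ok = sim[i][active[-1]] >= threshold or cosine_similarity(vecs[i], cen) >= threshold
        if ok and sum(wc[j] for j in active) + wc[i] <= max_words:
            active.append(i)
        else:
            boundaries.append(i)
            active = [i]
    return boundaries


# ---------------------------------------------------------------------------
# micro-headers
# ---------------------------------------------------------------------------


class TestMicroHeader:
    def test_fallback_exact_string(self):
        assert generate_micro_header("and the of to... !!") == HEADER_FALLBACK
        assert generate_micro_header("") == HEADER_FALLBACK

    def test_dominant_phrase_surfaces(self):
        body = (
            "Postoperative care starts now. Postoperative care includes rest. "
            "Good postoperative care prevents problems. Minor swelling happens."
        )
        header = generate_micro_header(body)
        assert "Postoperative Care" in header

    def test_word_count_bounds(self, corpus_doc):
        for raw in corpus_doc.text.split("\n\n")[:5]:
            header = generate_micro_header(raw)
            assert header != HEADER_FALLBACK
            assert len(header.split()) <= 15

    def test_deterministic(self):
        body = "splint splint care care healing healing process"
        assert generate_micro_header(body) == generate_micro_header(body)


# ---------------------------------------------------------------------------
# cross-strategy invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("strategy", STRATEGIES)
def test_sentence_coverage_exactly_once(strategy, corpus, backend):
    """Every sentence appears exactly once in non-overlap provenance."""
    cs = chunk_document(corpus.document, strategy, RunConfig(window=250), backend)
    sentences = corpus.sentences
    if strategy in ("semantic_cluster", "proposition", "adaptive"):
        seen = [i for c in cs.chunks for i in c.sentence_indices]
        assert sorted(seen) == list(range(len(sentences)))
    else:
        spans = sorted(s for c in cs.chunks for s in c.char_spans)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 <= a2  # non-overlapping
        if strategy == "recursive_char":
            for s in sentences:
                assert (
                    sum(1 for a, b in spans if a <= s.char_start and s.char_end <= b) == 1
                )


@pytest.mark.parametrize("strategy", STRATEGIES)
def test_headers_only_on_adaptive(strategy, corpus, backend):
    cs = chunk_document(corpus.document, strategy, RunConfig(window=250), backend)
    if strategy == "adaptive":
        assert all(c.header for c in cs.chunks)
    else:
        assert all(c.header is None for c in cs.chunks)


@pytest.mark.parametrize("strategy", STRATEGIES)
def test_deterministic_and_jsonl_roundtrip(strategy, corpus, backend):
    doc = corpus.document
    cfg = RunConfig(window=400)
    text1 = write_jsonl(chunk_document(doc, strategy, cfg, backend))
    text2 = write_jsonl(chunk_document(doc, strategy, cfg, backend))
    assert text1 == text2  # bitwise determinism
    cs = read_jsonl(text1)
    assert write_jsonl(cs) == text1  # bit-exact round trip
    assert len({c.chunk_id for c in cs.chunks}) == len(cs.chunks)


def test_size_caps(corpus, backend):
    doc = corpus.document
    for c in fixed_token_window_chunk(doc, 250).chunks:
        assert len(c.body.split()) <= 260  # 250 tokens, split is close enough
    for c in proposition_chunk_document(doc, backend).chunks:
        if "oversize_proposition" not in c.flags:
            assert c.word_count <= 520
    for c in adaptive_chunk(doc, backend).chunks:
        if "over_max" not in c.flags and not c.overlap_char_spans:
            assert c.word_count <= 500
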