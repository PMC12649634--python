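"""Canonical text model: documents, paragraphs, sentences, tokens.

Every chunking strategy works on top of this layer, so its conventions are
fixed once here:

* offsets are 0-based, half-open, into ``Document.text``;
* a *paragraph* is a maximal block delimited by runs of two or more newlines;
* a *sentence* ends at ``. ! ?`` followed by whitespace and an uppercase
  letter, digit or opening quote, unless the terminating token is a known
  abbreviation;
* a *word* is a maximal whitespace-delimited token (hyphenated forms count
  as one word);
* a *token* (for BM25 and token windows) is a lowercased maximal run of
  alphanumeric characters.

Sentence segmentation is deliberately rule-based so that results are
deterministic and offset-exact; a different segmenter can be swapped in by
passing any callable with the same contract to the chunkers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Document",
    "Paragraph",
    "Sentence",
    "DEFAULT_ABBREVIATIONS",
    "split_paragraphs",
    "segment_sentences",
    "count_words",
    "tokenize",
    "token_spans",
]

#: Tokens (lowercase, terminator included) that never end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"dr.", "e.g.", "i.e.", "vs.", "fig.", "no.", "mr.", "mrs.", "ms.", "st."}
)

_PARA_DELIM = re.compile(r"\n{2,}")
_TOKEN_RE = re.compile(r"[^\W_]+")
_TERMINATORS = ".!?"
_OPENERS = "\"'“‘(["


@dataclass(frozen=True)
class Document:
    """A raw input document with a corpus-unique identifier."""

    doc_id: str
    text: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class Paragraph:
    char_start: int
    char_end: int
    text: str


@dataclass(frozen=True)
class Sentence:
    index: int
    char_start: int
    char_end: int
    text: str

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError("sentence span must be non-empty")


def split_paragraphs(doc: Document) -> list[Paragraph]:
    """Split a document at runs of >=2 newlines, dropping empty blocks."""
    paragraphs: list[Paragraph] = []
    pos = 0
    text = doc.text
    for match in _PARA_DELIM.finditer(text):
        _append_paragraph(paragraphs, text, pos, match.start())
        pos = match.end()
    _append_paragraph(paragraphs, text, pos, len(text))
    return paragraphs


def _append_paragraph(out: list[Paragraph], text: str, start: int, end: int) -> None:
    segment = text[start:end]
    stripped = segment.strip()
    if not stripped:
        return
    lead = len(segment) - len(segment.lstrip())
    s = start + lead
    e = s + len(stripped)
    out.append(Paragraph(s, e, text[s:e]))


def segment_sentences(
    text: str,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Segment ``text`` into offset-exact sentences.

    Paragraph delimiters always break sentences; within a paragraph the
    terminator rule applies.  ``text[s.char_start:s.char_end] == s.text``
    for every returned sentence, and spans never overlap.
    """
    doc = Document("_", text) if text else None
    sentences: list[Sentence] = []
    if doc is None:
        return sentences
    for para in split_paragraphs(doc):
        for s, e in _sentence_spans(text, para.char_start, para.char_end, abbreviations):
            sentences.append(Sentence(len(sentences), s, e, text[s:e]))
    return sentences


def _sentence_spans(
    text: str, start: int, end: int, abbreviations
) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    sent_start = start
    i = start
    while i < end:
        ch = text[i]
        if ch in _TERMINATORS:
            # swallow a run of terminators, e.g. "?!"
            j = i
            while j + 1 < end and text[j + 1] in _TERMINATORS:
                j += 1
            if _is_boundary(text, j, end, abbreviations):
                spans.append((sent_start, j + 1))
                # advance to the next non-whitespace character
                k = j + 1
                while k < end and text[k].isspace():
                    k += 1
                sent_start = k
                i = k
                continue
            i = j + 1
            continue
        i += 1
    if sent_start < end:
        tail = text[sent_start:end].rstrip()
        if tail:
            spans.append((sent_start, sent_start + len(tail)))
    return spans


def _is_boundary(text: str, term_idx: int, end: int, abbreviations) -> bool:
    """True if the terminator at ``term_idx`` ends a sentence."""
    nxt = term_idx + 1
    if nxt >= end:
        return True
    if not text[nxt].isspace():
        return False
    k = nxt
    while k < end and text[k].isspace():
        k += 1
    if k >= end:
        return True
    follower = text[k]
    if not (follower.isupper() or follower.isdigit() or follower in _OPENERS):
        return False
    # abbreviation guard: the whitespace-delimited token ending at the terminator
    w = term_idx
    while w > 0 and not text[w - 1].isspace():
        w -= 1
    token = text[w : term_idx + 1].lower()
    return token not in abbreviations


def count_words(text: str) -> int:
    """Number of maximal whitespace-delimited tokens."""
    return len(text.split())


def tokenize(text: str) -> list[str]:
    """Lowercased maximal alphanumeric runs, in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


def token_spans(text: str) -> list[tuple[int, int, str]]:
    """Like :func:`tokenize` but with (start, end) offsets into ``text``."""
    return [(m.start(), m.end(), m.group().lower()) for m in _TOKEN_RE.finditer(text)]
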