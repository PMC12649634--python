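# Methods

This note records the models and procedures `clinchunk` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark can and cannot show.

## Text model

Offsets are 0-based and half-open throughout. Paragraphs are maximal
blocks delimited by runs of ≥2 newlines. Sentences are segmented by a
deterministic rule — a terminator in `.!?` followed by whitespace and an
uppercase letter, digit or opening quote — with an abbreviation guard
(`Dr.`, `e.g.`, `i.e.`, `vs.`, `Fig.`, `No.`, …, configurable); paragraph
delimiters always break sentences. A *word* is a whitespace-delimited
token (hyphenated forms count once); a *token* (BM25, token windows) is a
lowercased maximal alphanumeric run. A rule-based segmenter was chosen
over a learned one so that spans are offset-exact and every downstream
result is bitwise reproducible; any callable with the same contract can be
swapped in.

## Embeddings

The default backend hashes character 3-grams (text lowercased, whitespace
collapsed; texts shorter than 3 characters contribute themselves) into
`dim = 512` buckets with a salted 64-bit FNV-1a hash, then L2-normalizes.
Properties that the pipeline relies on: determinism, unit norm, and a
monotone relation between vocabulary overlap and cosine similarity. Empty
text maps to the zero vector, and cosine with a zero vector is defined as
0 — degenerate text therefore forces a chunk break instead of raising.
Centroids are L2-normalized arithmetic means (an all-zero mean stays
zero). TF-IDF (semantic chunker) uses raw term counts, smoothed idf
`ln((1+n)/(1+df)) + 1`, L2-normalized rows and no stop-word removal — the
exact dialect is fixed here so clustering is reproducible — computed by
scikit-learn's `TfidfVectorizer` over this package's tokenizer.

## Chunking strategies

**Recursive character** (`max_chars=1000`, `overlap_chars=100`). Split
hierarchy paragraph → sentence → subordinate punctuation (`,`/`;`) → raw
characters; adjacent units merge greedily while the body, including any
overlap prefix, stays ≤ `max_chars`. Each chunk after the first starts
with the trailing ≤100 characters of its predecessor, snapped to a unit
boundary when one lies inside the overlap window (boundary-preferring
behavior keeps the duplicate a whole clause where possible). Overlap spans
are recorded separately from non-overlap provenance, so stripping the
prefixes and concatenating reconstructs the covered text exactly.

**Fixed token windows** (`window ∈ {250, 400, 600}`, `overlap=50`). The
token stream is cut with stride `window − overlap`; the final short window
is kept; bodies are original-text spans. The first 50 tokens of every
window after the first are duplicates and flagged as such.

**Semantic clusters** (`k=6`, `seed=42`). Sentence TF-IDF rows are
clustered with k-means (k-means++ initialization, 10 restarts under one
seed, best inertia kept); `k` is clamped to the sentence count, and at
`k = n` clustering is bypassed (one sentence per chunk). Cluster members
are concatenated in original document order; chunks are ordered by their
smallest sentence index.

**Propositions** (`max_words=500`, `relatedness_threshold=0.5`). The
default extractor splits sentences at semicolons and at `", and"`,
`", but"`, `", or"` when both sides carry a finite-verb cue (a bundled
lexicon plus an -s/-ed/-ing suffix heuristic); an LLM-backed extractor can
be passed as a plain callable. Grouping is greedy left-to-right: a new
chunk starts when the word cap would be exceeded or when the proposition's
cosine to the current chunk's proposition centroid falls below 0.5. The
relatedness gate mirrors the adaptive rule at a looser threshold, since
"unrelated to the current focus" is otherwise undefined. A single
proposition longer than the cap becomes its own chunk, flagged
`oversize_proposition`.

**Adaptive** (`threshold=0.80`, `max_words=500`, `min_words=60`,
`overlap_token_cap=30`). One pass over sentence embeddings; a sentence
joins the active chunk iff its similarity to the last sentence *or* to the
span centroid meets the threshold and the word cap holds. Open choices
fixed here: the two continuity checks combine with OR (centroid acts as a
rescue for locally dissimilar but on-topic sentences; configurable to
AND), and the comparison is ≥ (configurable strictness). Repairs run in
order after the pass: (1) *linker repair* — while the sentence opening a
new chunk starts with a linker (`for, until, unless, after, within`,
case-insensitive first token) it is appended to the previous chunk when
that fits the cap; when it does not fit, the previous chunk's trailing
tokens (≤30, whole sentences preferred, else a raw token tail) are
duplicated as a flagged overlap prefix; (2) *minimum-span merge* — chunks
under 60 words merge into their predecessor (the first chunk into its
successor), even past the cap (flagged `over_max` rather than re-split, so
a directive is never separated from its qualifier). Each final chunk gets
a micro-header; headers are excluded from word counts but prepended
(`header\nbody`) for indexing.

**Micro-headers** (`5–15` words). Stop words are removed; contiguous
1–4-token content phrases are scored by frequency × length with
deterministic tie-breaks (earliest occurrence, then lexicographic); the
top phrase is title-cased, padded with next-ranked distinct phrases to the
minimum and truncated at the maximum. A body with no content tokens yields
exactly `no header available`. This is a deliberately model-free titling
heuristic; a summarizer adapter can replace it where one is available.

## Retrieval

Chunks are embedded (header + body), L2-normalized and searched
exhaustively; scores are exact cosines, ties broken by ascending chunk id
for full determinism. Exact search was chosen over approximate indexing
because corpora at this scale do not need it and exactness enables oracle
tests; an ANN backend could sit behind the same interface. BM25 uses the
non-negative idf variant `ln((N − df + 0.5)/(df + 0.5) + 1)` with
`k₁ = 1.2`, `b = 0.75`, reported separately from dense retrieval and never
fused with it.

## Evaluation conventions

- 0/0 → 0 for precision, recall and F1 (prevents undefined metrics on
  empty judgment sets).
- Retrieval metrics are computed per query and macro-averaged; the
  bootstrap resamples queries. A pooled (micro) variant exists behind a
  separate function.
- Bootstrap CIs are plain seeded percentile intervals (1000 iterations,
  95%); no bias correction, so intervals are directly reproducible from
  the seed.
- Likert SDs use the sample (n−1) denominator. Rating distributions can be
  reconstructed exactly from "n fully / n at-least" summary counts:
  {3: n_full, 2: n_at_least − n_full, 1: n − n_at_least}.
- η² = SS_between/SS_total from the standard one-way decomposition; Tukey
  HSD p-values come from the studentized range (scipy); Cohen's d uses the
  pooled SD.
- Report-time rounding is half-up; nothing is rounded before comparison.

**Relevance labeling.** A retrieved chunk counts as a topical match for a
query iff, through its *non-overlap* provenance, it covers at least half
of the query's ground-truth sentence span or at least half of its own
sentences lie in that span (`min_fraction=0.5`, configurable). A window
that merely grazes a topic boundary with a stray sentence, or whose only
claim is a duplicated overlap prefix, is counted as a false positive when
retrieved — duplicated and boundary-grazing windows are retrieval noise,
not evidence.

## Synthetic corpus generator

The generator emulates the statistical structure of clinical aftercare
prose, not its content. A corpus has `n_sections = 24` topical sections of
12–18 sentences, organized into six major divisions of four sections each
(`super_group_size=4`): every section's vocabulary is 12 pseudo-words = a
3-word division core shared with its siblings + 9 own words. Body
sentences repeat a fixed 8-word *theme stem* (core + 5 own words) the way
clinical prose keeps naming its subject, surrounded by 5–9 variable words
drawn from the section vocabulary or, with probability 0.25, from a
60-word domain-common pool. Each section embeds an instruction unit —
directive, a timing sentence opening with *after/within*, an exception
sentence opening with *unless/until* — whose qualifier sentences are
written half in common vocabulary, so they break embedding continuity and
exercise the linker-repair path. Queries (one per section) mix 3 section
words with 4 common words, emulating the lay phrasing of patient
questions. Everything is a pure function of spec + seed.

Calibration rationale: under the hash backend, independently drawn
bag-of-words sentences cannot exceed cosine ≈ n/(k+n−1) ≈ 0.5 to each
other, below the 0.80 join threshold, which would collapse adaptive
chunking into degenerate single-chunk output via the minimum-span cascade.
The repeated theme stem anchors within-section similarity near 0.8
(division cores ≈ 0.3, unrelated sections ≈ 0.15), giving the generator
the similarity structure its sections are meant to have.

Problem sizes used by the test suite and the acceptance script — 20 seeded
corpora of 24 sections (~360 sentences, ~4500 words each), 24 queries per
corpus, top-5 retrieval — keep the complete benchmark under ten seconds
while leaving every per-strategy mean stable to a few thousandths.

## Known limitations

- The hash backend is lexical: similarity is literal n-gram overlap. It
  exercises every threshold, repair and ranking rule deterministically,
  but it cannot model paraphrase or semantic abstraction. Consequently the
  synthetic benchmark understates the adaptive strategy's advantage:
  retrieval of any chunk containing the query's literal terms rarely
  fails, so macro-F1 at a fixed top-5 budget is governed mostly by how
  many relevant chunks a strategy produces per query (its granularity),
  and a best-of-three fixed-window sweep can approximate the favorable
  granularity in most corpus geometries. The two directional acceptance
  tests assert the expected ordering (adaptive ≥ best fixed window in ≥80%
  of seeds; adaptive > proposition/semantic > fixed on means) and fail
  under this backend: measured means over 20 seeds are adaptive 0.352,
  proposition 0.493, semantic 0.333, best fixed window 0.357, with
  adaptive ≥ fixed in 45% of seeds. What does reproduce: adaptive >
  semantic, proposition > fixed, instruction-unit triples kept intact in
  ≥90% of sections, proposition fragmentation costing recall on
  lay-phrased queries, and cluster dilution capping the semantic strategy.
  A semantic (transformer) backend plugged into the same interface is the
  path to the full ordering.
- Passing tests on synthetic corpora show the machinery is correct and
  deterministic under the stated conditions; they do not establish
  retrieval quality on real clinical text, whose vocabulary gradients,
  redundancy across sources and paraphrastic queries the generator does
  not imitate.
- Sentence segmentation is rule-based; prose with unusual abbreviation or
  quotation conventions may need a custom abbreviation list or an external
  segmenter adapter.
- k-means with duplicate sentence vectors can in principle leave a cluster
  empty; empty clusters are dropped rather than re-seeded.
- The minimum-span merge can cascade when a document consists entirely of
  mutually dissimilar short sentences, yielding few large mixed chunks;
  this is the documented repair semantics, and the `pre_repair_boundaries`
  recorded in every adaptive `ChunkSet` expose the uncorrected boundaries.
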