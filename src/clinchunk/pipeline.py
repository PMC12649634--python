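"""Orchestration: configuration, the chunk → index → retrieve → evaluate
pipeline, and the seeded strategy benchmark on synthetic corpora."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

from .chunkers import (
    ChunkSet,
    adaptive_chunk,
    fixed_token_window_chunk,
    proposition_chunk_document,
    recursive_char_chunk,
    semantic_cluster_chunk,
    write_jsonl,
)
from .embeddings import EmbeddingBackend, get_backend
from .evaluation import retrieval_report
from .retrieval import bm25_top_k, build_index, query_top_k
from .synthetic import (
    CorpusSpec,
    GroundTruth,
    SyntheticCorpus,
    generate_corpus,
    generate_queries,
    label_chunks,
)
from .text import Document, segment_sentences, tokenize

__all__ = [
    "RunConfig",
    "chunk_document",
    "run_pipeline",
    "directional_benchmark",
    "STRATEGIES",
]

STRATEGIES = ("recursive_char", "fixed_token", "semantic_cluster", "proposition", "adaptive")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the reference defaults."""

    strategy: str = "adaptive"
    # recursive character splitter
    max_chars: int = 1000
    overlap_chars: int = 100
    # semantic clustering
    k_clusters: int = 6
    cluster_seed: int = 42
    # proposition grouping
    max_words: int = 500
    relatedness_threshold: float = 0.5
    # adaptive chunking
    threshold: float = 0.80
    min_words: int = 60
    overlap_token_cap: int = 30
    # fixed token windows
    window: int = 400
    window_overlap: int = 50
    # retrieval
    k_retrieve: int = 5
    ranker: str = "dense"
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    # evaluation
    bootstrap_iterations: int = 1000
    bootstrap_level: float = 0.95
    # embeddings / seeds
    embedding_backend: str = "hash"
    embedding_dim: int = 512
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file; unknown keys rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            kwargs[key] = type(default)(value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def chunk_document(doc: Document, strategy: str, config: RunConfig,
                   backend: EmbeddingBackend | None = None) -> ChunkSet:
    """Dispatch a document to one segmentation strategy."""
    if backend is None:
        backend = get_backend(config.embedding_backend, config.embedding_dim)
    if strategy == "recursive_char":
        return recursive_char_chunk(doc, config.max_chars, config.overlap_chars)
    if strategy == "fixed_token":
        return fixed_token_window_chunk(doc, config.window, config.window_overlap)
    if strategy == "semantic_cluster":
        return semantic_cluster_chunk(doc, config.k_clusters, config.cluster_seed)
    if strategy == "proposition":
        return proposition_chunk_document(
            doc, backend, max_words=config.max_words,
            relatedness_threshold=config.relatedness_threshold,
        )
    if strategy == "adaptive":
        return adaptive_chunk(
            doc, backend, threshold=config.threshold, max_words=config.max_words,
            min_words=config.min_words, overlap_token_cap=config.overlap_token_cap,
        )
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def _rank_queries(
    chunks: ChunkSet,
    queries: Sequence[tuple[str, str]],
    config: RunConfig,
    backend: EmbeddingBackend,
) -> dict[str, list[tuple[str, float]]]:
    rankings: dict[str, list[tuple[str, float]]] = {}
    if config.ranker == "dense":
        index = build_index(chunks, backend)
        for qid, text in queries:
            rankings[qid] = query_top_k(index, text, config.k_retrieve, backend, qid).ranked
    elif config.ranker == "bm25":
        for qid, text in queries:
            rankings[qid] = bm25_top_k(
                chunks, tokenize(text), config.k_retrieve,
                k1=config.bm25_k1, b=config.bm25_b, query_id=qid,
            ).ranked
    else:
        raise ValueError(f"unknown ranker {config.ranker!r}")
    return rankings


def read_queries_csv(path: str | Path) -> list[tuple[str, str]]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [(r["query_id"], r["text"]) for r in rows]


def read_ground_truth_csv(path: str | Path) -> GroundTruth:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    targets = {
        r["query_id"]: (int(r["target_section"]), (int(r["sent_start"]), int(r["sent_end"])))
        for r in rows
    }
    return GroundTruth(targets=targets)


def write_rankings_csv(path: str | Path, rankings: Mapping[str, list[tuple[str, float]]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "rank", "chunk_id", "score"])
        for qid in sorted(rankings):
            for rank, (cid, score) in enumerate(rankings[qid], 1):
                writer.writerow([qid, rank, cid, repr(score)])


def run_pipeline(
    config: RunConfig,
    doc_path: str | Path,
    queries_path: str | Path,
    ground_truth_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Chunk → index → retrieve → evaluate; write every artifact.

    Returns the metrics report (also written to ``metrics.json``) with the
    effective configuration echoed for provenance.
    """
    for p in (doc_path, queries_path, ground_truth_path):
        if not Path(p).is_file():
            raise FileNotFoundError(f"input file not found: {p}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = Document(doc_id=Path(doc_path).stem, text=Path(doc_path).read_text())
    backend = get_backend(config.embedding_backend, config.embedding_dim)
    chunks = chunk_document(doc, config.strategy, config, backend)
    (out / "chunks.jsonl").write_text(write_jsonl(chunks))
    queries = read_queries_csv(queries_path)
    gt = read_ground_truth_csv(ground_truth_path)
    rankings = _rank_queries(chunks, queries, config, backend)
    write_rankings_csv(out / "rankings.csv", rankings)
    sentences = segment_sentences(doc.text)
    judgments = label_chunks(chunks, gt, sentences)
    report = retrieval_report(
        {qid: [cid for cid, _ in ranked] for qid, ranked in rankings.items()},
        judgments,
        iterations=config.bootstrap_iterations,
        level=config.bootstrap_level,
        seed=config.seed,
    )
    report["strategy"] = config.strategy
    report["n_chunks"] = len(chunks)
    report["config"] = config.to_dict()
    (out / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _strategy_macro_f1(
    corpus: SyntheticCorpus,
    chunks: ChunkSet,
    queries: Sequence[tuple[str, str]],
    gt: GroundTruth,
    backend: EmbeddingBackend,
    k: int,
) -> float:
    from .evaluation import confusion_counts, macro_ir_metrics, precision_recall_f1

    index = build_index(chunks, backend)
    judgments = label_chunks(chunks, gt, corpus.sentences)
    per_query = []
    for qid, text in queries:
        result = query_top_k(index, text, k, backend, qid)
        per_query.append(
            precision_recall_f1(confusion_counts(result.chunk_ids, judgments[qid]))
        )
    return macro_ir_metrics(per_query).f1


def directional_benchmark(
    n_seeds: int = 20,
    base_seed: int = 0,
    k: int = 5,
    windows: Sequence[int] = (250, 400, 600),
    spec_kwargs: Mapping | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Macro-F1 per strategy over seeded synthetic corpora.

    For each seed: generate a corpus + per-section queries, run every
    strategy (fixed windows at each size, the best size kept), retrieve
    top-k and macro-average F1 over queries.  Returns per-seed F1 values,
    means, and the fraction of seeds where adaptive >= the best fixed
    window.
    """
    config = config or RunConfig()
    backend = get_backend(config.embedding_backend, config.embedding_dim)
    per_seed: dict[str, list[float]] = {
        "adaptive": [], "proposition": [], "semantic_cluster": [],
        "recursive_char": [], "fixed_token_best": [],
    }
    for w in windows:
        per_seed[f"fixed_token_{w}"] = []
    for s in range(n_seeds):
        spec = CorpusSpec(seed=base_seed + s, **dict(spec_kwargs or {}))
        corpus = generate_corpus(spec)
        queries, gt = generate_queries(corpus)
        doc = corpus.document
        for strat in ("adaptive", "proposition", "semantic_cluster", "recursive_char"):
            chunks = chunk_document(doc, strat, config, backend)
            per_seed[strat].append(
                _strategy_macro_f1(corpus, chunks, queries, gt, backend, k)
            )
        fixed_scores = []
        for w in windows:
            chunks = fixed_token_window_chunk(doc, w, config.window_overlap)
            f1 = _strategy_macro_f1(corpus, chunks, queries, gt, backend, k)
            per_seed[f"fixed_token_{w}"].append(f1)
            fixed_scores.append(f1)
        per_seed["fixed_token_best"].append(max(fixed_scores))
    wins = sum(
        1 for a, f in zip(per_seed["adaptive"], per_seed["fixed_token_best"]) if a >= f
    )
    return {
        "n_seeds": n_seeds,
        "per_seed": per_seed,
        "mean_f1": {name: sum(v) / len(v) for name, v in per_seed.items()},
        "adaptive_ge_fixed_fraction": wins / n_seeds,
    }
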