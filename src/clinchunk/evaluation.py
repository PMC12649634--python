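"""Retrieval and rating evaluation: confusion counts, precision/recall/F1,
Likert summaries, bootstrap confidence intervals, one-way ANOVA with
eta-squared, Tukey HSD and Cohen's d.

Conventions fixed here (and recorded so results are reproducible):

* 0/0 cases of precision, recall and F1 return 0;
* retrieval metrics are computed per query and macro-averaged (the
  bootstrap resamples the queries);
* the bootstrap interval is the plain seeded percentile interval;
* Likert SDs are sample SDs (n − 1 denominator);
* report-time rounding is half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RelevanceJudgment",
    "ConfusionCounts",
    "IRMetrics",
    "LikertRating",
    "RatingSummary",
    "BootstrapCI",
    "AnovaResult",
    "confusion_counts",
    "precision_recall_f1",
    "macro_ir_metrics",
    "micro_ir_metrics",
    "reconstruct_rating_counts",
    "ratings_from_counts",
    "likert_summary",
    "one_way_anova",
    "tukey_hsd",
    "cohens_d",
    "bootstrap_ci",
    "retrieval_report",
    "round_half_up",
]

CONDITIONS = ("basic", "semantic", "proposition", "adaptive")
DIMENSIONS = ("accuracy", "relevance")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding, applied only when formatting report values."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RelevanceJudgment:
    query_id: str
    relevant_ids: frozenset[str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class IRMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class LikertRating:
    item_id: str
    condition: str
    dimension: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ValueError("score must be in {1, 2, 3}")


@dataclass(frozen=True)
class RatingSummary:
    n: int
    mean: float
    sd: float
    counts: Mapping[int, int]
    prop_full: float  # proportion at score 3
    prop_at_least: float  # proportion at score >= 2


@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    level: float = 0.95
    iterations: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    ss_between: float = field(default=0.0, compare=False)
    ss_within: float = field(default=0.0, compare=False)


def confusion_counts(
    retrieved: Sequence[str], judgment: RelevanceJudgment
) -> ConfusionCounts:
    """TP/FP/FN of one retrieved list against one relevance judgment."""
    if len(set(retrieved)) != len(retrieved):
        raise ValueError("retrieved ids must be distinct")
    got = set(retrieved)
    rel = set(judgment.relevant_ids)
    return ConfusionCounts(
        tp=len(got & rel), fp=len(got - rel), fn=len(rel - got)
    )


def precision_recall_f1(counts: ConfusionCounts) -> IRMetrics:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return IRMetrics(p, r, f1)


def macro_ir_metrics(per_query: Sequence[IRMetrics]) -> IRMetrics:
    """Arithmetic mean of each component across queries."""
    if not per_query:
        raise ValueError("macro average of zero queries is undefined")
    return IRMetrics(
        precision=float(np.mean([m.precision for m in per_query])),
        recall=float(np.mean([m.recall for m in per_query])),
        f1=float(np.mean([m.f1 for m in per_query])),
    )


def micro_ir_metrics(per_query: Sequence[ConfusionCounts]) -> IRMetrics:
    """Pooled-count alternative to the macro average."""
    if not per_query:
        raise ValueError("micro average of zero queries is undefined")
    total = ConfusionCounts(
        tp=sum(c.tp for c in per_query),
        fp=sum(c.fp for c in per_query),
        fn=sum(c.fn for c in per_query),
    )
    return precision_recall_f1(total)


def reconstruct_rating_counts(n: int, n_full: int, n_at_least: int) -> dict[int, int]:
    """Recover the 3-point score distribution from summary counts.

    ``n_full`` items scored 3 and ``n_at_least`` scored at least 2, so the
    distribution is {3: n_full, 2: n_at_least - n_full, 1: n - n_at_least}.
    """
    if not 0 <= n_full <= n_at_least <= n:
        raise ValueError("require 0 <= n_full <= n_at_least <= n")
    return {3: n_full, 2: n_at_least - n_full, 1: n - n_at_least}


def ratings_from_counts(
    counts: Mapping[int, int], condition: str = "adaptive", dimension: str = "accuracy"
) -> list[LikertRating]:
    """Expand a score→count map into rating records (deterministic order)."""
    out: list[LikertRating] = []
    for score in (3, 2, 1):
        for i in range(counts.get(score, 0)):
            out.append(LikertRating(f"{condition}-{score}-{i}", condition, dimension, score))
    return out


def _scores(ratings: Iterable) -> np.ndarray:
    vals = [r.score if isinstance(r, LikertRating) else int(r) for r in ratings]
    return np.asarray(vals, dtype=float)


def likert_summary(ratings: Sequence) -> RatingSummary:
    """Mean, sample SD and score proportions of a rating sample."""
    scores = _scores(ratings)
    if scores.size == 0:
        raise ValueError("cannot summarize zero ratings")
    counts = {s: int(np.sum(scores == s)) for s in (1, 2, 3)}
    n = int(scores.size)
    return RatingSummary(
        n=n,
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)) if n > 1 else 0.0,
        counts=counts,
        prop_full=counts[3] / n,
        prop_at_least=(counts[3] + counts[2]) / n,
    )


def one_way_anova(groups: Sequence[Sequence]) -> AnovaResult:
    """Standard one-way decomposition with eta-squared = SSB / SST."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires >= 2 groups of size >= 2")
    arrays = [_scores(g) for g in groups]
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    dfb = len(arrays) - 1
    dfw = allv.size - len(arrays)
    sst = ssb + ssw
    if ssw == 0.0:
        F = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(F, dfb, dfw))
    eta_sq = ssb / sst if sst > 0 else 0.0
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p,
                       eta_squared=eta_sq, ss_between=ssb, ss_within=ssw)


def tukey_hsd(groups: Sequence[Sequence]) -> dict[tuple[int, int], float]:
    """Studentized-range p-values for all group pairs (indices i < j)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Tukey HSD requires >= 2 groups of size >= 2")
    arrays = [_scores(g) for g in groups]
    res = stats.tukey_hsd(*arrays)
    out: dict[tuple[int, int], float] = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out[(i, j)] = float(res.pvalue[i, j])
    return out


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Standardized mean difference with pooled standard deviation."""
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero")
    return (mean1 - mean2) / float(np.sqrt(pooled_var))


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Seeded percentile bootstrap interval of ``statistic`` over resamples."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(iterations, vals.size))
    reps = np.array([float(statistic(vals[row])) for row in idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return BootstrapCI(lower=float(lo), upper=float(hi), level=level,
                       iterations=iterations, seed=seed)


def retrieval_report(
    ranked_ids: Mapping[str, Sequence[str]],
    judgments: Mapping[str, RelevanceJudgment],
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Macro precision/recall/F1 with bootstrap CIs over the query set."""
    per_query: dict[str, IRMetrics] = {}
    for qid in sorted(judgments):
        retrieved = list(ranked_ids.get(qid, []))
        per_query[qid] = precision_recall_f1(confusion_counts(retrieved, judgments[qid]))
    metrics = list(per_query.values())
    macro = macro_ir_metrics(metrics)
    report: dict = {
        "n_queries": len(metrics),
        "precision": macro.precision,
        "recall": macro.recall,
        "f1": macro.f1,
        "per_query": {
            qid: {"precision": m.precision, "recall": m.recall, "f1": m.f1}
            for qid, m in per_query.items()
        },
    }
    for name in ("precision", "recall", "f1"):
        vals = [getattr(m, name) for m in metrics]
        ci = bootstrap_ci(vals, np.mean, iterations=iterations, level=level, seed=seed)
        report[f"{name}_ci"] = [ci.lower, ci.upper]
    return report
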