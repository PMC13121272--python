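"""Ranking metrics for concept-mapping predictions.

All metrics are computed from the 1-based rank of the gold target in the
full-vocabulary similarity ranking (ties broken by concept id).  A rank
beyond 5 still contributes 1/rank to MRR but zero to NDCG@5; NDCG uses
binary gain with a single relevant item per source, so the ideal DCG is 1
and per-concept NDCG reduces to 1/log2(rank + 1) for ranks within the
cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TypeVar

import numpy as np

from .embedding import EmbeddingBackend, SuggestionList, build_store
from .models import SourceConcept, TargetConcept, Vocabulary

__all__ = [
    "MetricSet",
    "RankedEvaluation",
    "UnmappableConceptError",
    "rank_of_truth",
    "accuracy_at_k",
    "weighted_accuracy_at_k",
    "mean_reciprocal_rank",
    "ndcg_at_5",
    "pooled_proportion",
    "holdout_split",
    "rank_sources",
]

METRIC_NAMES = (
    "acc_top1",
    "acc_top5",
    "acc_top1_weighted",
    "acc_top5_weighted",
    "mrr",
    "ndcg5",
)


class UnmappableConceptError(KeyError):
    """The gold target is absent from the vocabulary being ranked."""


def rank_of_truth(suggestions: SuggestionList, gold: TargetConcept) -> int:
    """1-based position of the gold target in a full ranking."""
    for pos, (candidate, _) in enumerate(suggestions.candidates, start=1):
        if candidate.concept_id == gold.concept_id:
            return pos
    raise UnmappableConceptError(
        f"gold target {gold.concept_id!r} not present in the ranking"
    )


def _validate_ranks(ranks: Sequence[int]) -> np.ndarray:
    arr = np.asarray(ranks)
    if arr.size == 0:
        raise ValueError("no ranks to aggregate")
    if np.any(arr < 1):
        raise ValueError("ranks are 1-based positive integers")
    return arr


def accuracy_at_k(ranks: Sequence[int], k: int) -> float:
    """Fraction of concepts whose gold target ranks within the top k."""
    arr = _validate_ranks(ranks)
    return float(np.mean(arr <= k))


def weighted_accuracy_at_k(
    ranks: Sequence[int], frequencies: Sequence[float], k: int
) -> float:
    """Top-k accuracy with each concept weighted by its occurrence count."""
    arr = _validate_ranks(ranks)
    freq = np.asarray(frequencies, dtype=np.float64)
    if freq.shape != arr.shape:
        raise ValueError("frequencies must align with ranks")
    if np.any(freq < 0):
        raise ValueError("frequencies must be non-negative")
    total = freq.sum()
    if total == 0:
        raise ValueError("all-zero frequencies")
    return float(np.sum(freq * (arr <= k)) / total)


def mean_reciprocal_rank(ranks: Sequence[int]) -> float:
    arr = _validate_ranks(ranks)
    return float(np.mean(1.0 / arr))


def ndcg_at_5(ranks: Sequence[int]) -> float:
    arr = _validate_ranks(ranks)
    gains = np.where(arr <= 5, 1.0 / np.log2(arr + 1.0), 0.0)
    return float(np.mean(gains))


def pooled_proportion(
    correct: Sequence[float], totals: Sequence[float]
) -> float:
    """Pool per-stratum counts into one proportion: sum(correct)/sum(totals).

    Equivalent to the per-stratum proportions averaged with weights
    proportional to stratum size (the concept-weighted mean across
    hospitals).
    """
    c = np.asarray(correct, dtype=np.float64)
    t = np.asarray(totals, dtype=np.float64)
    if c.shape != t.shape or t.sum() <= 0:
        raise ValueError("correct/totals must align with positive grand total")
    return float(c.sum() / t.sum())


@dataclass(frozen=True)
class MetricSet:
    """The six ranking metrics over one evaluated concept set.

    The invariant chain ``acc_top1 <= ndcg5 <= acc_top5`` and
    ``acc_top1 <= mrr`` holds for any rank distribution and is asserted at
    construction.
    """

    acc_top1: float
    acc_top5: float
    acc_top1_weighted: float
    acc_top5_weighted: float
    mrr: float
    ndcg5: float
    n: int

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (
            self.acc_top1 <= self.acc_top5 + eps
            and self.acc_top1 <= self.mrr + eps
            and self.acc_top1 <= self.ndcg5 + eps
            and self.ndcg5 <= self.acc_top5 + eps
        ):
            raise ValueError(f"metric invariant chain violated: {self}")

    @classmethod
    def from_ranks(
        cls, ranks: Sequence[int], frequencies: Sequence[float]
    ) -> "MetricSet":
        return cls(
            acc_top1=accuracy_at_k(ranks, 1),
            acc_top5=accuracy_at_k(ranks, 5),
            acc_top1_weighted=weighted_accuracy_at_k(ranks, frequencies, 1),
            acc_top5_weighted=weighted_accuracy_at_k(ranks, frequencies, 5),
            mrr=mean_reciprocal_rank(ranks),
            ndcg5=ndcg_at_5(ranks),
            n=len(ranks),
        )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {"n": self.n}


T = TypeVar("T")


def holdout_split(
    concepts: Sequence[T], fraction: float = 0.10, seed: int = 7
) -> tuple[list[T], list[T]]:
    """Random disjoint (train_pool, test_set) partition.

    The test set holds ``ceil(fraction * n)`` items sampled uniformly
    without replacement; both halves preserve the input order.
    """
    n = len(concepts)
    if n < 2:
        raise ValueError("need at least 2 concepts to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n_test = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = [c for i, c in enumerate(concepts) if i not in test_idx]
    test = [c for i, c in enumerate(concepts) if i in test_idx]
    return train, test


# -- batched ranking ----------------------------------------------------------


@dataclass
class RankedEvaluation:
    """Full-vocabulary gold ranks for a batch of sources.

    Sources whose gold target is not in the vocabulary are excluded from
    the arrays and counted in ``n_unmappable``.
    """

    ranks: np.ndarray
    frequencies: np.ndarray
    top_similarities: np.ndarray
    top_correct: np.ndarray
    n_unmappable: int

    def metrics(self) -> MetricSet:
        return MetricSet.from_ranks(self.ranks, self.frequencies)


def rank_sources(
    backend: EmbeddingBackend,
    sources: Sequence[SourceConcept],
    gold_targets: Sequence[Optional[TargetConcept]],
    vocabulary: Vocabulary,
) -> RankedEvaluation:
    """Rank every source against the vocabulary and locate its gold target.

    Equivalent to calling :func:`conceptmap.embedding.predict_topk` with
    ``k = len(vocabulary)`` per source and reading off the gold position,
    but computed as one matrix pass.
    """
    if len(sources) != len(gold_targets):
        raise ValueError("sources and gold_targets must align")
    store = build_store(backend, vocabulary, sources)
    id_order = np.argsort(store.target_ids)  # lexicographic id order for ties
    id_rank = np.empty(len(id_order), dtype=np.intp)
    id_rank[id_order] = np.arange(len(id_order))
    col_of = {t: i for i, t in enumerate(store.target_ids)}

    sims = np.clip(store.source_vectors @ store.target_vectors.T, -1.0, 1.0)
    ranks, freqs, top_sims, top_ok = [], [], [], []
    n_unmappable = 0
    for i, (src, gold) in enumerate(zip(sources, gold_targets)):
        if gold is None or gold.concept_id not in col_of:
            n_unmappable += 1
            continue
        g = col_of[gold.concept_id]
        row = sims[i]
        higher = int(np.sum(row > row[g]))
        tied_before = int(np.sum((row == row[g]) & (id_rank < id_rank[g])))
        rank = 1 + higher + tied_before
        ranks.append(rank)
        freqs.append(src.frequency)
        top_sims.append(float(row.max()))
        top_ok.append(rank == 1)
    return RankedEvaluation(
        ranks=np.asarray(ranks, dtype=np.intp),
        frequencies=np.asarray(freqs, dtype=np.float64),
        top_similarities=np.asarray(top_sims, dtype=np.float64),
        top_correct=np.asarray(top_ok, dtype=bool),
        n_unmappable=n_unmappable,
    )
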