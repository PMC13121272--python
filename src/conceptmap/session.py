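"""Simulated human-in-the-loop review sessions and session-level statistics.

A review *session* walks the frequency-sorted queue of still-unmapped
source concepts, shows each one's ranked suggestions to a reviewer, and
records the decision: validate the top suggestion, correct it from the list
(or by manual search), mark junk names as not relevant, or skip.  After a
session the validated mappings feed the continuous-learning update and the
next session runs with the improved model.

The reviewer here is a seeded policy adjudicated by the corpus's gold
mappings — a stand-in for the human informatician that makes the workflow
reproducible, not a claim about human behaviour.  Two session-level
analyses mirror what one would ask of a real deployment: do cosine scores
separate correct from incorrect top suggestions (Welch's t), and does
hold-out accuracy trend upward across sessions (OLS slope)?
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .embedding import LexicalHashEmbedder, build_store, predict_topk
from .evaluation import holdout_split, rank_sources
from .models import (
    MappingRecord,
    MappingStatus,
    SourceConcept,
    TargetConcept,
    Vocabulary,
)
from .simulate import SyntheticCorpus
from .training import TrainingConfig, continuous_update

__all__ = [
    "ReviewerPolicy",
    "SessionLog",
    "ReviewState",
    "run_session",
    "run_review_campaign",
    "session_summary",
    "confidence_separation",
    "welch_from_stats",
    "trend_regression",
]


@dataclass(frozen=True)
class ReviewerPolicy:
    """Behaviour of the simulated reviewer.

    ``accept_threshold`` is the similarity below which the reviewer distrusts
    the top suggestion and digs into the data first; such concepts are
    tallied as requiring further data analysis, and the subset whose gold
    target is not even in the top five (5-10 minutes of digging) as
    difficult.  ``skip_rate`` is the chance a mappable concept is deferred
    (e.g. pending a query to the hospital); junk concepts are recognised and
    marked not relevant with probability ``not_relevant_detection``,
    otherwise skipped.
    """

    accept_threshold: float = 0.85
    skip_rate: float = 0.05
    not_relevant_detection: float = 0.9
    reviewer_id: str = "sim-reviewer"

    def __post_init__(self) -> None:
        for name in ("skip_rate", "not_relevant_detection"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SessionLog:
    """Counts and accuracies of one review session.

    ``n_map`` counts concepts resolved in-session (mapped or marked not
    relevant); ``n_not_rel`` is the not-relevant subset of those.  ``n_data``
    counts mapped concepts that needed a look at the underlying data, and
    ``n_difficult`` the harder subset of those, so ``n_difficult <= n_data``
    by construction.  Session accuracies score the pre-session model on this
    session's mapped concepts; hold-out accuracies score the post-update
    model on the fixed hold-out set.
    """

    session_index: int
    n_map: int = 0
    n_skipped: int = 0
    n_not_rel: int = 0
    n_data: int = 0
    n_difficult: int = 0
    decisions: list[MappingRecord] = field(default_factory=list)
    # per mapped decision, in order: was the model's top suggestion correct?
    top_correct: list[bool] = field(default_factory=list)
    acc_top1_session: Optional[float] = None
    acc_top5_session: Optional[float] = None
    acc_top1_holdout: Optional[float] = None
    acc_top5_holdout: Optional[float] = None

    def validate(self) -> None:
        counts = (
            self.n_map,
            self.n_skipped,
            self.n_not_rel,
            self.n_data,
            self.n_difficult,
        )
        if any(c < 0 for c in counts):
            raise ValueError("session counts must be non-negative")
        if self.n_not_rel > self.n_map:
            raise ValueError("n_not_rel cannot exceed n_map")
        if self.n_difficult > self.n_data:
            raise ValueError("n_difficult cannot exceed n_data")


@dataclass
class ReviewState:
    """Mutable queue state threaded through successive sessions."""

    corpus: SyntheticCorpus
    queue: list[SourceConcept]
    done: set[str] = field(default_factory=set)

    @classmethod
    def from_corpus(
        cls, corpus: SyntheticCorpus, exclude: Sequence[SourceConcept] = ()
    ) -> "ReviewState":
        excluded = {s.key for s in exclude}
        queue = [s for s in corpus.sources if s.key not in excluded]
        queue.sort(key=lambda s: (-s.frequency, s.normalized_name))
        return cls(corpus=corpus, queue=queue)

    @property
    def pending(self) -> list[SourceConcept]:
        return [s for s in self.queue if s.key not in self.done]


def run_session(
    state: ReviewState,
    backend: LexicalHashEmbedder,
    vocabulary: Vocabulary,
    policy: ReviewerPolicy,
    budget: int,
    rng: np.random.Generator,
    session_index: int = 1,
) -> SessionLog:
    """Review up to ``budget`` concepts from the front of the queue.

    Every examined concept consumes budget.  Junk concepts (gold status not
    relevant) are marked not relevant when recognised, otherwise skipped;
    concepts whose gold target is missing from the vocabulary are skipped;
    all other concepts end mapped to their gold target — validated directly
    when the model's top suggestion is correct, corrected from the list or
    by search otherwise.  The log's decisions list carries the session's
    mapping records for the continuous-learning update.
    """
    log = SessionLog(session_index=session_index)
    pending = state.pending
    if budget <= 0 or not pending:
        log.validate()
        return log
    batch = pending[:budget]
    gold_by_key = {r.source.key: r for r in state.corpus.gold}
    store = build_store(backend, vocabulary, batch)
    timestamp = datetime(2025, 6, 1) + timedelta(days=session_index)
    top1_hits: list[bool] = []
    top5_hits: list[bool] = []
    for src in batch:
        state.done.add(src.key)
        gold = gold_by_key.get(src.key)
        if gold is not None and gold.status is MappingStatus.NOT_RELEVANT:
            if rng.random() < policy.not_relevant_detection:
                log.n_map += 1
                log.n_not_rel += 1
                log.decisions.append(
                    MappingRecord(
                        source=src,
                        status=MappingStatus.NOT_RELEVANT,
                        reviewer_id=policy.reviewer_id,
                        timestamp=timestamp,
                    )
                )
            else:
                log.n_skipped += 1
            continue
        gold_target: Optional[TargetConcept] = gold.target if gold else None
        if gold_target is None or gold_target.concept_id not in vocabulary:
            log.n_skipped += 1
            continue
        if rng.random() < policy.skip_rate:
            log.n_skipped += 1
            continue
        suggestions = predict_topk(store, src, vocabulary, k=5)
        top_target, top_sim = suggestions.top
        correct_top1 = top_target.concept_id == gold_target.concept_id
        in_top5 = any(
            t.concept_id == gold_target.concept_id for t, _ in suggestions.candidates
        )
        top1_hits.append(correct_top1)
        top5_hits.append(in_top5)
        log.top_correct.append(correct_top1)
        log.n_map += 1
        if top_sim < policy.accept_threshold:
            log.n_data += 1
            if not in_top5:
                log.n_difficult += 1
        log.decisions.append(
            MappingRecord(
                source=src,
                status=MappingStatus.MAPPED,
                target=gold_target,
                similarity_at_decision=top_sim,
                reviewer_id=policy.reviewer_id,
                timestamp=timestamp,
            )
        )
    if top1_hits:
        log.acc_top1_session = float(np.mean(top1_hits))
        log.acc_top5_session = float(np.mean(top5_hits))
    log.validate()
    return log


def run_review_campaign(
    corpus: SyntheticCorpus,
    backend: LexicalHashEmbedder,
    policy: ReviewerPolicy = ReviewerPolicy(),
    n_sessions: int = 10,
    budget: int = 100,
    config: TrainingConfig = TrainingConfig(),
    holdout_fraction: float = 0.10,
    seed: int = 7,
) -> list[SessionLog]:
    """Run successive sessions with continuous-learning updates in between.

    A fixed hold-out set (10% of mapped gold) is excluded from the review
    queue; after each session the model is updated on the cumulative
    validated mappings and re-scored on the hold-out, so the per-session
    logs trace the continuous-learning curve.
    """
    vocabulary = corpus.vocabulary
    mapped = corpus.mapped_gold
    _, holdout = holdout_split(mapped, fraction=holdout_fraction, seed=seed)
    state = ReviewState.from_corpus(corpus, exclude=[r.source for r in holdout])
    rng = np.random.default_rng(seed)
    cumulative: list[MappingRecord] = []
    version = 0
    logs: list[SessionLog] = []
    for s in range(1, n_sessions + 1):
        log = run_session(
            state, backend, vocabulary, policy, budget, rng, session_index=s
        )
        backend, cumulative, version = continuous_update(
            backend, log.decisions, cumulative, config, vocabulary, version
        )
        ev = rank_sources(
            backend,
            [r.source for r in holdout],
            [r.target for r in holdout],
            vocabulary,
        )
        if len(ev.ranks):
            log.acc_top1_holdout = float(np.mean(ev.ranks == 1))
            log.acc_top5_holdout = float(np.mean(ev.ranks <= 5))
        logs.append(log)
    return logs


# -- summaries ----------------------------------------------------------------


def session_summary(logs: Sequence[SessionLog]) -> dict:
    """Totals, mean and sample sd of mapped counts, plus per-session mixes."""
    if not logs:
        raise ValueError("need at least one session log")
    n_map = np.array([log.n_map for log in logs], dtype=float)
    summary = {
        "n_sessions": len(logs),
        "total_mapped": int(n_map.sum()),
        "mean_mapped": float(n_map.mean()),
        "sd_mapped": float(np.std(n_map, ddof=1)) if len(logs) > 1 else None,
        "total_skipped": int(sum(log.n_skipped for log in logs)),
        "per_session": [],
    }
    for log in logs:
        denom = log.n_map if log.n_map else np.nan
        summary["per_session"].append(
            {
                "session_index": log.session_index,
                "n_map": log.n_map,
                "n_skipped": log.n_skipped,
                "not_rel_share": log.n_not_rel / denom,
                "data_share": log.n_data / denom,
                "difficult_share": log.n_difficult / denom,
                "acc_top1_session": log.acc_top1_session,
                "acc_top5_session": log.acc_top5_session,
                "acc_top1_holdout": log.acc_top1_holdout,
                "acc_top5_holdout": log.acc_top5_holdout,
            }
        )
    return summary


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    n_correct: int
    mean_correct: float
    sd_correct: float
    n_incorrect: int
    mean_incorrect: float
    sd_incorrect: float


def confidence_separation(
    similarities: Sequence[float], correct: Sequence[bool]
) -> WelchResult:
    """Welch's t on top-candidate similarities, correct vs incorrect.

    A positive t means correct predictions carry higher similarity — the
    model's cosine score acts as a usable confidence signal.
    """
    sims = np.asarray(similarities, dtype=float)
    flags = np.asarray(correct, dtype=bool)
    if sims.shape != flags.shape:
        raise ValueError("similarities and correctness flags must align")
    a = sims[flags]
    b = sims[~flags]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two members")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
        df = float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return WelchResult(
        t=t_stat,
        df=df,
        p=p,
        n_correct=len(a),
        mean_correct=float(a.mean()),
        sd_correct=float(a.std(ddof=1)),
        n_incorrect=len(b),
        mean_incorrect=float(b.mean()),
        sd_incorrect=float(b.std(ddof=1)),
    )


def welch_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> WelchResult:
    """Welch's t from group summary statistics (unequal variances)."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return WelchResult(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        n_correct=n1,
        mean_correct=mean1,
        sd_correct=sd1,
        n_incorrect=n2,
        mean_incorrect=mean2,
        sd_incorrect=sd2,
    )


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    stderr: float
    t: float
    p: float
    r_squared: float
    df: int


def trend_regression(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """OLS of y on x with intercept; t on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 aligned points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.ptp(y) == 0:
        return TrendResult(0.0, float(y[0]), 0.0, 0.0, 1.0, 0.0, len(x) - 2)
    res = stats.linregress(x, y)
    t_stat = res.slope / res.stderr if res.stderr > 0 else np.inf
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        t=float(t_stat),
        p=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        df=len(x) - 2,
    )
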