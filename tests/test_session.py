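import numpy as np
import pytest

from conceptmap.embedding import LexicalHashEmbedder
from conceptmap.models import MappingStatus
from conceptmap.session import (
    ReviewState,
    ReviewerPolicy,
    SessionLog,
    confidence_separation,
    run_review_campaign,
    run_session,
    session_summary,
    trend_regression,
    welch_from_stats,
)
from conceptmap.training import TrainingConfig


FAST_TRAINING = TrainingConfig(n_neg=20, n_epochs=2)


def _backend():
    return LexicalHashEmbedder(dimension=256)


def test_zero_budget_session_has_zero_counts(small_corpus, rng):
    state = ReviewState.from_corpus(small_corpus)
    log = run_session(state, _backend(), small_corpus.vocabulary, ReviewerPolicy(), 0, rng)
    assert (log.n_map, log.n_skipped, log.n_not_rel, log.n_data, log.n_difficult) == (
        0, 0, 0, 0, 0,
    )


def test_no_skips_with_zero_skip_rate_and_perfect_detection(small_corpus, rng):
    policy = ReviewerPolicy(skip_rate=0.0, not_relevant_detection=1.0)
    state = ReviewState.from_corpus(small_corpus)
    log = run_session(state, _backend(), small_corpus.vocabulary, policy, 50, rng)
    assert log.n_skipped == 0
    assert log.n_map == 50


def test_session_walks_queue_in_frequency_order(small_corpus, rng):
    state = ReviewState.from_corpus(small_corpus)
    freqs = [s.frequency for s in state.pending]
    assert freqs == sorted(freqs, reverse=True)
    log = run_session(
        state, _backend(), small_corpus.vocabulary, ReviewerPolicy(), 10, rng
    )
    reviewed_keys = state.done
    top10 = {s.key for s in state.queue[:10]}
    assert reviewed_keys == top10
    assert log.n_map + log.n_skipped == 10


def test_session_log_invariants_enforced():
    log = SessionLog(session_index=1, n_map=2, n_not_rel=5)
    with pytest.raises(ValueError):
        log.validate()
    log = SessionLog(session_index=1, n_data=1, n_difficult=2)
    with pytest.raises(ValueError):
        log.validate()


def test_session_decisions_are_valid_mapping_records(small_corpus, rng):
    state = ReviewState.from_corpus(small_corpus)
    log = run_session(
        state, _backend(), small_corpus.vocabulary, ReviewerPolicy(), 40, rng
    )
    gold_by_key = {r.source.key: r for r in small_corpus.gold}
    for rec in log.decisions:
        expected = gold_by_key[rec.source.key]
        if rec.status is MappingStatus.MAPPED:
            assert rec.target.concept_id == expected.target.concept_id
            assert rec.similarity_at_decision is not None
        else:
            assert rec.status is MappingStatus.NOT_RELEVANT


def test_session_summary_table_arithmetic():
    n_maps = [23, 32, 88, 51, 93, 109, 62, 88, 70, 30]
    logs = [
        SessionLog(session_index=i + 1, n_map=m, n_not_rel=0)
        for i, m in enumerate(n_maps)
    ]
    summary = session_summary(logs)
    assert summary["total_mapped"] == 646
    assert summary["mean_mapped"] == pytest.approx(64.6)
    assert summary["sd_mapped"] == pytest.approx(np.std(n_maps, ddof=1))


def test_session_summary_single_log_sd_absent():
    summary = session_summary([SessionLog(session_index=1, n_map=5)])
    assert summary["sd_mapped"] is None


def test_confidence_separation_null_case():
    sims = [0.5, 0.7, 0.5, 0.7]
    flags = [True, True, False, False]
    res = confidence_separation(sims, flags)
    assert res.t == pytest.approx(0.0)


def test_confidence_separation_sign_follows_mean_difference():
    rng = np.random.default_rng(2)
    good = 0.95 + 0.02 * rng.standard_normal(40)
    bad = 0.80 + 0.05 * rng.standard_normal(15)
    sims = np.concatenate([good, bad])
    flags = np.array([True] * 40 + [False] * 15)
    res = confidence_separation(sims, flags)
    assert res.t > 0
    assert res.p < 0.01
    res_flipped = confidence_separation(sims, ~flags)
    assert res_flipped.t == pytest.approx(-res.t)


def test_confidence_separation_needs_two_per_group():
    with pytest.raises(ValueError):
        confidence_separation([0.9, 0.8, 0.7], [True, False, False])


def test_welch_from_stats_matches_direct_computation():
    rng = np.random.default_rng(8)
    a = rng.normal(0.9, 0.05, size=30)
    b = rng.normal(0.7, 0.1, size=12)
    direct = confidence_separation(
        np.concatenate([a, b]), np.array([True] * 30 + [False] * 12)
    )
    from_stats = welch_from_stats(
        30, a.mean(), a.std(ddof=1), 12, b.mean(), b.std(ddof=1)
    )
    assert from_stats.t == pytest.approx(direct.t)
    assert from_stats.df == pytest.approx(direct.df)


def test_trend_regression_exact_fit():
    x = [1, 2, 3, 4, 5]
    y = [0.1, 0.2, 0.3, 0.4, 0.5]
    res = trend_regression(x, y)
    assert res.slope == pytest.approx(0.1)
    assert res.r_squared == pytest.approx(1.0)
    assert res.p < 1e-6


def test_trend_regression_constant_series():
    res = trend_regression([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5])
    assert res.slope == 0.0
    assert res.r_squared == 0.0
    with pytest.raises(ValueError):
        trend_regression([2, 2, 2], [0.1, 0.2, 0.3])


def test_trend_regression_matches_normal_equations():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(4, 20))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        res = trend_regression(x, y)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(beta[1])
        assert res.intercept == pytest.approx(beta[0])


def test_campaign_confidence_signal_and_bookkeeping(small_corpus):
    """Across a short campaign, correct top suggestions carry higher
    similarity than incorrect ones, and every log satisfies its count
    invariants."""
    logs = run_review_campaign(
        small_corpus,
        _backend(),
        ReviewerPolicy(),
        n_sessions=3,
        budget=40,
        config=FAST_TRAINING,
        seed=11,
    )
    assert len(logs) == 3
    sims, flags = [], []
    for log in logs:
        log.validate()
        mapped = [r for r in log.decisions if r.status is MappingStatus.MAPPED]
        assert len(mapped) == len(log.top_correct)
        sims.extend(r.similarity_at_decision for r in mapped)
        flags.extend(log.top_correct)
    res = confidence_separation(sims, flags)
    assert res.mean_correct > res.mean_incorrect
    assert res.t > 0
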