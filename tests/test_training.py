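import math
from collections import Counter

import numpy as np
import pytest

from conceptmap.embedding import LexicalHashEmbedder
from conceptmap.models import Domain, MappingRecord, MappingStatus, SourceConcept, TargetConcept, Vocabulary
from conceptmap.training import (
    PairLabel,
    TrainingConfig,
    augment_shuffle,
    build_pairs,
    continuous_update,
    contrastive_loss,
    contrastive_loss_grad,
    finetune,
    train_model,
)


def test_augment_shuffle_two_tokens_gives_the_other_order(rng):
    assert augment_shuffle("blood haemoglobin", rng) == "haemoglobin blood"


def test_augment_shuffle_single_token_upsamples(rng):
    assert augment_shuffle("sodium", rng) == "sodium"


def test_augment_shuffle_preserves_token_multiset(rng):
    for _ in range(20):
        n = int(rng.integers(2, 7))
        name = " ".join(f"tok{rng.integers(100)}" for _ in range(n))
        out = augment_shuffle(name, rng)
        assert Counter(out.split()) == Counter(name.split())
        assert out != name or len(set(name.split())) == 1


def _vocab(n):
    return Vocabulary("V", [TargetConcept(f"T{i}", f"analyte {i} in serum", "V") for i in range(n)])


def _gold(vocab, n_records):
    out = []
    for i in range(n_records):
        src = SourceConcept(f"variant {i}", f"site1", Domain.LAB_TEST, 1 + i)
        out.append(
            MappingRecord(src, MappingStatus.MAPPED, vocab.concepts[i % len(vocab)])
        )
    return out


def test_build_pairs_exhausts_small_vocabulary(rng):
    vocab = _vocab(5)
    config = TrainingConfig(n_neg=4)
    pairs = build_pairs(_gold(vocab, 1), vocab, config, rng)
    negs = {p.target_name for p in pairs if p.label is PairLabel.NEGATIVE}
    assert negs == {c.normalized_name for c in vocab.concepts[1:]}


def test_build_pairs_counts_clip_to_vocab_size(rng):
    vocab = _vocab(50)
    config = TrainingConfig(n_neg=100)
    pairs = build_pairs(_gold(vocab, 10), vocab, config, rng)
    positives = [p for p in pairs if p.label is PairLabel.POSITIVE]
    negatives = [p for p in pairs if p.label is PairLabel.NEGATIVE]
    assert len(positives) == 10
    assert len(negatives) == 10 * 49


def test_build_pairs_deterministic_per_seed():
    vocab = _vocab(20)
    config = TrainingConfig(n_neg=5)
    gold = _gold(vocab, 6)
    a = build_pairs(gold, vocab, config, np.random.default_rng(3))
    b = build_pairs(gold, vocab, config, np.random.default_rng(3))
    assert a == b


def test_build_pairs_rejects_singleton_vocabulary(rng):
    vocab = _vocab(1)
    with pytest.raises(ValueError):
        build_pairs(_gold(vocab, 1), vocab, TrainingConfig(n_neg=1), rng)


def test_contrastive_loss_symmetric_case_is_ln2():
    s = np.array([1.0, 0.0])
    p = np.array([0.0, 1.0])
    n = np.array([[0.0, 1.0]])
    for tau in (0.05, 0.5, 1.0):
        assert contrastive_loss(s, p, n, tau) == pytest.approx(math.log(2))


def test_contrastive_loss_separated_case_closed_form():
    s = np.array([1.0, 0.0])
    assert contrastive_loss(
        s, s, np.array([[-1.0, 0.0]]), 1.0
    ) == pytest.approx(math.log(1 + math.exp(-2)))


def test_contrastive_loss_monotone_in_positive_similarity():
    rng = np.random.default_rng(5)
    negs = rng.normal(size=(8, 4))
    s = np.array([1.0, 0.0, 0.0, 0.0])
    losses = []
    for cp in np.linspace(-0.9, 0.9, 7):
        p = np.array([cp, math.sqrt(1 - cp**2), 0.0, 0.0])
        losses.append(contrastive_loss(s, p, negs, 0.3))
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_contrastive_loss_permutation_invariant_in_negatives():
    rng = np.random.default_rng(6)
    s, p = rng.normal(size=4), rng.normal(size=4)
    negs = rng.normal(size=(6, 4))
    base = contrastive_loss(s, p, negs, 0.2)
    for _ in range(5):
        assert contrastive_loss(s, p, rng.permutation(negs), 0.2) == pytest.approx(base)


def test_contrastive_loss_argument_validation():
    s = np.ones(3)
    with pytest.raises(ValueError):
        contrastive_loss(s, s, np.empty((0, 3)), 0.5)
    with pytest.raises(ValueError):
        contrastive_loss(s, s, np.ones((1, 3)), 0.0)


def test_analytic_gradient_matches_central_differences():
    """Analytic d(loss)/dW agrees with finite differences to 1e-4 relative
    error on random small instances."""
    rng = np.random.default_rng(12)
    eps = 1e-6
    for _ in range(50):
        d = int(rng.integers(3, 9))
        n_cand = int(rng.integers(2, 6))
        W = rng.normal(size=(d, d))
        x = rng.normal(size=d)
        Y = rng.normal(size=(n_cand, d))
        tau = float(rng.uniform(0.1, 1.0))
        pos = int(rng.integers(n_cand))
        _, dW = contrastive_loss_grad(W, x, Y, pos, tau)
        num = np.zeros_like(W)
        for i in range(d):
            for j in range(d):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                lp, _ = contrastive_loss_grad(Wp, x, Y, pos, tau)
                lm, _ = contrastive_loss_grad(Wm, x, Y, pos, tau)
                num[i, j] = (lp - lm) / (2 * eps)
        denom = max(np.abs(num).max(), 1e-12)
        assert np.abs(num - dW).max() / denom < 1e-4


def _training_setup(n_targets=12, n_records=8, dimension=64):
    vocab = _vocab(n_targets)
    gold = _gold(vocab, n_records)
    backend = LexicalHashEmbedder(dimension=dimension)
    return vocab, gold, backend


def test_finetune_zero_learning_rate_is_a_noop(rng):
    vocab, gold, backend = _training_setup()
    config = TrainingConfig(n_neg=5, learning_rate=0.0, n_epochs=3)
    pairs = build_pairs(gold, vocab, config, rng)
    W_before = backend.W.copy()
    _, trace = finetune(backend, pairs, config)
    np.testing.assert_array_equal(backend.W, W_before)
    assert trace == pytest.approx([trace[0]] * len(trace))


def test_finetune_reduces_training_loss_and_is_deterministic():
    vocab, gold, _ = _training_setup()
    config = TrainingConfig(n_neg=5, n_epochs=4)
    b1, t1 = train_model(LexicalHashEmbedder(dimension=64), gold, vocab, config)
    b2, t2 = train_model(LexicalHashEmbedder(dimension=64), gold, vocab, config)
    assert t1[-1] < t1[0]
    assert t1 == t2
    np.testing.assert_array_equal(b1.W, b2.W)


def test_finetune_requires_trainable_backend(rng):
    vocab, gold, backend = _training_setup()
    config = TrainingConfig(n_neg=5)
    pairs = build_pairs(gold, vocab, config, rng)
    backend.trainable = False
    with pytest.raises(ValueError):
        finetune(backend, pairs, config)


def test_finetune_does_not_mutate_gold_or_vocabulary():
    vocab, gold, backend = _training_setup()
    gold_before = list(gold)
    names_before = [c.name for c in vocab]
    train_model(backend, gold, vocab, TrainingConfig(n_neg=5, n_epochs=2))
    assert gold == gold_before
    assert [c.name for c in vocab] == names_before


def test_batched_trainer_matches_dense_reference():
    """One epoch of batch-size-1 SGD reproduces per-group dense gradients."""
    vocab, gold, backend = _training_setup(n_targets=6, n_records=3, dimension=32)
    config = TrainingConfig(
        n_neg=3, n_epochs=1, batch_size=1, learning_rate=0.1, seed=5
    )
    rng = np.random.default_rng(config.seed)
    pairs = build_pairs(gold, vocab, config, rng)
    # replay manually with the dense reference implementation
    groups = []
    for p in pairs:
        if p.label is PairLabel.POSITIVE:
            groups.append((p.source_name, [p.target_name]))
        else:
            groups[-1][1].append(p.target_name)
    W = backend.W.copy()
    order = np.random.default_rng(config.seed).permutation(len(groups))
    for gi in order:
        source_name, target_names = groups[gi]
        x = np.asarray(backend.feature_matrix([source_name]).todense())[0]
        Y = np.asarray(backend.feature_matrix(target_names).todense())
        _, dW = contrastive_loss_grad(W, x, Y, 0, config.temperature)
        W = W - config.learning_rate * dW
    finetune(backend, pairs, config)  # frozen negatives: no vocabulary passed
    np.testing.assert_allclose(backend.W, W, atol=1e-10)


def test_continuous_update_versioning_and_dedup():
    vocab, gold, backend = _training_setup(n_targets=10, n_records=6)
    config = TrainingConfig(n_neg=4, n_epochs=2)
    first, second = gold[:3], gold[3:]
    b, cumulative, v = continuous_update(backend, first, [], config, vocab, version=0)
    assert v == 1 and len(cumulative) == 3
    b, cumulative, v = continuous_update(b, second, cumulative, config, vocab, version=v)
    assert v == 2 and len(cumulative) == 6
    W_after = b.W.copy()
    # already-seen records: deduplicated away, no retraining, same version
    b, cumulative, v = continuous_update(b, first, cumulative, config, vocab, version=v)
    assert v == 2 and len(cumulative) == 6
    np.testing.assert_array_equal(b.W, W_after)
    # empty update is a no-op too
    b, cumulative, v = continuous_update(b, [], cumulative, config, vocab, version=v)
    assert v == 2
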