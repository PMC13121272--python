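from collections import Counter

import numpy as np
import pytest
from scipy import stats

from conceptmap.models import MappingStatus
from conceptmap.normalize import normalize_name
from conceptmap.simulate import (
    SiteStyle,
    SyntheticConfig,
    corrupt,
    generate_corpus,
    generate_vocabulary,
    write_corpus,
)


@pytest.fixture
def style():
    return SiteStyle(
        site_id="site1",
        abbreviations={"haemoglobin": "hb", "sodium": "na"},
        panel_tokens=("fbc", "ue"),
        suffix_letters="rnd",
    )


def test_generate_vocabulary_distinct_and_normalized(rng):
    config = SyntheticConfig(n_targets=50, seed=1)
    vocab, analyte_of = generate_vocabulary(config, rng)
    names = [c.normalized_name for c in vocab]
    assert len(set(names)) == 50
    for c in vocab:
        assert normalize_name(c.name) == c.name
        assert analyte_of[c.concept_id] in c.name


def test_generate_vocabulary_deterministic():
    config = SyntheticConfig(n_targets=30, seed=5)
    v1, _ = generate_vocabulary(config, np.random.default_rng(5))
    v2, _ = generate_vocabulary(config, np.random.default_rng(5))
    assert v1 == v2


def test_generate_vocabulary_capacity_error(rng):
    with pytest.raises(ValueError):
        generate_vocabulary(SyntheticConfig(n_targets=10_000), rng)


def test_corrupt_abbreviate_replaces_analyte(style, rng):
    out = corrupt("haemoglobin mass concentration in blood", "abbreviate", style, rng)
    tokens = out.split()
    assert "hb" in tokens
    assert "haemoglobin" not in tokens


def test_corrupt_token_shuffle_preserves_multiset(style, rng):
    name = "sodium substance concentration in serum"
    for _ in range(10):
        out = corrupt(name, "token_shuffle", style, rng)
        assert Counter(out.split()) == Counter(name.split())
        assert out != name


def test_corrupt_punctuation_noise_only_respaces(style, rng):
    name = "platelet count in blood"
    for _ in range(10):
        out = corrupt(name, "punctuation_noise", style, rng)
        assert Counter(normalize_name(out).split()) == Counter(name.split())


def test_corrupt_panel_prefix_and_code_suffix(style, rng):
    prefixed = corrupt("haemoglobin", "panel_prefix", style, rng)
    assert prefixed.split()[0] in style.panel_tokens
    assert prefixed.split()[-1] == "haemoglobin"
    suffixed = corrupt("sodium", "code_suffix", style, rng)
    assert suffixed.startswith("sodium_")


def test_corrupt_unknown_operator(style, rng):
    with pytest.raises(ValueError):
        corrupt("sodium", "reverse", style, rng)


def test_generate_corpus_deterministic_files(tmp_path, small_corpus):
    config = SyntheticConfig(n_targets=40, n_sites=3, seed=11)
    again = generate_corpus(config)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_corpus(small_corpus, d1)
    write_corpus(again, d2)
    for name in ("vocabulary.csv", "sources.csv", "gold_mappings.csv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_generate_corpus_gold_totality_and_junk_rate(small_corpus):
    vocab_ids = {c.concept_id for c in small_corpus.vocabulary}
    n_junk = 0
    for rec in small_corpus.gold:
        if rec.status is MappingStatus.MAPPED:
            assert rec.target.concept_id in vocab_ids
        else:
            assert rec.status is MappingStatus.NOT_RELEVANT
            n_junk += 1
    junk_share = n_junk / len(small_corpus.gold)
    assert 0.10 <= junk_share <= 0.20  # configured not_relevant_rate 0.15


def test_generate_corpus_no_junk_when_rate_zero():
    corpus = generate_corpus(
        SyntheticConfig(n_targets=20, n_sites=2, not_relevant_rate=0.0, seed=3)
    )
    assert all(r.status is MappingStatus.MAPPED for r in corpus.gold)


def test_site_uniqueness_of_source_names(small_corpus):
    sites_per_name = Counter()
    for s in small_corpus.sources:
        sites_per_name[s.raw_name] = sites_per_name.get(s.raw_name, 0)
    by_name = {}
    for s in small_corpus.sources:
        by_name.setdefault(s.raw_name, set()).add(s.site_id)
    single = sum(1 for sites in by_name.values() if len(sites) == 1)
    assert single / len(by_name) >= 0.95


def test_source_keys_unique(small_corpus):
    keys = [s.key for s in small_corpus.sources]
    assert len(keys) == len(set(keys))


def test_frequency_marginal_follows_zipf(small_corpus):
    """log-frequency decreases roughly linearly in log-rank over targets."""
    totals = Counter()
    for rec in small_corpus.mapped_gold:
        totals[rec.target.concept_id] += rec.source.frequency
    freqs = np.sort(np.array(list(totals.values())))[::-1].astype(float)
    ranks = np.arange(1, len(freqs) + 1)
    rho, _ = stats.spearmanr(np.log(ranks), np.log(freqs))
    assert rho <= -0.9


def test_difficulty_dial_abbreviation_harder_than_punctuation():
    """Corpora corrupted by abbreviation + local codes defeat the untrained
    lexical model more than punctuation-noise-only corpora (seed-averaged)."""
    from conceptmap.embedding import LexicalHashEmbedder
    from conceptmap.evaluation import rank_sources

    def mean_acc(weights):
        accs = []
        for seed in range(5):
            config = SyntheticConfig(
                n_targets=40,
                n_sites=2,
                corruption_weights=weights,
                detail_drop=0.0,
                alias_rate=0.0,
                seed=100 + seed,
            )
            corpus = generate_corpus(config)
            gold = corpus.mapped_gold
            ev = rank_sources(
                LexicalHashEmbedder(dimension=256),
                [r.source for r in gold],
                [r.target for r in gold],
                corpus.vocabulary,
            )
            accs.append(ev.metrics().acc_top1)
        return float(np.mean(accs))

    hard = mean_acc((0.6, 0.0, 0.4, 0.0, 0.0))  # abbreviate + code_suffix
    easy = mean_acc((0.0, 0.0, 0.0, 0.0, 1.0))  # punctuation noise only
    assert hard < easy
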