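# conceptmap

Embedding-based mapping of hospital-local medical concept names to
standardized vocabularies, with contrastive fine-tuning from validated
mappings and a human-in-the-loop continuous-learning workflow.

## Who this is for

Health-informatics teams standardizing electronic health records face the
same bottleneck everywhere: every hospital names its laboratory tests and
medications its own way ("haemoglobin hb", "fbc fbc hb",
"U SODIUM_RAND_363_61"), and mapping those names to a canonical vocabulary
(a SNOMED-CT-style lab reference set, a VTM-level drug dictionary) is slow
expert work. `conceptmap` is a library + CLI that ranks candidate target
concepts for each source name, learns from every validated mapping, and
quantifies how much each round of review improves the next.

## The model

Names are normalized (lower-case, every character outside `[a-z0-9% ]`
becomes a space, whitespace collapsed — `"Platelets_B_%"` →
`"platelets b %"`) and embedded as unit vectors. For a source concept `s`,
the suggestions are the top-k targets `t` by cosine similarity
`cos(e_s, e_t)`. The built-in backend hashes character 2–4-grams into a
1024-dimensional bag and applies a trainable projection `W` (identity at
init); pretrained sentence encoders can plug in behind the same contract.

Fine-tuning minimizes an InfoNCE-style contrastive loss per validated
mapping, with `n_neg` negatives sampled from the vocabulary minus the gold
target:

    L = −log [ exp(cos(s,p)/τ) / (exp(cos(s,p)/τ) + Σ_j exp(cos(s,n_j)/τ)) ]

with defaults `n_epochs=5`, `n_pos=1`, `n_neg=100`, `τ=0.05`, SGD on `W`.
Evaluation reports top-1/top-5 accuracy (plain and frequency-weighted),
MRR over the full ranking, and NDCG@5 (binary gain, single relevant item),
across three scenarios: untrained baseline, iterative fine-tuning over a
training-fraction grid with a fixed 10% hold-out, and leave-one-site-out
onboarding with concept-weighted aggregation. A simulated review-session
driver replays the human-in-the-loop workflow: map/skip/not-relevant
decisions per session, continuous model updates between sessions, Welch's
t on the similarity of correct vs incorrect suggestions, and the OLS trend
of hold-out accuracy over sessions.

Because real multi-hospital corpora are access-restricted, the package
ships a synthetic corpus generator that reproduces the characteristic
pathologies of hospital feeds — abbreviations, panel prefixes, site-local
code suffixes, token shuffles, punctuation noise, near-total cross-site
uniqueness, Zipfian frequencies and administrative junk names — so the
full pipeline is testable offline. See `docs/methods.md` for what the
generator does and does not emulate.

## Worked example

```python
from conceptmap import (SyntheticConfig, generate_corpus, LexicalHashEmbedder,
                        build_store, predict_topk, holdout_split,
                        TrainingConfig, train_model, rank_sources)

corpus = generate_corpus(SyntheticConfig(n_targets=50, n_sites=3, seed=42))
gold = corpus.mapped_gold          # 192 validated source→target mappings
src = gold[5].source               # raw name 'crp_CML' → normalized 'crp cml'

backend = LexicalHashEmbedder()    # untrained: pure character n-grams
store = build_store(backend, corpus.vocabulary, [src])
for t, s in predict_topk(store, src, corpus.vocabulary, k=5).candidates:
    print(f"{s:6.3f}  {t.name}")
```

The untrained model has no idea what the site abbreviation "crp" with a
local code means — the gold target ("c reactive protein catalytic activity
in serum") is not in the top five:

```
 0.168  platelet count in cerebrospinal fluid
 0.157  cortisol arbitrary concentration in cerebrospinal fluid
 0.143  cholesterol catalytic activity in urine
 0.139  ammonia mass concentration in cerebrospinal fluid
 0.116  amylase substance concentration in cerebrospinal fluid
```

Fine-tune on the other validated mappings and re-rank:

```python
pool, hold = holdout_split(gold, 0.10, seed=42)
backend, trace = train_model(backend, pool, corpus.vocabulary,
                             TrainingConfig(seed=42))
m = rank_sources(backend, [r.source for r in hold],
                 [r.target for r in hold], corpus.vocabulary).metrics()
print([round(x, 3) for x in trace], round(m.acc_top1, 3), round(m.acc_top5, 3))
```

```
[1.175, 0.687, 0.453, 0.315, 0.241] 0.9 1.0
```

The per-epoch mean loss falls monotonically, hold-out top-1 accuracy rises
from 0.800 (untrained) to 0.900, top-5 from 0.950 to 1.000, and the same
source now resolves correctly at rank 1 (similarity 0.256 vs 0.192 for the
runner-up). The same pipeline is available from the shell:

```
conceptmap simulate --config sim.json --out corpus/
conceptmap embed --vocab corpus/vocabulary.csv --sources corpus/sources.csv --out store/
conceptmap predict --store store/ --vocab corpus/vocabulary.csv \
    --sources corpus/sources.csv --k 5 --out suggestions.csv
conceptmap train --gold corpus/gold_mappings.csv --vocab corpus/vocabulary.csv \
    --out-state state/
conceptmap evaluate --scenario onboarding --corpus corpus/ --out results/
```

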