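# Methods

## The problem

Hospitals record laboratory tests and medications under local names —
abbreviated, panel-prefixed, code-suffixed, reordered, and almost always
unique to one site. Research use of such data requires *concept mapping*:
assigning each local ("source") name to an entry of a standardized
("target") vocabulary such as a SNOMED-CT lab-observable reference set or
the VTM level of a drug dictionary. `conceptmap` implements an
embedding-based mapping assistant around three ideas:

1. **Atomic nearest-neighbour prediction.** Every source and target name is
   normalized (lower-case; every character outside `[a-z0-9% ]` becomes a
   space; whitespace collapsed) and embedded once into a unit vector.
   Suggestions for a source are the k targets with the highest cosine
   similarity; ties break by concept id so rankings are reproducible.
2. **Contrastive fine-tuning from validated mappings.** Each validated
   mapping contributes a positive pair and `n_neg` sampled negatives, and
   the embedder's trainable parameters are optimized under an InfoNCE-style
   loss `-log softmax(cos(s,p)/τ)` over the candidate set.
3. **Continuous learning.** Reviewer decisions from each session are folded
   back into the model by replaying the full cumulative validated set from
   the current parameter state, so suggestions improve session over
   session.

## The built-in embedder

The package's embedding backend is a *lexical hash embedder*: each
whitespace token is padded with word-boundary markers and decomposed into
character 2–4-grams; n-gram counts are hashed into `D` buckets (default
D=1024, seeded BLAKE2 hashing), L2-normalized, and projected by a trainable
square matrix `W` initialized to the identity. The output is re-normalized,
so cosine similarity is a dot product. With `W = I` the model is a pure
character n-gram similarity — a deliberately simple, download-free
representation whose *training mechanics* (not its absolute quality) are
the object of study. Transformer sentence embedders satisfy the same
`EmbeddingBackend` contract and can be plugged in.

Hash collisions are accepted as noise: at D=1024 a few n-grams share
buckets, perturbing similarities identically for every name.

`W` is exactly what the trainer updates. Gradients of the loss with respect
to `W` flow through both the source and the target side (both are projected
by the same matrix) and through the L2 normalization; the analytic gradient
is verified against central finite differences to 1e-4 relative error.

## Training

Defaults: `n_epochs=5`, `n_pos=1`, `n_neg=100`, temperature `τ=0.05`,
plain SGD with learning rate 0.05, batch size 32, seed 7. Negatives are
drawn uniformly without replacement from the vocabulary minus the gold
target (clipped to `|V|−1`) and re-sampled each epoch. When `n_pos>1`,
extra positives shuffle the word order of the source name; single-word
names are duplicated verbatim. Loss traces are monotone-decreasing at
these settings on the default corpus; a non-finite loss aborts with
diagnostics rather than silently continuing.

The batched trainer projects all unique target features once per batch
(sparse feature matrices keep this cheap) and accumulates the gradient as
two sparse-by-dense products, which makes a full default-corpus run
(≈720 mappings, 5 epochs, 100 negatives, D=1024) take on the order of ten
seconds on one CPU.

## The synthetic corpus

Real multi-hospital mapping data is access-restricted, so every experiment
runs on a generated corpus whose defaults are the package's study
conditions: 200 targets, 5 sites, geometric variants-per-target (mean 4,
cap 20), corruption operator weights 0.35/0.15/0.25/0.15/0.10 for
abbreviate / panel-prefix / code-suffix / token-shuffle / punctuation-noise,
Zipf(1.2) concept frequencies, 99% site-uniqueness of names, and 15% junk
(administrative/storage) names with no legitimate target.

Three generator mechanisms beyond the operator list reflect how real lab
feeds look and behave:

* **Detail dropping** (`detail_drop=0.7`): most variants derive from the
  bare analyte ("creatinine"), some keep one qualifying word, few spell
  the full reference-set phrase. Real source names almost never contain
  "substance concentration in serum"; without this the untrained lexical
  baseline is unrealistically strong (~0.8 top-1 instead of ~0.4).
* **Site-local alias codes** (`alias_rate=0.6`): each (site, target) pair
  owns an opaque short code ("creup"-style) that its variants reuse. These
  codes are meaningless to the untrained model but are exactly what
  fine-tuning learns, so they are the mechanism behind generalization to
  *unseen variants of seen targets* at a known site.
* **Home-site concentration** (`site_concentration=0.7`): a target's
  variants accrue mostly at one site, as in per-hospital feeds. Abbreviation
  tables are drawn per site with only a 0.35 chance of using a globally
  shared short form, which is what opens the gap between leave-one-site-out
  and all-data fine-tuning.

What the generator does **not** emulate: semantic similarity between
distinct analytes, units/value distributions, one-to-many panel
memberships, medication brand-name morphology, or the true variant-count
distribution of common tests (real counts run far higher than the desk-
scale mean of 4). Consequently, passing tests show that the *mechanics* —
ranking, training, evaluation, and the continuous-learning loop — behave
correctly and directionally as on real data; they do not certify real-data
accuracy levels, which depend on a pretrained biomedical encoder.

## Evaluation

Metrics are computed from the 1-based rank of the gold target in the
full-vocabulary ranking: top-1/top-5 accuracy, their frequency-weighted
variants, MRR over the full ranking, and NDCG@5 with binary gain and a
single relevant item (ideal DCG = 1, so a concept contributes
`1/log2(rank+1)` within the cutoff and 0 beyond it). The invariant chain
`acc_top1 ≤ ndcg5 ≤ acc_top5` and `acc_top1 ≤ mrr` is asserted on every
metric set. Concepts whose gold target is absent from the vocabulary are
excluded and counted, mirroring panel tests with no legitimate match.

Scenario machinery:

* **Hold-out splitting** uses `ceil(fraction·n)` for the test size (10% of
  2,261 concepts → 227 test / 2,034 train).
* **Iterative fine-tuning** trains a fresh backend per (fraction, repeat)
  cell over the grid {0, 0.2, …, 1.0} with 5 repeats, evaluating both the
  unsampled remainder (validation; empty and therefore absent at fraction
  1.0) and the fixed hold-out; aggregates are mean ± sample sd (ddof=1).
  Fraction 0 is the single deterministic untrained run.
* **Onboarding** holds each site out in turn, trains on the rest, and
  aggregates per-site metric sets by the concept-weighted mean (pooled
  counts).

All cell seeds derive from `(seed, fraction, repeat)` via
`numpy.random.SeedSequence`, so scenario runs are bit-reproducible.

## The review-session simulation

`run_session` walks the frequency-descending queue of unmapped concepts up
to a per-session budget (default 100). The reviewer is a seeded policy
adjudicated by the corpus's gold mappings: junk names are recognized and
marked *not relevant* with probability 0.9 (otherwise skipped), mappable
concepts are randomly deferred with probability 0.05 (emulating queries
back to the hospital), and every other concept ends mapped to its gold
target — validated directly when the model's top suggestion is correct,
corrected otherwise. Concepts whose top similarity falls below the
policy's `accept_threshold` (default 0.85) are tallied as requiring data
analysis; the subset whose gold target is not even in the top five as
difficult, so `n_difficult ≤ n_data` holds by construction. Session
accuracies use only mapped concepts with a gold target (not-relevant and
skipped concepts have no defined truth), scored against the *pre-session*
model; hold-out accuracies are scored after the post-session update.

`confidence_separation` applies Welch's unequal-variance t (via
`scipy.stats`) to top-candidate similarities of correct vs incorrect
predictions; `trend_regression` fits OLS of hold-out accuracy on session
index with a t on n−2 df. The degenerate all-equal case returns t=0 rather
than NaN, and a constant response returns a zero slope with R²=0.

## Numerical and design choices

* Embeddings are L2-normalized at embed time; cosine reduces to a dot
  product and values are clamped to [−1, 1] against round-off. The empty
  string embeds to the zero vector with a warning, never an exception, and
  a zero vector has similarity 0 to everything.
* Similarity ties break by concept id ascending everywhere (suggestions,
  ranks); frequency ties in queue order break by normalized name.
* float64 is used throughout training so the gradient check is meaningful;
  stores persist vectors as float32.
* The continuous update replays the cumulative gold set (not just the new
  records) from the current state — a guard against catastrophic
  forgetting — and increments its version tag only when an update actually
  ran; duplicate or empty submissions are no-ops.
* Problem sizes in tests and the acceptance script are the generator's
  defaults (200 targets, ≈850 mapped variants, 5 sites, ten sessions of
  budget 100), chosen as the desk-scale regime in which every experiment
  completes in minutes on one CPU while leaving all rates and
  hyperparameters at their stated values.

## Known limitations

* The lexical embedder has no semantics: synonyms that share no character
  n-grams ("cobalamin" vs "b12") are invisible to the untrained model and
  learnable only per string family. Real deployments would swap in a
  pretrained biomedical sentence encoder behind the same contract.
* One gold target per source; one-to-many (panel) mappings are out of
  scope.
* The simulated reviewer never makes an incorrect mapping; heterogeneity
  of human effort is reduced to skip/detection probabilities and the
  similarity-threshold bookkeeping.
* Confidence intervals on accuracies are not produced.
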