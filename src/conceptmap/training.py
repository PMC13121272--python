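"""Contrastive fine-tuning of embedding backends from validated mappings.

Each validated mapping contributes one positive (source name, gold target
name) pair plus ``n_neg`` negative pairs whose targets are sampled uniformly
without replacement from the vocabulary minus the gold target.  The loss is
the softmax-over-negatives (InfoNCE) form with temperature ``tau``

    L = -log  exp(cos(s,p)/tau) / (exp(cos(s,p)/tau) + sum_j exp(cos(s,n_j)/tau))

minimized by mini-batch gradient descent on the backend's trainable
parameters (the projection ``W`` for the built-in lexical embedder).  Both
source and target embeddings pass through ``W``, so the optimizer moves the
whole representation, not just the source side.

Extra positives (``n_pos > 1``) come from shuffling the word order of the
source name; single-word names are duplicated verbatim (upsampling).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from .embedding import LexicalHashEmbedder, cosine_similarity
from .models import MappingRecord, MappingStatus, Vocabulary

__all__ = [
    "TrainingConfig",
    "TrainingPair",
    "PairLabel",
    "PairOrigin",
    "TrainingDivergedError",
    "augment_shuffle",
    "build_pairs",
    "contrastive_loss",
    "contrastive_loss_grad",
    "finetune",
    "train_model",
    "continuous_update",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one fine-tuning run.

    Defaults follow the tuned operating point for this task: 5 epochs, one
    positive and 100 sampled negatives per source, InfoNCE temperature 0.05,
    plain SGD with learning rate 0.05 and batch size 32.
    """

    n_epochs: int = 5
    n_pos: int = 1
    n_neg: int = 100
    temperature: float = 0.05
    learning_rate: float = 0.05
    batch_size: int = 32
    seed: int = 7
    shuffle_augment: bool = True

    def __post_init__(self) -> None:
        if self.n_epochs < 1 or self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_epochs, n_pos and n_neg must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


class PairLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class PairOrigin(str, enum.Enum):
    GOLD = "gold"
    SHUFFLED = "shuffled"
    UPSAMPLED = "upsampled"


@dataclass(frozen=True)
class TrainingPair:
    source_name: str
    target_name: str
    label: PairLabel
    origin: PairOrigin


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


def augment_shuffle(name: str, rng: np.random.Generator) -> str:
    """Permute the words of a normalized name.

    Multi-word names receive a permutation drawn uniformly from the
    non-identity permutations; single-word (and empty) names are returned
    unchanged, which upsamples them as identical extra samples.
    """
    tokens = name.split()
    if len(tokens) < 2:
        return name
    while True:
        perm = rng.permutation(len(tokens))
        if not np.array_equal(perm, np.arange(len(tokens))):
            return " ".join(tokens[i] for i in perm)


def _sample_negatives(
    vocab_names: Sequence[str], gold_index: int, n_neg: int, rng: np.random.Generator
) -> list[str]:
    candidates = np.delete(np.arange(len(vocab_names)), gold_index)
    if len(candidates) == 0:
        raise ValueError("vocabulary of size 1 admits no negative examples")
    take = min(n_neg, len(candidates))
    chosen = rng.choice(candidates, size=take, replace=False)
    return [vocab_names[i] for i in chosen]


def build_pairs(
    gold: Iterable[MappingRecord],
    vocabulary: Vocabulary,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[TrainingPair]:
    """Expand validated mappings into labelled training pairs.

    Output is grouped: each positive pair is immediately followed by its
    negatives, so trainers can recover the group structure by scanning for
    positive labels.  Negatives are sampled uniformly without replacement
    from the vocabulary minus the gold target, clipped to ``|V| - 1``.
    """
    vocab_names = [c.normalized_name for c in vocabulary]
    id_index = {c.concept_id: i for i, c in enumerate(vocabulary)}
    pairs: list[TrainingPair] = []
    for rec in gold:
        if rec.status is not MappingStatus.MAPPED or rec.target is None:
            raise ValueError("build_pairs requires records with status=mapped")
        gi = id_index.get(rec.target.concept_id)
        if gi is None:
            raise ValueError(
                f"gold target {rec.target.concept_id!r} not in vocabulary"
            )
        source_name = rec.source.normalized_name
        target_name = vocab_names[gi]
        for p in range(config.n_pos):
            if p == 0:
                pos_name, origin = source_name, PairOrigin.GOLD
            elif config.shuffle_augment:
                pos_name = augment_shuffle(source_name, rng)
                origin = (
                    PairOrigin.SHUFFLED
                    if pos_name != source_name
                    else PairOrigin.UPSAMPLED
                )
            else:
                pos_name, origin = source_name, PairOrigin.UPSAMPLED
            pairs.append(
                TrainingPair(pos_name, target_name, PairLabel.POSITIVE, origin)
            )
            for neg in _sample_negatives(vocab_names, gi, config.n_neg, rng):
                pairs.append(TrainingPair(pos_name, neg, PairLabel.NEGATIVE, origin))
    return pairs


# -- loss ---------------------------------------------------------------------


def contrastive_loss(
    source_vec: np.ndarray,
    positive_vec: np.ndarray,
    negative_vecs: np.ndarray,
    tau: float,
) -> float:
    """InfoNCE loss for one source against its positive and negatives."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    negative_vecs = np.atleast_2d(np.asarray(negative_vecs, dtype=np.float64))
    if negative_vecs.shape[0] == 0:
        raise ValueError("at least one negative example is required")
    cos_p = cosine_similarity(source_vec, positive_vec)
    cos_n = np.array([cosine_similarity(source_vec, v) for v in negative_vecs])
    logits = np.concatenate(([cos_p], cos_n)) / tau
    return float(logsumexp(logits) - logits[0])


def contrastive_loss_grad(
    W: np.ndarray,
    x_source: np.ndarray,
    x_targets: np.ndarray,
    pos_index: int,
    tau: float,
) -> tuple[float, np.ndarray]:
    """Loss and analytic gradient w.r.t. the projection for one group.

    ``x_source`` (length-F) and ``x_targets`` (rows, one per candidate with
    ``pos_index`` marking the positive) are pre-projection feature vectors;
    embeddings are the L2-normalized projections ``W @ x``.  Dense reference
    implementation, used for gradient verification and small problems; the
    trainer's batched path computes the same quantity.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    x_targets = np.atleast_2d(np.asarray(x_targets, dtype=np.float64))
    if x_targets.shape[0] < 2:
        raise ValueError("need the positive and at least one negative")
    u = W @ x_source
    nu = np.linalg.norm(u)
    eu = u / nu
    V = x_targets @ W.T
    nv = np.linalg.norm(V, axis=1)
    safe_nv = np.where(nv == 0, 1.0, nv)
    Ev = V / safe_nv[:, None]
    c = Ev @ eu
    logits = c / tau
    log_z = logsumexp(logits)
    loss = float(log_z - logits[pos_index])
    p = np.exp(logits - log_z)
    g = p.copy()
    g[pos_index] -= 1.0
    g /= tau
    # dc_j/du = (Ev_j - c_j eu)/|u| ; dc_j/dv_j = (eu - c_j Ev_j)/|v_j|
    G_u = (g @ Ev - float(g @ c) * eu) / nu
    A = (g[:, None] * (eu[None, :] - c[:, None] * Ev)) / safe_nv[:, None]
    dW = np.outer(G_u, x_source) + A.T @ x_targets
    return loss, dW


# -- trainer ------------------------------------------------------------------


@dataclass
class _CompiledGroups:
    """Pair groups compiled to index arrays over unique names."""

    source_names: list[str]
    target_names: list[str]
    group_source: np.ndarray  # (n_groups,) index into source_names
    group_pos: np.ndarray  # (n_groups,) index into target_names
    group_negs: np.ndarray  # (n_groups, n_neg) indices into target_names


def _compile_groups(pairs: Sequence[TrainingPair]) -> _CompiledGroups:
    source_index: dict[str, int] = {}
    target_index: dict[str, int] = {}

    def s_idx(name: str) -> int:
        return source_index.setdefault(name, len(source_index))

    def t_idx(name: str) -> int:
        return target_index.setdefault(name, len(target_index))

    groups: list[tuple[int, int, list[int]]] = []
    for pair in pairs:
        if pair.label is PairLabel.POSITIVE:
            groups.append((s_idx(pair.source_name), t_idx(pair.target_name), []))
        else:
            if not groups:
                raise ValueError("pair list must start with a positive pair")
            groups[-1][2].append(t_idx(pair.target_name))
    n_neg = {len(g[2]) for g in groups}
    if len(n_neg) != 1 or 0 in n_neg:
        raise ValueError("every group needs the same positive count of negatives")
    return _CompiledGroups(
        source_names=list(source_index),
        target_names=list(target_index),
        group_source=np.array([g[0] for g in groups], dtype=np.intp),
        group_pos=np.array([g[1] for g in groups], dtype=np.intp),
        group_negs=np.array([g[2] for g in groups], dtype=np.intp),
    )


def _resample_group_negs(
    compiled: _CompiledGroups,
    vocab_positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fresh per-group negatives: uniform without replacement, gold excluded.

    ``vocab_positions`` maps vocabulary slots to rows of the compiled target
    name table (the table is extended in place if a vocabulary name never
    appeared in the original pairs).
    """
    n_groups = len(compiled.group_source)
    n_vocab = len(vocab_positions)
    n_neg = compiled.group_negs.shape[1]
    keys = rng.random((n_groups, n_vocab))
    pos_slot = np.empty(n_groups, dtype=np.intp)
    pos_of = {t: i for i, t in enumerate(vocab_positions)}
    for gi, tpos in enumerate(compiled.group_pos):
        pos_slot[gi] = pos_of[tpos]
    keys[np.arange(n_groups), pos_slot] = np.inf
    chosen = np.argpartition(keys, n_neg - 1, axis=1)[:, :n_neg]
    return vocab_positions[chosen]


def _batch_loss_grad(
    W: np.ndarray,
    Xs: sparse.csr_matrix,
    Xt: sparse.csr_matrix,
    src: np.ndarray,
    pos: np.ndarray,
    negs: np.ndarray,
    tau: float,
) -> tuple[float, np.ndarray]:
    """Mean loss and gradient over a batch of groups (vectorized)."""
    b = len(src)
    U = np.asarray(Xs[src] @ W.T)
    nu = np.linalg.norm(U, axis=1)
    safe_nu = np.where(nu == 0, 1.0, nu)
    Eu = U / safe_nu[:, None]
    V = np.asarray(Xt @ W.T)
    nv = np.linalg.norm(V, axis=1)
    safe_nv = np.where(nv == 0, 1.0, nv)
    Ev = V / safe_nv[:, None]

    cols = np.concatenate([pos[:, None], negs], axis=1)  # (b, n+1)
    C = np.einsum("bd,bjd->bj", Eu, Ev[cols])
    logits = C / tau
    log_z = logsumexp(logits, axis=1)
    losses = log_z - logits[:, 0]
    P = np.exp(logits - log_z[:, None])
    G = P.copy()
    G[:, 0] -= 1.0
    G /= tau

    G_u = (
        np.einsum("bj,bjd->bd", G, Ev[cols]) - np.sum(G * C, axis=1)[:, None] * Eu
    ) / safe_nu[:, None]

    rows_flat = np.repeat(np.arange(b), cols.shape[1])
    cols_flat = cols.ravel()
    g_flat = G.ravel()
    n_t = Xt.shape[0]
    P_mat = sparse.coo_matrix(
        (g_flat, (cols_flat, rows_flat)), shape=(n_t, b)
    ).tocsr()
    q = np.bincount(cols_flat, weights=(G * C).ravel(), minlength=n_t)
    A = (np.asarray(P_mat @ Eu) - q[:, None] * Ev) / safe_nv[:, None]

    dW = np.asarray((Xs[src].T @ G_u)).T + np.asarray((Xt.T @ A)).T
    return float(np.mean(losses)), dW / b


def finetune(
    backend: LexicalHashEmbedder,
    pairs: Sequence[TrainingPair],
    config: TrainingConfig,
    vocabulary: Optional[Vocabulary] = None,
) -> tuple[LexicalHashEmbedder, list[float]]:
    """Optimize the backend projection on contrastive pairs.

    Runs ``n_epochs`` of seeded mini-batch SGD and returns the backend (its
    state updated in place) plus the per-epoch mean loss trace.  When a
    ``vocabulary`` is supplied, each group's negatives are re-sampled every
    epoch from the vocabulary minus that group's gold target; otherwise the
    negatives frozen into ``pairs`` are reused.
    """
    if not getattr(backend, "trainable", False):
        raise ValueError("backend is not trainable")
    if not pairs:
        raise ValueError("no training pairs supplied")
    compiled = _compile_groups(pairs)

    vocab_positions: Optional[np.ndarray] = None
    if vocabulary is not None:
        t_index = {n: i for i, n in enumerate(compiled.target_names)}
        positions = []
        for c in vocabulary:
            if c.normalized_name not in t_index:
                t_index[c.normalized_name] = len(compiled.target_names)
                compiled.target_names.append(c.normalized_name)
            positions.append(t_index[c.normalized_name])
        vocab_positions = np.array(sorted(set(positions)), dtype=np.intp)

    Xs = backend.feature_matrix(compiled.source_names)
    Xt = backend.feature_matrix(compiled.target_names)
    rng = np.random.default_rng(config.seed)
    W = backend.W.copy()
    n_groups = len(compiled.group_source)
    trace: list[float] = []
    for epoch in range(config.n_epochs):
        negs = compiled.group_negs
        if vocab_positions is not None and len(vocab_positions) > negs.shape[1]:
            negs = _resample_group_negs(compiled, vocab_positions, rng)
        order = rng.permutation(n_groups)
        total = 0.0
        for start in range(0, n_groups, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grad = _batch_loss_grad(
                W,
                Xs,
                Xt,
                compiled.group_source[batch],
                compiled.group_pos[batch],
                negs[batch],
                config.temperature,
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch offset {start} "
                    f"(lr={config.learning_rate}, tau={config.temperature})"
                )
            W -= config.learning_rate * grad
            total += loss * len(batch)
        trace.append(total / n_groups)
    if config.learning_rate > 0:
        backend.set_projection(W)
    return backend, trace


def train_model(
    backend: LexicalHashEmbedder,
    gold: Iterable[MappingRecord],
    vocabulary: Vocabulary,
    config: TrainingConfig,
) -> tuple[LexicalHashEmbedder, list[float]]:
    """Build pairs from validated mappings and fine-tune in one call."""
    rng = np.random.default_rng(config.seed)
    pairs = build_pairs(gold, vocabulary, config, rng)
    return finetune(backend, pairs, config, vocabulary=vocabulary)


# -- continuous learning ------------------------------------------------------


def continuous_update(
    backend: LexicalHashEmbedder,
    new_records: Iterable[MappingRecord],
    cumulative_gold: Sequence[MappingRecord],
    config: TrainingConfig,
    vocabulary: Vocabulary,
    version: int = 0,
) -> tuple[LexicalHashEmbedder, list[MappingRecord], int]:
    """Fold newly validated mappings into the model.

    Training replays the full cumulative gold set (old plus genuinely new
    mapped records, deduplicated by source identity) rather than the new
    records alone, which guards against catastrophic forgetting.  Returns
    the backend, the merged gold set, and the version tag — incremented only
    when an update actually ran.
    """
    by_source = {rec.source.key: rec for rec in cumulative_gold}
    fresh = []
    for rec in new_records:
        if rec.status is not MappingStatus.MAPPED:
            continue
        prior = by_source.get(rec.source.key)
        if prior is not None and prior.target.concept_id == rec.target.concept_id:
            continue
        by_source[rec.source.key] = rec
        fresh.append(rec)
    if not fresh:
        return backend, list(cumulative_gold), version
    merged = list(by_source.values())
    # distinct seed per version so successive replays do not repeat batches
    run_config = replace(config, seed=(config.seed + 1009 * (version + 1)) % (2**31))
    finetune_backend, _ = train_model(backend, merged, vocabulary, run_config)
    return finetune_backend, merged, version + 1
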