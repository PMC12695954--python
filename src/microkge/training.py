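"""Negative sampling, losses, mini-batch SGD training, and grid search.

Embeddings are learned by contrasting observed triples against corrupted
("negative") ones.  Two corruption schemes are provided:

- **classical_head_tail** — replace the head or the tail (coin flip) by a
  uniformly drawn other entity; the standard KGE recipe.  Accidental true
  triples are *not* filtered out.
- **interaction_based** — keep both strains and the environment, and flip
  the interaction type to one of the other two, uniformly.  Because the
  prediction target is the interaction type, these negatives are exactly
  the alternatives the classifier must rule out, and they can never be
  accidentally true facts about a different strain pair.

Two losses are supported: the margin-based pairwise ranking loss
``sum max(0, margin - s_pos + s_neg)`` (each negative paired with its
source positive) and the pointwise logistic loss
``sum log(1 + exp(-l * s))`` with label ``l = +1`` for observed and ``-1``
for corrupted triples.  By convention TransE trains with the pairwise loss
and DistMult/SimplE with the logistic loss.

Optimization is plain mini-batch SGD with a constant learning rate and
analytic gradients (verified against central finite differences in the
test suite).  The SGD step uses the batch-mean gradient so the learning
rate is comparable across batch sizes.  All randomness flows from a single
seed through a documented stream split: ``SeedSequence(seed)`` spawns one
child for initialization and one for epoch shuffling/negative sampling, so
the two are independently reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .kg import INTERACTION_TYPES, KnowledgeGraph, Relation, Triple
from .models import EmbeddingSet, ModelKind, init_embeddings

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "corrupt_classical",
    "corrupt_interaction",
    "pairwise_loss",
    "logistic_loss",
    "loss_and_grads",
    "train",
    "grid_search",
]

_DEFAULT_LOSS = {
    ModelKind.TRANSE: "pairwise",
    ModelKind.DISTMULT: "logistic",
    ModelKind.SIMPLE: "logistic",
}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``loss=None`` resolves to the model's conventional loss (TransE ->
    pairwise, DistMult/SimplE -> logistic).  ``margin`` applies to the
    pairwise loss only.  ``transe_normalize`` re-projects TransE entity
    vectors onto the unit sphere before every batch, as in the original
    translational-embedding recipe.
    """

    model: ModelKind = ModelKind.SIMPLE
    dim: int = 32
    learning_rate: float = 0.5
    batch_size: int = 128
    epochs: int = 200
    margin: float = 1.0
    loss: Optional[str] = None
    ns_strategy: str = "classical_head_tail"
    negatives_per_positive: int = 1
    l2_reg: float = 0.0
    seed: int = 0
    transe_normalize: bool = True
    norm_kind: str = "l2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", ModelKind.parse(self.model))
        if self.loss is None:
            object.__setattr__(self, "loss", _DEFAULT_LOSS[self.model])
        if self.loss not in ("pairwise", "logistic"):
            raise ValueError(f"loss must be 'pairwise' or 'logistic', got {self.loss!r}")
        if self.ns_strategy not in ("classical_head_tail", "interaction_based"):
            raise ValueError(
                "ns_strategy must be 'classical_head_tail' or 'interaction_based', "
                f"got {self.ns_strategy!r}"
            )
        if self.dim <= 0:
            raise ValueError(f"dim must be positive, got {self.dim!r}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate!r}")
        if self.batch_size <= 0:
            raise ValueError(f"batch_size must be positive, got {self.batch_size!r}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be nonnegative, got {self.epochs!r}")
        if self.loss == "pairwise" and not self.margin > 0:
            raise ValueError(f"pairwise loss requires margin > 0, got {self.margin!r}")
        if self.negatives_per_positive <= 0:
            raise ValueError(
                f"negatives_per_positive must be positive, got {self.negatives_per_positive!r}"
            )
        if self.l2_reg < 0:
            raise ValueError(f"l2_reg must be nonnegative, got {self.l2_reg!r}")


@dataclass
class TrainedModel:
    """A trained embedding set together with its provenance."""

    embeddings: EmbeddingSet
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def entity_index(self) -> dict[str, int]:
        return self.embeddings.entity_index

    @property
    def relation_index(self) -> dict[Relation, int]:
        return self.embeddings.relation_index


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def corrupt_classical(
    triple: Triple, kg: KnowledgeGraph, rng: np.random.Generator
) -> Triple:
    """Corrupt the head or the tail (coin flip) with a uniform other entity."""
    n = len(kg.entities)
    if n < 2:
        raise ValueError("classical corruption needs at least two entities")
    ent_idx = kg.entity_index
    if rng.random() < 0.5:
        orig = ent_idx[triple.head]
        new = int(rng.integers(0, n - 1))
        new += new >= orig
        return Triple(kg.entities[new], triple.relation, triple.tail)
    orig = ent_idx[triple.tail]
    new = int(rng.integers(0, n - 1))
    new += new >= orig
    return Triple(triple.head, triple.relation, kg.entities[new])


def corrupt_interaction(triple: Triple, rng: np.random.Generator) -> Triple:
    """Flip the interaction type to one of the other two, uniformly.

    Head, tail, and environment are unchanged.
    """
    alternatives = [t for t in INTERACTION_TYPES if t != triple.relation.itype]
    new_type = alternatives[int(rng.integers(0, 2))]
    return Triple(
        triple.head, Relation(new_type, triple.relation.environment), triple.tail
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def pairwise_loss(pos_scores, neg_scores, margin: float) -> float:
    """Margin ranking loss summed over paired positive/negative scores."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError(
            f"paired score lists must have equal length, got {pos.shape} vs {neg.shape}"
        )
    if not margin > 0:
        raise ValueError(f"margin must be positive, got {margin!r}")
    return float(np.maximum(0.0, margin - pos + neg).sum())


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)) without overflow for large |x|
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def logistic_loss(scores, labels) -> float:
    """Pointwise logistic loss ``sum log(1 + exp(-l * s))`` with l in {+1, -1}."""
    s = np.asarray(scores, dtype=float)
    l = np.asarray(labels, dtype=float)
    if s.shape != l.shape:
        raise ValueError(f"scores and labels must align, got {s.shape} vs {l.shape}")
    if not np.all(np.isin(l, (-1.0, 1.0))):
        raise ValueError("labels must be +1 or -1")
    return float(_softplus(-l * s).sum())


# ---------------------------------------------------------------------------
# vectorized scoring with gradients
# ---------------------------------------------------------------------------

def _scores_and_cache(arrays, model, norm_kind, h, r, t):
    """Batch scores plus whatever backprop needs, per model."""
    if model is ModelKind.TRANSE:
        diff = arrays["ent"][h] + arrays["rel"][r] - arrays["ent"][t]
        if norm_kind == "l2":
            nrm = np.linalg.norm(diff, axis=1)
            return -nrm, (diff, nrm)
        return -np.abs(diff).sum(axis=1), (diff, None)
    if model is ModelKind.DISTMULT:
        H, R, T = arrays["ent"][h], arrays["rel"][r], arrays["ent"][t]
        return np.einsum("ij,ij,ij->i", H, R, T), (H, R, T)
    HH, HT = arrays["ent_head"][h], arrays["ent_tail"][h]
    TH, TT = arrays["ent_head"][t], arrays["ent_tail"][t]
    R, RI = arrays["rel"][r], arrays["rel_inv"][r]
    fwd = np.einsum("ij,ij,ij->i", HH, R, TT)
    inv = np.einsum("ij,ij,ij->i", HT, RI, TH)
    return 0.5 * (fwd + inv), (HH, HT, TH, TT, R, RI)


def _backprop(grads, arrays, model, norm_kind, h, r, t, cache, dscore):
    """Scatter d(loss)/d(embedding rows) for a batch into dense grad arrays."""
    d = dscore[:, None]
    if model is ModelKind.TRANSE:
        diff, nrm = cache
        if norm_kind == "l2":
            safe = np.where(nrm > 0, nrm, 1.0)[:, None]
            ddiff = -diff / safe * d  # d(-||diff||)/d(diff) = -diff/||diff||
        else:
            ddiff = -np.sign(diff) * d
        np.add.at(grads["ent"], h, ddiff)
        np.add.at(grads["rel"], r, ddiff)
        np.add.at(grads["ent"], t, -ddiff)
        return
    if model is ModelKind.DISTMULT:
        H, R, T = cache
        np.add.at(grads["ent"], h, R * T * d)
        np.add.at(grads["rel"], r, H * T * d)
        np.add.at(grads["ent"], t, H * R * d)
        return
    HH, HT, TH, TT, R, RI = cache
    half = 0.5 * d
    np.add.at(grads["ent_head"], h, R * TT * half)
    np.add.at(grads["ent_tail"], h, RI * TH * half)
    np.add.at(grads["ent_head"], t, HT * RI * half)
    np.add.at(grads["ent_tail"], t, HH * R * half)
    np.add.at(grads["rel"], r, HH * TT * half)
    np.add.at(grads["rel_inv"], r, HT * TH * half)


def _batch_loss_grads(arrays, model, norm_kind, pos_idx, neg_idx, loss, margin):
    """Loss value and gradients for one batch of paired positives/negatives.

    ``pos_idx`` / ``neg_idx`` are (h, r, t) integer-array triplets; under
    the pairwise loss the two must be the same length (negative *i* is
    paired with positive *i*).  Returns the summed loss and dense gradient
    arrays matching ``arrays``.
    """
    ph, pr, pt = pos_idx
    nh, nr, nt = neg_idx
    pos_s, pos_cache = _scores_and_cache(arrays, model, norm_kind, ph, pr, pt)
    neg_s, neg_cache = _scores_and_cache(arrays, model, norm_kind, nh, nr, nt)
    grads = {k: np.zeros_like(v) for k, v in arrays.items()}

    if loss == "pairwise":
        if pos_s.shape != neg_s.shape:
            raise ValueError("pairwise loss requires one negative per positive")
        active = (margin - pos_s + neg_s) > 0
        value = float(np.where(active, margin - pos_s + neg_s, 0.0).sum())
        dpos = np.where(active, -1.0, 0.0)
        dneg = np.where(active, 1.0, 0.0)
    else:
        # logistic: dL/ds = -l * sigmoid(-l * s)
        value = float(_softplus(-pos_s).sum() + _softplus(neg_s).sum())
        dpos = -1.0 / (1.0 + np.exp(pos_s))   # l = +1
        dneg = 1.0 / (1.0 + np.exp(-neg_s))   # l = -1

    _backprop(grads, arrays, model, norm_kind, ph, pr, pt, pos_cache, dpos)
    _backprop(grads, arrays, model, norm_kind, nh, nr, nt, neg_cache, dneg)
    return value, grads


def loss_and_grads(
    embeddings: EmbeddingSet,
    positives: Sequence[Triple],
    negatives: Sequence[Triple],
    loss: str,
    margin: float = 1.0,
) -> tuple[float, dict[str, np.ndarray]]:
    """Summed batch loss and its analytic gradient w.r.t. every embedding.

    Exposed so the gradients can be checked against finite differences.
    """
    ent_idx, rel_idx = embeddings.entity_index, embeddings.relation_index

    def to_idx(triples):
        h = np.array([ent_idx[t.head] for t in triples], dtype=int)
        r = np.array([rel_idx[t.relation] for t in triples], dtype=int)
        tt = np.array([ent_idx[t.tail] for t in triples], dtype=int)
        return h, r, tt

    return _batch_loss_grads(
        embeddings.arrays, embeddings.model, embeddings.norm_kind,
        to_idx(positives), to_idx(negatives), loss, margin,
    )


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _ins_alternative_table(kg: KnowledgeGraph) -> np.ndarray:
    """For each relation index, the indices of the two type-flipped relations.

    Requires every environment used by the graph's relations to carry all
    three interaction types in the relation vocabulary (full_grid mode).
    """
    rel_idx = kg.relation_index
    table = np.empty((len(kg.relations), 2), dtype=int)
    for i, rel in enumerate(kg.relations):
        alts = []
        for itype in INTERACTION_TYPES:
            if itype == rel.itype:
                continue
            alt = Relation(itype, rel.environment)
            if alt not in rel_idx:
                raise ValueError(
                    f"interaction-based negative sampling needs relation {alt} "
                    "in the vocabulary; rebuild the graph with "
                    "vocabulary_mode='full_grid'"
                )
            alts.append(rel_idx[alt])
        table[i] = alts
    return table


def train(train_kg: KnowledgeGraph, config: TrainConfig) -> TrainedModel:
    """Mini-batch SGD training of an embedding model on a knowledge graph.

    Per epoch the triples are shuffled and cut into batches; for each batch
    a negative batch is drawn with the configured corruption scheme
    (``negatives_per_positive`` each), the configured loss is computed over
    the union, and all referenced embeddings take one SGD step with the
    batch-mean gradient.  Fully reproducible under ``config.seed``.
    """
    if len(train_kg.triples) == 0:
        raise ValueError("cannot train on an empty knowledge graph")

    ss = np.random.SeedSequence(config.seed)
    init_ss, sample_ss = ss.spawn(2)
    embeddings = init_embeddings(
        train_kg.entities, train_kg.relations, config.model, config.dim,
        seed=np.random.default_rng(init_ss), norm_kind=config.norm_kind,
    )
    rng = np.random.default_rng(sample_ss)
    arrays = embeddings.arrays

    ent_idx, rel_idx = train_kg.entity_index, train_kg.relation_index
    H = np.array([ent_idx[t.head] for t in train_kg.triples], dtype=int)
    R = np.array([rel_idx[t.relation] for t in train_kg.triples], dtype=int)
    T = np.array([ent_idx[t.tail] for t in train_kg.triples], dtype=int)
    n_triples, n_ent = len(H), len(train_kg.entities)
    if config.ns_strategy == "classical_head_tail" and n_ent < 2:
        raise ValueError("classical corruption needs at least two entities")
    ins_table = (
        _ins_alternative_table(train_kg)
        if config.ns_strategy == "interaction_based" else None
    )
    npp = config.negatives_per_positive

    loss_history: list[float] = []
    for _ in range(config.epochs):
        perm = rng.permutation(n_triples)
        batch_means: list[float] = []
        for start in range(0, n_triples, config.batch_size):
            sel = perm[start: start + config.batch_size]
            ph, pr, pt = H[sel], R[sel], T[sel]
            # negatives: each positive repeated npp times, paired in order
            rh = np.repeat(ph, npp)
            rr = np.repeat(pr, npp)
            rt = np.repeat(pt, npp)
            if ins_table is not None:
                nr = ins_table[rr, rng.integers(0, 2, size=rr.size)]
                nh, nt = rh, rt
            else:
                corrupt_head = rng.random(rh.size) < 0.5
                draw = rng.integers(0, n_ent - 1, size=rh.size)
                orig = np.where(corrupt_head, rh, rt)
                draw = draw + (draw >= orig)
                nh = np.where(corrupt_head, draw, rh)
                nt = np.where(corrupt_head, rt, draw)
                nr = rr
            if config.model is ModelKind.TRANSE and config.transe_normalize:
                norms = np.linalg.norm(arrays["ent"], axis=1, keepdims=True)
                np.divide(arrays["ent"], norms, out=arrays["ent"])

            if config.loss == "pairwise":
                pos_idx = (rh, rr, rt)  # tiled to pair with each negative
            else:
                pos_idx = (ph, pr, pt)
            value, grads = _batch_loss_grads(
                arrays, config.model, config.norm_kind,
                pos_idx, (nh, nr, nt), config.loss, config.margin,
            )
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss ({value}) at epoch {len(loss_history)}; "
                    "reduce the learning rate"
                )
            scale = config.learning_rate / sel.size
            for name, g in grads.items():
                if config.l2_reg > 0:
                    touched = np.abs(g).sum(axis=1) > 0
                    g[touched] += config.l2_reg * arrays[name][touched]
                arrays[name] -= scale * g
            batch_means.append(value / sel.size)
        loss_history.append(float(np.mean(batch_means)))

    return TrainedModel(embeddings=embeddings, config=config,
                        loss_history=loss_history)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

#: default hyperparameter grid covering the cited models' conventional ranges
DEFAULT_GRID = {
    "dim": [16, 32, 64, 100],
    "learning_rate": [0.01, 0.05, 0.1],
    "margin": [1.0, 2.0],
    "batch_size": [128, 512],
}


def grid_search(
    train_kg: KnowledgeGraph,
    valid_kg: KnowledgeGraph,
    grid: dict[str, Sequence],
    base_config: Optional[TrainConfig] = None,
):
    """Exhaustive hyperparameter search scored by validation accuracy.

    Trains one model per grid point (the Cartesian product of the candidate
    lists, enumerated in key order) and scores each by interaction-type
    classification accuracy on the validation graph.  Returns the argmax
    config (first in enumeration order on ties) and the full results table.
    """
    from .evaluation import evaluate_classification  # late import: module cycle

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must map config fields to non-empty candidate lists")
    if len(valid_kg.triples) == 0:
        raise ValueError("validation set must be non-empty")
    base = base_config or TrainConfig()

    import pandas as pd

    keys = list(grid)
    rows = []
    best: tuple[float, int, TrainConfig] | None = None
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        cfg = replace(base, **dict(zip(keys, combo)))
        model = train(train_kg, cfg)
        acc = evaluate_classification(model, valid_kg).accuracy
        rows.append({**dict(zip(keys, combo)), "accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, i, cfg)
    table = pd.DataFrame(rows)
    return best[2], table
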