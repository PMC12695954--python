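"""Classification and ranking evaluation, null-model baselines, entropy.

Interaction-type prediction treats each test triple as a three-way
classification problem: score the triple under each candidate interaction
type for its environment and pick the argmax.  Link-prediction quality is
measured by raw mean reciprocal rank (MRR) and Hits@k over head- and
tail-side entity substitutions.  Five majority-class null models (global,
per-environment, per-receiver, per-sender, per-pair) calibrate how much of
the signal is explainable by simple frequency structure, and the Shannon
entropy of the label distribution summarizes class imbalance as an
effective number of interaction types ``2^H``.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kg import INTERACTION_TYPES, InteractionType, KnowledgeGraph, Relation, Triple
from .models import ModelKind, score_triple
from .training import TrainedModel

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "NullModelKind",
    "NullModel",
    "classify_interaction",
    "classification_metrics",
    "evaluate_classification",
    "rank_triple",
    "mrr_hits",
    "null_model_predict",
    "entropy",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 grid of counts, true class (rows) by predicted class (columns).

    Rows and columns follow the canonical type order Negative, Neutral,
    Positive.
    """

    counts: np.ndarray
    classes: tuple[InteractionType, ...] = INTERACTION_TYPES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (3, 3) or np.any(counts < 0):
            raise ValueError("confusion counts must be a nonnegative 3x3 grid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd
        labels = [c.label for c in self.classes]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass
class Metrics:
    """Classification and/or ranking results.

    Classification fields are populated by :func:`classification_metrics`;
    ranking fields (``mrr``, ``hits_at``) by :func:`mrr_hits`.
    """

    accuracy: Optional[float] = None
    precision: dict[InteractionType, float] = field(default_factory=dict)
    recall: dict[InteractionType, float] = field(default_factory=dict)
    f1: dict[InteractionType, float] = field(default_factory=dict)
    macro_f1: Optional[float] = None
    confusion: Optional[ConfusionMatrix] = None
    mrr: Optional[float] = None
    hits_at: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.accuracy is not None:
            out["accuracy"] = self.accuracy
            out["precision"] = {k.label: v for k, v in self.precision.items()}
            out["recall"] = {k.label: v for k, v in self.recall.items()}
            out["f1"] = {k.label: v for k, v in self.f1.items()}
            out["macro_f1"] = self.macro_f1
            out["confusion"] = self.confusion.counts.tolist()
        if self.mrr is not None:
            out["mrr"] = self.mrr
            out["hits_at"] = {str(k): v for k, v in self.hits_at.items()}
        return out


def classify_interaction(
    model: TrainedModel, sender: str, receiver: str, environment: str
) -> tuple[InteractionType, dict[InteractionType, float]]:
    """Predict the interaction type for a (sender, receiver, environment).

    Scores the triple under each candidate relation ``(I, environment)``
    present in the model's relation vocabulary and returns the argmax type
    (ties broken by canonical order) together with the per-type scores.
    """
    rel_index = model.relation_index
    scores: dict[InteractionType, float] = {}
    for itype in INTERACTION_TYPES:
        rel = Relation(itype, environment)
        if rel in rel_index:
            scores[itype] = score_triple(
                model.embeddings, Triple(sender, rel, receiver)
            )
    if not scores:
        raise ValueError(
            f"no candidate relation for environment {environment!r} in the model"
        )
    best = max(scores, key=lambda it: (scores[it], -int(it)))
    return best, scores


def classification_metrics(
    predictions: Sequence[InteractionType], truths: Sequence[InteractionType]
) -> Metrics:
    """Accuracy, per-class one-vs-rest precision/recall/F1, and confusion.

    Zero-denominator precision/recall (a class never predicted, or absent
    from the truths) is reported as 0 with a warning.
    """
    if len(predictions) != len(truths) or len(truths) == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    counts = np.zeros((3, 3), dtype=int)
    for p, t in zip(predictions, truths):
        counts[int(t), int(p)] += 1
    confusion = ConfusionMatrix(counts)

    metrics = Metrics(confusion=confusion)
    metrics.accuracy = float(np.trace(counts)) / counts.sum()
    f1s = []
    for itype in INTERACTION_TYPES:
        i = int(itype)
        tp = counts[i, i]
        predicted = counts[:, i].sum()
        actual = counts[i, :].sum()
        if predicted == 0:
            warnings.warn(f"class {itype.label} never predicted; precision set to 0")
        if actual == 0:
            warnings.warn(f"class {itype.label} absent from truths; recall set to 0")
        prec = tp / predicted if predicted else 0.0
        rec = tp / actual if actual else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        metrics.precision[itype] = float(prec)
        metrics.recall[itype] = float(rec)
        metrics.f1[itype] = float(f1)
        f1s.append(f1)
    metrics.macro_f1 = float(np.mean(f1s))
    return metrics


def evaluate_classification(model: TrainedModel, kg: KnowledgeGraph) -> Metrics:
    """Classify every triple of ``kg`` and compare against its true type."""
    preds, truths = [], []
    for t in kg.triples:
        pred, _ = classify_interaction(model, t.head, t.tail, t.relation.environment)
        preds.append(pred)
        truths.append(t.relation.itype)
    return classification_metrics(preds, truths)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _candidate_scores(model: TrainedModel, triple: Triple, side: str) -> np.ndarray:
    emb = model.embeddings
    ents = emb.entity_ids
    if side == "head":
        return np.array([
            score_triple(emb, Triple(e, triple.relation, triple.tail)) for e in ents
        ])
    if side == "tail":
        return np.array([
            score_triple(emb, Triple(triple.head, triple.relation, e)) for e in ents
        ])
    raise ValueError(f"side must be 'head' or 'tail', got {side!r}")


def rank_triple(
    model: TrainedModel,
    triple: Triple,
    side: str,
    filtered: bool = False,
    known_kg: Optional[KnowledgeGraph] = None,
) -> float:
    """Raw rank of the true triple among all entity substitutions on one side.

    The true triple competes against all ``|E|`` candidates (itself
    included); score ties receive the mean rank of the tied block, which
    avoids optimistic bias for untrained (near-constant) scorers.  With
    ``filtered=True`` candidates forming other known true triples of
    ``known_kg`` are excluded from the competition.
    """
    emb = model.embeddings
    if triple.head not in emb.entity_index or triple.tail not in emb.entity_index:
        raise KeyError(f"triple {triple} references an unknown entity")
    if triple.relation not in emb.relation_index:
        raise KeyError(f"unknown relation {str(triple.relation)!r}")
    scores = _candidate_scores(model, triple, side)
    own_idx = emb.entity_index[triple.head if side == "head" else triple.tail]
    own = scores[own_idx]
    keep = np.ones(len(scores), dtype=bool)
    if filtered:
        if known_kg is None:
            raise ValueError("filtered ranking requires known_kg")
        known = set(known_kg.triples)
        for i, e in enumerate(emb.entity_ids):
            if i == own_idx:
                continue
            cand = (
                Triple(e, triple.relation, triple.tail)
                if side == "head" else Triple(triple.head, triple.relation, e)
            )
            if cand in known:
                keep[i] = False
    others = scores[keep & (np.arange(len(scores)) != own_idx)]
    better = int(np.sum(others > own))
    ties = int(np.sum(others == own))
    return 1.0 + better + ties / 2.0


def mrr_hits(
    model: TrainedModel,
    test_kg: KnowledgeGraph,
    ks: Sequence[int] = (1, 3, 10),
    filtered: bool = False,
    known_kg: Optional[KnowledgeGraph] = None,
) -> Metrics:
    """Mean reciprocal rank and Hits@k over head- and tail-side ranks.

    Both sides of every test triple contribute, so the average runs over
    ``2N`` ranks for ``N`` test triples.
    """
    if len(test_kg.triples) == 0:
        raise ValueError("test set must be non-empty")
    ranks = []
    for t in test_kg.triples:
        for side in ("head", "tail"):
            ranks.append(rank_triple(model, t, side, filtered, known_kg))
    ranks_arr = np.array(ranks)
    metrics = Metrics()
    metrics.mrr = float(np.mean(1.0 / ranks_arr))
    metrics.hits_at = {int(k): float(np.mean(ranks_arr <= k)) for k in ks}
    return metrics


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

class NullModelKind(str, enum.Enum):
    """Majority-class baselines of increasing conditioning specificity."""

    A_GLOBAL = "A_global_majority"
    B_ENVIRONMENT = "B_environment_majority"
    C_RECEIVER = "C_receiver_majority"
    D_SENDER = "D_sender_majority"
    E_PAIR = "E_pair_majority"


def _majority(counter: Counter) -> InteractionType:
    # ties broken by canonical order (Negative < Neutral < Positive)
    return max(INTERACTION_TYPES, key=lambda it: (counter.get(it, 0), -int(it)))


@dataclass
class NullModel:
    """A fitted majority-class baseline.

    Predicts the most frequent training label within the conditioning
    stratum (nothing, the environment, the receiver, the sender, or the
    ordered pair); unseen strata fall back to the global majority.
    """

    kind: NullModelKind
    _global: InteractionType = InteractionType.NEGATIVE
    _strata: dict = field(default_factory=dict)

    def fit(self, train_kg: KnowledgeGraph) -> "NullModel":
        if len(train_kg.triples) == 0:
            raise ValueError("cannot fit a null model on an empty graph")
        global_counts: Counter = Counter()
        strata: dict = defaultdict(Counter)
        for t in train_kg.triples:
            label = t.relation.itype
            global_counts[label] += 1
            strata[self._stratum(t.head, t.tail, t.relation.environment)][label] += 1
        self._global = _majority(global_counts)
        self._strata = {k: _majority(v) for k, v in strata.items()}
        return self

    def _stratum(self, sender: str, receiver: str, environment: str):
        kind = NullModelKind(self.kind)
        if kind is NullModelKind.A_GLOBAL:
            return ()
        if kind is NullModelKind.B_ENVIRONMENT:
            return (environment,)
        if kind is NullModelKind.C_RECEIVER:
            return (receiver,)
        if kind is NullModelKind.D_SENDER:
            return (sender,)
        return (sender, receiver)

    def predict(self, sender: str, receiver: str, environment: str) -> InteractionType:
        return self._strata.get(
            self._stratum(sender, receiver, environment), self._global
        )

    def accuracy(self, kg: KnowledgeGraph) -> float:
        if len(kg.triples) == 0:
            raise ValueError("evaluation set must be non-empty")
        hits = sum(
            self.predict(t.head, t.tail, t.relation.environment) == t.relation.itype
            for t in kg.triples
        )
        return hits / len(kg.triples)


def null_model_predict(
    kind: "NullModelKind | str",
    train_kg: KnowledgeGraph,
    query: tuple[str, str, str],
) -> InteractionType:
    """One-shot null-model prediction for a (sender, receiver, environment)."""
    model = NullModel(NullModelKind(kind)).fit(train_kg)
    return model.predict(*query)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def entropy(class_counts: Sequence[float]) -> tuple[float, float]:
    """Shannon entropy (bits) of a label distribution and ``2^H``.

    ``2^H`` is the effective number of interaction types: 1 when one class
    dominates completely, 3 for a uniform three-class distribution.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("at least one class count must be positive")
    p = counts / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h, float(2.0 ** h)
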