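"""Embedding-consuming inference: unseen strains, environment transfer, recommendation.

Three procedures reuse a trained embedding model beyond plain triple
classification:

- **Unseen-strain prediction** — a strain absent from the graph gets a
  *synthetic embedding*: the convex combination of the embeddings of its
  ``k`` phylogenetically nearest in-graph strains, weighted by
  ``w_j = 1 / (1 + d_j)`` (normalized to unit sum), where ``d_j`` is the
  Euclidean distance in the phylogenetic feature space.  The synthetic
  embedding substitutes for the missing strain in the scoring function.
- **Environment-similarity rule** — each environment is represented by the
  concatenation of its three relation vectors (Negative | Neutral |
  Positive order); the interaction of a strain pair in one environment is
  predicted by copying the observed label of the same pair in the nearest
  environment that has one, walking down the similarity ranking on misses.
- **Recommendation** — candidate strains are ranked by the score of the
  query triple ``(candidate, (I, e), target)`` (or the reversed direction),
  answering "which strain is most likely to inhibit/promote the target in
  this environment".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kg import INTERACTION_TYPES, InteractionType, KnowledgeGraph, Relation, Triple
from .models import EmbeddingSet, ModelKind, score_distmult, score_simple, score_transe
from .phylo import PhyloFeatures
from .training import TrainedModel

__all__ = [
    "EnvironmentEmbedding",
    "Recommendation",
    "synthetic_embedding",
    "predict_unseen",
    "environment_embedding",
    "environment_distance",
    "environment_rule_predict",
    "recommend",
    "environment_distance_matrix",
    "strain_distance_matrix",
]


@dataclass(frozen=True)
class EnvironmentEmbedding:
    """Concatenated relation vectors representing one environment.

    Length ``3d`` for single-relation-vector models; ``6d`` for SimplE,
    where each type block is the concatenation of the forward and inverse
    relation vectors.
    """

    environment_id: str
    vector: np.ndarray


@dataclass(frozen=True)
class Recommendation:
    """Candidates ranked by descending query score, with min-max normalization."""

    candidates: tuple[str, ...]
    scores: tuple[float, ...]
    normalized_scores: tuple[float, ...]

    @property
    def best(self) -> str:
        return self.candidates[0]


# ---------------------------------------------------------------------------
# unseen-strain prediction
# ---------------------------------------------------------------------------

def _entity_roles(model_kind: ModelKind) -> tuple[str, ...]:
    return ("ent_head", "ent_tail") if model_kind is ModelKind.SIMPLE else ("ent",)


def synthetic_embedding(
    model: TrainedModel,
    features: PhyloFeatures,
    target: str,
    k: int = 5,
) -> dict[str, np.ndarray]:
    """Distance-weighted neighbour average standing in for an unseen strain.

    Selects the ``k`` in-graph strains with coordinates closest to the
    target (ties by canonical strain order), weights them by
    ``1 / (1 + distance)``, renormalizes the weights to sum to 1, and
    averages each embedding role independently.  Returns a mapping from
    role name (``ent``, or ``ent_head``/``ent_tail`` for SimplE) to vector.
    """
    emb = model.embeddings
    if target in emb.entity_index:
        raise ValueError(f"strain {target!r} is already in the graph; not unseen")
    target_vec = features.vector(target)
    available = [s for s in emb.entity_ids if s in features.index]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k!r}")
    if k > len(available):
        raise ValueError(
            f"k={k} exceeds the {len(available)} in-graph strains with coordinates"
        )
    dists = {s: float(np.linalg.norm(features.vector(s) - target_vec))
             for s in available}
    neighbours = sorted(available, key=lambda s: (dists[s], s))[:k]
    weights = np.array([1.0 / (1.0 + dists[s]) for s in neighbours])
    weights = weights / weights.sum()
    out: dict[str, np.ndarray] = {}
    for role in _entity_roles(emb.model):
        rows = np.stack([emb.arrays[role][emb.entity_index[s]] for s in neighbours])
        out[role] = weights @ rows
    return out


def _score_with_substitute(
    emb: EmbeddingSet,
    head: "str | dict[str, np.ndarray]",
    relation: Relation,
    tail: "str | dict[str, np.ndarray]",
) -> float:
    """Score a triple where head or tail may be a role->vector mapping."""
    ri = emb.relation_index[relation]

    def role_vec(side, role: str) -> np.ndarray:
        if isinstance(side, dict):
            return side[role]
        return emb.arrays[role][emb.entity_index[side]]

    if emb.model is ModelKind.TRANSE:
        return score_transe(role_vec(head, "ent"), emb.arrays["rel"][ri],
                            role_vec(tail, "ent"), emb.norm_kind)
    if emb.model is ModelKind.DISTMULT:
        return score_distmult(role_vec(head, "ent"), emb.arrays["rel"][ri],
                              role_vec(tail, "ent"))
    return score_simple(
        role_vec(head, "ent_head"), role_vec(head, "ent_tail"),
        role_vec(tail, "ent_head"), role_vec(tail, "ent_tail"),
        emb.arrays["rel"][ri], emb.arrays["rel_inv"][ri],
    )


def predict_unseen(
    model: TrainedModel,
    features: PhyloFeatures,
    target: str,
    queries: Sequence[tuple[str, str, str]],
    k: int = 5,
    neighbours: Optional[Sequence[str]] = None,
) -> list[InteractionType]:
    """Interaction-type predictions for an out-of-graph target strain.

    Each query is ``(partner, environment, direction)`` with direction
    ``'sender'`` (the target affects the partner) or ``'receiver'`` (the
    partner affects the target).  The target's synthetic embedding is
    substituted on the queried side and the highest-scoring interaction
    type is returned per query.  ``neighbours`` overrides the
    phylogenetic neighbour selection (used for random-neighbour
    baselines); the override is aggregated with uniform weights.
    """
    emb = model.embeddings
    if neighbours is None:
        synth = synthetic_embedding(model, features, target, k)
    else:
        if target in emb.entity_index:
            raise ValueError(f"strain {target!r} is already in the graph; not unseen")
        synth = {}
        for role in _entity_roles(emb.model):
            rows = np.stack(
                [emb.arrays[role][emb.entity_index[s]] for s in neighbours]
            )
            synth[role] = rows.mean(axis=0)

    predictions: list[InteractionType] = []
    for partner, environment, direction in queries:
        if partner not in emb.entity_index:
            raise KeyError(f"unknown partner strain {partner!r}")
        if direction not in ("sender", "receiver"):
            raise ValueError(f"direction must be 'sender' or 'receiver', got {direction!r}")
        scores: dict[InteractionType, float] = {}
        for itype in INTERACTION_TYPES:
            rel = Relation(itype, environment)
            if rel not in emb.relation_index:
                continue
            if direction == "sender":
                scores[itype] = _score_with_substitute(emb, synth, rel, partner)
            else:
                scores[itype] = _score_with_substitute(emb, partner, rel, synth)
        if not scores:
            raise ValueError(f"no candidate relation for environment {environment!r}")
        predictions.append(max(scores, key=lambda it: (scores[it], -int(it))))
    return predictions


# ---------------------------------------------------------------------------
# environment similarity
# ---------------------------------------------------------------------------

def environment_embedding(model: TrainedModel, environment: str) -> EnvironmentEmbedding:
    """Concatenation of the environment's three relation vectors.

    Requires all three interaction-type relations for the environment in
    the model's vocabulary; environments with a missing type are excluded
    from similarity analyses.
    """
    emb = model.embeddings
    blocks: list[np.ndarray] = []
    for itype in INTERACTION_TYPES:
        rel = Relation(itype, environment)
        if rel not in emb.relation_index:
            raise ValueError(
                f"incomplete environment {environment!r}: relation {rel} missing"
            )
        ri = emb.relation_index[rel]
        blocks.append(emb.arrays["rel"][ri])
        if emb.model is ModelKind.SIMPLE:
            blocks.append(emb.arrays["rel_inv"][ri])
    return EnvironmentEmbedding(environment, np.concatenate(blocks))


def environment_distance(v1, v2, metric: str = "euclidean") -> float:
    """Euclidean or cosine distance between environment vectors."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vectors must have equal length, got {a.shape} vs {b.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("cosine distance is undefined for zero vectors")
        return float(1.0 - float(a @ b) / (na * nb))
    raise ValueError(f"metric must be 'euclidean' or 'cosine', got {metric!r}")


def _complete_environments(model: TrainedModel) -> list[str]:
    rel_index = model.relation_index
    envs = sorted({r.environment for r in model.embeddings.relation_ids})
    return [
        e for e in envs
        if all(Relation(it, e) in rel_index for it in INTERACTION_TYPES)
    ]


def environment_rule_predict(
    model: TrainedModel,
    reference_kg: KnowledgeGraph,
    query: tuple[str, str, str],
    metric: str = "euclidean",
    max_distance: Optional[float] = None,
) -> tuple[InteractionType, str, float]:
    """Copy the pair's observed label from the most similar environment.

    Ranks all other complete environments by ascending embedding distance
    to the query environment (ties by environment name) and returns the
    label of the first one containing an observed ``sender -> receiver``
    triple in ``reference_kg``, together with the donor environment and its
    distance.  Donors beyond ``max_distance`` are skipped.
    """
    sender, receiver, environment = query
    query_vec = environment_embedding(model, environment).vector

    observed: dict[str, InteractionType] = {}
    for t in reference_kg.triples:
        if t.head == sender and t.tail == receiver:
            observed[t.relation.environment] = t.relation.itype

    ranked = []
    for env in _complete_environments(model):
        if env == environment:
            continue
        d = environment_distance(
            query_vec, environment_embedding(model, env).vector, metric
        )
        if max_distance is not None and d > max_distance:
            continue
        ranked.append((d, env))
    ranked.sort()
    for d, env in ranked:
        if env in observed:
            return observed[env], env, d
    raise LookupError(
        f"no donor observation for pair ({sender!r}, {receiver!r}) within reach "
        f"of environment {environment!r}"
    )


def environment_distance_matrix(model: TrainedModel, metric: str = "euclidean"):
    """Distances between all complete environments, as a labelled DataFrame."""
    import pandas as pd

    envs = _complete_environments(model)
    vecs = {e: environment_embedding(model, e).vector for e in envs}
    mat = np.zeros((len(envs), len(envs)))
    for i, a in enumerate(envs):
        for j, b in enumerate(envs):
            if i < j:
                mat[i, j] = mat[j, i] = environment_distance(vecs[a], vecs[b], metric)
    return pd.DataFrame(mat, index=envs, columns=envs)


def strain_distance_matrix(model: TrainedModel):
    """Euclidean distances between strain analysis vectors (SimplE: head|tail)."""
    import pandas as pd

    emb = model.embeddings
    ids = list(emb.entity_ids)
    vecs = np.stack([emb.entity_analysis_vector(s) for s in ids])
    diff = vecs[:, None, :] - vecs[None, :, :]
    mat = np.linalg.norm(diff, axis=2)
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# recommendation
# ---------------------------------------------------------------------------

def recommend(
    model: TrainedModel,
    target: str,
    interaction: InteractionType,
    environment: str,
    candidates: Sequence[str],
    direction: str = "candidates_affect_target",
) -> Recommendation:
    """Rank candidate strains by their likelihood of a desired interaction.

    ``candidates_affect_target`` scores ``(candidate, (I, e), target)``;
    ``target_affects_candidates`` scores the reversed triple.  Candidates
    are sorted by descending score (ties by canonical strain order) and
    min-max normalized within the candidate set (constant scores map to 1).
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if target in candidates:
        raise ValueError(f"target {target!r} must not be among the candidates")
    if direction not in ("candidates_affect_target", "target_affects_candidates"):
        raise ValueError(f"unknown direction {direction!r}")
    rel = Relation(interaction, environment)
    emb = model.embeddings
    if rel not in emb.relation_index:
        raise KeyError(f"relation {rel} not in the model's vocabulary")

    from .models import score_triple

    scored = []
    for c in candidates:
        triple = (
            Triple(c, rel, target) if direction == "candidates_affect_target"
            else Triple(target, rel, c)
        )
        scored.append((c, score_triple(emb, triple)))
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    names = tuple(c for c, _ in scored)
    scores = tuple(s for _, s in scored)
    lo, hi = min(scores), max(scores)
    if hi == lo:
        normalized = tuple(1.0 for _ in scores)
    else:
        normalized = tuple((s - lo) / (hi - lo) for s in scores)
    return Recommendation(names, scores, normalized)
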