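"""Embedding parameter containers and scoring functions.

Three classical knowledge-graph embedding models are implemented:

- **TransE** — relations are translations; the score of a triple is the
  negated norm ``-||h + r - t||`` (L1 or L2), so 0 is the best possible
  score, attained when the translation is exact.
- **DistMult** — a diagonal bilinear model; the score is the trilinear
  product ``sum_i h_i r_i t_i``.  It is symmetric in head and tail, which
  is its well-known limitation on directed relations.
- **SimplE** — each entity carries a head-role and a tail-role vector and
  each relation a forward and an inverse vector; the score is the mean of
  two trilinear terms, ``(⟨h_h, r, t_t⟩ + ⟨h_t, r_inv, t_h⟩) / 2``, which
  restores the ability to model asymmetric relations.

All scores are computed in double precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kg import Relation, Triple

__all__ = [
    "ModelKind",
    "EmbeddingSet",
    "init_embeddings",
    "score_transe",
    "score_distmult",
    "score_simple",
    "score_triple",
]


class ModelKind(str, enum.Enum):
    TRANSE = "transe"
    DISTMULT = "distmult"
    SIMPLE = "simple"

    @classmethod
    def parse(cls, text: "str | ModelKind") -> "ModelKind":
        if isinstance(text, ModelKind):
            return text
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown model kind {text!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: array names per model; entity arrays first, relation arrays second
_LAYOUT = {
    ModelKind.TRANSE: (("ent",), ("rel",)),
    ModelKind.DISTMULT: (("ent",), ("rel",)),
    ModelKind.SIMPLE: (("ent_head", "ent_tail"), ("rel", "rel_inv")),
}


@dataclass
class EmbeddingSet:
    """Learned vectors for the entities and relations of a knowledge graph.

    The arrays present depend on the model: TransE and DistMult keep one
    matrix per entity set and relation set (``ent``, ``rel``); SimplE keeps
    two of each (``ent_head``/``ent_tail``, ``rel``/``rel_inv``).  Row *i*
    of an entity array is the vector of ``entity_ids[i]``; likewise for
    relations.
    """

    model: ModelKind
    dim: int
    entity_ids: tuple[str, ...]
    relation_ids: tuple[Relation, ...]
    arrays: dict[str, np.ndarray]
    norm_kind: str = "l2"  # TransE only

    def __post_init__(self) -> None:
        self.model = ModelKind.parse(self.model)
        if self.dim <= 0:
            raise ValueError(f"dim must be positive, got {self.dim!r}")
        if self.norm_kind not in ("l1", "l2"):
            raise ValueError(f"norm_kind must be 'l1' or 'l2', got {self.norm_kind!r}")
        ent_names, rel_names = _LAYOUT[self.model]
        expected = set(ent_names) | set(rel_names)
        if set(self.arrays) != expected:
            raise ValueError(
                f"model {self.model.value} expects arrays {sorted(expected)}, "
                f"got {sorted(self.arrays)}"
            )
        for name in ent_names:
            self._check_shape(name, len(self.entity_ids))
        for name in rel_names:
            self._check_shape(name, len(self.relation_ids))

    def _check_shape(self, name: str, n_rows: int) -> None:
        a = self.arrays[name]
        if a.shape != (n_rows, self.dim):
            raise ValueError(
                f"array {name!r} must have shape ({n_rows}, {self.dim}), got {a.shape}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError(f"array {name!r} contains non-finite values")

    @property
    def entity_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def relation_index(self) -> dict[Relation, int]:
        return {r: i for i, r in enumerate(self.relation_ids)}

    def copy(self) -> "EmbeddingSet":
        return EmbeddingSet(
            self.model, self.dim, self.entity_ids, self.relation_ids,
            {k: v.copy() for k, v in self.arrays.items()}, self.norm_kind,
        )

    def entity_analysis_vector(self, strain: str) -> np.ndarray:
        """Single analysis vector per strain (SimplE: head-role | tail-role)."""
        i = self.entity_index[strain]
        if self.model is ModelKind.SIMPLE:
            return np.concatenate(
                [self.arrays["ent_head"][i], self.arrays["ent_tail"][i]]
            )
        return self.arrays["ent"][i].copy()


def init_embeddings(
    entity_ids: Sequence[str],
    relation_ids: Sequence[Relation],
    model: "str | ModelKind",
    dim: int,
    seed: "int | np.random.Generator" = 0,
    norm_kind: str = "l2",
) -> EmbeddingSet:
    """Random initialization, uniform on ``[-6/sqrt(d), +6/sqrt(d)]``.

    TransE entity vectors are additionally L2-normalized at initialization,
    matching the original translational-model recipe.  Reproducible under a
    fixed seed.
    """
    model = ModelKind.parse(model)
    if dim <= 0:
        raise ValueError(f"dim must be a positive integer, got {dim!r}")
    if len(entity_ids) <= 0 or len(relation_ids) <= 0:
        raise ValueError("entity and relation sets must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bound = 6.0 / np.sqrt(dim)
    ent_names, rel_names = _LAYOUT[model]
    arrays: dict[str, np.ndarray] = {}
    for name in ent_names:
        arrays[name] = rng.uniform(-bound, bound, size=(len(entity_ids), dim))
    for name in rel_names:
        arrays[name] = rng.uniform(-bound, bound, size=(len(relation_ids), dim))
    if model is ModelKind.TRANSE:
        norms = np.linalg.norm(arrays["ent"], axis=1, keepdims=True)
        arrays["ent"] = arrays["ent"] / norms
    return EmbeddingSet(model, dim, tuple(entity_ids), tuple(relation_ids),
                        arrays, norm_kind)


def _as_vectors(*vecs: Sequence[float]) -> list[np.ndarray]:
    out = [np.asarray(v, dtype=float) for v in vecs]
    lengths = {v.shape for v in out}
    if len(lengths) != 1 or out[0].ndim != 1:
        raise ValueError(f"vectors must be 1-D and of equal length, got shapes {lengths}")
    return out


def score_transe(h, r, t, norm_kind: str = "l2") -> float:
    """Translational score ``-||h + r - t||``; always <= 0."""
    h, r, t = _as_vectors(h, r, t)
    diff = h + r - t
    if norm_kind == "l2":
        return float(-np.linalg.norm(diff))
    if norm_kind == "l1":
        return float(-np.abs(diff).sum())
    raise ValueError(f"norm_kind must be 'l1' or 'l2', got {norm_kind!r}")


def score_distmult(h, r, t) -> float:
    """Trilinear score ``sum_i h_i r_i t_i`` (symmetric in h and t)."""
    h, r, t = _as_vectors(h, r, t)
    return float(np.sum(h * r * t))


def score_simple(h_head, h_tail, t_head, t_tail, r, r_inv) -> float:
    """Mean of the forward and inverse trilinear terms."""
    h_head, h_tail, t_head, t_tail, r, r_inv = _as_vectors(
        h_head, h_tail, t_head, t_tail, r, r_inv
    )
    return 0.5 * (float(np.sum(h_head * r * t_tail)) + float(np.sum(h_tail * r_inv * t_head)))


def score_triple(embeddings: EmbeddingSet, triple: Triple) -> float:
    """Score a triple under the embedding set's model, resolving index maps."""
    ent_idx = embeddings.entity_index
    rel_idx = embeddings.relation_index
    try:
        hi = ent_idx[triple.head]
    except KeyError:
        raise KeyError(f"unknown entity {triple.head!r}") from None
    try:
        ti = ent_idx[triple.tail]
    except KeyError:
        raise KeyError(f"unknown entity {triple.tail!r}") from None
    try:
        ri = rel_idx[triple.relation]
    except KeyError:
        raise KeyError(f"unknown relation {str(triple.relation)!r}") from None

    a = embeddings.arrays
    if embeddings.model is ModelKind.TRANSE:
        return score_transe(a["ent"][hi], a["rel"][ri], a["ent"][ti],
                            embeddings.norm_kind)
    if embeddings.model is ModelKind.DISTMULT:
        return score_distmult(a["ent"][hi], a["rel"][ri], a["ent"][ti])
    return score_simple(
        a["ent_head"][hi], a["ent_tail"][hi],
        a["ent_head"][ti], a["ent_tail"][ti],
        a["rel"][ri], a["rel_inv"][ri],
    )
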