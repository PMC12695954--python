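"""Knowledge-graph construction from pairwise coculture interaction measurements.

A pairwise interaction dataset records, for an ordered pair of microbial
strains (sender -> receiver) grown together in a carbon-source environment,
the effect of the sender on the receiver's growth yield.  The continuous
effect is the log ratio of the receiver's coculture yield over its
monoculture yield; its sign defines a discrete interaction type (Positive,
Negative, Neutral).  Each labelled measurement becomes one directed triple
``(sender, type@environment, receiver)`` in a knowledge graph whose entities
are strains and whose relation vocabulary is the product of interaction
types and environments.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionType",
    "InteractionRecord",
    "Relation",
    "Triple",
    "KnowledgeGraph",
    "compute_effect",
    "discretize_effect",
    "build_kg",
    "split_kg",
]


class InteractionType(enum.IntEnum):
    """Discrete outcome of a sender's effect on a receiver's growth.

    The integer values fix the canonical order Negative < Neutral < Positive
    used for deterministic tie-breaking and serialization throughout the
    package.
    """

    NEGATIVE = 0
    NEUTRAL = 1
    POSITIVE = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, text: str) -> "InteractionType":
        """Parse a label case-insensitively ('negative'|'neutral'|'positive')."""
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown interaction label {text!r}; expected one of "
                f"{[t.label for t in cls]}"
            ) from None


#: Canonical iteration order over interaction types.
INTERACTION_TYPES = (
    InteractionType.NEGATIVE,
    InteractionType.NEUTRAL,
    InteractionType.POSITIVE,
)


@dataclass(frozen=True)
class Relation:
    """A typed edge label: interaction type within a carbon-source environment."""

    itype: InteractionType
    environment: str

    def __str__(self) -> str:
        return f"{self.itype.label}@{self.environment}"

    @classmethod
    def parse(cls, text: str) -> "Relation":
        if "@" not in text:
            raise ValueError(f"relation {text!r} is not of the form 'type@environment'")
        type_part, env = text.split("@", 1)
        if "@" in env:
            raise ValueError(f"environment name {env!r} must not contain '@'")
        return cls(InteractionType.parse(type_part), env)


class Triple(NamedTuple):
    """One directed fact: head (sender) affects tail (receiver) via relation."""

    head: str
    relation: Relation
    tail: str


@dataclass
class InteractionRecord:
    """One sender -> receiver effect measurement in one environment.

    At least one of ``effect`` (continuous log ratio) or ``label`` (discrete
    type) must be present; sender and receiver must differ.
    """

    sender: str
    receiver: str
    environment: str
    effect: Optional[float] = None
    label: Optional[InteractionType] = None

    def __post_init__(self) -> None:
        if self.sender == self.receiver:
            raise ValueError(
                f"sender and receiver must differ (got {self.sender!r} twice)"
            )
        if self.effect is None and self.label is None:
            raise ValueError(
                f"record ({self.sender}, {self.receiver}, {self.environment}) "
                "has neither an effect nor a label"
            )
        if "@" in self.environment:
            raise ValueError(
                f"environment name {self.environment!r} must not contain '@'"
            )


def compute_effect(coculture_yield: float, monoculture_yield: float) -> float:
    """Log-ratio effect of a competitor on a focal strain's growth yield.

    Returns ``log(coculture_yield / monoculture_yield)`` (natural log).
    A positive value means the competitor enhanced the focal strain's
    growth, negative means inhibition, zero means no detected effect.
    Only the sign matters for the discrete interaction type, so the base of
    the logarithm is inert downstream.
    """
    if not (coculture_yield > 0 and monoculture_yield > 0):
        raise ValueError(
            "growth yields must be positive, got "
            f"coculture={coculture_yield!r}, monoculture={monoculture_yield!r}"
        )
    return math.log(coculture_yield / monoculture_yield)


def discretize_effect(effect: float, neutral_band: float = 0.0) -> InteractionType:
    """Map a continuous effect to an interaction type.

    Effects within ``[-neutral_band, +neutral_band]`` are Neutral; above the
    band Positive; below Negative.  The default band of 0 maps exactly-zero
    effects to Neutral and classifies everything else by sign.
    """
    if not math.isfinite(effect):
        raise ValueError(f"effect must be finite, got {effect!r}")
    if neutral_band < 0:
        raise ValueError(f"neutral_band must be nonnegative, got {neutral_band!r}")
    if abs(effect) <= neutral_band:
        return InteractionType.NEUTRAL
    return InteractionType.POSITIVE if effect > 0 else InteractionType.NEGATIVE


@dataclass(frozen=True)
class KnowledgeGraph:
    """A directed multigraph of strain-interaction triples.

    ``entities`` and ``relations`` are ordered (index maps for embedding
    tables are derived from their order); ``triples`` is duplicate-free.
    ``vocabulary_mode`` records whether ``relations`` holds only observed
    (type, environment) combinations or the full 3 x environments grid —
    interaction-based negative sampling needs the full grid so that
    corrupted relations are always resolvable.
    """

    entities: tuple[str, ...]
    relations: tuple[Relation, ...]
    triples: tuple[Triple, ...]
    vocabulary_mode: str = "observed_only"

    def __post_init__(self) -> None:
        ents = set(self.entities)
        rels = set(self.relations)
        for t in self.triples:
            if t.head not in ents or t.tail not in ents:
                raise ValueError(f"triple {t} references an unknown entity")
            if t.relation not in rels:
                raise ValueError(f"triple {t} references an unknown relation")
        if len(set(self.triples)) != len(self.triples):
            raise ValueError("duplicate triples are not allowed")

    # -- derived views -------------------------------------------------
    @property
    def environments(self) -> tuple[str, ...]:
        return tuple(sorted({r.environment for r in self.relations}))

    @property
    def entity_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entities)}

    @property
    def relation_index(self) -> dict[Relation, int]:
        return {r: i for i, r in enumerate(self.relations)}

    @property
    def observed_relations(self) -> tuple[Relation, ...]:
        """Relations appearing in at least one triple."""
        seen = {t.relation for t in self.triples}
        return tuple(r for r in self.relations if r in seen)

    def label_counts(self) -> Counter:
        return Counter(t.relation.itype for t in self.triples)

    def __len__(self) -> int:
        return len(self.triples)

    def with_triples(self, triples: Iterable[Triple]) -> "KnowledgeGraph":
        """A graph with the same vocabulary but a different triple set."""
        return KnowledgeGraph(self.entities, self.relations, tuple(triples),
                              self.vocabulary_mode)


def _canonical_relations(
    environments: Sequence[str], mode: str, observed: set[Relation]
) -> tuple[Relation, ...]:
    if mode == "full_grid":
        return tuple(
            Relation(itype, env)
            for env in sorted(environments)
            for itype in INTERACTION_TYPES
        )
    if mode == "observed_only":
        return tuple(
            r
            for env in sorted(environments)
            for itype in INTERACTION_TYPES
            if (r := Relation(itype, env)) in observed
        )
    raise ValueError(f"unknown vocabulary_mode {mode!r}")


def build_kg(
    records: Iterable[InteractionRecord],
    vocabulary_mode: str = "observed_only",
    neutral_band: Optional[float] = None,
) -> KnowledgeGraph:
    """Assemble a knowledge graph from labelled interaction records.

    Each record becomes one triple ``(sender, label@environment, receiver)``.
    Records lacking a label are discretized from their continuous effect if
    ``neutral_band`` is given, otherwise rejected.  Exact duplicate triples
    (replicate measurements with the same label) collapse to one with a
    logged warning; records mapping the same (sender, receiver, environment)
    cell to different labels are an error.
    """
    triples: list[Triple] = []
    seen: dict[tuple[str, str, str], InteractionType] = {}
    conflicts: list[tuple[str, str, str]] = []
    n_dupes = 0
    entities: set[str] = set()
    environments: set[str] = set()

    for rec in records:
        label = rec.label
        if label is None:
            if neutral_band is None:
                raise ValueError(
                    f"record ({rec.sender}, {rec.receiver}, {rec.environment}) "
                    "has no label; pass neutral_band= to discretize effects"
                )
            label = discretize_effect(rec.effect, neutral_band)
        cell = (rec.sender, rec.receiver, rec.environment)
        if cell in seen:
            if seen[cell] != label:
                conflicts.append(cell)
            else:
                n_dupes += 1
            continue
        seen[cell] = label
        entities.update((rec.sender, rec.receiver))
        environments.add(rec.environment)
        triples.append(Triple(rec.sender, Relation(label, rec.environment), rec.receiver))

    if conflicts:
        raise ValueError(
            "conflicting labels for cells (sender, receiver, environment): "
            f"{sorted(conflicts)}"
        )
    if n_dupes:
        logger.warning("collapsed %d duplicate records with identical labels", n_dupes)

    observed = {t.relation for t in triples}
    relations = _canonical_relations(sorted(environments), vocabulary_mode, observed)
    return KnowledgeGraph(tuple(sorted(entities)), relations, tuple(triples),
                          vocabulary_mode)


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer partition of n proportional to fractions, largest remainder."""
    raw = [f * n for f in fractions]
    sizes = [int(math.floor(x)) for x in raw]
    remainder = n - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_kg(
    kg: KnowledgeGraph,
    fractions: Sequence[float] = (0.9, 0.05, 0.05),
    mode: str = "random",
    holdout_ids: Optional[Sequence[str]] = None,
    n_holdout: Optional[int] = None,
    seed: int = 0,
) -> tuple[KnowledgeGraph, KnowledgeGraph, KnowledgeGraph]:
    """Partition triples into train / validation / test graphs.

    Modes:

    - ``random`` — uniform triple-level split with sizes given by the
      fractions (largest-remainder rounding, so a 90/5/5 split of 100
      triples yields exactly 90/5/5).
    - ``holdout_receivers`` — every triple whose *tail* is a held-out
      strain goes to test (the unseen receiver-environment protocol);
      the remainder is split train/valid by the first two fractions.
    - ``holdout_strain`` — every triple touching a held-out strain as
      head *or* tail goes to test (the unseen-strain protocol).

    Held-out strains are given explicitly via ``holdout_ids`` or sampled
    (``n_holdout`` of them) with the seed.  All three returned graphs share
    the parent's entity/relation vocabulary so embedding index maps built on
    the training graph remain valid on the others.
    """
    import numpy as np

    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three nonnegative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")

    rng = np.random.default_rng(seed)
    triples = list(kg.triples)

    if mode == "random":
        sizes = _largest_remainder_sizes(len(triples), fractions)
        perm = rng.permutation(len(triples))
        parts = (
            [triples[i] for i in perm[: sizes[0]]],
            [triples[i] for i in perm[sizes[0]: sizes[0] + sizes[1]]],
            [triples[i] for i in perm[sizes[0] + sizes[1]:]],
        )
    elif mode in ("holdout_receivers", "holdout_strain"):
        if holdout_ids is None:
            if n_holdout is None:
                raise ValueError(f"mode {mode!r} requires holdout_ids or n_holdout")
            holdout_ids = list(
                rng.choice(np.array(kg.entities), size=n_holdout, replace=False)
            )
        unknown = set(holdout_ids) - set(kg.entities)
        if unknown:
            raise ValueError(f"holdout strains not in graph: {sorted(unknown)}")
        held = set(holdout_ids)
        if mode == "holdout_receivers":
            in_test = [t.tail in held for t in triples]
        else:
            in_test = [t.head in held or t.tail in held for t in triples]
        test = [t for t, m in zip(triples, in_test) if m]
        rest = [t for t, m in zip(triples, in_test) if not m]
        pair_total = fractions[0] + fractions[1]
        if pair_total <= 0:
            train, valid = rest, []
        else:
            sizes = _largest_remainder_sizes(
                len(rest), (fractions[0] / pair_total, fractions[1] / pair_total)
            )
            perm = rng.permutation(len(rest))
            train = [rest[i] for i in perm[: sizes[0]]]
            valid = [rest[i] for i in perm[sizes[0]:]]
        if mode == "holdout_strain":
            # the held-out strains are truly unseen: drop them from the
            # train/valid vocabulary so no embedding is allocated for them
            kept = tuple(e for e in kg.entities if e not in held)
            train_kg = KnowledgeGraph(kept, kg.relations, tuple(train),
                                      kg.vocabulary_mode)
            valid_kg = KnowledgeGraph(kept, kg.relations, tuple(valid),
                                      kg.vocabulary_mode)
            return train_kg, valid_kg, kg.with_triples(test)
        parts = (train, valid, test)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    return tuple(kg.with_triples(p) for p in parts)  # type: ignore[return-value]
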