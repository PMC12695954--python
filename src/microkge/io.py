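"""File formats: interaction CSVs, phylo features, triple TSVs, checkpoints.

Interaction tables are UTF-8 CSVs with a header and columns ``sender``,
``receiver``, ``environment`` plus at least one of ``effect`` (decimal log
ratio) and ``label`` (``negative|neutral|positive``, case-insensitive).
Triples serialize one per line as ``head<TAB>type@environment<TAB>tail``
('@' is therefore forbidden in environment names).  Embedding checkpoints
are a single JSON document holding the config, index maps, and arrays;
JSON floats round-trip exactly, so save/load is lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kg import (
    InteractionRecord,
    InteractionType,
    KnowledgeGraph,
    Relation,
    Triple,
)
from .models import EmbeddingSet, ModelKind
from .phylo import PhyloFeatures
from .training import TrainConfig, TrainedModel

__all__ = [
    "read_interactions",
    "write_interactions",
    "read_phylo_features",
    "write_phylo_features",
    "read_triples",
    "write_triples",
    "save_checkpoint",
    "load_checkpoint",
]

_REQUIRED = ("sender", "receiver", "environment")


def read_interactions(
    path, columns: Optional[dict[str, str]] = None
) -> list[InteractionRecord]:
    """Parse an interaction CSV into records.

    ``columns`` optionally maps the canonical column names (``sender``,
    ``receiver``, ``environment``, ``effect``, ``label``) to the names used
    in the file, for tables with different headers.  Row numbers (1-based,
    excluding the header) are reported in error messages.
    """
    df = pd.read_csv(path, dtype=str)
    mapping = {k: k for k in (*_REQUIRED, "effect", "label")}
    if columns:
        mapping.update(columns)
    for canonical in _REQUIRED:
        if mapping[canonical] not in df.columns:
            raise ValueError(
                f"missing required column {mapping[canonical]!r} in {path}"
            )
    has_effect = mapping["effect"] in df.columns
    has_label = mapping["label"] in df.columns
    if not (has_effect or has_label):
        raise ValueError(f"{path} needs an 'effect' or a 'label' column")

    records: list[InteractionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        effect = None
        label = None
        if has_effect:
            raw = row_d[mapping["effect"]]
            if isinstance(raw, str) and raw.strip():
                effect = float(raw)
        if has_label:
            raw = row_d[mapping["label"]]
            if isinstance(raw, str) and raw.strip():
                label = InteractionType.parse(raw)
        try:
            records.append(
                InteractionRecord(
                    sender=str(row_d[mapping["sender"]]),
                    receiver=str(row_d[mapping["receiver"]]),
                    environment=str(row_d[mapping["environment"]]),
                    effect=effect,
                    label=label,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return records


def write_interactions(records: Sequence[InteractionRecord], path) -> None:
    df = pd.DataFrame(
        {
            "sender": [r.sender for r in records],
            "receiver": [r.receiver for r in records],
            "environment": [r.environment for r in records],
            "effect": [
                "" if r.effect is None else repr(float(r.effect)) for r in records
            ],
            "label": ["" if r.label is None else r.label.label for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_phylo_features(path) -> PhyloFeatures:
    """Read a strain-by-coordinates CSV (first column: strain id)."""
    df = pd.read_csv(path, float_precision="round_trip")
    ids = tuple(str(s) for s in df.iloc[:, 0])
    coords = df.iloc[:, 1:].to_numpy(dtype=float)
    return PhyloFeatures(ids, coords)


def write_phylo_features(features: PhyloFeatures, path) -> None:
    cols = {"strain_id": list(features.ids)}
    for j in range(features.coords.shape[1]):
        cols[f"f{j + 1}"] = [repr(float(x)) for x in features.coords[:, j]]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_triples(path, vocabulary_mode: str = "observed_only") -> KnowledgeGraph:
    """Read a triple TSV (head, type@environment, tail) into a graph."""
    triples: list[Triple] = []
    entities: set[str] = set()
    environments: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{i}: expected 3 tab-separated fields")
            head, rel_text, tail = parts
            rel = Relation.parse(rel_text)
            triples.append(Triple(head, rel, tail))
            entities.update((head, tail))
            environments.add(rel.environment)
    from .kg import _canonical_relations

    observed = {t.relation for t in triples}
    relations = _canonical_relations(sorted(environments), vocabulary_mode, observed)
    return KnowledgeGraph(
        tuple(sorted(entities)), relations, tuple(dict.fromkeys(triples)),
        vocabulary_mode,
    )


def write_triples(kg: KnowledgeGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def save_checkpoint(model: TrainedModel, path) -> None:
    """Serialize a trained model to a single JSON checkpoint."""
    emb = model.embeddings
    doc = {
        "format": "microkge-checkpoint-v1",
        "config": {
            **dataclasses.asdict(model.config),
            "model": model.config.model.value,
        },
        "model": emb.model.value,
        "dim": emb.dim,
        "norm_kind": emb.norm_kind,
        "entity_ids": list(emb.entity_ids),
        "relation_ids": [str(r) for r in emb.relation_ids],
        "arrays": {k: v.tolist() for k, v in emb.arrays.items()},
        "loss_history": list(model.loss_history),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_checkpoint(path) -> TrainedModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "microkge-checkpoint-v1":
        raise ValueError(f"{path} is not a recognized checkpoint file")
    emb = EmbeddingSet(
        model=ModelKind(doc["model"]),
        dim=int(doc["dim"]),
        entity_ids=tuple(doc["entity_ids"]),
        relation_ids=tuple(Relation.parse(r) for r in doc["relation_ids"]),
        arrays={k: np.asarray(v, dtype=float) for k, v in doc["arrays"].items()},
        norm_kind=doc["norm_kind"],
    )
    config = TrainConfig(**doc["config"])
    return TrainedModel(embeddings=emb, config=config,
                        loss_history=list(doc["loss_history"]))
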