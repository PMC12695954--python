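"""Phylogenetic feature space for strains.

Strains are embedded in a low-dimensional numeric coordinate space
(typically a PCA of 16S rRNA distances, computed upstream and consumed here
as a plain CSV).  Pairwise Euclidean distance in this space is the
phylogenetic distance used to weight neighbour embeddings when predicting
for strains absent from the knowledge graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhyloFeatures", "phylo_distance"]


@dataclass(frozen=True)
class PhyloFeatures:
    """Per-strain coordinates in a phylogenetic feature space."""

    ids: tuple[str, ...]
    coords: np.ndarray  # shape (n_strains, m)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[0] != len(self.ids):
            raise ValueError(
                f"coords must be (n_strains, m), got shape {coords.shape} "
                f"for {len(self.ids)} ids"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate strain ids in phylogenetic features")
        if not np.all(np.isfinite(coords)):
            raise ValueError("phylogenetic coordinates must be finite")

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.ids)}

    def vector(self, strain: str) -> np.ndarray:
        try:
            return self.coords[self.index[strain]]
        except KeyError:
            raise KeyError(f"strain {strain!r} has no phylogenetic coordinates") from None

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance between two strains' coordinates."""
        return float(np.linalg.norm(self.vector(a) - self.vector(b)))


def phylo_distance(features: PhyloFeatures, a: str, b: str) -> float:
    """Euclidean phylogenetic distance between strains ``a`` and ``b``."""
    return features.distance(a, b)
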