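"""Synthetic pairwise-interaction datasets with controllable structure.

The generator emulates the shape of a coculture interaction screen: a panel
of bacterial strains grown pairwise in a panel of carbon-source
environments, each ordered pair yielding a continuous log-ratio growth
effect that is discretized into Negative / Neutral / Positive.

Generative model
----------------
Each strain *i* carries a latent trait vector ``t_i ~ N(0, I_m)``.
Environments are grouped into a small number of archetypes; archetype *g*
carries a matrix ``M_g`` with i.i.d. ``N(0, 1/m)`` entries.  The effect of
sender *i* on receiver *j* in an environment of archetype *g* is the
bilinear form

    effect(i, j, e) = t_i' M_{g(e)} t_j + eps,   eps ~ N(0, noise_sd^2)

so environments within a group share label patterns up to noise, strains
with similar traits have similar interaction profiles, and effects are
pair-consistent across environments of one archetype.  Phylogenetic
coordinates are a convex mixture of the traits and independent noise,
``x_i = phylo_signal * t_i + (1 - phylo_signal) * z_i``, so at
``phylo_signal = 1`` phylogenetic proximity is exactly trait proximity.

Cells are dropped uniformly at random with probability ``missing_fraction``
to mimic incomplete screens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kg import InteractionRecord, discretize_effect
from .phylo import PhyloFeatures

__all__ = ["SyntheticConfig", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic interaction screen.

    Defaults mirror a 20-strain x 40-environment screen with a small number
    of missing wells.
    """

    n_strains: int = 20
    n_environments: int = 40
    trait_dim: int = 3
    env_groups: "int | None" = None  # default: min(8, n_environments)
    noise_sd: float = 0.1
    neutral_band: float = 0.25
    phylo_signal: float = 0.9
    missing_fraction: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.env_groups is None:
            object.__setattr__(
                self, "env_groups",
                min(8, self.n_environments) if isinstance(self.n_environments, int)
                and self.n_environments >= 1 else 1,
            )

    def validate(self) -> None:
        if not (isinstance(self.n_strains, int) and self.n_strains >= 2):
            raise ValueError(f"n_strains must be an integer >= 2, got {self.n_strains!r}")
        if not (isinstance(self.n_environments, int) and self.n_environments >= 1):
            raise ValueError(
                f"n_environments must be a positive integer, got {self.n_environments!r}"
            )
        if not (isinstance(self.trait_dim, int) and self.trait_dim >= 1):
            raise ValueError(f"trait_dim must be a positive integer, got {self.trait_dim!r}")
        if not (isinstance(self.env_groups, int) and 1 <= self.env_groups <= self.n_environments):
            raise ValueError(
                f"env_groups must be a positive integer <= n_environments, got {self.env_groups!r}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd!r}")
        if self.neutral_band < 0:
            raise ValueError(f"neutral_band must be nonnegative, got {self.neutral_band!r}")
        if not (0.0 <= self.phylo_signal <= 1.0):
            raise ValueError(f"phylo_signal must be in [0, 1], got {self.phylo_signal!r}")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError(
                f"missing_fraction must be in [0, 1), got {self.missing_fraction!r}"
            )


def _strain_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _env_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"E{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[InteractionRecord], PhyloFeatures]:
    """Generate an interaction table and matching phylogenetic features.

    Returns one record per ordered pair of distinct strains per environment
    (minus uniformly missing cells), each carrying both the continuous
    effect and its discretized label under ``config.neutral_band``.  The
    output is a deterministic function of the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, m, n_env = config.n_strains, config.trait_dim, config.n_environments
    strains = _strain_ids(n)
    envs = _env_ids(n_env)
    # environments are assigned to archetype groups round-robin
    group_of_env = np.arange(n_env) % config.env_groups

    traits = rng.standard_normal((n, m))
    archetypes = rng.standard_normal((config.env_groups, m, m)) / np.sqrt(m)

    # effects[e, i, j] = t_i' M_{g(e)} t_j
    base = np.einsum("im,gmk,jk->gij", traits, archetypes, traits)
    noise = rng.normal(0.0, config.noise_sd, size=(n_env, n, n)) if config.noise_sd > 0 \
        else np.zeros((n_env, n, n))
    missing = rng.random((n_env, n, n)) < config.missing_fraction

    records: list[InteractionRecord] = []
    for e_idx, env in enumerate(envs):
        eff_mat = base[group_of_env[e_idx]] + noise[e_idx]
        for i, sender in enumerate(strains):
            for j, receiver in enumerate(strains):
                if i == j or missing[e_idx, i, j]:
                    continue
                effect = float(eff_mat[i, j])
                records.append(
                    InteractionRecord(
                        sender=sender,
                        receiver=receiver,
                        environment=env,
                        effect=effect,
                        label=discretize_effect(effect, config.neutral_band),
                    )
                )

    phylo_noise = rng.standard_normal((n, m))
    coords = config.phylo_signal * traits + (1.0 - config.phylo_signal) * phylo_noise
    features = PhyloFeatures(tuple(strains), coords)
    return records, features


def with_overrides(config: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """A copy of ``config`` with the given fields replaced (validated)."""
    new = replace(config, **kwargs)
    new.validate()
    return new
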