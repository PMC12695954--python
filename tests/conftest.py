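import numpy as np
import pytest
from hypothesis import settings

import microkge as mk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small, strongly structured, noise-free synthetic screen."""
    return mk.SyntheticConfig(
        n_strains=8, n_environments=4, env_groups=2, noise_sd=0.0,
        phylo_signal=1.0, missing_fraction=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mk.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_kg(small_dataset):
    records, _ = small_dataset
    return mk.build_kg(records, vocabulary_mode="full_grid")


@pytest.fixture(scope="session")
def small_split(small_kg):
    return mk.split_kg(small_kg, seed=4)


@pytest.fixture(scope="session")
def trained_simple(small_split):
    train_kg, _, _ = small_split
    return mk.train(
        train_kg,
        mk.TrainConfig(model="simple", dim=16, epochs=150,
                       ns_strategy="interaction_based", seed=2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_model(model_kind, n_entities=5, n_environments=2, dim=4, seed=0):
    """An untrained model over a tiny full-grid vocabulary, for oracles."""
    entities = tuple(f"S{i}" for i in range(n_entities))
    relations = tuple(
        mk.Relation(it, f"E{j}")
        for j in range(n_environments)
        for it in mk.INTERACTION_TYPES
    )
    emb = mk.init_embeddings(entities, relations, model_kind, dim, seed=seed)
    cfg = mk.TrainConfig(model=model_kind, dim=dim, epochs=0, seed=seed)
    return mk.TrainedModel(embeddings=emb, config=cfg, loss_history=[])
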