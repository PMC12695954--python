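"""Predict interactions for a strain absent from the knowledge graph.

The target strain's triples are removed before training; its embedding is
then synthesized as a distance-weighted average of its five
phylogenetically closest in-graph strains and used for scoring.

Run:  python examples/02_unseen_strain.py
"""

import numpy as np

import microkge as mk

config = mk.SyntheticConfig(n_strains=20, n_environments=10, env_groups=3,
                            noise_sd=0.0, phylo_signal=1.0, seed=0)
records, phylo = mk.generate_dataset(config)
kg = mk.build_kg(records, vocabulary_mode="full_grid")

target = kg.entities[0]
train_kg, _, test_kg = mk.split_kg(
    kg, (0.95, 0.0, 0.05), mode="holdout_strain", holdout_ids=[target], seed=0,
)
print(f"held out {target}: {len(test_kg)} of its interactions to predict; "
      f"training graph has {len(train_kg.entities)} strains")

model = mk.train(train_kg, mk.TrainConfig(
    model="simple", dim=32, epochs=120, ns_strategy="interaction_based", seed=0,
))

queries, truths = [], []
for t in test_kg.triples:
    if t.head == target:
        queries.append((t.tail, t.relation.environment, "sender"))
    else:
        queries.append((t.head, t.relation.environment, "receiver"))
    truths.append(t.relation.itype)

preds = mk.predict_unseen(model, phylo, target, queries, k=5)
accuracy = np.mean([p == t for p, t in zip(preds, truths)])
print(f"accuracy from 5 phylogenetically nearest neighbours: {accuracy:.3f}")
# Each prediction substitutes the synthetic embedding for the unseen strain
# on the queried side of the triple; accuracy well above 1/3 shows the
# neighbours' embeddings carry over the target's interaction tendencies.
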