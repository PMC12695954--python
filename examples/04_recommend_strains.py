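"""Rank candidate strains by their likelihood of a desired interaction
with a target strain in a given environment.

Run:  python examples/04_recommend_strains.py
"""

import microkge as mk

config = mk.SyntheticConfig(n_strains=20, n_environments=10, env_groups=3,
                            noise_sd=0.0, seed=0)
records, _ = mk.generate_dataset(config)
kg = mk.build_kg(records, vocabulary_mode="full_grid")
train_kg, _, _ = mk.split_kg(kg, seed=0)
model = mk.train(train_kg, mk.TrainConfig(
    model="simple", dim=32, epochs=200, ns_strategy="interaction_based", seed=0,
))

target = "S01"
environment = "E01"
candidates = [s for s in kg.entities if s != target][:10]

rec = mk.recommend(
    model, target, mk.InteractionType.NEGATIVE, environment, candidates,
    direction="candidates_affect_target",
)
print(f"strains most likely to inhibit {target} in {environment}:")
for cand, score, norm in zip(rec.candidates, rec.scores,
                             rec.normalized_scores):
    print(f"  {cand}: score {score:+.3f} (normalized {norm:.2f})")
print(f"recommended: {rec.best}")
# Scores are the model's plausibility of (candidate, negative@env, target);
# the min-max normalization only eases comparison within this candidate set.
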