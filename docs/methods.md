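# Methods

## Data model

A coculture screen is a collection of measurements: sender strain, receiver
strain, carbon-source environment, and a continuous effect — the natural
log of the receiver's coculture growth yield over its monoculture yield.
(The base of the logarithm is immaterial downstream: only the sign enters
the labels, so `compute_effect` uses the natural log and documents it.)  Effects are discretized by a symmetric band around zero:
`|effect| <= neutral_band` → Neutral, above → Positive, below → Negative.
The band defaults to 0 — an exactly-zero effect is Neutral, everything else
is classified by sign — and is configurable because real screens typically
call "no detected effect" by a statistical criterion rather than exact
equality.

Each labelled measurement becomes one triple *(sender, type@environment,
receiver)*. The canonical interaction-type order Negative < Neutral <
Positive fixes serialization order and every tie-break in the package.
Self-interactions are not represented.  Duplicate measurements with the
same label collapse to one triple (warning); contradictory labels for the
same cell are an error rather than a silent overwrite.

Two relation-vocabulary modes exist. `observed_only` registers exactly the
(type, environment) pairs that occur in at least one triple — this is the
vocabulary under which the deposited 20-strain × 40-environment screen
yields 113 relations.  `full_grid` registers all 3 × environments
combinations and is the default for training whenever interaction-based
negative sampling is on, because a corrupted relation (I′, e) may be
unobserved.  Train/validation/test splits inherit the parent graph's full
entity and relation vocabulary so that embedding index maps remain valid
across splits; the one exception is the unseen-strain holdout, where the
held-out strains are removed from the training vocabulary precisely so that
no embedding exists for them.  Split sizes follow largest-remainder
rounding, so a 90/5/5 split of a size divisible by 20 is exact.

## Embedding models and training

TransE, DistMult, and SimplE are implemented over double-precision numpy
arrays.  Initialization is i.i.d. uniform on ±6/√d, the convention of the
original translational-embedding work; TransE entity vectors are
L2-normalized at initialization and, by default, re-normalized before
every batch (`transe_normalize`; the per-batch renormalization is a flag
because implementations differ on whether to keep it).

Losses: the pairwise margin ranking loss Σ max(0, γ − φ⁺ + φ⁻) with each
negative paired to its source positive, and the pointwise logistic loss
Σ log(1 + exp(−l·φ)) computed via an overflow-safe softplus.  By the usual
convention TransE trains with the pairwise loss, DistMult and SimplE with
the logistic loss; the pairing is overridable.

Optimization is plain mini-batch SGD at a constant learning rate.  The
update uses the batch-*mean* gradient so that the learning rate is
comparable across batch sizes; epoch loss history records the mean loss per
positive triple.  Gradients are analytic and verified against central
finite differences (h = 1e−5, relative tolerance 1e−6) for every model ×
loss combination in the test suite.  All randomness flows from one seed:
`SeedSequence(seed)` spawns one child stream for initialization and one for
shuffling/negative sampling, so the two are independently reproducible.
Defaults (d = 32, lr = 0.5, batch 128, 200 epochs, 1 negative per positive)
were chosen for reliable convergence on desk-scale screens; `grid_search`
enumerates a user grid in key order and scores each point by validation
classification accuracy, with first-in-order tie-breaking.

Negative sampling: classical corruption replaces head or tail (fair coin)
with a uniformly drawn other entity and — deliberately — does not filter
accidental true triples, matching common practice on dense graphs.
Interaction-based sampling flips the interaction type to one of the other
two (uniformly), keeping strains and environment fixed; it requires the
full-grid vocabulary and the trainer says so explicitly when it is missing.

## Evaluation

Classification: score the query under each candidate type for its
environment, take the argmax, break ties canonically.  Accuracy, one-vs-rest
precision/recall/F1 per class, macro-F1 and the 3×3 confusion matrix are
reported; zero-denominator precision/recall is defined as 0 with a warning.

Ranking: raw (unfiltered) ranks over all |E| entity substitutions on each
side, ties resolved to the mean rank of the tied block — this avoids the
optimistic bias a min-rank convention gives to near-constant (untrained)
scorers.  MRR averages head- and tail-side reciprocal ranks over 2N terms;
Hits@k counts both sides.  Filtered ranking is available behind a flag.
Note that a model trained *only* with interaction-based negatives is under
no pressure to rank entities, so its raw MRR is modest even when its
type-classification accuracy is high; entity ranking is the natural metric
for classically trained models.

Null models A–E predict the majority training label conditioned on nothing,
the environment, the receiver, the sender, or the ordered pair, with unseen
strata falling back to the global majority.  Label imbalance is summarized
by the base-2 Shannon entropy H and the effective class number 2^H ∈ [1, 3].

## Downstream procedures

*Unseen strains.*  Candidate neighbours are the in-graph strains with
phylogenetic coordinates; the k nearest (Euclidean distance, ties by strain
id) are averaged with weights 1/(1+d), normalized to unit sum — a convex
combination, so each coordinate of the synthetic embedding stays within the
neighbours' range.  For SimplE the head-role and tail-role matrices are
aggregated independently.  The default cap k = 5 keeps neighbourhoods
small enough that, on taxonomically clustered panels, neighbours stay
within the target's taxonomic order.  The evaluation harness retrains once per held-out strain and
compares against aggregating k uniformly random strains (uniform weights).

*Environment similarity.*  An environment's vector is the concatenation of
its three relation embeddings in canonical type order (3d; for SimplE each
block is forward|inverse, giving 6d — distances are invariant to any fixed
consistent order).  Environments missing a type in the vocabulary are
excluded.  The decision rule ranks all other complete environments by
ascending distance (Euclidean or cosine) and copies the queried pair's
label from the first environment that actually contains an observation,
optionally skipping donors beyond a distance threshold.

*Recommendation.*  Candidates are scored as φ(candidate, (I, e), target)
(or the reversed triple), sorted descending with ties broken by strain id,
and min-max normalized within the candidate set (a constant set maps to 1).

## Synthetic screens

The generator emulates the statistical structure the analyses assume.
Strain *i* has a latent trait vector tᵢ ~ N(0, I_m); environments are
assigned round-robin to a small number of archetypes, each carrying a
matrix M_g with N(0, 1/m) entries; the effect of sender i on receiver j in
an environment of archetype g is the bilinear form tᵢ′ M_g tⱼ plus
N(0, noise_sd²) noise.  Environments of one archetype therefore share label
patterns up to noise, and strains with similar traits have similar
interaction profiles.  Phylogenetic coordinates are the convex mixture
`phylo_signal·traits + (1−phylo_signal)·noise`, so at phylo_signal = 1
phylogenetic proximity *is* trait proximity.  Cells are dropped uniformly
at random with probability `missing_fraction`.

Defaults mirror the shape of the reference screen: 20 strains × 40
environments, with missing_fraction = 0.008 (the fraction of absent cells
in a 15,074-triple screen over 15,200 possible cells).  trait_dim = 3 keeps
profiles low-rank but not degenerate; env_groups defaults to min(8,
n_environments); noise_sd = 0.1 and neutral_band = 0.25 give roughly a
20% Neutral share; phylo_signal = 0.9 reflects strong but imperfect
phylogenetic conservation of interaction traits.  The Gaussian effect
distribution is a modelling convenience, not a claim about real screens.

What the generator does *not* emulate: absolute growth yields or dynamics
(effects are drawn directly on the log-ratio scale), the real screen's
class imbalance asymmetry (bilinear effects are roughly sign-symmetric),
replicate noise structure, or taxonomically clustered phylogenies.  Passing
benchmarks on these screens therefore demonstrates that each procedure
recovers the structure it assumes — not that it attains any particular
accuracy on real coculture data.

One caveat discovered while testing: because discretized labels saturate
away from the class boundaries, two strains with different but same-regime
traits can have *identical* label profiles, so the phylogenetically closest
pair is not guaranteed to be the strict argmin of label-profile
disagreement.  The exact closest-pair property holds for continuous effect
profiles with one-dimensional traits (where profile distance is
proportional to trait distance); for labels the package asserts the
statistical version — a positive rank correlation between phylogenetic
distance and profile disagreement across seeds.

## Benchmark problem sizes

The bundled benchmarks run at desk scale, chosen so the full suite
completes in minutes on one core: interaction prediction and negative-
sampling comparison on 20 strains × 10 environments (3 archetypes,
noise-free) over 5 seeds; leave-one-strain-out over all 20 strains at
phylo_signal = 1 (120 epochs per retrain); the environment rule on 15
strains × 12 environments with noise_sd = 0.3 and 20% missingness —
substantial missingness forces donor environments across the whole distance
range, which is the regime the distance-threshold analysis probes.  On
these screens the embedding model roughly doubles the accuracy of the best
null model, interaction-based sampling adds ~0.15 accuracy over classical
corruption, phylogeny-weighted synthetic embeddings beat random-neighbour
aggregation by ~0.3, and the similarity-based donor rule beats a random
donor by ~0.3 — the same orderings the method exhibits at full scale, at
desk-scale magnitudes.

## Known limitations

- No GPU path and no adaptive optimizers; plain SGD is adequate at the
  graph sizes targeted.
- No early stopping; epoch counts are fixed by the config.
- Raw MRR under interaction-based training understates the model (see
  above); compare like with like.
- The recommendation scores are class-plausibility scores, not estimates of
  interaction strength; rankings across runs can vary with initialization.
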