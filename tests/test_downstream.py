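"""Synthetic embeddings, environment similarity, and recommendation."""

import math

import numpy as np
import pytest

import microkge as mk
from microkge.downstream import (
    environment_distance,
    environment_embedding,
    environment_rule_predict,
    predict_unseen,
    recommend,
    synthetic_embedding,
    environment_distance_matrix,
    strain_distance_matrix,
)
from microkge.models import score_triple
from microkge.phylo import PhyloFeatures

from conftest import random_model

NEG, NEU, POS = mk.INTERACTION_TYPES


class TestPhyloDistance:
    def test_identity_and_pythagoras(self):
        f = PhyloFeatures(("a", "b", "c"), np.array([[0.0, 0], [3, 4], [0, 0]]))
        assert f.distance("a", "c") == 0.0
        assert f.distance("a", "b") == 5.0

    def test_symmetry(self, rng):
        coords = rng.standard_normal((6, 3))
        f = PhyloFeatures(tuple("abcdef"), coords)
        for a in "abc":
            for b in "def":
                assert f.distance(a, b) == pytest.approx(f.distance(b, a))

    def test_unknown_strain(self):
        f = PhyloFeatures(("a",), np.zeros((1, 2)))
        with pytest.raises(KeyError):
            f.distance("a", "zz")


def model_with_features(model_kind="distmult", n=5, dim=3, seed=0, coords=None):
    model = random_model(model_kind, n_entities=n, n_environments=2, dim=dim,
                         seed=seed)
    ids = list(model.embeddings.entity_ids) + ["NEW"]
    if coords is None:
        coords = np.random.default_rng(seed).standard_normal((n + 1, 2))
    return model, PhyloFeatures(tuple(ids), coords)


class TestSyntheticEmbedding:
    def test_single_neighbour_copies_its_embedding(self):
        coords = np.array([[0.0, 0], [5, 5], [6, 6], [7, 7], [8, 8], [0.1, 0]])
        model, features = model_with_features(coords=coords)
        out = synthetic_embedding(model, features, "NEW", k=1)
        np.testing.assert_allclose(
            out["ent"], model.embeddings.arrays["ent"][0]
        )

    def test_equal_distances_give_arithmetic_mean(self):
        coords = np.array([[1.0, 0], [-1, 0], [9, 9], [9, -9], [8, 8], [0, 0]])
        model, features = model_with_features(coords=coords)
        out = synthetic_embedding(model, features, "NEW", k=2)
        ent = model.embeddings.arrays["ent"]
        np.testing.assert_allclose(out["ent"], (ent[0] + ent[1]) / 2)

    def test_inverse_distance_weights(self):
        # neighbours at d=0 and d=1: weights 1 and 1/2 -> normalized 2/3, 1/3
        coords = np.array([[0.0, 0], [0, 1], [9, 9], [9, -9], [8, 8], [0, 0]])
        model, features = model_with_features(coords=coords)
        out = synthetic_embedding(model, features, "NEW", k=2)
        ent = model.embeddings.arrays["ent"]
        np.testing.assert_allclose(out["ent"], (2 / 3) * ent[0] + (1 / 3) * ent[1])

    def test_simple_roles_aggregated_independently(self):
        coords = np.array([[0.0, 0], [0, 1], [9, 9], [9, -9], [8, 8], [0, 0]])
        model, features = model_with_features("simple", coords=coords)
        out = synthetic_embedding(model, features, "NEW", k=2)
        for role in ("ent_head", "ent_tail"):
            arr = model.embeddings.arrays[role]
            np.testing.assert_allclose(
                out[role], (2 / 3) * arr[0] + (1 / 3) * arr[1]
            )

    def test_result_in_convex_hull_of_neighbours(self):
        model, features = model_with_features(seed=3)
        out = synthetic_embedding(model, features, "NEW", k=3)
        ent = model.embeddings.arrays["ent"]
        lo, hi = ent.min(axis=0), ent.max(axis=0)
        assert np.all(out["ent"] >= lo - 1e-12)
        assert np.all(out["ent"] <= hi + 1e-12)

    def test_in_graph_target_rejected(self):
        model, features = model_with_features()
        with pytest.raises(ValueError, match="not unseen"):
            synthetic_embedding(model, features, "S0", k=2)

    def test_k_exceeding_neighbours_rejected(self):
        model, features = model_with_features()
        with pytest.raises(ValueError, match="k=9"):
            synthetic_embedding(model, features, "NEW", k=9)


class TestPredictUnseen:
    def test_coincident_target_matches_in_graph_classification(self):
        """A target sitting exactly on an in-graph strain with k=1 must
        reproduce that strain's predictions."""
        model = random_model("simple", n_entities=5, n_environments=2,
                             dim=4, seed=6)
        coords = np.array(
            [[0.0, 0], [3, 3], [4, 4], [5, 5], [6, 6], [0, 0]]  # NEW == S0
        )
        ids = list(model.embeddings.entity_ids) + ["NEW"]
        features = PhyloFeatures(tuple(ids), coords)
        queries = [("S1", "E0", "sender"), ("S2", "E1", "receiver")]
        preds = predict_unseen(model, features, "NEW", queries, k=1)
        expected = [
            mk.classify_interaction(model, "S0", "S1", "E0")[0],
            mk.classify_interaction(model, "S2", "S0", "E1")[0],
        ]
        assert preds == expected


class TestEnvironmentEmbedding:
    def test_concatenation_in_canonical_order(self):
        model = random_model("distmult", n_entities=3, n_environments=1, dim=2)
        emb = model.embeddings
        ri = {r.itype: i for i, r in enumerate(emb.relation_ids)}
        emb.arrays["rel"][ri[NEG]] = [1.0, 2.0]
        emb.arrays["rel"][ri[NEU]] = [3.0, 4.0]
        emb.arrays["rel"][ri[POS]] = [5.0, 6.0]
        v = environment_embedding(model, "E0").vector
        np.testing.assert_allclose(v, [1, 2, 3, 4, 5, 6])

    def test_length_3d_for_single_vector_models(self):
        model = random_model("transe", n_entities=3, n_environments=2, dim=7)
        assert environment_embedding(model, "E1").vector.shape == (21,)

    def test_length_6d_for_simple(self):
        model = random_model("simple", n_entities=3, n_environments=1, dim=5)
        assert environment_embedding(model, "E0").vector.shape == (30,)

    def test_incomplete_environment_rejected(self):
        records = [
            mk.InteractionRecord("A", "B", "e", label=POS),
            mk.InteractionRecord("B", "A", "e", label=NEG),
        ]
        kg = mk.build_kg(records, vocabulary_mode="observed_only")
        emb = mk.init_embeddings(kg.entities, kg.relations, "distmult", 4, seed=0)
        model = mk.TrainedModel(emb, mk.TrainConfig(model="distmult"), [])
        with pytest.raises(ValueError, match="incomplete"):
            environment_embedding(model, "e")


class TestEnvironmentDistance:
    def test_identity(self):
        v = np.array([1.0, 2, 3])
        assert environment_distance(v, v, "euclidean") == 0.0
        assert environment_distance(v, v, "cosine") == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_unit_vectors(self):
        a, b = np.array([1.0, 0]), np.array([0.0, 1])
        assert environment_distance(a, b, "cosine") == pytest.approx(1.0)
        assert environment_distance(a, b, "euclidean") == pytest.approx(math.sqrt(2))

    def test_antipodal_cosine(self):
        v = np.array([0.3, -2.0, 1.1])
        assert environment_distance(v, -v, "cosine") == pytest.approx(2.0)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(25):
            a, b, c = rng.standard_normal((3, 4))
            for metric in ("euclidean", "cosine"):
                assert environment_distance(a, b, metric) == pytest.approx(
                    environment_distance(b, a, metric)
                )
            ab = environment_distance(a, b, "euclidean")
            bc = environment_distance(b, c, "euclidean")
            ac = environment_distance(a, c, "euclidean")
            assert ac <= ab + bc + 1e-12

    def test_zero_vector_cosine_rejected(self):
        with pytest.raises(ValueError):
            environment_distance(np.zeros(3), np.ones(3), "cosine")


def rule_fixture():
    """A model whose E0 is near E1 and far from E2, plus observations."""
    model = random_model("distmult", n_entities=4, n_environments=3, dim=2,
                         seed=0)
    emb = model.embeddings
    for i, rel in enumerate(emb.relation_ids):
        base = {"E0": 0.0, "E1": 0.1, "E2": 10.0}[rel.environment]
        emb.arrays["rel"][i] = [base + int(rel.itype), base]
    return model


class TestEnvironmentRule:
    def test_first_hit_copies_nearest_donor(self):
        model = rule_fixture()
        records = [
            mk.InteractionRecord("S0", "S1", "E1", label=POS),
            mk.InteractionRecord("S0", "S1", "E2", label=NEG),
        ]
        ref = mk.build_kg(records, vocabulary_mode="full_grid")
        pred, donor, dist = environment_rule_predict(
            model, ref, ("S0", "S1", "E0")
        )
        assert (pred, donor) == (POS, "E1")
        assert dist < 1.0

    def test_fallback_to_second_nearest(self):
        model = rule_fixture()
        records = [mk.InteractionRecord("S0", "S1", "E2", label=NEG)]
        ref = mk.build_kg(records, vocabulary_mode="full_grid")
        pred, donor, _ = environment_rule_predict(model, ref, ("S0", "S1", "E0"))
        assert (pred, donor) == (NEG, "E2")

    def test_max_distance_excludes_far_donors(self):
        model = rule_fixture()
        records = [mk.InteractionRecord("S0", "S1", "E2", label=NEG)]
        ref = mk.build_kg(records, vocabulary_mode="full_grid")
        with pytest.raises(LookupError, match="no donor"):
            environment_rule_predict(
                model, ref, ("S0", "S1", "E0"), max_distance=1.0
            )

    def test_no_observation_anywhere_rejected(self):
        model = rule_fixture()
        ref = mk.build_kg(
            [mk.InteractionRecord("S2", "S3", "E1", label=NEU)],
            vocabulary_mode="full_grid",
        )
        with pytest.raises(LookupError):
            environment_rule_predict(model, ref, ("S0", "S1", "E0"))


class TestRecommend:
    def test_ordering_and_min_max_normalization(self):
        model = random_model("distmult", n_entities=4, n_environments=1, dim=2)
        emb = model.embeddings
        rel = emb.relation_ids[0]
        emb.arrays["rel"][0] = [1.0, 0.0]
        emb.arrays["ent"][0] = [1.0, 0.0]  # target
        emb.arrays["ent"][1] = [3.0, 0.0]
        emb.arrays["ent"][2] = [1.0, 0.0]
        rec = recommend(model, "S0", rel.itype, "E0", ["S1", "S2"])
        assert rec.candidates == ("S1", "S2")
        assert rec.best == "S1"
        assert rec.normalized_scores == (1.0, 0.0)

    def test_best_is_argmax_of_raw_scores(self, trained_simple):
        ents = trained_simple.embeddings.entity_ids
        env = trained_simple.embeddings.relation_ids[0].environment
        rec = recommend(trained_simple, ents[0], NEG, env, list(ents[1:]))
        assert rec.scores[0] == max(rec.scores)
        assert rec.best == rec.candidates[0]

    @pytest.mark.parametrize("direction", [
        "candidates_affect_target", "target_affects_candidates",
    ])
    def test_agreement_with_rescoring_oracle(self, trained_simple, direction):
        emb = trained_simple.embeddings
        ents = emb.entity_ids
        env = emb.relation_ids[0].environment
        rel = mk.Relation(POS, env)
        rec = recommend(trained_simple, ents[0], POS, env, list(ents[1:]),
                        direction)
        for cand, score in zip(rec.candidates, rec.scores):
            triple = (
                mk.Triple(cand, rel, ents[0])
                if direction == "candidates_affect_target"
                else mk.Triple(ents[0], rel, cand)
            )
            assert score == pytest.approx(score_triple(emb, triple))

    def test_permutation_invariance(self, trained_simple, rng):
        ents = list(trained_simple.embeddings.entity_ids)
        env = trained_simple.embeddings.relation_ids[0].environment
        cands = ents[1:]
        rec1 = recommend(trained_simple, ents[0], NEU, env, cands)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        rec2 = recommend(trained_simple, ents[0], NEU, env, shuffled)
        assert rec1.candidates == rec2.candidates
        assert rec1.scores == rec2.scores

    def test_constant_scores_normalize_to_one(self):
        model = random_model("distmult", n_entities=4, n_environments=1, dim=2)
        model.embeddings.arrays["rel"][:] = 0.0
        rel = model.embeddings.relation_ids[0]
        rec = recommend(model, "S0", rel.itype, "E0", ["S1", "S2", "S3"])
        assert rec.normalized_scores == (1.0, 1.0, 1.0)

    def test_validation_errors(self, trained_simple):
        ents = trained_simple.embeddings.entity_ids
        env = trained_simple.embeddings.relation_ids[0].environment
        with pytest.raises(ValueError):
            recommend(trained_simple, ents[0], NEG, env, [])
        with pytest.raises(ValueError):
            recommend(trained_simple, ents[0], NEG, env, [ents[0], ents[1]])


class TestDistanceMatrices:
    def test_environment_matrix_is_symmetric_with_zero_diagonal(
        self, trained_simple
    ):
        df = environment_distance_matrix(trained_simple)
        mat = df.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        assert list(df.index) == list(df.columns)

    def test_strain_matrix_covers_all_strains(self, trained_simple):
        df = strain_distance_matrix(trained_simple)
        assert list(df.index) == list(trained_simple.embeddings.entity_ids)
        assert np.allclose(df.to_numpy(), df.to_numpy().T)
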