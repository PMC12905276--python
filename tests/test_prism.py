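"""Tests for similarity matrices, the pair kernel, and pair prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from repurposekit.prism import (
    KroneckerKernel,
    MaterializationError,
    SimilarityMatrix,
    combine_similarities,
    cooccurrence_similarity,
    guilt_by_association_score,
    jaccard_target_similarity,
    kronecker_kernel,
    ontology_similarity,
    predict_pairs,
    tanimoto_matrix,
    train_pair_classifier,
)
from repurposekit.simulate import generate_similarity_world

from oracles import brute_force_gba


def _identity_kernel(ids):
    return SimilarityMatrix(ids=tuple(ids), values=np.eye(len(ids)), source="combined")


def _random_psd(n, rng):
    a = rng.normal(size=(n, n))
    m = a @ a.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    return SimilarityMatrix(ids=tuple(f"e{i}" for i in range(n)), values=m)


class TestTanimoto:
    def test_identical_fingerprints_score_one(self):
        fps = {"a": np.array([1, 1, 0, 1]), "b": np.array([1, 1, 0, 1])}
        assert tanimoto_matrix(fps)["a", "b"] == 1.0

    def test_hand_example_one_third(self):
        fps = {"a": np.array([1, 1, 0, 0]), "b": np.array([1, 0, 1, 0])}
        assert tanimoto_matrix(fps)["a", "b"] == pytest.approx(1 / 3)

    def test_disjoint_fingerprints_score_zero(self):
        fps = {"a": np.array([1, 1, 0, 0]), "b": np.array([0, 0, 1, 1])}
        assert tanimoto_matrix(fps)["a", "b"] == 0.0

    def test_both_empty_convention(self):
        fps = {"a": np.zeros(4, dtype=int), "b": np.zeros(4, dtype=int)}
        m = tanimoto_matrix(fps)
        assert m["a", "b"] == 0.0
        assert m["a", "a"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto_matrix({"a": np.ones(4, dtype=int), "b": np.ones(5, dtype=int)})


class TestJaccardTargets:
    def test_equal_sets_score_one(self):
        m = jaccard_target_similarity({"a": {"T1", "T2"}, "b": {"T1", "T2"}})
        assert m["a", "b"] == 1.0

    def test_hand_example_one_third(self):
        m = jaccard_target_similarity({"a": {"T1", "T2"}, "b": {"T2", "T3"}})
        assert m["a", "b"] == pytest.approx(1 / 3)

    def test_empty_against_nonempty_scores_zero(self):
        m = jaccard_target_similarity({"a": {"T1"}, "b": set()})
        assert m["a", "b"] == 0.0


class TestOntologySimilarity:
    EDGES = [("p", "root"), ("c", "p"), ("q", "root")]

    def test_same_term_scores_one(self):
        m = ontology_similarity(self.EDGES, {"d1": {"c"}, "d2": {"c"}})
        assert m["d1", "d2"] == 1.0

    def test_parent_child_chain_two_thirds(self):
        """Ancestors {p, root} vs {c, p, root} -> Jaccard 2/3."""
        m = ontology_similarity(self.EDGES, {"d1": {"c"}, "d2": {"p"}})
        assert m["d1", "d2"] == pytest.approx(2 / 3)

    def test_depth_one_siblings_one_third(self):
        m = ontology_similarity(self.EDGES, {"d1": {"p"}, "d2": {"q"}})
        assert m["d1", "d2"] == pytest.approx(1 / 3)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            ontology_similarity([("a", "b"), ("b", "a")], {"d": {"a"}})

    def test_unannotated_disease_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            ontology_similarity(self.EDGES, {"d1": set()})


class TestCooccurrenceSimilarity:
    def test_proportional_profiles_score_one(self):
        counts = pd.DataFrame([[2, 4, 0], [1, 2, 0], [0, 0, 5]],
                              index=list("abc"), columns=list("abc"))
        assert cooccurrence_similarity(counts)["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_profiles_score_zero(self):
        counts = pd.DataFrame([[1, 0, 0], [0, 2, 0], [0, 0, 1]],
                              index=list("abc"), columns=list("abc"))
        m = cooccurrence_similarity(counts)
        assert m["a", "b"] == 0.0

    def test_hand_cosine_half(self):
        counts = pd.DataFrame([[1, 1, 0], [1, 0, 1], [0, 1, 1]],
                              index=list("abc"), columns=list("abc"))
        assert cooccurrence_similarity(counts)["a", "b"] == pytest.approx(0.5)

    def test_zero_profile_warns_and_scores_zero(self):
        counts = pd.DataFrame([[1, 0, 0], [0, 1, 0], [0, 0, 0]],
                              index=list("abc"), columns=list("abc"))
        with pytest.warns(UserWarning, match="all-zero"):
            m = cooccurrence_similarity(counts)
        assert m["a", "c"] == 0.0 and m["c", "c"] == 1.0


class TestCombineSimilarities:
    def test_single_psd_matrix_unchanged(self, rng):
        m = _random_psd(6, rng)
        combined = combine_similarities([m], [1.0])
        assert np.allclose(combined.values, m.values, atol=1e-10)

    def test_equal_matrices_unchanged(self, rng):
        m = _random_psd(5, rng)
        combined = combine_similarities([m, m], [0.5, 0.5])
        assert np.allclose(combined.values, m.values, atol=1e-10)

    def test_indefinite_matrix_repaired_to_psd(self):
        v = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        m = SimilarityMatrix(ids=("a", "b", "c"), values=v)
        assert m.min_eigenvalue() < -1e-8  # genuinely indefinite input
        repaired = combine_similarities([m], [1.0])
        assert repaired.min_eigenvalue() >= -1e-8
        assert np.allclose(np.diag(repaired.values), 1.0)

    def test_id_mismatch_rejected(self, rng):
        a = _random_psd(4, rng)
        b = SimilarityMatrix(ids=("x", "y", "z", "w"), values=np.eye(4))
        with pytest.raises(ValueError, match="entity ids"):
            combine_similarities([a, b])


class TestKroneckerKernel:
    def test_identity_components_give_identity_pair_kernel(self):
        kc = _identity_kernel(["c1", "c2"])
        kd = _identity_kernel(["d1", "d2"])
        full = kronecker_kernel(kc, kd).materialize()
        assert np.array_equal(full, np.eye(4))

    def test_definitional_product(self, rng):
        kc = _random_psd(4, rng)
        kd = _random_psd(3, rng)
        k = kronecker_kernel(kc, kd)
        got = k.value((kc.ids[0], kd.ids[1]), (kc.ids[2], kd.ids[2]))
        assert got == pytest.approx(kc.values[0, 2] * kd.values[1, 2])

    def test_eigenvalues_are_pairwise_products(self, rng):
        """Spectrum of the pair kernel = all products of component spectra."""
        kc = _random_psd(5, rng)
        kd = _random_psd(5, rng)
        full = kronecker_kernel(kc, kd).materialize()
        got = np.sort(np.linalg.eigvalsh(full))
        ec = np.linalg.eigvalsh(kc.values)
        ed = np.linalg.eigvalsh(kd.values)
        expected = np.sort(np.outer(ec, ed).ravel())
        assert np.allclose(got, expected, atol=1e-8)

    def test_block_matches_materialized(self, rng):
        kc = _random_psd(3, rng)
        kd = _random_psd(2, rng)
        k = kronecker_kernel(kc, kd)
        pairs = [(c, d) for c in kc.ids for d in kd.ids]
        assert np.allclose(k.block(pairs, pairs), k.materialize(), atol=1e-12)

    def test_materialization_cap_enforced(self, rng):
        kc = _random_psd(4, rng)
        kd = _random_psd(4, rng)
        k = KroneckerKernel(kc=kc, kd=kd, materialize_cap=10)
        with pytest.raises(MaterializationError):
            k.materialize()


class TestPairClassifier:
    def test_separable_block_world_perfect_holdout_auroc(self):
        """Zero structural noise: held-out within-block pairs rank first."""
        w = generate_similarity_world(n_compounds=16, n_diseases=8, n_blocks=4,
                                      fp_flip_prob=0.0, holdout_frac=0.5, seed=0)
        kc = tanimoto_matrix(w.fingerprints)
        kd = ontology_similarity(w.ontology_edges, w.disease_terms)
        model = train_pair_classifier(kc, kd, w.indications, seed=0)
        holdout = sorted(w.truth.holdout_pairs)
        negatives = [(c, d) for c in kc.ids for d in kd.ids
                     if (c, d) not in w.truth.true_pairs]
        scores = model.decision_function(holdout + negatives)
        y = [1] * len(holdout) + [0] * len(negatives)
        assert roc_auc_score(y, scores) == 1.0

    def test_identity_kernels_score_at_chance(self):
        aurocs = []
        for seed in range(10):
            w = generate_similarity_world(n_compounds=12, n_diseases=8,
                                          n_blocks=4, holdout_frac=0.5, seed=seed)
            kc = _identity_kernel(w.compound_ids)
            kd = _identity_kernel(w.disease_ids)
            model = train_pair_classifier(kc, kd, w.indications, seed=seed)
            holdout = sorted(w.truth.holdout_pairs)
            negatives = [(c, d) for c in kc.ids for d in kd.ids
                         if (c, d) not in w.truth.true_pairs]
            scores = model.decision_function(holdout + negatives)
            y = [1] * len(holdout) + [0] * len(negatives)
            aurocs.append(roc_auc_score(y, scores))
        assert 0.4 <= np.mean(aurocs) <= 0.6

    def test_empty_positives_rejected(self):
        kc = _identity_kernel(["c1", "c2"])
        kd = _identity_kernel(["d1", "d2"])
        with pytest.raises(ValueError):
            train_pair_classifier(kc, kd, [], seed=0)

    def test_out_of_universe_pair_rejected(self):
        kc = _identity_kernel(["c1", "c2"])
        kd = _identity_kernel(["d1", "d2"])
        with pytest.raises(ValueError, match="universe"):
            train_pair_classifier(kc, kd, [("nope", "d1")], seed=0)


class TestGuiltByAssociation:
    def test_nearest_neighbor_scenario(self):
        """B treats A; D resembles B and C resembles A, so (D, C) beats a
        compound E dissimilar to every treating compound."""
        kc = SimilarityMatrix(
            ids=("B", "D", "E"),
            values=np.array([[1.0, 0.9, 0.05], [0.9, 1.0, 0.05], [0.05, 0.05, 1.0]]),
        )
        kd = SimilarityMatrix(
            ids=("A", "C"),
            values=np.array([[1.0, 0.8], [0.8, 1.0]]),
        )
        scores = guilt_by_association_score(kc, kd, [("B", "A")])
        assert scores.at["D", "C"] > scores.at["E", "C"]

    def test_known_pair_scores_one(self):
        kc = _identity_kernel(["c1", "c2"])
        kd = _identity_kernel(["d1", "d2"])
        scores = guilt_by_association_score(kc, kd, [("c1", "d1")])
        assert scores.at["c1", "d1"] == 1.0

    def test_no_similar_treating_compound_scores_zero(self):
        kc = _identity_kernel(["c1", "c2"])
        kd = _identity_kernel(["d1", "d2"])
        scores = guilt_by_association_score(kc, kd, [("c1", "d1")])
        assert scores.at["c2", "d2"] == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        kc = _random_psd(8, rng)
        kd = _random_psd(10, rng)
        pairs = [(kc.ids[i], kd.ids[j])
                 for i, j in zip(rng.integers(0, 8, 6), rng.integers(0, 10, 6))]
        got = guilt_by_association_score(kc, kd, pairs)
        expected = brute_force_gba(kc.to_frame(), kd.to_frame(), pairs)
        for (c, d), v in expected.items():
            assert got.at[c, d] == pytest.approx(v, abs=1e-12)


@pytest.fixture(scope="module")
def model_and_world():
    w = generate_similarity_world(n_compounds=12, n_diseases=8, n_blocks=4,
                                  holdout_frac=0.5, seed=3)
    kc = combine_similarities(
        [tanimoto_matrix(w.fingerprints),
         jaccard_target_similarity(w.target_sets)], source="compound")
    kd = combine_similarities(
        [ontology_similarity(w.ontology_edges, w.disease_terms),
         cooccurrence_similarity(w.disease_comention)], source="disease")
    model = train_pair_classifier(kc, kd, w.indications, seed=3)
    return model, w


class TestPredictPairs:
    def test_all_known_candidates_leave_no_novel_ranking(self, model_and_world):
        model, w = model_and_world
        known = list(w.indications)
        table = predict_pairs(model, known, known_pairs=known)
        assert table["known"].all()
        assert table["novel_rank"].isna().all()

    def test_output_covers_all_candidates(self, model_and_world):
        model, w = model_and_world
        candidates = [(c, d) for c in w.compound_ids for d in w.disease_ids]
        table = predict_pairs(model, candidates)
        assert len(table) == len(candidates)

    def test_permutation_equivariance_of_scores(self, rng):
        """Relabeling entities permutes but does not change pair scores."""
        w = generate_similarity_world(n_compounds=8, n_diseases=8, n_blocks=4,
                                      holdout_frac=0.0, seed=5)
        kc = tanimoto_matrix(w.fingerprints)
        kd = ontology_similarity(w.ontology_edges, w.disease_terms)
        model = train_pair_classifier(kc, kd, w.indications, seed=1)
        pairs = [(c, d) for c in kc.ids for d in kd.ids]
        base = dict(zip(pairs, model.decision_function(pairs)))

        relabel = {c: f"z_{c}" for c in kc.ids}
        kc2 = SimilarityMatrix(ids=tuple(relabel[c] for c in kc.ids),
                               values=kc.values, source="fingerprint")
        model2 = train_pair_classifier(
            kc2, kd, [(relabel[c], d) for c, d in w.indications], seed=1)
        for (c, d), s in base.items():
            s2 = model2.decision_function([(relabel[c], d)])[0]
            assert s2 == pytest.approx(s, abs=1e-8)

    def test_unknown_candidate_rejected(self, model_and_world):
        model, _ = model_and_world
        with pytest.raises(ValueError, match="universe"):
            predict_pairs(model, [("ghost", "Dis001")])
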