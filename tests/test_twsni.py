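import numpy as np
import pytest

from mcsdti.containers import InteractionMatrix, ScoreMatrix, SimilarityMatrix
from mcsdti.partitioning import partition_targets
from mcsdti.twsni import (
    evaluate_twsni,
    nearest_neighbor,
    np_drug_side,
    np_pair_score,
    np_target_side,
    run_twsni_fold,
)


def sim(ids, values):
    return SimilarityMatrix(tuple(ids), np.array(values, dtype=float))


class TestNearestNeighbor:
    S = staticmethod(
        lambda: sim(
            ("a", "b", "q"),
            [[1.0, 0.5, 0.2], [0.5, 1.0, 0.9], [0.2, 0.9, 1.0]],
        )
    )

    def test_picks_maximum(self):
        nn = nearest_neighbor(self.S(), "q", {"a", "b"})
        assert nn.neighbor_id == "b" and nn.similarity == 0.9

    def test_tie_breaks_lexicographically(self):
        S = sim(("a", "b", "q"), [[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        assert nearest_neighbor(S, "q", {"a", "b"}).neighbor_id == "a"

    def test_query_self_excluded(self):
        nn = nearest_neighbor(self.S(), "q", {"a", "b", "q"})
        assert nn.neighbor_id != "q"

    def test_empty_candidates(self):
        with pytest.raises(ValueError, match="no candidates"):
            nearest_neighbor(self.S(), "q", {"q"})


class TestProfileRules:
    def test_target_side_scales_neighbor_column(self):
        # s_t(t_new, t*) = 0.7, Y[:, t*] = [1, 0, 1] -> [0.7, 0, 0.7]
        S_t = sim(("t*", "tn"), [[1.0, 0.7], [0.7, 1.0]])
        Y = InteractionMatrix(("d1", "d2", "d3"), ("t*", "tn"), [[1, 0], [0, 0], [1, 0]])
        col = np_target_side(S_t, Y, "tn", {"t*"})
        np.testing.assert_allclose(col, [0.7, 0.0, 0.7])

    def test_zero_similarity_zero_column(self):
        S_t = sim(("t*", "tn"), [[1.0, 0.0], [0.0, 1.0]])
        Y = InteractionMatrix(("d1", "d2"), ("t*", "tn"), [[1, 0], [1, 0]])
        np.testing.assert_allclose(np_target_side(S_t, Y, "tn", {"t*"}), [0.0, 0.0])

    def test_unit_similarity_copies_column(self):
        S_t = sim(("t*", "tn"), [[1.0, 1.0], [1.0, 1.0]])
        Y = InteractionMatrix(("d1", "d2"), ("t*", "tn"), [[1, 0], [0, 0]])
        np.testing.assert_allclose(np_target_side(S_t, Y, "tn", {"t*"}), [1.0, 0.0])

    def test_drug_side_scales_neighbor_row(self):
        # s_d = 0.8, neighbour row [1, 1, 0] -> [0.8, 0.8, 0]
        S_d = sim(("d*", "dn"), [[1.0, 0.8], [0.8, 1.0]])
        Y = InteractionMatrix(("d*", "dn"), ("t1", "t2", "t3"), [[1, 1, 0], [0, 0, 0]])
        np.testing.assert_allclose(np_drug_side(S_d, Y, "dn", {"d*"}), [0.8, 0.8, 0.0])

    def test_all_zero_neighbor_row(self):
        S_d = sim(("d*", "dn"), [[1.0, 0.9], [0.9, 1.0]])
        Y = InteractionMatrix(("d*", "dn"), ("t1", "t2"), [[0, 0], [0, 0]])
        np.testing.assert_allclose(np_drug_side(S_d, Y, "dn", {"d*"}), [0.0, 0.0])

    @pytest.mark.parametrize(
        "a,b,expected", [(0.8, 0.0, 0.4), (0.3, 0.3, 0.3), (0.0, 0.0, 0.0)]
    )
    def test_pair_score_is_mean(self, a, b, expected):
        assert np_pair_score(a, b) == pytest.approx(expected)


class TestRunFold:
    def micro_world(self):
        """Two targets, one training drug: the worked chain-rule example."""
        S_d = sim(("d*", "dn"), [[1.0, 0.8], [0.8, 1.0]])
        S_t = sim(("t", "t*"), [[1.0, 0.5], [0.5, 1.0]])
        Y = InteractionMatrix(("d*", "dn"), ("t", "t*"), [[1, 0], [0, 0]])
        return S_d, S_t, Y

    def test_worked_chain_example(self):
        """Drug side 0.8 x 1; target side 0.5 x (0.8 x 0); mean 0.4."""
        S_d, S_t, Y = self.micro_world()
        scores = run_twsni_fold(S_d, S_t, Y, {"d*"}, {"dn"})
        assert scores.scores[0, scores.target_index("t")] == pytest.approx(0.4)
        # and for t*: drug side 0.8*0=0, target side 0.5*(0.8*1)=0.4 -> 0.2
        assert scores.scores[0, scores.target_index("t*")] == pytest.approx(0.2)

    def test_all_cells_scored(self, small_dataset):
        Y, _, _, S_d, S_t = small_dataset
        drugs = list(Y.drug_ids)
        scores = run_twsni_fold(S_d, S_t, Y, set(drugs[:20]), set(drugs[20:]))
        assert scores.mask.all()
        assert scores.scores.shape == (10, Y.n_targets)
        assert scores.scores.min() >= 0 and scores.scores.max() <= 1

    def test_duplicate_training_drug_copies_row(self):
        # dn identical to training drug da (tanimoto 1): drug side copies da's row
        S_d = sim(("da", "db", "dn"), [[1, 0, 1], [0, 1, 0], [1, 0, 1]])
        S_t = sim(("t1", "t2"), np.eye(2))
        Y = InteractionMatrix(("da", "db", "dn"), ("t1", "t2"), [[1, 0], [0, 1], [0, 0]])
        scores = run_twsni_fold(S_d, S_t, Y, {"da", "db"}, {"dn"})
        # identity S_t: target side = 0 everywhere -> final = drug_side / 2
        np.testing.assert_allclose(scores.scores[0], [0.5, 0.0])

    def test_identity_target_similarity_halves_drug_side(self, small_dataset):
        Y, _, _, S_d, _ = small_dataset
        S_t = SimilarityMatrix(Y.target_ids, np.eye(Y.n_targets))
        drugs = list(Y.drug_ids)
        train, test = set(drugs[:20]), set(drugs[20:])
        scores = run_twsni_fold(S_d, S_t, Y, train, test)
        from mcsdti.twsni import np_drug_side

        for i, d in enumerate(scores.drug_ids):
            np.testing.assert_allclose(
                scores.scores[i], 0.5 * np_drug_side(S_d, Y, d, train)
            )

    def test_no_test_label_leakage(self, small_dataset):
        Y, _, _, S_d, S_t = small_dataset
        drugs = list(Y.drug_ids)
        train, test = set(drugs[:20]), set(drugs[20:])
        before = run_twsni_fold(S_d, S_t, Y, train, test)
        tampered = Y.values.copy()
        test_rows = [Y.drug_index(d) for d in test]
        tampered[test_rows] = 1 - tampered[test_rows]
        Y2 = InteractionMatrix(Y.drug_ids, Y.target_ids, tampered)
        after = run_twsni_fold(S_d, S_t, Y2, train, test)
        np.testing.assert_array_equal(before.scores, after.scores)


class TestEvaluate:
    def test_perfect_separation(self):
        Y = InteractionMatrix(("a", "b"), ("t1", "t2"), [[1, 0], [0, 0]])
        part = partition_targets(Y, 1)
        scores = ScoreMatrix(
            ("a", "b"), ("t1", "t2"),
            np.array([[0.9, 0.1], [0.2, 0.0]]), np.ones((2, 2), dtype=bool),
        )
        assert evaluate_twsni(scores, Y, part).pooled_auc == 1.0

    def test_constant_scores_give_half(self):
        Y = InteractionMatrix(("a", "b"), ("t1", "t2"), [[1, 0], [0, 0]])
        part = partition_targets(Y, 1)
        scores = ScoreMatrix(
            ("a", "b"), ("t1", "t2"), np.full((2, 2), 0.3), np.ones((2, 2), dtype=bool)
        )
        assert evaluate_twsni(scores, Y, part).pooled_auc == 0.5

    def test_single_class_pool_not_evaluable(self):
        Y = InteractionMatrix(("a", "b"), ("t1",), [[0], [0]])
        part = partition_targets(Y, 1)
        scores = ScoreMatrix(("a", "b"), ("t1",), np.zeros((2, 1)), np.ones((2, 1), dtype=bool))
        result = evaluate_twsni(scores, Y, part)
        assert result.pooled_auc is None and result.status == "not-evaluable"

    def test_empty_twsni_part(self, tiny_Y):
        part = partition_targets(tiny_Y, 0)
        # force an empty small part by using tau=-? use a Y where all counts > 0
        Y = InteractionMatrix(("a", "b"), ("t1",), [[1], [1]])
        part = partition_targets(Y, 0)
        assert part.twsni_ids == ()
        scores = ScoreMatrix(("a",), ("t1",), np.zeros((1, 1)), np.ones((1, 1), dtype=bool))
        assert evaluate_twsni(scores, Y, part).pooled_auc is None
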