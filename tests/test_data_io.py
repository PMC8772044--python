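import json

import numpy as np
import pytest

from mcsdti.containers import (
    InteractionMatrix,
    SimilarityMatrix,
    ValidationError,
)
from mcsdti.data_io import (
    dataset_summary,
    degree_concentration,
    format_mean_sd,
    read_dense_matrix,
    read_pair_list,
    read_report,
    write_dense_matrix,
    write_pair_list,
    write_report,
)


class TestPairList:
    def test_pairs_build_matrix(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("dA\tt1\ndA\tt2\ndB\tt1\n")
        Y = read_pair_list(path)
        assert Y.drug_ids == ("dA", "dB") and Y.target_ids == ("t1", "t2")
        assert Y.values.sum() == 3
        assert Y.values[Y.drug_index("dB"), Y.target_index("t2")] == 0

    def test_duplicate_pair_is_idempotent(self, tmp_path, caplog):
        path = tmp_path / "pairs.tsv"
        path.write_text("dA\tt1\ndA\tt1\ndB\tt2\n")
        with caplog.at_level("WARNING", logger="mcsdti"):
            Y = read_pair_list(path)
        assert Y.values.sum() == 2
        assert "duplicate pair" in caplog.text

    def test_unknown_identifier_in_supplied_universe(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("dX\tt9\n")
        with pytest.raises(ValidationError, match="t9"):
            read_pair_list(path, all_drugs=["dX"], all_targets=["t1", "t2"])

    def test_target_drug_column_order(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("t1\tdA\n")
        Y = read_pair_list(path, column_order="target-drug")
        assert Y.drug_ids == ("dA",) and Y.target_ids == ("t1",)

    def test_round_trip(self, tmp_path, tiny_Y):
        path = tmp_path / "pairs.tsv"
        write_pair_list(tiny_Y, path)
        back = read_pair_list(path, all_drugs=tiny_Y.drug_ids, all_targets=tiny_Y.target_ids)
        np.testing.assert_array_equal(back.values, tiny_Y.values)


class TestDenseMatrix:
    def test_interaction_round_trip(self, tmp_path):
        Y = InteractionMatrix(("d1", "d2"), ("t1", "t2"), [[0, 1], [1, 0]])
        path = tmp_path / "y.tsv"
        write_dense_matrix(Y, path)
        back = read_dense_matrix(path, "interaction")
        assert back.drug_ids == Y.drug_ids
        np.testing.assert_array_equal(back.values, Y.values)

    def test_non_binary_interaction_names_cell(self, tmp_path):
        path = tmp_path / "y.tsv"
        path.write_text("\tt1\tt2\nd1\t0\t2\nd2\t1\t0\n")
        with pytest.raises(ValidationError, match=r"\(d1, t2\)"):
            read_dense_matrix(path, "interaction")

    def test_asymmetric_similarity_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("\ta\tb\na\t1.0\t0.3\nb\t0.7\t1.0\n")
        with pytest.raises(ValidationError, match="asymmetric"):
            read_dense_matrix(path, "similarity")

    def test_identity_similarity_valid(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("\ta\tb\na\t1.0\t0.0\nb\t0.0\t1.0\n")
        S = read_dense_matrix(path, "similarity")
        assert isinstance(S, SimilarityMatrix)

    def test_feature_round_trip(self, tmp_path, small_dataset):
        _, D, T, _, _ = small_dataset
        for obj, kind in ((D, "drug"), (T, "target")):
            path = tmp_path / f"{kind}.tsv"
            write_dense_matrix(obj, path)
            back = read_dense_matrix(path, "feature", feature_kind=kind)
            np.testing.assert_allclose(back.values, obj.values)
            assert back.row_ids == obj.row_ids

    def test_similarity_round_trip(self, tmp_path, small_dataset):
        *_, S_d, S_t = small_dataset
        for name, S in (("sd", S_d), ("st", S_t)):
            path = tmp_path / f"{name}.tsv"
            write_dense_matrix(S, path)
            back = read_dense_matrix(path, "similarity")
            np.testing.assert_allclose(back.values, S.values, atol=1e-9)


class TestDatasetSummary:
    # printed benchmark sizes: (drugs, targets, interactions, pct, decimals)
    BENCHMARKS = [
        ("NR", 54, 26, 90, 6.4, 1),
        ("IC", 210, 204, 1476, 3.4, 1),
        ("GPCR", 223, 95, 635, 3.0, 1),
        ("E", 445, 664, 2926, 0.99, 2),
        ("DB", 5877, 3348, 12674, 0.064, 3),
    ]

    @pytest.mark.parametrize("name,u,v,n,pct,dec", BENCHMARKS)
    def test_benchmark_densities(self, name, u, v, n, pct, dec):
        """Interaction density matches each benchmark's printed proportion."""
        rng = np.random.default_rng(0)
        # a matrix with exactly n interactions is enough; placement is irrelevant
        flat = np.zeros(u * v, dtype=np.int8)
        flat[rng.choice(u * v, size=n, replace=False)] = 1
        Y = InteractionMatrix(
            tuple(f"d{i}" for i in range(u)),
            tuple(f"t{j}" for j in range(v)),
            flat.reshape(u, v),
        )
        summary = dataset_summary(Y)
        assert summary.n_interactions == n
        assert summary.density_rounded(dec) == pct

    def test_all_zero_matrix(self):
        Y = InteractionMatrix(("d1", "d2", "d3"), ("t1", "t2", "t3"), np.zeros((3, 3)))
        s = dataset_summary(Y)
        assert s.n_interactions == 0 and s.density_percent == 0.0


class TestDegreeConcentration:
    def test_hand_counted_example(self):
        # degrees [5, 3, 1, 1]; top 25% = 1 target -> 5/10
        values = np.zeros((5, 4), dtype=int)
        for j, deg in enumerate([5, 3, 1, 1]):
            values[:deg, j] = 1
        Y = InteractionMatrix(tuple("abcde"), ("t1", "t2", "t3", "t4"), values)
        assert degree_concentration(Y, 0.25) == pytest.approx(0.5)

    def test_single_dominant_target(self):
        values = np.zeros((4, 5), dtype=int)
        values[:, 0] = 1
        Y = InteractionMatrix(tuple("wxyz"), tuple("abcde"), values)
        assert degree_concentration(Y, 0.2) == 1.0

    def test_uniform_degrees(self):
        Y = InteractionMatrix(
            ("d1", "d2"), tuple(f"t{j}" for j in range(10)), np.ones((2, 10), dtype=int)
        )
        assert degree_concentration(Y, 0.2) == pytest.approx(0.2)

    def test_monotone_in_top_fraction(self, default_dataset):
        Y = default_dataset[0]
        fractions = np.linspace(0.05, 1.0, 20)
        shares = [degree_concentration(Y, f) for f in fractions]
        assert all(b >= a for a, b in zip(shares, shares[1:]))
        assert shares[-1] == 1.0

    def test_zero_interactions_error(self):
        Y = InteractionMatrix(("d1",), ("t1",), [[0]])
        with pytest.raises(ValidationError):
            degree_concentration(Y, 0.5)


class TestReportIO:
    def test_mean_sd_line(self):
        assert format_mean_sd([0.8, 0.9]) == "0.8500 ± 0.0707"

    def test_round_trip_identity(self, tmp_path):
        report = {
            "per_fold": [{"fold": 0, "twlni": {"macro_auc": 0.8}}],
            "aggregate": {
                "twlni": {"fold_values": [0.8, 0.9], "mean": 0.85, "sd": 0.0707},
                "twsni": {"fold_values": [], "mean": None, "sd": None},
            },
            "config": {"tau": 1, "seed": 5},
        }
        path = tmp_path / "report.json"
        write_report(report, path)
        assert read_report(path) == report
        text = (tmp_path / "report.txt").read_text()
        assert "0.8500 ± 0.0707" in text
        assert "TWSNI: not evaluated" in text
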