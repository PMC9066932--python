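import numpy as np
import pytest

from circdrug import similarity
from circdrug.data_io import SequenceRecord
from circdrug.errors import StructureParseError, ValidationError
from conftest import dp_levenshtein_ratio


class TestLevenshteinRatio:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("ACGT", "", 0.0),
            ("", "", 1.0),
            ("ACGT", "ACCT", 0.75),  # one substitution (cost 2): (8-2)/8
        ],
    )
    def test_known_values(self, a, b, expected):
        assert similarity.levenshtein_ratio(a, b) == pytest.approx(expected)

    def test_agrees_with_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGT"))
        for _ in range(200):
            a = "".join(alphabet[rng.integers(4, size=rng.integers(0, 31))])
            b = "".join(alphabet[rng.integers(4, size=rng.integers(0, 31))])
            assert similarity.levenshtein_ratio(a, b) == pytest.approx(
                dp_levenshtein_ratio(a, b), abs=1e-12
            )

    def test_symmetry(self):
        assert similarity.levenshtein_ratio("ACGTT", "GGT") == \
            similarity.levenshtein_ratio("GGT", "ACGTT")


class TestSequenceSimilarity:
    def test_identical_sequences_give_ones(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        m = similarity.sequence_similarity(recs)
        assert np.allclose(m.values, 1.0)

    def test_off_diagonal_matches_pair_oracle(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACCT")]
        m = similarity.sequence_similarity(recs)
        assert m.values[0, 1] == pytest.approx(0.75)

    def test_shape_and_invariants(self):
        rng = np.random.default_rng(3)
        alphabet = np.array(list("ACGT"))
        recs = [
            SequenceRecord(f"s{i}", "".join(alphabet[rng.integers(4, size=20)]))
            for i in range(6)
        ]
        m = similarity.sequence_similarity(recs)
        assert m.values.shape == (6, 6)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            similarity.sequence_similarity([])


class TestFingerprints:
    def test_same_smiles_deterministic(self):
        f1 = similarity.smiles_to_fingerprint("CCO")
        f2 = similarity.smiles_to_fingerprint("CCO")
        assert (f1 == f2).all() and f1.shape == (2048,)

    def test_equivalent_smiles_writings_match(self):
        # same molecule written in two ways canonicalises identically
        assert (similarity.smiles_to_fingerprint("CCO")
                == similarity.smiles_to_fingerprint("OCC")).all()

    def test_unparsable_structure_raises(self):
        with pytest.raises(StructureParseError, match="d7"):
            similarity.smiles_to_fingerprint("not_a_smiles", drug_id="d7")

    def test_custom_bit_length(self):
        assert similarity.smiles_to_fingerprint("c1ccccc1", n_bits=512).shape == (512,)


class TestTanimoto:
    def test_known_values(self):
        a = np.zeros(8, dtype=int); a[[0, 1, 2]] = 1
        b = np.zeros(8, dtype=int); b[[1, 2, 3]] = 1
        assert similarity.tanimoto(a, a) == 1.0
        assert similarity.tanimoto(a, 1 - a) == 0.0
        assert similarity.tanimoto(a, b) == pytest.approx(0.5)  # 2/4
        assert similarity.tanimoto(np.zeros(8), np.zeros(8)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            similarity.tanimoto(np.zeros(4), np.zeros(5))

    def test_agrees_with_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = (rng.random(32) < 0.3).astype(int)
            b = (rng.random(32) < 0.3).astype(int)
            on_a, on_b = set(np.flatnonzero(a)), set(np.flatnonzero(b))
            union = on_a | on_b
            expected = len(on_a & on_b) / len(union) if union else 0.0
            assert similarity.tanimoto(a, b) == pytest.approx(expected, abs=1e-12)


class TestDrugStructureSimilarity:
    def test_identical_fingerprints_give_ones(self):
        fp = np.tile((np.arange(16) % 3 == 0).astype(int), (3, 1))
        m = similarity.drug_structure_similarity(fp)
        assert np.allclose(m.values, 1.0)

    def test_disjoint_fingerprints_give_identity(self):
        fp = np.eye(4, 16, dtype=int)
        m = similarity.drug_structure_similarity(fp)
        assert np.allclose(m.values, np.eye(4))

    def test_matches_pairwise_tanimoto(self):
        rng = np.random.default_rng(5)
        fp = (rng.random((5, 24)) < 0.4).astype(int)
        m = similarity.drug_structure_similarity(fp)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert m.values[i, j] == pytest.approx(
                        similarity.tanimoto(fp[i], fp[j])
                    )
        assert np.allclose(np.diag(m.values), 1.0)


class TestGipKernel:
    def test_identical_profiles_similarity_one(self):
        p = np.array([[1, 0, 1], [1, 0, 1]])
        assert similarity.gip_kernel(p).values[0, 1] == pytest.approx(1.0)

    def test_identity_profiles_closed_form(self):
        # 2x2 identity: gamma = 1, ||IP1 - IP2||^2 = 2 -> exp(-2)
        k = similarity.gip_kernel(np.eye(2, dtype=int))
        assert k.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_all_zero_profiles_return_identity(self):
        k = similarity.gip_kernel(np.zeros((3, 4), dtype=int))
        assert (k.values == np.eye(3)).all()

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(9)
        p = (rng.random((6, 10)) < 0.4).astype(int)
        perm = rng.permutation(10)
        k1 = similarity.gip_kernel(p).values
        k2 = similarity.gip_kernel(p[:, perm]).values
        assert np.allclose(k1, k2)

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            similarity.gip_kernel(np.array([[0.5, 1.0]]))


class TestFuseAndBinarize:
    def test_fusion_branches(self):
        ids = ("a", "b")
        sp = similarity.SimilarityMatrix(ids, np.array([[1.0, 0.4], [0.4, 1.0]]))
        sg = similarity.SimilarityMatrix(ids, np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert similarity.fuse(sp, sg).values[0, 1] == pytest.approx(0.5)
        sp0 = similarity.SimilarityMatrix(ids, np.array([[1.0, 0.0], [0.0, 1.0]]))
        sg3 = similarity.SimilarityMatrix(ids, np.array([[1.0, 0.3], [0.3, 1.0]]))
        assert similarity.fuse(sp0, sg3).values[0, 1] == pytest.approx(0.3)

    def test_fuse_idempotent_on_equal_positive_inputs(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 1.0, size=(4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        s = similarity.SimilarityMatrix(tuple("abcd"), vals)
        assert np.allclose(similarity.fuse(s, s).values, vals)

    def test_fused_matrix_keeps_invariants(self):
        rng = np.random.default_rng(8)
        v1 = rng.uniform(0, 1, (5, 5)); v1 = (v1 + v1.T) / 2; np.fill_diagonal(v1, 1)
        v2 = rng.uniform(0, 1, (5, 5)); v2 = (v2 + v2.T) / 2; np.fill_diagonal(v2, 1)
        ids = tuple("abcde")
        fused = similarity.fuse(similarity.SimilarityMatrix(ids, v1),
                                similarity.SimilarityMatrix(ids, v2))
        assert np.allclose(fused.values, fused.values.T)
        assert np.allclose(np.diag(fused.values), 1.0)

    def test_fuse_id_mismatch_rejected(self):
        s1 = similarity.SimilarityMatrix(("a",), np.ones((1, 1)))
        s2 = similarity.SimilarityMatrix(("b",), np.ones((1, 1)))
        with pytest.raises(ValidationError):
            similarity.fuse(s1, s2)

    def test_binarize_strictly_greater(self):
        ids = ("a", "b", "c")
        vals = np.array([[1.0, 0.71, 0.70],
                         [0.71, 1.0, 0.1],
                         [0.70, 0.1, 1.0]])
        g = similarity.binarize(similarity.SimilarityMatrix(ids, vals), 0.7)
        assert g.adjacency[0, 1] == 1      # 0.71 > 0.7
        assert g.adjacency[0, 2] == 0      # 0.70 == threshold -> 0
        assert (np.diag(g.adjacency) == 1).all()

    def test_binarize_threshold_range_checked(self):
        s = similarity.SimilarityMatrix(("a",), np.ones((1, 1)))
        with pytest.raises(ValidationError):
            similarity.binarize(s, 1.5)

    def test_self_loops_at_any_threshold(self):
        s = similarity.SimilarityMatrix(("a", "b"), np.eye(2) * 0 + np.eye(2))
        for t in (0.0, 0.5, 1.0):
            assert (np.diag(similarity.binarize(s, t).adjacency) == 1).all()


class TestSimilarityMatrixValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            similarity.SimilarityMatrix(("a", "b"),
                                        np.array([[1.0, 0.2], [0.8, 1.0]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            similarity.SimilarityMatrix(("a", "b"),
                                        np.array([[1.0, 1.2], [1.2, 1.0]]))

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, (3, 3)); v = (v + v.T) / 2; np.fill_diagonal(v, 1)
        s = similarity.SimilarityMatrix(("x", "y", "z"), v)
        p = tmp_path / "s.csv"
        similarity.write_similarity(s, p)
        back = similarity.read_similarity(p)
        assert back.ids == s.ids
        assert np.allclose(back.values, s.values)
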