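"""Identity matrices, diagonal square clustering, divergence, global alignment."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as hst

from _oracles import affine_global_score, exhaustive_diagonal_clusters
from gefprobe import synth
from gefprobe.msa import (
    IdentityMatrix,
    Msa,
    average_identity,
    diagonal_square_clusters,
    global_align,
    key_residue_divergence,
    pairwise_identity_matrix,
    read_msa,
)


class TestIdentityMatrix:
    def test_identical_rows_give_100(self):
        m = Msa(names=["a", "b"], rows=["ACDEF", "ACDEF"])
        im = pairwise_identity_matrix(m)
        assert im.values[0, 1] == pytest.approx(100.0)

    def test_single_substitution_hand_count(self):
        m = Msa(names=["a", "b"], rows=["ACDEFGHIKL", "ACDEFGHIKV"])
        assert pairwise_identity_matrix(m).values[0, 1] == pytest.approx(90.0)

    def test_gap_handling_differs_by_mode(self):
        m = Msa(names=["a", "b"], rows=["AC-DE", "ACQDE"])
        assert pairwise_identity_matrix(m, "both_ungapped").values[0, 1] == pytest.approx(100.0)
        assert pairwise_identity_matrix(m, "alignment_length").values[0, 1] == pytest.approx(80.0)

    def test_symmetric_with_diagonal_100(self):
        msa, _ = synth.make_synthetic_msa([2, 3], 70, 20, length=120, seed=2)
        im = pairwise_identity_matrix(msa)
        np.testing.assert_allclose(im.values, im.values.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(im.values), 100.0)
        assert im.values.min() >= 0 and im.values.max() <= 100

    def test_row_permutation_permutes_values_consistently(self, rng):
        msa, _ = synth.make_synthetic_msa([3, 2], 70, 20, length=120, seed=3)
        im = pairwise_identity_matrix(msa)
        perm = rng.permutation(msa.n_sequences)
        shuffled = Msa(names=[msa.names[i] for i in perm],
                       rows=[msa.rows[i] for i in perm])
        im2 = pairwise_identity_matrix(shuffled)
        np.testing.assert_allclose(im2.values, im.values[np.ix_(perm, perm)],
                                   atol=1e-9)

    def test_reads_fasta_msa(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAC-DE\n>s2\nACQDE\n")
        m = read_msa(p)
        assert m.rows == ["AC-DE", "ACQDE"]


def _im(values):
    n = values.shape[0]
    return IdentityMatrix(labels=[f"s{i}" for i in range(n)], values=values)


def _random_identity_matrix(rng, n=8):
    v = rng.uniform(0, 100, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 100.0)
    return v


class TestClusters:
    def test_all_identical_single_cluster(self):
        v = np.full((5, 5), 100.0)
        cs = diagonal_square_clusters(_im(v), threshold=35)
        assert cs.clusters == [(0, 4)]

    def test_all_dissimilar_gives_singletons(self):
        v = np.zeros((4, 4))
        np.fill_diagonal(v, 100.0)
        cs = diagonal_square_clusters(_im(v), threshold=35)
        assert cs.clusters == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_two_block_matrix_recovered(self):
        v = np.full((6, 6), 10.0)
        v[:3, :3] = 50.0
        v[3:, 3:] = 60.0
        np.fill_diagonal(v, 100.0)
        for criterion in ("mean_offdiag", "min_pairwise"):
            cs = diagonal_square_clusters(_im(v), threshold=35, criterion=criterion)
            assert cs.clusters == [(0, 2), (3, 5)]
            assert cs.clusters == exhaustive_diagonal_clusters(v, 35, criterion)

    @pytest.mark.parametrize("criterion", ["mean_offdiag", "min_pairwise"])
    def test_matches_exhaustive_oracle_on_random_matrices(self, criterion):
        rng = np.random.default_rng(77)
        for _ in range(100):
            v = _random_identity_matrix(rng)
            got = diagonal_square_clusters(_im(v), threshold=35,
                                           criterion=criterion).clusters
            assert got == exhaustive_diagonal_clusters(v, 35, criterion)

    def test_block_msa_recovered_with_strict_criterion(self):
        msa, _ = synth.make_synthetic_msa([3, 3], 60, 10, seed=5)
        im = pairwise_identity_matrix(msa)
        cs = diagonal_square_clusters(im, threshold=35, criterion="min_pairwise")
        assert cs.clusters == [(0, 2), (3, 5)]

    def test_threshold_monotone_on_block_matrices(self):
        msa, _ = synth.make_synthetic_msa([3, 4, 2], 75, 20, seed=6)
        im = pairwise_identity_matrix(msa)
        prev = diagonal_square_clusters(im, threshold=30, criterion="min_pairwise")
        for thr in (45, 60, 90):
            cur = diagonal_square_clusters(im, threshold=thr, criterion="min_pairwise")
            # every current cluster fits inside one previous cluster
            for i, j in cur.clusters:
                assert any(a <= i and j <= b for a, b in prev.clusters)
            prev = cur


class TestAverageIdentity:
    def test_uniform_offdiagonals(self):
        v = np.full((3, 3), 40.0)
        np.fill_diagonal(v, 100.0)
        avg = average_identity(_im(v))
        np.testing.assert_allclose(avg.to_numpy(), 40.0)

    def test_outlier_is_argmin(self):
        v = np.array([[100.0, 10, 20], [10, 100, 80], [20, 80, 100]])
        avg = average_identity(_im(v))
        assert avg.idxmin() == "s0"
        assert avg["s0"] == pytest.approx(15.0)

    def test_matches_row_sum_oracle(self, rng):
        v = _random_identity_matrix(rng, 7)
        avg = average_identity(_im(v)).to_numpy()
        oracle = np.array([(v[i].sum() - 100.0) / 6 for i in range(7)])
        np.testing.assert_allclose(avg, oracle, atol=1e-9)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            average_identity(IdentityMatrix(labels=["x"], values=np.array([[100.0]])))


class TestDivergence:
    MSA = Msa(
        names=["q", "a", "b", "c"],
        rows=["ACDEF", "AKDGF", "AKDGF", "AKDWF"],
    )

    def test_identical_query_counts_zero(self):
        m = Msa(names=["q", "a", "b"], rows=["ACDEF"] * 3)
        rep = key_residue_divergence(m, positions=[0, 2, 4], query_label="q")
        assert rep.n_divergent == 0

    def test_constructed_mismatches_counted(self):
        # cols 1 and 3: query differs from a conserved majority (col 3 only
        # 2/3 -> below quorum 0.8, excluded); col 1 unanimous K vs query C.
        rep = key_residue_divergence(self.MSA, positions=[0, 1, 2, 3, 4],
                                     query_label="q")
        assert rep.flagged_positions == [1]
        assert rep.not_conserved == [3]
        assert rep.n_divergent == 1

    def test_quorum_relaxation_includes_column(self):
        rep = key_residue_divergence(self.MSA, positions=[3], query_label="q",
                                     conservation_quorum=0.5)
        assert rep.flagged_positions == [3]

    def test_out_of_range_position_rejected(self):
        with pytest.raises(IndexError):
            key_residue_divergence(self.MSA, positions=[99], query_label="q")


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln = global_align("ACDEFGHIKL", "ACDEFGHIKL")
        assert aln.percent_identity == pytest.approx(100.0)
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_score_matches_independent_dp_oracle(self):
        blosum = substitution_matrices.load("BLOSUM62")
        sub = {(a, b): float(blosum[a][b])
               for a in blosum.alphabet for b in blosum.alphabet}
        pairs = [("HEAGAWGHEE", "PAWHEAE"), ("MKTAYIAK", "MKTYIAK"),
                 ("GATTACA", "GCATGCG"), ("WWWW", "WAWDW")]
        for a, b in pairs:
            aln = global_align(a, b, gap_open=10, gap_extend=0.5)
            assert aln.score == pytest.approx(
                affine_global_score(a, b, sub, 10.0, 0.5), abs=1e-9
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=hst.text(alphabet="ACDEFGHIKL", min_size=1, max_size=12),
        b=hst.text(alphabet="ACDEFGHIKL", min_size=1, max_size=12),
    )
    def test_score_symmetric_and_identity_bounded(self, a, b):
        f = global_align(a, b)
        r = global_align(b, a)
        assert f.score == pytest.approx(r.score, abs=1e-9)
        assert 0.0 <= f.percent_identity <= 100.0

    def test_synthetic_ortholog_pair_identity_matches_construction(self):
        a, b, truth = synth.make_ortholog_pair(length=190,
                                               substitution_rate=0.05, seed=1)
        aln = global_align(a, b)
        assert aln.percent_identity == pytest.approx(truth["true_identity"], abs=0.5)
        assert aln.percent_identity >= 90.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")
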