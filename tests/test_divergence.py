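"""Alignment, identity matrices, divergence summaries and subfamilies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfd.divergence import (
    AlignmentPolicy,
    PairwiseAlignment,
    align_global,
    default_policy,
    group_subfamilies,
    pairwise_matrix,
    percent_identity,
    residue_change_map,
    residue_changes,
    summarize_divergence,
    vs_reference_values,
)
from conftest import make_gene
from oracles import brute_force_align_score

NT = default_policy("nt")
AA = default_policy("aa")


class TestAlignGlobal:
    def test_identity_alignment_no_gaps(self):
        aln = align_global("ACGT", "ACGT", NT)
        assert aln.aligned_a == aln.aligned_b == "ACGT"
        assert aln.score == 4 * 2.0

    def test_single_mismatch_no_gaps(self):
        # oracle: exhaustive enumeration agrees for length-4 inputs
        aln = align_global("ACGT", "ACGA", NT)
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == brute_force_align_score(
            "ACGT", "ACGA", NT.substitution, NT.gap_open, NT.gap_extend
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_global("A", "", NT)

    def test_gap_penalty_sign_enforced(self):
        with pytest.raises(ValueError):
            AlignmentPolicy("nt", (2, -3), gap_open=5.0, gap_extend=-1.0)

    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=6),
        b=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_matches_exhaustive_enumeration_nt(self, a, b):
        aln = align_global(a, b, NT)
        expected = brute_force_align_score(a, b, NT.substitution, NT.gap_open, NT.gap_extend)
        assert aln.score == pytest.approx(expected)

    @given(s=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_self_alignment_is_100_percent_identical(self, s):
        assert percent_identity(align_global(s, s, AA)) == 100.0


class TestPercentIdentity:
    def test_mismatch_fraction(self):
        aln = PairwiseAlignment("a", "b", "ACGT", "ACGA", 0.0, NT)
        assert percent_identity(aln) == 75.0

    def test_gap_column_excluded_by_default(self):
        aln = PairwiseAlignment("a", "b", "AC-T", "ACGT", 0.0, NT)
        assert percent_identity(aln) == 100.0

    def test_alignment_length_denominator(self):
        policy = AlignmentPolicy("nt", (2, -3), -5, -2, "alignment_length")
        aln = PairwiseAlignment("a", "b", "AC-T", "ACGT", 0.0, policy)
        assert percent_identity(aln) == pytest.approx(75.0)

    def test_ambiguity_never_matches(self):
        aln = PairwiseAlignment("a", "b", "ANGT", "ANGT", 0.0, NT)
        assert percent_identity(aln) == pytest.approx(75.0)

    def test_all_gap_columns_error(self):
        aln = PairwiseAlignment("a", "b", "A-", "-T", 0.0, NT)
        with pytest.raises(ValueError, match="denominator"):
            percent_identity(aln)


class TestPairwiseMatrix:
    def test_identical_proteins_zero_divergence(self):
        genes = [("p1", "MKV"), ("p2", "MKV"), ("p3", "MKV")]
        m = pairwise_matrix(genes, metric="aa_divergence")
        assert np.all(m.offdiag_counts() == 0)
        assert np.all(m.values == 0.0)

    def test_hand_counted_divergences(self):
        genes = [("p1", "MKV"), ("p2", "MKI"), ("p3", "MRI")]
        m = pairwise_matrix(genes, metric="aa_divergence")
        assert sorted(m.offdiag_counts()) == [1, 1, 2]

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="two genes"):
            pairwise_matrix([("p1", "MKV")])

    def test_symmetry_and_diagonal_identity_metric(self, rng):
        seqs = [
            ("g%d" % i, "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(5)
        ]
        m = pairwise_matrix(seqs, metric="nt_identity")
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)
        assert m.values.min() >= 0 and m.values.max() <= 100

    def test_tsv_round_trip(self, tmp_path, rng):
        seqs = [("g%d" % i, "".join(rng.choice(list("ACGT"), size=20))) for i in range(4)]
        m = pairwise_matrix(seqs, metric="nt_identity")
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        from gfd.divergence import IdentityMatrix

        m2 = IdentityMatrix.from_tsv(p)
        assert m2.gene_ids == m.gene_ids
        assert np.allclose(m2.values, m.values, atol=1e-6)

    def test_gene_model_protein_metric_requires_protein(self):
        g = make_gene("g1", 0, "ATGAAATAA")
        g2 = make_gene("g2", 100, "ATGAAATAA")
        m = pairwise_matrix([g, g2], metric="aa_identity")
        assert m.values[0, 1] == 100.0


class TestDivergenceMetricProperties:
    @given(
        seqs=st.lists(
            st.text(alphabet="ACDEFG", min_size=8, max_size=8), min_size=3, max_size=3
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_triangle_inequality_on_equal_length_sets(self, seqs):
        a, b, c = seqs

        def d(x, y):
            return residue_changes(align_global(x, y, AA))

        # Hamming-style counts on gap-free equal-length strings
        dab = sum(x != y for x, y in zip(a, b))
        dbc = sum(x != y for x, y in zip(b, c))
        dac = sum(x != y for x, y in zip(a, c))
        assert dac <= dab + dbc
        # alignment-based count can only be <= the gapless count
        assert d(a, c) <= dac


class TestSummaries:
    def test_all_zero(self):
        s = summarize_divergence([0, 0, 0])
        assert (s.median, s.lower_quartile, s.upper_quartile) == (0, 0, 0)

    def test_order_statistics_linear_interpolation(self):
        # oracle: numpy percentile with linear interpolation on {1,2,3,4}
        s = summarize_divergence([1, 2, 3, 4])
        assert s.median == 2.5
        assert s.lower_quartile == pytest.approx(1.75)
        assert s.upper_quartile == pytest.approx(3.25)

    def test_vs_reference_median(self):
        vals = vs_reference_values(
            [("g", "MKVL")], [("r1", "MKII"), ("r2", "MRII")], metric="aa_divergence"
        )
        # hand: MKVL vs MKII -> 2 diffs; vs MRII -> 3 diffs
        assert sorted(vals) == [2, 3]
        assert summarize_divergence(vals).median == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_divergence([])

    def test_vs_reference_invariant_to_order(self, rng):
        genes = [("g%d" % i, "".join(rng.choice(list("ACDEFGHIK"), 10))) for i in range(3)]
        refs = [("r%d" % i, "".join(rng.choice(list("ACDEFGHIK"), 10))) for i in range(2)]
        v1 = sorted(vs_reference_values(genes, refs))
        v2 = sorted(vs_reference_values(genes[::-1], refs[::-1]))
        assert v1 == v2


class TestSubfamilies:
    def _genes(self, proteins):
        out = []
        for i, p in enumerate(proteins):
            g = make_gene(f"g{i}", i * 100)
            g.protein_seq = p
            out.append(g)
        return out

    def test_exact_partition(self):
        subs = group_subfamilies(self._genes(["MKV", "MKV", "MKI"]))
        members = sorted(tuple(s.member_ids) for s in subs)
        assert members == [("g0", "g1"), ("g2",)]

    def test_all_unique(self):
        subs = group_subfamilies(self._genes(["MKV", "MKI", "MRI"]))
        assert len(subs) == 3 and all(len(s.member_ids) == 1 for s in subs)

    def test_n_diff_vs_reference(self):
        subs = group_subfamilies(self._genes(["MKI"]), reference_proteins=["MKV"])
        assert subs[0].n_diff_vs_reference == 1


class TestResidueChangeMap:
    def _subfamilies(self, proteins):
        return group_subfamilies(
            [
                g
                for i, p in enumerate(proteins)
                for g in [make_gene(f"g{i}", i * 100)]
                if not setattr(g, "protein_seq", p)
            ]
        )

    def test_no_changes_nothing_flagged(self):
        ref = "MKVLI"
        subs = self._subfamilies([ref, ref, ref])
        assert residue_change_map(subs, ref).flagged_positions == []

    def test_threshold_boundary(self):
        ref = "MKVLI"
        subs = self._subfamilies(["MKALI", "MKGLI", "MKWLI"])  # 3 subfamilies, pos 3
        m = residue_change_map(subs, ref, min_subfamilies=3)
        assert m.flagged_positions == [3]
        assert m.counts[2] == 3

    def test_below_threshold_not_flagged(self):
        ref = "MKVLI"
        subs = self._subfamilies(["MKALI", "MKGLI"])
        assert residue_change_map(subs, ref, min_subfamilies=3).flagged_positions == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            residue_change_map([], "MKV")
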