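"""Distances, NJ, pruning likelihood, monophyly and parsimony."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from gfd.cluster_synteny import ClusterAssignment
from gfd.core_io import read_newick
from gfd.phylo import (
    fitch_parsimony,
    intron_presence_matrix,
    is_monophyletic,
    jc69_distance,
    jc69_matrix,
    monophyly_comparison,
    neighbor_joining,
    optimize_branch_lengths,
    pruning_log_likelihood,
    random_topology,
    tree_newick,
)
from conftest import make_gene
from oracles import (
    brute_force_jc69_lnl,
    brute_force_parsimony,
    path_distance_matrix,
    random_binary_tree,
    splits_with_lengths,
)


def unrooted_tree(newick: str) -> dendropy.Tree:
    t = read_newick(newick).tree
    t.is_rooted = False
    return t


class TestJC69:
    def test_identical_is_zero(self):
        assert jc69_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        a = "A" * 80
        b = "C" * 3 + "A" * 77  # p = 3/80
        p = 3 / 80
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert jc69_distance(a, b) == pytest.approx(expected)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="0.75"):
            jc69_distance("AAAA", "CCCC")

    def test_gap_columns_excluded(self):
        assert jc69_distance("AC-T", "ACGT") == 0.0


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        tree = neighbor_joining(d)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self, rng):
        source = random_binary_tree(list("ABCD"), rng)
        d = path_distance_matrix(source)
        tree = neighbor_joining(d)
        assert splits_with_lengths(tree).keys() == splits_with_lengths(source).keys()

    def test_additive_recovery_5_to_8_leaves(self, rng):
        for trial in range(12):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            source = random_binary_tree(labels, rng)
            d = path_distance_matrix(source)
            tree = neighbor_joining(d)
            s_true = splits_with_lengths(source)
            s_est = splits_with_lengths(tree)
            assert s_est.keys() == s_true.keys()
            for k in s_true:
                assert s_est[k] == pytest.approx(s_true[k], abs=1e-8)

    def test_equal_distances_deterministic(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=list("ABCD"), columns=list("ABCD"))
        t1 = tree_newick(neighbor_joining(d))
        t2 = tree_newick(neighbor_joining(d))
        assert t1 == t2

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [3, 0, 1], [2, 1, 0]], index=list("ABC"),
                         columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)


class TestPruningLikelihood:
    def test_two_leaves_t0_single_site(self):
        tree = unrooted_tree("(A:0.0,B:0.0);")
        res = pruning_log_likelihood(tree, {"A": "A", "B": "A"})
        assert res.log_likelihood == pytest.approx(math.log(0.25))

    def test_stationary_limit(self):
        tree = unrooted_tree("((A:50,B:50):50,(C:50,D:50):50);")
        res = pruning_log_likelihood(tree, {"A": "A", "B": "C", "C": "G", "D": "T"})
        assert res.log_likelihood == pytest.approx(4 * math.log(0.25), abs=1e-6)

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 6))
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng, min_len=0.05, max_len=0.8)
            seqs = {
                lb: "".join(rng.choice(list("ACGT"), size=5)) for lb in labels
            }
            fast = pruning_log_likelihood(tree, seqs).log_likelihood
            slow = brute_force_jc69_lnl(tree, seqs)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_gaps_are_missing_data(self, rng):
        tree = random_binary_tree(list("ABCD"), rng)
        seqs = {"A": "AC-GT", "B": "ACNGT", "C": "ACGGT", "D": "ACTGT"}
        fast = pruning_log_likelihood(tree, seqs).log_likelihood
        slow = brute_force_jc69_lnl(tree, seqs)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_per_site_sums_to_total(self, rng):
        tree = random_binary_tree(list("ABCD"), rng)
        seqs = {lb: "".join(rng.choice(list("ACGT"), 8)) for lb in "ABCD"}
        res = pruning_log_likelihood(tree, seqs, per_site=True)
        assert res.per_site.sum() == pytest.approx(res.log_likelihood)

    def test_leaf_mismatch_rejected(self):
        tree = unrooted_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="mismatch"):
            pruning_log_likelihood(tree, {"A": "A", "B": "A", "X": "A"})

    def test_unequal_lengths_rejected(self):
        tree = unrooted_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="equal length"):
            pruning_log_likelihood(tree, {"A": "AC", "B": "A", "C": "AC"})


class TestMonophyly:
    def test_clan_queries(self):
        tree = unrooted_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})
        assert not is_monophyletic(tree, {"A", "C"})

    def test_complement_side_counts(self):
        tree = unrooted_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, {"A", "B", "C"})  # complement of {D}? no: {D} side
        assert is_monophyletic(tree, {"B", "C", "D"})

    def test_trivial_sets_rejected(self):
        tree = unrooted_tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            is_monophyletic(tree, set())
        with pytest.raises(ValueError):
            is_monophyletic(tree, {"A", "B", "C", "D"})


def _clusters(memberships):
    return [
        ClusterAssignment(f"c{i}", "sp", "chr1", list(m), (i * 1000, i * 1000 + 10))
        for i, m in enumerate(memberships)
    ]


class TestMonophylyComparison:
    def _identical_cluster_data(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=120))
        other = list(base)
        for i in rng.choice(120, size=40, replace=False):
            other[i] = rng.choice([b for b in "ACGT" if b != base[i]])
        other = "".join(other)
        seqs = {"a1": base, "a2": base, "b1": other, "b2": other}
        return seqs, _clusters([["a1", "a2"], ["b1", "b2"]])

    def test_identical_members_force_monophyly_and_zero_delta(self, rng):
        seqs, clusters = self._identical_cluster_data(rng)
        res = monophyly_comparison(seqs, clusters, n_random_starts=2, seed=4)
        assert all(res.per_clade_monophyletic.values())
        assert res.delta == 0.0
        assert res.unconstrained_lnL >= res.constrained_lnL

    def test_four_gene_delta_matches_topology_enumeration(self, rng):
        seqs, clusters = self._identical_cluster_data(rng)
        res = monophyly_comparison(seqs, clusters, n_random_starts=3, seed=9)
        # oracle: optimize branch lengths on all 3 unrooted 4-leaf topologies
        topologies = [
            "((a1:0.1,a2:0.1):0.1,(b1:0.1,b2:0.1):0.1);",
            "((a1:0.1,b1:0.1):0.1,(a2:0.1,b2:0.1):0.1);",
            "((a1:0.1,b2:0.1):0.1,(a2:0.1,b1:0.1):0.1);",
        ]
        lnls = []
        for nwk in topologies:
            t = unrooted_tree(nwk)
            lnls.append(optimize_branch_lengths(t, seqs))
        best_overall = max(lnls)
        best_constrained = lnls[0]
        assert res.constrained_lnL == pytest.approx(best_constrained, abs=1e-4)
        assert res.unconstrained_lnL == pytest.approx(best_overall, abs=1e-4)
        assert res.delta == pytest.approx(max(0.0, best_overall - best_constrained), abs=1e-3)

    def test_zero_random_starts_rejected(self, rng):
        seqs, clusters = self._identical_cluster_data(rng)
        with pytest.raises(ValueError):
            monophyly_comparison(seqs, clusters, n_random_starts=0)

    def test_small_cluster_skipped_with_warning(self, rng):
        seqs, clusters = self._identical_cluster_data(rng)
        seqs["x"] = seqs["a1"]
        clusters = clusters + _clusters([["x"]])
        with pytest.warns(UserWarning, match="skipped"):
            res = monophyly_comparison(seqs, clusters, n_random_starts=1, seed=0)
        assert set(res.clades_tested) == {"c0", "c1"}


class TestFitchParsimony:
    def test_uniform_state_no_changes(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        chars = pd.DataFrame({"i1": [1, 1, 1, 1]}, index=list("ABCD"))
        rec = fitch_parsimony(tree, chars)
        assert rec.min_changes == 0
        assert rec.root_states == [{1}]

    def test_alternating_pattern_needs_two_changes(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        chars = pd.DataFrame({"i1": [0, 1, 0, 1]}, index=list("ABCD"))
        assert fitch_parsimony(tree, chars).min_changes == 2

    def test_missing_leaf_state_takes_best_completion(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        chars = pd.DataFrame({"i1": [1, "?", 1, 1]}, index=list("ABCD"))
        rec = fitch_parsimony(tree, chars)
        oracle_min, oracle_root = brute_force_parsimony(
            tree.tree, {"A": 1, "B": "?", "C": 1, "D": 1}
        )
        assert rec.min_changes == oracle_min == 0
        assert rec.root_states[0] == oracle_root

    def test_matches_exhaustive_on_all_64_patterns(self):
        tree = read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        species = list("ABCDEF")
        for pattern in range(64):
            states = [(pattern >> i) & 1 for i in range(6)]
            chars = pd.DataFrame({"i1": states}, index=species)
            rec = fitch_parsimony(tree, chars)
            oracle_min, oracle_root = brute_force_parsimony(
                tree.tree, dict(zip(species, states))
            )
            assert rec.min_changes == oracle_min
            assert rec.root_states[0] == oracle_root

    def test_unknown_species_rejected(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        chars = pd.DataFrame({"i1": [1]}, index=["Z"])
        with pytest.raises(ValueError, match="absent"):
            fitch_parsimony(tree, chars)

    def test_ancestral_two_exon_state_recovered(self):
        """Species keeping the ancestral early intron on both sides of the
        root imply an ancestral two-exon gene; independent lineage losses do
        not pull the root state to intron-absent."""
        tree = read_newick("(((v1:1,v2:1):1,(v3:1,v4:1):1):1,(o1:1,o2:1):1);")
        chars = pd.DataFrame(
            {"intron_after_aa10": [1, 0, 1, 1, 1, 1]},
            index=["v1", "v2", "v3", "v4", "o1", "o2"],
        )
        rec = fitch_parsimony(tree, chars)
        assert rec.root_states == [{1}]
        assert rec.min_changes == 1


class TestIntronMatrix:
    def test_presence_union_over_copies(self):
        models = {
            "A": [make_gene("a1", 0, introns=[1]), make_gene("a2", 100)],
            "B": [make_gene("b1", 0, introns=[1, 2])],
        }
        df = intron_presence_matrix(models)
        assert list(df.columns) == ["intron_after_aa1", "intron_after_aa2"]
        assert df.loc["A"].tolist() == [1, 0]
        assert df.loc["B"].tolist() == [1, 1]
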