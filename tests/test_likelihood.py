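import numpy as np
import pytest

from famexpand.codon import (
    BranchSiteModel,
    CodonAlignment,
    CodonSubstModel,
    SiteClassModel,
    clean_alignment,
    log_likelihood,
)
from famexpand.codon.likelihood import TreeIndex, compress_patterns, mixture_log_likelihood
from famexpand.codon.models import BACKGROUND, FOREGROUND
from famexpand.family_data import FamilyDataError, read_newick

from .oracles import brute_force_loglik


class TestZeroTimeLimit:
    def test_identical_sequences_zero_lengths(self, uniform_pi):
        tree = read_newick("(a_MUSAC:0.0,b_ARATH:0.0);")
        aln = CodonAlignment(["a_MUSAC", "b_ARATH"], np.array([[5], [5]], dtype=np.int16))
        m = CodonSubstModel(2.0, 0.5, uniform_pi)
        assert log_likelihood(aln, tree, m) == pytest.approx(np.log(uniform_pi[5]), abs=1e-9)


class TestEnumerationOracle:
    def test_two_leaf_single_omega(self, uniform_pi):
        tree = read_newick("(a_MUSAC:0.15,b_ARATH:0.4);")
        rng = np.random.default_rng(0)
        aln = CodonAlignment(
            ["a_MUSAC", "b_ARATH"], rng.integers(0, 61, size=(2, 4)).astype(np.int16)
        )
        m = CodonSubstModel(2.0, 0.5, uniform_pi)
        ours = log_likelihood(aln, tree, m)
        oracle = brute_force_loglik(
            tree, aln, 2.0, uniform_pi, [1.0], [{BACKGROUND: 0.5}]
        )
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_three_leaf_nonuniform_pi(self, three_leaf_tree):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61) * 3)
        aln = CodonAlignment(
            ["a_MUSAC", "b_ARATH", "c_AMBTC"],
            rng.integers(0, 61, size=(3, 5)).astype(np.int16),
        )
        m = CodonSubstModel(3.0, 0.2, pi)
        ours = log_likelihood(aln, three_leaf_tree, m)
        oracle = brute_force_loglik(
            three_leaf_tree, aln, 3.0, pi, [1.0], [{BACKGROUND: 0.2}]
        )
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_three_leaf_site_mixture(self, three_leaf_tree, uniform_pi):
        rng = np.random.default_rng(2)
        aln = CodonAlignment(
            ["a_MUSAC", "b_ARATH", "c_AMBTC"],
            rng.integers(0, 61, size=(3, 3)).astype(np.int16),
        )
        model = SiteClassModel("M8", p0=0.8, p_beta=0.5, q_beta=1.5, omega_s=3.0, K=3)
        props, maps = model.classes()
        ours = log_likelihood(aln, three_leaf_tree, model, kappa=2.0, pi=uniform_pi)
        oracle = brute_force_loglik(three_leaf_tree, aln, 2.0, uniform_pi, props, maps)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_branch_site_partition_against_oracle(self, three_leaf_tree, uniform_pi):
        rng = np.random.default_rng(3)
        aln = CodonAlignment(
            ["a_MUSAC", "b_ARATH", "c_AMBTC"],
            rng.integers(0, 61, size=(3, 3)).astype(np.int16),
        )
        model = BranchSiteModel(p0=0.6, p1=0.25, omega0=0.15, omega2=4.0)
        props, maps = model.classes()
        ti = TreeIndex(three_leaf_tree, aln)
        # mark the branch above the (a, b) clade as foreground
        fg_node = [n for n in three_leaf_tree.preorder()
                   if not n.is_leaf and n.parent is not None][0]
        labels = [FOREGROUND if ti.nodes[i] is fg_node else BACKGROUND
                  for i in range(ti.n_nodes)]
        patterns, counts, _ = compress_patterns(aln)
        ours = mixture_log_likelihood(
            ti, patterns, counts, uniform_pi, 2.0, props, maps, labels=labels
        )
        oracle = brute_force_loglik(
            three_leaf_tree, aln, 2.0, uniform_pi, props, maps,
            labels_of=lambda n: FOREGROUND if n is fg_node else BACKGROUND,
        )
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_missing_data_marginalized(self, uniform_pi):
        tree = read_newick("(a_MUSAC:0.15,b_ARATH:0.4);")
        aln = CodonAlignment(
            ["a_MUSAC", "b_ARATH"], np.array([[5, -1], [7, 12]], dtype=np.int16)
        )
        m = CodonSubstModel(2.0, 0.5, uniform_pi)
        ours = log_likelihood(aln, tree, m)
        oracle = brute_force_loglik(tree, aln, 2.0, uniform_pi, [1.0], [{BACKGROUND: 0.5}])
        assert ours == pytest.approx(oracle, abs=1e-8)
        # a fully missing column contributes exactly zero log-likelihood
        aln_gap = CodonAlignment(
            ["a_MUSAC", "b_ARATH"], np.array([[5, -1], [7, -1]], dtype=np.int16)
        )
        aln_nogap = CodonAlignment(
            ["a_MUSAC", "b_ARATH"], np.array([[5], [7]], dtype=np.int16)
        )
        assert log_likelihood(aln_gap, tree, m) == pytest.approx(
            log_likelihood(aln_nogap, tree, m), abs=1e-10
        )


class TestReversibility:
    def test_rerooting_invariance(self, uniform_pi):
        # same unrooted tree, rooted on two different edges
        t1 = read_newick("((a_MUSAC:0.1,b_ARATH:0.2):0.05,c_AMBTC:0.3);")
        t2 = read_newick("(a_MUSAC:0.04,(b_ARATH:0.2,c_AMBTC:0.35):0.06);")
        rng = np.random.default_rng(4)
        aln = CodonAlignment(
            ["a_MUSAC", "b_ARATH", "c_AMBTC"],
            rng.integers(0, 61, size=(3, 20)).astype(np.int16),
        )
        m = CodonSubstModel(2.0, 0.5, uniform_pi)
        assert log_likelihood(aln, t1, m) == pytest.approx(
            log_likelihood(aln, t2, m), abs=1e-6
        )


class TestCleanAlignment:
    def test_identity_when_no_gaps(self):
        aln = CodonAlignment(["a", "b"], np.array([[1, 2], [3, 4]], dtype=np.int16))
        cleaned, colmap = clean_alignment(aln, 0.5)
        assert cleaned.n_codons == 2 and list(colmap) == [0, 1]

    def test_all_gap_column_removed_with_mapping(self):
        aln = CodonAlignment(
            ["a", "b"], np.array([[1, -1, 2], [3, -1, 4]], dtype=np.int16)
        )
        cleaned, colmap = clean_alignment(aln, 0.5)
        assert cleaned.n_codons == 2 and list(colmap) == [0, 2]

    def test_all_removed_is_error(self):
        aln = CodonAlignment(["a", "b"], np.array([[-1], [-1]], dtype=np.int16))
        with pytest.raises(FamilyDataError, match="gap fraction"):
            clean_alignment(aln, 0.5)

    def test_composed_mapping_reports_original_coordinates(self):
        aln = CodonAlignment(
            ["a", "b"],
            np.array([[1, -1, 2, 5, -1], [3, -1, 4, -1, -1]], dtype=np.int16),
        )
        cleaned, colmap = clean_alignment(aln, 0.4)
        # column k of cleaned data maps to original column colmap[k]
        for k, orig in enumerate(colmap):
            assert np.array_equal(cleaned.codons[:, k], aln.codons[:, orig])


class TestAlignmentValidation:
    def test_stop_codon_rejected(self):
        with pytest.raises(FamilyDataError, match="stop"):
            CodonAlignment.from_sequences([("a", "ATGTAA")])

    def test_ambiguity_is_missing(self):
        from famexpand.codon.genetic_code import CODON_INDEX

        aln = CodonAlignment.from_sequences([("a", "ATGNNN---")])
        assert list(aln.codons[0]) == [CODON_INDEX["ATG"], -1, -1]

    def test_taxa_tree_mismatch_is_error(self, uniform_pi):
        tree = read_newick("(a_MUSAC:0.1,b_ARATH:0.2);")
        aln = CodonAlignment(["a_MUSAC", "x_OTHER"], np.zeros((2, 1), dtype=np.int16))
        with pytest.raises(FamilyDataError):
            log_likelihood(aln, tree, CodonSubstModel(2.0, 0.5, uniform_pi))
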