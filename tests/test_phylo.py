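import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from oracles import random_additive_matrix
from sulfsig.conservation import Msa
from sulfsig.phylo import (
    PhyloError,
    _bipartitions,
    bootstrap_support,
    clade_membership,
    from_newick,
    neighbor_joining,
    p_distance_matrix,
    path_length_matrix,
    to_newick,
)
from sulfsig.synth import FamilySpec, generate_dataset


class TestPDistance:
    def test_identical_rows_are_zero(self):
        msa = Msa([("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")])
        assert np.allclose(p_distance_matrix(msa).data, 0.0)

    def test_single_mismatch(self):
        msa = Msa([("a", "MKV"), ("b", "MKL"), ("c", "MKV")])
        d = p_distance_matrix(msa)
        assert d["a", "b"] == pytest.approx(1 / 3)

    def test_pairwise_deletion_ignores_gapped_columns(self):
        msa = Msa([("a", "M-V"), ("b", "MKV"), ("c", "MKL")])
        d = p_distance_matrix(msa)
        assert d["a", "b"] == 0.0  # M/V match over the 2 shared columns

    def test_no_shared_columns_raises_naming_the_pair(self):
        msa = Msa([("a", "M--"), ("b", "-KV"), ("c", "MKV")])
        with pytest.raises(PhyloError, match="'a' and 'b'"):
            p_distance_matrix(msa)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float), list("abc"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 4.0}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        d = np.array([
            [0, 3, 6, 4],
            [3, 0, 7, 5],
            [6, 7, 0, 4],
            [4, 5, 4, 0],
        ], float)
        dm = DistanceMatrix(d, list("ABCD"))
        tree = neighbor_joining(dm)
        assert np.abs(path_length_matrix(tree, list("ABCD")).data - d).max() < 1e-9
        tips = frozenset("ABCD")
        assert _bipartitions(tree, tips) == {frozenset("AB")} or \
            _bipartitions(tree, tips) == {frozenset("CD")}

    def test_additive_matrices_reconstructed_to_machine_precision(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            labels, d = random_additive_matrix(rng, n)
            tree = neighbor_joining(DistanceMatrix(d, labels))
            err = np.abs(path_length_matrix(tree, labels).data - d).max()
            assert err < 1e-9

    def test_label_order_invariance_up_to_isomorphism(self):
        rng = np.random.default_rng(7)
        labels, d = random_additive_matrix(rng, 6)
        t1 = neighbor_joining(DistanceMatrix(d, labels))
        perm = rng.permutation(len(labels))
        d2 = d[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(d2, [labels[i] for i in perm]))
        tips = frozenset(labels)
        assert _bipartitions(t1, tips) == _bipartitions(t2, tips)

    def test_agrees_with_reference_nj_topology(self):
        rng = np.random.default_rng(99)
        labels, d = random_additive_matrix(rng, 7)
        dm = DistanceMatrix(d, labels)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        tips = frozenset(labels)
        assert _bipartitions(ours, tips) == _bipartitions(theirs, tips)

    def test_rejects_fewer_than_three_taxa(self):
        with pytest.raises(PhyloError):
            neighbor_joining(DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["a", "b"]))


class TestNewick:
    def test_round_trip_preserves_tree(self):
        rng = np.random.default_rng(5)
        labels, d = random_additive_matrix(rng, 6)
        tree = neighbor_joining(DistanceMatrix(d, labels))
        back = from_newick(to_newick(tree))
        tips = frozenset(labels)
        assert _bipartitions(back, tips) == _bipartitions(tree, tips)
        assert np.abs(path_length_matrix(back, labels).data -
                      path_length_matrix(tree, labels).data).max() < 1e-6

    def test_parse_four_leaves(self):
        tree = from_newick("(A:1,B:2,(C:3,D:1):1);")
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C", "D"]

    def test_labels_with_spaces_survive_round_trip(self):
        tree = from_newick("('taxon one':1,B:2,(C:3,D:1):1);")
        back = from_newick(to_newick(tree))
        assert "taxon one" in {t.name for t in back.tips()}

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(PhyloError):
            from_newick("((A:1,B:2;")


@pytest.fixture(scope="module")
def two_family_msa():
    specs = [
        FamilySpec(label="fam1", n_sequences=6, ancestor_length=120,
                   background_substitution=0.05, seed=1),
        FamilySpec(label="fam2", n_sequences=6, ancestor_length=120,
                   background_substitution=0.05, seed=2),
    ]
    seqs, _ = generate_dataset(specs, inter_family_divergence=0.6, seed=0)
    return Msa([(s.id, s.residues) for s in seqs])


class TestBootstrap:
    def test_deterministic_given_seed(self, two_family_msa):
        t1 = bootstrap_support(two_family_msa, 25, seed=11)
        t2 = bootstrap_support(two_family_msa, 25, seed=11)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
        assert s1 == s2

    def test_supports_bounded(self, two_family_msa):
        tree = bootstrap_support(two_family_msa, 25, seed=3)
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                assert 0.0 <= n.support <= 100.0

    def test_family_split_strongly_supported(self, two_family_msa):
        tree = bootstrap_support(two_family_msa, 100, seed=0)
        fam1 = frozenset(i for i in two_family_msa.ids if i.startswith("fam1"))
        tips = frozenset(two_family_msa.ids)
        support = None
        for n in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in n.tips())
            if side in (fam1, tips - fam1):
                support = n.support
        assert support is not None and support >= 95.0

    def test_doubling_replicates_changes_supports_little(self, two_family_msa):
        def support_map(n_reps, seed):
            tree = bootstrap_support(two_family_msa, n_reps, seed=seed)
            tips = frozenset(two_family_msa.ids)
            return {
                frozenset(t.name for t in n.tips()): n.support
                for n in tree.non_tips(include_self=False) if hasattr(n, "support")
            }

        s100 = support_map(100, 0)
        s200 = support_map(200, 0)
        fam1 = frozenset(i for i in two_family_msa.ids if i.startswith("fam1"))
        tips = frozenset(two_family_msa.ids)
        for key in (fam1, tips - fam1):
            if key in s100 and key in s200:
                assert abs(s100[key] - s200[key]) <= 5.0


@pytest.fixture()
def labeled_tree():
    return from_newick(
        "(((f1:0.01,f2:0.01):0.05,(f3:0.02,cand:0.0):0.04):0.4,"
        "(og1:0.05,og2:0.05):0.4,far:0.5);"
    )


class TestCladeMembership:

    def test_zero_distance_candidate_is_inside(self, labeled_tree):
        verdict = clade_membership(labeled_tree, ["f1", "f2", "f3"], ["og1", "og2"], "cand")
        assert verdict == "inside"

    def test_outgroup_leaf_is_outside(self, labeled_tree):
        verdict = clade_membership(labeled_tree, ["f1", "f2", "f3"], ["og2"], "og1")
        assert verdict == "outside"

    def test_invariant_under_newick_round_trip(self, labeled_tree):
        back = from_newick(to_newick(labeled_tree))
        for cand in ("cand", "far"):
            assert clade_membership(back, ["f1", "f2", "f3"], ["og1", "og2"], cand) == \
                clade_membership(labeled_tree, ["f1", "f2", "f3"], ["og1", "og2"], cand)

    def test_unknown_label_rejected(self, labeled_tree):
        with pytest.raises(PhyloError):
            clade_membership(labeled_tree, ["f1"], ["og1"], "missing")

    def test_non_monophyletic_outgroup_warns_and_proceeds(self, labeled_tree):
        with pytest.warns(UserWarning):
            clade_membership(labeled_tree, ["f1", "f2"], ["og1", "far"], "cand")
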