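import numpy as np
import pytest

from conftest import random_tree_and_matrix
from oracles import brute_force_fitch

from phylogem.core_io import ValidationError, parse_matrix, parse_newick
from phylogem.parsimony_core import (char_min_max, changes_to_tsv,
                                     classify_synapomorphies,
                                     edge_min_changes, fitch_length,
                                     optimize_states)
from phylogem.tree_search import root_with_outgroup


class TestFitchLength:
    def test_constant_character(self):
        m = parse_matrix("a\t0\nb\t0\nc\t0\nd\t0\n")
        t = parse_newick("((a,b),(c,d));")
        assert fitch_length(t, m).total_length == 0

    def test_quartet_one_vs_two_steps(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\n")
        good = parse_newick("((a,b),(c,d));")
        bad = parse_newick("((a,c),(b,d));")
        assert fitch_length(good, m).total_length == 1
        assert fitch_length(bad, m).total_length == 2
        # agree with exhaustive enumeration
        assert brute_force_fitch(good, m) == 1
        assert brute_force_fitch(bad, m) == 2

    def test_missing_leaf_named(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\n")
        t = parse_newick("((a,b),(c,zz));")
        with pytest.raises(ValidationError, match="zz"):
            fitch_length(t, m)

    def test_missing_data_any_state(self):
        m = parse_matrix("a\t0\nb\t?\nc\t1\nd\t-\n")
        t = parse_newick("((a,b),(c,d));")
        assert fitch_length(t, m).total_length == 1

    def test_polytomy_scored(self):
        m = parse_matrix("a\t0\nb\t1\nc\t2\nd\t0\n")
        t = parse_newick("(a,b,c,d);")
        assert fitch_length(t, m).total_length == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        tree, matrix = random_tree_and_matrix(rng, n, n_char=5,
                                              n_states=int(rng.integers(2, 5)),
                                              missing_prob=0.15)
        assert fitch_length(tree, matrix).total_length == \
            brute_force_fitch(tree, matrix)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(99)
        tree, matrix = random_tree_and_matrix(rng, 7, n_char=6, n_states=3)
        base = fitch_length(tree, matrix).total_length
        for leaf in tree.leaf_labels():
            assert fitch_length(root_with_outgroup(tree, leaf),
                                matrix).total_length == base


class TestIndices:
    def test_char_min_max_example(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\ne\t1\n")
        assert char_min_max(m, 0) == (1, 2)

    def test_single_variant_taxon(self):
        m = parse_matrix("a\t0\nb\t0\nc\t0\nd\t1\n")
        assert char_min_max(m, 0) == (1, 1)

    def test_constant(self):
        m = parse_matrix("a\t0\nb\t0\nc\t0\n")
        assert char_min_max(m, 0) == (0, 0)

    def test_ci_one_iff_minimal(self):
        m = parse_matrix("a\t01\nb\t01\nc\t10\nd\t10\n")
        t = parse_newick("((a,b),(c,d));")
        s = fitch_length(t, m)
        assert s.ensemble_ci == 1.0
        assert np.array_equal(s.per_char_length, s.per_char_min)

    def test_homoplasy_lowers_ci(self):
        clean = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\n")
        noisy = parse_matrix("a\t00\nb\t01\nc\t11\nd\t10\n")
        t = parse_newick("((a,b),(c,d));")
        assert fitch_length(t, noisy).ensemble_ci < \
            fitch_length(t, clean).ensemble_ci

    def test_invariant_identities(self):
        rng = np.random.default_rng(5)
        tree, matrix = random_tree_and_matrix(rng, 8, n_char=12, n_states=3)
        s = fitch_length(tree, matrix)
        assert s.total_length == int(s.per_char_length.sum())
        assert np.all(s.per_char_min <= s.per_char_length)
        assert np.all(s.per_char_length <= s.per_char_max)
        assert 0 < s.ensemble_ci <= 1
        assert 0 <= s.ensemble_ri <= 1


class TestOptimizeStates:
    def test_unambiguous_same_under_both(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\n")
        t = parse_newick("((a,b),(c,d));")
        ra = optimize_states(t, m, "ACCTRAN")
        rd = optimize_states(t, m, "DELTRAN")
        assert [(c.character, c.from_state, c.to_state) for c in ra.changes] == \
            [(c.character, c.from_state, c.to_state) for c in rd.changes]
        assert {id(c.node) for c in ra.changes} == {id(c.node) for c in rd.changes}

    def test_textbook_ambiguity(self):
        # outgroup 0; successive ingroup leaves 1, 0, 1 on a pectinate tree
        m = parse_matrix("o\t0\np\t1\nq\t0\nr\t1\n")
        t = parse_newick("(o,(p,(q,r)));")
        acc = optimize_states(t, m, "ACCTRAN")
        delt = optimize_states(t, m, "DELTRAN")
        acc_moves = sorted((c.from_state, c.to_state) for c in acc.changes)
        del_moves = sorted((c.from_state, c.to_state) for c in delt.changes)
        assert acc_moves == [(0, 1), (1, 0)]     # gain then secondary loss
        assert del_moves == [(0, 1), (0, 1)]     # two independent gains
        assert len(acc.changes) == len(delt.changes) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_equal_fitch_length(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree, matrix = random_tree_and_matrix(rng, 7, n_char=8, n_states=3,
                                              missing_prob=0.1)
        s = fitch_length(tree, matrix)
        for flavor in ("ACCTRAN", "DELTRAN"):
            rec = optimize_states(tree, matrix, flavor)
            assert np.array_equal(rec.changes_per_char(matrix.n_char),
                                  s.per_char_length)


class TestEdgeMinChanges:
    def test_forced_change(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\n")
        t = parse_newick("((a,b),(c,d));")
        emin = edge_min_changes(t, m)
        internal = [n for n in t.postorder()
                    if not n.is_leaf() and n is not t.root]
        assert sum(emin[n] for n in internal) >= 1

    def test_unsupported_edge_zero(self):
        # character is uninformative: the inner branch can always be change-free
        m = parse_matrix("a\t0\nb\t0\nc\t0\nd\t1\n")
        t = parse_newick("((a,b),(c,d));")
        emin = edge_min_changes(t, m)
        for n in t.postorder():
            if not n.is_leaf() and n is not t.root:
                assert emin[n] == 0


class TestSynapomorphies:
    def test_single_change_on_stem_is_exclusive(self):
        m = parse_matrix("o1\t0\no2\t0\nx\t1\ny\t1\n")
        t = parse_newick("((o1,o2),(x,y));")
        rec = optimize_states(t, m, "DELTRAN")
        out = classify_synapomorphies(t, m, rec, ["x", "y"])
        assert len(out["exclusive"]) == 1
        assert not out["homoplastic"]

    def test_homoplastic_stem_change(self):
        # state 1 arises on the (x,y) stem and again in the far leaf z
        m = parse_matrix("o1\t0\no2\t0\nz\t1\nx\t1\ny\t1\n")
        t = parse_newick("((o1,(o2,z)),(x,y));")
        rec = optimize_states(t, m, "DELTRAN")
        out = classify_synapomorphies(t, m, rec, ["x", "y"])
        assert len(out["homoplastic"]) == 1
        assert not out["exclusive"]

    def test_unknown_clade_errors(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\n")
        t = parse_newick("((a,b),(c,d));")
        rec = optimize_states(t, m)
        with pytest.raises(ValidationError):
            classify_synapomorphies(t, m, rec, ["a", "c"])

    def test_tsv_export(self):
        m = parse_matrix("a\t0\nb\t0\nc\t1\nd\t1\n")
        t = parse_newick("((a,b),(c,d));")
        rec = optimize_states(t, m)
        text = changes_to_tsv(t, m, rec)
        assert text.startswith("character\tbranch\t")
        assert "yes" in text
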